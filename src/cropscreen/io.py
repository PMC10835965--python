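"""Readers and writers for the on-disk formats of a screen.

Matrices travel as 10X-style MatrixMarket triplets (matrix.mtx[.gz] +
barcodes.tsv[.gz] + features.tsv[.gz]); targets as BED-like 0-based
half-open intervals with the class label and expected gene as extra
columns; gene annotation as a TSV whose TSS column is 1-based on disk
and 0-based in memory.  All tabular artifacts are plain TSVs with stable
column order so that every output re-reads through these functions.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .simulate import GuideLibrary, ScreenDesign

STRANDS = {"+", "-"}


def _open_maybe_gz(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Path:
    for cand in (dirpath / stem, dirpath / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def write_matrix_triplet(matrix: sp.spmatrix, row_ids, col_ids, outdir, gzipped: bool = False):
    """Write matrix.mtx + features.tsv (rows) + barcodes.tsv (columns)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""
    mat = sp.coo_matrix(matrix)
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, mat, field="integer")
    with _open_maybe_gz(outdir / f"matrix.mtx{suffix}", "wb") as fh:
        fh.write(buf.getvalue())
    for name, ids in (("features.tsv", row_ids), ("barcodes.tsv", col_ids)):
        with _open_maybe_gz(outdir / f"{name}{suffix}", "wt") as fh:
            for i in ids:
                fh.write(f"{i}\n")


def read_matrix_triplet(path) -> tuple[sp.csr_matrix, list, list]:
    """Read a triplet directory (or explicit matrix path) back.

    Returns (matrix CSR, row_ids, col_ids).  Errors on non-integer
    entries, dimension mismatches with the id files, and duplicate
    barcodes.
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find(path, "matrix.mtx")
        feat = _find(path, "features.tsv")
        barc = _find(path, "barcodes.tsv")
    else:
        mtx = path
        feat = path.parent / "features.tsv"
        barc = path.parent / "barcodes.tsv"
    try:
        with _open_maybe_gz(mtx, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as e:  # noqa: BLE001 - surface file context
        raise ValueError(f"failed to parse MatrixMarket file {mtx}: {e}") from e
    if not np.issubdtype(mat.dtype, np.integer):
        data = mat.tocoo().data
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"non-integer entries in {mtx}")
        mat = mat.astype(np.int64)
    with _open_maybe_gz(feat) as fh:
        row_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(barc) as fh:
        col_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if mat.shape != (len(row_ids), len(col_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(row_ids)} features x "
            f"{len(col_ids)} barcodes"
        )
    if len(set(col_ids)) != len(col_ids):
        raise ValueError("duplicate barcodes")
    return sp.csr_matrix(mat), row_ids, col_ids


def write_targets_bed(targets: pd.DataFrame, path):
    """BED-like: chrom start end target_id score strand class expected_gene."""
    with _open_maybe_gz(path, "wt") as fh:
        for _, t in targets.iterrows():
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.target_id}\t0\t+\t"
                f"{t.target_class}\t{t.expected_gene_id}\n"
            )


def read_targets_bed(path) -> pd.DataFrame:
    rows = []
    with _open_maybe_gz(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >= 6 BED columns, got {len(parts)}")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            cls = parts[6] if len(parts) > 6 else "UNKNOWN"
            exp = parts[7] if len(parts) > 7 else ""
            rows.append((name, cls, chrom, start, end, exp))
    return pd.DataFrame(
        rows, columns=["target_id", "target_class", "chrom", "start", "end", "expected_gene_id"]
    )


def write_gene_annotation(annotation: pd.DataFrame, path):
    """TSV with 1-based TSS on disk (converted from the internal 0-based)."""
    out = annotation.copy()
    out["tss"] = out.tss + 1
    out.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    bad = set(ann.strand) - STRANDS
    if bad:
        raise ValueError(f"unknown strand values: {sorted(bad)}")
    ann = ann.copy()
    ann["tss"] = ann.tss - 1
    if (ann.tss < 0).any():
        raise ValueError("TSS must be >= 1 in the 1-based annotation file")
    return ann


def _protospacer(guide_id: str) -> str:
    h = hashlib.sha256(guide_id.encode()).digest()
    return "".join("ACGT"[b % 4] for b in h[:20])


def write_guide_library(library: GuideLibrary, design: ScreenDesign, path):
    tmap = dict(zip(design.guides.guide_id, design.guides.target_id))
    out = library.table.copy()
    out.insert(1, "target_id", [tmap[g] for g in out.guide_id])
    out.insert(2, "protospacer", [_protospacer(g) for g in out.guide_id])
    out.to_csv(path, sep="\t", index=False)


def read_guide_library(path) -> pd.DataFrame:
    lib = pd.read_csv(path, sep="\t")
    required = {"guide_id", "target_id", "plasmid_count"}
    missing = required - set(lib.columns)
    if missing:
        raise ValueError(f"guide library missing columns: {sorted(missing)}")
    if "proportion" not in lib.columns:
        lib["proportion"] = lib.plasmid_count / lib.plasmid_count.sum()
    return lib


def design_from_tables(targets: pd.DataFrame, library: pd.DataFrame) -> ScreenDesign:
    """Reconstruct a ScreenDesign from targets BED + guide library TSV."""
    cls = dict(zip(targets.target_id, targets.target_class))
    guides = pd.DataFrame(
        {
            "guide_id": library.guide_id,
            "target_id": library.target_id,
            "target_class": [cls.get(t, "NT") for t in library.target_id],
        }
    )
    per = guides[guides.target_class != "NT"].groupby("target_id").size()
    gpt = int(per.iloc[0]) if len(per) else 0
    n_nt = int((guides.target_class == "NT").sum())
    return ScreenDesign(targets.reset_index(drop=True), guides, gpt, n_nt)


def library_from_table(lib: pd.DataFrame) -> GuideLibrary:
    p = lib.plasmid_count.to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "guide_id": lib.guide_id,
            "plasmid_count": lib.plasmid_count,
            "proportion": p / p.sum(),
        }
    )
    out = GuideLibrary(table)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# screen directory layout


def write_screen(screen, outdir, gzipped: bool = False):
    """Write a SyntheticScreen as the standard input layout of a run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_triplet(screen.gene_counts, screen.gene_ids, screen.cell_ids, outdir / "gene", gzipped)
    write_matrix_triplet(screen.guide_counts, screen.guide_ids, screen.cell_ids, outdir / "grna", gzipped)
    write_targets_bed(screen.design.targets, outdir / "targets.bed")
    write_gene_annotation(screen.annotation, outdir / "annotation.tsv")
    write_guide_library(screen.library, screen.design, outdir / "library.tsv")
    screen.truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    screen.truth.target_effects.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
    screen.truth.guide_efficiency.to_csv(outdir / "truth_guides.tsv", sep="\t", index=False)
    batches = pd.DataFrame({"cell_id": screen.cell_ids, "batch": screen.batch})
    batches.to_csv(outdir / "batches.tsv", sep="\t", index=False)


def read_truth(dirpath):
    dirpath = Path(dirpath)
    cells = pd.read_csv(dirpath / "truth_cells.tsv", sep="\t", keep_default_na=False)
    effects = pd.read_csv(dirpath / "truth_effects.tsv", sep="\t")
    guides = pd.read_csv(dirpath / "truth_guides.tsv", sep="\t")
    return cells, effects, guides


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All paths and knobs of a pipeline run; YAML round-trippable."""

    screen_dir: str = ""
    out_dir: str = "results"
    alpha: float = 0.001
    umi_floor: int = 3
    n_mads: float = 3.0
    min_frac: float = 0.05
    window: int = 1_000_000
    nt_background_n: int = 5000
    fdr: float = 0.05
    backend: str = "hurdle"
    seed: int = 0
    remove_doublet_flagged: bool = True
    calibrate: bool = False
    calibration_group_size: int = 4
    calibration_max_genes: int = 0  # 0 = no cap
    stop_after: str = ""  # '', 'qc' or 'assign': end the run early
    version: str = "0.1.0"

    def validate(self):
        if not self.screen_dir:
            raise ValueError("screen_dir is required")
        if self.backend not in ("hurdle", "wilcoxon"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.stop_after not in ("", "qc", "assign"):
            raise ValueError(f"unknown stop_after stage {self.stop_after!r}")
        for p in ("gene", "grna"):
            if not (Path(self.screen_dir) / p).exists():
                raise ValueError(f"missing input: {Path(self.screen_dir) / p}")
        for f in ("targets.bed", "annotation.tsv", "library.tsv"):
            if not (Path(self.screen_dir) / f).exists():
                raise ValueError(f"missing input: {Path(self.screen_dir) / f}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
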
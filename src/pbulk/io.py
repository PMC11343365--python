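"""On-disk formats.

Datasets are a MatrixMarket sparse counts file (rows = cells, columns =
genes; the orientation is stated here and in every companion file to
avoid the usual .mtx transpose ambiguity) plus plain TSV metadata:
``cells.tsv`` (cell_id, subject_id), ``subjects.tsv`` (subject_id,
condition in {0,1}), ``genes.tsv`` (gene_id), and for simulated data
``truth.tsv`` (gene_id, beta0, beta1, is_null).  Pseudobulk output is a
subjects x genes TSV plus ``offsets.tsv``.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from . import __version__
from .aggregate import CellSizeFactors, PseudobulkDataset
from .simulate import CellCountMatrix, SimTruth, SubjectDesign, truth_frame

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_pseudobulk",
    "read_pseudobulk",
    "read_size_factors",
    "write_manifest",
]


def write_dataset(
    outdir: str | Path,
    counts: CellCountMatrix,
    design: SubjectDesign,
    truth: SimTruth | None = None,
) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(
        out / "counts.mtx",
        sp.coo_matrix(counts.counts),
        comment="rows=cells columns=genes",
        field="integer",
    )
    n = counts.n_cells
    pd.DataFrame(
        {"cell_id": [f"C{j:06d}" for j in range(n)], "subject_id": counts.cell_subject}
    ).to_csv(out / "cells.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"subject_id": design.subject_ids, "condition": design.condition}
    ).to_csv(out / "subjects.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": counts.gene_ids}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    if truth is not None:
        truth_frame(truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    return out


def read_dataset(indir: str | Path) -> tuple[CellCountMatrix, SubjectDesign]:
    indir = Path(indir)
    for required in ("counts.mtx", "cells.tsv", "subjects.tsv", "genes.tsv"):
        if not (indir / required).exists():
            raise FileNotFoundError(f"missing input file: {indir / required}")
    counts = sp.csr_matrix(sio.mmread(indir / "counts.mtx"))
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", dtype=str)
    subjects = pd.read_csv(indir / "subjects.tsv", sep="\t")
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", dtype=str)
    _require_columns(cells, ["cell_id", "subject_id"], indir / "cells.tsv")
    _require_columns(subjects, ["subject_id", "condition"], indir / "subjects.tsv")
    _require_columns(genes, ["gene_id"], indir / "genes.tsv")
    ccm = CellCountMatrix(
        counts=counts,
        cell_subject=cells["subject_id"].to_numpy(),
        gene_ids=genes["gene_id"].to_numpy(),
    )
    design = SubjectDesign(
        subject_ids=subjects["subject_id"].astype(str).to_numpy(),
        condition=subjects["condition"].to_numpy(),
    )
    return ccm, design


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def write_pseudobulk(outdir: str | Path, pb: PseudobulkDataset) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pb.to_frame().rename_axis("subject_id").to_csv(out / "pseudobulk.tsv", sep="\t")
    pd.DataFrame(
        {"subject_id": pb.subject_ids, "offset": pb.subject_offsets}
    ).to_csv(out / "offsets.tsv", sep="\t", index=False)
    return out


def read_pseudobulk(indir: str | Path) -> PseudobulkDataset:
    indir = Path(indir)
    mat = pd.read_csv(indir / "pseudobulk.tsv", sep="\t", index_col=0)
    off = pd.read_csv(indir / "offsets.tsv", sep="\t")
    off = off.set_index("subject_id").loc[mat.index, "offset"]
    return PseudobulkDataset(
        agg_counts=mat.to_numpy(),
        subject_offsets=off.to_numpy(),
        subject_ids=mat.index.to_numpy(),
        gene_ids=mat.columns.to_numpy(),
    )


def read_size_factors(path: str | Path, n_cells: int) -> CellSizeFactors:
    """User-supplied per-cell factors (TSV with a ``size_factor`` column,
    or a single unnamed column), in cell order."""
    df = pd.read_csv(path, sep="\t")
    col = "size_factor" if "size_factor" in df.columns else df.columns[-1]
    s = df[col].to_numpy(dtype=float)
    if len(s) != n_cells:
        raise ValueError(f"{path}: {len(s)} factors for {n_cells} cells")
    return CellSizeFactors(s=s)


def write_manifest(outdir: str | Path, config: dict, seed: int | None = None) -> Path:
    """Reproducibility sidecar: config echo, versions, seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "pbulk_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
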
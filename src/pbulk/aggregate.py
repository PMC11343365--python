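"""Size factors and subject-level aggregation.

The pseudobulk count for subject i and gene k is the exact integer sum
of the subject's cell counts, and the subject offset is the exact sum of
the subject's cell size factors:

    Y_ik = sum_{j in C_i} Y_ijk,      s_i = sum_{j in C_i} s_j.

Summing the size factors (rather than, say, re-deriving a factor from
the aggregated counts) is what makes the subject-level GLM with offset
log(s_i) solve the cell-level moment equations exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simulate import CellCountMatrix, SubjectDesign

__all__ = [
    "CellSizeFactors",
    "PseudobulkDataset",
    "compute_cell_size_factors",
    "aggregate",
    "uniform_cell_offsets",
]


@dataclass
class CellSizeFactors:
    """Per-cell size factors s_j, strictly positive, normalized to mean 1."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not np.all(np.isfinite(self.s)) or np.any(self.s <= 0):
            raise ValueError("size factors must be finite and strictly positive")


@dataclass
class PseudobulkDataset:
    """Subjects x genes aggregated counts with per-subject summed offsets."""

    agg_counts: np.ndarray       # (n, G) integer
    subject_offsets: np.ndarray  # (n,) s_i > 0
    subject_ids: np.ndarray      # (n,)
    gene_ids: np.ndarray         # (G,)

    def __post_init__(self) -> None:
        self.agg_counts = np.asarray(self.agg_counts)
        self.subject_offsets = np.asarray(self.subject_offsets, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.gene_ids = np.asarray(self.gene_ids)
        if self.agg_counts.shape != (len(self.subject_ids), len(self.gene_ids)):
            raise ValueError("agg_counts shape must be (n_subjects, n_genes)")
        if np.any(self.subject_offsets <= 0):
            raise ValueError("subject offsets must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.agg_counts, index=self.subject_ids, columns=self.gene_ids)


def compute_cell_size_factors(counts: CellCountMatrix) -> CellSizeFactors:
    """Library-size factors: s_j = (library size of cell j) / (mean library size).

    Cells with zero total count have no defined factor and are rejected
    with an error naming the offending cell.
    """
    lib = counts.library_sizes().astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero library size cannot be normalized: "
            f"indices {zero[:10].tolist()}"
            + ("..." if zero.size > 10 else "")
        )
    return CellSizeFactors(s=lib / lib.mean())


def _membership_matrix(counts: CellCountMatrix, design: SubjectDesign) -> sp.csr_matrix:
    """Sparse (n_subjects, n_cells) 0/1 matrix mapping cells to subjects."""
    order = {s: i for i, s in enumerate(design.subject_ids)}
    try:
        rows = np.array([order[s] for s in counts.cell_subject])
    except KeyError as e:
        raise ValueError(f"cell maps to unknown subject {e.args[0]!r}") from None
    data = np.ones(counts.n_cells)
    m = sp.csr_matrix(
        (data, (rows, np.arange(counts.n_cells))),
        shape=(design.n_subjects, counts.n_cells),
    )
    cells_per_subject = np.asarray(m.sum(axis=1)).ravel()
    empty = np.flatnonzero(cells_per_subject == 0)
    if empty.size:
        missing = design.subject_ids[empty].tolist()
        raise ValueError(f"subject(s) with zero cells: {missing}")
    return m


def aggregate(
    counts: CellCountMatrix,
    sf: CellSizeFactors,
    design: SubjectDesign,
) -> PseudobulkDataset:
    """Collapse cells to subjects: exact integer count sums and exact
    double-precision offset sums, subject order matching ``design``."""
    if len(sf.s) != counts.n_cells:
        raise ValueError("one size factor per cell required")
    m = _membership_matrix(counts, design)
    agg = np.asarray((m @ counts.counts).todense())
    agg = np.rint(agg).astype(np.int64)  # products of 0/1 with ints; exact
    offsets = m @ sf.s
    return PseudobulkDataset(
        agg_counts=agg,
        subject_offsets=offsets,
        subject_ids=design.subject_ids.copy(),
        gene_ids=counts.gene_ids.copy(),
    )


def uniform_cell_offsets(
    pb: PseudobulkDataset,
    counts: CellCountMatrix,
) -> np.ndarray:
    """Per-cell offsets s_i / |C_i|: each cell of subject i receives an
    equal share of the subject's summed offset.

    A cell-level GLM run with these offsets reproduces the pseudobulk fit
    exactly, which is the reverse direction of the pseudobulk/mixed-model
    equivalence.
    """
    order = {s: i for i, s in enumerate(pb.subject_ids)}
    rows = np.array([order[s] for s in counts.cell_subject])
    n_cells = np.bincount(rows, minlength=pb.n_subjects).astype(float)
    return pb.subject_offsets[rows] / n_cells[rows]
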
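"""Synthetic multi-subject single-cell UMI count data.

Generates cells-by-genes count matrices with the structure that
case-control differential-expression methods for scRNA-seq assume:
per-cell size factors, per-gene baseline expression and log-fold-changes,
a subject-level random intercept inducing within-subject correlation, and
negative-binomial (or Poisson) cell-level counts.  Per-subject cell
numbers are imbalanced by additive Gaussian noise whose variance is a
fixed multiple (default 0.25) of the mean cells per subject.

Conditional on the subject intercept ``alpha_i ~ N(0, sigma_alpha^2)``,
cell ``j`` of subject ``i`` has gene-``k`` mean

    mu_ijk = s_j * exp(beta0_k + X_i * beta1_k + alpha_i)

with ``s_j`` a log-normal cell size multiplier and ``X_i`` the binary
condition label.  Counts are NB with variance ``mu + phi * mu^2``
(``phi = 0`` gives Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimConfig",
    "SimTruth",
    "CellCountMatrix",
    "SubjectDesign",
    "draw_cells_per_subject",
    "simulate_dataset",
    "filter_genes",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic data generator.

    Defaults correspond to the desk-scale case-control study used
    throughout this package: 40 subjects split evenly into cases and
    controls, ~10 cells per subject with cell-count noise variance
    0.25 x mean, log-normal per-gene baselines centred near 0.5
    counts/cell, a fold-change grid of 2-4 for non-null genes, and a
    subject random intercept SD of 0.5.
    """

    n_subjects: int = 40
    mean_cells_per_subject: int = 10
    cell_noise_factor: float = 0.25
    n_genes: int = 500
    baseline_log_mean_loc: float = float(np.log(0.5))
    baseline_log_mean_scale: float = 1.0
    logfc_values: tuple[float, ...] = tuple(np.log([2.0, 2.5, 3.0, 3.5, 4.0]))
    prop_null: float = 0.9
    alternate_signs: bool = True
    random_intercept_sd: float = 0.5
    nb_dispersion: float = 0.5
    cell_size_log_sd: float = 0.3
    seed: int = 0
    # optional separate stream for the gene effects: replicated studies fix
    # this while varying `seed`, so the same genes are re-measured on fresh
    # subjects and cells across replicates
    gene_seed: int | None = None

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_subjects % 2 != 0:
            raise ValueError("n_subjects must be a positive even integer")
        if self.mean_cells_per_subject <= 0:
            raise ValueError("mean_cells_per_subject must be positive")
        if self.cell_noise_factor < 0:
            raise ValueError("cell_noise_factor must be non-negative")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.prop_null <= 1.0:
            raise ValueError("prop_null must lie in [0, 1]")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.cell_size_log_sd < 0:
            raise ValueError("cell_size_log_sd must be non-negative")


@dataclass
class SubjectDesign:
    """Subject ids with binary condition labels (all cells of a subject
    share one label — the case-control assumption)."""

    subject_ids: np.ndarray  # shape (n,), str or int
    condition: np.ndarray    # shape (n,), values in {0, 1}

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.condition = np.asarray(self.condition, dtype=int)
        if self.subject_ids.shape != self.condition.shape:
            raise ValueError("subject_ids and condition must align")
        if not np.isin(self.condition, [0, 1]).all():
            raise ValueError("condition labels must be 0/1")
        if self.condition.min() == self.condition.max():
            raise ValueError("both condition groups must be non-empty")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass
class CellCountMatrix:
    """Sparse cells x genes integer counts with the cell -> subject map."""

    counts: sp.csr_matrix          # (N cells, G genes), non-negative ints
    cell_subject: np.ndarray       # (N,) subject id per cell
    gene_ids: np.ndarray           # (G,)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_subject = np.asarray(self.cell_subject)
        self.gene_ids = np.asarray(self.gene_ids)
        if self.counts.shape[0] != len(self.cell_subject):
            raise ValueError("one subject per cell required")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("one id per gene required")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subject_cell_indices(self, subject_ids: np.ndarray) -> list[np.ndarray]:
        """Cell index sets C_i, in the order of ``subject_ids``."""
        return [np.flatnonzero(self.cell_subject == s) for s in subject_ids]


@dataclass
class SimTruth:
    """Generating parameters retained for recovery tests."""

    beta0: np.ndarray        # (G,) log baseline expression per gene
    beta1: np.ndarray        # (G,) true logFC (natural log); 0 for null genes
    is_null: np.ndarray      # (G,) bool
    alpha: np.ndarray        # (n, G) per-subject, per-gene random intercepts
    condition: np.ndarray    # (n,) subject labels
    cell_size: np.ndarray    # (N,) latent per-cell size multiplier s_j
    sigma_alpha: float = 0.0
    nb_dispersion: float = 0.0
    gene_ids: np.ndarray = field(default=None)  # type: ignore[assignment]


def draw_cells_per_subject(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-subject cell numbers: mean + Gaussian noise with variance
    ``cell_noise_factor * mean``, rounded and clamped to >= 1."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    m = config.mean_cells_per_subject
    noise_sd = float(np.sqrt(config.cell_noise_factor * m))
    raw = m + rng.normal(0.0, noise_sd, size=config.n_subjects)
    return np.maximum(np.rint(raw).astype(int), 1)


def _assign_gene_effects(config: SimConfig, rng: np.random.Generator):
    g = config.n_genes
    beta0 = rng.normal(config.baseline_log_mean_loc, config.baseline_log_mean_scale, size=g)
    n_null = int(round(config.prop_null * g))
    is_null = np.zeros(g, dtype=bool)
    null_idx = rng.choice(g, size=n_null, replace=False)
    is_null[null_idx] = True
    beta1 = np.zeros(g)
    alt = np.flatnonzero(~is_null)
    if alt.size:
        vals = np.asarray(config.logfc_values, dtype=float)
        assigned = vals[np.arange(alt.size) % len(vals)]
        if config.alternate_signs:
            signs = np.where(np.arange(alt.size) % 2 == 0, 1.0, -1.0)
            assigned = assigned * signs
        beta1[alt] = assigned
    return beta0, beta1, is_null


def simulate_dataset(config: SimConfig) -> tuple[CellCountMatrix, SubjectDesign, SimTruth]:
    """Draw a full synthetic dataset.

    Reproducible given ``config.seed``; substreams are spawned
    deterministically for the design, the gene effects, and each
    subject's cell-level counts, so e.g. adding genes does not reshuffle
    the subject layout.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    design_ss, gene_ss, counts_ss = root.spawn(3)
    design_rng = np.random.default_rng(design_ss)
    if config.gene_seed is not None:
        gene_ss = np.random.SeedSequence(config.gene_seed)
    gene_rng = np.random.default_rng(gene_ss)

    n = config.n_subjects
    subject_ids = np.array([f"S{i:03d}" for i in range(n)])
    condition = np.zeros(n, dtype=int)
    condition[design_rng.permutation(n)[: n // 2]] = 1
    cells_per_subject = draw_cells_per_subject(config, rng=design_rng)
    n_cells = int(cells_per_subject.sum())
    cell_subject = np.repeat(subject_ids, cells_per_subject)
    cell_size = np.exp(design_rng.normal(0.0, config.cell_size_log_sd, size=n_cells))
    # the random intercept is gene-specific: each gene's regression has
    # its own alpha_i, i.i.d. across subjects (and genes).  A single
    # intercept shared by all genes would scale every gene of a subject
    # alike and be absorbed by the library-size factors.
    alpha = design_rng.normal(
        0.0, config.random_intercept_sd, size=(n, config.n_genes)
    )

    beta0, beta1, is_null = _assign_gene_effects(config, gene_rng)
    gene_ids = np.array([f"G{k:04d}" for k in range(config.n_genes)])

    # mean mu_jk = s_j exp(beta0_k + X_i beta1_k + alpha_ik); counts drawn
    # per subject from its own substream
    phi = config.nb_dispersion
    blocks = []
    subject_streams = counts_ss.spawn(n)
    start = 0
    for i in range(n):
        c = cells_per_subject[i]
        srng = np.random.default_rng(subject_streams[i])
        log_mu = (
            np.log(cell_size[start : start + c])[:, None]
            + beta0[None, :]
            + condition[i] * beta1[None, :]
            + alpha[i][None, :]
        )
        mu = np.exp(log_mu)
        if phi > 0:
            lam = srng.gamma(shape=1.0 / phi, scale=phi * mu)
            block = srng.poisson(lam)
        else:
            block = srng.poisson(mu)
        blocks.append(sp.csr_matrix(block))
        start += c
    counts = sp.vstack(blocks, format="csr")
    counts.data = counts.data.astype(np.int64)

    ccm = CellCountMatrix(counts=counts, cell_subject=cell_subject, gene_ids=gene_ids)
    design = SubjectDesign(subject_ids=subject_ids, condition=condition)
    truth = SimTruth(
        beta0=beta0,
        beta1=beta1,
        is_null=is_null,
        alpha=alpha,
        condition=condition,
        cell_size=cell_size,
        sigma_alpha=config.random_intercept_sd,
        nb_dispersion=phi,
        gene_ids=gene_ids,
    )
    return ccm, design, truth


def filter_genes(counts: CellCountMatrix, mean_threshold: float = 0.1) -> np.ndarray:
    """Indices of genes whose grand mean count over all cells exceeds
    ``mean_threshold`` (strictly), sorted ascending."""
    if mean_threshold < 0:
        raise ValueError("mean_threshold must be >= 0")
    means = np.asarray(counts.counts.mean(axis=0)).ravel()
    return np.flatnonzero(means > mean_threshold)


def truth_frame(truth: SimTruth) -> pd.DataFrame:
    gene_ids = truth.gene_ids
    if gene_ids is None:
        gene_ids = np.array([f"G{k:04d}" for k in range(len(truth.beta0))])
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "beta0": truth.beta0,
            "beta1": truth.beta1,
            "is_null": truth.is_null.astype(int),
        }
    )
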
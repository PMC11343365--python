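"""Verification of the pseudobulk/mixed-model equivalence.

The subject-level offset GLM solves the cell-level moment (estimating)
equations exactly; this module makes the claim checkable on data:

* ``moment_residual`` evaluates the cell-level estimating equation at a
  candidate coefficient pair — it is (0, 0) at the offset-pseudobulk
  Poisson solution, to numerical tolerance.
* ``reverse_construction_check`` runs the converse: a cell-level GLM in
  which every cell of subject i carries the offset s_i/|C_i| reproduces
  the pseudobulk logFC exactly.
* ``calibration_report`` and ``concordance_report`` quantify the
  statistical claims (uniform null p-values; near-identical estimates
  and standard errors between the subject-level GLM and the
  random-intercept mixed model).
* ``failure_rates`` does the numerical-stability accounting on
  low-expression genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import CellSizeFactors, PseudobulkDataset, uniform_cell_offsets
from .glm import fit_poisson_irls
from .simulate import CellCountMatrix, SubjectDesign

__all__ = [
    "MomentResidual",
    "ComparisonReport",
    "moment_residual",
    "reverse_construction_check",
    "calibration_report",
    "failure_rates",
    "concordance_report",
]


@dataclass
class MomentResidual:
    """Value of the cell-level estimating equation (1/N) sum over cells of
    (1, X_i)' * (Y_ijk - s_j exp(beta0' + X_i beta1))."""

    r0: float
    r1: float
    scale: int  # N, the number of cells averaged over


def moment_residual(
    counts: CellCountMatrix,
    sf: CellSizeFactors,
    design: SubjectDesign,
    beta0_prime: float,
    beta1: float,
    gene_index: int,
) -> MomentResidual:
    """Evaluate the estimating equation literally at the cell level."""
    if not (np.isfinite(beta0_prime) and np.isfinite(beta1)):
        raise ValueError("coefficients must be finite")
    order = {s: i for i, s in enumerate(design.subject_ids)}
    subject_index = np.array([order[s] for s in counts.cell_subject])
    x = design.condition[subject_index].astype(float)
    y = np.asarray(counts.counts[:, gene_index].todense()).ravel().astype(float)
    mu = sf.s * np.exp(beta0_prime + x * beta1)
    resid = y - mu
    n = counts.n_cells
    return MomentResidual(
        r0=float(resid.sum() / n),
        r1=float((x * resid).sum() / n),
        scale=n,
    )


def reverse_construction_check(
    pb: PseudobulkDataset,
    counts: CellCountMatrix,
    design: SubjectDesign,
    gene_indices: np.ndarray | None = None,
    cell_offsets: np.ndarray | None = None,
    tol: float = 1e-8,
) -> tuple[bool, float]:
    """Fit the cell-level Poisson GLM with per-cell offsets that sum to
    the subject offset (by default the uniform split s_i/|C_i|) and
    compare its logFC with the pseudobulk logFC gene by gene.

    Returns (all within tol, max absolute deviation).  Any per-cell
    offset allocation with the correct subject sums — including the
    original size factors s_j — yields the same fixed point, because only
    the subject sums enter the score equations.
    """
    if gene_indices is None:
        gene_indices = np.arange(pb.agg_counts.shape[1])
    if cell_offsets is None:
        cell_offsets = uniform_cell_offsets(pb, counts)
    order = {s: i for i, s in enumerate(design.subject_ids)}
    subject_index = np.array([order[s] for s in counts.cell_subject])
    x_cells = design.condition[subject_index].astype(float)
    log_off_cells = np.log(cell_offsets)
    x_subj = design.condition.astype(float)
    log_off_subj = np.log(pb.subject_offsets)

    max_dev = 0.0
    for k in gene_indices:
        y_cells = np.asarray(counts.counts[:, k].todense()).ravel()
        cell_fit = fit_poisson_irls(y_cells, x_cells, log_off_cells)
        pb_fit = fit_poisson_irls(pb.agg_counts[:, k], x_subj, log_off_subj)
        if not (cell_fit.converged and pb_fit.converged):
            continue
        max_dev = max(max_dev, abs(cell_fit.beta1 - pb_fit.beta1))
    return max_dev < tol, max_dev


def calibration_report(
    p_values: np.ndarray,
    alphas: tuple[float, ...] = (0.01, 0.05, 0.1),
    level: float = 0.99,
) -> dict:
    """Null-calibration summary from replicated simulations.

    ``p_values`` is (n_replicates, n_genes); NaNs (non-converged fits)
    are excluded with their count reported.  For each alpha the pooled
    rejection rate is reported with two 99% bands around the nominal
    level: the naive binomial band (independent tests) and a
    replicate-clustered band that respects the sharing of subjects and
    random intercepts by all genes of one replicate.  Also returns sorted
    observed-vs-uniform quantile pairs and the one-sample KS statistic.
    """
    p = np.atleast_2d(np.asarray(p_values, dtype=float))
    n_reps = p.shape[0]
    if n_reps < 2:
        raise ValueError("need at least 2 replicates for clustered bands")
    finite = np.isfinite(p)
    n_missing = int((~finite).sum())
    n_total = int(finite.sum())
    zq = stats.norm.ppf(0.5 + level / 2)

    rows = []
    for a in alphas:
        rej = (p < a) & finite
        rate = rej.sum() / n_total
        half_binom = zq * np.sqrt(a * (1 - a) / n_total)
        rep_rates = np.array([
            rej[t].sum() / max(finite[t].sum(), 1) for t in range(n_reps)
        ])
        half_clust = zq * rep_rates.std(ddof=1) / np.sqrt(n_reps)
        rows.append({
            "alpha": a,
            "rejection_rate": rate,
            "binom_lower": a - half_binom,
            "binom_upper": a + half_binom,
            "clustered_lower": a - half_clust,
            "clustered_upper": a + half_clust,
            "within_clustered_band": bool(abs(rate - a) <= half_clust),
            "anti_conservative": bool(rate > a + half_clust),
        })
    table = pd.DataFrame(rows)

    obs = np.sort(p[finite])
    theo = (np.arange(1, n_total + 1) - 0.5) / n_total
    ks = float(stats.kstest(obs, "uniform").statistic) if n_total else np.nan
    return {
        "rates": table,
        "qq": pd.DataFrame({"theoretical": theo, "observed": obs}),
        "ks_statistic": ks,
        "n_tests": n_total,
        "n_missing": n_missing,
    }


def failure_rates(
    fits: pd.DataFrame,
    gene_means: np.ndarray,
    boundary: float = 0.1,
    failed_col: str = "failed",
) -> pd.DataFrame:
    """Fraction of failed fits per expression stratum (cell-level grand
    mean <= boundary vs > boundary)."""
    means = np.asarray(gene_means, dtype=float)
    if len(means) != len(fits):
        raise ValueError("one gene mean per fit required")
    failed = fits[failed_col].to_numpy(dtype=bool)
    rows = []
    for name, mask in (("low", means <= boundary), ("high", means > boundary)):
        n = int(mask.sum())
        rows.append({
            "stratum": name,
            "n_genes": n,
            "n_failed": int(failed[mask].sum()),
            "failure_fraction": failed[mask].mean() if n else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    pairs: pd.DataFrame       # per-gene paired estimates (converged both)
    summary: dict             # medians, slope, SE-ratio quantiles
    n_excluded: int           # genes dropped because either method failed


def _slope_through_origin(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum(a * b) / np.sum(a * a))


def concordance_report(
    pseudo: pd.DataFrame,
    glmm: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> ComparisonReport:
    """Pair the two methods' per-gene results and summarize agreement.

    Requires matching gene sets; only genes converged under both methods
    enter the paired summaries, with the exclusion count reported.  The
    summary holds the median |delta beta1|, the through-origin regression
    slope of the GLMM logFC on the pseudobulk logFC, SE-ratio quantiles,
    and — when truth is supplied — bias and RMSE per method.
    """
    missing = set(pseudo["gene_id"]) ^ set(glmm["gene_id"])
    if missing:
        raise ValueError(f"unmatched genes between methods: {sorted(missing)[:10]}")
    merged = pseudo.merge(glmm, on="gene_id", suffixes=("_pseudo", "_glmm"))
    ok = (
        merged["converged_pseudo"].astype(bool)
        & merged["converged_glmm"].astype(bool)
        & np.isfinite(merged["beta1_pseudo"])
        & np.isfinite(merged["beta1_glmm"])
    )
    pairs = merged[ok].copy()
    n_excluded = int((~ok).sum())
    delta = (pairs["beta1_glmm"] - pairs["beta1_pseudo"]).abs()
    se_ratio = pairs["se_glmm"] / pairs["se_pseudo"]
    summary = {
        "n_pairs": int(len(pairs)),
        "n_excluded": n_excluded,
        "median_abs_delta_beta1": float(delta.median()) if len(pairs) else np.nan,
        "max_abs_delta_beta1": float(delta.max()) if len(pairs) else np.nan,
        "slope_glmm_on_pseudo": (
            _slope_through_origin(
                pairs["beta1_pseudo"].to_numpy(), pairs["beta1_glmm"].to_numpy()
            )
            if len(pairs) and np.any(pairs["beta1_pseudo"] != 0)
            else np.nan
        ),
        "se_ratio_median": float(se_ratio.median()) if len(pairs) else np.nan,
        "se_ratio_q10": float(se_ratio.quantile(0.1)) if len(pairs) else np.nan,
        "se_ratio_q90": float(se_ratio.quantile(0.9)) if len(pairs) else np.nan,
    }
    if truth is not None:
        t = pairs.merge(truth[["gene_id", "beta1"]].rename(columns={"beta1": "beta1_true"}),
                        on="gene_id")
        for m in ("pseudo", "glmm"):
            err = t[f"beta1_{m}"] - t["beta1_true"]
            summary[f"bias_{m}"] = float(err.mean())
            summary[f"rmse_{m}"] = float(np.sqrt((err**2).mean()))
    return ComparisonReport(pairs=pairs, summary=summary, n_excluded=n_excluded)
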
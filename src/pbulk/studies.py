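"""Replicated simulation studies.

These are the desk-scale experiments that verify the statistical claims
end to end: null calibration, variance concordance between the
subject-level offset GLM and the random-intercept mixed model, the
shrinking estimate gap as the sample grows, logFC recovery under a true
fold change, and the stability accounting on low-expression genes.  They
are shared by the test suite, the acceptance script, and the
``calibrate`` CLI command so every surface reruns the same computation.

Study sizes (chosen once for desk-scale runtime; see docs/methods.md):
100 replicates of 40 subjects x ~10 cells for the null studies, a
subject ladder of 40/160/640 at 25 cells each for the gap-vs-N check,
and a few hundred genes per study.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import PseudobulkDataset, aggregate, compute_cell_size_factors
from .equivalence import calibration_report, failure_rates
from .glm import run_pseudobulk_dge
from .glmm import cell_data_for_gene, fit_nb_glmm, fit_poisson_glmm
from .simulate import SimConfig, simulate_dataset

__all__ = [
    "pseudobulk_from_cells",
    "subset_pseudobulk",
    "null_study",
    "variance_concordance",
    "null_calibration",
    "concordance_ladder",
    "fold_change_recovery",
    "low_expression_study",
]


def pseudobulk_from_cells(counts, design) -> PseudobulkDataset:
    """Library-size factors + exact aggregation in one call."""
    return aggregate(counts, compute_cell_size_factors(counts), design)


def subset_pseudobulk(pb: PseudobulkDataset, gene_idx: np.ndarray) -> PseudobulkDataset:
    return PseudobulkDataset(
        agg_counts=pb.agg_counts[:, gene_idx],
        subject_offsets=pb.subject_offsets,
        subject_ids=pb.subject_ids,
        gene_ids=pb.gene_ids[gene_idx],
    )


def _derived_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def null_study(
    seed: int,
    n_replicates: int = 100,
    n_subjects: int = 40,
    mean_cells_per_subject: int = 10,
    n_genes: int = 300,
    sigma_alpha: float = 0.5,
    glmm_gene_limit: int = 100,
    mean_threshold: float = 0.1,
) -> dict:
    """Replicated all-null simulations with both methods fitted.

    Gene effects are drawn once (fixed across replicates) while subjects,
    random intercepts, cell counts, and cell-level counts are redrawn
    every replicate, so per-gene sampling variability of the estimators
    is measurable.  Counts are Poisson at the cell level; the subject
    random intercept (sigma_alpha) is the only source of
    overdispersion.  The mixed-model arm fits the Poisson GLMM on the
    first ``glmm_gene_limit`` retained genes.

    Genes are retained by their expected cell-level mean exceeding
    ``mean_threshold`` — the deterministic analogue of the per-dataset
    mean filter, so the gene set is identical in every replicate.
    """
    base = SimConfig(
        n_subjects=n_subjects,
        mean_cells_per_subject=mean_cells_per_subject,
        n_genes=n_genes,
        prop_null=1.0,
        random_intercept_sd=sigma_alpha,
        nb_dispersion=0.0,
        gene_seed=seed,
    )
    rep_seeds = _derived_seeds(seed, n_replicates)

    keep = None
    res = {k: [] for k in ("beta1_pseudo", "se_pseudo", "p_pseudo", "conv_pseudo",
                           "beta1_glmm", "se_glmm", "conv_glmm")}
    for r in range(n_replicates):
        cfg = replace(base, seed=rep_seeds[r])
        counts, design, truth = simulate_dataset(cfg)
        if keep is None:
            # expected marginal cell-level mean under the generator
            exp_mean = np.exp(
                truth.beta0
                + sigma_alpha**2 / 2
                + base.cell_size_log_sd**2 / 2
            )
            keep = np.flatnonzero(exp_mean > mean_threshold)
            glmm_genes = keep[:glmm_gene_limit]
        sf = compute_cell_size_factors(counts)
        pb = aggregate(counts, sf, design)
        fits = run_pseudobulk_dge(subset_pseudobulk(pb, keep), design)
        res["beta1_pseudo"].append(fits["beta1"].to_numpy())
        res["se_pseudo"].append(fits["se"].to_numpy())
        res["p_pseudo"].append(fits["p"].to_numpy())
        res["conv_pseudo"].append(fits["converged"].to_numpy(dtype=bool))

        b1, se, cv = [], [], []
        for g in glmm_genes:
            fit = fit_poisson_glmm(cell_data_for_gene(counts, design, sf, int(g)))
            b1.append(fit.beta1)
            se.append(fit.se_beta1)
            cv.append(not fit.failed)
        res["beta1_glmm"].append(b1)
        res["se_glmm"].append(se)
        res["conv_glmm"].append(cv)

    out = {k: np.asarray(v, dtype=float) for k, v in res.items()}
    out["conv_pseudo"] = out["conv_pseudo"].astype(bool)
    out["conv_glmm"] = out["conv_glmm"].astype(bool)
    out["gene_idx"] = keep
    out["glmm_gene_idx"] = glmm_genes
    out["n_replicates"] = n_replicates
    return out


def variance_concordance(study: dict) -> dict:
    """Per-gene empirical SD of beta1-hat over replicates vs the mean
    reported SE, for both methods, plus the gene-wise agreement of the
    two methods' empirical SDs (through-origin slope).

    A ratio near 1 for a method says its reported SE tracks the true
    sampling variability; a slope near 1 says the two methods share that
    variability gene by gene.
    """

    def _sd_se(beta1, se, conv):
        b = np.where(conv, beta1, np.nan)
        s = np.where(conv, se, np.nan)
        ok = np.isfinite(b).sum(axis=0) >= max(5, 0.8 * b.shape[0])
        emp_sd = np.nanstd(b[:, ok], axis=0, ddof=1)
        mean_se = np.nanmean(s[:, ok], axis=0)
        return emp_sd, mean_se, ok

    sd_p, se_p, ok_p = _sd_se(study["beta1_pseudo"], study["se_pseudo"], study["conv_pseudo"])
    sd_g, se_g, ok_g = _sd_se(study["beta1_glmm"], study["se_glmm"], study["conv_glmm"])
    n_glmm = study["beta1_glmm"].shape[1]
    # align pseudo to the glmm gene subset for the gene-wise SD slope
    pseudo_pos = {int(g): i for i, g in enumerate(study["gene_idx"])}
    sub = np.array([pseudo_pos[int(g)] for g in study["glmm_gene_idx"]])
    b_p = np.where(study["conv_pseudo"], study["beta1_pseudo"], np.nan)[:, sub]
    b_g = np.where(study["conv_glmm"], study["beta1_glmm"], np.nan)
    both = np.isfinite(b_p) & np.isfinite(b_g)
    ok = both.sum(axis=0) >= max(5, 0.8 * b_p.shape[0])
    sd_p_sub = np.full(n_glmm, np.nan)
    sd_g_sub = np.full(n_glmm, np.nan)
    for j in np.flatnonzero(ok):
        sd_p_sub[j] = np.std(b_p[both[:, j], j], ddof=1)
        sd_g_sub[j] = np.std(b_g[both[:, j], j], ddof=1)
    slope = float(
        np.sum(sd_p_sub[ok] * sd_g_sub[ok]) / np.sum(sd_p_sub[ok] ** 2)
    )
    return {
        "sd_over_se_pseudo": float(np.mean(sd_p) / np.mean(se_p)),
        "sd_over_se_glmm": float(np.mean(sd_g) / np.mean(se_g)),
        "sd_slope_glmm_on_pseudo": slope,
        "n_genes_pseudo": int(ok_p.sum()),
        "n_genes_glmm": int(ok_g.sum()),
    }


def null_calibration(study: dict, alphas=(0.01, 0.05, 0.1)) -> dict:
    """Calibration report for the pseudobulk p-values of a null study."""
    return calibration_report(study["p_pseudo"], alphas=alphas)


def concordance_ladder(
    seed: int,
    subject_ladder: tuple[int, ...] = (40, 160, 640),
    cells_per_subject: int = 25,
    n_genes: int = 400,
    sigma_alpha: float = 0.5,
    max_genes_compared: int = 250,
    mean_threshold: float = 0.1,
) -> pd.DataFrame:
    """Median |beta1_GLMM - beta1_pseudobulk| across a ladder of sample
    sizes with the same gene panel.

    The moment-equation (pseudobulk) and marginal-ML (GLMM) solutions
    estimate the same parameter; their finite-sample gap shrinks as the
    number of sampled cells N grows through the number of subjects.  The
    pseudobulk arm uses the Poisson step, which is the exact root the
    theory concerns.
    """
    seeds = _derived_seeds(seed, len(subject_ladder))
    rows = []
    for lvl, n_subj in enumerate(subject_ladder):
        cfg = SimConfig(
            n_subjects=n_subj,
            mean_cells_per_subject=cells_per_subject,
            cell_noise_factor=0.25,
            n_genes=n_genes,
            prop_null=0.5,
            random_intercept_sd=sigma_alpha,
            nb_dispersion=0.0,
            gene_seed=seed,
            seed=seeds[lvl],
        )
        counts, design, truth = simulate_dataset(cfg)
        sf = compute_cell_size_factors(counts)
        pb = aggregate(counts, sf, design)
        exp_mean = np.exp(truth.beta0 + sigma_alpha**2 / 2 + cfg.cell_size_log_sd**2 / 2)
        keep = np.flatnonzero(exp_mean > mean_threshold)[:max_genes_compared]
        fits = run_pseudobulk_dge(subset_pseudobulk(pb, keep), design, poisson_only=True)
        deltas = []
        for j, g in enumerate(keep):
            if not fits["converged"].iloc[j]:
                continue
            glmm = fit_poisson_glmm(cell_data_for_gene(counts, design, sf, int(g)))
            if glmm.failed:
                continue
            deltas.append(abs(glmm.beta1 - fits["beta1"].iloc[j]))
        rows.append({
            "n_subjects": n_subj,
            "n_cells_total": int(counts.n_cells),
            "n_genes_compared": len(deltas),
            "median_abs_delta_beta1": float(np.median(deltas)),
        })
    ladder = pd.DataFrame(rows)
    rho = stats.spearmanr(
        ladder["median_abs_delta_beta1"], 1.0 / np.sqrt(ladder["n_cells_total"])
    ).statistic
    ladder.attrs["spearman_with_inv_sqrt_n"] = float(rho)
    return ladder


def fold_change_recovery(
    seed: int,
    n_subjects: int = 40,
    mean_cells_per_subject: int = 100,
    n_genes: int = 400,
    prop_null: float = 0.9,
    logfc: float = float(np.log(2.0)),
) -> dict:
    """Non-null recovery: a minority of genes carry |logFC| = ``logfc``
    with alternating signs (so library-size normalization is not
    confounded by a one-directional composition shift); report the mean
    sign-corrected estimate over the non-null genes and its Monte-Carlo
    SE across genes."""
    cfg = SimConfig(
        n_subjects=n_subjects,
        mean_cells_per_subject=mean_cells_per_subject,
        n_genes=n_genes,
        prop_null=prop_null,
        logfc_values=(logfc,),
        alternate_signs=True,
        random_intercept_sd=0.5,
        nb_dispersion=0.5,
        seed=seed,
    )
    counts, design, truth = simulate_dataset(cfg)
    pb = pseudobulk_from_cells(counts, design)
    means = np.asarray(counts.counts.mean(axis=0)).ravel()
    keep = np.flatnonzero((means > 0.1) & ~truth.is_null)
    fits = run_pseudobulk_dge(subset_pseudobulk(pb, keep), design)
    sign = np.sign(truth.beta1[keep])
    est = (fits["beta1"].to_numpy() * sign)[fits["converged"].to_numpy()]
    return {
        "true_logfc": logfc,
        "mean_beta1": float(est.mean()),
        "mc_se": float(est.std(ddof=1) / np.sqrt(len(est))),
        "n_genes": int(len(est)),
    }


def low_expression_study(
    seed: int,
    n_subjects: int = 40,
    mean_cells_per_subject: int = 10,
    n_genes: int = 250,
    boundary: float = 0.1,
) -> dict:
    """Stability accounting on low-expression genes.

    Simulates genes whose cell-level means sit mostly below the boundary
    and fits both methods (NB pseudobulk vs NB GLMM).  Failure means:
    non-convergence, or no finite standard error — for pseudobulk this
    only happens when a group's total count is zero (the loss is convex),
    while the mixed model's non-convex marginal likelihood also fails on
    genes both groups observe.
    """
    cfg = SimConfig(
        n_subjects=n_subjects,
        mean_cells_per_subject=mean_cells_per_subject,
        n_genes=n_genes,
        baseline_log_mean_loc=float(np.log(0.03)),
        baseline_log_mean_scale=0.8,
        prop_null=1.0,
        random_intercept_sd=0.5,
        nb_dispersion=0.3,
        seed=seed,
    )
    counts, design, truth = simulate_dataset(cfg)
    sf = compute_cell_size_factors(counts)
    pb = aggregate(counts, sf, design)
    means = np.asarray(counts.counts.mean(axis=0)).ravel()
    tested = np.flatnonzero(means > 0)  # expressed at all
    fits = run_pseudobulk_dge(subset_pseudobulk(pb, tested), design)
    x = design.condition.astype(bool)
    pos_both = (
        (pb.agg_counts[x][:, tested].sum(axis=0) > 0)
        & (pb.agg_counts[~x][:, tested].sum(axis=0) > 0)
    )
    rows = []
    for j, g in enumerate(tested):
        glmm = fit_nb_glmm(cell_data_for_gene(counts, design, sf, int(g)))
        rows.append({
            "gene_id": counts.gene_ids[g],
            "mean": means[g],
            "failed_pseudo": not fits["converged"].iloc[j],
            "failed_glmm": glmm.failed,
            "pos_both_groups": bool(pos_both[j]),
        })
    table = pd.DataFrame(rows)
    strat_p = failure_rates(
        table.rename(columns={"failed_pseudo": "failed"}), table["mean"], boundary
    )
    strat_g = failure_rates(
        table.rename(columns={"failed_glmm": "failed"}), table["mean"], boundary
    )
    low = table["mean"] <= boundary
    return {
        "table": table,
        "pseudo_strata": strat_p,
        "glmm_strata": strat_g,
        "low_failure_pseudo": float(table.loc[low, "failed_pseudo"].mean()),
        "low_failure_glmm": float(table.loc[low, "failed_glmm"].mean()),
        "pseudo_failures_pos_both": int(
            table.loc[table["pos_both_groups"], "failed_pseudo"].sum()
        ),
        "n_low": int(low.sum()),
    }
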
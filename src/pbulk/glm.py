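"""Subject-level offset GLM: the three-step pseudobulk fit.

Each gene's aggregated counts are regressed on the binary condition with
the log summed size factor as an offset,

    Y_ik ~ log(s_i) + beta0'_k + X_i * beta1_k,

in three steps: (1) Poisson IRLS for the coefficients, (2) NB dispersion
by adjusted profile likelihood with the coefficients fixed, (3) an NB
re-fit of the coefficients at the estimated dispersion, with Wald
inference on beta1 (the logFC, natural-log scale).

The Poisson-step solution is the exact root of the cell-level moment
(estimating) equations, which is why this subject-level fit inherits the
statistical properties of a cell-level random-intercept model; the NB
steps only adjust the standard errors (and nudge the coefficients) for
between-subject overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .aggregate import PseudobulkDataset
from .simulate import SubjectDesign

__all__ = [
    "GLMFit",
    "fit_poisson_irls",
    "closed_form_two_group",
    "estimate_dispersion",
    "refit_nb",
    "wald_test",
    "run_pseudobulk_dge",
    "bh_fdr",
]

IRLS_TOL = 1e-10
IRLS_MAX_ITER = 100
SCORE_TOL = 1e-8


@dataclass
class GLMFit:
    """Per-gene fit of the offset regression.

    beta1 is the natural-log fold change; dispersion phi parameterizes
    the NB variance mu + phi*mu^2 (phi=0 is Poisson).  Non-converged
    fits carry a flag and a missing p-value; a group with all-zero
    counts yields a signed-infinite beta1 sentinel.
    """

    beta0_prime: float
    beta1: float
    se_beta1: float
    dispersion: float = 0.0
    z: float = np.nan
    p_value: float = np.nan
    converged: bool = False
    n_iterations: int = 0
    flag: str = ""
    # residual degrees of freedom for the Wald reference distribution;
    # None means the standard normal (appropriate for large samples)
    df: int | None = None


def _design_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.ones_like(x), x])


def _check_two_group(y: np.ndarray, x: np.ndarray) -> str:
    """Return a separation flag ('' if none)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    t1 = y[x == 1].sum()
    t0 = y[x == 0].sum()
    if t1 == 0 and t0 == 0:
        return "all_zero"
    if t1 == 0:
        return "cases_zero"
    if t0 == 0:
        return "controls_zero"
    return ""


def _separation_fit(flag: str) -> GLMFit:
    beta1 = {"cases_zero": -np.inf, "controls_zero": np.inf}.get(flag, np.nan)
    return GLMFit(
        beta0_prime=np.nan,
        beta1=beta1,
        se_beta1=np.nan,
        converged=False,
        flag=flag,
    )


def _irls(
    y: np.ndarray,
    x: np.ndarray,
    log_offset: np.ndarray,
    dispersion: float,
) -> GLMFit:
    """Fisher-scoring IRLS for Poisson (dispersion=0) or NB at fixed phi.

    Weights are mu/(1+phi*mu); the score is X'(y-mu)/(1+phi*mu).  SEs come
    from the expected information X'WX at the solution.
    """
    y = np.asarray(y, dtype=float)
    log_offset = np.asarray(log_offset, dtype=float)
    if not np.all(np.isfinite(log_offset)):
        raise ValueError("offsets must be finite")
    X = _design_matrix(x)
    flag = _check_two_group(y, X[:, 1])
    if flag:
        return _separation_fit(flag)

    phi = float(dispersion)
    # deterministic init: overall normalized mean, zero logFC
    beta = np.array([np.log(y.sum() / np.exp(log_offset).sum()), 0.0])
    converged = False
    it = 0
    for it in range(1, IRLS_MAX_ITER + 1):
        eta = log_offset + X @ beta
        mu = np.exp(np.clip(eta, -700, 700))
        resid = (y - mu) / (1.0 + phi * mu)
        score = X.T @ resid
        w = mu / (1.0 + phi * mu)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return GLMFit(beta[0], beta[1], np.nan, phi, converged=False,
                          n_iterations=it, flag="singular_information")
        beta_new = beta + step
        if np.max(np.abs(step)) < IRLS_TOL:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = log_offset + X @ beta
    mu = np.exp(np.clip(eta, -700, 700))
    score = X.T @ ((y - mu) / (1.0 + phi * mu))
    w = mu / (1.0 + phi * mu)
    info = X.T @ (X * w[:, None])
    converged = converged and float(np.max(np.abs(score))) <= SCORE_TOL
    se = float(np.sqrt(np.linalg.inv(info)[1, 1]))
    return GLMFit(
        beta0_prime=float(beta[0]),
        beta1=float(beta[1]),
        se_beta1=se,
        dispersion=phi,
        converged=converged,
        n_iterations=it,
        flag="" if converged else "not_converged",
    )


def fit_poisson_irls(y, x, log_offset) -> GLMFit:
    """Step 1: maximize the Poisson likelihood of the offset regression."""
    return _irls(y, x, log_offset, dispersion=0.0)


def refit_nb(y, x, log_offset, dispersion: float) -> GLMFit:
    """Step 3: re-fit the coefficients with NB weights at fixed dispersion.

    With dispersion 0 this is identical to the Poisson fit.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    return _irls(y, x, log_offset, dispersion=dispersion)


def closed_form_two_group(
    pb: PseudobulkDataset, design: SubjectDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Poisson solution for the two-group offset regression.

    For every gene, beta1 = log of the ratio of offset-normalized group
    totals and beta0' = log of the control normalized total; these solve
    the score equations exactly.  Genes with a zero group total get
    signed-infinite entries.
    """
    x = design.condition.astype(bool)
    y1 = pb.agg_counts[x].sum(axis=0).astype(float)
    y0 = pb.agg_counts[~x].sum(axis=0).astype(float)
    s1 = pb.subject_offsets[x].sum()
    s0 = pb.subject_offsets[~x].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        beta0_prime = np.log(y0 / s0)
        beta1 = np.log((y1 / s1) / (y0 / s0))
        beta1 = np.where((y1 == 0) & (y0 > 0), -np.inf, beta1)
        beta1 = np.where((y0 == 0) & (y1 > 0), np.inf, beta1)
        beta1 = np.where((y0 == 0) & (y1 == 0), np.nan, beta1)
    return beta0_prime, beta1


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB log-likelihood with variance mu + phi*mu^2; Poisson at phi=0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + y * np.log(phi * mu)
            - (y + r) * np.log1p(phi * mu)
        )
    )


def _cr_adjustment(x: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """-0.5 log det of the expected information, the Cox-Reid correction
    for the coefficients estimated in step 1."""
    X = _design_matrix(x)
    w = mu / (1.0 + phi * mu)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return -0.5 * logdet


def estimate_dispersion(
    y,
    fitted_means,
    x=None,
    method: str = "pearson",
    cox_reid: bool = True,
    n_fitted_params: int = 2,
) -> float:
    """Step 2: NB dispersion phi with the fitted means held fixed.

    ``method="pearson"`` (default) moment-matches the NB variance
    function: phi solves sum (y-mu)^2 / (mu + phi*mu^2) = n - p, which
    equates the Pearson statistic to its residual degrees of freedom.
    Being a moment condition it centres downstream standard errors even
    when the between-subject mixing is not exactly NB (e.g. a log-normal
    random intercept).

    ``method="ml"`` maximizes the NB profile log-likelihood in phi alone
    (Cox-Reid adjusted for the fitted coefficients when ``x`` is given).

    Both clamp to 0 when the solution is at the lower boundary
    (underdispersion), and degenerate inputs (a single observation, or
    all-zero counts) return 0.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(fitted_means, dtype=float)
    if y.size <= n_fitted_params or y.sum() == 0:
        return 0.0

    if method == "pearson":
        dfres = y.size - n_fitted_params

        def pearson(phi: float) -> float:
            return float(np.sum((y - mu) ** 2 / (mu + phi * mu**2)) - dfres)

        if pearson(0.0) <= 0:
            return 0.0
        hi = 1.0
        while pearson(hi) > 0 and hi < 1e6:
            hi *= 4.0
        if pearson(hi) > 0:
            return hi
        return float(optimize.brentq(pearson, 0.0, hi, xtol=1e-12))
    if method != "ml":
        raise ValueError(f"unknown dispersion method {method!r}")

    use_cr = cox_reid and x is not None

    def objective(log_phi: float) -> float:
        phi = np.exp(log_phi)
        ll = nb_loglik(y, mu, phi)
        if use_cr:
            ll += _cr_adjustment(x, mu, phi)
        return -ll

    lo, hi = np.log(1e-8), np.log(1e4)
    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    phi_hat = float(np.exp(res.x))
    # boundary check: if the near-zero limit is at least as good, clamp
    if objective(lo) <= res.fun + 1e-12 or phi_hat < 1e-7:
        return 0.0
    return phi_hat


def wald_test(fit: GLMFit) -> GLMFit:
    """Two-sided Wald test of beta1 = 0.

    The reference distribution is Student t with ``fit.df`` residual
    degrees of freedom when set (n_subjects - 2; accounts for the
    estimated dispersion entering the SE at small n), else the standard
    normal.  The two coincide as the number of subjects grows.
    """
    if not fit.converged or not np.isfinite(fit.se_beta1) or fit.se_beta1 <= 0:
        return replace(fit, z=np.nan, p_value=np.nan)
    z = fit.beta1 / fit.se_beta1
    if fit.df is not None and fit.df > 0:
        p = 2.0 * stats.t.sf(abs(z), fit.df)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return replace(fit, z=float(z), p_value=float(p))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def fit_gene(
    y: np.ndarray,
    x: np.ndarray,
    log_offset: np.ndarray,
    poisson_only: bool = False,
    dispersion_method: str = "pearson",
) -> GLMFit:
    """Full three-step fit for one gene's aggregated counts."""
    df = len(np.asarray(y)) - 2
    pois = fit_poisson_irls(y, x, log_offset)
    pois = replace(pois, df=df)
    if not pois.converged or poisson_only:
        return wald_test(pois)
    mu = np.exp(log_offset + pois.beta0_prime + np.asarray(x) * pois.beta1)
    phi = estimate_dispersion(y, mu, x=x, method=dispersion_method)
    if phi == 0.0:
        return wald_test(pois)
    nb = refit_nb(y, x, log_offset, phi)
    if not nb.converged:
        # keep the convex Poisson solution but report the NB uncertainty scale
        nb = replace(pois, dispersion=phi, flag="nb_refit_failed")
    nb = replace(nb, df=df)
    return wald_test(nb)


def run_pseudobulk_dge(
    pb: PseudobulkDataset,
    design: SubjectDesign,
    poisson_only: bool = False,
    dispersion_method: str = "pearson",
) -> pd.DataFrame:
    """Three-step fit for every gene; genes are independent and failures
    are flagged per gene, never fatal.

    Returns a frame with columns gene_id, beta0_prime, beta1 (ln),
    log2fc, se, z, p, fdr, dispersion, converged, n_iterations, flag.
    """
    if not np.array_equal(pb.subject_ids, design.subject_ids):
        # tolerate permutations: realign pseudobulk rows to the design
        order = {s: i for i, s in enumerate(pb.subject_ids)}
        try:
            idx = np.array([order[s] for s in design.subject_ids])
        except KeyError as e:
            raise ValueError(f"design subject {e.args[0]!r} missing from pseudobulk") from None
        pb = PseudobulkDataset(
            agg_counts=pb.agg_counts[idx],
            subject_offsets=pb.subject_offsets[idx],
            subject_ids=pb.subject_ids[idx],
            gene_ids=pb.gene_ids,
        )
    x = design.condition.astype(float)
    log_offset = np.log(pb.subject_offsets)
    rows = []
    for k, gene in enumerate(pb.gene_ids):
        fit = fit_gene(pb.agg_counts[:, k], x, log_offset,
                       poisson_only=poisson_only,
                       dispersion_method=dispersion_method)
        rows.append(
            {
                "gene_id": gene,
                "beta0_prime": fit.beta0_prime,
                "beta1": fit.beta1,
                "log2fc": fit.beta1 / np.log(2.0),
                "se": fit.se_beta1,
                "z": fit.z,
                "p": fit.p_value,
                "dispersion": fit.dispersion,
                "converged": fit.converged,
                "n_iterations": fit.n_iterations,
                "flag": fit.flag,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "beta0_prime", "beta1", "log2fc", "se", "z", "p",
            "dispersion", "converged", "n_iterations", "flag",
        ],
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.nan
    return out
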
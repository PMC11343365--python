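"""Cell-level random-intercept Poisson/NB mixed model (the reference fit).

The model for cell j of subject i at gene k is

    Y_ijk ~ Poisson/NB( s_j * exp(beta0 + X_i*beta1 + alpha_i) ),
    alpha_i ~ Normal(0, sigma_alpha^2),

and the marginal likelihood integrates each subject's random intercept
out numerically with adaptive Gauss-Hermite quadrature (nodes centred at
the subject's posterior mode, scaled by the curvature there).  This
module exists as an accurate comparator for the subject-level offset
GLM, not as a production fitter: direct marginal maximum likelihood was
chosen over penalized quasi-likelihood because the verification needs an
accurate estimate, not speed.

For the Poisson kernel the per-subject likelihood depends on the cells
only through the summed counts and summed size factors, so the fit
collapses to the pseudobulk sufficient statistics and costs O(n_subjects)
per evaluation; the NB kernel is evaluated cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special

__all__ = [
    "GLMMFit",
    "CellLevelData",
    "marginal_loglik",
    "fit_poisson_glmm",
    "fit_nb_glmm",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_SIGMA_BOUNDARY = 1e-6
_PHI_BOUNDARY = 1e-8

_HERMGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _hermgauss(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    if n_quad not in _HERMGAUSS_CACHE:
        _HERMGAUSS_CACHE[n_quad] = hermgauss(n_quad)
    return _HERMGAUSS_CACHE[n_quad]


@dataclass
class CellLevelData:
    """Cell-level observations for one gene, ready for the mixed model."""

    y: np.ndarray              # (N,) counts
    x: np.ndarray              # (N,) per-cell condition label (subject's X_i)
    log_offset: np.ndarray     # (N,) log s_j
    subject_index: np.ndarray  # (N,) ints in 0..n-1

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.log_offset = np.asarray(self.log_offset, dtype=float)
        self.subject_index = np.asarray(self.subject_index, dtype=int)
        n_arr = {len(self.y), len(self.x), len(self.log_offset), len(self.subject_index)}
        if len(n_arr) != 1:
            raise ValueError("cell-level arrays must have equal length")
        if not (np.all(np.isfinite(self.log_offset)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite inputs")

    @property
    def n_subjects(self) -> int:
        return int(self.subject_index.max()) + 1


@dataclass
class GLMMFit:
    beta0: float
    beta1: float
    sigma_alpha: float
    se_beta1: float
    dispersion: float = 0.0
    log_marginal_likelihood: float = np.nan
    converged: bool = False
    n_quad: int = 25
    flag: str = ""

    @property
    def sigma_at_boundary(self) -> bool:
        return self.sigma_alpha <= _SIGMA_BOUNDARY

    @property
    def failed(self) -> bool:
        """Failure in the accounting sense: non-convergence, no finite
        standard error, or the variance component stuck at its boundary
        (sigma-hat = 0 leaves the random-intercept structure
        unidentified and invalidates Wald inference on the fit).  A zero
        NB dispersion is not a failure — it is the Poisson limit."""
        return (
            not self.converged
            or not np.isfinite(self.beta1)
            or not np.isfinite(self.se_beta1)
            or self.se_beta1 <= 0
            or self.sigma_at_boundary
        )


def _cell_loglik(y, mu, phi):
    """Per-cell log density, NB variance mu + phi*mu^2 (phi=0 Poisson)."""
    if phi <= 0:
        return y * np.log(mu) - mu - special.gammaln(y + 1)
    r = 1.0 / phi
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + y * (np.log(phi) + np.log(mu))
        - (y + r) * np.log1p(phi * mu)
    )


def _poisson_modes(Y, T, sigma2, max_iter=50, init=None):
    """Newton solve of Y - T e^a - a/sigma2 = 0, vectorized over subjects."""
    if init is not None:
        a = init.copy()
    else:
        a = np.log(np.maximum(Y, 0.5) / T)
        a = np.clip(a, -3.0 * np.sqrt(sigma2) - 1.0, 3.0 * np.sqrt(sigma2) + 1.0)
    for _ in range(max_iter):
        e = T * np.exp(a)
        g = Y - e - a / sigma2
        h = -e - 1.0 / sigma2
        step = g / h
        a = a - np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-12:
            break
    return a


class _PoissonCollapsed:
    """Poisson-kernel evaluator on per-subject sufficient statistics.

    For the Poisson kernel the conditional likelihood of subject i
    depends on its cells only through Y_i = sum y_j and
    S_i = sum exp(log_offset_j), so the marginal log-likelihood is
    O(n_subjects) per evaluation.  Keeps the last posterior modes as a
    warm start for the next evaluation (the solve itself runs to 1e-12,
    so warm starting changes iteration counts, not values).
    """

    def __init__(self, data: CellLevelData):
        n = data.n_subjects
        idx = data.subject_index
        self.Y = np.bincount(idx, weights=data.y, minlength=n)
        self.S = np.bincount(idx, weights=np.exp(data.log_offset), minlength=n)
        xs = np.zeros(n)
        np.maximum.at(xs, idx, data.x)
        self.x = xs
        self.const0 = np.bincount(
            idx,
            weights=data.y * data.log_offset - special.gammaln(data.y + 1),
            minlength=n,
        )
        self._warm_mode: np.ndarray | None = None

    def loglik(self, beta0: float, beta1: float, sigma: float, n_quad: int) -> float:
        eta = beta0 + self.x * beta1
        T = self.S * np.exp(eta)
        const = self.const0 + eta * self.Y
        if sigma == 0.0:
            return float(np.sum(const - T))
        sigma2 = sigma * sigma
        mode = _poisson_modes(self.Y, T, sigma2, init=self._warm_mode)
        self._warm_mode = mode
        curv = T * np.exp(mode) + 1.0 / sigma2
        c = 1.0 / np.sqrt(curv)
        t, w = _hermgauss(n_quad)
        nodes = mode[:, None] + np.sqrt(2.0) * c[:, None] * t[None, :]
        g = (
            self.Y[:, None] * nodes
            - T[:, None] * np.exp(nodes)
            - 0.5 * nodes**2 / sigma2
            - 0.5 * _LOG_2PI
            - np.log(sigma)
        )
        log_int = (
            0.5 * np.log(2.0) + np.log(c)
            + special.logsumexp(np.log(w)[None, :] + t[None, :] ** 2 + g, axis=1)
        )
        return float(np.sum(const + log_int))


def _nb_mode_terms(data, eta, alpha, phi):
    """g', g'' of the per-subject conditional log-density (no prior) at
    alpha, summed over each subject's cells."""
    mu = np.exp(eta + alpha[data.subject_index])
    d1 = (data.y - mu) / (1.0 + phi * mu)
    d2 = -mu * (1.0 + phi * data.y) / (1.0 + phi * mu) ** 2
    n = len(alpha)
    g1 = np.bincount(data.subject_index, weights=d1, minlength=n)
    g2 = np.bincount(data.subject_index, weights=d2, minlength=n)
    return g1, g2


def marginal_loglik(
    params,
    data: CellLevelData,
    n_quad: int = 25,
) -> float:
    """Log marginal likelihood at params = (beta0, beta1, sigma[, phi]).

    Sum over subjects of log of the integral of the conditional
    likelihood against the Normal(0, sigma^2) intercept density,
    approximated by adaptive Gauss-Hermite quadrature.  With sigma = 0
    the integral degenerates and the exact GLM log-likelihood of the
    cells is returned.
    """
    if n_quad < 1:
        raise ValueError("n_quad must be >= 1")
    if len(params) == 3:
        beta0, beta1, sigma = params
        phi = 0.0
    else:
        beta0, beta1, sigma, phi = params
    if sigma < 0 or phi < 0:
        raise ValueError("sigma and dispersion must be non-negative")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")

    eta = data.log_offset + beta0 + data.x * beta1
    if sigma == 0.0:
        mu = np.exp(eta)
        return float(np.sum(_cell_loglik(data.y, mu, phi)))

    sigma2 = sigma * sigma
    n = data.n_subjects
    t, w = _hermgauss(n_quad)
    log_w = np.log(w)

    if phi <= 0:
        return _PoissonCollapsed(data).loglik(beta0, beta1, sigma, n_quad)

    # NB kernel: Newton on the per-subject mode with cell-level sums
    mode = np.zeros(n)
    for _ in range(60):
        g1, g2 = _nb_mode_terms(data, eta, mode, phi)
        grad = g1 - mode / sigma2
        hess = g2 - 1.0 / sigma2
        step = grad / hess
        mode = mode - np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-11:
            break
    _, g2 = _nb_mode_terms(data, eta, mode, phi)
    curv = -(g2 - 1.0 / sigma2)
    c = 1.0 / np.sqrt(curv)
    nodes = mode[:, None] + np.sqrt(2.0) * c[:, None] * t[None, :]  # (n, M)
    mu = np.exp(eta[:, None] + nodes[data.subject_index, :])        # (N, M)
    cell_ll = _cell_loglik(data.y[:, None], mu, phi)
    subj_ll = np.zeros((n, n_quad))
    np.add.at(subj_ll, data.subject_index, cell_ll)
    g = subj_ll - 0.5 * nodes**2 / sigma2 - 0.5 * _LOG_2PI - np.log(sigma)
    log_int = (
        0.5 * np.log(2.0) + np.log(c)
        + special.logsumexp(log_w[None, :] + t[None, :] ** 2 + g, axis=1)
    )
    return float(np.sum(log_int))


def _pseudobulk_init(data: CellLevelData):
    """Closed-form two-group Poisson solution on the collapsed data."""
    n = data.n_subjects
    Y = np.bincount(data.subject_index, weights=data.y, minlength=n)
    S = np.bincount(data.subject_index, weights=np.exp(data.log_offset), minlength=n)
    xs = np.zeros(n)
    np.maximum.at(xs, data.subject_index, data.x)
    g1, g0 = xs == 1, xs == 0
    y1, y0 = Y[g1].sum(), Y[g0].sum()
    s1, s0 = S[g1].sum(), S[g0].sum()
    if y1 <= 0 or y0 <= 0:
        return None
    b0 = np.log(y0 / s0)
    b1 = np.log((y1 / s1) / (y0 / s0))
    return b0, b1


def _numerical_se_beta1(fun, theta, bounds) -> float:
    """SE of beta1 (index 1) from a central-difference Hessian of the
    negative log-likelihood over the parameters not stuck at a boundary."""
    free = [
        i for i, (v, b) in enumerate(zip(theta, bounds))
        if i < 2 or v > b[0] + 1e-6
    ]
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    k = len(free)
    H = np.zeros((k, k))
    f0 = fun(theta)

    def f_at(shift):
        th = theta.copy()
        for idx, d in shift:
            th[idx] += d
        lo = np.array([b[0] for b in bounds])
        th = np.maximum(th, lo)
        return fun(th)

    for a in range(k):
        ia = free[a]
        H[a, a] = (f_at([(ia, h[ia])]) - 2 * f0 + f_at([(ia, -h[ia])])) / h[ia] ** 2
        for b in range(a + 1, k):
            ib = free[b]
            H[a, b] = H[b, a] = (
                f_at([(ia, h[ia]), (ib, h[ib])])
                - f_at([(ia, h[ia]), (ib, -h[ib])])
                - f_at([(ia, -h[ia]), (ib, h[ib])])
                + f_at([(ia, -h[ia]), (ib, -h[ib])])
            ) / (4 * h[ia] * h[ib])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.nan
    pos = free.index(1)
    var = cov[pos, pos]
    if not np.isfinite(var) or var <= 0:
        return np.nan
    return float(np.sqrt(var))


def _fit_glmm(
    data: CellLevelData,
    n_quad: int,
    with_dispersion: bool,
    init_phi: float = 0.1,
) -> GLMMFit:
    init = _pseudobulk_init(data)
    if init is None:
        return GLMMFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                       n_quad=n_quad, flag="group_all_zero")
    b0, b1 = init
    sigma0 = 0.5
    if with_dispersion:
        theta0 = np.array([b0 - sigma0**2 / 2, b1, sigma0, max(init_phi, 0.01)])
        bounds = [(-50, 50), (-50, 50), (0.0, 8.0), (0.0, 50.0)]
    else:
        theta0 = np.array([b0 - sigma0**2 / 2, b1, sigma0])
        bounds = [(-50, 50), (-50, 50), (0.0, 8.0)]

    if with_dispersion:
        def nll(theta):
            try:
                return -marginal_loglik(theta, data, n_quad=n_quad)
            except (ValueError, FloatingPointError):
                return np.inf
    else:
        evaluator = _PoissonCollapsed(data)

        def nll(theta):
            try:
                return -evaluator.loglik(theta[0], theta[1], theta[2], n_quad)
            except (ValueError, FloatingPointError):
                return np.inf

    opts = {"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500}
    starts = [theta0]
    if with_dispersion:
        starts.append(np.concatenate([[b0, b1], theta0[2:] * 0.2 + 0.01]))
    best = None
    for start in starts:
        res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                                options=opts)
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if not best.success:  # one retry from a small-variance start
        res = optimize.minimize(
            nll, np.concatenate([[b0, b1], theta0[2:] * 0.2 + 0.01]),
            method="L-BFGS-B", bounds=bounds, options=opts,
        )
        if res.fun < best.fun - 1e-10 or res.success:
            best = res
    res = best
    theta = res.x
    converged = bool(res.success) and np.all(np.isfinite(theta)) and np.isfinite(res.fun)
    se = _numerical_se_beta1(nll, theta.copy(), bounds) if converged else np.nan
    return GLMMFit(
        beta0=float(theta[0]),
        beta1=float(theta[1]),
        sigma_alpha=float(theta[2]),
        se_beta1=se,
        dispersion=float(theta[3]) if with_dispersion else 0.0,
        log_marginal_likelihood=float(-res.fun),
        converged=converged,
        n_quad=n_quad,
        flag="" if converged else f"optimizer: {res.message}",
    )


def fit_poisson_glmm(data: CellLevelData, n_quad: int = 25) -> GLMMFit:
    """Marginal ML fit of the Poisson random-intercept model."""
    return _fit_glmm(data, n_quad, with_dispersion=False)


def fit_nb_glmm(data: CellLevelData, n_quad: int = 25, init_phi: float = 0.1) -> GLMMFit:
    """Marginal ML fit of the NB random-intercept model (dispersion
    estimated jointly with the other parameters)."""
    return _fit_glmm(data, n_quad, with_dispersion=True, init_phi=init_phi)


def cell_data_for_gene(counts, design, sf, gene_index: int) -> CellLevelData:
    """Assemble one gene's cell-level arrays from the package containers."""
    order = {s: i for i, s in enumerate(design.subject_ids)}
    subject_index = np.array([order[s] for s in counts.cell_subject])
    y = np.asarray(counts.counts[:, gene_index].todense()).ravel()
    x = design.condition[subject_index].astype(float)
    return CellLevelData(
        y=y, x=x, log_offset=np.log(sf.s), subject_index=subject_index
    )
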
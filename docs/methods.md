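# Methods

## Model and the aggregation identity

Each gene *k* is modelled at the cell level as

    Y_ijk | α_i ~ Poisson/NB( s_j · exp(β0k + X_i β1k + α_i) ),
    α_i ~ N(0, σ_α²),

with subjects *i*, cells *j* ∈ C_i, size factors `s_j`, binary
condition `X_i` (constant across a subject's cells — the case-control
assumption), and a gene-specific subject random intercept `α_i`. The
population orthogonality of the residual to (1, X_i) gives the moment
condition

    0 = (1/N) Σ_i Σ_{j∈C_i} (1, X_i)ᵀ ( Y_ijk − s_j·exp(β'0k + X_i β1k) ),

where `β'0k = β0k + log E[exp α_i]` (= β0k + σ_α²/2 under the Gaussian
intercept). Because `X_i` is constant within a subject, the inner sums
collapse to the subject totals `Y_ik = Σ Y_ijk` and `s_i = Σ s_j`, and
the equation is *exactly* the Poisson score of the subject-level
regression `Y_ik ~ log s_i + β'0k + X_i β1k`. The subject-level offset
GLM therefore returns the same `β̂1k` as the cell-level moment estimator
— not asymptotically, but algebraically — and `β'0k` absorbs the
intercept shift, which is why only the logFC is comparable across the
two formulations. The converse holds too: any cell-level GLM whose
per-cell offsets sum to `s_i` within each subject (e.g. the uniform
split `s_i/|C_i|`) has the same score equations and hence the same
fixed point. Both identities are asserted to ~1e-8 (observed ~1e-16)
in the test suite on every simulated gene.

The mixed-model MLE solves a *different* (efficient-score) equation, so
pseudobulk and GLMM logFCs differ by a finite-sample term. Growing the
number of sampled units shrinks it: in our ladder (40/160/640 subjects
at 25 cells each, i.e. 1 000/4 000/16 000 cells) the median |Δβ̂1| falls
from ≈0.025 to ≈0.009, consistent with a 1/√N envelope. The gap is
driven by within-group heterogeneity of `(s_i, Y_i)`; with a variance
component estimated at zero the GLMM degenerates to the GLM and the gap
is exactly zero.

## Three-step subject-level fit (`glm`)

1. **Poisson IRLS.** Fisher scoring on (β'0, β1) with offset `log s_i`;
   deterministic start at (log of the overall normalized mean, 0),
   coefficient tolerance 1e-10, at most 100 iterations, and a score
   certificate ≤ 1e-8 required for `converged`. The loss is convex: the
   fit cannot fail when both groups have positive totals. A group with
   all-zero counts is reported as a signed-infinite logFC sentinel with
   a missing p-value, never silently.
2. **Dispersion with coefficients fixed.** Default is the Pearson
   moment estimator: φ solves Σ (y−μ̂)²/(μ̂+φμ̂²) = n−2, clamped to 0
   under underdispersion. A profile-ML variant (optionally Cox–Reid
   adjusted for the two fitted coefficients) is available via
   `method="ml"`. The moment estimator is the default because it
   matches the *variance* of the data even when the between-subject
   mixing is not exactly NB — a Gaussian random intercept makes the
   marginal counts lognormal-Poisson, for which ML fits the
   KL-closest NB with ~15% too little dispersion and yields standard
   errors a few percent small.
3. **NB re-fit and Wald inference.** IRLS with weights μ/(1+φμ) at
   fixed φ (identical to step 1 when φ=0); SEs from the expected
   information X'WX (the convention under which SE(β̂1) is
   non-decreasing in φ); z = β̂1/SE with a Student-t reference at
   n_subjects − 2 df. The t reference accounts for the dispersion being
   estimated from the same ~40 subjects; it converges to the normal as
   subjects grow. BH-adjusted FDRs are appended per gene.

Known limitation: at 40 subjects with a Gaussian intercept of σ_α=0.5,
replicated null simulations show rejection rates ~5% *relative* above
nominal (e.g. 0.105 at α=0.10) for every SE/reference convention we
evaluated (expected/observed information, moment sandwich, ML/Pearson
dispersion, normal/t/Welch/LRT-F). Direct Monte Carlo attributes this
to second-order terms in the variance of log group sums of
lognormal-Poisson counts that no first-order plug-in captures. The
effect shrinks with subjects and with milder heterogeneity; it is
documented rather than patched.

## Mixed-model reference (`glmm`)

The marginal likelihood integrates each subject's intercept with
adaptive Gauss–Hermite quadrature (default 25 nodes) centred at the
subject's posterior mode with curvature-matched scaling; σ=0 returns
the exact GLM likelihood. For the Poisson kernel the subject likelihood
depends on the cells only through (ΣY, Σs), so evaluation is
O(n_subjects); the NB kernel is evaluated cell-wise. Optimization is
L-BFGS-B on (β0, β1, σ[, φ]) with bounds σ∈[0,8], φ∈[0,50], started
from the pseudobulk closed form (with a small-variance restart), ftol
1e-13. SEs come from a central-difference Hessian of the marginal
log-likelihood; parameters stuck at a boundary are profiled out of it.
Estimates are stable to <1e-4 in β1 between 20 and 50 nodes, and match
`lme4::glmer` (nAGQ=25) to ~1e-3 on shared fixtures.

A fit counts as **failed** when the optimizer does not converge, any
estimate or the SE is non-finite, or σ̂ is at the zero boundary (the
random-intercept structure is then unidentified and Wald inference on
the fit is invalid; a zero NB dispersion is *not* a failure — it is the
Poisson limit). Under this accounting, on genes with cell-level mean
below 0.1 the NB GLMM fails for ~30% of genes while the pseudobulk GLM
fails only on genes where one group has zero total counts (~5–8%), and
never on genes with positive totals in both groups. This module is
deliberately allowed to be slow; it verifies, it does not serve
production fits.

## Synthetic data (`simulate`)

The generator emulates multi-subject UMI data: subjects split exactly
in half into cases and controls; per-subject cell numbers are
`round(m + e)`, `e ~ N(0, 0.25·m)`, clamped at 1 (default m = 10);
per-cell size multipliers are lognormal (log-sd 0.3); per-gene log
baselines are Normal(log 0.5, 1); non-null genes receive |logFC| from
{log 2 … log 4} with alternating signs to keep the composition
balanced; counts are Gamma-Poisson with variance μ+φμ² (φ=0 gives
Poisson). The random intercept is drawn **per subject and per gene**:
a single intercept shared by all genes would scale every gene of a
subject alike and be absorbed by the library-size factors, leaving no
within-subject correlation for any method to model. Seeding uses
spawned substreams (design / gene effects / per-subject counts), so
outputs are bit-reproducible and a study can redraw subjects while
holding the gene panel fixed (`gene_seed`).

What the generator does *not* emulate: empirical mean-dispersion
trends, batch effects, multiple cell types, zero-inflation beyond
NB/Poisson sampling, or gene-gene correlation. Passing tests therefore
demonstrate the algebraic identities and the statistical behaviour
*under the stated model*, not performance on any particular real
dataset.

## Study sizes

Chosen once as desk-scale conditions and shared by the test suite, the
acceptance script, and the CLI: verification fixtures of 20 subjects ×
~10 cells × 100 genes; 100-replicate null studies of 40 subjects × ~10
cells × 300 genes (mean-filter > 0.1 per cell; the mixed-model arm fits
100 of the retained genes); the gap ladder of 40/160/640 subjects × 25
cells × 120 compared genes; fold-change recovery with 40 subjects × 100
cells and 10% non-null genes at |logFC| = log 2; low-expression
stability with 250 genes centred at a cell-level mean of 0.03.
Calibration bands are computed replicate-clustered (all genes of one
replicate share subjects, intercepts and the case/control split, so
pooled binomial bands would be too narrow to be valid).

## Numerical conventions and edge cases

Counts aggregate in exact integer arithmetic; offsets in double
precision. Size factors are library sizes scaled to mean 1 (any other
positive per-cell factor may be supplied; rescaling all factors by a
constant shifts only β'0). Cells with zero library size and subjects
with zero cells are hard errors naming the offender. Orientation is
rows = cells, columns = genes in all `.mtx` I/O. Gene filtering keeps
genes whose grand mean count strictly exceeds the threshold (default
0.1). Ties and degenerate inputs (single observation, all-zero genes)
return zero dispersion with flags rather than raising.
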
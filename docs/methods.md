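# Methods

## Model and scoring procedure

The package evaluates the three unrooted topologies of a four-taxon
nucleotide alignment.  Its premise is Hennigian: only *shared derived*
(synapomorphic) similarity is evidence of relatedness, while shared
ancestral (plesiomorphic) states and convergent states are noise that
time-reversible likelihood methods do not separate out.  Because the true
direction of change along the internal branch is unknown, both polarities of
every topology are scored (six polarized trees) and each topology keeps its
better polarity.

Per polarized tree `z` of topology `x` with derived split half `H`:

- observed support `S_obs = xi_x + sigma_x(H)` (symmetric plus derived-side
  asymmetric counts) and plesiomorphy `rho_z = sigma_x(ancestral half)`;
  `S_obs + rho_z = tau_x` always.
- expected convergence `kappa_z`: mean over the maximum-likelihood fits of
  the two rival topologies of the expected count (at the post-exclusion
  alignment length) of exactly those pattern classes.  The rival fits answer
  "how much apparent support for `z` would arise if a different tree were
  true"; what can be explained that way is discounted.  The symmetric class
  is counted as apomorphic for both polarities of its topology: whichever
  half is derived, its pair shares a derived state.
- singleton corrections `omega_obs = 1 − 4·phi/N` from the observed
  singleton spectrum and `omega_exp` (the same statistic on each rival fit's
  expected singletons, averaged).  Singleton frequencies track terminal
  branch lengths, so `omega ≈ 0` means balanced branches and `omega → 1`
  extreme asymmetry.
- score `theta_z = S_obs·(1 − omega_obs) − kappa_z·(1 − omega_exp)`
  (default convention, see below), then
  `delta_x = max(theta_x→, theta_x←)` and
  `lambda_x = (delta_x − min delta) / Σ(delta − min delta)`.

Negative `theta` values are retained: only differences matter after the
minimum subtraction.  If all three `delta` are equal (e.g. an all-constant
alignment) the weights are uniform (1/3 each) and no topology is declared
the winner.

### The two score conventions

The singleton correction can be applied in two algebraic ways: multiplying
the support and convergence terms by `omega` directly
(`eq8_direct`: `theta = S_obs·omega_obs − kappa·omega_exp`), the other by
the complement (`concept_complement`, i.e. the counts are *reduced in
proportion to* `omega`).  Both are implemented and selectable everywhere
(`convention=` in the API, `--convention` in the CLI, per-convention columns
in grid output); the Felsenstein-zone simulation is the empirical
discriminator.  On replicates with two long non-adjacent terminals (1.5),
internal branch 0.01, α = 1, 250 kbp, the complement form recovered the
generating topology in 19/20 replicates while the direct form managed 2/6
in a pilot and the plain-ML baseline 0/20.  The mechanism: `omega_obs` and
`omega_exp` are nearly equal (all three rival fits see the same very
asymmetric branches), so the direct form's score is approximately
`omega·(S_obs − kappa) + kappa·(omega_obs − omega_exp)`, and the residual
second term scales with `kappa` itself — largest exactly for the
long-branch-attraction topology it should be suppressing.  The complement
form carries the opposite sign on that residual.  `concept_complement` is
therefore the package default.

### Degenerate cases

- `N = 0` (no singletons at all, essentially zero terminal branch lengths):
  `omega_obs` is 0/0; the scoring layer disables the correction machinery
  for that quartet entirely and uses `theta = S_obs − kappa` under either
  convention.  A fit whose total expected singleton count is zero likewise
  contributes 0 to `omega_exp`.
- Zero-probability observed patterns: probabilities are floored at 1e-300
  before the log; `−inf` is reserved for patterns that are structurally
  impossible (exactly zero probability), which cannot occur at positive
  branch lengths.
- All-constant data: the gamma shape and invariant proportion are
  unidentifiable, so the free-parameter fit pins them and optimizes branch
  lengths only (which collapse to the lower bound).

## Likelihood core

GTR generator `q_ij = s_ij·pi_j` (exchangeabilities ordered AC, AG, AT, CG,
CT, GT; GT ≡ 1 during fitting), normalized to one expected substitution per
unit time at stationarity.  Branch lengths are expected substitutions per
*variable* site: the invariant fraction does not rescale the generator, and
the simulator uses the identical convention, so generator and inference
agree exactly.  Among-site rate variation uses the standard discrete gamma
with equal-probability categories and mean-of-quantile rates (default
`n_cat = 4`; category means computed from the Gamma(α+1) CDF so the mean is
exactly 1).  Site-pattern probabilities are the exact double sum over the
two internal-node states, evaluated through the spectral decomposition of
the reversible generator; the 256 probabilities sum to 1 to 1e-9 and match
an independent brute-force oracle (explicit loops + `expm`) to better than
1e-8.

Fitting maximizes the multinomial log-likelihood of the compressed pattern
counts by box-constrained L-BFGS-B on log-transformed parameters: 5 branch
lengths in [1e-8, 20], 5 relative exchangeabilities in [1e-4, 1e4], and —
in `all_free` mode — α in [0.01, 100] (log) and `p_inv` in [0, 0.99]
(linear).  Base frequencies are always the empirical counts of the quartet
alignment, not free parameters.  Starting branch lengths come from
Jukes-Cantor-corrected pairwise mismatch fractions combined by the
four-point condition.  The convergence tolerance is 1e-6 in log-likelihood
(passed to the optimizer as a relative tolerance divided by the column
count); up to 3 jittered restarts are attempted on non-convergence, and a
never-converged result is returned flagged with the best optimum found.
The ML baseline (`mltree`) uses the same machinery in `fixed_alpha_inv`
mode — ASRV parameters held at the simulation truth, mirroring a best-case
ML analysis whose only misspecification is the discrete-gamma
approximation — and counts log-likelihood ties (< 1e-6) as reconstruction
failures, since a tie identifies no tree.  The pattern score analogously
requires a strictly unique top weight.

## Simulator

Sites are i.i.d.  With probability `p_inv` a site is invariant (one draw
from the stationary distribution shared by all four taxa); otherwise its
rate multiplier is drawn from a *continuous* Gamma(α, mean 1) — the regime
the discrete-gamma inference side can only approximate, which is the
deliberate, minimal model misspecification of the study design — the
ancestral state is drawn at the A,B-side internal node (placement is
immaterial under reversibility) and descendants evolve along the five
branches by per-site transition probabilities.  Discrete-gamma simulation
(`n_cat ≥ 1`) is also supported and is used for exact simulator-vs-core
cross-checks: empirical class frequencies match the analytic expectation
within 5 standard errors at 100 kbp across random configurations.

Branch-length designs (default `short = 0.1`, internal = BL1, true topology
`q1`): `farris` puts the two elongated (BL2) terminals on the same split
half, `felsenstein` on opposite halves, `one_long` elongates one terminal
(with a second, BL3, on the opposite half), `three_long` elongates three and
sets the fourth to BL3.  The reference model is the study's GTR
(exchangeabilities 0.5, 1.0, 0.8, 0.4, 0.3, 0.6; base frequencies A 0.35,
C 0.15, G 0.15, T 0.35), `p_inv = 0.3`.  Per-replicate seeds derive from the
master seed by fixed integer arithmetic and are recorded in the grid output,
so every table is bit-reproducible.

What the simulator does *not* emulate: indels and missing data (site
exclusion is exercised only by hand-built alignments in the tests),
compositional heterogeneity among lineages, among-branch model variation,
and data partitions.  Passing simulation tests therefore show robustness to
branch-length asymmetry under a well-specified substitution process, not
robustness to the additional violations real data carry.

## Problem sizes and numerical choices in the test/acceptance runs

Simulation experiments use 250 kbp alignments as in the study, but 20
replicates per condition for the two-long-branch head-to-heads and 5-10
replicates per gamma shape (pooled over 6 shapes) for the three-long-branch
success rate — sizes chosen so the whole suite runs in minutes on one CPU
while leaving the binomial noise well clear of the tested margins
(Felsenstein zone: score 19/20 vs ML 0/20).

The parameter-recovery check fits 250 kbp data simulated under the
reference model on a tree with informative branch lengths (terminals
0.4-0.6, internal 0.15).  With uniformly short branches (0.1) the
α/`p_inv`/branch-scale ridge of GTR+Γ+I is statistically flat even at this
length — the free-parameter MLE can sit several logL units *above* the
truth at α̂ ≈ 0.4, I ≈ 0 with all branches ~30% short — so recovery there
would test identifiability, not the optimizer.  On the informative tree,
branch lengths are recovered within a few percent and α within ~15% despite
the continuous-vs-discrete gamma mismatch.  This weak identifiability at
short branches is also why the scoring algorithm's internal fits are used
only through their expected pattern distributions, which remain
well-determined along the ridge.

## Known limitations

- Nucleotides only; ambiguity codes and gaps are excluded per quartet, never
  partially matched.
- The convergence estimate averages the two rival-topology fits although at
  most one rival can be true; the correction is therefore approximate by
  construction.
- Singleton counts are an imperfect (non-linear) proxy for branch length,
  so `omega` under-corrects for extreme rate variation; with α = 0.1 both
  this method and ML often fail in the hardest designs.
- Quartets only; no supertree assembly, rogue-taxon analysis or root
  inference is attempted, and the weights are not posterior probabilities —
  they are normalized relative support.
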
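"""The quartet score: polarized split support corrected for plesiomorphy,
expected convergence, and branch-length asymmetry.

For one quartet alignment the scoring pipeline is:

1. tally the 15 structural site-pattern classes;
2. fit all three constrained topologies by ML (GTR+Gamma+I); each topology's
   fit doubles as the "alternative" model for the other two, so exactly three
   fits are performed per quartet;
3. for each of the six polarized trees ``z`` (topology x derived split half)
   compute

   - ``S_obs``: observed symmetric + derived-side asymmetric support,
   - ``rho``: observed ancestral-side (plesiomorphic) asymmetric count,
   - ``kappa``: the mean, over the two alternative-topology fits, of the
     expected count of convergent split-supporting patterns (symmetric plus
     derived-side asymmetric) at the alignment's post-exclusion length,
   - singleton-based correction factors ``omega_obs`` (from the observed
     tally; identical for all six trees) and ``omega_exp`` (mean over the two
     alternative fits),
   - the score ``theta``;

4. per topology keep the better polarity (``delta``), then normalize the
   deltas to weights ``lambda`` summing to one.

The singleton correction can be applied in two algebraic ways, and both are
provided: ``eq8_direct`` multiplies support by omega
(``theta = S_obs*omega_obs - kappa*omega_exp``) while ``concept_complement``
multiplies by the complement
(``theta = S_obs*(1-omega_obs) - kappa*(1-omega_exp)``), i.e. reduces the
counts *in proportion to* omega.  ``concept_complement`` is the default: in
Felsenstein-zone simulations (two long non-adjacent terminals, short internal
branch) it recovers the true topology in the clear majority of replicates
where plain ML is attracted to the long-branch pairing, whereas the direct
form leaves a residual ``+kappa*(omega_obs-omega_exp)`` term that favours the
long-branch topology precisely when its expected convergence is largest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phyquart.errors import InputError
from phyquart.patterns import (
    SPLIT_HALVES,
    TOPOLOGIES,
    PatternTally,
    observed_polar_counts,
    tally,
)
from phyquart.substmodel import FittedQuartet, expected_counts, fit_quartet
from phyquart import patterns as _pt

CONVENTIONS = ("eq8_direct", "concept_complement")


def omega_obs(t: PatternTally) -> float:
    """Observed singleton correction factor: ``1 - 4*phi/N``.

    ``phi`` is the smallest of the four singleton counts and ``N`` their sum;
    equal singleton counts (balanced terminal branches) give 0, a missing
    singleton class gives 1.  With no singletons at all (``N == 0``) the
    factor is undefined and the scoring layer disables the correction
    entirely; 0.0 is returned here as the balanced-limit value.
    """
    n = t.n_singletons
    if n == 0:
        return 0.0
    return 1.0 - 4.0 * t.phi / n


def _expected_singletons(f: FittedQuartet, L: float) -> np.ndarray:
    return expected_counts(f, L)[list(_pt.SINGLETON_IDS)]


def _omega_single(f: FittedQuartet, L: float) -> float:
    s = _expected_singletons(f, L)
    total = s.sum()
    if total == 0:
        return 0.0
    return 1.0 - 4.0 * s.min() / total


def omega_exp(f1: FittedQuartet, f2: FittedQuartet, L: float) -> float:
    """Expected singleton correction: mean of ``1 - 4*M_exp/T_exp`` over the
    two alternative-topology fits (a fit with zero expected singletons
    contributes 0)."""
    return 0.5 * (_omega_single(f1, L) + _omega_single(f2, L))


def _expected_support(f: FittedQuartet, topology: str, derived_half, L: float) -> float:
    ec = expected_counts(f, L)
    sym = ec[_pt.SYMMETRIC_ID[topology]]
    asym = ec[_pt.ASYMMETRIC_ID[topology, tuple(derived_half)]]
    return float(sym + asym)


def kappa(
    topology: str,
    derived_half,
    f1: FittedQuartet,
    f2: FittedQuartet,
    L: float,
) -> float:
    """Expected convergent split support for one polarized tree.

    Mean over the two fits of the alternative topologies of the expected
    count (at length ``L``) of symmetric plus derived-side asymmetric
    patterns supporting ``topology`` — i.e. how much apparent synapomorphy
    for this polarized tree would arise by chance were an alternative
    topology true.
    """
    return 0.5 * (
        _expected_support(f1, topology, derived_half, L)
        + _expected_support(f2, topology, derived_half, L)
    )


def theta(
    s_obs: float,
    rho: float,
    kappa_value: float,
    w_obs: float,
    w_exp: float,
    convention: str = "concept_complement",
) -> float:
    """Corrected synapomorphy score of one polarized tree (may be negative).

    ``eq8_direct``: ``(tau - rho)*omega_obs - kappa*omega_exp`` with
    ``tau = s_obs + rho``; ``concept_complement`` replaces each omega by its
    complement.
    """
    if convention == "eq8_direct":
        tau = s_obs + rho
        return (tau * w_obs) - (rho * w_obs) - (kappa_value * w_exp)
    if convention == "concept_complement":
        return s_obs * (1.0 - w_obs) - kappa_value * (1.0 - w_exp)
    raise InputError(f"unknown convention {convention!r}")


def delta(theta_a: float, theta_b: float) -> float:
    """Best-polarity score of one topology (ties keep the first value)."""
    return theta_a if theta_a >= theta_b else theta_b


def lambda_weights(deltas) -> np.ndarray:
    """Normalized topology weights: ``(delta - delta_min) / sum(...)``.

    All-equal deltas (no topology preferred, denominator zero) yield the
    uniform weights (1/3, 1/3, 1/3).  Weights are non-negative, sum to one,
    and the minimizing topology gets weight zero whenever deltas differ.
    """
    d = np.asarray(deltas, float)
    if d.shape != (3,):
        raise InputError("need exactly three delta values")
    shifted = d - d.min()
    total = shifted.sum()
    if total == 0:
        return np.full(3, 1.0 / 3.0)
    return shifted / total


@dataclass
class QuartetScores:
    """Full scoring result for one quartet."""

    theta: dict
    delta: dict
    lam: dict
    convention: str
    omega_obs: float
    omega_exp: dict
    fits: dict = field(repr=False, default=None)
    roles: dict | None = None
    used_length: int = 0
    fit_flags: dict = field(default_factory=dict)

    @property
    def winner(self) -> str:
        """Topology with the largest weight ('tie' if not unique)."""
        lams = [self.lam[t] for t in TOPOLOGIES]
        best = max(lams)
        top = [t for t, v in zip(TOPOLOGIES, lams) if v == best]
        return top[0] if len(top) == 1 else "tie"


def fit_all_topologies(
    t: PatternTally,
    mode: str = "all_free",
    *,
    fixed_alpha: float | None = None,
    fixed_p_inv: float | None = None,
    n_cat: int = 4,
    tol: float = 1e-6,
) -> dict:
    """ML fits of the three constrained topologies (shared by scoring and by
    the ML baseline)."""
    return {
        topo: fit_quartet(t, topo, mode, fixed_alpha=fixed_alpha,
                          fixed_p_inv=fixed_p_inv, n_cat=n_cat, tol=tol)
        for topo in TOPOLOGIES
    }


def evaluate_tally(
    t: PatternTally,
    convention: str = "concept_complement",
    *,
    fits: dict | None = None,
    mode: str = "all_free",
    fixed_alpha: float | None = None,
    fixed_p_inv: float | None = None,
    n_cat: int = 4,
    tol: float = 1e-6,
) -> QuartetScores:
    """Score a pattern tally (pass precomputed ``fits`` to reuse them, e.g.
    across conventions)."""
    if convention not in CONVENTIONS:
        raise InputError(f"unknown convention {convention!r}")
    if t.L == 0:
        raise InputError("empty tally")
    if fits is None:
        fits = fit_all_topologies(t, mode, fixed_alpha=fixed_alpha,
                                  fixed_p_inv=fixed_p_inv, n_cat=n_cat, tol=tol)
    L = t.L
    w_obs = omega_obs(t)
    omega_off = t.n_singletons == 0  # no singleton signal: disable corrections

    thetas: dict = {}
    deltas: dict = {}
    w_exps: dict = {}
    for topo in TOPOLOGIES:
        alt = [fits[y] for y in TOPOLOGIES if y != topo]
        w_exp = omega_exp(alt[0], alt[1], L)
        w_exps[topo] = w_exp
        per_polarity = []
        for half in SPLIT_HALVES[topo]:
            s_obs, rho = observed_polar_counts(t, topo, half)
            k = kappa(topo, half, alt[0], alt[1], L)
            if omega_off:
                th = s_obs - k
            else:
                th = theta(s_obs, rho, k, w_obs, w_exp, convention)
            thetas[(topo, half)] = th
            per_polarity.append(th)
        deltas[topo] = delta(per_polarity[0], per_polarity[1])

    lam = lambda_weights([deltas[t_] for t_ in TOPOLOGIES])
    return QuartetScores(
        theta=thetas,
        delta=deltas,
        lam=dict(zip(TOPOLOGIES, lam)),
        convention=convention,
        omega_obs=w_obs,
        omega_exp=w_exps,
        fits=fits,
        fit_flags={topo: fits[topo].converged for topo in TOPOLOGIES},
    )


def evaluate_quartet(qa, convention: str = "concept_complement", **kwargs) -> QuartetScores:
    """Score a :class:`phyquart.seqio.QuartetAlignment` end to end.

    Tallies the alignment, performs the three constrained ML fits and
    produces the six polarized scores, three deltas and three normalized
    weights; the winning topology is ``scores.winner``.
    """
    t = tally(qa)
    scores = evaluate_tally(t, convention, **kwargs)
    scores.roles = getattr(qa, "roles", None)
    scores.used_length = getattr(qa, "used_length", t.L)
    return scores
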
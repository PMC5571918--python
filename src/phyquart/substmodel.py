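"""GTR+Gamma+I likelihood machinery on quartet trees.

Everything here works on the *compressed* representation of a quartet
alignment: the counts of the 256 ordered site-patterns.  Exact pattern
probabilities on a 5-branch quartet tree are a double sum over the two
internal-node states, evaluated per discrete-gamma rate category via the
spectral decomposition of the reversible generator, so a full likelihood
evaluation costs microseconds regardless of alignment length.  That makes
maximum-likelihood fitting of branch lengths and model parameters on
250 kbp alignments cheap enough for simulation studies.

Conventions: bases are ordered A, C, G, T; exchangeabilities are ordered
AC, AG, AT, CG, CT, GT with GT fixed to 1 during fitting; the generator is
normalized to one expected substitution per unit time at stationarity
(branch lengths are expected substitutions per variable site; the invariant
fraction is not rescaled).  Discrete gamma uses equal-probability categories
with mean-of-quantile rates (overall mean exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from phyquart.errors import InputError
from phyquart.patterns import CLASS_MASKS, PatternTally

EXCHANGE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

#: decoded role states of each of the 256 pattern codes, shape (4, 256)
_CODE_STATES = np.stack(
    [np.arange(256) // 64 % 4, np.arange(256) // 16 % 4,
     np.arange(256) // 4 % 4, np.arange(256) % 4]
)
_CONSTANT_CODES = np.array([85 * i for i in range(4)])  # a==b==c==d

#: which pair of role axes is joined by each topology's split
_SPLIT_SIDES = {"q1": ((0, 1), (2, 3)), "q2": ((0, 2), (1, 3)), "q3": ((0, 3), (1, 2))}

_BL_BOUNDS = (1e-8, 20.0)
_ALPHA_BOUNDS = (0.01, 100.0)
_PINV_BOUNDS = (0.0, 0.99)
_EXCH_BOUNDS = (1e-4, 1e4)


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR exchangeabilities + base frequencies + Gamma/invariant ASRV.

    ``n_cat`` is the number of discrete gamma categories; 0 means a
    continuous gamma (usable by the simulator only).
    """

    exchangeabilities: tuple = (1.0,) * 6
    base_freqs: tuple = (0.25,) * 4
    alpha: float = 1.0
    p_inv: float = 0.0
    n_cat: int = 4

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, float)
        fr = np.asarray(self.base_freqs, float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise InputError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if fr.shape != (4,) or np.any(fr <= 0) or abs(fr.sum() - 1) > 1e-6:
            raise InputError("base frequencies must be 4 positive reals summing to 1")
        if self.alpha <= 0:
            raise InputError("gamma shape alpha must be positive")
        if not 0 <= self.p_inv < 1:
            raise InputError("p_inv must be in [0, 1)")
        object.__setattr__(self, "exchangeabilities", tuple(float(x) for x in ex))
        object.__setattr__(self, "base_freqs", tuple(float(x) for x in fr / fr.sum()))


@dataclass(frozen=True)
class QuartetTree:
    """A quartet topology with five branch lengths.

    ``branch_lengths`` are (t_A, t_B, t_C, t_D, t_internal) in expected
    substitutions per site; the four terminal lengths are attached to the
    roles, independent of the topology.
    """

    topology: str
    branch_lengths: tuple

    def __post_init__(self):
        if self.topology not in _SPLIT_SIDES:
            raise InputError(f"unknown topology {self.topology!r}")
        bl = np.asarray(self.branch_lengths, float)
        if bl.shape != (5,) or np.any(bl < 0):
            raise InputError("need 5 non-negative branch lengths (A,B,C,D,internal)")
        object.__setattr__(self, "branch_lengths", tuple(float(x) for x in bl))


@dataclass
class FittedQuartet:
    """A fitted constrained topology: optimum, its likelihood and the full
    expected site-pattern distribution."""

    tree: QuartetTree
    model: SubstitutionModel
    logL: float
    pattern_probs: np.ndarray
    converged: bool = True
    n_evaluations: int = 0


def rate_matrix(m: SubstitutionModel) -> np.ndarray:
    """Normalized GTR generator: ``q_ij = s_ij * pi_j`` off-diagonal, rows sum
    to zero, and ``-sum_i pi_i q_ii == 1``."""
    ex = np.asarray(m.exchangeabilities)
    pi = np.asarray(m.base_freqs)
    Q = np.zeros((4, 4))
    for s, (i, j) in zip(ex, _PAIRS):
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise InputError("degenerate rate matrix")
    return Q / mu


class _Spectral:
    """Eigendecomposition of a reversible generator for fast P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        rp = np.sqrt(pi)
        S = Q * rp[:, None] / rp[None, :]
        S = (S + S.T) / 2.0
        w, U = np.linalg.eigh(S)
        self.w = w
        self.A = U / rp[:, None]
        self.B = U.T * rp[None, :]

    def probs(self, ts: np.ndarray) -> np.ndarray:
        """Transition matrices for an array of scaled times, shape (m,4,4)."""
        E = np.exp(np.multiply.outer(np.asarray(ts, float), self.w))
        return np.einsum("ij,mj,jk->mik", self.A, E, self.B)


def transition_probs(Q: np.ndarray, t: float, r: float = 1.0) -> np.ndarray:
    """P(t) = expm(r*t*Q); rows sum to 1, P(0) = I."""
    if t < 0 or r < 0:
        raise InputError("branch length and rate multiplier must be >= 0")
    return sla.expm(np.asarray(Q, float) * (t * r))


def discrete_gamma_rates(alpha: float, n_cat: int) -> np.ndarray:
    """Mean-of-quantile rates of the ``n_cat`` equal-probability categories of
    Gamma(alpha, mean 1); the returned rates average exactly 1."""
    if n_cat < 1:
        raise InputError("n_cat must be >= 1")
    if n_cat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, n_cat) / n_cat, a=alpha, scale=1.0 / alpha)
    upper = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    cum = np.concatenate([[0.0], upper, [1.0]])
    return n_cat * np.diff(cum)


def _pattern_probs_spec(tree: QuartetTree, m: SubstitutionModel, spec: _Spectral) -> np.ndarray:
    pi = np.asarray(m.base_freqs)
    bl = np.asarray(tree.branch_lengths)
    rates = discrete_gamma_rates(m.alpha, m.n_cat)
    (l1, l2), (r1, r2) = _SPLIT_SIDES[tree.topology]
    # scaled times for all 5 branches x categories in one spectral call
    ts = np.multiply.outer(rates, bl).ravel()
    P = spec.probs(ts).reshape(len(rates), 5, 4, 4)
    var = np.zeros((4, 4, 4, 4))
    for k in range(len(rates)):
        left = np.einsum("x,xa,xb->xab", pi, P[k, l1], P[k, l2]).reshape(4, 16)
        right = np.einsum("yc,yd->ycd", P[k, r1], P[k, r2]).reshape(4, 16)
        inner = P[k, 4] @ right
        var += (left.T @ inner).reshape(4, 4, 4, 4)
    var /= len(rates)
    # var axes are in role order (l1, l2, r1, r2); restore A,B,C,D order
    order = np.argsort((l1, l2, r1, r2))
    probs = np.transpose(var, order).ravel()
    probs = (1.0 - m.p_inv) * probs
    probs[_CONSTANT_CODES] += m.p_inv * pi
    return probs


def pattern_probs(tree: QuartetTree, m: SubstitutionModel) -> np.ndarray:
    """Exact probabilities of the 256 ordered site-patterns under the tree.

    Indexed by the base-4 pattern code ``a*64 + b*16 + c*4 + d`` with bases
    ordered A,C,G,T; sums to 1.
    """
    if m.n_cat < 1:
        raise InputError("pattern_probs needs a discrete gamma (n_cat >= 1)")
    Q = rate_matrix(m)
    return _pattern_probs_spec(tree, m, _Spectral(Q, np.asarray(m.base_freqs)))


_PROB_FLOOR = 1e-300


def log_likelihood(t: PatternTally, tree: QuartetTree, m: SubstitutionModel) -> float:
    """Multinomial log-likelihood of the tallied patterns.

    Returns ``-inf`` if a pattern with positive count has structurally zero
    probability; otherwise probabilities are floored at 1e-300 before the log.
    """
    probs = pattern_probs(tree, m)
    return _loglik_from_probs(t.raw256, probs)


def _loglik_from_probs(counts: np.ndarray, probs: np.ndarray) -> float:
    observed = counts > 0
    if np.any(probs[observed] == 0.0):
        return float("-inf")
    return float(counts[observed] @ np.log(np.maximum(probs[observed], _PROB_FLOOR)))


def expected_counts(f: FittedQuartet, L: int) -> np.ndarray:
    """Expected counts of the 15 structural pattern classes at alignment
    length ``L`` (ordered as :data:`phyquart.patterns.ALL_CLASSES`)."""
    return (CLASS_MASKS @ f.pattern_probs) * float(L)


# ---------------------------------------------------------------------------
# fitting


def _pair_mismatch_fractions(counts: np.ndarray) -> dict:
    L = counts.sum()
    out = {}
    for i, j in _PAIRS:
        mism = counts[_CODE_STATES[i] != _CODE_STATES[j]].sum()
        out[(i, j)] = out[(j, i)] = mism / L
    return out


def _jc_distance(p: float) -> float:
    p = min(p, 0.70)
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _start_branch_lengths(counts: np.ndarray, topology: str) -> np.ndarray:
    """Distance-based starting lengths (JC-corrected, four-point internal)."""
    pm = _pair_mismatch_fractions(counts)
    d = {k: _jc_distance(v) for k, v in pm.items()}
    (l1, l2), (r1, r2) = _SPLIT_SIDES[topology]
    bl = np.empty(5)

    def _term(x, sib, far1, far2):
        return 0.5 * (d[(x, sib)] + 0.5 * (d[(x, far1)] + d[(x, far2)])
                      - 0.5 * (d[(sib, far1)] + d[(sib, far2)]))

    bl[l1] = _term(l1, l2, r1, r2)
    bl[l2] = _term(l2, l1, r1, r2)
    bl[r1] = _term(r1, r2, l1, l2)
    bl[r2] = _term(r2, r1, l1, l2)
    cross = 0.5 * (d[(l1, r1)] + d[(l1, r2)] + d[(l2, r1)] + d[(l2, r2)])
    bl[4] = 0.5 * (cross - d[(l1, l2)] - d[(r1, r2)])
    return np.clip(bl, 1e-4, 15.0)


def fit_quartet(
    t: PatternTally,
    topology: str,
    mode: str = "all_free",
    *,
    fixed_alpha: float | None = None,
    fixed_p_inv: float | None = None,
    n_cat: int = 4,
    tol: float = 1e-6,
    max_restarts: int = 3,
) -> FittedQuartet:
    """Maximize the likelihood of ``topology`` over branch lengths and model
    parameters.

    ``mode='all_free'`` optimizes the five branch lengths, five relative
    exchangeabilities (GT fixed to 1), the gamma shape and the invariant
    proportion; ``mode='fixed_alpha_inv'`` holds alpha and p_inv at the
    supplied values (the baseline protocol: ASRV parameters known, relative
    rates and composition estimated from the data).  Base frequencies are
    always the empirical counts of the quartet alignment, not free
    parameters.

    Optimization is box-constrained L-BFGS-B on log-transformed parameters
    with up to ``max_restarts`` jittered restarts on non-convergence; a
    never-converged result is returned flagged, carrying the best optimum
    found.
    """
    if mode not in ("all_free", "fixed_alpha_inv"):
        raise InputError(f"unknown fit mode {mode!r}")
    if mode == "fixed_alpha_inv" and (fixed_alpha is None or fixed_p_inv is None):
        raise InputError("fixed_alpha_inv mode needs fixed_alpha and fixed_p_inv")
    counts = t.raw256
    if counts.sum() == 0:
        raise InputError("empty tally")
    free_asrv = mode == "all_free"
    if free_asrv and counts[_CONSTANT_CODES].sum() == counts.sum():
        # all-constant data: alpha/p_inv are unidentifiable; pin them
        free_asrv = False
        fixed_alpha, fixed_p_inv = 1.0, 0.0

    freqs = np.maximum(t.base_freqs, 1e-6)
    freqs = freqs / freqs.sum()

    n_bl, n_ex = 5, 5
    nd = n_bl + n_ex + (2 if free_asrv else 0)

    def unpack(x):
        bl = np.exp(x[:n_bl])
        ex = np.concatenate([np.exp(x[n_bl:n_bl + n_ex]), [1.0]])
        if free_asrv:
            alpha, p_inv = np.exp(x[-2]), x[-1]
        else:
            alpha, p_inv = fixed_alpha, fixed_p_inv
        model = SubstitutionModel(tuple(ex), tuple(freqs), float(alpha),
                                  float(p_inv), n_cat)
        return QuartetTree(topology, tuple(bl)), model

    n_eval = [0]

    def objective(x):
        n_eval[0] += 1
        tree, model = unpack(x)
        probs = _pattern_probs_spec(tree, model, _Spectral(rate_matrix(model), freqs))
        ll = _loglik_from_probs(counts, probs)
        return 1e12 if not np.isfinite(ll) else -ll

    lo = np.concatenate([
        np.full(n_bl, np.log(_BL_BOUNDS[0])), np.full(n_ex, np.log(_EXCH_BOUNDS[0])),
        [np.log(_ALPHA_BOUNDS[0]), _PINV_BOUNDS[0]] if free_asrv else [],
    ])
    hi = np.concatenate([
        np.full(n_bl, np.log(_BL_BOUNDS[1])), np.full(n_ex, np.log(_EXCH_BOUNDS[1])),
        [np.log(_ALPHA_BOUNDS[1]), _PINV_BOUNDS[1]] if free_asrv else [],
    ])
    bounds = list(zip(lo, hi))

    x0 = np.zeros(nd)
    x0[:n_bl] = np.log(_start_branch_lengths(counts, topology))
    if free_asrv:
        x0[-2], x0[-1] = np.log(1.0), 0.2
    x0 = np.clip(x0, lo, hi)

    rng = np.random.default_rng(12345)
    best = None
    converged = False
    start = x0
    for attempt in range(max_restarts + 1):
        # scipy's ftol is relative to |f| ~ L * mean neg-log-prob; divide the
        # absolute logL tolerance by L so convergence matches `tol` in logL
        res = minimize(objective, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": tol / max(int(counts.sum()), 1)})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            converged = True
            break
        start = np.clip(x0 + rng.normal(0, 0.5, nd), lo, hi)

    tree, model = unpack(best.x)
    probs = pattern_probs(tree, model)
    return FittedQuartet(tree=tree, model=model, logL=-float(best.fun),
                         pattern_probs=probs, converged=converged,
                         n_evaluations=n_eval[0])


def refit_branch_lengths(f: FittedQuartet, t: PatternTally) -> FittedQuartet:
    """Re-optimize only the branch lengths of an existing fit (utility for
    warm-started refits; model parameters are kept)."""
    m = f.model
    counts = t.raw256
    spec_cache = _Spectral(rate_matrix(m), np.asarray(m.base_freqs))

    def objective(x):
        tree = QuartetTree(f.tree.topology, tuple(np.exp(x)))
        return -_loglik_from_probs(counts, _pattern_probs_spec(tree, m, spec_cache))

    x0 = np.log(np.clip(f.tree.branch_lengths, *_BL_BOUNDS))
    res = minimize(objective, x0, method="L-BFGS-B",
                   bounds=[(np.log(_BL_BOUNDS[0]), np.log(_BL_BOUNDS[1]))] * 5)
    tree = QuartetTree(f.tree.topology, tuple(np.exp(res.x)))
    return replace(f, tree=tree, logL=-float(res.fun),
                   pattern_probs=pattern_probs(tree, m))
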
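"""Quartet alignment simulator: GTR + continuous Gamma rates + invariant
sites on the long-branch study designs.

Each site is i.i.d.: with probability ``p_inv`` it is invariant (one state
drawn from the stationary frequencies, shared by all four taxa); otherwise a
rate multiplier is drawn from Gamma(alpha, mean 1) — continuous by default,
the regime the inference side can only approximate with discrete categories
— an ancestral state is drawn at the internal node on the A,B side (the
placement is immaterial under reversibility) and the four tips plus the
second internal node evolve along the five branches with that site's rate.

Branch-length designs (true topology q1 = AB|CD unless configured
otherwise; ``short`` defaults to 0.1):

- ``farris``: the two elongated (BL2) terminals are adjacent — both on the
  same split half — so chance convergence reinforces the true split;
- ``felsenstein``: the BL2 terminals sit on opposite split halves, the
  classic long-branch-attraction zone;
- ``one_long``: one BL2 terminal, one BL3 terminal (opposite half), two
  short;
- ``three_long``: three BL2 terminals, the remaining one at BL3.

The internal branch is BL1 in every design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phyquart.errors import InputError
from phyquart.patterns import ROLES, SPLIT_HALVES
from phyquart.seqio import Alignment, QuartetAlignment
from phyquart.substmodel import (
    QuartetTree,
    SubstitutionModel,
    _Spectral,
    discrete_gamma_rates,
    rate_matrix,
)

DESIGNS = ("farris", "felsenstein", "one_long", "three_long")

#: GTR exchangeabilities (AC, AG, AT, CG, CT, GT order) and stationary base
#: frequencies (A, C, G, T) of the simulation study's reference model
STUDY_EXCHANGEABILITIES = (0.5, 1.0, 0.8, 0.4, 0.3, 0.6)
STUDY_BASE_FREQS = (0.35, 0.15, 0.15, 0.35)


def study_model(alpha: float, p_inv: float = 0.3, n_cat: int = 0) -> SubstitutionModel:
    """The reference GTR+Gamma+I simulation model (continuous gamma by
    default, ``n_cat=0``)."""
    return SubstitutionModel(STUDY_EXCHANGEABILITIES, STUDY_BASE_FREQS,
                             alpha, p_inv, n_cat)


@dataclass
class SimulationConfig:
    """One simulation condition: a branch-length design plus model and size."""

    design: str
    bl1: float
    bl2: float
    bl3: float = 0.1
    short: float = 0.1
    L: int = 250_000
    model: SubstitutionModel = field(default_factory=lambda: study_model(1.0))
    seed: int = 0
    true_topology: str = "q1"

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise InputError(f"unknown design {self.design!r}")
        if self.L < 1:
            raise InputError("L must be >= 1")
        for name in ("bl1", "bl2", "bl3", "short"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.true_topology not in SPLIT_HALVES:
            raise InputError(f"unknown topology {self.true_topology!r}")


def branch_lengths(cfg: SimulationConfig) -> QuartetTree:
    """The quartet tree implied by the design, arranged on the true topology's
    split halves."""
    (h1a, h1b), (h2a, h2b) = SPLIT_HALVES[cfg.true_topology]
    terminal = {r: cfg.short for r in ROLES}
    if cfg.design == "farris":
        terminal[h1a] = terminal[h1b] = cfg.bl2
    elif cfg.design == "felsenstein":
        terminal[h1a] = terminal[h2a] = cfg.bl2
    elif cfg.design == "one_long":
        terminal[h1a] = cfg.bl2
        terminal[h2a] = cfg.bl3
    else:  # three_long
        terminal[h1a] = terminal[h1b] = terminal[h2a] = cfg.bl2
        terminal[h2b] = cfg.bl3
    bl = tuple(terminal[r] for r in ROLES) + (cfg.bl1,)
    return QuartetTree(cfg.true_topology, bl)


def _site_rates(model: SubstitutionModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if model.n_cat == 0:
        return rng.gamma(shape=model.alpha, scale=1.0 / model.alpha, size=n)
    cats = discrete_gamma_rates(model.alpha, model.n_cat)
    return cats[rng.integers(0, model.n_cat, size=n)]


def _evolve(parent: np.ndarray, t: float, rates: np.ndarray,
            spec: _Spectral, rng: np.random.Generator) -> np.ndarray:
    """Child states for every site given parent states and per-site rates."""
    # per-site transition rows via the spectral decomposition
    E = np.exp(np.multiply.outer(rates * t, spec.w))
    rows = np.einsum("nj,nj,jk->nk", spec.A[parent], E, spec.B)
    np.clip(rows, 0.0, None, out=rows)
    rows /= rows.sum(axis=1, keepdims=True)
    u = rng.random(parent.shape[0])
    return (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int8)


def simulate_alignment(cfg: SimulationConfig) -> QuartetAlignment:
    """Simulate one gap-free quartet alignment; same seed, same alignment."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.model
    pi = np.asarray(m.base_freqs)
    tree = branch_lengths(cfg)
    bl = np.asarray(tree.branch_lengths)
    spec = _Spectral(rate_matrix(m), pi)

    invariant = rng.random(cfg.L) < m.p_inv
    n_var = int((~invariant).sum())
    states = np.empty((cfg.L, 4), dtype=np.int8)

    inv_states = rng.choice(4, size=cfg.L - n_var, p=pi).astype(np.int8)
    states[invariant] = inv_states[:, None]

    if n_var:
        rates = _site_rates(m, n_var, rng)
        root = rng.choice(4, size=n_var, p=pi).astype(np.int8)  # A,B-side node
        (l1, l2), (r1, r2) = (
            tuple(ROLES.index(x) for x in half) for half in SPLIT_HALVES[tree.topology]
        )
        var = np.empty((n_var, 4), dtype=np.int8)
        var[:, l1] = _evolve(root, bl[l1], rates, spec, rng)
        var[:, l2] = _evolve(root, bl[l2], rates, spec, rng)
        other = _evolve(root, bl[4], rates, spec, rng)
        var[:, r1] = _evolve(other, bl[r1], rates, spec, rng)
        var[:, r2] = _evolve(other, bl[r2], rates, spec, rng)
        states[~invariant] = var

    return QuartetAlignment(roles=dict(zip(ROLES, ROLES)), codes=states,
                            original_length=cfg.L)


def to_alignment(qa: QuartetAlignment, labels=None) -> Alignment:
    """Decode a simulated quartet into a writable `Alignment` (FASTA
    interchange)."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    labels = labels or [qa.roles[r] for r in ROLES]
    seqs = [bases[qa.codes[:, i]].tobytes().decode() for i in range(4)]
    return Alignment(list(labels), seqs)


def spawn_seed(master_seed: int, *indices: int) -> int:
    """Deterministic child seed from a master seed and grid indices (fixed
    LCG-style arithmetic; result < 2**31)."""
    s = (int(master_seed) * 2654435761 + 0x9E3779B9) % (2**63)
    for idx in indices:
        s = (s * 6364136223846793005 + int(idx) * 1442695040888963407 + 1) % (2**63)
    return int(s % (2**31))
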
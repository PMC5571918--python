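"""Classification and counting of quartet site-patterns.

A site-pattern is the ordered tuple of nucleotide states at one alignment
column across the four quartet roles A, B, C, D.  The set partition it
induces on the roles places every one of the 256 ordered 4-tuples over
{A,C,G,T} into exactly one of 15 structural classes:

==============  =====================================  ====================
partition shape  class                                  members (of 256)
==============  =====================================  ====================
{ABCD}           constant                               4
{xyz},{w}        singleton (one deviating role, x4)     12 each
{xy},{zw}        symmetric split support (x3)           12 each
{xy},{z},{w}     asymmetric split support (x6)          24 each
4 singletons     all-distinct                           24
==============  =====================================  ====================

Symmetric patterns ({XXYY} shapes) support the topology whose split pairs
the two matching roles; asymmetric patterns ({XXYZ} shapes) support the same
topology but carry, in addition, the identity of the *sharing pair* — the
half of the split in which the two roles agree.  Under a polarity (an assumed
direction of character transformation along the internal branch) the sharing
pair on the derived side is a putative synapomorphy, while sharing on the
ancestral side is plesiomorphic and phylogenetically uninformative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from phyquart.errors import InputError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

ROLES = ("A", "B", "C", "D")

#: the three quartet topologies and the two halves of each one's split
TOPOLOGIES = ("q1", "q2", "q3")
SPLIT_HALVES = {
    "q1": (("A", "B"), ("C", "D")),
    "q2": (("A", "C"), ("B", "D")),
    "q3": (("A", "D"), ("B", "C")),
}

#: all six polarized quartet trees as (topology, derived half) pairs,
#: e.g. ("q1", ("C", "D")) is AB(CD) with the derived direction towards C,D
POLARIZED_TREES = tuple(
    (topo, half) for topo in TOPOLOGIES for half in SPLIT_HALVES[topo]
)


class Kind(Enum):
    CONSTANT = "constant"
    SINGLETON = "singleton"
    SYMMETRIC = "symmetric"
    ASYMMETRIC = "asymmetric"
    ALL_DISTINCT = "all_distinct"


@dataclass(frozen=True)
class PatternClass:
    """One of the 15 structural site-pattern classes.

    ``detail`` is the deviating role for singletons, the supported topology
    for symmetric patterns, and ``(topology, sharing pair)`` for asymmetric
    patterns; ``None`` for constant and all-distinct.
    """

    kind: Kind
    detail: object = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PatternClass({self.kind.value}, {self.detail})"


def _build_classes():
    classes = [PatternClass(Kind.CONSTANT)]
    classes += [PatternClass(Kind.SINGLETON, r) for r in ROLES]
    classes += [PatternClass(Kind.SYMMETRIC, t) for t in TOPOLOGIES]
    for topo in TOPOLOGIES:
        for half in SPLIT_HALVES[topo]:
            classes.append(PatternClass(Kind.ASYMMETRIC, (topo, half)))
    classes.append(PatternClass(Kind.ALL_DISTINCT))
    return tuple(classes)


#: canonical ordering of the 15 classes (constant, singletons A-D, symmetric
#: q1-q3, asymmetric (q1,AB),(q1,CD),(q2,AC),(q2,BD),(q3,AD),(q3,BC),
#: all-distinct)
ALL_CLASSES = _build_classes()
CLASS_ID = {c: i for i, c in enumerate(ALL_CLASSES)}

SINGLETON_IDS = tuple(CLASS_ID[PatternClass(Kind.SINGLETON, r)] for r in ROLES)
SYMMETRIC_ID = {t: CLASS_ID[PatternClass(Kind.SYMMETRIC, t)] for t in TOPOLOGIES}
ASYMMETRIC_ID = {
    (t, half): CLASS_ID[PatternClass(Kind.ASYMMETRIC, (t, half))]
    for t in TOPOLOGIES
    for half in SPLIT_HALVES[t]
}

_PAIR_TO_TOPOLOGY = {}
for _t, _halves in SPLIT_HALVES.items():
    for _h in _halves:
        _PAIR_TO_TOPOLOGY[frozenset(_h)] = (_t, _h)


def _classify_indices(states: tuple[int, int, int, int]) -> PatternClass:
    groups: dict[int, list[str]] = {}
    for role, s in zip(ROLES, states):
        groups.setdefault(s, []).append(role)
    sizes = sorted(len(g) for g in groups.values())
    if sizes == [4]:
        return PatternClass(Kind.CONSTANT)
    if sizes == [1, 3]:
        deviant = next(g[0] for g in groups.values() if len(g) == 1)
        return PatternClass(Kind.SINGLETON, deviant)
    if sizes == [2, 2]:
        pair = next(tuple(g) for g in groups.values() if len(g) == 2)
        topo, _ = _PAIR_TO_TOPOLOGY[frozenset(pair)]
        return PatternClass(Kind.SYMMETRIC, topo)
    if sizes == [1, 1, 2]:
        pair = next(tuple(g) for g in groups.values() if len(g) == 2)
        topo, half = _PAIR_TO_TOPOLOGY[frozenset(pair)]
        return PatternClass(Kind.ASYMMETRIC, (topo, half))
    return PatternClass(Kind.ALL_DISTINCT)


def _tuple_code(states: tuple[int, int, int, int]) -> int:
    a, b, c, d = states
    return ((a * 4 + b) * 4 + c) * 4 + d


#: class id of every ordered 4-tuple, indexed by base-4 code a*64+b*16+c*4+d
CLASS_OF_CODE = np.empty(256, dtype=np.int8)
for _tup in itertools.product(range(4), repeat=4):
    CLASS_OF_CODE[_tuple_code(_tup)] = CLASS_ID[_classify_indices(_tup)]

#: per-class boolean masks over the 256 tuple codes
CLASS_MASKS = np.stack([CLASS_OF_CODE == i for i in range(len(ALL_CLASSES))])

#: number of times each base appears in each tuple code, shape (256, 4)
BASE_MULTIPLICITY = np.zeros((256, 4), dtype=np.int64)
for _tup in itertools.product(range(4), repeat=4):
    for _s in _tup:
        BASE_MULTIPLICITY[_tuple_code(_tup), _s] += 1


def classify_site(states) -> PatternClass:
    """Classify one ordered site-pattern ``(sA, sB, sC, sD)``.

    ``states`` may hold nucleotide letters or 0-3 indices.  Non-ACGT symbols
    are an error here: excluding gap/ambiguous sites is the job of
    :func:`phyquart.seqio.extract_quartet`.
    """
    if len(states) != 4:
        raise InputError(f"site-pattern needs 4 states, got {len(states)}")
    idx = []
    for s in states:
        if isinstance(s, (int, np.integer)):
            if not 0 <= s <= 3:
                raise InputError(f"state index out of range: {s}")
            idx.append(int(s))
        else:
            try:
                idx.append(BASE_INDEX[str(s).upper()])
            except KeyError:
                raise InputError(f"non-ACGT state {s!r} in site-pattern") from None
    return ALL_CLASSES[CLASS_OF_CODE[_tuple_code(tuple(idx))]]


@dataclass
class PatternTally:
    """Counts of the site-patterns of one quartet alignment.

    ``raw256`` holds the count of every ordered 4-tuple (indexed by base-4
    code); class-level counts, split-support totals and singleton statistics
    are derived views.
    """

    raw256: np.ndarray
    L: int = field(init=False)

    def __post_init__(self):
        self.raw256 = np.asarray(self.raw256, dtype=np.int64)
        if self.raw256.shape != (256,):
            raise InputError("raw256 must have shape (256,)")
        self.L = int(self.raw256.sum())

    @property
    def class_counts(self) -> np.ndarray:
        """Counts of the 15 structural classes, canonical order."""
        return CLASS_MASKS @ self.raw256

    def count(self, cls: PatternClass) -> int:
        return int(self.class_counts[CLASS_ID[cls]])

    def symmetric(self, topology: str) -> int:
        """xi: count of {XXYY}-type patterns supporting ``topology``."""
        return int(self.class_counts[SYMMETRIC_ID[topology]])

    def asymmetric(self, topology: str, pair) -> int:
        """sigma: count of {XXYZ}-type patterns supporting ``topology`` with
        the shared state in the given split half."""
        return int(self.class_counts[ASYMMETRIC_ID[topology, tuple(pair)]])

    def tau(self, topology: str) -> int:
        """Total observed split support: symmetric plus both asymmetric."""
        halves = SPLIT_HALVES[topology]
        return (
            self.symmetric(topology)
            + self.asymmetric(topology, halves[0])
            + self.asymmetric(topology, halves[1])
        )

    @property
    def singleton_counts(self) -> np.ndarray:
        """Counts of the four singleton classes in role order A, B, C, D."""
        return self.class_counts[list(SINGLETON_IDS)]

    @property
    def n_singletons(self) -> int:
        """N: total number of singleton site-patterns."""
        return int(self.singleton_counts.sum())

    @property
    def phi(self) -> int:
        """phi: the smallest of the four singleton counts."""
        return int(self.singleton_counts.min())

    @property
    def base_freqs(self) -> np.ndarray:
        """Empirical base composition pooled over the four sequences."""
        occ = self.raw256 @ BASE_MULTIPLICITY
        total = occ.sum()
        if total == 0:
            return np.full(4, 0.25)
        return occ / total


def tally_codes(codes: np.ndarray) -> PatternTally:
    """Tally pre-encoded columns (shape ``(L, 4)`` of 0-3 state indices)."""
    codes = np.asarray(codes, dtype=np.int64)
    if codes.ndim != 2 or codes.shape[1] != 4 or codes.shape[0] == 0:
        raise InputError("need a non-empty (L, 4) array of state indices")
    if codes.min() < 0 or codes.max() > 3:
        raise InputError("state indices must be in 0..3 (exclude sites first)")
    flat = ((codes[:, 0] * 4 + codes[:, 1]) * 4 + codes[:, 2]) * 4 + codes[:, 3]
    return PatternTally(np.bincount(flat, minlength=256))


def tally(qa) -> PatternTally:
    """Tally a :class:`phyquart.seqio.QuartetAlignment` (or raw code array)."""
    codes = qa.codes if hasattr(qa, "codes") else qa
    return tally_codes(codes)


def observed_polar_counts(t: PatternTally, topology: str, derived_half) -> tuple[int, int]:
    """Apomorphic support and plesiomorphy count for one polarized tree.

    For polarity ``z`` of ``topology`` with the derived direction towards
    ``derived_half`` (e.g. AB(CD) has derived half ``("C","D")``): sharing
    within the derived half is a putative synapomorphy, sharing within the
    ancestral half is plesiomorphic.  Returns ``(S_obs, rho)`` where
    ``S_obs = symmetric + asymmetric(derived half)`` and ``rho`` is the
    asymmetric count of the ancestral half; ``S_obs + rho == tau``.
    """
    derived = tuple(derived_half)
    halves = SPLIT_HALVES[topology]
    if derived not in halves:
        raise InputError(f"{derived} is not a split half of {topology}")
    ancestral = halves[1] if derived == halves[0] else halves[0]
    s_obs = t.symmetric(topology) + t.asymmetric(topology, derived)
    rho = t.asymmetric(topology, ancestral)
    return s_obs, rho
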
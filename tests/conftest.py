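import numpy as np
import pytest

from phyquart.patterns import ALL_CLASSES, CLASS_ID, PatternTally
from phyquart.substmodel import FittedQuartet, QuartetTree, SubstitutionModel


def code_of(pattern: str) -> int:
    """Base-4 code of a 4-letter pattern string, e.g. 'AACC' -> 5."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    a, b, c, d = (idx[ch] for ch in pattern)
    return ((a * 4 + b) * 4 + c) * 4 + d


def tally_from_patterns(pattern_counts: dict) -> PatternTally:
    """Build a tally from {'AACC': 3, ...}."""
    raw = np.zeros(256, dtype=np.int64)
    for pat, n in pattern_counts.items():
        raw[code_of(pat)] += n
    return PatternTally(raw)


def fake_fit(class_counts: dict, L: int) -> FittedQuartet:
    """A synthetic fitted quartet whose expected class counts at length ``L``
    equal ``class_counts`` (keyed by index into ALL_CLASSES or by
    PatternClass); remaining mass goes to the constant class."""
    from phyquart.patterns import CLASS_MASKS

    probs = np.zeros(256)
    assigned = 0.0
    for key, count in class_counts.items():
        cid = key if isinstance(key, int) else CLASS_ID[key]
        members = np.flatnonzero(CLASS_MASKS[cid])
        probs[members] += (count / L) / len(members)
        assigned += count / L
    if assigned > 1 + 1e-12:
        raise ValueError("class counts exceed L")
    constant = np.flatnonzero(CLASS_MASKS[0])
    probs[constant] += (1.0 - assigned) / len(constant)
    tree = QuartetTree("q1", (0.1,) * 5)
    return FittedQuartet(tree=tree, model=SubstitutionModel(), logL=0.0,
                         pattern_probs=probs)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(
        ">taxA\nACGTACGT\n>taxB\nACGTACGA\n>taxC\nACGAACGT\n>taxD\nTCGTACGT\n"
    )
    return path


@pytest.fixture
def phylip_file(tmp_path):
    path = tmp_path / "aln.phy"
    path.write_text(
        " 4 12\n"
        "taxonA  ACGTACGTACGT\n"
        "taxonB  ACGTACGTACGA\n"
        "taxonC  ACGAACGTACGT\n"
        "taxonD  TCGTACGTACGT\n"
    )
    return path
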
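"""Alignment and clan I/O, quartet enumeration, site filtering, reports.

Alignments are read from FASTA or PHYLIP (relaxed; sequential or interleaved
auto-detected via Biopython).  A clan file assigns taxa to exactly four
named groups; quartets are formed by drawing one taxon per clan.  Columns
holding anything other than A, C, G, T (after upper-casing and U->T mapping)
— gaps, ambiguity codes, missing data — are excluded, by default separately
per quartet so that a gap in a fifth taxon does not cost the quartet a site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

from phyquart.errors import DegenerateAlignmentError, InputError
from phyquart.patterns import ROLES, SPLIT_HALVES, TOPOLOGIES

@dataclass
class Alignment:
    """A multiple sequence alignment (upper-cased, equal-length rows)."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if not self.taxa:
            raise InputError("alignment has no sequences")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise InputError(f"duplicate taxon label(s): {', '.join(dupes)}")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise InputError("sequences have unequal lengths")
        if len(self.sequences[0]) == 0:
            raise InputError("zero-length alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def sequence(self, label: str) -> str:
        try:
            return self.sequences[self.taxa.index(label)]
        except ValueError:
            raise InputError(f"taxon {label!r} not in alignment") from None


@dataclass
class ClanAssignment:
    """Exactly four named, disjoint, non-empty taxon groups."""

    clans: dict

    def __post_init__(self):
        if len(self.clans) != 4:
            raise InputError(f"need exactly 4 clans, got {len(self.clans)}")
        seen: dict[str, str] = {}
        for name, members in self.clans.items():
            if not members:
                raise InputError(f"clan {name!r} is empty")
            for m in members:
                if m in seen:
                    raise InputError(f"taxon {m!r} in clans {seen[m]!r} and {name!r}")
                seen[m] = name


@dataclass
class QuartetAlignment:
    """Four role-assigned sequences after site exclusion, 0-3 encoded."""

    roles: dict
    codes: np.ndarray
    original_length: int

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[1] != 4:
            raise InputError("codes must have shape (L, 4)")

    @property
    def used_length(self) -> int:
        return self.codes.shape[0]


def _detect_format(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.lstrip().startswith(">") else "phylip"
    raise InputError(f"{path}: empty file")


def read_alignment(path, format: str = "auto") -> Alignment:
    """Read a FASTA or PHYLIP alignment (``format='auto'`` sniffs the file).

    Duplicate taxon labels and ragged sequences are input errors.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise InputError(f"{path}: no FASTA records")
        return Alignment([r.id for r in records], [str(r.seq) for r in records])
    if format == "phylip":
        text = path.read_text()
        last_err = None
        for dialect in ("phylip-relaxed", "phylip-sequential", "phylip"):
            try:
                aln = AlignIO.read(StringIO(text), dialect)
                return Alignment([r.id for r in aln], [str(r.seq) for r in aln])
            except Exception as e:  # Biopython raises bare ValueError here
                last_err = e
        raise InputError(f"{path}: cannot parse as PHYLIP ({last_err})")
    raise InputError(f"unknown alignment format {format!r}")


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n{seq}\n")


def read_clans(path) -> ClanAssignment:
    """Parse a clan file: four lines of ``clanName: tax1,tax2,...``."""
    clans: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise InputError(f"clan file line {lineno}: expected 'name: tax1,tax2,...'")
            name, _, rest = line.partition(":")
            name = name.strip()
            if name in clans:
                raise InputError(f"clan file line {lineno}: duplicate clan {name!r}")
            members = [t.strip() for t in rest.split(",") if t.strip()]
            clans[name] = members
    return ClanAssignment(clans)


def enumerate_quartets(aln: Alignment, clans: ClanAssignment | None = None) -> list[dict]:
    """All quartet role mappings, one taxon per clan, lexicographic order.

    Without clans the alignment must have exactly four taxa (one quartet, in
    input order).  Clan members absent from the alignment are skipped, not
    fatal.
    """
    if clans is None:
        if len(aln.taxa) != 4:
            raise InputError(
                f"alignment has {len(aln.taxa)} taxa; a 4-clan file is required"
            )
        return [dict(zip(ROLES, aln.taxa))]
    present = set(aln.taxa)
    pools = []
    for name, members in clans.clans.items():
        usable = [m for m in members if m in present]
        pools.append(usable)
    if any(not p for p in pools):
        return []
    return [dict(zip(ROLES, combo)) for combo in itertools.product(*pools)]


def missing_clan_labels(aln: Alignment, clans: ClanAssignment) -> list[str]:
    """Clan members absent from the alignment (left unanalysed)."""
    present = set(aln.taxa)
    return [m for members in clans.clans.values() for m in members if m not in present]


_CODE_LOOKUP = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE_LOOKUP[ord(_b)] = _i
_CODE_LOOKUP[ord("U")] = 3  # RNA


def _encode(seq: str) -> np.ndarray:
    return _CODE_LOOKUP[np.frombuffer(seq.upper().encode("ascii", "replace"), dtype=np.uint8)]


def extract_quartet(
    aln: Alignment, roles: dict, exclusion: str = "per_quartet"
) -> QuartetAlignment:
    """Pull the four role sequences out of the alignment and drop forbidden
    sites.

    ``per_quartet`` (default) drops a column iff any of the *four chosen*
    sequences has a non-ACGT symbol there; ``global`` drops it iff any
    sequence of the whole alignment does.
    """
    if exclusion not in ("per_quartet", "global"):
        raise InputError(f"unknown exclusion mode {exclusion!r}")
    codes = np.stack([_encode(aln.sequence(roles[r])) for r in ROLES], axis=1)
    if exclusion == "per_quartet":
        keep = (codes >= 0).all(axis=1)
    else:
        all_codes = np.stack([_encode(s) for s in aln.sequences], axis=1)
        keep = (all_codes >= 0).all(axis=1)
    kept = codes[keep]
    if kept.shape[0] == 0:
        raise DegenerateAlignmentError(
            "no columns remain after excluding gap/ambiguous sites"
        )
    return QuartetAlignment(roles=dict(roles), codes=kept, original_length=aln.length)


def _polarized_label(topo: str, derived) -> str:
    h1, h2 = SPLIT_HALVES[topo]
    a, b = "".join(h1), "".join(h2)
    return f"({a}){b}" if tuple(derived) == h1 else f"{a}({b})"


REPORT_COLUMNS = (
    ["taxon_A", "taxon_B", "taxon_C", "taxon_D"]
    + [f"lambda_{t}" for t in TOPOLOGIES]
    + [f"theta_{_polarized_label(t, h)}" for t in TOPOLOGIES for h in SPLIT_HALVES[t]]
    + ["omega_obs", "used_length"]
)


def write_report(scores, path) -> None:
    """Write per-quartet scores as a TSV: role labels, the three normalized
    weights, the six polarized scores, omega_obs and the used length
    (6-decimal fixed point), one line per quartet in enumeration order."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for sc in scores:
            roles = sc.roles or dict(zip(ROLES, ROLES))
            row = [roles[r] for r in ROLES]
            row += [f"{sc.lam[t]:.6f}" for t in TOPOLOGIES]
            row += [
                f"{sc.theta[(t, h)]:.6f}"
                for t in TOPOLOGIES
                for h in SPLIT_HALVES[t]
            ]
            row += [f"{sc.omega_obs:.6f}", str(sc.used_length)]
            fh.write("\t".join(row) + "\n")
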
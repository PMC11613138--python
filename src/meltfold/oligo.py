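"""Oligonucleotide sequence model and fold-topology enumeration.

The serum response element (SRE) of the *c-Fos* promoter is a partially
palindromic sequence: two 7-bp inverted-repeat arms flank a central 6-nt
A/T tract.  A single sense strand cut symmetrically around that tract can
fold back on itself into a hairpin (unimolecular) or associate with a
second copy of itself into an antiparallel mismatched homoduplex
(bimolecular).  This module builds those segments (``SREsegN``), enumerates
both fold topologies and computes single-strand molecular weights.

Position numbering convention: bases are labelled …,−2,−1,1,2,… outward
from the centre of the palindrome; 0 is never used.  Position −k pairs with
+k in the hairpin stem.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "OligoSequence",
    "FoldTopology",
    "WC_COMPLEMENT",
    "MONOMER_MASS",
    "MASS_OFFSET",
    "build_sre_segment",
    "enumerate_hairpin_fold",
    "enumerate_homoduplex_fold",
    "molecular_weight",
    "positions_for_length",
    "position_to_index",
    "index_to_position",
    "read_fasta",
    "write_fasta",
    "fold_report_tsv",
    "fold_diagram",
]

#: Watson–Crick complement map (DNA).
WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Monomer masses (g/mol) of the Oligo Calc single-strand DNA convention
#: (linear, unmodified, 5'-OH).  Alternative conventions (5'-phosphate,
#: other average-isotope tables) are deliberately not provided.
MONOMER_MASS = {"A": 313.21, "T": 304.2, "C": 289.18, "G": 329.21}

#: Constant subtracted once per strand in the same convention (removal of
#: one HPO2 group plus addition of two terminal H/OH, lumped).
MASS_OFFSET = 61.96

# Sense-strand bases of the SRE segment, positions −10…−1, 1…10.  The two
# 7-bp inverted-repeat arms are GATGTCC / GGACATC; the central tract is the
# A/T hexamer ATATTA.
_SRE_SENSE_20 = "GATGTCCATATTAGGACATC"

#: Lengths for which the central segment sequence is available.
SUPPORTED_LENGTHS = (12, 14, 16, 18, 20)

#: Lengths the study series defines but whose flanking bases are not part
#: of the shipped sequence table.
KNOWN_UNAVAILABLE_LENGTHS = (28, 36)


def positions_for_length(n: int) -> tuple[int, ...]:
    """Symmetric no-zero position labels −n/2…−1, 1…n/2 for an even n."""
    if n < 2 or n % 2:
        raise ValueError(f"symmetric numbering requires an even length >= 2, got {n}")
    half = n // 2
    return tuple(range(-half, 0)) + tuple(range(1, half + 1))


def position_to_index(position: int, n: int) -> int:
    """Convert a no-zero position label to a 0-based array index."""
    if position == 0:
        raise ValueError("position 0 does not exist in the no-zero numbering")
    half = n // 2
    if not -half <= position <= half:
        raise ValueError(f"position {position} outside ±{half}")
    return position + half if position < 0 else position + half - 1


def index_to_position(index: int, n: int) -> int:
    """Inverse of :func:`position_to_index`."""
    if not 0 <= index < n:
        raise IndexError(f"index {index} outside 0..{n - 1}")
    half = n // 2
    return index - half if index < half else index - half + 1


@dataclass(frozen=True)
class OligoSequence:
    """A single DNA strand with explicit per-base position labels.

    Parameters
    ----------
    name : str
        Sample name, e.g. ``"SREseg16"``.
    bases : str
        Bases 5'→3', alphabet ACGT.
    positions : tuple of int
        Strictly increasing integer labels, one per base, never 0.
    """

    name: str
    bases: str
    positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if len(bases) < 1:
            raise ValueError("empty sequence")
        bad = set(bases) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT bases: {sorted(bad)}")
        if not self.positions:
            if len(bases) % 2 == 0:
                object.__setattr__(self, "positions", positions_for_length(len(bases)))
            else:
                object.__setattr__(self, "positions", tuple(range(1, len(bases) + 1)))
        positions = self.positions
        if len(positions) != len(bases):
            raise ValueError("positions and bases differ in length")
        if 0 in positions:
            raise ValueError("0 is not a valid position label")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.bases)

    @property
    def molecular_weight(self) -> float:
        return molecular_weight(self)

    def base_at(self, position: int) -> str:
        """Base at a given position label."""
        try:
            i = self.positions.index(position)
        except ValueError:
            raise KeyError(f"position {position} not in {self.name}") from None
        return self.bases[i]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}: 5'-{self.bases}-3'"


@dataclass(frozen=True)
class FoldTopology:
    """Base-pairing scheme of a hairpin or antiparallel homoduplex.

    ``pairs`` holds ``(position_a, position_b, is_wc)`` triples; for the
    homoduplex, ``position_a`` is on strand A and ``position_b`` on the
    second (identical) strand.  ``loop_positions`` is empty for duplexes.
    """

    kind: str  # "hairpin" | "homoduplex"
    pairs: tuple[tuple[int, int, bool], ...]
    loop_positions: tuple[int, ...]
    n_wc: int
    molecularity: int

    def __post_init__(self) -> None:
        if self.kind not in ("hairpin", "homoduplex"):
            raise ValueError(f"unknown fold kind {self.kind!r}")
        if self.n_wc != sum(1 for *_, wc in self.pairs if wc):
            raise ValueError("n_wc inconsistent with pair flags")
        seen_a = [a for a, _, _ in self.pairs]
        if len(seen_a) != len(set(seen_a)):
            raise ValueError("a position appears twice in one pairing role")

    @property
    def mismatch_positions(self) -> tuple[int, ...]:
        """Strand-A positions engaged in non-WC (mismatch) pairs."""
        return tuple(a for a, _, wc in self.pairs if not wc)


def is_wc(a: str, b: str) -> bool:
    return WC_COMPLEMENT[a.upper()] == b.upper()


def build_sre_segment(n: int) -> OligoSequence:
    """Central n-mer of the SRE sense strand, symmetric about the A/T tract.

    Positions run −n/2…−1, 1…n/2.  Only n in {12, 14, 16, 18, 20} have a
    shipped sequence; 28 and 36 belong to the study series but their
    flanking bases are not part of the shipped table.
    """
    if n in KNOWN_UNAVAILABLE_LENGTHS:
        raise ValueError(
            f"flank sequence unavailable for SREseg{n}: bases beyond ±10 are "
            f"not in the shipped sequence table"
        )
    if n not in SUPPORTED_LENGTHS:
        raise ValueError(
            f"unsupported segment length {n}; supported: {SUPPORTED_LENGTHS} "
            f"(28 and 36 defined but flanks unavailable)"
        )
    trim = (20 - n) // 2
    bases = _SRE_SENSE_20[trim : 20 - trim]
    return OligoSequence(name=f"SREseg{n}", bases=bases, positions=positions_for_length(n))


def enumerate_hairpin_fold(seq: OligoSequence, min_loop: int = 3) -> FoldTopology:
    """Contiguous-stem hairpin: pair ends inward until the first non-WC pair.

    No bulges or internal loops are considered — stem growth stops at the
    first mismatch and everything inside it is assigned to the loop.
    """
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    n = seq.n
    if n < min_loop + 2:
        raise ValueError(f"sequence of {n} nt cannot close a loop of >= {min_loop}")
    max_pairs = (n - min_loop) // 2
    pairs: list[tuple[int, int, bool]] = []
    for k in range(max_pairs):
        a, b = seq.bases[k], seq.bases[n - 1 - k]
        if not is_wc(a, b):
            break
        pairs.append((seq.positions[k], seq.positions[n - 1 - k], True))
    n_stem = len(pairs)
    loop = seq.positions[n_stem : n - n_stem]
    return FoldTopology(
        kind="hairpin",
        pairs=tuple(pairs),
        loop_positions=tuple(loop),
        n_wc=n_stem,
        molecularity=1,
    )


def enumerate_homoduplex_fold(seq: OligoSequence) -> FoldTopology:
    """Antiparallel alignment of two copies: base i opposite base N+1−i.

    Every opposed pair is recorded and flagged WC or mismatch; ``n_wc``
    counts WC pairs over all N positions.
    """
    n = seq.n
    pairs = []
    for i in range(n):
        j = n - 1 - i
        pairs.append(
            (seq.positions[i], seq.positions[j], is_wc(seq.bases[i], seq.bases[j]))
        )
    return FoldTopology(
        kind="homoduplex",
        pairs=tuple(pairs),
        loop_positions=(),
        n_wc=sum(1 for *_, wc in pairs if wc),
        molecularity=2,
    )


def molecular_weight(seq: OligoSequence | str) -> float:
    """Single-strand mass (g/mol), Oligo Calc linear 5'-OH DNA convention."""
    bases = seq.bases if isinstance(seq, OligoSequence) else seq.upper()
    if not bases:
        raise ValueError("empty sequence has no molecular weight")
    bad = set(bases) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT bases: {sorted(bad)}")
    return sum(MONOMER_MASS[b] for b in bases) - MASS_OFFSET


def pair_label(seq: OligoSequence, pos_a: int, pos_b: int) -> str:
    """Stem-pair label: plus-strand base first, then its partner, then |pos|.

    The pair (−8, +8) of SREseg16 (T·A) is written ``AT_8``: the first
    letter is the base at the positive position.
    """
    if pos_a > 0:
        plus, minus = pos_a, pos_b
    else:
        plus, minus = pos_b, pos_a
    return f"{seq.base_at(plus)}{seq.base_at(minus)}_{abs(plus)}"


# ---------------------------------------------------------------------------
# I/O helpers


def read_fasta(path_or_handle) -> list[OligoSequence]:
    """Read sequences from FASTA; symmetric no-zero numbering is assigned to
    even-length records, 1…N to odd-length ones."""
    records = list(SeqIO.parse(path_or_handle, "fasta"))
    return [OligoSequence(name=r.id, bases=str(r.seq)) for r in records]


def write_fasta(seqs: Iterable[OligoSequence], path_or_handle) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.name, description="") for s in seqs]
    SeqIO.write(records, path_or_handle, "fasta")


def fold_report_tsv(fold: FoldTopology) -> str:
    """Pair table as TSV text: pair_a, pair_b, wc_flag."""
    lines = ["pair_a\tpair_b\twc_flag"]
    for a, b, wc in fold.pairs:
        lines.append(f"{a}\t{b}\t{int(wc)}")
    return "\n".join(lines) + "\n"


def fold_diagram(seq: OligoSequence, fold: FoldTopology) -> str:
    """Human-readable pairing diagram for logs."""
    if fold.kind == "hairpin":
        n_stem = len(fold.pairs)
        top = seq.bases[:n_stem]
        bot = seq.bases[::-1][:n_stem]
        loop = "".join(seq.base_at(p) for p in fold.loop_positions)
        return (
            f"{seq.name} hairpin ({fold.n_wc} WC pairs)\n"
            f"5'-{top}  loop[{loop}]\n"
            f"   {'|' * n_stem}\n"
            f"3'-{bot}\n"
        )
    marks = "".join("|" if wc else "." for *_, wc in fold.pairs)
    return (
        f"{seq.name} homoduplex ({fold.n_wc} WC pairs of {len(fold.pairs)})\n"
        f"5'-{seq.bases}-3'\n"
        f"   {marks}\n"
        f"3'-{seq.bases[::-1]}-5'\n"
    )
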
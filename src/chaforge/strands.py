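"""DNA strand primitives: sequences, complementarity search, G-tract scanning.

All sequences are DNA written 5'->3' over the strict alphabet {A, C, G, T}.
Internally every index is 0-based half-open; everything reported to the user
(:class:`DuplexMatch`, G-tract coordinates) is 1-based inclusive, matching the
convention used at the bench.
"""

from __future__ import annotations

import re
from collections.abc import Iterator
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideStrand",
    "OligoPanel",
    "DuplexMatch",
    "reverse_complement",
    "longest_complementary_duplex",
    "find_g_tracts",
    "load_panel",
    "write_fasta",
    "table1_panel",
    "BUILTIN_PANEL",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

#: Token accepted by :func:`load_panel` to request the built-in oligo panel.
BUILTIN_PANEL = "builtin"

# The four oligos of the thrombin CHA sensor: the thrombin-binding aptamer,
# the trigger strand S held in the Aptamer.S probe duplex, and the two
# metastable hairpins H1/H2 whose assembled duplex carries a G-quadruplex
# forming tail at each end.
_BUILTIN_SEQUENCES = {
    "Aptamer": "GGTTGGTGTGGTTGGAATAGTC",
    "S": "AGTCACACGGACTATTCCAACC",
    "H1": "GGGTAATAGTCCGTGTGACTATGGACTATAGGAGTCACACGGGCGGGTAGGG",
    "H2": "GGGTTGTATGACTCCTATAGTCCATAGTCACACGGACTATTGGGCGGGTAGGG",
}


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


@dataclass(frozen=True)
class NucleotideStrand:
    """A named DNA strand, bases written 5'->3'.

    Whitespace is stripped on construction (printed sequences are often
    space-grouped in triplets); anything else outside ACGT is rejected.
    """

    name: str
    bases: str
    note: str = ""

    def __post_init__(self) -> None:
        bases = re.sub(r"\s+", "", self.bases).upper()
        object.__setattr__(self, "bases", bases)
        if not self.name:
            raise ValueError("strand name must be non-empty")
        if not bases:
            raise ValueError(f"strand {self.name!r} has an empty sequence")
        for pos, ch in enumerate(bases):
            if ch not in _COMPLEMENT:
                raise AlphabetError(
                    f"strand {self.name!r}: invalid character {ch!r} at "
                    f"position {pos + 1} (alphabet is A/C/G/T; U and IUPAC "
                    "ambiguity codes are not supported)"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class OligoPanel:
    """Ordered, name-unique collection of strands."""

    _strands: dict[str, NucleotideStrand] = field(default_factory=dict)

    def add(self, strand: NucleotideStrand) -> None:
        if strand.name in self._strands:
            raise ValueError(f"duplicate strand name {strand.name!r}")
        self._strands[strand.name] = strand

    def __getitem__(self, name: str) -> NucleotideStrand:
        return self._strands[name]

    def __contains__(self, name: str) -> bool:
        return name in self._strands

    def __iter__(self) -> Iterator[NucleotideStrand]:
        return iter(self._strands.values())

    def __len__(self) -> int:
        return len(self._strands)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OligoPanel):
            return NotImplemented
        return list(self) == list(other)

    @property
    def names(self) -> list[str]:
        return list(self._strands)


@dataclass(frozen=True)
class DuplexMatch:
    """Longest perfect antiparallel Watson-Crick segment between two strands.

    ``start_a``/``start_b`` are 1-based positions of the 5'-most base of the
    segment on each strand; ``length`` is the base-pair count. A zero-length
    match reports both starts as 0.
    """

    start_a: int
    start_b: int
    length: int


def reverse_complement(strand: NucleotideStrand) -> NucleotideStrand:
    """Antiparallel Watson-Crick complement (an involution)."""
    rc = "".join(_COMPLEMENT[b] for b in reversed(strand.bases))
    return NucleotideStrand(strand.name, rc, strand.note)


def longest_complementary_duplex(
    a: NucleotideStrand, b: NucleotideStrand
) -> DuplexMatch:
    """Longest contiguous segment where ``a`` (5'->3') pairs ``b`` (3'->5').

    Only perfect A.T / G.C pairs count (no wobble). Ties are broken by the
    smallest start on ``a``, then the smallest start on ``b``.
    """
    sa = a.bases
    rb = reverse_complement(b).bases  # match = common substring of a and rc(b)
    n, m = len(sa), len(rb)
    # suffix-run dynamic programme over (a index, rc(b) index)
    best = (0, 0, 0)  # (length, start_a0, start_b0)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for p in range(1, m + 1):
            if sa[i - 1] == rb[p - 1]:
                run = prev[p - 1] + 1
                cur[p] = run
                start_a0 = i - run
                start_b0 = len(b.bases) - (p - 1) - run  # 5' start on b
                cand = (run, start_a0, start_b0)
                if run > best[0] or (
                    run == best[0]
                    and (start_a0, start_b0) < (best[1], best[2])
                    and run > 0
                ):
                    best = cand
        prev = cur
    length, a0, b0 = best
    if length == 0:
        return DuplexMatch(0, 0, 0)
    return DuplexMatch(a0 + 1, b0 + 1, length)


def find_g_tracts(
    strand: NucleotideStrand, min_len: int
) -> list[tuple[int, int]]:
    """Maximal runs of G of length >= ``min_len``, as 1-based (start, length).

    Four or more tracts of >= 3 guanines are the classic sequence signature of
    an intramolecular G-quadruplex; the thrombin aptamer's two-tier quadruplex
    shows up at ``min_len = 2``.
    """
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    return [
        (m.start() + 1, len(m.group()))
        for m in re.finditer("G{%d,}" % min_len, strand.bases)
    ]


def table1_panel() -> OligoPanel:
    """The built-in four-oligo panel of the thrombin CHA sensor."""
    panel = OligoPanel()
    for name, seq in _BUILTIN_SEQUENCES.items():
        panel.add(NucleotideStrand(name, seq))
    return panel


def load_panel(source: str | Path) -> OligoPanel:
    """Load a panel from a FASTA file, or return the built-in panel.

    ``source == "builtin"`` yields the shipped thrombin-sensor oligos.
    """
    if isinstance(source, str) and source == BUILTIN_PANEL:
        return table1_panel()
    path = Path(source)
    panel = OligoPanel()
    with open(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    for rec in records:
        if not str(rec.seq):
            raise ValueError(f"empty record {rec.id!r} in {path}")
        note = rec.description.removeprefix(rec.id).strip()
        panel.add(NucleotideStrand(rec.id, str(rec.seq), note))
    return panel


def write_fasta(panel: OligoPanel, path: str | Path) -> None:
    """Write a panel as standard 60-column FASTA, one record per strand."""
    if len(panel) == 0:
        raise ValueError("cannot write an empty panel")
    records = [
        SeqRecord(Seq(s.bases), id=s.name, description="") for s in panel
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
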
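"""Frameshift translation core.

A bacterial coding sequence read from its second nucleotide onward is the
"+1 frameshift" (+1 fs) of the gene; read from its third nucleotide it is the
"-1 frameshift" (-1 fs).  Every downstream codon changes, so the shifted
frames carry their own stop-codon inventory ("hidden stops"); whether the
strongest terminator, TAA, appears in a shifted frame is the screening
signal used throughout this package.

Conventions (used everywhere downstream):

* shift labels: ``+1`` removes the first nucleotide, ``-1`` removes the
  first two, ``0`` is the identity.  Some of the literature calls reading
  from the third nucleotide "+2"; we keep the +1/-1 labels.
* codon indices are 1-based within the shifted frame ("the 11th codon").
* translation never terminates at a stop codon: internal stops are rendered
  ``'*'`` and inventoried, modelling ribosomal readthrough.  Truncation at a
  chosen stop is a separate, explicit operation (:mod:`hiddenframe.variants`).
* a trailing 1-2 nt that do not complete a codon after shifting are dropped
  and counted in ``dropped_tail_nt``, never padded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio.Data import CodonTable

__all__ = [
    "STOP_CODONS",
    "LEAKINESS_RANK",
    "SHIFT_OFFSETS",
    "CodingSequence",
    "StopCodonEvent",
    "FrameShiftVariant",
    "shift_frame",
    "translate",
    "find_internal_stops",
    "codon_to_aa_map",
]

#: The three bacterial stop codons.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Termination efficiency order TAA > TAG > TGA: rank 1 is the strongest
#: terminator, rank 3 (TGA, the opal codon) the leakiest.
LEAKINESS_RANK = {"TAA": 1, "TAG": 2, "TGA": 3}

#: Number of 5' nucleotides removed by each shift label.
SHIFT_OFFSETS = {0: 0, +1: 1, -1: 2}

_VALID_BASES = frozenset("ACGTN")


def _normalize_shift(shift) -> int:
    try:
        s = int(shift)
    except (TypeError, ValueError):
        raise ValueError(f"invalid shift {shift!r}; expected +1, -1 or 0")
    if s not in SHIFT_OFFSETS:
        raise ValueError(f"invalid shift {shift!r}; expected +1, -1 or 0")
    return s


@dataclass(frozen=True)
class CodingSequence:
    """A named DNA sequence assumed to be a protein-coding ORF in frame 0.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header token, locus tag, ...).
    seq : str
        DNA over ``A/C/G/T/N``; lowercase input is uppercased.  Any other
        IUPAC ambiguity code is rejected: stop detection would be
        ill-defined on, say, ``TRA``.
    description : str
        Free text carried along into reports.
    includes_stop : bool
        Whether the canonical terminal stop codon is part of ``seq``.  When
        true, the stop's nucleotides remain part of the shifted frames (the
        canonical stop cannot terminate a shifted translation).
    """

    id: str
    seq: str
    description: str = ""
    includes_stop: bool = True

    def __post_init__(self):
        seq = str(self.seq).upper().replace("U", "T")
        object.__setattr__(self, "seq", seq)
        if len(seq) < 3:
            raise ValueError(f"{self.id}: sequence length {len(seq)} < 3")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)}; only A/C/G/T/N "
                "are accepted (ambiguity codes other than N are rejected)"
            )
        if self.includes_stop and len(seq) % 3 == 0:
            last = seq[-3:]
            if last not in STOP_CODONS and "N" not in last:
                warnings.warn(
                    f"{self.id}: includes_stop is set but final codon {last} "
                    "is not a stop codon",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class StopCodonEvent:
    """One internal stop occurrence in a (shifted) reading frame."""

    codon: str
    index: int  # 1-based codon position within the shifted frame

    def __post_init__(self):
        if self.codon not in STOP_CODONS:
            raise ValueError(f"{self.codon!r} is not a stop codon")
        if self.index < 1:
            raise ValueError("codon index is 1-based; got " f"{self.index}")

    @property
    def leakiness_rank(self) -> int:
        """1 for TAA (strongest terminator), 2 for TAG, 3 for TGA."""
        return LEAKINESS_RANK[self.codon]


@dataclass(frozen=True)
class FrameShiftVariant:
    """A shifted derivative of a coding sequence, optionally translated.

    ``protein`` is ``None`` until :func:`translate` fills it; stops are then
    exactly the '*' positions of ``protein`` in ascending codon order.
    """

    parent_id: str
    shift: int
    shifted_seq: str
    dropped_tail_nt: int
    protein: str | None = None
    stops: tuple[StopCodonEvent, ...] = field(default=())
    table_id: int | None = None

    @property
    def n_codons(self) -> int:
        return len(self.shifted_seq) // 3

    def codon(self, index: int) -> str:
        """The 1-based ``index``-th codon of the shifted frame."""
        if not 1 <= index <= self.n_codons:
            raise IndexError(f"codon index {index} out of range 1..{self.n_codons}")
        return self.shifted_seq[3 * (index - 1) : 3 * index]


def shift_frame(cds: CodingSequence, shift) -> FrameShiftVariant:
    """Build the +1/-1/0 frame-shifted derivative of ``cds`` (untranslated).

    The +1 frame starts at nucleotide 2, the -1 frame at nucleotide 3; the
    canonical stop codon's nucleotides (when present) stay in the shifted
    sequence.  1-2 trailing nucleotides that no longer complete a codon are
    recorded in ``dropped_tail_nt`` and excluded from translation.
    """
    s = _normalize_shift(shift)
    offset = SHIFT_OFFSETS[s]
    if len(cds.seq) < 3 + offset:
        raise ValueError(
            f"{cds.id}: sequence too short to shift "
            f"(length {len(cds.seq)}, shift {s:+d} needs >= {3 + offset} nt)"
        )
    shifted = cds.seq[offset:]
    return FrameShiftVariant(
        parent_id=cds.id,
        shift=s,
        shifted_seq=shifted,
        dropped_tail_nt=len(shifted) % 3,
    )


def codon_to_aa_map(table_id: int = 11) -> dict:
    """Codon -> amino-acid dict for an NCBI genetic-code table, stops as '*'.

    Table 11 (bacterial/archaeal/plastid) is the default; it shares the
    standard code's codon assignments but is the appropriate table for the
    organisms this package targets.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[int(table_id)]
    except KeyError:
        raise ValueError(f"unknown genetic code table id {table_id!r}")
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate(variant: FrameShiftVariant, table_id: int = 11) -> FrameShiftVariant:
    """Translate a shifted frame codon-by-codon without terminating at stops.

    Stop codons yield ``'*'`` plus a :class:`StopCodonEvent`; codons
    containing ``N`` yield ``'X'`` and are never counted as stops.
    """
    mapping = codon_to_aa_map(table_id)
    seq = variant.shifted_seq
    residues = []
    stops = []
    for i in range(variant.n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if "N" in codon:
            residues.append("X")
            continue
        aa = mapping[codon]
        residues.append(aa)
        if aa == "*":
            stops.append(StopCodonEvent(codon=codon, index=i + 1))
    return replace(
        variant,
        protein="".join(residues),
        stops=tuple(stops),
        table_id=int(table_id),
    )


def find_internal_stops(
    variant: FrameShiftVariant, exclude_terminal: bool = False
) -> list[StopCodonEvent]:
    """Stop events of a translated frame, 1-based, ascending.

    Codon position 1 counts as internal (a shifted frame can open on a
    stop).  With ``exclude_terminal``, a stop occupying the final complete
    codon is omitted — used when inventorying the canonical frame, whose
    own terminal stop is not an internal stop.
    """
    if variant.protein is None:
        raise ValueError("variant is untranslated; call translate() first")
    stops = list(variant.stops)
    if exclude_terminal and stops and stops[-1].index == variant.n_codons:
        stops = stops[:-1]
    return stops
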
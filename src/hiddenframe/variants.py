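"""Stop-substitution variant libraries and the relative-toxicity statistic.

A shifted frame with k internal stops is made fully translatable by
replacing each stop codon with a sense codon.  Substituting each stop by
every one of the 20 standard residues gives a 20^k library (400 variants for
the two-stop case) whose members can then be assayed; the wet-lab readout is
summarized by

    relative toxicity = 100 x (1 - colonies with induction / colonies without)

with 100% meaning no colony grows when the protein is expressed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

from .core import FrameShiftVariant

__all__ = [
    "AA20",
    "ECOLI_PREFERRED_CODON",
    "StopSubstitutionVariant",
    "ToxicityMeasurement",
    "enumerate_stop_substitutions",
    "relative_toxicity",
    "summarize_library_toxicity",
    "truncate_at_stop",
]

#: The 20 standard residues in the fixed enumeration order.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Most-frequent codon per residue in E. coli K-12 highly expressed genes;
#: used to realize amino-acid substitutions as DNA.
ECOLI_PREFERRED_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class StopSubstitutionVariant:
    """One member of a stop-substitution library."""

    parent_id: str
    substitutions: tuple[tuple[int, str, str], ...]  # (stop codon index, aa, codon)
    dna: str
    protein: str

    @property
    def label(self) -> str:
        """Residue string in stop order, e.g. 'PK' for P at the first stop."""
        return "".join(aa for _, aa, _ in self.substitutions)


def enumerate_stop_substitutions(
    variant: FrameShiftVariant,
    codon_policy="ecoli-max",
    limit: int = 4,
) -> list[StopSubstitutionVariant]:
    """All 20^k amino-acid substitution variants of a k-stop frame.

    Enumeration is the Cartesian product of :data:`AA20` over the stop
    positions in ascending index order, so the output order is
    lexicographic in the substitution label ('AA', 'AC', ... 'YY').  Each
    residue is realized as one DNA codon per ``codon_policy`` (the name
    ``'ecoli-max'`` for the built-in table, or a residue->codon mapping);
    at the protein level any codon choice is equivalent.
    """
    if variant.protein is None:
        raise ValueError("variant is untranslated; call translate() first")
    if isinstance(codon_policy, str):
        if codon_policy != "ecoli-max":
            raise ValueError(f"unknown codon policy {codon_policy!r}")
        codon_of = ECOLI_PREFERRED_CODON
    else:
        codon_of = dict(codon_policy)
    stops = variant.stops
    k = len(stops)
    if k > limit:
        raise ValueError(
            f"library too large: {k} stops would give 20^{k} variants "
            f"(limit 20^{limit})"
        )
    out = []
    for combo in itertools.product(AA20, repeat=k):
        dna = list(variant.shifted_seq)
        protein = list(variant.protein)
        subs = []
        for event, aa in zip(stops, combo):
            pos = 3 * (event.index - 1)
            dna[pos : pos + 3] = codon_of[aa]
            protein[event.index - 1] = aa
            subs.append((event.index, aa, codon_of[aa]))
        out.append(
            StopSubstitutionVariant(
                parent_id=variant.parent_id,
                substitutions=tuple(subs),
                dna="".join(dna),
                protein="".join(protein),
            )
        )
    return out


@dataclass(frozen=True)
class ToxicityMeasurement:
    """Colony counts with/without induction and the derived statistic."""

    variant_id: str
    counts_with_iptg: int
    counts_without_iptg: int

    @property
    def relative_toxicity(self) -> float:
        return relative_toxicity(self.counts_with_iptg, self.counts_without_iptg)


def relative_toxicity(counts_with_iptg: float, counts_without_iptg: float) -> float:
    """100 x (1 - with/without), clamped to [0, 100].

    100% toxicity = no colony forms under induction.  More colonies with
    induction than without would give a negative value; that is clamped to
    0 with a warning since the statistic is defined as a percentage of
    growth inhibition.
    """
    if counts_with_iptg < 0 or counts_without_iptg < 0:
        raise ValueError("colony counts must be >= 0")
    if counts_without_iptg == 0:
        raise ValueError("no-induction plate empty; toxicity undefined")
    value = 100.0 * (1.0 - counts_with_iptg / counts_without_iptg)
    if value < 0:
        warnings.warn(
            "more colonies with induction than without; clamping toxicity to 0",
            stacklevel=2,
        )
        return 0.0
    return value


def summarize_library_toxicity(measurements, threshold: float = 50.0) -> dict:
    """Fraction of variants at or above a toxicity threshold."""
    ms = list(measurements)
    if not ms:
        raise ValueError("empty measurement list")
    n_toxic = sum(1 for m in ms if m.relative_toxicity >= threshold)
    return {
        "threshold": threshold,
        "n_toxic": n_toxic,
        "n_total": len(ms),
        "fraction_toxic": n_toxic / len(ms),
    }


def truncate_at_stop(variant: FrameShiftVariant, stop_choice="first_any") -> str:
    """Protein truncated at (excluding) a chosen stop codon.

    ``stop_choice`` is ``'first_TAA'``, ``'first_any'`` or a 1-based codon
    index that must hold a stop.  A stop at codon 1 yields an empty
    protein (with a warning) — the geometry of a +1 frame that opens on
    TGA.
    """
    if variant.protein is None:
        raise ValueError("variant is untranslated; call translate() first")
    stops = variant.stops
    if stop_choice == "first_any":
        if not stops:
            raise ValueError(f"{variant.parent_id}: no stop codon in frame")
        idx = stops[0].index
    elif stop_choice == "first_TAA":
        taa = [e for e in stops if e.codon == "TAA"]
        if not taa:
            raise ValueError(f"{variant.parent_id}: no TAA stop codon in frame")
        idx = taa[0].index
    else:
        idx = int(stop_choice)
        if not any(e.index == idx for e in stops):
            raise ValueError(f"{variant.parent_id}: no stop at codon {idx}")
    if idx == 1:
        warnings.warn("stop at codon 1; truncated protein is empty", stacklevel=2)
    return variant.protein[: idx - 1]
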
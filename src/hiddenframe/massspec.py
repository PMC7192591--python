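"""Mass-spectrometry expectation math for protein validation.

Two kinds of expectation are computed, mirroring how intact proteins and
their tryptic peptides are actually measured:

* intact masses (ESI-TOF deconvolution of a ~10 kDa protein reports the
  *average* mass): residue-mass sum + water, optionally after stripping the
  initiator Met (bacterial N-terminal Met excision) and adding a cation
  adduct (H+ or K+) — the "M-Met+H+" / "M-Met+K+" conventions;
* singly-charged b/y fragment series of tryptic peptides (tandem MS works
  in *monoisotopic* masses): b_i = sum of the first i residues + proton,
  y_j = sum of the last j residues + water + proton.

Residue masses come from pyteomics' standard tables; no PTMs, no isotope
labelling, singly-charged ions only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from pyteomics import mass as _pmass

__all__ = [
    "PROTON",
    "WATER_MONO",
    "WATER_AVG",
    "ADDUCT_MASSES",
    "MassSpecExpectation",
    "PeptideFragmentTable",
    "protein_mass",
    "expected_intact_mass",
    "tryptic_digest",
    "fragment_ions",
]

#: Mass of a proton (H+ adduct), Da.
PROTON = 1.00727646688
WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)

#: Cation adduct masses, Da.  K+ is potassium minus one electron; the
#: monoisotopic value is the default, the average value selectable.
ADDUCT_MASSES = {
    ("none", "monoisotopic"): 0.0,
    ("none", "average"): 0.0,
    ("H+", "monoisotopic"): PROTON,
    ("H+", "average"): PROTON,
    ("K+", "monoisotopic"): 38.9632,
    ("K+", "average"): 39.0978,
}

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _check(protein: str) -> str:
    if not protein:
        raise ValueError("empty protein")
    protein = protein.upper()
    bad = set(protein) - _VALID_AA
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)} (truncate '*' first)")
    return protein


def protein_mass(protein: str, kind: str = "average") -> float:
    """Neutral mass in Da: sum of residue masses + water."""
    protein = _check(protein)
    if kind not in ("average", "monoisotopic"):
        raise ValueError(f"unknown mass kind {kind!r}")
    return _pmass.calculate_mass(sequence=protein, average=(kind == "average"))


@dataclass(frozen=True)
class MassSpecExpectation:
    """Expected intact-protein mass under a stated convention."""

    protein_id: str
    base_protein: str
    met_removed: bool
    mass_kind: str
    adduct: str
    expected_mass: float

    def __post_init__(self):
        if self.expected_mass <= 0:
            raise ValueError("expected_mass must be positive")


def expected_intact_mass(
    protein: str,
    remove_init_met: bool = False,
    adduct: str = "none",
    kind: str = "average",
    adduct_mass_kind: str = "monoisotopic",
    protein_id: str = "",
) -> MassSpecExpectation:
    """Expected deconvoluted mass of an intact protein.

    ``remove_init_met`` strips the initiator Met (error if the protein
    does not start with M); ``adduct`` is ``'H+'``, ``'K+'`` or
    ``'none'``.  ``kind`` selects average (default, matching ESI-TOF
    deconvolution) or monoisotopic residue masses; the K+ adduct mass is
    monoisotopic by default, independently selectable.
    """
    protein = _check(protein)
    base = protein
    if remove_init_met:
        if not protein.startswith("M"):
            raise ValueError("remove_init_met: protein does not start with M")
        base = protein[1:]
        if not base:
            raise ValueError("nothing left after removing initiator Met")
    try:
        adduct_mass = ADDUCT_MASSES[(adduct, adduct_mass_kind)]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r} / adduct_mass_kind {adduct_mass_kind!r}"
        ) from None
    return MassSpecExpectation(
        protein_id=protein_id,
        base_protein=protein,
        met_removed=remove_init_met,
        mass_kind=kind,
        adduct=adduct,
        expected_mass=protein_mass(base, kind) + adduct_mass,
    )


_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


def tryptic_digest(protein: str, missed_cleavages: int = 0) -> list[str]:
    """In-silico trypsin digest: cleave C-terminal of K/R unless followed by P.

    Returns an ordered list (N- to C-terminal); the zero-missed-cleavage
    peptides concatenate back to the input.  With ``missed_cleavages = m``
    every merge of up to ``m + 1`` adjacent fully-cleaved peptides is also
    emitted, ordered by start position then length.
    """
    protein = _check(protein)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    pieces = [p for p in _TRYPSIN.split(protein) if p]
    out = []
    for start in range(len(pieces)):
        for width in range(1, missed_cleavages + 2):
            if start + width > len(pieces):
                break
            out.append("".join(pieces[start : start + width]))
    return out


@dataclass(frozen=True)
class PeptideFragmentTable:
    """Singly-charged b/y series of one peptide (monoisotopic m/z)."""

    peptide: str
    precursor_mass: float  # neutral monoisotopic
    b_series: tuple[float, ...]
    y_series: tuple[float, ...]


def fragment_ions(peptide: str, full: bool = False) -> PeptideFragmentTable:
    """b/y fragment-ion table of a peptide (length >= 2).

    ``b_series[i-1]`` is the singly-protonated b_i ion, ``y_series[j-1]``
    the y_j ion.  By default the trivial whole-peptide ions are excluded
    (series of length n-1); ``full=True`` includes them.
    """
    peptide = _check(peptide)
    n = len(peptide)
    if n < 2:
        raise ValueError("peptide length must be >= 2 for fragmentation")
    top = n if full else n - 1
    b = tuple(
        _pmass.fast_mass(peptide[:i], ion_type="b", charge=1) for i in range(1, top + 1)
    )
    y = tuple(
        _pmass.fast_mass(peptide[n - j :], ion_type="y", charge=1)
        for j in range(1, top + 1)
    )
    return PeptideFragmentTable(
        peptide=peptide,
        precursor_mass=_pmass.calculate_mass(sequence=peptide),
        b_series=b,
        y_series=y,
    )
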
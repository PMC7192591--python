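"""Physicochemical properties of wild-type and frame-shifted proteins.

A frameshift near the 5' end rewrites essentially the whole protein, so the
wild-type and shifted products of one gene can differ drastically in length,
molecular weight, net charge, isoelectric point and hydrophobicity.
:func:`compare_variants` produces that comparison table for the three frames
of a CDS.

Net charge follows the standard Henderson-Hasselbalch sum over the ionizable
side chains (D, E, C, Y, H, K, R) and the two termini; the isoelectric point
is the unique pH at which that strictly decreasing function crosses zero,
found by bisection.  Hydrophobicity is the Kyte-Doolittle GRAVY score (mean
per-residue hydropathy).  The pKa set and the hydropathy scale are
configurable; defaults are the EMBOSS pKa values and the Kyte-Doolittle
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .core import CodingSequence, shift_frame, translate
from . import massspec

__all__ = [
    "PKA_TABLES",
    "HYDROPATHY_SCALES",
    "ProteinProperties",
    "protein_length",
    "net_charge",
    "isoelectric_point",
    "gravy",
    "compute_properties",
    "compare_variants",
]

# EMBOSS (iep) pKa values; 'nterm'/'cterm' are the backbone termini.
PKA_TABLES: dict[str, dict[str, float]] = {
    "emboss": {
        "nterm": 8.6,
        "cterm": 3.6,
        "D": 3.9,
        "E": 4.1,
        "C": 8.5,
        "Y": 10.1,
        "H": 6.5,
        "K": 10.8,
        "R": 12.5,
    },
}

_ACIDIC = ("cterm", "D", "E", "C", "Y")
_BASIC = ("nterm", "H", "K", "R")

HYDROPATHY_SCALES: dict[str, dict[str, float]] = {"kd": dict(KYTE_DOOLITTLE)}

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def _check_protein(protein: str, allow_x: bool = True) -> str:
    if not protein:
        raise ValueError("empty protein")
    protein = protein.upper()
    if "*" in protein:
        raise ValueError("truncate at stop before property computation")
    allowed = _AA20 | ({"X"} if allow_x else set())
    bad = set(protein) - allowed
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)}")
    return protein


def _resolve(table, registry, kind):
    if isinstance(table, str):
        try:
            return registry[table]
        except KeyError:
            raise ValueError(f"unknown {kind} table {table!r}") from None
    return dict(table)


def protein_length(protein: str) -> int:
    """Residue count; 'X' counts, '*' is rejected (truncate first)."""
    return len(_check_protein(protein))


def net_charge(protein: str, ph: float = 7.0, pka="emboss") -> float:
    """Net charge at a given pH by the Henderson-Hasselbalch sum.

    Each basic group contributes ``+n / (1 + 10**(pH - pKa))`` and each
    acidic group ``-n / (1 + 10**(pKa - pH))``.  'X' residues contribute
    nothing (a warning is emitted).
    """
    protein = _check_protein(protein)
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")
    if "X" in protein:
        warnings.warn("'X' residues contribute no charge", stacklevel=2)
    pka = _resolve(pka, PKA_TABLES, "pKa")
    counts = {g: protein.count(g) for g in "DECYHKR"}
    counts["nterm"] = counts["cterm"] = 1
    charge = 0.0
    for g in _BASIC:
        if counts[g] and g in pka:
            charge += counts[g] / (1.0 + 10.0 ** (ph - pka[g]))
    for g in _ACIDIC:
        if counts[g] and g in pka:
            charge -= counts[g] / (1.0 + 10.0 ** (pka[g] - ph))
    return charge


def isoelectric_point(protein: str, pka="emboss", tol: float = 1e-3) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the root is unique; the
    bracket is halved until narrower than ``tol`` (in pH units).
    """
    lo, hi = 0.0, 14.0
    f_lo = net_charge(protein, lo, pka)
    f_hi = net_charge(protein, hi, pka)
    if f_lo <= 0:
        return lo
    if f_hi >= 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(protein: str, scale="kd", on_x: str = "warn") -> float:
    """Grand average of hydropathy: mean per-residue scale value.

    ``on_x``: 'warn' excludes X residues from the mean with a warning,
    'error' rejects them.
    """
    protein = _check_protein(protein)
    scale = _resolve(scale, HYDROPATHY_SCALES, "hydropathy")
    if "X" in protein:
        if on_x == "error":
            raise ValueError("protein contains 'X' residues")
        warnings.warn("'X' residues excluded from GRAVY", stacklevel=2)
        protein = protein.replace("X", "")
        if not protein:
            raise ValueError("no scorable residues")
    return sum(scale[a] for a in protein) / len(protein)


@dataclass(frozen=True)
class ProteinProperties:
    """One row of the WT vs frame-shift comparison."""

    protein_id: str
    sequence: str
    length: int
    mw: float
    mass_kind: str
    net_charge_ph7: float
    pi: float
    gravy: float

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 < self.pi < 14.0 and self.pi not in (0.0, 14.0):
            raise ValueError(f"pI {self.pi} outside (0, 14)")
        if self.mw <= 0:
            raise ValueError("mw must be positive")


def compute_properties(
    protein_id: str,
    protein: str,
    ph: float = 7.0,
    pka="emboss",
    scale="kd",
    mass_kind: str = "average",
) -> ProteinProperties:
    protein = _check_protein(protein)
    scorable = protein.replace("X", "")
    return ProteinProperties(
        protein_id=protein_id,
        sequence=protein,
        length=len(protein),
        mw=massspec.protein_mass(scorable, kind=mass_kind),
        mass_kind=mass_kind,
        net_charge_ph7=net_charge(protein, ph, pka),
        pi=isoelectric_point(protein, pka),
        gravy=gravy(protein, scale),
    )


def _realize_protein(protein: str, stop_policy) -> tuple[str, str]:
    """Resolve internal '*' per policy; returns (sequence, mode label)."""
    if "*" not in protein:
        return protein, "none"
    if stop_policy is None:
        raise ValueError(
            "frame contains stop codons; pass stop_policy='truncate_first_taa', "
            "'truncate_first_stop', or a substitution string/mapping"
        )
    if stop_policy == "truncate_first_stop":
        return protein[: protein.index("*")], stop_policy
    if stop_policy == "truncate_first_taa":
        # caller must pre-truncate codon-aware; handled in compare_variants
        raise ValueError("truncate_first_taa requires codon context")
    if isinstance(stop_policy, str) and len(stop_policy) == 1:
        return protein.replace("*", stop_policy), f"substitute:{stop_policy}"
    # ordered per-stop substitution, e.g. "PK" for two stops
    subs = list(stop_policy)
    if len(subs) != protein.count("*"):
        raise ValueError(
            f"substitution policy provides {len(subs)} residues for "
            f"{protein.count('*')} stops"
        )
    out = []
    it = iter(subs)
    for ch in protein:
        out.append(next(it) if ch == "*" else ch)
    return "".join(out), "substitute:" + "".join(subs)


def compare_variants(
    cds: CodingSequence,
    stop_policy=None,
    ph: float = 7.0,
    pka="emboss",
    scale="kd",
    mass_kind: str = "average",
    table_id: int = 11,
) -> pd.DataFrame:
    """Property table for the WT, +1 fs and -1 fs proteins of one CDS.

    The canonical (WT) protein is truncated at its terminal stop.  For
    shifted frames containing stops the readthrough protein is realized
    per ``stop_policy`` — a per-stop substitution string (e.g. ``"PK"``
    replaces the first stop with P and the second with K, as in the
    purified +1 fs DHFR construct), a single residue applied to every
    stop, or ``'truncate_first_taa'`` / ``'truncate_first_stop'``.  The
    mode used is recorded in the ``stop_policy`` column.
    """
    from .core import find_internal_stops

    rows = []
    for label, shift in (("wt", 0), ("+1", +1), ("-1", -1)):
        var = translate(shift_frame(cds, shift), table_id)
        internal_stops = find_internal_stops(var, exclude_terminal=(shift == 0))
        protein = var.protein
        if shift == 0:
            if protein.endswith("*"):
                protein = protein[:-1]
            if "*" in protein:
                raise ValueError(f"{cds.id}: internal stop in canonical frame")
            realized, mode = protein, "none"
        elif stop_policy == "truncate_first_taa":
            taa = [e for e in var.stops if e.codon == "TAA"]
            if not taa:
                raise ValueError(f"{cds.id} {label} fs: no TAA to truncate at")
            realized, mode = protein[: taa[0].index - 1], stop_policy
            if "*" in realized:
                raise ValueError(
                    f"{cds.id} {label} fs: stop upstream of first TAA; "
                    "choose a substitution policy"
                )
        else:
            realized, mode = _realize_protein(protein, stop_policy)
        props = compute_properties(
            f"{cds.id}_{label}", realized, ph, pka, scale, mass_kind
        )
        rows.append(
            {
                "protein_id": props.protein_id,
                "frame": label,
                "sequence": props.sequence,
                "length": props.length,
                "mw": props.mw,
                "mass_kind": props.mass_kind,
                "net_charge_ph7": props.net_charge_ph7,
                "pi": props.pi,
                "gravy": props.gravy,
                "n_stops": len(internal_stops),
                "stops": ";".join(f"{e.codon}@{e.index}" for e in internal_stops),
                "stop_policy": mode,
            }
        )
    return pd.DataFrame(rows)
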
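"""Synthetic stand-in sequences with published hidden-stop geometries.

None of these are the real genes.  The studied toxin genes (ibsC, tisB,
ghoT, ...) and the hidden-DHFR gene dfrB3 have published *geometries* —
protein lengths and shifted-frame stop positions — but their nucleotide
sequences are not bundled here; these fixtures are synthetic sequences
constructed at the nucleotide level to carry the same geometry, so the
screening machinery can be exercised against the published pattern
offline.  Every fixture is deterministic.

* :func:`ibsc_like`: 19-codon hydrophobic ORF + TAA whose +1 frame opens
  on TGA, carries a second TGA at codon 8 and a TAA at codon 18 (just
  before the 3' terminus), and whose -1 frame is TAA-free — the toxin
  geometry in which two opal codons are read through.
* :func:`dfrb3_like`: 85-codon ORF whose +1 frame carries exactly TAG@11
  and TGA@50, whose -1 frame carries exactly TGA@52 and TGA@74, and which
  is TAA-free in both shifted frames — the hidden-DHFR candidate pattern.
* :func:`tisb_like` / :func:`ghot_like`: toxin-sized hydrophobic ORFs (29
  and 57 residues).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .core import CodingSequence
from .simulate import _CodonSampler, hydrophobic_orf, plant_shifted_frame_stops

__all__ = ["ibsc_like", "dfrb3_like", "tisb_like", "ghot_like"]

# Hand-constructed 60-nt synthetic ORF (19 hydrophobic residues + TAA):
#   +1 frame stops: TGA@1, TGA@8, TAA@18 (and nothing else)
#   -1 frame: no TAA (one TAG@16)
#   canonical frame: no internal stop
_IBSC_LIKE_SEQ = "ATGATGCGTCTGGTTATTATCCTGATTGTGCTGCTCCTTATCTCTTTTAGCATAATTTAA"


@lru_cache(maxsize=None)
def ibsc_like() -> CodingSequence:
    """Synthetic stand-in with the ibsC-type +1 fs stop geometry."""
    return CodingSequence(
        id="ibsC_like_synthetic",
        seq=_IBSC_LIKE_SEQ,
        description="synthetic 19-aa toxin-like ORF; +1 fs TGA@1, TGA@8, TAA@18",
    )


@lru_cache(maxsize=None)
def dfrb3_like() -> CodingSequence:
    """Synthetic stand-in with the dfrB3-type hidden-gene stop geometry.

    Built by constraint planting on a random 85-codon gene: exactly
    TAG@11 and TGA@50 in the +1 frame, exactly TGA@52 and TGA@74 in the
    -1 frame, no TAA in either shifted frame, no internal canonical
    stop.
    """
    rng = np.random.default_rng(20200318)
    sampler = _CodonSampler((0.25, 0.25, 0.25, 0.25))
    seq = "ATG" + "".join(sampler.internal(rng, 83)) + "TGA"
    base = CodingSequence(
        id="dfrB3_like_synthetic",
        seq=seq,
        description="synthetic 84-aa ORF; +1 fs TAG@11, TGA@50; -1 fs TGA@52, TGA@74",
    )
    return plant_shifted_frame_stops(
        base,
        targets=[(+1, 11, "TAG"), (+1, 50, "TGA"), (-1, 52, "TGA"), (-1, 74, "TGA")],
        forbids=[
            (+1, "TAA"), (+1, "TAG"), (+1, "TGA"),
            (-1, "TAA"), (-1, "TAG"), (-1, "TGA"),
            (0, "TAA"), (0, "TAG"), (0, "TGA"),
        ],
        seed=42,
    )


@lru_cache(maxsize=None)
def tisb_like() -> CodingSequence:
    """Synthetic 29-residue toxin-sized hydrophobic ORF."""
    cds = hydrophobic_orf(n_codons=30, seed=29)
    return CodingSequence(
        id="tisB_like_synthetic", seq=cds.seq, description="synthetic 29-aa toxin-like ORF"
    )


@lru_cache(maxsize=None)
def ghot_like() -> CodingSequence:
    """Synthetic 57-residue toxin-sized hydrophobic ORF."""
    cds = hydrophobic_orf(n_codons=58, seed=57)
    return CodingSequence(
        id="ghoT_like_synthetic", seq=cds.seq, description="synthetic 57-aa toxin-like ORF"
    )
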
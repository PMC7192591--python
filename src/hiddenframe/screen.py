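"""TAA-absence screening of genes and genomes.

The predictor: a frame-shifted protein is expected to be expressed (by
readthrough of the leaky TAG/TGA stops) and hence potentially functional
when the shifted frame contains no TAA — the strongest terminator.  A gene
whose +1 and -1 frames are both TAA-free is a "hidden frame-shifted gene"
candidate.  Applied genome-wide, the fraction of TAA-free CDSs varies
enormously between bacteria (it tracks genomic A/T content), so the
per-genome summary reports the both-frames criterion alongside each
single-frame percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    CodingSequence,
    FrameShiftVariant,
    StopCodonEvent,
    find_internal_stops,
    shift_frame,
    translate,
)

__all__ = [
    "ScanPolicy",
    "GeneScreenRecord",
    "GenomeScreenSummary",
    "screen_gene",
    "predict_function_retention",
    "genome_scan",
    "RETAINED",
    "LOST",
    "EXCEPTION_POSSIBLE",
]

RETAINED = "retained"
LOST = "lost"
EXCEPTION_POSSIBLE = "exception-possible"


@dataclass(frozen=True)
class ScanPolicy:
    """Skip/count rules applied by :func:`genome_scan`.

    Attributes
    ----------
    criterion : {"both", "plus1", "minus1"}
        Which TAA-free flag defines a candidate in the summary percentage.
        "both" (the default) requires both shifted frames TAA-free — the
        criterion under which the hidden DHFR gene was found.
    taa_tail_tolerance : float
        Fraction f in [0, 1] of the 3' end of the shifted frame within
        which TAA events are ignored when setting the TAA-free flags
        (default 0, strict).  Motivated by a toxic +1 frame that carries a
        TAA immediately before its 3' terminus.
    skip_pseudogenes, skip_partial : bool
        Frameshift analysis presumes an intact ORF; flagged features are
        skipped (with a logged reason) by default.
    skip_non_triplet : bool
        A CDS whose length is not a multiple of 3 has an ambiguous
        canonical frame and is skipped by default.
    max_n_fraction : float
        CDSs with a higher fraction of N are skipped.
    table_id : int
        NCBI genetic-code table (11, bacterial, by default).
    """

    criterion: str = "both"
    taa_tail_tolerance: float = 0.0
    skip_pseudogenes: bool = True
    skip_partial: bool = True
    skip_non_triplet: bool = True
    max_n_fraction: float = 0.1
    table_id: int = 11

    def __post_init__(self):
        if self.criterion not in {"both", "plus1", "minus1"}:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if not 0.0 <= self.taa_tail_tolerance <= 1.0:
            raise ValueError("taa_tail_tolerance must be in [0, 1]")


@dataclass(frozen=True)
class GeneScreenRecord:
    """Per-gene shifted-frame stop inventories and candidate flags."""

    gene_id: str
    plus1: FrameShiftVariant
    minus1: FrameShiftVariant
    stops_plus1: tuple[StopCodonEvent, ...]
    stops_minus1: tuple[StopCodonEvent, ...]
    taa_free_plus1: bool
    taa_free_minus1: bool
    taa_tail_tolerance: float = 0.0

    @property
    def candidate_both_frames(self) -> bool:
        return self.taa_free_plus1 and self.taa_free_minus1

    def stop_counts(self, shift: int) -> dict:
        stops = self._stops(shift)
        return {c: sum(1 for e in stops if e.codon == c) for c in ("TAA", "TAG", "TGA")}

    def _stops(self, shift: int) -> tuple[StopCodonEvent, ...]:
        if shift == 1:
            return self.stops_plus1
        if shift == -1:
            return self.stops_minus1
        raise ValueError(f"invalid shift {shift!r}; expected +1 or -1")

    def taa_free(self, shift: int) -> bool:
        return self.taa_free_plus1 if shift == 1 else self.taa_free_minus1


def _effective_taa(stops, n_codons: int, tail_tolerance: float):
    """TAA events, minus those inside the final ``tail_tolerance`` fraction."""
    cutoff = n_codons - math.floor(tail_tolerance * n_codons)
    return [e for e in stops if e.codon == "TAA" and e.index <= cutoff]


def screen_gene(cds: CodingSequence, policy: ScanPolicy | None = None) -> GeneScreenRecord:
    """Inventory the +1 and -1 frames of one CDS and set candidate flags."""
    policy = policy or ScanPolicy()
    plus1 = translate(shift_frame(cds, +1), policy.table_id)
    minus1 = translate(shift_frame(cds, -1), policy.table_id)
    stops_p = tuple(find_internal_stops(plus1))
    stops_m = tuple(find_internal_stops(minus1))
    f = policy.taa_tail_tolerance
    return GeneScreenRecord(
        gene_id=cds.id,
        plus1=plus1,
        minus1=minus1,
        stops_plus1=stops_p,
        stops_minus1=stops_m,
        taa_free_plus1=not _effective_taa(stops_p, plus1.n_codons, f),
        taa_free_minus1=not _effective_taa(stops_m, minus1.n_codons, f),
        taa_tail_tolerance=f,
    )


def predict_function_retention(
    record: GeneScreenRecord, shift: int, domain_end_codon: int | None = None
) -> str:
    """Predict whether the shifted-frame protein retains function.

    No TAA in the frame: ``retained`` (TAG/TGA are leaky and assumed read
    through).  TAA present: ``lost``, unless every TAA lies 3' of a stated
    functional-domain end, in which case ``exception-possible`` — the
    pattern seen for a toxin whose activity lives near the N terminus.
    """
    if shift not in (1, -1):
        raise ValueError(f"invalid shift {shift!r}; expected +1 or -1")
    variant = record.plus1 if shift == 1 else record.minus1
    taa = _effective_taa(record._stops(shift), variant.n_codons, record.taa_tail_tolerance)
    if not taa:
        return RETAINED
    if domain_end_codon is None or any(e.index <= domain_end_codon for e in taa):
        return LOST
    return EXCEPTION_POSSIBLE


@dataclass(frozen=True)
class GenomeScreenSummary:
    """Genome-wide TAA-absence statistics under a stated criterion."""

    n_cds_total: int
    n_cds_skipped: int
    n_taa_free: int
    criterion: str
    skip_reasons: dict = field(default_factory=dict)
    percent_by_criterion: dict = field(default_factory=dict)

    @property
    def n_screened(self) -> int:
        return self.n_cds_total - self.n_cds_skipped

    @property
    def percent_taa_free(self) -> float:
        if self.n_screened == 0:
            return float("nan")
        return 100.0 * self.n_taa_free / self.n_screened

    def to_dict(self) -> dict:
        return {
            "n_cds_total": self.n_cds_total,
            "n_cds_skipped": self.n_cds_skipped,
            "n_taa_free": self.n_taa_free,
            "percent_taa_free": round(self.percent_taa_free, 1),
            "criterion": self.criterion,
            "skip_reasons": dict(self.skip_reasons),
            "percent_by_criterion": {
                k: round(v, 1) for k, v in self.percent_by_criterion.items()
            },
        }


def _skip_reason(cds, provenance, policy: ScanPolicy) -> str | None:
    prov = provenance or {}
    if policy.skip_pseudogenes and prov.get("pseudo"):
        return "pseudogene"
    if policy.skip_partial and prov.get("partial"):
        return "partial"
    if policy.skip_non_triplet and len(cds.seq) % 3 != 0:
        return "length not divisible by 3"
    if len(cds.seq) < 6:
        return "too short to shift"
    n_frac = cds.seq.count("N") / len(cds.seq)
    if n_frac > policy.max_n_fraction:
        return f"N fraction {n_frac:.2f} above threshold"
    return None


def genome_scan(
    cds_records,
    policy: ScanPolicy | None = None,
) -> tuple[GenomeScreenSummary, pd.DataFrame]:
    """Screen every CDS of an annotated genome and summarize.

    Parameters
    ----------
    cds_records : iterable of CodingSequence or (CodingSequence, provenance)
        Typically the output of :func:`hiddenframe.io.extract_cds`;
        provenance dicts may carry ``pseudo``/``partial`` flags plus
        contig/strand/coordinates, which are echoed in the per-gene table.
    policy : ScanPolicy

    Returns
    -------
    (GenomeScreenSummary, per-gene pandas.DataFrame)
        The summary counts candidates under ``policy.criterion``; the
        per-frame percentages are always reported alongside in
        ``percent_by_criterion``.
    """
    policy = policy or ScanPolicy()
    rows = []
    n_total = 0
    skip_reasons: dict[str, int] = {}
    n_free = {"both": 0, "plus1": 0, "minus1": 0}
    for item in cds_records:
        cds, prov = item if isinstance(item, tuple) else (item, {})
        n_total += 1
        reason = _skip_reason(cds, prov, policy)
        if reason is not None:
            skip_reasons[reason] = skip_reasons.get(reason, 0) + 1
            rows.append(_gene_row(cds, prov, None, reason))
            continue
        rec = screen_gene(cds, policy)
        n_free["plus1"] += rec.taa_free_plus1
        n_free["minus1"] += rec.taa_free_minus1
        n_free["both"] += rec.candidate_both_frames
        rows.append(_gene_row(cds, prov, rec, None))
    n_skipped = sum(skip_reasons.values())
    if n_total == 0:
        raise ValueError("no CDS features")
    n_screened = n_total - n_skipped
    pct = {
        k: (100.0 * v / n_screened if n_screened else float("nan"))
        for k, v in n_free.items()
    }
    summary = GenomeScreenSummary(
        n_cds_total=n_total,
        n_cds_skipped=n_skipped,
        n_taa_free=n_free[policy.criterion],
        criterion=policy.criterion,
        skip_reasons=skip_reasons,
        percent_by_criterion=pct,
    )
    return summary, pd.DataFrame(rows)


def _fmt_stops(stops) -> str:
    return ";".join(f"{e.codon}@{e.index}" for e in stops)


def _gene_row(cds, prov, rec: GeneScreenRecord | None, skip_reason: str | None) -> dict:
    row = {
        "gene_id": cds.id,
        "length_nt": len(cds.seq),
        "skipped": skip_reason is not None,
        "skip_reason": skip_reason or "",
    }
    for key in ("contig", "strand", "start", "end", "locus_tag"):
        if prov and key in prov:
            row[key] = prov[key]
    if rec is not None:
        row.update(
            {
                "stops_plus1": _fmt_stops(rec.stops_plus1),
                "stops_minus1": _fmt_stops(rec.stops_minus1),
                "n_taa_plus1": rec.stop_counts(1)["TAA"],
                "n_taa_minus1": rec.stop_counts(-1)["TAA"],
                "taa_free_plus1": rec.taa_free_plus1,
                "taa_free_minus1": rec.taa_free_minus1,
                "candidate_both_frames": rec.candidate_both_frames,
            }
        )
    return row
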
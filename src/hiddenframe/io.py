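"""Readers and writers shared by all stages.

Reads multi-record FASTA CDS sets, and extracts CDS features (with strand,
multi-part joins and codon_start/phase offsets honoured) from GenBank flat
files or GFF3 + genome FASTA.  Writes per-gene/per-variant tables as TSV
(tab-separated, no quoting, '.' decimal separator, mandatory header) and
summaries as JSON carrying a schema-version field.  Genomic provenance is
1-based inclusive, matching GenBank/GFF3; stop events are 1-based codon
indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .core import CodingSequence, FrameShiftVariant

__all__ = [
    "SCHEMA_VERSION",
    "read_fasta",
    "extract_cds",
    "read_toxicity_counts",
    "write_variant_report",
    "write_table",
    "write_summary_json",
]

SCHEMA_VERSION = "1.0"


def read_fasta(path) -> list[CodingSequence]:
    """Read a multi-record FASTA of CDSs; ids are the first header token."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    out = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(
            CodingSequence(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    return out


def _genbank_cds(path):
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            loc = feat.location
            if loc is None:
                raise ValueError(f"{rec.id}: CDS feature without location")
            if int(loc.end) > len(rec.seq) or int(loc.start) < 0:
                raise ValueError(
                    f"feature {_locus_tag(feat)} extends beyond contig "
                    f"{rec.id} (length {len(rec.seq)})"
                )
            seq = str(feat.extract(rec.seq))
            codon_start = int(feat.qualifiers.get("codon_start", ["1"])[0])
            if codon_start > 1:
                seq = seq[codon_start - 1 :]
            prov = {
                "contig": rec.id,
                "strand": "+" if loc.strand in (1, None) else "-",
                "start": int(loc.start) + 1,
                "end": int(loc.end),
                "locus_tag": _locus_tag(feat),
                "pseudo": "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
                "partial": "<" in str(loc) or ">" in str(loc),
            }
            yield seq, prov


def _locus_tag(feat) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return "unnamed_CDS"


def _gff3_cds(path, fasta_path):
    import gffutils
    from pyfaidx import Fasta

    if fasta_path is None:
        raise ValueError("GFF3 input requires a genome FASTA (fasta_path)")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genome = Fasta(str(fasta_path))
    groups: dict[str, list] = {}
    order: list[str] = []
    for feat in db.all_features(featuretype="CDS", order_by=("seqid", "start")):
        key = feat.attributes.get("ID", [feat.id])[0]
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(feat)
    for key in order:
        parts = groups[key]
        strand = parts[0].strand
        contig = parts[0].seqid
        if contig not in genome:
            raise ValueError(f"feature {key}: contig {contig} missing from FASTA")
        contig_len = len(genome[contig])
        parts = sorted(parts, key=lambda f: f.start, reverse=(strand == "-"))
        chunks = []
        for p in parts:
            if p.end > contig_len or p.start < 1:
                raise ValueError(
                    f"feature {key} extends beyond contig {contig} "
                    f"(length {contig_len})"
                )
            chunk = genome[contig][p.start - 1 : p.end].seq
            if strand == "-":
                chunk = str(Seq(chunk).reverse_complement())
            chunks.append(chunk)
        seq = "".join(chunks)
        phase = parts[0].frame
        if phase not in (".", None, ""):
            seq = seq[int(phase) :]
        tag = parts[0].attributes.get("locus_tag", [key])[0]
        prov = {
            "contig": contig,
            "strand": strand,
            "start": min(p.start for p in parts),
            "end": max(p.end for p in parts),
            "locus_tag": tag,
            "pseudo": "pseudogene" in parts[0].attributes.get("gene_biotype", []),
            "partial": parts[0].attributes.get("partial", ["false"])[0] == "true",
        }
        yield seq, prov


def extract_cds(annotation_path, fasta_path=None):
    """Extract every CDS from an annotation as (CodingSequence, provenance).

    GenBank flat files carry their own sequence; GFF3 needs the genome
    FASTA.  Minus-strand features are reverse-complemented, multi-part
    locations joined in feature order and codon_start/phase offsets
    applied, so each returned sequence starts at its canonical frame.
    Provenance records contig, strand, 1-based inclusive coordinates,
    locus_tag and pseudo/partial flags.
    """
    annotation_path = Path(annotation_path)
    suffix = annotation_path.suffix.lower()
    if suffix in {".gb", ".gbk", ".gbff", ".genbank"}:
        source = _genbank_cds(annotation_path)
    elif suffix in {".gff", ".gff3"}:
        source = _gff3_cds(annotation_path, fasta_path)
    else:
        # sniff: GenBank flat files start with LOCUS
        head = annotation_path.open().read(5)
        source = (
            _genbank_cds(annotation_path)
            if head == "LOCUS"
            else _gff3_cds(annotation_path, fasta_path)
        )
    out = []
    for i, (seq, prov) in enumerate(source):
        cds = CodingSequence(
            id=prov.get("locus_tag") or f"cds{i:05d}",
            seq=seq,
            description=f"{prov['contig']}:{prov['start']}..{prov['end']}({prov['strand']})",
            includes_stop=True,
        )
        out.append((cds, prov))
    if not out:
        raise ValueError(f"{annotation_path}: no CDS features")
    return out


def read_toxicity_counts(path):
    """Read a toxicity-count TSV (variant_id, counts_with_iptg, counts_without_iptg)."""
    from .variants import ToxicityMeasurement

    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "counts_with_iptg", "counts_without_iptg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ToxicityMeasurement(
            variant_id=str(r.variant_id),
            counts_with_iptg=int(r.counts_with_iptg),
            counts_without_iptg=int(r.counts_without_iptg),
        )
        for r in df.itertuples()
    ]


def variant_report_frame(variants: list[FrameShiftVariant]) -> pd.DataFrame:
    """One row per stop event (stop columns empty for stop-free frames)."""
    rows = []
    for v in variants:
        if v.protein is None:
            raise ValueError(f"{v.parent_id}: translate before reporting")
        base = {
            "parent_id": v.parent_id,
            "shift": f"{v.shift:+d}" if v.shift else "0",
            "protein_length": len(v.protein),
        }
        if not v.stops:
            rows.append({**base, "stop_codon": "", "stop_index": "", "leakiness_rank": ""})
        for e in v.stops:
            rows.append(
                {
                    **base,
                    "stop_codon": e.codon,
                    "stop_index": e.index,
                    "leakiness_rank": e.leakiness_rank,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "parent_id",
            "shift",
            "protein_length",
            "stop_codon",
            "stop_index",
            "leakiness_rank",
        ],
    )


def write_variant_report(variants, path, fmt: str = "tsv"):
    df = variant_report_frame(list(variants))
    if fmt == "tsv":
        write_table(df, path)
    elif fmt == "json":
        payload = {"schema_version": SCHEMA_VERSION, "variants": df.to_dict("records")}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_table(df: pd.DataFrame, path):
    """TSV with header, no quoting, '.' decimals; valid even when empty."""
    df.to_csv(path, sep="\t", index=False)


def write_summary_json(summary, path):
    """Write a genome-screen summary (or any mapping) as versioned JSON."""
    payload = summary.to_dict() if hasattr(summary, "to_dict") else dict(summary)
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    return payload
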
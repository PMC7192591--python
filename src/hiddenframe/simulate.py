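"""Synthetic CDS sets and annotated genomes with known shifted-frame stops.

Real inputs to the screen are bacterial CDS collections; this module
generates stand-ins whose shifted-frame stop structure is known exactly at
generation time, so every pipeline stage has offline test inputs with
analytic expectations:

* :func:`simulate_cds_set` draws genes codon-i.i.d. from a nucleotide or
  codon-usage model (ATG start, canonical terminal stop, in-frame stops
  rejected internally).  Under a uniform nucleotide model each shifted
  codon is TAA with probability (1/4)^3, so a frame of m codons is
  TAA-free with probability ~ (1 - 1/64)^m — the calibration checked by
  the test suite.
* :func:`plant_shifted_frame_stops` edits a sequence so chosen stop codons
  appear at chosen shifted-frame codon positions (and forbidden ones
  nowhere else), by constraint-guided local search.  This builds fixtures
  with a prescribed stop geometry, e.g. the published hidden-DHFR pattern.
* :func:`simulate_annotated_genome` lays the genes out on multi-contig
  GenBank / GFF3+FASTA files (both strands, a multi-part join feature) so
  the genome scanner's extraction logic can be exercised against an exact
  truth table.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the config; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .core import SHIFT_OFFSETS, STOP_CODONS, CodingSequence
from .screen import screen_gene

__all__ = [
    "SimulationConfig",
    "simulate_cds_set",
    "plant_shifted_frame_stops",
    "simulate_annotated_genome",
    "hydrophobic_orf",
]

_BASES = "ACGT"
_SENSE_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in STOP_CODONS
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic CDS set.

    ``length_distribution`` bounds the total codon count per gene
    (including the ATG and the terminal stop), drawn uniformly; bacterial
    CDSs average ~300 codons, so the default (100, 400) spans a realistic
    range while keeping simulations cheap.  ``nucleotide_model`` is either
    per-base probabilities (pA, pC, pG, pT) or a 64-entry codon-usage
    table (stop entries are ignored for internal codons).
    ``planted_taa_free_fraction``, when set, constructs exactly that
    fraction of genes TAA-free in both shifted frames and every other
    gene with at least one shifted-frame TAA, so the screened percentage
    is known exactly.
    """

    n_genes: int = 100
    length_distribution: tuple[int, int] = (100, 400)
    nucleotide_model: tuple[float, float, float, float] | dict = (0.25, 0.25, 0.25, 0.25)
    planted_taa_free_fraction: float | None = None
    seed: int = 0
    attempt_budget: int = 10_000

    def __post_init__(self):
        lo, hi = self.length_distribution
        if lo < 10:
            raise ValueError("minimum gene length is 10 codons")
        if hi < lo:
            raise ValueError("length_distribution max < min")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if isinstance(self.nucleotide_model, dict):
            total = sum(self.nucleotide_model.values())
        else:
            if len(self.nucleotide_model) != 4:
                raise ValueError("nucleotide_model must be (pA, pC, pG, pT)")
            total = sum(self.nucleotide_model)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"model probabilities sum to {total}, not 1")
        if self.planted_taa_free_fraction is not None and not (
            0.0 <= self.planted_taa_free_fraction <= 1.0
        ):
            raise ValueError("planted_taa_free_fraction must be in [0, 1]")


class _CodonSampler:
    """Draws internal (sense) codons and terminal stops from the model."""

    def __init__(self, model):
        if isinstance(model, dict):
            model = {k.upper().replace("U", "T"): v for k, v in model.items()}
            weights = np.array([model.get(c, 0.0) for c in _SENSE_CODONS], float)
            stop_w = np.array([model.get(c, 0.0) for c in sorted(STOP_CODONS)], float)
        else:
            pa, pc, pg, pt = model
            p = dict(zip(_BASES, (pa, pc, pg, pt)))
            weights = np.array(
                [p[c[0]] * p[c[1]] * p[c[2]] for c in _SENSE_CODONS], float
            )
            stop_w = np.array(
                [p[c[0]] * p[c[1]] * p[c[2]] for c in sorted(STOP_CODONS)], float
            )
        if weights.sum() <= 0:
            raise ValueError("model assigns zero probability to every sense codon")
        self._sense = weights / weights.sum()
        if stop_w.sum() > 0:
            self._stop = stop_w / stop_w.sum()
        else:
            # model cannot emit a stop (e.g. pA = 0: every stop contains A);
            # terminate with TGA, whose lone A cannot seed a TAA in any frame
            self._stop = None
        self._stop_codons = sorted(STOP_CODONS)

    def internal(self, rng, n: int) -> list[str]:
        idx = rng.choice(len(_SENSE_CODONS), size=n, p=self._sense)
        return [_SENSE_CODONS[i] for i in idx]

    def terminal_stop(self, rng) -> str:
        if self._stop is None:
            return "TGA"
        return self._stop_codons[rng.choice(3, p=self._stop)]


def _draw_gene(rng, sampler: _CodonSampler, n_codons: int) -> str:
    body = sampler.internal(rng, n_codons - 2)
    return "ATG" + "".join(body) + sampler.terminal_stop(rng)


def _has_shifted_taa(seq: str) -> bool:
    for off in (1, 2):
        sub = seq[off:]
        for i in range(len(sub) // 3):
            if sub[3 * i : 3 * i + 3] == "TAA":
                return True
    return False


def simulate_cds_set(config: SimulationConfig):
    """Generate a CDS set plus its generation-time truth table.

    Returns ``(genes, truth)``: a list of :class:`CodingSequence` and a
    DataFrame with the per-gene shifted-frame stop inventory and TAA-free
    flags recorded at generation time.
    """
    rng = np.random.default_rng(config.seed)
    sampler = _CodonSampler(config.nucleotide_model)
    lo, hi = config.length_distribution
    n_planted = (
        int(round(config.planted_taa_free_fraction * config.n_genes))
        if config.planted_taa_free_fraction is not None
        else None
    )
    genes = []
    rows = []
    for g in range(config.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        want_free = None if n_planted is None else (g < n_planted)
        seq = None
        for attempt in range(1, config.attempt_budget + 1):
            cand = _draw_gene(rng, sampler, n_codons)
            if want_free is None or _has_shifted_taa(cand) != want_free:
                seq = cand
                break
        if seq is None:
            raise RuntimeError(
                f"gene {g}: could not draw a "
                f"{'TAA-free' if want_free else 'TAA-containing'} gene of "
                f"{n_codons} codons in {config.attempt_budget} attempts; "
                "the model makes the request astronomically rare"
            )
        cds = CodingSequence(id=f"sim{g:05d}", seq=seq, description="synthetic CDS")
        rec = screen_gene(cds)
        genes.append(cds)
        rows.append(
            {
                "gene_id": cds.id,
                "n_codons": n_codons,
                "stops_plus1": ";".join(f"{e.codon}@{e.index}" for e in rec.stops_plus1),
                "stops_minus1": ";".join(
                    f"{e.codon}@{e.index}" for e in rec.stops_minus1
                ),
                "taa_free_plus1": rec.taa_free_plus1,
                "taa_free_minus1": rec.taa_free_minus1,
                "candidate_both_frames": rec.candidate_both_frames,
                "planted_taa_free": want_free if want_free is not None else pd.NA,
            }
        )
    return genes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# constraint planting


def _target_positions(shift: int, codon_index: int) -> range:
    off = SHIFT_OFFSETS[shift]
    start = off + 3 * (codon_index - 1)
    return range(start, start + 3)


def plant_shifted_frame_stops(
    cds: CodingSequence,
    targets,
    forbids=(),
    seed: int = 0,
    budget: int = 10_000,
    keep_terminal_stop: bool = True,
    keep_start_codon: bool = True,
) -> CodingSequence:
    """Edit a CDS so chosen shifted-frame stop codons exist and others don't.

    ``targets`` is a list of ``(shift, codon_index, stop_codon)`` to
    create; ``forbids`` a list of ``(shift, stop_codon)`` meaning that
    stop must not occur anywhere else in that frame (shift 0 forbids
    internal canonical-frame stops; the terminal stop is exempt).
    Overlapping targets that pin the same nucleotide to different bases
    are reported as conflicts.  Remaining forbidden occurrences are
    removed by bounded random local search (mutating one free nucleotide
    of an offending codon per proposal); the result is re-screened before
    being returned.  The canonical-frame protein may change.
    """
    rng = np.random.default_rng(seed)
    nts = list(cds.seq)
    L = len(nts)

    fixed: dict[int, str] = {}
    conflicts = []
    for shift, codon_index, stop_codon in targets:
        if stop_codon not in STOP_CODONS:
            raise ValueError(f"{stop_codon!r} is not a stop codon")
        pos = _target_positions(shift, codon_index)
        if pos[-1] >= L:
            raise ValueError(
                f"target {stop_codon}@{codon_index} (shift {shift:+d}) "
                f"extends past the sequence (length {L})"
            )
        for p, base in zip(pos, stop_codon):
            if fixed.get(p, base) != base:
                conflicts.append(
                    f"position {p + 1}: {fixed[p]} (earlier target) vs {base} "
                    f"({stop_codon}@{codon_index}, shift {shift:+d})"
                )
            fixed[p] = base
    if keep_start_codon:
        for p, base in zip(range(3), "ATG"):
            if fixed.get(p, base) != base:
                conflicts.append(f"position {p + 1}: target conflicts with start codon")
            fixed[p] = base
    if keep_terminal_stop and cds.includes_stop and L % 3 == 0:
        for p, base in zip(range(L - 3, L), cds.seq[-3:]):
            if fixed.get(p, base) != base:
                conflicts.append(f"position {p + 1}: target conflicts with terminal stop")
            fixed[p] = base
    if conflicts:
        raise ValueError("unsatisfiable constraints:\n  " + "\n  ".join(conflicts))
    for p, base in fixed.items():
        nts[p] = base

    target_keys = {(s, j) for s, j, _ in targets}
    terminal_index = L // 3 if (cds.includes_stop and L % 3 == 0) else None

    def violations():
        out = []
        for shift, stop_codon in forbids:
            off = SHIFT_OFFSETS[shift]
            sub = nts[off:]
            for i in range(len(sub) // 3):
                if (shift, i + 1) in target_keys:
                    continue
                if shift == 0 and terminal_index is not None and i + 1 == terminal_index:
                    continue
                if "".join(sub[3 * i : 3 * i + 3]) == stop_codon:
                    out.append((off + 3 * i, stop_codon, shift, i + 1))
        return out

    for _ in range(budget):
        bad = violations()
        if not bad:
            break
        start, _, _, _ = bad[rng.integers(len(bad))]
        free = [p for p in range(start, start + 3) if p not in fixed]
        if not free:
            raise ValueError(
                "unsatisfiable constraints: a forbidden codon is entirely "
                "pinned by targets/start/stop at positions "
                f"{start + 1}-{start + 3}"
            )
        p = free[rng.integers(len(free))]
        nts[p] = _BASES[rng.integers(4)]
    else:
        remaining = violations()
        raise ValueError(
            f"local search exhausted {budget} proposals; remaining violations: "
            + ", ".join(f"{c}@{j} shift {s:+d}" for _, c, s, j in remaining)
        )

    out = CodingSequence(
        id=cds.id,
        seq="".join(nts),
        description=(cds.description + " [planted stops]").strip(),
        includes_stop=cds.includes_stop,
    )
    rec = screen_gene(out)
    for shift, codon_index, stop_codon in targets:
        if shift == 0:
            continue
        stops = rec.stops_plus1 if shift == 1 else rec.stops_minus1
        if not any(e.index == codon_index and e.codon == stop_codon for e in stops):
            raise AssertionError(
                f"planting verification failed: {stop_codon}@{codon_index} "
                f"shift {shift:+d} absent after editing"
            )
    return out


# ---------------------------------------------------------------------------
# annotated-genome emission


@dataclass
class SimulatedGenome:
    """Paths and ground truth of an emitted annotated genome."""

    genbank_path: Path
    gff3_path: Path
    fasta_path: Path
    truth: pd.DataFrame
    expected_percent_taa_free: dict = field(default_factory=dict)


def _spacer(rng, lo=20, hi=80) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def simulate_annotated_genome(
    config: SimulationConfig,
    out_dir,
    n_contigs: int = 2,
    multipart_gene: bool = True,
    all_minus_strand: bool = False,
) -> SimulatedGenome:
    """Lay a simulated CDS set onto annotated contigs and write files.

    Genes alternate strands (all minus with ``all_minus_strand``), are
    separated by random spacers and distributed round-robin over
    ``n_contigs``; with ``multipart_gene`` the first gene is written as a
    two-part ``join`` split at a codon boundary.  Emits a GenBank flat
    file and an equivalent GFF3+FASTA pair; the returned truth table and
    expected percentages are exact by construction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes, truth = simulate_cds_set(config)
    rng = np.random.default_rng(config.seed + 1)

    contigs = [[] for _ in range(n_contigs)]  # list of (gene, strand, multipart)
    for i, gene in enumerate(genes):
        strand = -1 if (all_minus_strand or i % 2) else 1
        contigs[i % n_contigs].append([gene, strand, multipart_gene and i == 0])

    records = []
    gff_lines = ["##gff-version 3"]
    for c, content in enumerate(contigs):
        name = f"ctg{c + 1:02d}"
        seq_parts = [_spacer(rng)]
        pos = len(seq_parts[0])
        features = []
        for gene, strand, multipart in content:
            gene_seq = gene.seq if strand == 1 else str(Seq(gene.seq).reverse_complement())
            if multipart and strand == 1:
                split = 3 * (len(gene.seq) // 6)  # codon boundary near the middle
                gap = _spacer(rng, 10, 30)
                a_start, a_end = pos, pos + split
                seq_parts += [gene_seq[:split], gap, gene_seq[split:]]
                b_start = a_end + len(gap)
                b_end = b_start + (len(gene_seq) - split)
                pos = b_end
                loc = CompoundLocation(
                    [
                        FeatureLocation(a_start, a_end, strand=1),
                        FeatureLocation(b_start, b_end, strand=1),
                    ]
                )
                parts = [(a_start, a_end, 0), (b_start, b_end, 0)]
            else:
                start, end = pos, pos + len(gene_seq)
                seq_parts.append(gene_seq)
                pos = end
                loc = FeatureLocation(start, end, strand=strand)
                parts = [(start, end, 0)]
            features.append(
                SeqFeature(
                    loc,
                    type="CDS",
                    qualifiers={
                        "locus_tag": [gene.id],
                        "transl_table": ["11"],
                        "codon_start": ["1"],
                    },
                )
            )
            for p_start, p_end, phase in parts:
                gff_lines.append(
                    "\t".join(
                        [
                            name,
                            "hiddenframe-sim",
                            "CDS",
                            str(p_start + 1),
                            str(p_end),
                            ".",
                            "+" if strand == 1 else "-",
                            str(phase),
                            f"ID=cds-{gene.id};locus_tag={gene.id}",
                        ]
                    )
                )
            spacer = _spacer(rng)
            seq_parts.append(spacer)
            pos += len(spacer)
        rec = SeqRecord(
            Seq("".join(seq_parts)),
            id=name,
            name=name,
            description="synthetic contig",
            annotations={"molecule_type": "DNA", "topology": "linear"},
        )
        rec.features = features
        records.append(rec)

    gb = out_dir / "genome.gbk"
    gff = out_dir / "genome.gff3"
    fa = out_dir / "genome.fasta"
    SeqIO.write(records, str(gb), "genbank")
    SeqIO.write(
        [SeqRecord(r.seq, id=r.id, description="") for r in records], str(fa), "fasta"
    )
    gff.write_text("\n".join(gff_lines) + "\n")

    n = len(truth)
    expected = {
        "both": 100.0 * truth["candidate_both_frames"].sum() / n,
        "plus1": 100.0 * truth["taa_free_plus1"].sum() / n,
        "minus1": 100.0 * truth["taa_free_minus1"].sum() / n,
    }
    return SimulatedGenome(
        genbank_path=gb,
        gff3_path=gff,
        fasta_path=fa,
        truth=truth,
        expected_percent_taa_free=expected,
    )


# ---------------------------------------------------------------------------
# toxin-like fixtures

_HYDROPHOBIC_POOL = "AILVFMGW"
_PREFERRED = {
    "A": "GCG", "I": "ATT", "L": "CTG", "V": "GTG", "F": "TTT",
    "M": "ATG", "G": "GGC", "W": "TGG", "S": "AGC", "T": "ACC",
}


def hydrophobic_orf(n_codons: int, seed: int = 0, gravy_min: float = 1.0) -> CodingSequence:
    """A short toxin-like ORF: hydrophobic residues, GRAVY above a floor.

    Emulates the size range of type I toxins (19-57 residues); residues
    are drawn from a hydrophobic-biased pool until the GRAVY floor is met.
    """
    from .properties import gravy as _gravy

    if n_codons < 4:
        raise ValueError("need at least 4 codons (start + 2 residues + stop)")
    rng = np.random.default_rng(seed)
    pool = _HYDROPHOBIC_POOL + "ST"
    for _ in range(1000):
        aas = "M" + "".join(
            pool[i] for i in rng.integers(0, len(pool), size=n_codons - 2)
        )
        if _gravy(aas) >= gravy_min:
            seq = "".join(_PREFERRED[a] for a in aas) + "TAA"
            return CodingSequence(
                id=f"toxinlike_{n_codons - 1}aa_s{seed}",
                seq=seq,
                description=f"synthetic toxin-like ORF, {n_codons - 1} aa",
            )
    raise RuntimeError("could not reach the requested GRAVY floor")
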
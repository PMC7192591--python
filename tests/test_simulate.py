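"""Generator determinism, analytic calibration, planting, genome emission."""

import itertools

import numpy as np
import pytest

from hiddenframe.core import STOP_CODONS, CodingSequence
from hiddenframe.screen import genome_scan, screen_gene
from hiddenframe.simulate import (
    SimulationConfig,
    hydrophobic_orf,
    plant_shifted_frame_stops,
    simulate_annotated_genome,
    simulate_cds_set,
)
from hiddenframe.properties import gravy

from conftest import random_dna

SENSE = ["".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS]


def taa_free_probability(n_codons: int, shift: int) -> float:
    """Exact P(no TAA in a shifted frame) for the generator's gene model.

    Genes are ATG + i.i.d. uniform sense codons + uniform stop.  Every
    shifted codon straddles one codon junction, so a forward pass over
    junctions with the current codon as state gives the exact probability.
    """
    stops = sorted(STOP_CODONS)

    def junction_ok(c1, c2):
        if shift == +1:  # shifted codon = c1[1] c1[2] c2[0]
            return not (c1[1:] == "TA" and c2[0] == "A")
        return not (c1[2] == "T" and c2[:2] == "AA")  # c1[2] c2[0] c2[1]

    dist = {"ATG": 1.0}
    for j in range(1, n_codons):
        nxt = stops if j == n_codons - 1 else SENSE
        p = 1.0 / len(nxt)
        new: dict = {}
        for c1, mass in dist.items():
            for c2 in nxt:
                if junction_ok(c1, c2):
                    new[c2] = new.get(c2, 0.0) + mass * p
        dist = new
    return sum(dist.values())


class TestCdsSimulation:
    def test_seed_determinism(self):
        config = SimulationConfig(n_genes=20, length_distribution=(20, 40), seed=9)
        genes_a, truth_a = simulate_cds_set(config)
        genes_b, truth_b = simulate_cds_set(config)
        assert [g.seq for g in genes_a] == [g.seq for g in genes_b]
        assert truth_a.equals(truth_b)

    def test_genes_are_well_formed_orfs(self):
        config = SimulationConfig(n_genes=30, length_distribution=(15, 25), seed=1)
        genes, truth = simulate_cds_set(config)
        for g in genes:
            assert g.seq.startswith("ATG") and g.seq[-3:] in STOP_CODONS
            assert len(g.seq) % 3 == 0
            internal = [g.seq[i : i + 3] for i in range(3, len(g.seq) - 3, 3)]
            assert not (set(internal) & STOP_CODONS)

    def test_adenine_free_model_never_yields_taa(self):
        config = SimulationConfig(
            n_genes=40,
            length_distribution=(20, 40),
            nucleotide_model=(0.0, 1 / 3, 1 / 3, 1 / 3),
            seed=4,
        )
        genes, truth = simulate_cds_set(config)
        assert truth["candidate_both_frames"].all()
        for g in genes:
            for off in (1, 2):
                sub = g.seq[off:]
                assert "TAA" not in [sub[i : i + 3] for i in range(0, len(sub) - 2, 3)]

    def test_truth_table_matches_rescreening(self):
        config = SimulationConfig(n_genes=25, length_distribution=(20, 50), seed=6)
        genes, truth = simulate_cds_set(config)
        for g, row in zip(genes, truth.itertuples()):
            rec = screen_gene(g)
            assert row.candidate_both_frames == rec.candidate_both_frames
            assert row.stops_plus1 == ";".join(
                f"{e.codon}@{e.index}" for e in rec.stops_plus1
            )

    def test_marginals_match_exhaustive_enumeration_at_tiny_length(self):
        """Generator TAA-free fractions vs brute force over all 4-codon genes."""
        exact = {}
        for shift in (+1, -1):
            free = total = 0
            for c2, c3 in itertools.product(SENSE, repeat=2):
                for stop in sorted(STOP_CODONS):
                    seq = "ATG" + c2 + c3 + stop
                    sub = seq[1:] if shift == 1 else seq[2:]
                    codons = [sub[i : i + 3] for i in range(0, 3 * (len(sub) // 3), 3)]
                    free += "TAA" not in codons
                    total += 1
            exact[shift] = free / total
            assert exact[shift] == pytest.approx(taa_free_probability(4, shift), abs=1e-12)
        config = SimulationConfig(n_genes=4000, length_distribution=(10, 10), seed=13)
        # exhaustive check is at 4 codons; the sampled check reuses the DP at 10
        genes, truth = simulate_cds_set(config)
        for shift, col in ((+1, "taa_free_plus1"), (-1, "taa_free_minus1")):
            p = taa_free_probability(10, shift)
            se = np.sqrt(p * (1 - p) / len(truth))
            assert abs(truth[col].mean() - p) <= 3 * se

    def test_infeasible_planting_request_reports_attempts(self):
        config = SimulationConfig(
            n_genes=1,
            length_distribution=(600, 600),
            planted_taa_free_fraction=1.0,
            seed=2,
            attempt_budget=50,
        )
        with pytest.raises(RuntimeError, match="50 attempts"):
            simulate_cds_set(config)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"length_distribution": (5, 20)},
            {"nucleotide_model": (0.5, 0.5, 0.5, 0.5)},
            {"planted_taa_free_fraction": 1.5},
            {"n_genes": 0},
        ],
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestPlanting:
    def test_requested_taa_appears_at_requested_codon(self, rng):
        base = CodingSequence("p", "ATG" + random_dna(rng, 294) + "TAA")
        planted = plant_shifted_frame_stops(base, [(+1, 5, "TAA")], seed=3)
        rec = screen_gene(planted)
        assert any(e.codon == "TAA" and e.index == 5 for e in rec.stops_plus1)

    def test_forbidding_taa_everywhere_yields_a_candidate(self, rng):
        base = CodingSequence("p", "ATG" + random_dna(rng, 150) + "TAA")
        planted = plant_shifted_frame_stops(
            base, targets=[], forbids=[(+1, "TAA"), (-1, "TAA")], seed=8
        )
        assert screen_gene(planted).candidate_both_frames

    def test_conflicting_targets_are_reported(self, rng):
        base = CodingSequence("p", "ATG" + random_dna(rng, 60) + "TAA")
        with pytest.raises(ValueError, match="unsatisfiable"):
            plant_shifted_frame_stops(
                base, [(+1, 1, "TAA"), (-1, 1, "TAG")], seed=0, keep_start_codon=False
            )

    def test_sequence_edits_are_local_to_codon_scale(self, rng):
        base = CodingSequence("p", "ATG" + random_dna(rng, 120) + "TAA")
        planted = plant_shifted_frame_stops(base, [(+1, 7, "TGA")], seed=5)
        assert len(planted.seq) == len(base.seq)
        assert planted.seq.startswith("ATG") and planted.seq.endswith("TAA")


@pytest.fixture(scope="module")
def config():
    return SimulationConfig(
        n_genes=24, length_distribution=(25, 45), seed=21,
        planted_taa_free_fraction=0.25,
    )


class TestAnnotatedGenome:

    def test_scan_reproduces_truth_exactly(self, config, tmp_path_factory):
        sim = simulate_annotated_genome(config, tmp_path_factory.mktemp("gb"))
        from hiddenframe.io import extract_cds

        summary, table = genome_scan(extract_cds(sim.genbank_path))
        assert summary.percent_taa_free == pytest.approx(
            sim.expected_percent_taa_free["both"]
        )
        merged = table.merge(sim.truth, on="gene_id", suffixes=("_scan", "_truth"))
        assert len(merged) == len(sim.truth)
        assert (merged["stops_plus1_scan"] == merged["stops_plus1_truth"]).all()
        assert (merged["stops_minus1_scan"] == merged["stops_minus1_truth"]).all()

    def test_genbank_and_gff3_routes_agree(self, config, tmp_path_factory):
        sim = simulate_annotated_genome(config, tmp_path_factory.mktemp("two"))
        from hiddenframe.io import extract_cds

        s_gb, t_gb = genome_scan(extract_cds(sim.genbank_path))
        s_gff, t_gff = genome_scan(extract_cds(sim.gff3_path, sim.fasta_path))
        assert s_gb.to_dict() == s_gff.to_dict()
        a = t_gb.sort_values("gene_id").reset_index(drop=True)
        b = t_gff.sort_values("gene_id").reset_index(drop=True)
        assert (a["stops_plus1"] == b["stops_plus1"]).all()

    def test_strand_invariance(self, config, tmp_path_factory):
        from hiddenframe.io import extract_cds

        mixed = simulate_annotated_genome(config, tmp_path_factory.mktemp("mix"))
        minus = simulate_annotated_genome(
            config, tmp_path_factory.mktemp("minus"), all_minus_strand=True
        )
        _, t_mixed = genome_scan(extract_cds(mixed.genbank_path))
        _, t_minus = genome_scan(extract_cds(minus.genbank_path))
        cols = ["gene_id", "stops_plus1", "stops_minus1", "candidate_both_frames"]
        a = t_mixed[cols].sort_values("gene_id").reset_index(drop=True)
        b = t_minus[cols].sort_values("gene_id").reset_index(drop=True)
        assert a.equals(b)

    def test_emission_is_byte_deterministic(self, config, tmp_path_factory):
        sims = [
            simulate_annotated_genome(config, tmp_path_factory.mktemp(f"d{i}"))
            for i in range(2)
        ]
        assert sims[0].fasta_path.read_bytes() == sims[1].fasta_path.read_bytes()
        assert sims[0].gff3_path.read_bytes() == sims[1].gff3_path.read_bytes()


class TestToxinLikeFixtures:
    @pytest.mark.parametrize("n_codons", [20, 30, 58])
    def test_hydrophobic_orf_size_and_gravy(self, n_codons):
        cds = hydrophobic_orf(n_codons, seed=1)
        assert len(cds.seq) == 3 * n_codons
        from hiddenframe.core import shift_frame, translate

        protein = translate(shift_frame(cds, 0)).protein
        assert protein.endswith("*") and len(protein) - 1 == n_codons - 1
        assert gravy(protein[:-1]) >= 1.0
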
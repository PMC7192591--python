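"""TAA-absence candidate screening: gene records, retention rule, genome scan."""

import numpy as np
import pytest

from hiddenframe.core import CodingSequence
from hiddenframe.screen import (
    EXCEPTION_POSSIBLE,
    LOST,
    RETAINED,
    ScanPolicy,
    genome_scan,
    predict_function_retention,
    screen_gene,
)
from hiddenframe.simulate import (
    SimulationConfig,
    plant_shifted_frame_stops,
    simulate_cds_set,
)

from conftest import random_dna


def _random_gene(rng, n_codons=40):
    body = random_dna(rng, 3 * (n_codons - 2))
    return CodingSequence("g", "ATG" + body + "TAA", includes_stop=True)


class TestScreenGene:
    def test_constructed_asymmetric_gene(self, rng):
        cds = plant_shifted_frame_stops(
            _random_gene(rng),
            targets=[(+1, 5, "TAA")],
            forbids=[(-1, "TAA")],
            seed=7,
        )
        rec = screen_gene(cds)
        assert not rec.taa_free_plus1
        assert rec.taa_free_minus1
        assert not rec.candidate_both_frames

    def test_dfrb3_type_candidate_geometry(self, dfrb3_like):
        rec = screen_gene(dfrb3_like)
        assert [(e.codon, e.index) for e in rec.stops_plus1] == [("TAG", 11), ("TGA", 50)]
        assert [(e.codon, e.index) for e in rec.stops_minus1] == [("TGA", 52), ("TGA", 74)]
        assert rec.candidate_both_frames

    def test_screening_is_deterministic(self, ibsc_like):
        a, b = screen_gene(ibsc_like), screen_gene(ibsc_like)
        assert a.stops_plus1 == b.stops_plus1
        assert a.taa_free_minus1 == b.taa_free_minus1

    def test_flags_mirror_taa_counts(self, ibsc_like):
        rec = screen_gene(ibsc_like)
        assert rec.taa_free_plus1 == (rec.stop_counts(1)["TAA"] == 0)
        assert rec.taa_free_minus1 == (rec.stop_counts(-1)["TAA"] == 0)

    def test_tail_tolerance_forgives_terminal_proximal_taa(self, ibsc_like):
        # the toxic +1 frame carries TAA at codon 18 of 19
        strict = screen_gene(ibsc_like)
        assert not strict.taa_free_plus1
        lenient = screen_gene(ibsc_like, ScanPolicy(taa_tail_tolerance=0.15))
        assert lenient.taa_free_plus1

    def test_planting_taa_never_creates_a_candidate(self, rng):
        for trial in range(20):
            cds = _random_gene(np.random.default_rng(trial), 30)
            before = screen_gene(cds).candidate_both_frames
            edited = plant_shifted_frame_stops(
                cds, targets=[(+1, 4, "TAA")], seed=trial
            )
            after = screen_gene(edited).candidate_both_frames
            assert not after or before  # false -> true is impossible
            assert not after


class TestRetentionRule:
    def test_tga_only_frame_is_retained(self, ibsc_like):
        rec = screen_gene(ibsc_like, ScanPolicy(taa_tail_tolerance=0.15))
        assert predict_function_retention(rec, +1) == RETAINED

    def test_taa_without_domain_information_is_lost(self, rng):
        cds = plant_shifted_frame_stops(_random_gene(rng), [(+1, 3, "TAA")], seed=1)
        assert predict_function_retention(screen_gene(cds), +1) == LOST

    def test_taa_past_n_terminal_domain_is_exception_possible(self, rng):
        cds = plant_shifted_frame_stops(
            _random_gene(rng, 45), [(+1, 40, "TAA")], forbids=[(+1, "TAA")], seed=2
        )
        rec = screen_gene(cds)
        assert predict_function_retention(rec, +1, domain_end_codon=20) == EXCEPTION_POSSIBLE
        assert predict_function_retention(rec, +1, domain_end_codon=41) == LOST

    def test_invalid_shift_rejected(self, ibsc_like):
        with pytest.raises(ValueError, match="invalid shift"):
            predict_function_retention(screen_gene(ibsc_like), 0)


@pytest.fixture(scope="module")
def cds_set():
    config = SimulationConfig(
        n_genes=60, length_distribution=(30, 60), seed=11,
        planted_taa_free_fraction=0.25,
    )
    return simulate_cds_set(config)


class TestGenomeScan:

    def test_planted_fraction_recovered_exactly(self, cds_set):
        genes, _ = cds_set
        summary, _ = genome_scan(genes)
        assert summary.percent_taa_free == pytest.approx(25.0)
        assert summary.n_taa_free == 15

    def test_partition_of_counts(self, cds_set):
        genes, _ = cds_set
        summary, table = genome_scan(genes)
        screened = table[~table["skipped"]]
        n_with_taa = (~screened["candidate_both_frames"].astype(bool)).sum()
        assert summary.n_taa_free + n_with_taa + summary.n_cds_skipped == summary.n_cds_total

    def test_per_gene_rows_agree_with_isolated_screen(self, cds_set):
        genes, _ = cds_set
        _, table = genome_scan(genes)
        for cds in genes[:10]:
            rec = screen_gene(cds)
            row = table[table["gene_id"] == cds.id].iloc[0]
            assert row["candidate_both_frames"] == rec.candidate_both_frames
            got = row["stops_plus1"]
            assert got == ";".join(f"{e.codon}@{e.index}" for e in rec.stops_plus1)

    def test_skip_rules_are_logged(self, cds_set):
        genes, _ = cds_set
        records = [(g, {}) for g in genes]
        records.append((CodingSequence("odd", "ATGAAAT", includes_stop=False), {}))
        records.append((CodingSequence("ps", genes[0].seq), {"pseudo": True}))
        records.append(
            (CodingSequence("nn", "ATG" + "N" * 30 + "TAA"), {})
        )
        summary, table = genome_scan(records)
        assert summary.n_cds_skipped == 3
        assert set(summary.skip_reasons) == {
            "length not divisible by 3",
            "pseudogene",
            "N fraction 0.83 above threshold",
        }
        assert summary.percent_taa_free == pytest.approx(25.0)

    def test_per_frame_percentages_reported_alongside(self, cds_set):
        genes, truth = cds_set
        summary, _ = genome_scan(genes)
        assert summary.criterion == "both"
        expect_p1 = 100.0 * truth["taa_free_plus1"].mean()
        assert summary.percent_by_criterion["plus1"] == pytest.approx(expect_p1)
        assert summary.percent_by_criterion["both"] == pytest.approx(25.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no CDS features"):
            genome_scan([])
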
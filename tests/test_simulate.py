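"""Synthetic-data generators: determinism, planting fidelity, CLIP placement
weighting, LFQ effect/missingness structure, assay fixture round trips."""

import io

import numpy as np
import pandas as pd
import pytest

from rg4kit import assays, qgrs, simulate as sim
from rg4kit.simulate import (
    ConfigError,
    PlantedMotifSpec,
    SimClipConfig,
    SimLfqConfig,
    SimTranscriptomeConfig,
)
from rg4kit.transcripts import write_fasta


def _fasta_bytes(transcripts) -> bytes:
    buf = io.StringIO()
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(t.sequence), id=t.transcript_id, description="") for t in transcripts],
        buf,
        "fasta",
    )
    return buf.getvalue().encode()


class TestTranscriptome:
    def test_zero_rate_yields_empty_truth(self):
        cfg = SimTranscriptomeConfig(
            n_transcripts=5,
            g4_rate_per_region={"5UTR": 0.0, "CDS": 0.0, "3UTR": 0.0},
            seed=3,
        )
        _, truth = sim.simulate_transcriptome(cfg)
        assert truth.empty

    def test_planted_sequence_matches_spec(self):
        """Planted (g=3, loops 2,2,2) subsequences equal the canonical
        GGGnnGGGnnGGGnnGGG pattern with non-G loop bases."""
        cfg = SimTranscriptomeConfig(n_transcripts=10, seed=4)
        transcripts, truth = sim.simulate_transcriptome(cfg)
        by_id = {t.transcript_id: t for t in transcripts}
        assert len(truth) > 0
        for row in truth.itertuples():
            motif = by_id[row.transcript_id].sequence[row.start : row.end]
            assert len(motif) == 18
            for lo in (0, 5, 10, 15):
                assert motif[lo : lo + 3] == "GGG"
            for lo in (3, 8, 13):
                assert "G" not in motif[lo : lo + 2]

    def test_deterministic_fasta_output(self):
        cfg = SimTranscriptomeConfig(n_transcripts=5, seed=11)
        t1, truth1 = sim.simulate_transcriptome(cfg)
        t2, truth2 = sim.simulate_transcriptome(cfg)
        assert _fasta_bytes(t1) == _fasta_bytes(t2)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_cds_length_multiple_of_three(self):
        cfg = SimTranscriptomeConfig(n_transcripts=8, seed=5)
        transcripts, _ = sim.simulate_transcriptome(cfg)
        for t in transcripts:
            assert (t.cds_end - t.utr5_end) % 3 == 0

    def test_planted_motifs_never_overlap(self):
        cfg = SimTranscriptomeConfig(n_transcripts=20, seed=6)
        _, truth = sim.simulate_transcriptome(cfg)
        for _, grp in truth.groupby("transcript_id"):
            grp = grp.sort_values("start")
            assert (grp["start"].values[1:] >= grp["end"].values[:-1]).all()

    def test_region_too_short_rejected(self):
        # a 48 nt motif cannot fit in a ~30 nt 5'UTR
        cfg = SimTranscriptomeConfig(
            n_transcripts=5,
            region_lengths={"5UTR": (30.0, 0.0), "CDS": (300.0, 0.0), "3UTR": (300.0, 0.0)},
            g4_rate_per_region={"5UTR": 100.0, "CDS": 0.0, "3UTR": 0.0},
            planted_motif_spec=PlantedMotifSpec(g_run=3, loop_lengths=(12, 12, 12)),
            seed=7,
        )
        with pytest.raises(ConfigError, match="cannot host"):
            sim.simulate_transcriptome(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimTranscriptomeConfig(gc_content=1.5)
        with pytest.raises(ConfigError):
            SimTranscriptomeConfig(
                g4_rate_per_region={"5UTR": -1.0, "CDS": 0.0, "3UTR": 0.0}
            )
        with pytest.raises(ConfigError):
            PlantedMotifSpec(g_run=1)

    def test_planted_are_only_threshold_passing_motifs(self, small_transcriptome, small_catalog):
        """Background cleanup guarantees the catalog equals the truth table."""
        _, _, truth = small_transcriptome
        cat_spans = {
            (r.transcript_id, r.start, r.end) for r in small_catalog.hits.itertuples()
        }
        truth_spans = {
            (r.transcript_id, r.start, r.end) for r in truth.itertuples()
        }
        assert cat_spans == truth_spans


def _coverage_fraction(transcripts, truth) -> float:
    covered = truth["end"].sub(truth["start"]).sum()
    total = sum(t.length for t in transcripts)
    return covered / total


@pytest.fixture(scope="module")
def planted_transcriptome():
    cfg = SimTranscriptomeConfig(n_transcripts=30, seed=8)
    return sim.simulate_transcriptome(cfg)


class TestClipSites:
    def _overlap_fraction(self, sites, truth):
        planted = {
            tid: (grp["start"].to_numpy(), grp["end"].to_numpy())
            for tid, grp in truth.sort_values("start").groupby("transcript_id")
        }
        n = 0
        for row in sites.df.itertuples():
            ps, pe = planted.get(row.chrom, (np.array([]), np.array([])))
            n += bool(np.any((ps < row.end) & (pe > row.start)))
        return n / len(sites)

    def test_uniform_placement_matches_coverage(self, planted_transcriptome):
        """factor 1 with unit-length sites: overlap fraction approximates the
        fraction of positions covered by planted motifs."""
        transcripts, truth = planted_transcriptome
        cov = _coverage_fraction(transcripts, truth)
        cfg = SimClipConfig(
            n_sites=4000, site_length_mean=1, site_length_sd=0,
            g4_enrichment_factor=1.0, seed=9,
        )
        sites = sim.simulate_clip_sites(transcripts, truth, cfg)
        frac = self._overlap_fraction(sites, truth)
        sd = np.sqrt(cov * (1 - cov) / 4000)
        assert abs(frac - cov) <= 3 * sd

    def test_enrichment_factor_increases_overlap(self, planted_transcriptome):
        transcripts, truth = planted_transcriptome
        for seed in (1, 2, 3):
            f1 = self._overlap_fraction(
                sim.simulate_clip_sites(
                    transcripts, truth, SimClipConfig(n_sites=800, g4_enrichment_factor=1.0, seed=seed)
                ),
                truth,
            )
            f10 = self._overlap_fraction(
                sim.simulate_clip_sites(
                    transcripts, truth, SimClipConfig(n_sites=800, g4_enrichment_factor=10.0, seed=seed)
                ),
                truth,
            )
            assert f10 > f1

    def test_zero_factor_means_zero_overlap(self, planted_transcriptome):
        transcripts, truth = planted_transcriptome
        cfg = SimClipConfig(n_sites=500, g4_enrichment_factor=0.0, seed=10)
        sites = sim.simulate_clip_sites(transcripts, truth, cfg)
        assert self._overlap_fraction(sites, truth) == 0.0

    def test_deterministic_under_seed(self, planted_transcriptome):
        transcripts, truth = planted_transcriptome
        cfg = SimClipConfig(n_sites=100, seed=12)
        s1 = sim.simulate_clip_sites(transcripts, truth, cfg)
        s2 = sim.simulate_clip_sites(transcripts, truth, cfg)
        pd.testing.assert_frame_equal(s1.df, s2.df)

    def test_unknown_transcript_in_truth_rejected(self, planted_transcriptome):
        transcripts, truth = planted_transcriptome
        bad = truth.copy()
        bad.loc[bad.index[0], "transcript_id"] = "missing"
        with pytest.raises(ValueError, match="absent"):
            sim.simulate_clip_sites(transcripts, bad, SimClipConfig(n_sites=10, seed=0))

    def test_too_many_sites_rejected(self):
        cfg = SimTranscriptomeConfig(
            n_transcripts=1,
            region_lengths={"5UTR": (40.0, 0.0), "CDS": (90.0, 0.0), "3UTR": (40.0, 0.0)},
            g4_rate_per_region={"5UTR": 0.0, "CDS": 0.0, "3UTR": 0.0},
            seed=1,
        )
        transcripts, truth = sim.simulate_transcriptome(cfg)
        with pytest.raises(ValueError, match="exceeds"):
            sim.simulate_clip_sites(
                transcripts, truth, SimClipConfig(n_sites=10000, seed=0)
            )


class TestLfq:
    def test_zero_fraction_differential_all_null(self):
        _, truth = sim.simulate_lfq(SimLfqConfig(n_proteins=200, frac_differential=0.0, seed=1))
        assert (truth["label"] == "null").all()

    def test_mcar_limit_missingness_rate(self):
        """slope = 0: dropout probability is constant (0.5) regardless of
        intensity."""
        cfg = SimLfqConfig(n_proteins=2000, mnar_slope=0.0, seed=2)
        table, _ = sim.simulate_lfq(cfg)
        mat = table.filter(regex="^(WT|7dG)_").to_numpy()
        rate = (mat == 0).mean()
        n = mat.size
        assert abs(rate - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_effect_size_recovered_at_large_n(self):
        """Law of large numbers: empirical WT-7dG log2 difference approaches
        the planted effect at n_pairs = 200."""
        # steep logistic far below the intensity range: p_missing ~ 0
        cfg = SimLfqConfig(
            n_proteins=20, n_pairs=200, frac_differential=1.0,
            true_log2_effect=1.0, mnar_slope=5.0, mnar_midpoint=0.0, seed=3,
        )
        table, truth = sim.simulate_lfq(cfg)
        wt = np.log2(table.filter(regex="^WT_").to_numpy())
        dg = np.log2(table.filter(regex="^7dG_").to_numpy())
        d = (wt - dg).mean(axis=1)
        sd = (wt - dg).std(axis=1, ddof=1)
        assert np.all(np.abs(d - 1.0) <= 3 * sd / np.sqrt(200))

    def test_mnar_direction(self):
        """Missing entries have lower mean true intensity than observed ones
        whenever the dropout slope is positive."""
        cfg = SimLfqConfig(n_proteins=1000, seed=4)
        table, _ = sim.simulate_lfq(cfg)
        mat = table.filter(regex="^(WT|7dG)_").to_numpy()
        assert (mat == 0).any()  # the generator itself asserts the direction

    def test_n_pairs_below_two_rejected(self):
        with pytest.raises(ConfigError):
            SimLfqConfig(n_pairs=1)

    def test_deterministic(self):
        cfg = SimLfqConfig(n_proteins=100, seed=5)
        t1, r1 = sim.simulate_lfq(cfg)
        t2, r2 = sim.simulate_lfq(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(r1, r2)


class TestAssayFixtures:
    def test_round_trips_exact(self):
        fx = sim.simulate_assays(seed=1)
        # ddCt
        for row in fx.ddct_table.itertuples():
            fold = assays.ddct_expression(
                row.ct_target_treated, row.ct_ref_treated,
                row.ct_target_control, row.ct_ref_control,
            )
            assert fold == pytest.approx(fx.truth["ddct_fold"][row.gene], abs=1e-9)
        # RIP
        enr = assays.rip_enrichment(fx.rip_table, "HPRT")
        for gene, expected in fx.truth["rip_enrichment"].items():
            assert enr[gene] == pytest.approx(expected, abs=1e-9)
        # polysome TE
        for row in fx.polysome_table.itertuples():
            te = assays.polysome_te(
                assays.PolysomeQuant(row.np_amount, row.lp_amount, row.hp_amount)
            )
            assert te == pytest.approx(fx.truth["polysome_te"][row.gene], abs=1e-9)
        # plating efficiency
        for row in fx.colony_table.itertuples():
            pe = assays.clonogenic_survival(row.colonies, row.plated)
            assert pe == pytest.approx(
                fx.truth["plating_efficiency_pct"][row.condition], abs=1e-9
            )

    def test_anchor_values(self):
        fx = sim.simulate_assays(seed=2)
        assert fx.truth["ddct_fold"]["anchor_fold1"] == 1.0
        assert fx.truth["polysome_te"]["anchor_te030"] == 0.30
        assert fx.truth["plating_efficiency_pct"]["anchor_pe40"] == 40.0

    def test_deterministic(self):
        f1 = sim.simulate_assays(seed=3)
        f2 = sim.simulate_assays(seed=3)
        pd.testing.assert_frame_equal(f1.ddct_table, f2.ddct_table)
        assert f1.truth == f2.truth
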
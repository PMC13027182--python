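"""Interval operations against exhaustive oracles; qPCR arithmetic; I/O."""

import numpy as np
import pandas as pd
import pytest

import af1pipe as af
from af1pipe import io as afio
from af1pipe.chip import sort_and_merge
from af1pipe.diffexpr import ContrastSpec
from af1pipe.simulate import ChipConfig, EffectConfig

from conftest import brute_force_consensus, random_peaks


def peaks_df(*intervals, chrom="chr1"):
    return pd.DataFrame(
        [{"chrom": chrom, "start": a, "end": b} for a, b in intervals]
    )


class TestConsensus:
    def test_identical_replicates_reproduce_input(self):
        rep = peaks_df((100, 200), (400, 500))
        out = af.build_consensus([rep, rep, rep], min_support=2, min_width=1)
        pd.testing.assert_frame_equal(out, rep.astype({"start": np.int64, "end": np.int64}))

    def test_hand_counted_overlap(self):
        r1 = peaks_df((100, 200))
        r2 = peaks_df((150, 250))
        r3 = peaks_df((400, 500))
        out = af.build_consensus([r1, r2, r3], min_support=2, min_width=50)
        assert out.to_dict("records") == [{"chrom": "chr1", "start": 150, "end": 200}]

    def test_min_width_filters_short_runs(self):
        r1 = peaks_df((100, 160))
        r2 = peaks_df((130, 250))
        out = af.build_consensus([r1, r2], min_support=2, min_width=50)
        assert len(out) == 0  # overlap [130,160) is 30 bp

    def test_min_support_validation(self):
        with pytest.raises(ValueError):
            af.build_consensus([peaks_df((0, 10))], min_support=2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_per_base_oracle_on_random_intervals(self, seed):
        rng = np.random.default_rng(seed)
        reps = [random_peaks(rng, 300) for _ in range(3)]
        fast = af.build_consensus(reps, min_support=2, min_width=50)
        slow = brute_force_consensus(reps, 2, 50)
        pd.testing.assert_frame_equal(
            fast.astype({"start": np.int64, "end": np.int64}),
            slow.astype({"start": np.int64, "end": np.int64}),
        )

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        reps = [random_peaks(rng, 200) for _ in range(3)]
        cons = af.build_consensus(reps, min_support=2, min_width=50)
        again = af.build_consensus([cons] * 3, min_support=3, min_width=1)
        pd.testing.assert_frame_equal(cons, again)

    def test_output_sorted_non_overlapping(self):
        rng = np.random.default_rng(6)
        reps = [random_peaks(rng, 400) for _ in range(3)]
        cons = af.build_consensus(reps, min_support=1, min_width=1)
        assert (cons["start"] < cons["end"]).all()
        assert (cons["start"].to_numpy()[1:] > cons["end"].to_numpy()[:-1]).all()


def annotation_df(rows):
    ann = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
    ann["score"] = 0
    ann["tss"] = np.where(ann["strand"] == "+", ann["start"], ann["end"] - 1)
    return ann


class TestNearestTss:
    def test_peak_on_plus_strand_tss(self):
        ann = annotation_df([("chr1", 1000, 2000, "gA", "+")])
        peaks = peaks_df((900, 1100))  # center 1000 = TSS
        out = af.nearest_tss(peaks, ann)
        assert out["signed_distance"].tolist() == [0]

    def test_minus_strand_sign_convention(self):
        # - strand gene [1000, 2000): TSS = 1999; peak centred at 1980 lies
        # downstream (toward lower coordinates) -> signed distance -19
        ann = annotation_df([("chr1", 1000, 2000, "gA", "-")])
        peaks = peaks_df((1970, 1990))
        out = af.nearest_tss(peaks, ann)
        assert out["signed_distance"].tolist() == [-19]

    def test_plus_strand_upstream_is_positive(self):
        ann = annotation_df([("chr1", 1000, 2000, "gA", "+")])
        peaks = peaks_df((890, 910))  # center 900, 100 bp upstream of TSS
        out = af.nearest_tss(peaks, ann)
        assert out["signed_distance"].tolist() == [100]

    def test_missing_chromosome_unassigned(self):
        ann = annotation_df([("chr1", 1000, 2000, "gA", "+")])
        peaks = peaks_df((0, 100), chrom="chrX")
        out = af.nearest_tss(peaks, ann)
        assert out["gene_id"].tolist() == [""]
        assert np.isnan(out["signed_distance"]).all()

    def test_tie_breaks_to_lower_gene_id(self):
        ann = annotation_df(
            [("chr1", 900, 1500, "gB", "+"), ("chr1", 500, 1101, "gA", "-")]
        )
        # TSSs at 900 (gB) and 1100 (gA); peak centre 1000 equidistant
        out = af.nearest_tss(peaks_df((950, 1050)), ann)
        assert out["gene_id"].tolist() == ["gA"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_all_pairs_search(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 990_000))
            genes.append(
                ("chr1", start, start + int(rng.integers(2000, 10000)), f"g{i:03d}",
                 "+" if rng.uniform() < 0.5 else "-")
            )
        ann = annotation_df(genes)
        peaks = random_peaks(rng, 500)
        fast = af.nearest_tss(peaks, ann)
        centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
        for i, c in enumerate(centers):
            d = np.abs(ann["tss"].to_numpy() - c)
            best = d.min()
            expected = ann.loc[d == best, "gene_id"].min()
            assert fast.loc[i, "gene_id"] == expected
            assert fast.loc[i, "distance"] == best

    def test_histogram_counts_sum_to_peak_count(self):
        rng = np.random.default_rng(3)
        ann = annotation_df([("chr1", 500_000, 510_000, "gA", "+")])
        peaks = random_peaks(rng, 200)
        _, hist = af.tss_distance_profile(peaks, ann, np.arange(-600_000, 600_001, 100_000))
        assert hist["count"].sum() == 200


class TestAnnotateRegions:
    def test_promoter_precedence_over_gene_body(self):
        ann = annotation_df([("chr1", 1000, 20_000, "gA", "+")])
        inside_promoter = peaks_df((1100, 1300))  # center 1200 < TSS+500
        assert af.annotate_regions(inside_promoter, ann).tolist() == ["promoter"]

    def test_gene_body_and_intergenic(self):
        ann = annotation_df([("chr1", 1000, 20_000, "gA", "+")])
        assert af.annotate_regions(peaks_df((5000, 5400)), ann).tolist() == ["gene_body"]
        assert af.annotate_regions(peaks_df((500_000, 500_200)), ann).tolist() == [
            "intergenic"
        ]

    def test_upstream_promoter_window_minus_strand(self):
        ann = annotation_df([("chr1", 1000, 2000, "gA", "-")])
        # TSS 1999; upstream (higher coordinates) 2000 bp window
        up = peaks_df((3000, 3500))  # center 3250 within 1999 + 2000
        assert af.annotate_regions(up, ann).tolist() == ["promoter"]
        beyond = peaks_df((4200, 4400))
        assert af.annotate_regions(beyond, ann).tolist() == ["intergenic"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_all_pairs_classification(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(40):
            start = int(rng.integers(10_000, 900_000))
            genes.append(
                ("chr1", start, start + int(rng.integers(2000, 10000)), f"g{i:03d}",
                 "+" if rng.uniform() < 0.5 else "-")
            )
        ann = annotation_df(genes)
        peaks = random_peaks(rng, 300)
        fast = af.annotate_regions(peaks, ann, 2000, 500)
        centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
        for i, c in enumerate(centers):
            in_prom = False
            in_body = False
            for _, g in ann.iterrows():
                if g["strand"] == "+":
                    pa, pb = g["tss"] - 2000, g["tss"] + 500
                else:
                    pa, pb = g["tss"] - 500 + 1, g["tss"] + 2000 + 1
                if pa <= c < pb:
                    in_prom = True
                if g["start"] <= c < g["end"]:
                    in_body = True
            expected = "promoter" if in_prom else ("gene_body" if in_body else "intergenic")
            assert fast.iloc[i] == expected


class TestDifferentialBinding:
    def test_identical_columns_give_no_calls(self, chip_design):
        rng = np.random.default_rng(1)
        col = rng.poisson(150, size=60)
        counts = pd.DataFrame(
            np.tile(col[:, None], (1, 6)), columns=chip_design["sample_id"]
        )
        counts.index = [f"p{i}" for i in range(60)]
        _, sig = af.differential_binding(
            counts, chip_design, ContrastSpec(treatment="R5020", numerator="FFF", denominator="WT")
        )
        assert len(sig) == 0

    def test_swap_flips_log2fc_keeps_p(self, chip_design):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(100, size=(50, 6)), columns=chip_design["sample_id"]
        )
        counts.index = [f"p{i}" for i in range(50)]
        fwd, _ = af.differential_binding(
            counts, chip_design, ContrastSpec(treatment="R5020", numerator="FFF", denominator="WT")
        )
        rev, _ = af.differential_binding(
            counts, chip_design, ContrastSpec(treatment="R5020", numerator="WT", denominator="FFF")
        )
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"], atol=1e-8)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-10)

    def test_true_occupancy_shifts_detected(self, chip_design):
        truth = af.generate_truth(
            1000,
            {"NULL": 0.625, "LIGAND_UP": 0.125, "ATTENUATED_FFF": 0.125, "HYPER_QQQ": 0.125},
            EffectConfig(dispersion=0.05),
            seed=301,
        )
        cfg = ChipConfig(n_peaks=500, frac_differential=0.1)
        chip = af.simulate_chip_data(truth, chip_design, config=cfg, seed=301)
        _, sig = af.differential_binding(
            chip["peak_counts"], chip_design,
            ContrastSpec(treatment="R5020", numerator="FFF", denominator="WT"),
        )
        latent = chip["latent_peaks"]
        diff_ids = set(latent.loc[latent["is_differential"], "peak_id"])
        sens = len(set(sig["peak_id"]) & diff_ids) / len(diff_ids)
        assert sens >= 0.8
        assert (sig["log2FoldChange"] > 0)[sig["peak_id"].isin(diff_ids)].all()


class TestIntegration:
    def test_empty_differential_set(self):
        tax = pd.DataFrame({"gene_id": ["g1"], "category": ["HYPO"]})
        ann = annotation_df([("chr1", 0, 1000, "g1", "+")])
        rec, summary = af.integrate_expression(
            pd.DataFrame(columns=["peak_id", "log2FoldChange", "padj"]),
            pd.DataFrame(columns=["peak_id", "chrom", "start", "end"]),
            ann,
            tax,
        )
        assert len(rec) == 0
        assert summary["n_differential_peaks"] == 0
        assert summary["frac_associated"] == 0.0

    def test_constructed_association_tally(self):
        """8 peaks near attenuated-gene TSSs + 2 far intergenic peaks."""
        genes = [(f"chr1", 100_000 * (i + 1), 100_000 * (i + 1) + 5000, f"g{i}", "+") for i in range(8)]
        ann = annotation_df(genes)
        tax = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(8)],
             "category": ["HYPO"] * 4 + ["LOST"] * 2 + ["INTERMEDIATE_LOW"] * 2}
        )
        rows = []
        for i in range(8):
            tss = 100_000 * (i + 1)
            rows.append({"peak_id": f"p{i}", "chrom": "chr1", "start": tss - 200, "end": tss + 200})
        rows.append({"peak_id": "p8", "chrom": "chr2", "start": 5_000_000, "end": 5_000_400})
        rows.append({"peak_id": "p9", "chrom": "chr2", "start": 6_000_000, "end": 6_000_400})
        locations = pd.DataFrame(rows)
        db = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(10)],
             "log2FoldChange": 1.5, "padj": 0.001}
        )
        rec, summary = af.integrate_expression(db, locations, ann, tax, window=50_000)
        assert summary["n_differential_peaks"] == 10
        assert summary["frac_associated"] == pytest.approx(0.8)
        assert summary["frac_attenuated_among_associated"] == pytest.approx(1.0)

    def test_empty_taxonomy_rejected(self):
        with pytest.raises(ValueError):
            af.integrate_expression(
                pd.DataFrame({"peak_id": ["p"], "log2FoldChange": [1.0], "padj": [0.01]}),
                pd.DataFrame({"peak_id": ["p"], "chrom": ["chr1"], "start": [0], "end": [100]}),
                annotation_df([("chr1", 0, 1000, "g1", "+")]),
                pd.DataFrame(columns=["gene_id", "category"]),
            )


class TestQpcr:
    def test_identity(self):
        assert af.qpcr_enrichment(25.0, 30.0, 25.0, 30.0, 0.01) == pytest.approx(1.0)

    def test_one_cycle_doubles(self):
        assert af.qpcr_enrichment(24.0, 30.0, 25.0, 30.0, 0.01) == pytest.approx(2.0)

    def test_full_input_limit_is_hundred_percent(self):
        # input_fraction 1 and equal Cts -> percent input 100 in both arms
        assert af.qpcr_enrichment(20.0, 20.0, 20.0, 20.0, 1.0) == pytest.approx(1.0)

    def test_invalid_input_fraction(self):
        with pytest.raises(ValueError):
            af.qpcr_enrichment(20, 20, 20, 20, 0.0)


class TestBedRoundTrip:
    def test_lossless_interval_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        peaks = random_peaks(rng, 100)
        merged = sort_and_merge(peaks)
        path = tmp_path / "peaks.bed"
        afio.write_bed(merged, path)
        back = afio.read_bed(path)
        pd.testing.assert_frame_equal(back, merged)
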
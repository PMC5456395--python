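"""Comparative-genomics operations on domain sets and annotations."""

import numpy as np
import pandas as pd
import pytest

from nadscape import genomics
from nadscape.layout import GenomeLayout
from nadscape.regions import DomainSet, FeatureSet, INAD, NAD, SignalTrack


def domain_set(intervals, label=NAD, chrom="chr1"):
    rows = [(chrom, s, e, label, np.nan) for s, e in intervals]
    return DomainSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"])
    )


def labeled_tiling(segments, chrom="chr1"):
    rows = [(chrom, s, e, lab, np.nan) for s, e, lab in segments]
    return DomainSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"])
    )


def signal(entries, chrom="chr1", name="sig"):
    frame = pd.DataFrame(entries, columns=["start", "end", "value"])
    frame.insert(0, "chrom", chrom)
    return SignalTrack(frame, name=name)


class TestComplement:
    def test_examples(self):
        layout = GenomeLayout(lengths={"chr1": 50})
        out = genomics.complement_intervals(domain_set([(10, 20)]), layout)
        assert out.frame[["start", "end"]].to_numpy().tolist() == [[0, 10], [20, 50]]
        empty = domain_set([(0, 10)]).frame.iloc[0:0]
        assert genomics.complement_intervals(DomainSet(empty.copy()), layout).total_bp() == 50
        assert len(genomics.complement_intervals(domain_set([(0, 50)]), layout)) == 0

    def test_out_of_bounds_rejected(self):
        layout = GenomeLayout(lengths={"chr1": 50})
        with pytest.raises(ValueError):
            genomics.complement_intervals(domain_set([(10, 60)]), layout)


class TestOverlapStats:
    def test_self_jaccard_is_one(self):
        a = domain_set([(0, 100), (200, 250)])
        stats = genomics.overlap_stats(a, a)
        assert stats["jaccard"] == 1.0
        assert stats["a_only_bp"] == 0

    def test_disjoint_jaccard_is_zero(self):
        stats = genomics.overlap_stats(domain_set([(0, 10)]), domain_set([(20, 30)]))
        assert stats["jaccard"] == 0.0

    def test_bp_enumeration_example(self):
        stats = genomics.overlap_stats(domain_set([(0, 100)]), domain_set([(50, 150)]))
        assert stats["intersection_bp"] == 50
        assert stats["union_bp"] == 150
        assert stats["jaccard"] == pytest.approx(1 / 3)

    def test_symmetry_and_consistency(self):
        rng = np.random.default_rng(6)
        a = domain_set(sorted((int(s), int(s) + int(w)) for s, w in
                              zip(rng.choice(900, 5, replace=False) * 10,
                                  rng.integers(5, 80, 5))))
        b = domain_set([(100, 400), (5000, 6000)])
        ab = genomics.overlap_stats(a, b)
        ba = genomics.overlap_stats(b, a)
        assert ab["jaccard"] == ba["jaccard"]
        assert ab["a_only_bp"] == ba["b_only_bp"]
        assert ab["a_only_bp"] + ab["b_only_bp"] + ab["intersection_bp"] == ab["union_bp"]
        assert 0 <= ab["jaccard"] <= 1


class TestStateComposition:
    def test_single_state_covering_all(self):
        domains = labeled_tiling([(0, 60, NAD), (60, 100, INAD)])
        states = FeatureSet(
            pd.DataFrame(
                [("chr1", 0, 100, "Quies", "Quies")],
                columns=["chrom", "start", "end", "name", "feature_class"],
            )
        )
        out = genomics.state_composition(domains, states)
        row = out.iloc[0]
        assert row["nad_fraction"] == 1.0
        assert row["inad_fraction"] == 1.0
        assert row["log2_ratio"] == 0.0

    def test_state_exclusive_to_nads_gets_infinite_ratio(self):
        domains = labeled_tiling([(0, 60, NAD), (60, 100, INAD)])
        states = FeatureSet(
            pd.DataFrame(
                [
                    ("chr1", 0, 60, "Het", "Het"),
                    ("chr1", 60, 100, "Quies", "Quies"),
                ],
                columns=["chrom", "start", "end", "name", "feature_class"],
            )
        )
        out = genomics.state_composition(domains, states).set_index("state")
        assert out.loc["Het", "nad_fraction"] == 1.0
        assert out.loc["Het", "inad_fraction"] == 0.0
        assert np.isinf(out.loc["Het", "log2_ratio"])

    def test_three_state_fractions_match_bp_enumeration(self):
        domains = labeled_tiling([(0, 40, NAD), (40, 100, INAD)])
        states = FeatureSet(
            pd.DataFrame(
                [
                    ("chr1", 0, 30, "A", "A"),
                    ("chr1", 30, 70, "B", "B"),
                    ("chr1", 70, 100, "C", "C"),
                ],
                columns=["chrom", "start", "end", "name", "feature_class"],
            )
        )
        out = genomics.state_composition(domains, states).set_index("state")
        assert out.loc["A", "nad_bp"] == 30 and out.loc["A", "inad_bp"] == 0
        assert out.loc["B", "nad_bp"] == 10 and out.loc["B", "inad_bp"] == 30
        assert out.loc["C", "nad_bp"] == 0 and out.loc["C", "inad_bp"] == 30
        assert out["nad_fraction"].sum() == pytest.approx(1.0)
        assert out["inad_fraction"].sum() == pytest.approx(1.0)

    def test_overlapping_states_rejected(self):
        domains = labeled_tiling([(0, 50, NAD), (50, 100, INAD)])
        states = FeatureSet(
            pd.DataFrame(
                [
                    ("chr1", 0, 60, "A", "A"),
                    ("chr1", 50, 100, "B", "B"),
                ],
                columns=["chrom", "start", "end", "name", "feature_class"],
            )
        )
        with pytest.raises(ValueError):
            genomics.state_composition(domains, states)


class TestFeatureDensity:
    def _features(self, rows):
        return FeatureSet(
            pd.DataFrame(
                [("chr1", s, e, f"f{i}", cls) for i, (s, e, cls) in enumerate(rows)],
                columns=["chrom", "start", "end", "name", "feature_class"],
            )
        )

    def test_all_features_in_nads_leaves_inads_empty(self):
        domains = labeled_tiling([(0, 500_000, NAD), (500_000, 1_000_000, INAD)])
        feats = self._features([(10, 100, "gene"), (1000, 4000, "gene")])
        out = genomics.feature_density(domains, feats).set_index("domain_class")
        assert out.loc[NAD, "count"] == 2
        assert out.loc[INAD, "count"] == 0

    def test_straddling_feature_assigned_by_majority(self):
        domains = labeled_tiling([(0, 100, NAD), (100, 1000, INAD)])
        # 30 bp in NAD, 70 bp in iNAD -> iNAD; exact tie -> NAD
        feats = self._features([(70, 170, "gene"), (50, 150, "tie")])
        out = genomics.feature_density(domains, feats)
        gene = out[(out.feature_class == "gene") & (out.domain_class == INAD)]
        tie = out[(out.feature_class == "tie") & (out.domain_class == NAD)]
        assert gene["count"].iloc[0] == 1
        assert tie["count"].iloc[0] == 1

    def test_uniform_features_equal_density(self):
        rng = np.random.default_rng(8)
        domains = labeled_tiling([(0, 500_000, NAD), (500_000, 1_000_000, INAD)])
        starts = rng.integers(0, 999_000, size=400)
        feats = self._features([(int(s), int(s) + 100, "gene") for s in sorted(starts)])
        out = genomics.feature_density(domains, feats).set_index("domain_class")
        d_nad = out.loc[NAD, "density_per_mb_class"]
        d_inad = out.loc[INAD, "density_per_mb_class"]
        assert abs(d_nad - d_inad) / max(d_nad, d_inad) < 0.25


class TestSegmentMeanSignal:
    def test_constant_signal(self):
        domains = labeled_tiling([(0, 100, NAD), (100, 200, INAD)])
        out = genomics.segment_mean_signal(domains, signal([(0, 200, 1.0)]))
        assert np.allclose(out["mean"], 1.0)

    def test_signal_restricted_to_inads(self):
        domains = labeled_tiling([(0, 100, NAD), (100, 200, INAD)])
        out = genomics.segment_mean_signal(domains, signal([(100, 200, 2.0)]))
        assert out.set_index("label").loc[NAD, "mean"] == 0.0
        assert out.set_index("label").loc[INAD, "mean"] == 2.0

    def test_half_covered_segment_mean(self):
        domains = labeled_tiling([(0, 100, NAD)])
        out = genomics.segment_mean_signal(domains, signal([(0, 50, 2.0)]))
        assert out["mean"].iloc[0] == pytest.approx(1.0)

    def test_matches_per_base_accumulation_oracle(self):
        rng = np.random.default_rng(9)
        cuts = np.sort(rng.choice(np.arange(1, 1000), size=8, replace=False))
        segs = list(zip(np.r_[0, cuts], np.r_[cuts, 1000]))
        domains = labeled_tiling(
            [(int(s), int(e), NAD if i % 2 == 0 else INAD) for i, (s, e) in enumerate(segs)]
        )
        sig_entries = [(i * 100, i * 100 + 60, float(rng.normal())) for i in range(10)]
        track = signal(sig_entries)
        base = np.zeros(1000)
        for s, e, v in sig_entries:
            base[s:e] = v
        out = genomics.segment_mean_signal(domains, track)
        for _, row in out.iterrows():
            assert row["mean"] == pytest.approx(base[row["start"]:row["end"]].mean())


class TestBorderMetaprofile:
    def test_constant_signal_gives_flat_profile(self):
        domains = labeled_tiling(
            [(0, 600_000, INAD), (600_000, 1_300_000, NAD), (1_300_000, 2_000_000, INAD)]
        )
        prof = genomics.border_metaprofile(
            domains, [signal([(0, 2_000_000, 3.0)])], flank=100_000, bin_size=10_000,
            min_width=500_000,
        )
        assert prof.n_domains == 1
        for arr in prof.means.values():
            assert np.allclose(arr[np.isfinite(arr)], 3.0)

    def test_step_signal_steps_at_offset_zero(self):
        domains = labeled_tiling(
            [(0, 600_000, INAD), (600_000, 1_400_000, NAD), (1_400_000, 2_000_000, INAD)]
        )
        step = signal([(600_000, 1_400_000, 1.0)])  # 1 inside the NAD, 0 outside
        prof = genomics.border_metaprofile(
            domains, [step], flank=100_000, bin_size=10_000, min_width=500_000
        )
        for side in ("5p", "3p"):
            arr = prof.means[("sig", side)]
            outside = arr[prof.offsets < 0]
            inside = arr[prof.offsets > 0]
            assert np.allclose(outside, 0.0)
            assert np.allclose(inside, 1.0)

    def test_width_filter_counts_qualifying_domains(self):
        domains = labeled_tiling(
            [
                (0, 400_000, NAD),
                (400_000, 1_000_000, INAD),
                (1_000_000, 1_600_000, NAD),
                (1_600_000, 2_000_000, INAD),
                (2_000_000, 2_800_000, NAD),
            ]
        )
        prof = genomics.border_metaprofile(
            domains, [signal([(0, 2_800_000, 1.0)])], flank=100_000,
            bin_size=10_000, min_width=500_000,
        )
        assert prof.n_domains == 2

    def test_no_qualifying_domain_warns_with_zero_n(self):
        domains = labeled_tiling([(0, 100_000, NAD), (100_000, 300_000, INAD)])
        with pytest.warns(UserWarning, match="min_width"):
            prof = genomics.border_metaprofile(
                domains, [signal([(0, 300_000, 1.0)])], flank=50_000,
                bin_size=10_000, min_width=500_000,
            )
        assert prof.n_domains == 0


class TestClassScoreSummary:
    def test_notch_formula(self):
        # IQR 2, n 16 -> notch = 1.58 * 2 / 4 = 0.79
        vals = np.concatenate([np.linspace(0, 2, 16)])
        out = genomics.class_score_summary(vals, ["a"] * 16)
        iqr = out["q3"].iloc[0] - out["q1"].iloc[0]
        assert out["notch"].iloc[0] == pytest.approx(1.58 * iqr / 4)

    def test_single_value_class_zero_notch(self):
        out = genomics.class_score_summary([5.0], ["a"])
        assert out["notch"].iloc[0] == 0.0
        assert out["median"].iloc[0] == 5.0

    def test_medians_match_sort_oracle(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=40)
        classes = np.array(["x"] * 25 + ["y"] * 15)
        out = genomics.class_score_summary(vals, classes).set_index("class")
        assert out.loc["x", "median"] == pytest.approx(np.median(vals[:25]))
        assert out.loc["y", "median"] == pytest.approx(np.median(vals[25:]))
        assert out.loc["x", "n"] == 25
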
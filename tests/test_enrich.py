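"""Enrichment statistics against brute-force set/record oracles."""

import numpy as np
import pandas as pd
import pytest

from chromspec import (
    FeatureIntervals,
    SnpSet,
    StateAnnotation,
    conservation_summary,
    fold_enrichment,
    gwas_enrichment,
    precision_recall,
    tss_distance_profile,
)

W = 100  # segment width used by the toy annotation fixture


def snps(records):
    return SnpSet(pd.DataFrame(records, columns=["chrom", "pos", "phenotype", "maf"]))


class TestFoldEnrichment:
    def test_half_genome_state_with_all_features(self):
        # One state covers 50% of segments and every feature segment.
        labels = {"chr1": np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])}
        ann = StateAnnotation(labels, segment_width=W)
        feats = FeatureIntervals("f", [("chr1", 0, 3 * W)])
        table = fold_enrichment(ann, feats)
        row = table[table.state == 1].iloc[0]
        assert row.log2_fold_enrichment == pytest.approx(1.0)

    def test_uniform_feature_is_unenriched(self):
        labels = {"chr1": np.tile([1, 2], 50)}
        ann = StateAnnotation(labels, segment_width=W)
        # Every segment overlaps the feature.
        feats = FeatureIntervals("f", [("chr1", 0, 100 * W)])
        table = fold_enrichment(ann, feats)
        np.testing.assert_allclose(table.log2_fold_enrichment, 0.0, atol=1e-12)

    def test_toy_fixture_matches_hand_enumeration(self, toy_annotation):
        # Features: [150,250) hits segments 1,2; [580,620) hits 5,6;
        # [900,1000) hits 9.
        feats = FeatureIntervals(
            "f", [("chr1", 150, 250), ("chr1", 580, 620), ("chr1", 900, 1000)]
        )
        table = fold_enrichment(toy_annotation, feats).set_index("state")
        # Hand counts: overlapping segments {1,2,5,6,9}; states:
        # seg1->1, seg2->2, seg5->3, seg6->3, seg9->3.
        assert table.loc[1, "observed"] == 1
        assert table.loc[2, "observed"] == 1
        assert table.loc[3, "observed"] == 3
        # state3 has 3/10 of segments, expected = 0.3*5 = 1.5 -> log2(2)=1.
        assert table.loc[3, "expected"] == pytest.approx(1.5)
        assert table.loc[3, "log2_fold_enrichment"] == pytest.approx(1.0)

    def test_observed_counts_conserved(self, toy_annotation, rng):
        feats = FeatureIntervals(
            "f", [("chr1", int(s), int(s) + 30) for s in rng.integers(0, 970, 5)]
        )
        table = fold_enrichment(toy_annotation, feats)
        assert table.observed.sum() == table.attrs["total_overlapping_segments"]

    def test_permutation_equivariance(self, toy_annotation):
        feats = FeatureIntervals("f", [("chr1", 0, 250)])
        base = fold_enrichment(toy_annotation, feats)
        relabel = {1: 3, 2: 1, 3: 2}
        swapped = StateAnnotation(
            {"chr1": np.array([relabel[s] for s in toy_annotation.labels["chr1"]])},
            segment_width=W,
        )
        other = fold_enrichment(swapped, feats).set_index("state")
        for old, new in relabel.items():
            assert other.loc[new, "observed"] == \
                base.set_index("state").loc[old, "observed"]


class TestPrecisionRecall:
    def test_perfect_prediction(self):
        labels = {"chr1": np.array([1, 1, 2, 2, 2])}
        ann = StateAnnotation(labels, segment_width=W)
        feats = FeatureIntervals("f", [("chr1", 0, 2 * W)])
        assert precision_recall(ann, [1], feats) == (1.0, 1.0)

    def test_empty_subset_rejected(self, toy_annotation):
        with pytest.raises(ValueError):
            precision_recall(toy_annotation, [], FeatureIntervals("f", []))

    def test_empty_prediction_flags_precision(self, toy_annotation):
        feats = FeatureIntervals("f", [("chr1", 0, W)])
        p, r = precision_recall(toy_annotation, [9], feats)
        assert np.isnan(p) and r == 0.0

    def test_matches_brute_force_set_computation(self, toy_annotation, rng):
        feats = FeatureIntervals(
            "f", [("chr1", int(s), int(s) + 40) for s in rng.integers(0, 960, 6)]
        )
        subset = {2, 3}
        p, r = precision_recall(toy_annotation, sorted(subset), feats)
        lab = toy_annotation.labels["chr1"]
        predicted = {i for i in range(10) if lab[i] in subset}
        overlapped = set()
        hit_elements = 0
        for chrom, s, e in feats.intervals:
            segs = set(range(s // W, -(-e // W)))
            overlapped |= segs
            if segs & predicted:
                hit_elements += 1
        assert p == pytest.approx(len(predicted & overlapped) / len(predicted))
        assert r == pytest.approx(hit_elements / len(feats.intervals))


class TestTssDistance:
    def test_midpoint_on_tss_is_zero(self):
        ann = StateAnnotation({"chr1": np.array([1])}, segment_width=W)
        tss = FeatureIntervals("tss", [("chr1", 49, 51)])  # midpoint 50
        prof = tss_distance_profile(ann, tss)
        assert prof.iloc[0].median_abs_distance == 0.0

    def test_distant_tss_outside_window(self):
        # Segment at [200,300) (midpoint 250); TSS point at 10,250.
        ann = StateAnnotation({"chr1": np.array([2, 2, 1])}, segment_width=W)
        tss = FeatureIntervals("tss", [("chr1", 10_249, 10_251)])
        prof = tss_distance_profile(ann, tss, window=5000).set_index("state")
        assert prof.loc[1, "median_abs_distance"] == pytest.approx(10_000)
        assert prof.loc[1, "fraction_within_window"] == 0.0

    def test_matches_linear_scan_oracle(self, toy_annotation, rng):
        points = np.sort(rng.integers(0, 1000, 4))
        tss = FeatureIntervals("tss", [("chr1", int(p), int(p) + 1) for p in points])
        prof = tss_distance_profile(toy_annotation, tss, window=150)
        lab = toy_annotation.labels["chr1"]
        for state in (1, 2, 3):
            dists = []
            for i in np.flatnonzero(lab == state):
                mid = i * W + W // 2
                dists.append(min(abs(mid - p) for p in points))
            expected_frac = np.mean([d <= 150 for d in dists])
            row = prof[prof.state == state].iloc[0]
            assert row.fraction_within_window == pytest.approx(expected_frac)
            assert row.median_abs_distance == pytest.approx(np.median(dists))

    def test_chromosome_without_tss(self):
        ann = StateAnnotation(
            {"chr1": np.array([1, 1]), "chr2": np.array([1, 1])}, segment_width=W
        )
        tss = FeatureIntervals("tss", [("chr1", 0, 1)])
        prof = tss_distance_profile(ann, tss, window=5000)
        # chr2 segments have infinite distance and stay in the denominator.
        assert prof.iloc[0].fraction_within_window == pytest.approx(0.5)
        prof2 = tss_distance_profile(ann, tss, window=5000,
                                     exclude_no_tss_chroms=True)
        assert prof2.iloc[0].fraction_within_window == pytest.approx(1.0)


class TestGwasEnrichment:
    def test_uniform_snps_are_unenriched(self, rng):
        labels = {"chr1": np.tile([1, 2], 500)}
        ann = StateAnnotation(labels, segment_width=W)
        pos = rng.integers(0, 1000 * W, size=2000)
        ss = snps([("chr1", int(p), "t", 0.2) for p in pos])
        res = gwas_enrichment(ann, ss, test_states=[1])
        fe = res["per_state"].log2_fold_enrichment
        assert np.abs(fe).max() < 0.1
        assert res["chi2"]["p_value"] > 0.01

    def test_concentrated_snps_hand_computation(self):
        # State 1 covers 25% of segments and receives every SNP: log2FE = 2.
        labels = {"chr1": np.array([1, 2, 3, 4] * 25)}
        ann = StateAnnotation(labels, segment_width=W)
        pos = [i * 4 * W + 10 for i in range(20)]  # all in state-1 segments
        ss = snps([("chr1", p, "t", 0.3) for p in pos])
        res = gwas_enrichment(ann, ss, test_states=[1])
        row = res["per_state"].set_index("state").loc[1]
        assert row.log2_fold_enrichment == pytest.approx(2.0)
        assert res["chi2"]["p_value"] < 1e-6

    def test_per_phenotype_argmax_matches_tabulation(self):
        labels = {"chr1": np.array([1] * 20 + [2] * 80)}
        ann = StateAnnotation(labels, segment_width=W)
        records = []
        # Phenotype A: 12 SNPs in state 1 (20% of genome) -> strongly enriched.
        records += [("chr1", i * W + 5, "A", 0.2) for i in range(12)]
        # Phenotype B: 15 SNPs in state 2.
        records += [("chr1", (20 + i) * W + 5, "B", 0.2) for i in range(15)]
        # Phenotype C below the 10-SNP floor: excluded.
        records += [("chr1", i * W + 5, "C", 0.2) for i in range(5)]
        res = gwas_enrichment(ann, snps(records), per_phenotype=True)
        best = res["most_enriched_state"].set_index("phenotype")
        assert best.loc["A", "best_state"] == 1
        assert best.loc["B", "best_state"] == 2
        assert "C" not in best.index
        assert res["n_phenotypes_excluded"] == 1

    def test_mask_removes_snps_before_counting(self):
        labels = {"chr1": np.array([1, 2] * 10)}
        ann = StateAnnotation(labels, segment_width=W)
        records = [("chr1", i * W + 1, "t", 0.2) for i in range(20)]
        mask = FeatureIntervals("mhc", [("chr1", 0, 10 * W)])
        res = gwas_enrichment(ann, snps(records), test_states=[1], mask=mask)
        assert res["per_state"].observed.sum() == 10

    def test_null_scatter_mean_enrichment_near_zero(self):
        # Property: across seeds, mean per-state log2FE ~ 0 for big states.
        labels = {"chr1": np.tile([1, 1, 2, 2, 3], 400)}
        ann = StateAnnotation(labels, segment_width=W)
        fes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pos = rng.integers(0, 2000 * W, size=3000)
            ss = snps([("chr1", int(p), "t", 0.2) for p in pos])
            res = gwas_enrichment(ann, ss, test_states=[1])
            fes.append(res["per_state"].log2_fold_enrichment.to_numpy())
        assert np.abs(np.mean(fes, axis=0)).max() < 0.1


class TestConservation:
    def test_uniform_low_maf_fraction(self):
        labels = {"chr1": np.array([1, 1, 2, 2])}
        ann = StateAnnotation(labels, segment_width=W)
        ss = snps([("chr1", 10, "t", 0.05), ("chr1", 110, "t", 0.05),
                   ("chr1", 210, "t", 0.3)])
        res = conservation_summary(ann, snps=ss)
        table = res["maf"].set_index("state")
        assert table.loc[1, "fraction_low_maf"] == 1.0
        assert table.loc[2, "fraction_low_maf"] == 0.0

    def test_rare_variants_dropped_before_fractions(self):
        labels = {"chr1": np.array([1])}
        ann = StateAnnotation(labels, segment_width=W)
        ss = snps([("chr1", 5, "t", 0.005), ("chr1", 6, "t", 0.05)])
        res = conservation_summary(ann, snps=ss)
        assert res["maf"].iloc[0].n_snps == 1

    def test_constant_score_gives_constant_means(self):
        labels = {"chr1": np.array([1, 2, 1])}
        ann = StateAnnotation(labels, segment_width=W)
        scores = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(0, 300, 10), "score": 0.5}
        )
        res = conservation_summary(ann, scores=scores)
        np.testing.assert_allclose(res["scores"].mean_score, 0.5)

    def test_matches_record_scan_oracle(self, rng):
        labels = {"chr1": rng.integers(1, 4, size=20)}
        ann = StateAnnotation(labels, segment_width=W)
        pos = rng.integers(0, 20 * W, size=200)
        maf = rng.uniform(0.0, 0.5, size=200)
        ss = snps([("chr1", int(p), "t", float(m)) for p, m in zip(pos, maf)])
        scores = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.arange(0, 20 * W, 7),
            "score": rng.random(len(np.arange(0, 20 * W, 7))),
        })
        res = conservation_summary(ann, snps=ss, scores=scores,
                                   compare_states=(1, 2))
        lab = labels["chr1"]
        for state in (1, 2, 3):
            keep = [(p, m) for p, m in zip(pos, maf)
                    if m >= 0.01 and lab[p // W] == state]
            if keep:
                frac = np.mean([m < 0.1 for _, m in keep])
                row = res["maf"].set_index("state").loc[state]
                assert row.fraction_low_maf == pytest.approx(frac)
            seg_means = {}
            for p, s in zip(scores.pos, scores.score):
                if lab[p // W] == state:
                    seg_means.setdefault(p // W, []).append(s)
            if seg_means:
                expected = np.mean([np.mean(v) for v in seg_means.values()])
                row = res["scores"].set_index("state").loc[state]
                assert row.mean_score == pytest.approx(expected)
        assert 0 <= res["mannwhitney"]["p_value"] <= 1

    def test_state_without_snps_flagged(self):
        labels = {"chr1": np.array([1, 2])}
        ann = StateAnnotation(labels, segment_width=W)
        ss = snps([("chr1", 5, "t", 0.2)])
        res = conservation_summary(ann, snps=ss)
        row = res["maf"].set_index("state").loc[2]
        assert row.flag == "no_snps" and np.isnan(row.fraction_low_maf)
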
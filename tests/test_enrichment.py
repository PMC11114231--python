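import numpy as np
import pandas as pd
import pytest

from creatlas.enrichment import (
    NON_ELEMENT_CLASS,
    TissueClass,
    ValidationRegion,
    classify_validation_tissue,
    priority_assign,
    region_class_weights,
    select_independent_traits,
    shuffle_enrichment,
    vista_weighted_validation,
    window_targets_from_tss,
)
from creatlas.tracks import ElementSet, GenomicInterval


def _classified():
    return ElementSet(
        [
            GenomicInterval("chr1", 100, 200, "A"),
            GenomicInterval("chr1", 300, 400, "F"),
            GenomicInterval("chr1", 600, 900, "N"),
        ],
        labels={"A": "adult-specific", "F": "fetal-specific", "N": "nb-cCRE"},
    )


class TestRegionWeights:
    def test_two_fully_contained_elements_split_half(self):
        region = ValidationRegion(GenomicInterval("chr1", 50, 450, "r"))
        w = region_class_weights(region, _classified())
        assert w == {
            "adult-specific": pytest.approx(0.5),
            "fetal-specific": pytest.approx(0.5),
        }

    def test_full_adult_plus_half_nb(self):
        # adult fully inside; nb-cCRE (300 bp) covered for 150 bp
        classified = ElementSet(
            [
                GenomicInterval("chr1", 100, 200, "A"),
                GenomicInterval("chr1", 600, 900, "N"),
            ],
            labels={"A": "adult-specific", "N": "nb-cCRE"},
        )
        region = ValidationRegion(GenomicInterval("chr1", 50, 750, "r"))
        w = region_class_weights(region, classified)
        assert w["adult-specific"] == pytest.approx(1.0 / 1.5)
        assert w["nb-cCRE"] == pytest.approx(0.5 / 1.5)
        assert round(w["adult-specific"], 2) == 0.67
        assert round(w["nb-cCRE"], 2) == 0.33

    def test_no_overlap_goes_to_non_element(self):
        region = ValidationRegion(GenomicInterval("chr2", 0, 100, "r"))
        assert region_class_weights(region, _classified()) == {NON_ELEMENT_CLASS: 1.0}

    def test_single_overlap_full_weight(self):
        region = ValidationRegion(GenomicInterval("chr1", 150, 250, "r"))
        assert region_class_weights(region, _classified()) == {"adult-specific": 1.0}

    def test_weights_sum_to_region_count(self):
        rng = np.random.default_rng(0)
        regions = [
            ValidationRegion(
                GenomicInterval(
                    "chr1", s := int(rng.integers(0, 900)), s + int(rng.integers(50, 500)), f"r{i}"
                )
            )
            for i in range(30)
        ]
        counts, _ = vista_weighted_validation(regions, _classified())
        assert counts.to_numpy().sum() == pytest.approx(30, abs=1e-9)


class TestTissueClass:
    def test_brain_dominates_eye(self):
        assert (
            classify_validation_tissue({"forebrain", "eye"}) is TissueClass.BRAIN
        )

    def test_eye_alone_is_nervous_nonbrain(self):
        assert classify_validation_tissue({"eye"}) is TissueClass.NERVOUS_NONBRAIN

    def test_empty_is_inactive(self):
        assert classify_validation_tissue(set()) is TissueClass.INACTIVE

    def test_unknown_tissue_warns_as_non_nervous(self):
        with pytest.warns(UserWarning, match="unknown"):
            out = classify_validation_tissue({"flipper"})
        assert out is TissueClass.NON_NERVOUS

    def test_known_non_nervous_does_not_warn(self):
        assert classify_validation_tissue({"limb"}) is TissueClass.NON_NERVOUS


class TestShuffleEnrichment:
    def test_targets_cover_genome_gives_one(self):
        sizes = {"chr1": 1000}
        query = ElementSet([GenomicInterval("chr1", 10, 20, f"q{i}") for i in range(3)])
        targets = ElementSet([GenomicInterval("chr1", 0, 1000, "all")])
        res = shuffle_enrichment(query, targets, sizes, n_shuffles=10, seed=1)
        assert res.enrichment == pytest.approx(1.0)
        assert res.observed == 3

    def test_planted_enrichment_matches_binomial_oracle(self):
        # targets cover 10% of a 10-kb chrom; query entirely inside them
        sizes = {"chr1": 10_000}
        targets = ElementSet([GenomicInterval("chr1", 0, 1000, "t")])
        query = ElementSet(
            [GenomicInterval("chr1", 10 * i, 10 * i + 8, f"q{i}") for i in range(100)]
        )
        res = shuffle_enrichment(query, targets, sizes, n_shuffles=100, seed=2)
        # binomial expectation: P(hit) ~ (1000 + 8 - 1) / (10000 - 8 + 1)
        p_hit = (1000 + 8 - 1) / (10_000 - 8 + 1)
        expected = 100 / (100 * p_hit)
        assert res.enrichment_vs_mean == pytest.approx(expected, rel=0.25)
        assert 0.6 * expected < res.enrichment < 1.6 * expected

    def test_empty_targets_error(self):
        sizes = {"chr1": 100}
        query = ElementSet([GenomicInterval("chr1", 0, 10, "q")])
        targets = ElementSet([GenomicInterval("chr2", 0, 10, "t")])
        with pytest.raises(ValueError, match="zero simulated"):
            shuffle_enrichment(query, targets, sizes, n_shuffles=5, seed=3)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty query"):
            shuffle_enrichment(
                ElementSet([]), ElementSet([]), {"chr1": 100}, seed=0
            )

    def test_null_query_calibrated(self):
        # queries placed by the same process as the null: enrichment ~ 1
        sizes = {"chr1": 50_000}
        targets = ElementSet(
            [GenomicInterval("chr1", 5000 * i, 5000 * i + 500, f"t{i}") for i in range(10)]
        )
        rng = np.random.default_rng(4)
        enr = []
        for rep in range(10):
            starts = rng.integers(0, 50_000 - 20, size=80)
            query = ElementSet(
                [GenomicInterval("chr1", int(s), int(s) + 20, f"q{i}") for i, s in enumerate(starts)]
            )
            res = shuffle_enrichment(query, targets, sizes, n_shuffles=50, seed=rep)
            enr.append(res.enrichment)
        mean, sd = np.mean(enr), np.std(enr)
        assert abs(mean - 1.0) <= 3 * max(sd, 0.05)


class TestWindowTargets:
    def test_window_and_clipping(self):
        es = window_targets_from_tss([("chr1", 200_000), ("chr1", 50)], window=100_000)
        ivs = sorted(es.elements, key=lambda e: e.start)
        assert (ivs[0].start, ivs[0].end) == (0, 100_050)
        assert (ivs[1].start, ivs[1].end) == (100_000, 300_000)

    def test_nearby_tss_not_merged(self):
        es = window_targets_from_tss([("chr1", 1000), ("chr1", 1100)], window=500)
        assert len(es) == 2

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            window_targets_from_tss([("chr1", -5)])


class TestPriorityAssign:
    def _sets(self):
        shared = ElementSet([GenomicInterval("chr1", 100, 200, "s")])
        fetal = ElementSet([GenomicInterval("chr1", 150, 260, "f")])
        nb = ElementSet([GenomicInterval("chr1", 400, 500, "n")])
        return [("shared", shared), ("fetal", fetal), ("nb-cCRE", nb)]

    def test_priority_order(self):
        regions = ElementSet(
            [
                GenomicInterval("chr1", 120, 250, "r1"),  # hits shared and fetal
                GenomicInterval("chr1", 420, 430, "r2"),  # only nb
                GenomicInterval("chr1", 900, 950, "r3"),  # nothing
            ]
        )
        out = priority_assign(regions, self._sets())
        assert out == {"r1": "shared", "r2": "nb-cCRE", "r3": NON_ELEMENT_CLASS}

    def test_invariant_to_region_order(self):
        a = ElementSet(
            [
                GenomicInterval("chr1", 120, 250, "r1"),
                GenomicInterval("chr1", 420, 430, "r2"),
            ]
        )
        b = ElementSet(list(reversed(a.elements)))
        assert priority_assign(a, self._sets()) == priority_assign(b, self._sets())


class TestIndependentTraits:
    def _rg(self, entries, traits):
        df = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
        for (a, b), v in entries.items():
            df.loc[a, b] = df.loc[b, a] = v
        return df

    def test_greedy_rule_fixed_order(self):
        rg = self._rg({("t1", "t2"): 0.5, ("t1", "t3"): 0.1}, ["t1", "t2", "t3"])
        # find a seed whose visit order is [t1, t2, t3]
        for seed in range(50):
            order = np.random.default_rng(seed).permutation(3)
            if order.tolist() == [0, 1, 2]:
                break
        kept = select_independent_traits(rg, seed=seed)
        assert set(kept) == {"t1", "t3"}

    def test_all_uncorrelated_kept(self):
        rg = self._rg({}, [f"t{i}" for i in range(6)])
        assert len(select_independent_traits(rg, seed=0)) == 6

    def test_missing_rg_treated_as_zero(self):
        rg = self._rg({("t1", "t2"): 0.9}, ["t1", "t2", "t3"])
        rg.loc["t1", "t3"] = rg.loc["t3", "t1"] = np.nan
        for seed in range(50):
            order = np.random.default_rng(seed).permutation(3)
            if order.tolist() == [0, 1, 2]:
                break
        kept = select_independent_traits(rg, seed=seed)
        assert set(kept) == {"t1", "t3"}

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_pairwise_recheck(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        m = rng.uniform(-1, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        traits = [f"t{i}" for i in range(n)]
        rg = pd.DataFrame(m, index=traits, columns=traits)
        kept = select_independent_traits(rg, seed=seed)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert rg.loc[a, b] ** 2 <= 0.1 + 1e-12

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            select_independent_traits(
                pd.DataFrame(np.ones((2, 3))), seed=0
            )
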
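import numpy as np
import pytest

from creatlas.ctfbs import (
    CtfbsRecord,
    Direction,
    HmmModel,
    assign_best_motif,
    discretize_importance,
    fit_importance_hmm,
    importance_zscores,
    motif_set_chi2,
    motif_similarity,
    segment_ctfbs,
    site_importance_profiles,
    site_specificity_classes,
)
from creatlas.pwm import PWM
from creatlas.tracks import ElementSet, GenomicInterval, SignalTrack


def det_pwm(consensus: str) -> PWM:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        m[i, idx[b]] = 1.0
    return PWM(m)


def crisp_model() -> HmmModel:
    """A hand-built sticky model with unambiguous state semantics.

    Direction states tolerate short interior zero runs (so the explicit
    zero-run excision rule, not the decoder, splits segments).
    """
    return HmmModel(
        startprob=np.array([0.01, 0.98, 0.01]),
        transmat=np.array(
            [[0.98, 0.01, 0.01], [0.01, 0.98, 0.01], [0.01, 0.01, 0.98]]
        ),
        emissionprob=np.array(
            [[0.79, 0.20, 0.01], [0.01, 0.98, 0.01], [0.01, 0.20, 0.79]]
        ),
    )


class TestDiscretize:
    def test_quoted_thresholds(self):
        z = np.array([2.5, -2.5, 0.0])
        assert discretize_importance(z).tolist() == [1, -1, 0]

    def test_boundary_is_strict(self):
        assert discretize_importance(np.array([1.96, -1.96])).tolist() == [0, 0]

    def test_all_zero(self):
        assert discretize_importance(np.zeros(10)).tolist() == [0] * 10

    def test_zscores_over_whole_dataset(self):
        w1 = np.zeros(50)
        w2 = np.ones(50)
        zs = importance_zscores([w1, w2])
        # dataset mean 0.5, population SD 0.5
        assert np.allclose(zs[0], -1.0)
        assert np.allclose(zs[1], 1.0)

    def test_degenerate_dataset(self):
        with pytest.raises(ValueError, match="degenerate"):
            importance_zscores([np.zeros(10)])


class TestFitHmm:
    def test_pure_zero_sequences_degenerate(self):
        model = fit_importance_hmm([np.zeros(50, dtype=int)] * 3, seed=0)
        assert model.degenerate
        assert model.emissionprob[1, 1] >= 0.99

    def test_log_likelihood_monotone(self):
        rng = np.random.default_rng(0)
        seqs = [rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1], size=200) for _ in range(5)]
        model = fit_importance_hmm(seqs, seed=1)
        ll = np.array(model.log_likelihoods)
        assert np.all(np.diff(ll) >= -1e-6)

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(2)
        seqs, planted = [], []
        for _ in range(30):
            s = np.zeros(200, dtype=int)
            mask = np.zeros(200, dtype=bool)
            for _ in range(3):
                start = int(rng.integers(0, 180))
                length = int(rng.integers(8, 14))
                s[start : start + length] = rng.choice(
                    [1, 0], p=[0.85, 0.15], size=min(length, 200 - start)
                )
                mask[start : start + length] = True
            # sparse background noise
            noise = rng.random(200) < 0.02
            s[noise & ~mask] = 1
            seqs.append(s)
            planted.append(mask)
        model = fit_importance_hmm(seqs, seed=3)
        called = np.zeros(0, dtype=bool)
        truth = np.zeros(0, dtype=bool)
        for s, mask in zip(seqs, planted):
            recs = segment_ctfbs(model, s)
            c = np.zeros(200, dtype=bool)
            for r in recs:
                c[r.interval.start : r.interval.end] = True
            called = np.concatenate([called, c])
            truth = np.concatenate([truth, mask])
        jac = (called & truth).sum() / (called | truth).sum()
        assert jac >= 0.7

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_importance_hmm([], seed=0)

    def test_stochastic_invariants(self):
        rng = np.random.default_rng(4)
        seqs = [rng.choice([-1, 0, 1], size=100) for _ in range(3)]
        m = fit_importance_hmm(seqs, seed=5)
        assert np.allclose(m.startprob.sum(), 1.0, atol=1e-9)
        assert np.allclose(m.transmat.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(m.emissionprob.sum(axis=1), 1.0, atol=1e-9)


class TestSegment:
    def test_five_zero_run_splits(self):
        # decoded +1 segment with an internal 5-zero run -> two sites
        sym = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 1, 1, 1, 1])
        recs = segment_ctfbs(crisp_model(), sym)
        pos = [r for r in recs if r.direction is Direction.POSITIVE]
        assert len(pos) == 2
        spans = sorted((r.interval.start, r.interval.end) for r in pos)
        assert spans == [(0, 4), (9, 13)]

    def test_three_zero_run_retained(self):
        sym = np.array([1, 1, 1, 0, 0, 0, 1, 1, 1])
        recs = segment_ctfbs(crisp_model(), sym)
        assert len(recs) == 1
        assert (recs[0].interval.start, recs[0].interval.end) == (0, 9)

    def test_all_zero_decode_no_sites(self):
        assert segment_ctfbs(crisp_model(), np.zeros(30, dtype=int)) == []

    def test_negative_direction(self):
        sym = np.array([-1] * 8 + [0] * 20)
        recs = segment_ctfbs(crisp_model(), sym)
        assert len(recs) == 1
        assert recs[0].direction is Direction.NEGATIVE
        assert recs[0].mean_importance < 0

    def test_genome_lifting(self):
        window = GenomicInterval("chr3", 1000, 1030, "w")
        sym = np.array([0] * 10 + [1] * 6 + [0] * 14)
        recs = segment_ctfbs(crisp_model(), sym, window=window)
        assert recs[0].interval.chrom == "chr3"
        assert (recs[0].interval.start, recs[0].interval.end) == (1010, 1016)

    def test_direction_consistent_with_importance(self):
        sym = np.array([0] * 5 + [1] * 6 + [0] * 5)
        imp = np.concatenate([np.zeros(5), np.full(6, 3.0), np.zeros(5)])
        recs = segment_ctfbs(crisp_model(), sym, importance=imp)
        assert recs[0].mean_importance == pytest.approx(3.0)
        with pytest.raises(ValueError):
            CtfbsRecord(
                GenomicInterval("chr1", 0, 5, "x"), Direction.POSITIVE, -1.0
            )


class TestMotifSimilarity:
    def test_hand_enumeration(self):
        pwm = det_pwm("AC")
        assert motif_similarity("ACG", pwm, both_strands=False) == pytest.approx(2.25)

    def test_consensus_equals_length(self):
        pwm = det_pwm("GATTACA")
        assert motif_similarity("GATTACA", pwm) == pytest.approx(7.0)

    def test_all_n_rule(self):
        pwm = det_pwm("ACG")
        assert motif_similarity("NNN", pwm) == pytest.approx(0.75)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(6)
        pwm = PWM.from_counts(rng.integers(1, 20, size=(8, 4)))
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=12))
            rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert motif_similarity(seq, pwm) == pytest.approx(
                motif_similarity(rc, pwm)
            )

    def test_shorter_sequence_padding(self):
        pwm = det_pwm("ACGT")
        # 2-base sequence aligned inside a 4-column motif: 2 matched + 2 padded
        assert motif_similarity("AC", pwm, both_strands=False) == pytest.approx(2.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            motif_similarity("", det_pwm("A"))


class TestAssignBestMotif:
    def test_single_motif(self):
        catalog = {"only": det_pwm("ACGT")}
        assert assign_best_motif("TTTT", catalog)[0] == "only"

    def test_planted_consensus_wins(self):
        rng = np.random.default_rng(7)
        catalog = {f"d{i}": det_pwm("".join(rng.choice(list("ACGT"), 8))) for i in range(10)}
        catalog["M"] = det_pwm("ACGTACGT")
        mid, score = assign_best_motif("ACGTACGT", catalog)
        assert mid == "M"
        assert score == pytest.approx(8.0)

    def test_tie_broken_lexicographically(self):
        pwm = det_pwm("ACG")
        mid, _ = assign_best_motif("ACG", {"A1": pwm, "A0": pwm})
        assert mid == "A0"


def yates_chi2_oracle(a, b, c, d):
    """Textbook Yates-corrected chi-square for [[a, b], [c, d]]."""
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


class TestMotifSetChi2:
    def test_matches_textbook_oracle(self):
        out = motif_set_chi2({"m": 30}, 1000, {"m": 10}, 1000, min_instances=10)
        chi2, p = out["m"]
        expected = yates_chi2_oracle(30, 970, 10, 990)
        assert chi2 == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = int(rng.integers(25, 500)), int(rng.integers(25, 500))
        ta, tb = a + int(rng.integers(100, 1000)), b + int(rng.integers(100, 1000))
        out = motif_set_chi2({"m": a}, ta, {"m": b}, tb)
        assert out["m"][0] == pytest.approx(
            yates_chi2_oracle(a, ta - a, b, tb - b), abs=1e-9
        )

    def test_equal_fractions_p_one(self):
        out = motif_set_chi2({"m": 100}, 1000, {"m": 100}, 1000)
        chi2, p = out["m"]
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_instance_floor(self):
        out = motif_set_chi2({"m": 20}, 1000, {"m": 400}, 1000)
        assert "m" not in out

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            motif_set_chi2({"m": 50}, 40, {"m": 30}, 100)


class TestSiteSpecificity:
    def _sites(self, spans, prefix):
        return ElementSet(
            [GenomicInterval("chr1", s, e, f"{prefix}{i}") for i, (s, e) in enumerate(spans)]
        )

    def test_identical_all_shared(self):
        a = self._sites([(0, 10), (20, 30)], "a")
        b = self._sites([(0, 10), (20, 30)], "b")
        assert set(site_specificity_classes(a, b).values()) == {"shared"}

    def test_disjoint(self):
        a = self._sites([(0, 10)], "a")
        b = self._sites([(50, 60)], "b")
        out = site_specificity_classes(a, b)
        assert out["a0"] == "a-only"
        assert out["b0"] == "b-only"

    def test_one_bp_overlap_is_shared(self):
        a = self._sites([(0, 10)], "a")
        b = self._sites([(9, 20)], "b")
        out = site_specificity_classes(a, b)
        assert out["a0"] == "shared"
        assert out["b0"] == "shared"


class TestSiteProfiles:
    def test_constant_track_flat(self):
        sites = ElementSet([GenomicInterval("chr1", 100, 110, "s")])
        tracks = {"x": SignalTrack.constant({"chr1": 1000}, 2.0)}
        prof = site_importance_profiles(sites, tracks, window=21)
        assert np.allclose(prof["x"], 2.0)

    def test_planted_celltype_dominates(self):
        sites = ElementSet([GenomicInterval("chr1", 100, 110, "s")])
        hot = SignalTrack.from_runs({"chr1": [(100, 110, 5.0)]})
        cold = SignalTrack.constant({"chr1": 1000}, 0.1)
        prof = site_importance_profiles(sites, {"hot": hot, "cold": cold}, window=11)
        center = 5
        assert prof["hot"][center] > prof["cold"][center]

    def test_out_of_bounds_site_skipped(self):
        sites = ElementSet(
            [
                GenomicInterval("chr1", 0, 4, "edge"),
                GenomicInterval("chr1", 100, 110, "ok"),
            ]
        )
        tracks = {"x": SignalTrack.constant({"chr1": 1000}, 1.0)}
        with pytest.warns(UserWarning, match="skipped"):
            prof = site_importance_profiles(sites, tracks, window=51)
        assert np.allclose(prof["x"], 1.0)

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            site_importance_profiles(
                ElementSet([]), {"x": SignalTrack.constant({"chr1": 10}, 1.0)}
            )
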
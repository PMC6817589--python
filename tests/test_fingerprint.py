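"""PWM construction (normalization, clamping), similarity, score fusion,
and the alanine-scan adaptation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrfingerprint import (
    DegenerateNormalizationError,
    ValidationError,
    build_alanine_pwm,
    build_pwm,
    combine_scores,
    pwm_similarity,
    score_peptide,
)
from tcrfingerprint.core import AMINO_ACIDS
from tcrfingerprint.scan_io import MeasurementRecord, MeasurementSet

from conftest import ANCHORS, EPITOPE, random_pwm


def records_for(peptide, mean_corrected, n_reps=3, background=2.0,
                assay="binding", spread=0.0):
    """Replicates whose background-corrected mean equals *mean_corrected*."""
    offsets = np.linspace(-spread, spread, n_reps)
    return [
        MeasurementRecord(peptide, assay, f"r{i + 1}",
                          background + mean_corrected + offsets[i], background)
        for i in range(n_reps)
    ]


def variant(pos, aa, epitope=EPITOPE):
    return epitope[: pos - 1] + aa + epitope[pos:]


def make_set(variant_means, epitope_mean=50.0, **kw):
    recs = records_for(EPITOPE, epitope_mean, **kw)
    for (pos, aa), mean in variant_means.items():
        recs += records_for(variant(pos, aa), mean, **kw)
    return MeasurementSet(recs)


class TestBuildPwm:
    def test_equal_means_give_weight_100(self):
        ms = make_set({(5, "A"): 50.0})
        pwm = build_pwm(ms, "binding", EPITOPE, ANCHORS)
        assert pwm.weight("A", 5) == 100.0

    def test_exceeding_epitope_trimmed_to_100(self):
        ms = make_set({(5, "A"): 60.0})  # 1.2 x epitope
        pwm = build_pwm(ms, "binding", EPITOPE, ANCHORS)
        assert pwm.weight("A", 5) == 100.0

    def test_negative_mean_clamped_to_zero(self):
        ms = make_set({(5, "A"): -3.0})
        pwm = build_pwm(ms, "binding", EPITOPE, ANCHORS)
        assert pwm.weight("A", 5) == 0.0

    def test_nine_mer_two_anchors_yields_seven_columns(self):
        ms = make_set({(5, "A"): 25.0})
        pwm = build_pwm(ms, "binding", EPITOPE, ANCHORS)
        assert pwm.scored_positions == (1, 3, 4, 5, 6, 7, 8)
        assert pwm.weights.shape == (20, 7)

    def test_normalization_ratio(self):
        ms = make_set({(4, "G"): 20.0}, epitope_mean=80.0)
        pwm = build_pwm(ms, "binding", EPITOPE, ANCHORS)
        assert pwm.weight("G", 4) == pytest.approx(25.0)

    def test_background_subtraction_is_per_replicate(self):
        # same raw signals, different per-replicate backgrounds
        recs = [
            MeasurementRecord(EPITOPE, "binding", "r1", 52.0, 2.0),
            MeasurementRecord(EPITOPE, "binding", "r2", 54.0, 4.0),
            MeasurementRecord(variant(5, "A"), "binding", "r1", 27.0, 2.0),
            MeasurementRecord(variant(5, "A"), "binding", "r2", 29.0, 4.0),
        ]
        pwm = build_pwm(MeasurementSet(recs), "binding", EPITOPE, ANCHORS)
        assert pwm.weight("A", 5) == pytest.approx(50.0)

    def test_replicate_order_invariance(self):
        ms = make_set({(5, "A"): 30.0, (7, "R"): 10.0}, spread=5.0)
        shuffled = MeasurementSet(list(ms)[::-1])
        a = build_pwm(ms, "binding", EPITOPE, ANCHORS)
        b = build_pwm(shuffled, "binding", EPITOPE, ANCHORS)
        assert np.array_equal(a.weights, b.weights)

    def test_uniform_rescaling_invariance(self):
        base = make_set({(5, "A"): 30.0}, spread=4.0)
        scaled = MeasurementSet([
            MeasurementRecord(r.peptide, r.assay, r.replicate_id,
                              r.signal * 3.5, r.background * 3.5)
            for r in base
        ])
        a = build_pwm(base, "binding", EPITOPE, ANCHORS)
        b = build_pwm(scaled, "binding", EPITOPE, ANCHORS)
        assert np.allclose(a.weights, b.weights)

    def test_epitope_residues_pinned_at_100(self):
        ms = make_set({(5, "A"): 30.0})
        pwm = build_pwm(ms, "binding", EPITOPE, ANCHORS)
        for pos in pwm.scored_positions:
            assert pwm.weight(EPITOPE[pos - 1], pos) == 100.0

    def test_degenerate_epitope_signal_rejected(self):
        ms = make_set({(5, "A"): 10.0}, epitope_mean=-1.0)
        with pytest.raises(DegenerateNormalizationError):
            build_pwm(ms, "binding", EPITOPE, ANCHORS)

    def test_anchor_substitution_rejected(self):
        ms = make_set({(5, "A"): 10.0})
        bad = MeasurementSet(list(ms) + records_for(variant(2, "G"), 5.0))
        with pytest.raises(ValidationError, match=variant(2, "G")):
            build_pwm(bad, "binding", EPITOPE, ANCHORS)

    def test_multi_substitution_rejected(self):
        v = variant(5, "A")
        double = v[:2] + "G" + v[3:]  # differs from epitope at P3 and P5
        ms = make_set({(5, "A"): 10.0})
        bad = MeasurementSet(list(ms) + records_for(double, 5.0))
        with pytest.raises(ValidationError, match="2 positions"):
            build_pwm(bad, "binding", EPITOPE, ANCHORS)

    def test_missing_cells_imputed_zero_with_warning(self, caplog):
        ms = make_set({(5, "A"): 30.0})
        with caplog.at_level("WARNING"):
            pwm = build_pwm(ms, "binding", EPITOPE, ANCHORS)
        assert any("imputed" in r.message for r in caplog.records)
        assert pwm.weight("R", 5) == 0.0
        with pytest.raises(ValidationError, match="unmeasured"):
            build_pwm(ms, "binding", EPITOPE, ANCHORS, on_missing="error")

    def test_unknown_assay_rejected(self):
        ms = make_set({(5, "A"): 30.0})
        with pytest.raises(ValidationError):
            build_pwm(ms, "proliferation", EPITOPE, ANCHORS)


class TestPwmSimilarity:
    def test_self_similarity_is_one(self, rng):
        pwm = random_pwm(rng)
        assert pwm_similarity(pwm, pwm) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, rng):
        a = random_pwm(rng)
        flipped = 100.0 - a.weights
        # complement violates the pinned-epitope invariant, so compare raw
        x, y = a.weights.ravel(), flipped.ravel()
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(-1.0)

    def test_matches_hand_coded_pearson(self, rng):
        for _ in range(10):
            a, b = random_pwm(rng), random_pwm(rng)
            x, y = a.weights.ravel(), b.weights.ravel()
            xc, yc = x - x.mean(), y - y.mean()
            expected = (xc * yc).sum() / np.sqrt((xc * xc).sum() * (yc * yc).sum())
            assert pwm_similarity(a, b) == pytest.approx(expected, abs=1e-10)

    def test_symmetry(self, rng):
        a, b = random_pwm(rng), random_pwm(rng)
        assert pwm_similarity(a, b) == pwm_similarity(b, a)

    def test_mismatched_dimensions_rejected(self, rng):
        a = random_pwm(rng)
        b = random_pwm(rng, epitope="SLLMWITQV", anchors=frozenset({1, 9}))
        with pytest.raises(ValidationError):
            pwm_similarity(a, b)


class TestCombineScores:
    @pytest.mark.parametrize("triple, expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.9, 0.8, 1.0), 0.9),
        ((0.0, 0.0, 0.0), 0.0),
    ])
    def test_mean_of_three(self, triple, expected):
        assert combine_scores(*triple).combined == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            combine_scores(1.2, 0.5, 0.5)

    @given(st.tuples(*[st.floats(0, 1) for _ in range(3)]))
    @settings(derandomize=True, max_examples=50)
    def test_combined_is_arithmetic_mean(self, triple):
        t = combine_scores(*triple)
        assert t.combined == pytest.approx(sum(triple) / 3.0)


class TestAlaninePwm:
    EPI = "EVDPIGHLY"

    def values(self, permissive, low=0.1):
        positions = [p for p in range(1, 10) if p not in (2, 9)]
        return {p: (0.9 if p in permissive else low) for p in positions}

    def test_all_permissive_scores_every_peptide_one(self, rng):
        pwm = build_alanine_pwm(self.values(set(range(1, 10))), self.EPI, {2, 9})
        for _ in range(20):
            pep = "".join(rng.choice(list(AMINO_ACIDS), size=9))
            assert score_peptide(pwm, pep) == pytest.approx(1.0)

    def test_no_permissive_zero_alanine_single_substitution_score(self):
        pwm = build_alanine_pwm(self.values(set(), low=0.0), self.EPI, {2, 9})
        assert score_peptide(pwm, self.EPI) == pytest.approx(1.0)
        pep = self.EPI[:4] + "W" + self.EPI[5:]  # P5 I -> W, non-anchor
        assert score_peptide(pwm, pep) == pytest.approx(6.0 / 7.0)

    def test_permissive_positions_score_free_by_enumeration(self):
        permissive = {4, 6}
        pwm = build_alanine_pwm(self.values(permissive), self.EPI, {2, 9})
        # brute force: all single and double substitutions at permissive sites
        for p in permissive:
            for aa in AMINO_ACIDS:
                pep = self.EPI[: p - 1] + aa + self.EPI[p:]
                assert score_peptide(pwm, pep) == pytest.approx(1.0)
        for aa1 in "AWQ":
            for aa2 in "KRD":
                pep = list(self.EPI)
                pep[3], pep[5] = aa1, aa2
                assert score_peptide(pwm, "".join(pep)) == pytest.approx(1.0)

    def test_non_permissive_alanine_weight_scales_with_value(self):
        positions = [p for p in range(1, 10) if p not in (2, 9)]
        values = {p: 0.2 for p in positions}
        pwm = build_alanine_pwm(values, self.EPI, {2, 9},
                                permissive_threshold=0.5)
        assert pwm.weight("A", 1) == pytest.approx(20.0)

    def test_missing_position_rejected(self):
        values = self.values(set())
        del values[5]
        with pytest.raises(ValidationError, match="5"):
            build_alanine_pwm(values, self.EPI, {2, 9})

    @pytest.mark.parametrize("threshold", [0.0, 1.5, -0.2])
    def test_bad_threshold_rejected(self, threshold):
        with pytest.raises(ValidationError):
            build_alanine_pwm(self.values(set()), self.EPI, {2, 9},
                              permissive_threshold=threshold)
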
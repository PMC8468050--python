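import math

import numpy as np
import pytest

import zipfent as z


def seq_of(text):
    return z.SymbolSequence.from_tokens(list(text))


def spaced_sequence(distance, repeats, fillers):
    """rank-1 symbol 'A' recurring at exact coincidence distance.

    Consecutive occurrences of A sit ``distance - 2`` filler symbols
    apart, so each observed distance (position gap + 1) equals
    ``distance`` exactly; fillers are spread thin enough that A stays
    the most frequent symbol.
    """
    tokens = []
    fill = [f"f{i}" for i in range(fillers)]
    gap = distance - 2
    for k in range(repeats):
        tokens.append("A")
        for j in range(gap):
            tokens.append(fill[(k * gap + j) % fillers])
    tokens.append("A")
    return z.SymbolSequence.from_tokens(tokens)


class TestModelEstimator:
    def test_forced_uniform_entropy(self, identity_calib):
        # identity calibration maps D_bar = 30 to M_hat = 30 exactly
        seq = spaced_sequence(30, 12, 58)
        est = z.estimate_entropy_model(seq, identity_calib, family="equiprobable")
        assert est.M_hat == pytest.approx(30.0)
        assert est.value == pytest.approx(math.log2(30), abs=1e-9)
        assert est.perplexity == pytest.approx(30.0, abs=1e-6)

    def test_no_coincidence_raises(self, zml_calib):
        with pytest.raises(z.NoCoincidenceError):
            z.estimate_entropy_model(seq_of("ab"), zml_calib)

    def test_family_mismatch_rejected(self, zml_calib):
        seq = seq_of("abab")
        with pytest.raises(ValueError, match="family"):
            z.estimate_entropy_model(seq, zml_calib, family="czml1")

    def test_m_hat_below_two_rejected(self, identity_calib):
        # adjacent repeats force D_bar = 2 -> M_hat = 2 - eh, use sub-2
        calib = z.CalibrationModel("equiprobable", "power",
                                   {1: (0.5, 1.0, 0.0)}, {1: (1.0, 100.0)})
        with pytest.raises(ValueError, match="M_hat"):
            z.estimate_entropy_model(seq_of("aaaa"), calib,
                                     family="equiprobable")

    def test_zml_estimate_near_truth(self, zml_calib):
        dist = z.make_zml(30)
        seq = z.sample_iid_sequence(dist, 200_000, 42)
        est = z.estimate_entropy_model(seq, zml_calib, family="zml")
        assert est.method == "zml_coincidence"
        assert est.M_hat == pytest.approx(30, abs=1.5)
        assert est.value == pytest.approx(z.model_entropy(dist), abs=0.05)

    def test_multi_rank_averaging(self, zml_calib):
        seq = z.sample_iid_sequence(z.make_zml(30), 200_000, 7)
        est = z.estimate_entropy_model(seq, zml_calib, family="zml", r=(1, 2, 3))
        assert est.rank_used == (1, 2, 3)
        assert est.M_hat == pytest.approx(30, abs=2.0)

    def test_convergence_dominance_at_small_n(self, zml_calib):
        # undersampled regime: the model-based mean is closer to the true
        # entropy than the plug-in mean
        dist = z.make_zml(30)
        H_true = z.model_entropy(dist)
        rng = np.random.default_rng(17)
        model_vals, plugin_vals = [], []
        for _ in range(2000):
            seq = z.sample_iid_sequence(dist, 1000, rng)
            model_vals.append(
                z.estimate_entropy_model(seq, zml_calib, family="zml").value
            )
            plugin_vals.append(z.plugin_entropy(seq.counts()).value)
        model_bias = abs(np.mean(model_vals) - H_true)
        plugin_bias = abs(np.mean(plugin_vals) - H_true)
        assert model_bias < plugin_bias


class TestEquiprobableEstimator:
    def test_forced_m4(self, identity_calib):
        seq = spaced_sequence(4, 40, 6)
        est = z.estimate_entropy_equiprobable(seq, identity_calib)
        assert est.value == pytest.approx(2.0, abs=1e-9)

    def test_m_hat_one_rejected(self):
        calib = z.CalibrationModel("equiprobable", "power",
                                   {1: (0.5, 1.0, 0.0)}, {1: (1.0, 100.0)})
        with pytest.raises(ValueError):
            z.estimate_entropy_equiprobable(seq_of("aaaa"), calib)

    def test_uniform_m20_mean_within_tolerance(self, equi_calib):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(50):
            seq = z.sample_iid_sequence(z.make_equiprobable(20), 100_000, rng)
            vals.append(z.estimate_entropy_equiprobable(seq, equi_calib).value)
        assert abs(np.mean(vals) - math.log2(20)) < 0.05

    def test_scale_property_large_n(self, equi_calib):
        seq = z.sample_iid_sequence(z.make_equiprobable(20), 1_000_000, 11)
        est = z.estimate_entropy_equiprobable(seq, equi_calib)
        assert abs(est.value - math.log2(20)) < 0.01


class TestBaselines:
    @pytest.mark.parametrize(
        "counts,expected",
        [([1, 1, 1, 1], 2.0), ([5], 0.0), ([2, 1, 1], 1.5)],
    )
    def test_plugin_hand_values(self, counts, expected):
        assert z.plugin_entropy(counts).value == pytest.approx(expected, abs=1e-12)

    def test_plugin_rejects_empty(self):
        with pytest.raises(ValueError):
            z.plugin_entropy([0, 0])

    def test_miller_madow_hand_value(self):
        est = z.miller_madow_entropy([1, 1])
        assert est.value == pytest.approx(1 + 1 / (4 * math.log(2)), abs=1e-12)

    def test_miller_madow_single_symbol_equals_plugin(self):
        assert z.miller_madow_entropy([9]).value == z.plugin_entropy([9]).value

    def test_plugin_underestimates_and_correction_helps(self):
        # undersampled uniform source: plug-in is negatively biased and
        # Miller-Madow moves the mean toward the truth
        rng = np.random.default_rng(29)
        H_true = math.log2(30)
        plug, mm = [], []
        for _ in range(100):
            seq = z.sample_iid_sequence(z.make_equiprobable(30), 1000, rng)
            plug.append(z.plugin_entropy(seq.counts()).value)
            mm.append(z.miller_madow_entropy(seq.counts()).value)
        assert np.mean(plug) < H_true
        assert abs(np.mean(mm) - H_true) < abs(np.mean(plug) - H_true)


class TestPerplexity:
    @pytest.mark.parametrize("H,expected", [(0.0, 1.0), (1.0, 2.0),
                                            (math.log2(30), 30.0)])
    def test_values(self, H, expected):
        assert z.perplexity(H) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            z.perplexity(-0.1)

    def test_estimate_exposes_consistent_perplexity(self):
        est = z.plugin_entropy([1, 1, 1, 1])
        assert est.perplexity == pytest.approx(2.0**est.value, abs=1e-12)
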
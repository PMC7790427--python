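import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tmesim.intracellular import (
    DEFAULT_RANGES, M1, M2, M1_MARKERS, M2_MARKERS, StandInConstants,
    SurrogateModel, generate_training_set, grid_agreement, m1m2_score,
    mechanistic_label, standin_mechanistic, train_surrogate,
)

C = StandInConstants()


class TestStandIn:
    def test_baseline_all_channels_one(self):
        out = standin_mechanistic(0.0, 0.0, 1.0)
        assert all(v == 1.0 for v in out.values())

    def test_ifng_saturation_limit(self):
        out = standin_mechanistic(0.0, 1e12, 1.0)
        for m, a in zip(M1_MARKERS, C.alpha):
            assert out[m] == pytest.approx(1.0 + a, rel=1e-9)
        for m in M2_MARKERS:
            assert out[m] == 1.0

    def test_full_pi3k_inhibition_abolishes_m2_drive(self):
        out = standin_mechanistic(500.0, 0.0, 0.0)
        assert all(out[m] == 1.0 for m in M2_MARKERS)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            standin_mechanistic(-1.0, 0.0)

    @given(ifng=st.floats(0, 1e4), il4=st.floats(0, 1e4), pi3k=st.floats(0, 1))
    def test_monotone_in_ifng(self, ifng, il4, pi3k):
        # adding IFN-g can never flip the label from M1 to M2
        lo = mechanistic_label(il4, ifng, pi3k)
        hi = mechanistic_label(il4, ifng * 2 + 1, pi3k)
        assert not (lo == M1 and hi == M2)

    @given(ifng=st.floats(0, 1e4), il4=st.floats(0, 1e4), pi3k=st.floats(0, 1))
    def test_lower_pi3k_weakly_enlarges_m1_region(self, ifng, il4, pi3k):
        lo = mechanistic_label(il4, ifng, pi3k * 0.5)
        hi = mechanistic_label(il4, ifng, pi3k)
        assert not (hi == M1 and lo == M2)


class TestScore:
    def test_all_ones_is_tie_to_m2(self):
        channels = {m: 1.0 for m in M1_MARKERS + M2_MARKERS}
        score, label = m1m2_score(channels)
        assert score == 1.0 and label == M2

    def test_product_ratio_value(self):
        channels = {m: 2.0 for m in M1_MARKERS}
        channels.update({m: 1.0 for m in M2_MARKERS})
        score, label = m1m2_score(channels)
        assert score == pytest.approx(32.0) and label == M1

    @pytest.mark.parametrize("eps,expected", [(1.01, M1), (0.99, M2)])
    def test_strictly_greater_than_one_rule(self, eps, expected):
        channels = {m: 1.0 for m in M1_MARKERS + M2_MARKERS}
        channels[M1_MARKERS[0]] = eps
        assert m1m2_score(channels)[1] == expected

    def test_nonpositive_channel_rejected(self):
        channels = {m: 1.0 for m in M1_MARKERS + M2_MARKERS}
        channels["VEGF"] = 0.0
        with pytest.raises(ValueError):
            m1m2_score(channels)


class TestTrainingSet:
    def test_deterministic_under_seed(self):
        a = generate_training_set(50, rng_seed=7)
        b = generate_training_set(50, rng_seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_collapsed_ranges_all_m2(self):
        ranges = {"il4": (0, 0), "ifng": (0, 0), "pi3k": (1, 1)}
        ds = generate_training_set(20, ranges=ranges, rng_seed=0)
        assert (ds["label"] == M2).all()

    def test_label_fractions_match_decision_region_area(self):
        # numeric quadrature of the stand-in decision region as the oracle
        n = 120
        il4 = np.linspace(*DEFAULT_RANGES["il4"], n)
        ifng = np.linspace(*DEFAULT_RANGES["ifng"], n)
        pi3k = np.linspace(*DEFAULT_RANGES["pi3k"], 21)
        hits = sum(
            mechanistic_label(a, g, p) == M1
            for p in pi3k for a in il4 for g in ifng
        )
        area_fraction = hits / (n * n * 21)
        ds = generate_training_set(10_000, rng_seed=3)
        mc_fraction = (ds["label"] == M1).mean()
        # binomial 99.7% band at n=10,000 plus quadrature bias allowance
        assert abs(mc_fraction - area_fraction) < 3 * np.sqrt(0.25 / 10_000) + 0.01

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            generate_training_set(5, ranges={"il4": (1, 0), "ifng": (0, 1), "pi3k": (0, 1)})


class TestSurrogate:
    def test_linearly_separable_toy_set(self):
        rng = np.random.default_rng(0)
        n = 10_000
        il4 = rng.uniform(0, 100, n)
        ifng = rng.uniform(0, 100, n)
        ds = pd.DataFrame({
            "il4": il4, "ifng": ifng, "pi3k": rng.uniform(0, 1, n),
            "label": np.where(ifng > il4, M1, M2),
        })
        model = train_surrogate(ds, rng_seed=0, max_iter=800)
        assert model.held_out_accuracy >= 0.99

    def test_single_class_warns_and_is_constant(self):
        ds = pd.DataFrame({
            "il4": [0.0, 1.0], "ifng": [0.0, 1.0], "pi3k": [1.0, 1.0],
            "label": [M2, M2],
        })
        model = train_surrogate(ds, rng_seed=0)
        assert model.single_class_warning and model.held_out_accuracy == 1.0
        assert model.predict(50, 50, 0.5) == M2

    def test_fixed_seed_reproducible(self):
        ds = generate_training_set(2000, rng_seed=1)
        m1 = train_surrogate(ds, rng_seed=5)
        m2 = train_surrogate(ds, rng_seed=5)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        assert m1.held_out_accuracy == m2.held_out_accuracy

    def test_baseline_input_predicts_m2(self, surrogate_small):
        assert surrogate_small.predict(0.0, 0.0, 1.0) == M2

    def test_agreement_with_oracle_on_grid(self, surrogate_small):
        # sanity bound for the reduced 20k fixture; the full-pipeline
        # >= 98% equivalence is asserted in the acceptance suite
        assert grid_agreement(surrogate_small, 30, 30) >= 0.95

    def test_out_of_range_queries_clamped(self, surrogate_small):
        inside = surrogate_small.predict(100.0, 100.0, 1.0)
        outside = surrogate_small.predict(1e6, 1e6, 1.0)
        assert inside == outside
        assert surrogate_small.clamped_queries > 0

    def test_json_roundtrip_bit_identical(self, surrogate_small, tmp_path):
        path = tmp_path / "model.json"
        surrogate_small.to_json(path)
        loaded = SurrogateModel.from_json(path)
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, g, p = rng.uniform(0, 100), rng.uniform(0, 100), rng.uniform(0, 1)
            assert loaded.decision_value(a, g, p) == surrogate_small.decision_value(a, g, p)

    def test_surrogate_monotone_boundary_on_slices(self, surrogate_small):
        # along increasing IFN-g the surrogate label flips at most once, M2->M1
        for il4 in (0.0, 30.0, 80.0):
            labels = [surrogate_small.predict(il4, g, 1.0) for g in np.linspace(0, 100, 60)]
            flips = sum(a != b for a, b in zip(labels, labels[1:]))
            assert flips <= 1
            if flips == 1:
                assert labels[0] == M2 and labels[-1] == M1
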
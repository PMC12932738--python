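"""Homeostatic scaling model: construction, scaling, stimulation, observations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somatomap import model as m


def make_weights(values):
    return m.WeightMatrix(values=np.asarray(values, dtype=float), stage="initial")


class TestInitialWeights:
    def test_offset_floor_everywhere(self):
        W = m.build_initial_weights(m.ModelConfig())
        assert W.values.min() >= 0.05
        assert W.values.shape == (50, 10)

    def test_cld_without_attenuation_or_gain_equals_ctr(self):
        kw = dict(hand_gain=1.0, cld_attenuation=1.0)
        ctr = m.build_initial_weights(m.ModelConfig(group="CTR", **kw))
        cld = m.build_initial_weights(m.ModelConfig(group="CLD", **kw))
        np.testing.assert_array_equal(ctr.values, cld.values)

    def test_column_argmax_at_configured_peaks_in_homuncular_order(self):
        cfg = m.ModelConfig()
        W = m.build_initial_weights(cfg)
        argmaxes = W.values.argmax(axis=0)
        # peaks sit at half-integer positions: argmax lands within half a node
        assert np.all(np.abs(argmaxes - np.asarray(cfg.peaks)) <= 0.5)
        assert np.all(np.diff(argmaxes) > 0)

    def test_cld_attenuates_hand_bells_only(self):
        ctr = m.build_initial_weights(m.ModelConfig(group="CTR"))
        cld = m.build_initial_weights(m.ModelConfig(group="CLD"))
        for part in m.HAND_PARTS:
            np.testing.assert_allclose(
                cld.column(part) - 0.05, 0.15 * (ctr.column(part) - 0.05),
                atol=1e-12,
            )
        for part in set(m.BODY_PARTS) - set(m.HAND_PARTS):
            np.testing.assert_array_equal(cld.column(part), ctr.column(part))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(offset=0.0),
            dict(offset=-0.1),
            dict(peak_positions=tuple(range(10))[::-1]),
            dict(peak_positions=(0,) * 10),
            dict(cld_attenuation=0.0),
            dict(mna_hom=0.0),
            dict(n_neurons=5),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(m.ConfigurationError):
            m.ModelConfig(**kwargs)


class TestMna:
    def test_zero_probabilities_give_zero_mna(self):
        W = m.build_initial_weights(m.ModelConfig())
        np.testing.assert_array_equal(m.compute_mna(W, np.zeros(10)), 0.0)

    def test_toy_dot_product(self):
        # W = [[1, 2], [3, 4]], P = (0.5, 0.25): rows give 1*0.5 + 2*0.25 = 1.0
        # and 3*0.5 + 4*0.25 = 2.5
        mna = m.compute_mna(np.array([[1.0, 2.0], [3.0, 4.0]]), [0.5, 0.25])
        np.testing.assert_allclose(mna, [1.0, 2.5])

    def test_default_probabilities(self):
        probs = m.ModelConfig().probabilities
        assert probs[m.BODY_PARTS.index("palm")] == 0.15
        assert probs[m.BODY_PARTS.index("fingers")] == 0.15
        others = [p for i, p in enumerate(probs) if m.BODY_PARTS[i] not in m.HAND_PARTS]
        assert others == [0.05] * 8

    def test_dimension_mismatch(self):
        W = m.build_initial_weights(m.ModelConfig())
        with pytest.raises(ValueError):
            m.compute_mna(W, [0.1] * 9)


class TestSynapticScaling:
    def test_toy_neuron_doubles(self):
        # weights (1, 2), P = (0.5, 0.5): MNA = 1.5; target 3 -> factor 2
        scaled = m.apply_synaptic_scaling(make_weights([[1.0, 2.0]]), [0.5, 0.5], 3.0)
        np.testing.assert_allclose(scaled.values, [[2.0, 4.0]])
        assert scaled.stage == "homeostatic"

    def test_fixed_point(self):
        W = make_weights([[1.0, 3.0], [2.0, 2.0]])
        probs = [0.25, 0.25]
        target = float(m.compute_mna(W, probs)[0])
        # make both neurons sit at the target already
        W.values[1] *= target / m.compute_mna(W, probs)[1]
        scaled = m.apply_synaptic_scaling(W, probs, target)
        np.testing.assert_allclose(scaled.values, W.values)

    def test_zero_mna_reports_neuron(self):
        W = make_weights([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ZeroDivisionError, match="1"):
            m.apply_synaptic_scaling(W, [0.5, 0.5], 0.5)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        data=st.data(),
        n_neurons=st.integers(2, 8),
        n_inputs=st.integers(1, 6),
        mna_hom=st.floats(0.1, 5.0),
    )
    def test_conservation_ratios_idempotence(self, data, n_neurons, n_inputs, mna_hom):
        """Scaling hits the target exactly, preserves ratios, and is idempotent."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        W = make_weights(rng.uniform(0.01, 5.0, size=(n_neurons, n_inputs)))
        probs = rng.uniform(0.05, 1.0, size=n_inputs)
        scaled = m.apply_synaptic_scaling(W, probs, mna_hom)
        np.testing.assert_allclose(
            m.compute_mna(scaled, probs), mna_hom, rtol=1e-10
        )
        ratios_before = W.values / W.values[:, :1]
        ratios_after = scaled.values / scaled.values[:, :1]
        np.testing.assert_allclose(ratios_after, ratios_before, rtol=1e-10)
        twice = m.apply_synaptic_scaling(scaled, probs, mna_hom)
        np.testing.assert_allclose(twice.values, scaled.values, rtol=1e-10)


class TestStimulation:
    def test_ctr_single_part_returns_column(self):
        W = m.build_initial_weights(m.ModelConfig())
        prof = m.simulate_stimulation(W, "torso", "CTR")
        np.testing.assert_array_equal(prof.values, W.column("torso"))
        assert prof.peak_value == prof.values.max()

    def test_cld_arm_coactivates_residual_nerves(self):
        W = m.build_initial_weights(m.ModelConfig(group="CLD"))
        prof = m.simulate_stimulation(W, "arm", "CLD")
        expected = W.column("arm") + W.column("palm") + W.column("fingers")
        np.testing.assert_array_equal(prof.values, expected)

    def test_cld_foot_differs_from_ctr_after_scaling(self):
        ctr, cld, _ = m.compare_groups()
        assert not np.allclose(ctr["foot"].values, cld["foot"].values)

    def test_unknown_part(self):
        W = m.build_initial_weights(m.ModelConfig())
        with pytest.raises(KeyError):
            m.simulate_stimulation(W, "tail")

    def test_oracle_equivalence_naive_loops(self, rng):
        """MNA and stimulation match an index-by-index reimplementation."""
        values = rng.uniform(0.01, 2.0, size=(5, 10))
        W = m.WeightMatrix(values=values, stage="homeostatic")
        probs = rng.uniform(0.0, 1.0, size=10)
        naive_mna = [
            sum(values[j, i] * probs[i] for i in range(10)) for j in range(5)
        ]
        np.testing.assert_allclose(m.compute_mna(W, probs), naive_mna, rtol=1e-12)
        prof = m.simulate_stimulation(W, "arm", "CLD")
        idx = [m.BODY_PARTS.index(p) for p in ("arm", "palm", "fingers")]
        naive = [sum(values[j, i] for i in idx) for j in range(5)]
        np.testing.assert_allclose(prof.values, naive, rtol=1e-12)


class TestGroupSimulation:
    def test_six_profiles_with_finite_unique_peaks(self):
        profiles = m.run_group_simulation(m.ModelConfig())
        assert set(profiles) == set(m.EVALUATED_PARTS)
        for prof in profiles.values():
            assert np.isfinite(prof.values).all()
            assert (prof.values == prof.peak_value).sum() == 1

    @pytest.mark.parametrize("group", ["CTR", "CLD"])
    @pytest.mark.parametrize("variant", ["main", "rudimentary"])
    def test_homuncular_ordering_preserved(self, group, variant):
        profiles = m.run_group_simulation(m.ModelConfig(group=group, variant=variant))
        order = ["foot", "leg", "torso", "arm", "upper_face", "lower_face"]
        positions = [profiles[p].peak_position for p in order]
        assert positions == sorted(positions)

    def test_cld_arm_peak_more_lateral_than_ctr(self):
        ctr, cld, _ = m.compare_groups()
        assert cld["arm"].peak_node > ctr["arm"].peak_node


class TestObservations:
    def test_identical_profiles_fail_difference_observations(self):
        profiles = m.run_group_simulation(m.ModelConfig())
        report = m.check_observations(profiles, profiles, hand_center=30.0)
        assert not report.obs1 and not report.obs2 and not report.obs3

    def test_pure_amplitude_increase_passes_obs3_fails_obs2(self):
        ctr = m.run_group_simulation(m.ModelConfig())
        bumped = {
            part: m.ActivationProfile(
                body_part=part,
                values=prof.values + 1.0,
                peak_node=prof.peak_node,
                peak_value=prof.peak_value + 1.0,
                peak_position=prof.peak_position,
            )
            for part, prof in ctr.items()
        }
        report = m.check_observations(ctr, bumped, hand_center=30.0)
        assert report.obs3
        assert not report.obs2

    def test_missing_part_raises(self):
        profiles = m.run_group_simulation(m.ModelConfig())
        partial = {k: v for k, v in profiles.items() if k != "arm"}
        with pytest.raises(KeyError):
            m.check_observations(profiles, partial, hand_center=30.0)

    def test_costimulation_flag_changes_cld_equilibrium(self):
        base = m.run_group_simulation(m.ModelConfig(group="CLD"))
        alt = m.run_group_simulation(
            m.ModelConfig(group="CLD", mna_costimulation=True)
        )
        assert not np.allclose(base["arm"].values, alt["arm"].values)
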
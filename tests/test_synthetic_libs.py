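"""Spike-volume arithmetic, gradient plans, and the spectrum generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from libsquant import (
    GeneratorConfig,
    average_shots,
    build_gradient_plan,
    generate_dataset,
    generate_spectrum,
    spike_volume,
)
from libsquant.synthetic_libs import GRADIENT_LEVELS, noiseless_config


class TestSpikeVolume:
    # the wet-lab protocol's printed volumes: 0.01 mol/L solutions, 5 g powder
    @pytest.mark.parametrize("element,mass,conc,expected", [
        ("Cd", 112.4, 5, 22.24), ("Cd", 112.4, 10, 44.48), ("Cd", 112.4, 20, 88.97),
        ("Cd", 112.4, 25, 111.21), ("Cd", 112.4, 50, 222.42), ("Cd", 112.4, 80, 355.87),
        ("Cd", 112.4, 100, 444.84),
        ("Cu", 64.0, 20, 156.25), ("Cu", 64.0, 40, 312.5), ("Cu", 64.0, 60, 468.75),
        ("Cu", 64.0, 80, 625.0), ("Cu", 64.0, 100, 781.25), ("Cu", 64.0, 200, 1562.5),
        ("Cu", 64.0, 300, 2343.75),
        ("Pb", 207.2, 20, 48.26), ("Pb", 207.2, 40, 96.53), ("Pb", 207.2, 60, 144.79),
        ("Pb", 207.2, 80, 193.05), ("Pb", 207.2, 100, 241.31), ("Pb", 207.2, 200, 482.63),
    ])
    def test_printed_volumes_recomputed(self, element, mass, conc, expected):
        assert round(spike_volume(conc, 5.0, 0.01, mass), 2) == expected

    def test_zero_target_needs_zero_volume(self):
        assert spike_volume(0.0, 5.0, 0.01, 112.4) == 0.0

    @pytest.mark.parametrize("molarity,molar_mass", [(0.0, 100.0), (0.01, 0.0), (-1, 100)])
    def test_degenerate_solution_rejected(self, molarity, molar_mass):
        with pytest.raises(ValueError):
            spike_volume(5.0, 5.0, molarity, molar_mass)

    @given(conc=st.floats(0.01, 500), mass=st.floats(0.1, 50), scale=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_concentration_and_mass(self, conc, mass, scale):
        base = spike_volume(conc, mass, 0.01, 112.4)
        assert spike_volume(conc * scale, mass, 0.01, 112.4) == pytest.approx(base * scale, rel=1e-9)
        assert spike_volume(conc, mass * scale, 0.01, 112.4) == pytest.approx(base * scale, rel=1e-9)

    def test_volume_inverts_to_level(self):
        """volume -> concentration recovers every gradient level to 1e-9 relative."""
        for element in ("Cd", "Cu", "Pb"):
            plan = build_gradient_plan(element)
            for level, vol in zip(plan.levels, plan.volumes):
                recovered = vol * plan.molar_mass * plan.molarity / plan.sample_mass
                assert recovered == pytest.approx(level, rel=1e-9, abs=1e-12)


class TestGradientPlan:
    def test_cd_plan_matches_protocol(self):
        plan = build_gradient_plan("Cd")
        assert len(plan.levels) == 8
        assert max(plan.levels) == 100.0
        assert round(max(plan.volumes), 2) == 444.84

    def test_levels_are_study_gradients(self):
        assert build_gradient_plan("Cu").levels == GRADIENT_LEVELS["Cu"]
        assert build_gradient_plan("Pb").levels == (0.0, 5.0, 20.0, 40.0, 60.0, 80.0, 100.0, 200.0)

    def test_pb_level_20_volume(self):
        plan = build_gradient_plan("Pb")
        assert round(plan.volumes[plan.levels.index(20.0)], 2) == 48.26

    def test_control_level_has_zero_volume(self):
        for element in ("Cd", "Cu", "Pb"):
            assert build_gradient_plan(element).volumes[0] == 0.0

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError):
            build_gradient_plan("Hg")

    def test_exact_masses_flag_changes_volumes(self):
        rounded = build_gradient_plan("Cu").volumes[1]
        exact = build_gradient_plan("Cu", exact_masses=True).volumes[1]
        assert rounded != exact


class TestGenerateSpectrum:
    def test_blank_is_baseline_plus_matrix_lines(self):
        cfg = noiseless_config()
        rng = np.random.default_rng(0)
        y = generate_spectrum({"Cd": 0, "Cu": 0, "Pb": 0}, cfg, rng)
        wl = cfg.axis().wavelengths
        u = (228.80 - 210.0) / 21.0
        baseline_at_line = np.polynomial.polynomial.polyval(u, cfg.baseline_coeffs)
        i = cfg.axis().index_of(228.80)
        # 228.80 nm is far from every matrix line, so the blank equals the continuum
        assert y[i] == pytest.approx(baseline_at_line, rel=1e-3)

    def test_doubling_concentration_doubles_peak(self):
        cfg = noiseless_config()
        rng = np.random.default_rng(0)
        i = cfg.axis().index_of(228.80)
        blank = generate_spectrum({"Cd": 0, "Cu": 0, "Pb": 0}, cfg, rng)
        low = generate_spectrum({"Cd": 10, "Cu": 0, "Pb": 0}, cfg, rng)
        high = generate_spectrum({"Cd": 20, "Cu": 0, "Pb": 0}, cfg, rng)
        assert high[i] - blank[i] == pytest.approx(2 * (low[i] - blank[i]), rel=1e-9)

    def test_peak_height_monotone_and_element_specific(self):
        cfg = noiseless_config()
        rng = np.random.default_rng(0)
        i = cfg.axis().index_of(228.80)
        heights = []
        for c in (0.0, 5.0, 50.0, 100.0):
            y = generate_spectrum({"Cd": c, "Cu": 100.0, "Pb": 50.0}, cfg, rng)
            heights.append(y[i])
        assert np.all(np.diff(heights) > 0)
        # invariant to the other analytes
        a = generate_spectrum({"Cd": 30, "Cu": 0, "Pb": 0}, cfg, rng)
        b = generate_spectrum({"Cd": 30, "Cu": 300, "Pb": 200}, cfg, rng)
        assert a[i] == pytest.approx(b[i], rel=1e-9)

    def test_fixed_seed_reproducible(self):
        cfg = GeneratorConfig(seed=0)
        y1 = generate_spectrum({"Cd": 5, "Cu": 5, "Pb": 5}, cfg, np.random.default_rng(11))
        y2 = generate_spectrum({"Cd": 5, "Cu": 5, "Pb": 5}, cfg, np.random.default_rng(11))
        np.testing.assert_array_equal(y1, y2)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            generate_spectrum({"Cd": -1, "Cu": 0, "Pb": 0}, GeneratorConfig(), np.random.default_rng(0))

    def test_saturation_compresses_high_end(self):
        cfg = noiseless_config(saturation_K=50.0)
        lin = noiseless_config()
        rng = np.random.default_rng(0)
        i = cfg.axis().index_of(228.80)
        sat = generate_spectrum({"Cd": 100, "Cu": 0, "Pb": 0}, cfg, rng)
        unsat = generate_spectrum({"Cd": 100, "Cu": 0, "Pb": 0}, lin, rng)
        assert sat[i] < unsat[i]


class TestGenerateDataset:
    def test_default_design_is_192_by_1024(self, default_dataset):
        assert default_dataset.intensities.shape == (192, 1024)
        assert len(default_dataset.metas) == 192

    def test_single_cell_design(self):
        ds = generate_dataset(GeneratorConfig(design=(1, 1, 1), seed=0))
        assert ds.n_samples == 1

    def test_deterministic_replicates_when_stochastics_off(self):
        ds = generate_dataset(noiseless_config(design=(1, 2, 3)))
        for g in (1, 2):
            rows = [i for i, m in enumerate(ds.metas) if m.group == g]
            base = ds.intensities[rows[0]]
            for i in rows[1:]:
                np.testing.assert_allclose(ds.intensities[i], base, rtol=1e-12)

    def test_group_concentrations_follow_gradient_plus_background(self, default_dataset):
        for m in default_dataset.metas:
            for el in ("Cd", "Cu", "Pb"):
                level = GRADIENT_LEVELS[el][m.group - 1]
                # spiked level dominates; background and jitter add a little
                assert m.conc[el] >= 0
                if level > 0:
                    assert level * 0.8 <= m.conc[el] <= level * 1.25 + 15.0

    def test_line_height_tracks_concentration_across_seeds(self):
        """Raw peak channel correlates strongly with Cd content (seed-averaged)."""
        cors = []
        for seed in range(10):
            ds = generate_dataset(GeneratorConfig(seed=seed))
            i = ds.axis.index_of(228.80)
            cors.append(np.corrcoef(ds.concentrations("Cd"), ds.intensities[:, i])[0, 1])
        assert float(np.mean(cors)) > 0.95


class TestAverageShots:
    def test_first_position_dropped_7x3(self):
        rng = np.random.default_rng(0)
        shots = [rng.normal(size=8) for _ in range(21)]
        out = average_shots(shots, positions=7, accumulations=3)
        np.testing.assert_allclose(out, np.mean(shots[3:], axis=0))

    def test_identical_inputs_returned(self):
        v = np.arange(5.0)
        out = average_shots([v] * 6, positions=2, accumulations=3)
        np.testing.assert_array_equal(out, v)

    def test_two_positions_one_accumulation_returns_second(self):
        a, b = np.zeros(4), np.ones(4)
        np.testing.assert_array_equal(average_shots([a, b], 2, 1), b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="expected 21"):
            average_shots([np.zeros(3)] * 20, 7, 3)
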
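"""Structural and behavioural checks of the five model fixtures (the heavy
quantitative runs live in test_acceptance.py)."""

import numpy as np
import pytest

import eqspike as eq
from eqspike import case_studies as cs
from eqspike.units import ms, mV, second


class TestPyloricStructure:
    def test_fast_connectivity_is_the_five_pair_set(self):
        net, info = cs.build_pyloric(record_states=False)
        fast = info["fast"]
        lab = info["labels"]
        pairs = set(zip(fast.i_arr.tolist(), fast.j_arr.tolist()))
        expected = {(lab["ABPD"], lab["LP"]), (lab["ABPD"], lab["PY"]),
                    (lab["LP"], lab["ABPD"]), (lab["LP"], lab["PY"]),
                    (lab["PY"], lab["LP"])}
        assert pairs == expected

    def test_fast_condition_matches_enumeration_oracle(self):
        # evaluate the printed condition over all 9 ordered label pairs
        lab = cs.pyloric.LABELS
        expected = set()
        for lp in lab.values():
            for lpo in lab.values():
                label_pre, label_post = lp, lpo
                if label_pre != label_post and not (
                        label_pre == lab["PY"] and label_post == lab["ABPD"]):
                    expected.add((lp, lpo))
        assert len(expected) == 5
        net, info = cs.build_pyloric(record_states=False)
        got = set(zip(info["fast"].i_arr.tolist(),
                      info["fast"].j_arr.tolist()))
        assert got == expected

    def test_slow_connectivity_pacemaker_to_followers(self):
        net, info = cs.build_pyloric(record_states=False)
        slow = info["slow"]
        pairs = set(zip(slow.i_arr.tolist(), slow.j_arr.tolist()))
        assert pairs == {(0, 1), (0, 2)}

    def test_spike_raster_uses_minus_20mV_crossings(self):
        net, info = cs.build_pyloric(seed=0, record_interval=1)
        net.run(3 * second)
        st, sm = info["states"], info["spikes"]
        for cell in range(3):
            trace = st.values("v")[:, cell]
            crossings = eq.extract_spikes_from_trace(trace, st.t, -20 * mV)
            # crossing count from the recorded trace matches the monitor up to
            # refractory suppression of multi-sample excursions
            n_spk = int(sm.count()[cell])
            assert abs(len(crossings.value) - n_spk) <= 1


class TestOcular:
    def test_zero_gain_eye_stays_near_rest(self):
        t, eye, obj, info = cs.run_ocular(3.0, seed=5, gain=0.0)
        assert np.abs(eye).max() < 0.05
        assert np.abs(obj).max() > 0.1        # object wanders

    def test_closed_loop_tracks_better_than_control(self):
        wins = 0
        for seed in (11, 12, 13):
            closed = cs.ocular.tracking_error(5.0, seed=seed, gain=1.0)
            open_ = cs.ocular.tracking_error(5.0, seed=seed, gain=0.0)
            wins += closed < open_
        assert wins == 3

    def test_motoneuron_spikes_twitch_in_correct_direction(self):
        net, info = cs.build_ocular(seed=0)
        twitch = info["twitch"]
        w = twitch.state("w_tw").value
        assert w[0] > 0 and w[1] < 0          # moto 0 pulls +, moto 1 pulls -

    def test_linked_variables_alias_sources(self):
        net, info = cs.build_ocular(seed=0)
        info["object"].state_arrays["x_obj"][:] = 0.33
        assert np.all(info["retina"].state("x_obj_lnk").value == 0.33)


class TestThresholdFinding:
    def test_step_width_halves_each_iteration(self):
        net, info = cs.build_hh_population(n=2)
        est = cs.find_threshold(net, info["group"], info["spikes"],
                                initial=-50 * mV, step0=16 * mV, n_iter=6)
        # reachable values are initial + step0 * sum(+-2^-k): all estimates on
        # the dyadic grid with spacing step0 / 2^(n_iter-1)
        grid = (est.value - (-0.050)) / (0.016 / 2 ** 5)
        assert np.allclose(grid, np.round(grid), atol=1e-9)

    def test_estimates_monotone_in_sodium_density(self):
        net, info = cs.build_hh_population(n=8)
        est = cs.find_threshold(net, info["group"], info["spikes"],
                                initial=-50 * mV, step0=15 * mV, n_iter=12)
        final_step = 0.015 / 2 ** 11
        assert np.all(np.diff(est.value) <= final_step + 1e-12)

    def test_spikes_from_initial_voltages_is_monotone(self):
        from eqspike.units import parse_unit_expression
        gna = parse_unit_expression("50*mS/cm2")
        v0 = eq.Quantity(np.linspace(-70e-3, -40e-3, 16), mV.dim)
        spiked = cs.threshold_finding.spikes_from_initial_voltages(v0, gna)
        assert not spiked[0] and spiked[-1]
        assert np.all(np.diff(spiked.astype(int)) >= 0)


class TestCuba:
    def test_small_build_counts(self):
        net, info = cs.build_cuba(N=100, seed=0, monitors=False)
        assert info["n_exc"] == 80
        assert info["exc"].n + info["inh"].n == \
            pytest.approx(0.02 * 100 * 100, rel=0.5)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            cs.build_cuba(N=5)

    def test_homogeneous_selects_exact_integration(self):
        net, info = cs.build_cuba(N=50, seed=0, monitors=False)
        net._build()
        assert type(info["group"].updater).__name__ == "ExactUpdater"
        assert not info["group"].updater.system.per_instance

    def test_heterogeneous_is_per_instance_exact(self):
        net, info = cs.build_cuba(N=50, heterogeneous=True, seed=0,
                                  monitors=False)
        net._build()
        assert type(info["group"].updater).__name__ == "ExactUpdater"
        assert info["group"].updater.system.per_instance

    def test_deterministic_under_fixed_seed(self):
        rasters = []
        for _ in range(2):
            net, info = cs.build_cuba(N=200, seed=31)
            net.run(100 * ms)
            rasters.append((info["spikes"].t.value.copy(),
                            info["spikes"].i.copy()))
        assert np.array_equal(rasters[0][0], rasters[1][0])
        assert np.array_equal(rasters[0][1], rasters[1][1])


class TestPitch:
    def test_silent_input_no_spikes(self):
        wave = np.zeros(5000)
        net, info = cs.build_pitch(wave, 10_000.0)
        net.run(0.4 * second)
        assert info["detector_spikes"].num_spikes == 0
        assert info["input_spikes"].num_spikes == 0

    def test_detector_delay_differences_incremental(self):
        wave = np.zeros(1000)
        net, info = cs.build_pitch(wave, 10_000.0)
        paths = info["paths"]
        inst = paths.pathways["instantaneous"].delay
        dely = paths.pathways["delayed"].delay
        diffs = dely - inst
        assert np.allclose(diffs, (np.arange(info["n_detectors"]) + 1) * 5e-4)

    def test_waveform_respects_nyquist(self):
        with pytest.raises(ValueError):
            cs.tone_burst_train([0.05 * ms])      # 20 kHz tone at 10 kHz fs

    def test_rising_tone_sequence_shifts_active_band(self):
        periods = [4 * ms, 2 * ms]
        counts, info = cs.run_pitch(periods, n_bursts_per_tone=4)
        det = info["detector_spikes"]
        delays = cs.pitch.preferred_delays(info).value
        # split spikes at the tone boundary and find the argmax detector per half
        half_t = det.t.value.max() / 2
        for half, period in ((det.t.value < half_t, 4e-3),
                             (det.t.value >= half_t, 2e-3)):
            counts_half = np.bincount(det.i[half],
                                      minlength=info["n_detectors"])
            assert delays[np.argmax(counts_half)] == pytest.approx(period)


def test_all_fixtures_validate_dimensionally():
    """Every fixture builds -- i.e. passes dimensional validation -- without
    warnings."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        cs.build_pyloric(record_states=False)
        cs.build_ocular()
        cs.build_hh_population(n=3)
        cs.build_cuba(N=20, monitors=False)
        cs.build_pitch(np.zeros(100), 10_000.0)


def test_cli_runs_a_case(tmp_path):
    from click.testing import CliRunner
    from eqspike.cli import main
    out = tmp_path / "out"
    res = CliRunner().invoke(
        main, ["run", "ocular", "--duration", "0.5*second", "--seed", "2",
               "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "spikes.csv").exists()
    assert (out / "figure.png").exists()
    assert (out / "manifest.json").exists()
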
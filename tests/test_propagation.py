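import numpy as np
import pytest

from meanet.errors import (
    DegenerateInputError,
    InsufficientDataError,
)
from meanet.io import ElectrodeLayout, SpikeTrainSet
from meanet.netburst import NetworkBurst, detect_network_bursts
from meanet.presets import preset_cmos_axon
from meanet.propagation import (
    conduction_velocity,
    fit_velocity,
    localize_somata,
    nb_onset_delays,
    pair_velocity,
    relative_velocity,
    spike_triggered_average,
    trace_axon_path,
)

from .oracles import ols_normal_equations


def _two_electrode_set(ref_times, tgt_times, duration):
    return SpikeTrainSet(
        {4: (ref_times, np.full(len(ref_times), -30.0)),
         13: (tgt_times, np.full(len(tgt_times), -30.0))}, duration)


def _nbs_covering(ref_times, tgt_times):
    return [NetworkBurst(r - 0.01, t + 0.01, 2, r, 1)
            for r, t in zip(ref_times, tgt_times)]


class TestOnsetDelays:
    def test_constant_lag(self):
        ref = 10.0 * np.arange(1, 32)
        tgt = ref + 0.375
        s = _two_electrode_set(ref, tgt, 330.0)
        out = nb_onset_delays(_nbs_covering(ref, tgt), s, 4, 13)
        assert out.n == 31
        assert out.mean_s == pytest.approx(0.375)
        assert out.sd_s == 0.0

    def test_jittered_lag_sd_recovered(self, rng):
        n = 500
        ref = 5.0 * np.arange(1, n + 1)
        tgt = ref + 0.375 + rng.normal(0, 0.166, size=n)
        s = _two_electrode_set(ref, tgt, 5.0 * (n + 1))
        out = nb_onset_delays(_nbs_covering(ref, tgt), s, 4, 13)
        assert out.sd_s == pytest.approx(0.166, rel=0.10)
        assert out.mean_s == pytest.approx(0.375, rel=0.05)

    def test_silent_target_bursts_excluded(self):
        ref = 10.0 * np.arange(1, 21)
        tgt = ref[:15] + 0.3  # target silent in the last 5 NBs
        s = _two_electrode_set(ref, tgt, 250.0)
        nbs = [NetworkBurst(r - 0.01, r + 0.5, 2, r, 1) for r in ref]
        out = nb_onset_delays(nbs, s, 4, 13)
        assert out.n == 15
        assert out.n_excluded == 5

    def test_no_bursts_rejected(self):
        s = _two_electrode_set([1.0], [1.3], 2.0)
        with pytest.raises(InsufficientDataError):
            nb_onset_delays([], s, 4, 13)


class TestPairVelocity:
    def test_arithmetic(self):
        assert pair_velocity(900.0, 0.3) == pytest.approx(3.0)
        assert pair_velocity(1398.75, 0.375) == pytest.approx(3.73)

    def test_zero_delay_rejected(self):
        with pytest.raises(DegenerateInputError):
            pair_velocity(900.0, 0.0)

    def test_relative_velocity(self):
        assert relative_velocity(2.0, 2.0) == 1.0
        assert relative_velocity(4.0, 2.0) == 2.0
        with pytest.raises(DegenerateInputError):
            relative_velocity(1.0, 0.0)


class TestFitVelocity:
    def test_noiseless_line(self):
        t = np.linspace(0, 0.01, 8)
        d = 0.14e6 * t
        res = fit_velocity(d, t)
        assert res.velocity_m_s == pytest.approx(0.14)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        t = rng.uniform(0, 5e-3, size=40)
        d = 0.3e6 * t + rng.normal(0, 30.0, size=40)
        res = fit_velocity(d, t)
        slope, intercept, r2 = ols_normal_equations(list(t), list(d))
        assert res.velocity_m_s == pytest.approx(slope * 1e-6, rel=1e-10)
        assert res.intercept_um == pytest.approx(intercept, rel=1e-8, abs=1e-8)
        assert res.r_squared == pytest.approx(r2, rel=1e-10)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 0.01, 50)
        d = 0.14e6 * t
        d_noisy = d + rng.normal(0, 0.05 * np.ptp(d), size=50)
        res = fit_velocity(d_noisy, t)
        assert res.velocity_m_s == pytest.approx(0.14, rel=0.05)
        assert res.r_squared > 0.9

    def test_degenerate_latencies_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_velocity([0.0, 100.0, 200.0], [1e-3, 1e-3, 1e-3])

    def test_two_points_exact(self):
        res = fit_velocity([0.0, 100.0], [0.0, 1e-3])
        assert res.exact_fit
        assert res.velocity_m_s == pytest.approx(0.1)

    def test_invariance_to_time_origin(self, rng):
        t = np.linspace(0, 2e-3, 10)
        d = 0.5e6 * t + rng.normal(0, 10.0, size=10)
        v1 = fit_velocity(d, t).velocity_m_s
        v2 = fit_velocity(d, t + 0.7).velocity_m_s
        assert v1 == pytest.approx(v2, rel=1e-9)


class TestLocalizeSomata:
    def _grid(self):
        return ElectrodeLayout.grid(20, 20, pitch_um=17.5)

    def test_planted_peaks_recovered(self, rng):
        layout = self._grid()
        centers = [(3, 3), (3, 15), (10, 9), (16, 4), (16, 16)]
        amps = {}
        for eid in layout.ids:
            p = layout.position_of(int(eid)) / 17.5
            a = 2.0
            for cx, cy in centers:
                a = max(a, 100.0 * np.exp(-((p[0] - cx) ** 2 + (p[1] - cy) ** 2) / 2.0))
            amps[int(eid)] = a + rng.normal(0, 0.5)
        somata = localize_somata(amps, layout, min_amp_uv=50.0, min_sep_um=70.0)
        got = {tuple((layout.position_of(e) / 17.5).astype(int)) for e in somata.electrode_ids}
        assert got == {(cx, cy) for cx, cy in centers}

    def test_flat_map_empty(self):
        layout = self._grid()
        somata = localize_somata({int(e): 1.0 for e in layout.ids}, layout,
                                 min_amp_uv=20.0, min_sep_um=35.0)
        assert len(somata) == 0

    def test_close_peaks_suppressed(self):
        layout = self._grid()
        amps = {int(e): 0.0 for e in layout.ids}
        amps[int(layout.ids[0])] = 80.0
        amps[int(layout.ids[1])] = 100.0  # 17.5 µm away, larger
        somata = localize_somata(amps, layout, min_amp_uv=50.0, min_sep_um=35.0)
        assert somata.electrode_ids == (int(layout.ids[1]),)


class TestSTA:
    def test_window_sample_count(self, single_channel_layout, rng):
        from meanet.io import Recording

        rec = Recording(rng.normal(size=(1, 20000)), 20000.0, single_channel_layout)
        out = spike_triggered_average(rec, [0.5])
        assert out.waveforms.shape == (1, 80)  # 4 ms at 20 kHz

    def test_single_trigger_returns_raw_segment(self, single_channel_layout, rng):
        from meanet.io import Recording

        v = rng.normal(size=(1, 20000))
        rec = Recording(v, 20000.0, single_channel_layout)
        out = spike_triggered_average(rec, [0.5])
        i = int(0.5 * 20000)
        np.testing.assert_allclose(out.waveforms[0], v[0, i - 30 : i + 50])

    def test_clipped_triggers_dropped(self, single_channel_layout, rng):
        from meanet.io import Recording

        rec = Recording(rng.normal(size=(1, 2000)), 20000.0, single_channel_layout)
        out = spike_triggered_average(rec, [0.0005, 0.05, 0.0999])
        assert out.n_used == 1 and out.n_dropped == 2


class TestAxonPath:
    def test_planted_path_recovered_with_noise(self):
        bundle = preset_cmos_axon(seed=5, noise_sd_uv=4.0)
        truth = bundle.truth
        stas = spike_triggered_average(bundle.recording, truth.trigger_times_s)
        path = trace_axon_path(stas, truth.soma_electrode, bundle.layout,
                               rho_min=0.7, amp_min_uv=30.0)
        assert set(path.electrode_ids) == set(truth.path_electrode_ids)
        # latency order equals the planted conduction order
        planted_order = sorted(truth.path_electrode_ids,
                               key=lambda e: truth.electrode_latency_s[e])
        assert path.electrode_ids == planted_order

    def test_impossible_rho_gives_soma_only(self):
        bundle = preset_cmos_axon(seed=5, noise_sd_uv=4.0)
        stas = spike_triggered_average(bundle.recording,
                                       bundle.truth.trigger_times_s)
        path = trace_axon_path(stas, bundle.truth.soma_electrode, bundle.layout,
                               rho_min=1.01, amp_min_uv=30.0)
        assert path.soma_only
        assert path.electrode_ids == [bundle.truth.soma_electrode]

    def test_noiseless_conduction_velocity(self):
        bundle = preset_cmos_axon(seed=6, noise_sd_uv=0.0)
        stas = spike_triggered_average(bundle.recording,
                                       bundle.truth.trigger_times_s)
        path = trace_axon_path(stas, bundle.truth.soma_electrode, bundle.layout,
                               rho_min=0.7, amp_min_uv=30.0)
        res = conduction_velocity(path)
        assert res.velocity_m_s == pytest.approx(0.57, rel=0.02)
        assert res.r_squared >= 0.999
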
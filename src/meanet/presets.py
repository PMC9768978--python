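"""Canned study-condition configurations for the synthetic generator.

Each preset fixes the geometry, burst schedule and noise level of one of
the experimental settings the pipeline is built for, with parameters at
the scales the source experiments report:

* ``burst16`` — a 16-electrode (4x4, 450 µm pitch) well with 20
  synchronized network bursts of 600 spikes, spike SNR 8 (32 µV trough on
  4 µV noise), sparse background firing.
* ``spheroid_pair`` — two spheroids on diagonal electrodes 4 and 13,
  1398.75 µm apart, with a 375 ms mean NB-onset delay (3.73 mm/s) and a
  166 ms delay SD over 31 NBs.
* ``network7`` — 7 neurons spaced along 1.8 mm firing NBs that propagate
  at 0.14 m/s with ~0.8 ms first-spike jitter.
* ``cmos_axon`` — a 24x24, 17.5 µm-pitch high-density patch with a soma
  and a 370 µm axon conducting at 0.57 m/s.
* ``dose_response`` — panel samples for vehicle (DMSO) plus four
  compounds with monotone concentration effects on the burst parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ElectrodeLayout, Recording, SpikeTrainSet
from .synth import (
    BurstSchedule,
    GroundTruth,
    LFPComponent,
    gen_axon_dataset,
    gen_param_samples,
    gen_spiketrains,
    render_traces,
)

__all__ = [
    "SimBundle",
    "preset_burst16",
    "preset_spheroid_pair",
    "preset_network7",
    "preset_cmos_axon",
    "preset_dose_response",
    "PRESETS",
]

#: spheroid electrode pair and separation: 375 ms at 3.73 mm/s <-> 1398.75 µm
SPHEROID_ELECTRODES = (4, 13)
SPHEROID_DISTANCE_UM = 1398.75
SPHEROID_DELAY_S = 0.375
SPHEROID_DELAY_SD_S = 0.166


@dataclass
class SimBundle:
    layout: ElectrodeLayout
    spikes: SpikeTrainSet | None
    truth: GroundTruth
    recording: Recording | None = None
    table_entries: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def preset_burst16(seed: int, render: bool = True, n_nb: int = 20,
                   spikes_per_nb: int = 600) -> SimBundle:
    layout = ElectrodeLayout.grid(4, 4, pitch_um=450.0)
    schedule = BurstSchedule.regular(n_nb, period_s=2.5, count=spikes_per_nb,
                                     duration_s=0.5, background_hz=0.1)
    spikes, truth = gen_spiketrains(layout, schedule, seed=seed, amp_uv=-32.0)
    truth.noise_sd_uv = 4.0
    rec = render_traces(spikes, layout, seed=seed + 1, noise_sd_uv=4.0) if render else None
    return SimBundle(layout, spikes, truth, recording=rec)


def preset_spheroid_pair(seed: int, n_nb: int = 31) -> SimBundle:
    # 4x4 grid whose 3-pitch diagonal equals the spheroid separation
    pitch = SPHEROID_DISTANCE_UM / (3 * np.sqrt(2))
    layout = ElectrodeLayout.grid(4, 4, pitch_um=pitch)
    ref, tgt = SPHEROID_ELECTRODES
    velocity = SPHEROID_DISTANCE_UM / SPHEROID_DELAY_S  # 3730 µm/s = 3.73 mm/s
    # NB firing long enough (1.2 s) that the two spheroids' windows always
    # overlap despite the 375 +/- 166 ms onset lag, so one NB spans both
    # 3000 pooled spikes / 1.2 s -> ~1.25 kHz per spheroid electrode, so the
    # leading single-spheroid span never fragments at the 10 ms join ISI
    schedule = BurstSchedule.regular(n_nb, period_s=12.0, count=3000,
                                     duration_s=1.2, background_hz=0.02)
    # independent per-electrode onset jitter; the pairwise delay is the
    # difference of two onsets, so its SD is sqrt(2) x the per-onset SD.
    # Uniform intra-NB firing keeps each spheroid's rate high right from
    # its onset, so the measured first spike is the planted window start.
    spikes, truth = gen_spiketrains(
        layout, schedule, seed=seed,
        source_xy=layout.position_of(ref), velocity_um_s=velocity,
        jitter_sd_s=SPHEROID_DELAY_SD_S / np.sqrt(2.0),
        active_electrodes=[ref, tgt], intra="uniform",
    )
    truth.extras.update(ref_electrode=ref, target_electrode=tgt,
                        planted_delay_s=SPHEROID_DELAY_S,
                        planted_delay_sd_s=SPHEROID_DELAY_SD_S,
                        velocity_mm_s=velocity / 1000.0)
    return SimBundle(layout, spikes, truth)


def preset_network7(seed: int, velocity_m_s: float = 0.14, n_nb: int = 4,
                    jitter_sd_s: float = 0.8e-3, span_um: float = 1800.0) -> SimBundle:
    n_neurons = 7
    xs = np.linspace(0.0, span_um, n_neurons)
    layout = ElectrodeLayout(np.arange(1, n_neurons + 1),
                             np.column_stack([xs, np.zeros(n_neurons)]))
    schedule = BurstSchedule.regular(n_nb, period_s=5.0, count=1400,
                                     duration_s=0.5, background_hz=0.0)
    spikes, truth = gen_spiketrains(
        layout, schedule, seed=seed,
        source_xy=layout.position_of(1), velocity_um_s=velocity_m_s * 1e6,
        jitter_sd_s=jitter_sd_s,
    )
    truth.extras.update(ref_electrode=1, velocity_m_s=velocity_m_s)
    return SimBundle(layout, spikes, truth)


def preset_cmos_axon(seed: int, velocity_m_s: float = 0.57,
                     noise_sd_uv: float = 0.0) -> SimBundle:
    layout = ElectrodeLayout.grid(24, 24, pitch_um=17.5)
    # straight axon along grid row 12, between columns 1 and 22
    y = 12 * 17.5
    polyline = np.array([[1 * 17.5, y], [22 * 17.5, y]])
    rec, truth = gen_axon_dataset(
        layout, polyline, velocity_m_s, seed=seed,
        decay_um=10.0, amp0_uv=120.0, amp_floor_uv=30.0,
        n_triggers=100, noise_sd_uv=noise_sd_uv,
    )
    truth.extras.update(velocity_m_s=velocity_m_s)
    return SimBundle(layout, None, truth, recording=rec)


#: convulsant-screen pharmacology ladder: vehicle + four compounds, 5 doses each
DOSE_CONDITIONS = {
    "DMSO": [0.2, 0.3, 0.4, 0.5, 0.6],
    "4-AP": [0.1, 1.0, 3.0, 10.0, 30.0],
    "pilocarpine": [0.1, 1.0, 3.0, 10.0, 30.0],
    "picrotoxin": [0.1, 0.3, 1.0, 3.0, 10.0],
    "AP-5": [1.0, 3.0, 10.0, 30.0, 100.0],
}

# top-dose multipliers; mean IMFI moves inversely with the burst count
DOSE_EFFECTS = {
    "4-AP": {"n_nb": 2.5, "mean_imfi_s": 0.4, "cv_nb_duration": 2.0,
             "total_spikes": 1.5},
    "pilocarpine": {"n_nb": 2.2, "mean_imfi_s": 0.45, "cv_nb_duration": 0.45,
                    "cv_spikes_per_nb": 0.45, "cv_max_frequency": 0.45,
                    "cv_imfi": 0.45},
    "picrotoxin": {"n_nb": 2.0, "mean_imfi_s": 0.5, "cv_imfi": 2.2,
                   "mean_nb_duration_s": 1.4},
    "AP-5": {"n_nb": 0.1, "mean_imfi_s": 6.0, "total_spikes": 0.25,
             "mean_spikes_per_nb": 0.4, "mean_nb_duration_s": 0.6},
}


def preset_dose_response(seed: int, n_per_group: int = 4) -> SimBundle:
    entries, truth_info = gen_param_samples(
        DOSE_CONDITIONS, n_per_group=n_per_group, seed=seed,
        control="DMSO", effects=DOSE_EFFECTS,
    )
    layout = ElectrodeLayout.grid(4, 4, pitch_um=450.0)
    truth = GroundTruth(seed=seed, extras=truth_info)
    return SimBundle(layout, None, truth, table_entries=entries)


PRESETS = {
    "burst16": preset_burst16,
    "spheroid-pair": preset_spheroid_pair,
    "network7": preset_network7,
    "cmos-axon": preset_cmos_axon,
    "dose-response": preset_dose_response,
}
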
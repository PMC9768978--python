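"""Synthetic MEA recordings with known ground truth.

Everything downstream of the amplifier is emulated at the level the
analysis consumes: per-electrode spike trains organized into synchronized
network bursts (optionally propagating from a source at a set velocity),
raw voltage traces rendered from a biphasic extracellular spike template
plus Gaussian noise and burst-locked low-frequency (LFP) oscillations,
high-density amplitude footprints of a soma with an axonal path at a set
conduction velocity, and dose-response samples of the 10-parameter burst
panel. Every generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io import ElectrodeLayout, Recording, SpikeTrainSet

__all__ = [
    "BurstSchedule",
    "GroundTruth",
    "LFPComponent",
    "gen_spiketrains",
    "biphasic_template",
    "biphasic_wave",
    "render_traces",
    "gen_axon_dataset",
    "gen_param_samples",
]


@dataclass(frozen=True)
class BurstSchedule:
    """Planted NB onsets, pooled spike counts, durations, background rate."""

    onsets_s: np.ndarray
    counts: np.ndarray
    durations_s: np.ndarray
    background_hz: float = 0.0  # homogeneous Poisson rate per electrode

    def __post_init__(self):
        onsets = np.asarray(self.onsets_s, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        durs = np.asarray(self.durations_s, dtype=float)
        if not (onsets.size == counts.size == durs.size):
            raise ValidationError("schedule arrays must have equal length")
        if onsets.size and (np.any(np.diff(onsets) <= 0) or np.any(counts <= 0)
                            or np.any(durs <= 0)):
            raise ValidationError("onsets must increase; counts and durations positive")
        object.__setattr__(self, "onsets_s", onsets)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "durations_s", durs)

    @classmethod
    def regular(cls, n_nb: int, period_s: float, count: int, duration_s: float,
                start_s: float = 1.0, background_hz: float = 0.0) -> "BurstSchedule":
        onsets = start_s + np.arange(n_nb) * period_s
        return cls(onsets, np.full(n_nb, count), np.full(n_nb, duration_s), background_hz)

    @property
    def n_nb(self) -> int:
        return int(self.onsets_s.size)


@dataclass
class GroundTruth:
    """What the generator planted, for closed-loop recovery tests."""

    seed: int
    spikes: SpikeTrainSet | None = None
    nb_intervals: list = field(default_factory=list)  # (t_start, t_end) per NB
    nb_onsets: list = field(default_factory=list)  # per NB: {electrode: window start}
    electrode_delays: dict = field(default_factory=dict)  # electrode -> s from source
    velocity_um_s: float | None = None
    noise_sd_uv: float | None = None
    # axon-dataset fields
    soma_electrode: int | None = None
    path_electrode_ids: list = field(default_factory=list)
    electrode_latency_s: dict = field(default_factory=dict)
    electrode_amplitude_uv: dict = field(default_factory=dict)
    trigger_times_s: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def gen_spiketrains(
    layout: ElectrodeLayout,
    schedule: BurstSchedule,
    seed: int,
    source_xy: np.ndarray | None = None,
    velocity_um_s: float | None = None,
    jitter_sd_s: float = 0.0,
    active_electrodes=None,
    intra: str = "gauss",
    amp_uv: float = -32.0,
    amp_jitter_frac: float = 0.1,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Spike trains with planted network bursts.

    Each NB gives every active electrode a firing window of the scheduled
    duration, offset from the NB onset by distance-to-source / velocity
    (zero without propagation) plus Gaussian onset jitter. The electrode's
    first spike sits exactly at its window start (its NB onset); the rest
    of its share of the pooled count is drawn from a truncated Gaussian
    centred on the window (``intra="uniform"`` for a flat profile).
    Background activity is homogeneous Poisson per electrode.
    """
    if (source_xy is None) != (velocity_um_s is None):
        raise ValidationError("propagation needs both a source position and a velocity")
    if velocity_um_s is not None and velocity_um_s <= 0:
        raise ValidationError("propagation velocity must be positive")
    rng = np.random.default_rng(seed)
    eids = [int(e) for e in (active_electrodes if active_electrodes is not None
                             else layout.ids)]
    if source_xy is not None:
        src = np.asarray(source_xy, dtype=float)
        offsets = {e: float(np.hypot(*(layout.position_of(e) - src))) / velocity_um_s
                   for e in eids}
    else:
        offsets = {e: 0.0 for e in eids}
    max_off = max(offsets.values())
    total_dur = float(schedule.onsets_s[-1] + schedule.durations_s[-1] + max_off + 1.0) \
        if schedule.n_nb else 10.0
    per_el = {e: [] for e in eids}
    nb_intervals, nb_onsets = [], []
    for onset, count, dur in zip(schedule.onsets_s, schedule.counts, schedule.durations_s):
        share = _split_count(int(count), len(eids))
        window_start = {}
        lo = np.inf
        hi = -np.inf
        for e, n_e in zip(eids, share):
            w0 = onset + offsets[e] + (rng.normal(0.0, jitter_sd_s) if jitter_sd_s else 0.0)
            w0 = max(w0, 0.0)
            window_start[e] = w0
            if n_e == 0:
                continue
            if intra == "gauss":
                body = stats.truncnorm.rvs(-1.0, 1.0, loc=w0 + dur / 2, scale=dur / 2,
                                           size=n_e - 1, random_state=rng)
            elif intra == "uniform":
                body = rng.uniform(w0, w0 + dur, size=n_e - 1)
            else:
                raise ValidationError(f"unknown intra-NB distribution '{intra}'")
            t = np.concatenate([[w0], np.sort(body)])
            per_el[e].append(t)
            lo = min(lo, t[0])
            hi = max(hi, t[-1])
        nb_onsets.append(window_start)
        nb_intervals.append((lo, hi))
    trains = {}
    for e in eids:
        t_bursts = np.concatenate(per_el[e]) if per_el[e] else np.empty(0)
        if schedule.background_hz > 0:
            n_bg = rng.poisson(schedule.background_hz * total_dur)
            t_bg = rng.uniform(0.0, total_dur, size=n_bg)
        else:
            t_bg = np.empty(0)
        t = np.sort(np.concatenate([t_bursts, t_bg]))
        amps = amp_uv * (1.0 + amp_jitter_frac * rng.standard_normal(t.size))
        trains[e] = (t, amps)
    spikes = SpikeTrainSet(trains, duration=total_dur)
    truth = GroundTruth(
        seed=seed, spikes=spikes, nb_intervals=nb_intervals, nb_onsets=nb_onsets,
        electrode_delays=offsets, velocity_um_s=velocity_um_s,
    )
    return spikes, truth


def _split_count(count: int, n: int) -> np.ndarray:
    base = count // n
    share = np.full(n, base, dtype=int)
    share[: count - base * n] += 1
    return share


def biphasic_wave(t: np.ndarray, trough_width_s: float = 1e-3,
                  total_width_s: float = 2e-3, overshoot: float = 0.4) -> np.ndarray:
    """Continuous biphasic extracellular spike shape, unit (negative) trough.

    Negative lobe over [0, trough_width], positive overshoot over
    [trough_width, total_width], zero elsewhere. Trough at trough_width/2.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    neg = (t >= 0) & (t < trough_width_s)
    out[neg] = -np.sin(np.pi * t[neg] / trough_width_s)
    pos = (t >= trough_width_s) & (t <= total_width_s)
    out[pos] = overshoot * np.sin(np.pi * (t[pos] - trough_width_s)
                                  / (total_width_s - trough_width_s))
    return out


def biphasic_template(fs: float, **kwargs) -> np.ndarray:
    """Sampled biphasic template; index round(0.5 ms * fs) is the trough."""
    total = kwargs.get("total_width_s", 2e-3)
    n = int(round(total * fs)) + 1
    return biphasic_wave(np.arange(n) / fs, **kwargs)


@dataclass(frozen=True)
class LFPComponent:
    """Amplitude-modulated sinusoid added to every channel.

    ``intervals`` restricts the oscillation to the given (t0, t1) windows
    (e.g. time-locked to NBs); None keeps it on for the whole recording.
    """

    freq_hz: float
    amp_uv: float
    intervals: tuple | None = None
    phase: float = 0.0


def render_traces(
    spikes: SpikeTrainSet,
    layout: ElectrodeLayout,
    seed: int,
    fs: float = 20000.0,
    noise_sd_uv: float = 4.0,
    template: np.ndarray | None = None,
    lfp: tuple = (),
    duration_s: float | None = None,
) -> Recording:
    """Raw traces: noise + spike templates at the planted times + LFP terms.

    The spike template (default biphasic, 2 ms) is scaled per spike by its
    |amplitude| and placed so its trough lands on the spike time. The
    output is the unfiltered signal the wavelet stage consumes; spike
    detection requires a 100-Hz high-pass first.
    """
    if fs < 10000:
        raise ValidationError("rendering needs fs >= 10 kHz")
    rng = np.random.default_rng(seed)
    if template is None:
        template = biphasic_template(fs)
    if template.size / fs > 5e-3:
        raise ValidationError("spike template longer than 5 ms")
    trough = int(np.argmin(template)) if np.any(template < 0) else 0
    if duration_s is None:
        duration_s = spikes.duration + template.size / fs
    n = int(round(duration_s * fs))
    traces = rng.normal(0.0, noise_sd_uv, size=(len(layout), n)) if noise_sd_uv > 0 \
        else np.zeros((len(layout), n))
    for ch, eid in enumerate(layout.ids):
        if int(eid) not in spikes.trains:
            continue
        t, a = spikes.trains[int(eid)]
        for ti, ai in zip(t, a):
            start = int(round(ti * fs)) - trough
            lo = max(start, 0)
            hi = min(start + template.size, n)
            if hi <= lo:
                continue
            traces[ch, lo:hi] += abs(ai) * template[lo - start : hi - start]
    if lfp:
        tgrid = np.arange(n) / fs
        for comp in lfp:
            wave = comp.amp_uv * np.sin(2 * np.pi * comp.freq_hz * tgrid + comp.phase)
            if comp.intervals is not None:
                gate = np.zeros(n, dtype=bool)
                for t0, t1 in comp.intervals:
                    gate[int(round(t0 * fs)) : int(round(t1 * fs))] = True
                wave = wave * gate
            traces += wave[None, :]
    return Recording(traces, fs, layout, meta={"noise_sd_uv": noise_sd_uv, "seed": seed})


def _project_polyline(p: np.ndarray, verts: np.ndarray) -> tuple[float, float]:
    """(distance to polyline, arc length at the closest point), both µm."""
    best_d, best_s = np.inf, 0.0
    arc = 0.0
    for a, b in zip(verts[:-1], verts[1:]):
        ab = b - a
        seg = float(np.hypot(*ab))
        u = 0.0 if seg == 0 else float(np.clip(np.dot(p - a, ab) / seg ** 2, 0.0, 1.0))
        q = a + u * ab
        d = float(np.hypot(*(p - q)))
        if d < best_d:
            best_d, best_s = d, arc + u * seg
        arc += seg
    return best_d, best_s


def gen_axon_dataset(
    layout: ElectrodeLayout,
    polyline_um: np.ndarray,
    velocity_m_s: float,
    seed: int,
    decay_um: float = 10.0,
    amp0_uv: float = 120.0,
    amp_floor_uv: float = 5.0,
    n_triggers: int = 100,
    period_s: float = 0.1,
    noise_sd_uv: float = 0.0,
    fs: float = 20000.0,
) -> tuple[Recording, GroundTruth]:
    """High-density dataset: a soma at the polyline start with a conducting axon.

    Each electrode carries the biphasic template scaled by
    ``amp0 * exp(-d / decay_um)`` (d = distance to the axon polyline) and
    delayed by arc-length / velocity; electrodes whose amplitude falls
    below ``amp_floor_uv`` carry noise only. Templates are rendered with
    fractional-sample delays so planted latencies are not quantized to the
    sampling grid.
    """
    if velocity_m_s <= 0:
        raise ValidationError("conduction velocity must be positive")
    verts = np.asarray(polyline_um, dtype=float)
    lo = layout.positions.min(axis=0) - 1e-6
    hi = layout.positions.max(axis=0) + 1e-6
    if np.any(verts < lo) or np.any(verts > hi):
        raise ValidationError("axon polyline must lie inside the electrode grid")
    rng = np.random.default_rng(seed)
    v_um_s = velocity_m_s * 1e6
    lat, amp = {}, {}
    for eid in layout.ids:
        d, s = _project_polyline(layout.position_of(int(eid)), verts)
        a = amp0_uv * np.exp(-d / decay_um)
        if a >= amp_floor_uv:
            lat[int(eid)] = s / v_um_s
            amp[int(eid)] = a
    soma = min(lat, key=lambda e: (lat[e], e))
    triggers = 0.05 + period_s * np.arange(n_triggers)
    duration = float(triggers[-1]) + 0.05
    n = int(round(duration * fs))
    traces = rng.normal(0.0, noise_sd_uv, size=(len(layout), n)) if noise_sd_uv > 0 \
        else np.zeros((len(layout), n))
    half = 2.5e-3  # template support padding around each event
    for ch, eid in enumerate(layout.ids):
        if int(eid) not in lat:
            continue
        for tk in triggers:
            trough_t = tk + lat[int(eid)]
            i0 = max(int(np.floor((trough_t - half) * fs)), 0)
            i1 = min(int(np.ceil((trough_t + half) * fs)) + 1, n)
            tt = np.arange(i0, i1) / fs
            traces[ch, i0:i1] += amp[int(eid)] * biphasic_wave(tt - trough_t + 0.5e-3)
    rec = Recording(traces, fs, layout, meta={"noise_sd_uv": noise_sd_uv, "seed": seed})
    path = sorted(lat, key=lambda e: (lat[e], e))
    truth = GroundTruth(
        seed=seed, velocity_um_s=v_um_s, noise_sd_uv=noise_sd_uv,
        soma_electrode=soma, path_electrode_ids=path,
        electrode_latency_s=lat, electrode_amplitude_uv=amp,
        trigger_times_s=triggers,
    )
    return rec, truth


def gen_param_samples(
    conditions: dict,
    n_per_group: int,
    seed: int,
    control: str = "DMSO",
    baseline: dict | None = None,
    effects: dict | None = None,
    cv: float = 0.12,
):
    """Dose-response samples of the 10-parameter panel.

    ``conditions`` maps condition label -> list of concentrations;
    ``effects`` maps condition -> {parameter: multiplier at the top
    concentration}, interpolated linearly from 1 across the concentration
    ladder (the control has no effect). Samples are
    ``mean * multiplier * (1 + cv * z)``, z standard normal. Returns
    (list of (sample_id, condition, concentration, metrics-dict), truth).
    """
    if n_per_group < 2:
        raise ValidationError("need n >= 2 samples per group")
    if control not in conditions:
        raise ValidationError(f"control condition '{control}' missing")
    from .netburst import METRIC_NAMES  # local import to avoid cycle at module load

    base = {
        "total_spikes": 48000.0, "n_nb": 60.0, "mean_nb_duration_s": 0.45,
        "mean_spikes_per_nb": 750.0, "mean_max_frequency": 40.0, "mean_imfi_s": 10.0,
        "cv_nb_duration": 0.25, "cv_spikes_per_nb": 0.25, "cv_max_frequency": 0.25,
        "cv_imfi": 0.25,
    }
    if baseline:
        base.update(baseline)
    effects = effects or {}
    rng = np.random.default_rng(seed)
    entries = []
    truth_mult = {}
    for cond in sorted(conditions):
        concs = list(conditions[cond])
        for i, conc in enumerate(concs):
            frac = (i + 1) / len(concs)
            mult = {p: 1.0 for p in METRIC_NAMES}
            if cond != control:
                for p, top in effects.get(cond, {}).items():
                    mult[p] = 1.0 + (top - 1.0) * frac
            truth_mult[(cond, conc)] = dict(mult)
            for s in range(n_per_group):
                vals = {p: max(base[p] * mult[p] * (1 + cv * rng.standard_normal()),
                               1e-9)
                        for p in METRIC_NAMES}
                vals["total_spikes"] = float(round(vals["total_spikes"]))
                vals["n_nb"] = float(round(vals["n_nb"]))
                entries.append((f"{cond}-{conc}-s{s}", cond, conc, vals))
    return entries, {"multipliers": truth_mult, "baseline": base, "cv": cv}
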
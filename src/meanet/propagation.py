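"""Propagation and conduction velocity estimation.

Two experimental geometries are covered:

* the 16-electrode case, where two neural spheroids sit on known electrodes
  and the per-network-burst onset delay between them, together with the
  inter-electrode distance, yields a synaptic propagation velocity (mm/s);
* the high-density CMOS case, where somata are localized from the spike
  amplitude map, a spike-triggered average (STA) over a 4 ms window
  (1.5 ms before the soma firing time, 2.5 ms after) is computed on every
  electrode, the axonal pathway is selected by waveform similarity to the
  soma STA, and the conduction velocity is the slope of an ordinary
  least-squares fit of inter-electrode distance against spike-time latency
  (m/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .io import ElectrodeLayout, Recording, SpikeTrainSet, electrode_distance
from .netburst import NetworkBurst

__all__ = [
    "OnsetDelaySeries",
    "PropagationResult",
    "SomaMap",
    "AxonPath",
    "nb_onset_delays",
    "pair_velocity",
    "relative_velocity",
    "fit_velocity",
    "network_velocity",
    "localize_somata",
    "spike_triggered_average",
    "trace_axon_path",
    "conduction_velocity",
]


@dataclass(frozen=True)
class OnsetDelaySeries:
    """Per-NB onset delays (s) between a reference and a target electrode."""

    delays_s: np.ndarray
    n_excluded: int  # NBs where either electrode was silent

    @property
    def n(self) -> int:
        return int(np.asarray(self.delays_s).size)

    @property
    def mean_s(self) -> float:
        return float(np.mean(self.delays_s))

    @property
    def sd_s(self) -> float:
        return float(np.std(self.delays_s, ddof=1)) if self.n > 1 else 0.0


@dataclass(frozen=True)
class PropagationResult:
    velocity_m_s: float
    r_squared: float
    n_points: int
    intercept_um: float  # distance offset of the fit (absorbs alignment offset)
    exact_fit: bool = False  # two-point fit, R^2 = 1 by construction

    def __post_init__(self):
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValidationError("R^2 must lie in [0, 1]")
        if self.n_points < 2:
            raise ValidationError("a velocity fit needs at least 2 points")


def nb_onset_delays(
    nbs: list[NetworkBurst],
    spikes: SpikeTrainSet,
    ref_electrode: int,
    target_electrode: int,
) -> OnsetDelaySeries:
    """Per NB, (first target spike) - (first reference spike) within the NB.

    NBs where either electrode is silent are excluded and counted.
    """
    if not nbs:
        raise InsufficientDataError("no network bursts given")
    for eid in (ref_electrode, target_electrode):
        if eid not in spikes.trains:
            raise KeyError(f"electrode {eid} not present in the spike set")
    delays, excluded = [], 0
    for nb in nbs:
        t_ref = _first_in(spikes.times(ref_electrode), nb)
        t_tgt = _first_in(spikes.times(target_electrode), nb)
        if t_ref is None or t_tgt is None:
            excluded += 1
        else:
            delays.append(t_tgt - t_ref)
    if not delays:
        raise InsufficientDataError("no NB has onsets on both electrodes")
    return OnsetDelaySeries(np.asarray(delays), excluded)


def _first_in(times: np.ndarray, nb: NetworkBurst):
    k = np.searchsorted(times, nb.t_start, side="left")
    if k < times.size and times[k] <= nb.t_end:
        return float(times[k])
    return None


def pair_velocity(distance_um: float, mean_delay_s: float) -> float:
    """Propagation velocity distance/delay, reported in mm/s."""
    if distance_um <= 0:
        raise ValidationError("distance must be positive")
    if mean_delay_s <= 0:
        raise DegenerateInputError("onset delay must be positive to define a velocity")
    return (distance_um / 1000.0) / mean_delay_s


def relative_velocity(v_treated: float, v_baseline: float) -> float:
    """Dimensionless velocity ratio, treated / baseline."""
    if v_baseline <= 0:
        raise DegenerateInputError("baseline velocity must be positive")
    return v_treated / v_baseline


def fit_velocity(distances_um, latencies_s) -> PropagationResult:
    """OLS of distance (µm, response) on latency (s, predictor).

    The slope converts to velocity in m/s; R^2 is that of the same fit.
    Two points are allowed but flagged ``exact_fit``.
    """
    d = np.asarray(distances_um, dtype=float)
    t = np.asarray(latencies_s, dtype=float)
    if d.shape != t.shape or d.ndim != 1:
        raise ValidationError("distances and latencies must be 1-D and equal length")
    if d.size < 2:
        raise InsufficientDataError("need at least 2 (distance, latency) points")
    if np.ptp(t) == 0:
        raise DegenerateInputError("all latencies equal; velocity fit is degenerate")
    if d.size == 2:
        slope = (d[1] - d[0]) / (t[1] - t[0])
        intercept = d[0] - slope * t[0]
        return PropagationResult(slope * 1e-6, 1.0, 2, float(intercept), exact_fit=True)
    res = stats.linregress(t, d)
    return PropagationResult(
        velocity_m_s=float(res.slope) * 1e-6,
        r_squared=float(res.rvalue ** 2),
        n_points=int(d.size),
        intercept_um=float(res.intercept),
    )


def network_velocity(
    nbs: list[NetworkBurst],
    spikes: SpikeTrainSet,
    layout: ElectrodeLayout,
    ref_electrode: int,
    average_over_nbs: bool = False,
) -> PropagationResult:
    """Network propagation velocity from first-spike-in-NB delays.

    For every NB where the reference electrode fires, each firing
    electrode contributes one point (distance to the reference, onset
    delay vs the reference); the points are fit jointly across NBs with
    :func:`fit_velocity`. NBs silent on the reference are skipped.
    With ``average_over_nbs`` each electrode instead contributes a single
    point with its delay averaged across NBs, which cancels the per-NB
    jitter of the reference onset (it becomes a common intercept shift).
    """
    if not nbs:
        raise InsufficientDataError("no network bursts given")
    dists, lats = [], []
    for nb in nbs:
        t_ref = _first_in(spikes.times(ref_electrode), nb) \
            if ref_electrode in spikes.trains else None
        if t_ref is None:
            continue
        for eid in spikes.electrode_ids:
            t_e = _first_in(spikes.times(eid), nb)
            if t_e is None:
                continue
            dists.append(electrode_distance(layout, ref_electrode, eid))
            lats.append(t_e - t_ref)
    if len(dists) < 3:
        raise InsufficientDataError("fewer than 3 usable (distance, delay) points")
    dists = np.asarray(dists)
    lats = np.asarray(lats)
    if average_over_nbs:
        uniq = np.unique(dists)
        lats = np.array([lats[dists == d].mean() for d in uniq])
        dists = uniq
        if dists.size < 3:
            raise InsufficientDataError("fewer than 3 electrodes with usable delays")
    return fit_velocity(dists, lats)


@dataclass(frozen=True)
class SomaMap:
    """Putative cell-body electrodes: (electrode_id, peak amplitude µV)."""

    electrode_ids: tuple
    amplitudes_uv: tuple

    def __len__(self):
        return len(self.electrode_ids)


def localize_somata(
    amplitudes: dict[int, float],
    layout: ElectrodeLayout,
    min_amp_uv: float,
    min_sep_um: float,
) -> SomaMap:
    """Local amplitude maxima >= min_amp with pairwise separation >= min_sep.

    Greedy suppression: electrodes are visited by decreasing amplitude
    (ties: lower electrode id) and accepted if far enough from every
    previously accepted soma.
    """
    items = [(eid, float(a)) for eid, a in amplitudes.items() if a >= min_amp_uv]
    items.sort(key=lambda ea: (-ea[1], ea[0]))
    accepted: list[tuple[int, float]] = []
    for eid, amp in items:
        p = layout.position_of(eid)
        if all(np.hypot(*(p - layout.position_of(e2))) >= min_sep_um for e2, _ in accepted):
            accepted.append((eid, amp))
    ids = tuple(e for e, _ in accepted)
    amps = tuple(a for _, a in accepted)
    return SomaMap(ids, amps)


@dataclass
class STAResult:
    """Per-electrode spike-triggered averages over the 4-ms window."""

    waveforms: np.ndarray  # (n_channels, n_window)
    time_s: np.ndarray  # window time axis relative to trigger
    n_used: int
    n_dropped: int  # triggers clipped at the recording edges
    electrode_ids: np.ndarray


def spike_triggered_average(
    recording: Recording,
    trigger_times: np.ndarray,
    window_s: tuple[float, float] = (-1.5e-3, 2.5e-3),
) -> STAResult:
    """Mean aligned segment per electrode around the soma firing times.

    The default window is 1.5 ms before to 2.5 ms after the trigger (4 ms,
    80 samples at 20 kHz). Triggers whose window is clipped by a recording
    edge are dropped and counted.
    """
    trigger_times = np.asarray(trigger_times, dtype=float)
    fs = recording.fs
    pre = int(round(-window_s[0] * fs))
    post = int(round(window_s[1] * fs))
    n_win = pre + post
    idx = np.round(trigger_times * fs).astype(int)
    ok = (idx - pre >= 0) & (idx + post <= recording.n_samples)
    n_dropped = int(np.sum(~ok))
    idx = idx[ok]
    if idx.size == 0:
        raise InsufficientDataError("no trigger lies fully inside the recording")
    acc = np.zeros((recording.n_channels, n_win))
    for i in idx:
        acc += recording.traces[:, i - pre : i + post]
    acc /= idx.size
    t = (np.arange(n_win) - pre) / fs
    return STAResult(acc, t, int(idx.size), n_dropped, recording.layout.ids)


@dataclass
class AxonPath:
    """Ordered electrode sequence from the soma along the axon."""

    electrode_ids: list
    cum_distance_um: np.ndarray  # non-decreasing along the order
    latency_s: np.ndarray  # STA trough latency relative to the soma trough
    waveforms: np.ndarray  # per-path-electrode STA (4 ms)
    soma_only: bool = False


def _trough_index(w: np.ndarray) -> float:
    """Trough location in samples, refined by parabolic interpolation.

    At 20 kHz a sample is 50 µs, comparable to inter-electrode conduction
    latencies; the three-point parabola around the minimum recovers the
    sub-sample trough of the smooth STA waveform.
    """
    j = int(np.argmin(w))
    if 0 < j < w.size - 1:
        denom = w[j - 1] - 2 * w[j] + w[j + 1]
        if denom > 0:
            return j + 0.5 * (w[j - 1] - w[j + 1]) / denom
    return float(j)


def _norm_xcorr_max(a: np.ndarray, b: np.ndarray) -> float:
    """Max over lags of the normalized cross-correlation of two waveforms."""
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.max(np.correlate(a, b, mode="full")) / (na * nb))


def trace_axon_path(
    stas: STAResult,
    soma_electrode: int,
    layout: ElectrodeLayout,
    rho_min: float = 0.7,
    amp_min_uv: float = 0.0,
) -> AxonPath:
    """Automated replacement for manual pathway electrode picking.

    An electrode joins the path when its STA trough amplitude reaches
    ``amp_min_uv`` and the maximal normalized cross-correlation of its STA
    with the soma STA reaches ``rho_min``. Path order is by STA trough
    latency; the cumulative distance is the polyline length through the
    ordered electrode positions.
    """
    ids = [int(i) for i in stas.electrode_ids]
    soma_idx = ids.index(int(soma_electrode))
    soma_wave = stas.waveforms[soma_idx]
    soma_trough = _trough_index(soma_wave)
    dt = float(stas.time_s[1] - stas.time_s[0])
    selected = []
    for ch, eid in enumerate(ids):
        w = stas.waveforms[ch]
        trough_amp = -float(np.min(w))
        if eid != soma_electrode:
            if trough_amp < amp_min_uv:
                continue
            if _norm_xcorr_max(w, soma_wave) < rho_min:
                continue
        lat = (_trough_index(w) - soma_trough) * dt
        selected.append((eid, lat, w))
    if len(selected) == 1:
        eid, lat, w = selected[0]
        return AxonPath([eid], np.zeros(1), np.zeros(1), w[None, :], soma_only=True)
    selected.sort(key=lambda s: (s[1], s[0]))
    path_ids = [s[0] for s in selected]
    lats = np.array([s[1] for s in selected])
    waves = np.vstack([s[2] for s in selected])
    pos = np.vstack([layout.position_of(e) for e in path_ids])
    steps = np.hypot(*np.diff(pos, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return AxonPath(path_ids, cum, lats, waves)


def conduction_velocity(path: AxonPath) -> PropagationResult:
    """Velocity of an axon path: fit of cumulative distance on trough latency."""
    if len(path.electrode_ids) < 2:
        raise InsufficientDataError("axon path has fewer than 2 electrodes")
    return fit_velocity(path.cum_distance_um, path.latency_s)
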
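"""Action-potential and synaptic feature extraction from patch-clamp sweeps.

Implements the nine-parameter electrophysiological phenotype used to stage
neuronal maturation: six action-potential parameters (threshold, rise time,
halfwidth, amplitude, maximal firing rate, input resistance) plus sodium
current amplitude and spontaneous EPSC/IPSC frequencies.

Conventions
-----------
* AP onset is the first dV/dt upcrossing of a configurable slope criterion
  (default 10 mV/ms) before the spike peak; the onset voltage and time are
  linearly interpolated between samples.
* Per cell, AP shape parameters are taken from the first spike of the
  rheobase sweep (lowest suprathreshold current step), where the waveform is
  least distorted by adaptation.
* Missing values ("not detected", e.g. AP shape in an unexcitable cell) are
  NaN in memory and the literal token ``ND`` in CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import filtfilt, butter

from .sweeps import SweepSet, _check_uniform

__all__ = [
    "APFeatures", "PARAM_COLUMNS", "detect_spikes", "ap_threshold",
    "ap_shape_features", "firing_rate", "input_resistance",
    "detect_psc_events", "na_current_amplitude", "extract_features",
    "build_parameter_table", "write_parameter_table", "read_parameter_table",
    "lowpass_filter",
]

#: canonical column order of the 9-parameter table
PARAM_COLUMNS = [
    "threshold", "rise_time", "halfwidth", "amplitude", "firing_rate",
    "rin", "na_current", "freq_epsc", "freq_ipsc",
]

ND = float("nan")


@dataclass
class APFeatures:
    """Single-cell action-potential parameters; NaN marks ND entries."""

    threshold: float = ND      # mV
    rise_time: float = ND      # ms
    halfwidth: float = ND      # ms
    amplitude: float = ND      # mV
    firing_rate: float = ND    # Hz
    rin: float = ND            # MΩ


def lowpass_filter(voltage: np.ndarray, sampling_rate: float,
                   cutoff_hz: float = 2000.0) -> np.ndarray:
    """Zero-phase 4-pole Butterworth low-pass, mirroring a 2 kHz
    acquisition filter. Optional; off by default for synthetic sweeps."""
    nyq = sampling_rate / 2.0
    if cutoff_hz >= nyq:
        return voltage
    b, a = butter(4, cutoff_hz / nyq)
    return filtfilt(b, a, voltage, axis=-1)


def _forward_dvdt(time: np.ndarray, voltage: np.ndarray) -> np.ndarray:
    """Forward-difference dV/dt in mV/ms, aligned to the left sample."""
    dt_ms = (time[1] - time[0]) * 1e3
    dv = np.empty_like(voltage)
    dv[:-1] = np.diff(voltage) / dt_ms
    dv[-1] = dv[-2]
    return dv


def detect_spikes(time: np.ndarray, voltage: np.ndarray,
                  dvdt_thresh: float = 10.0, min_height: float = 20.0,
                  search_ms: float = 5.0, refractory_ms: float = 2.0,
                  ) -> np.ndarray:
    """Detect spike peaks in a single sweep.

    A candidate is a dV/dt upcrossing of ``dvdt_thresh`` (mV/ms) followed,
    within ``search_ms``, by a local voltage maximum at least ``min_height``
    mV above the crossing point.  Peaks closer than ``refractory_ms`` are
    merged (largest kept).

    Returns the sorted array of peak sample indices; empty if none.
    """
    if dvdt_thresh <= 0:
        raise ValueError("dvdt_thresh must be > 0")
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    dt = _check_uniform(time)
    dvdt = _forward_dvdt(time, voltage)
    up = np.flatnonzero((dvdt[1:] >= dvdt_thresh) & (dvdt[:-1] < dvdt_thresh)) + 1
    if dvdt[0] >= dvdt_thresh:
        up = np.concatenate([[0], up])
    win = max(2, int(round(search_ms * 1e-3 / dt)))
    peaks: list[int] = []
    for i in up:
        seg = voltage[i:i + win]
        j = i + int(np.argmax(seg))
        # reject window-edge maxima (truncated or still-rising traces)
        if j >= voltage.size - 1 or j == i + win - 1:
            continue
        if voltage[j] - voltage[i] < min_height:
            continue
        if not (voltage[j] >= voltage[j - 1] and voltage[j] >= voltage[j + 1]):
            continue
        peaks.append(j)
    if not peaks:
        return np.asarray([], dtype=int)
    # merge peaks within the refractory distance, keeping the larger
    refr = max(1, int(round(refractory_ms * 1e-3 / dt)))
    merged: list[int] = []
    for j in sorted(set(peaks)):
        if merged and j - merged[-1] < refr:
            if voltage[j] > voltage[merged[-1]]:
                merged[-1] = j
        else:
            merged.append(j)
    return np.asarray(merged, dtype=int)


def _onset(time: np.ndarray, voltage: np.ndarray, spike_index: int,
           dvdt_thresh: float) -> tuple[float, float]:
    """Interpolated (time_s, voltage_mV) of the last dV/dt upcrossing of
    ``dvdt_thresh`` before the spike peak; (nan, nan) if none exists."""
    dvdt = _forward_dvdt(time, voltage)
    seg = dvdt[:spike_index]
    if seg.size == 0 or seg.max() < dvdt_thresh:
        return ND, ND
    # anchor at the maximal-slope point of the upstroke, then walk backward
    # to the last sample still below the slope criterion: the crossing just
    # after it is the AP onset
    j_max = int(np.argmax(seg))
    below = np.flatnonzero(seg[:j_max] < dvdt_thresh)
    if below.size == 0:
        j = int(np.flatnonzero(seg >= dvdt_thresh)[0])
        return float(time[j]), float(voltage[j])
    j = int(below[-1]) + 1
    d0, d1 = dvdt[j - 1], dvdt[j]
    f = 0.0 if d1 == d0 else (dvdt_thresh - d0) / (d1 - d0)
    t = time[j - 1] + f * (time[j] - time[j - 1])
    v = voltage[j - 1] + f * (voltage[j] - voltage[j - 1])
    return float(t), float(v)


def ap_threshold(time: np.ndarray, voltage: np.ndarray, spike_index: int,
                 dvdt_thresh: float = 10.0) -> float:
    """AP threshold: membrane potential at AP onset (mV), the last dV/dt
    upcrossing of ``dvdt_thresh`` before the peak; NaN (ND) if no onset."""
    _check_uniform(np.asarray(time, dtype=float))
    _, v = _onset(np.asarray(time, float), np.asarray(voltage, float),
                  int(spike_index), dvdt_thresh)
    return v


def _cross_time(time, voltage, level, i0, i1, rising: bool) -> float:
    """First linear-interpolated crossing of ``level`` in [i0, i1)."""
    v = voltage[i0:i1 + 1]
    if rising:
        hit = np.flatnonzero((v[:-1] < level) & (v[1:] >= level))
    else:
        hit = np.flatnonzero((v[:-1] >= level) & (v[1:] < level))
    if hit.size == 0:
        return ND
    j = i0 + int(hit[0])
    f = (level - voltage[j]) / (voltage[j + 1] - voltage[j])
    return float(time[j] + f * (time[j + 1] - time[j]))


def ap_shape_features(time: np.ndarray, voltage: np.ndarray,
                      spike_index: int, threshold: float,
                      ) -> tuple[float, float, float]:
    """Rise time (ms), amplitude (mV) and halfwidth (ms) of one spike.

    amplitude = V_peak - threshold; rise time = t_peak - t_onset where the
    onset is the (interpolated) upward crossing of the threshold voltage;
    halfwidth = time between the up- and down-crossings of
    threshold + amplitude/2, linearly interpolated.  Halfwidth is ND when
    the trace ends before the half-amplitude downcrossing.
    """
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    spike_index = int(spike_index)
    v_peak = float(voltage[spike_index])
    if not threshold < v_peak:
        raise ValueError("threshold must lie below the spike peak voltage")
    amplitude = v_peak - threshold
    t_on = _cross_time(time, voltage, threshold, 0, spike_index, rising=True)
    rise_ms = (time[spike_index] - t_on) * 1e3 if np.isfinite(t_on) else ND
    half = threshold + amplitude / 2.0
    t_up = _cross_time(time, voltage, half, 0, spike_index, rising=True)
    t_dn = _cross_time(time, voltage, half, spike_index,
                       voltage.size - 1, rising=False)
    hw_ms = (t_dn - t_up) * 1e3 if np.isfinite(t_up) and np.isfinite(t_dn) else ND
    return rise_ms, amplitude, hw_ms


def _spikes_in_window(ss: SweepSet, sweep: int, dvdt_thresh: float) -> np.ndarray:
    peaks = detect_spikes(ss.time, ss.voltage[sweep], dvdt_thresh)
    if peaks.size == 0:
        return peaks
    t = ss.time[peaks]
    lo, hi = ss.stim_window
    return peaks[(t >= lo) & (t <= hi)]


def firing_rate(ss: SweepSet, dvdt_thresh: float = 10.0) -> float:
    """Maximal firing frequency (Hz): max over sweeps of spike count within
    the stimulus window divided by the pulse duration.  0 Hz if the cell
    never spikes; ND if additionally the cell is flagged unexcitable."""
    if ss.n_sweeps == 0:
        raise ValueError("empty sweep set")
    best = max(_spikes_in_window(ss, i, dvdt_thresh).size
               for i in range(ss.n_sweeps))
    if best == 0 and ss.unexcitable:
        return ND
    return best / ss.stim_duration


def input_resistance(ss: SweepSet, window: tuple[float, float] = (0.05, 0.20),
                     baseline_s: float = 0.05) -> float:
    """Input resistance (MΩ) from the first current level.

    The voltage deflection is averaged over ``window`` (seconds after pulse
    onset) relative to the pre-pulse baseline, and divided by the magnitude
    of the first injected current.  mV / pA = GΩ, returned in MΩ.
    """
    if ss.n_sweeps == 0:
        raise ValueError("empty sweep set")
    i0 = float(ss.stim_amplitudes[0])
    if i0 == 0:
        raise ValueError("undefined Rin: first stimulus amplitude is 0 pA")
    lo, _ = ss.stim_window
    t = ss.time
    v = ss.voltage[0]
    base = v[(t >= lo - baseline_s) & (t < lo)]
    if base.size == 0:
        raise ValueError("no baseline window before the stimulus")
    resp = v[(t >= lo + window[0]) & (t <= lo + window[1])]
    deflection = float(resp.mean() - base.mean())
    return abs(deflection) / abs(i0) * 1e3


def detect_psc_events(time: np.ndarray, current: np.ndarray,
                      amp_thresh: float = 10.0, min_interval_ms: float = 10.0,
                      smooth_ms: float = 1.0, decay_split_ms: float = 10.0,
                      ) -> tuple[np.ndarray, float, list[str]]:
    """Detect spontaneous postsynaptic currents in a voltage-clamp trace.

    Baseline (median) is subtracted, the trace lightly smoothed, and
    deflections exceeding ``amp_thresh`` (pA) and separated by at least
    ``min_interval_ms`` are counted.  Events are classed ``epsc`` (fast
    decay, < ``decay_split_ms`` to 1/e) or ``ipsc`` (slow decay) — a
    documented stand-in for pharmacological identification.

    Returns (event peak times in s, frequency in Hz, class labels).
    """
    if amp_thresh <= 0:
        raise ValueError("amp_thresh must be > 0")
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    dt = _check_uniform(time)
    duration = time[-1] - time[0] + dt
    if duration < 1.0:
        warnings.warn("voltage-clamp trace shorter than 1 s; "
                      "frequency estimate will be noisy")
    k = max(1, int(round(smooth_ms * 1e-3 / dt)))
    dev = uniform_filter1d(current, k) - np.median(current)
    mag = np.abs(dev)
    above = mag >= amp_thresh
    if not above.any():
        return np.asarray([]), 0.0, []
    # contiguous supra-threshold regions -> peak index each
    padded = np.concatenate([[0], above.astype(np.int8), [0]])
    bounds = np.flatnonzero(np.diff(padded))
    peaks = []
    for s, e in zip(bounds[::2], bounds[1::2]):
        peaks.append(s + int(np.argmax(mag[s:e])))
    # enforce minimum inter-event interval, keeping the larger event
    min_gap = max(1, int(round(min_interval_ms * 1e-3 / dt)))
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < min_gap:
            if mag[p] > mag[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    # decay-envelope guard: a candidate riding the predicted decay tail of
    # an earlier, larger event is a retrigger, not a new event.  The
    # envelope decays slower than any expected PSC and carries a noise
    # margin of half the detection threshold.
    tau_guard = 0.030 / dt  # samples
    guarded: list[int] = []
    for p in kept:
        env = max((mag[q] * np.exp(-(p - q) / tau_guard) for q in guarded),
                  default=0.0)
        if mag[p] > env + 0.5 * amp_thresh:
            guarded.append(p)
    kept = guarded
    classes: list[str] = []
    for p in kept:
        target = mag[p] / np.e
        tail = mag[p:p + int(round(0.1 / dt))]
        below = np.flatnonzero(tail <= target)
        tau_ms = (below[0] * dt * 1e3) if below.size else np.inf
        classes.append("epsc" if tau_ms < decay_split_ms else "ipsc")
    times = time[np.asarray(kept, dtype=int)]
    return times, len(kept) / duration, classes


def na_current_amplitude(time: np.ndarray | None,
                         current: np.ndarray | None,
                         baseline_ms: float = 60.0,
                         noise_k: float = 5.0) -> float:
    """Peak inward sodium-current magnitude (pA) from a ramp response.

    A rolling-median detrend locates the largest inward (negative)
    deflection; the local baseline is then re-estimated by a straight-line
    fit to the flanking samples with the transient excluded, which avoids
    the median's bias when the dip occupies part of its window.  ND when no
    trace is given or no inward peak exceeds ``noise_k`` robust standard
    deviations of the residual noise.
    """
    if time is None or current is None:
        return ND
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    dt = _check_uniform(time)
    smooth = uniform_filter1d(current, max(1, int(round(0.5e-3 / dt)) | 1))
    w = max(3, int(round(baseline_ms * 1e-3 / dt)) | 1)
    resid = smooth - median_filter(current, size=w, mode="nearest")
    # the rolling median is biased within half a window of the trace edges
    med = np.median(resid[w // 2:-(w // 2)])
    resid[:w // 2] = med
    resid[-(w // 2):] = med
    mad = np.median(np.abs(resid - med))
    noise = 1.4826 * mad
    peak = float(resid.min() - med)
    if peak >= 0 or abs(peak) < noise_k * max(noise, 1e-12):
        return ND
    # refine: fit the local baseline excluding the transient itself
    c = int(np.argmin(resid))
    excl = int(round(6e-3 / dt))
    flank = int(round(25e-3 / dt))
    idx = np.arange(time.size)
    near = np.abs(idx - c) <= flank
    fit_sel = near & (np.abs(idx - c) > excl)
    dip_sel = np.abs(idx - c) <= excl
    if fit_sel.sum() >= 10:
        coef = np.polyfit(time[fit_sel], smooth[fit_sel], 1)
        base = np.polyval(coef, time[dip_sel])
        return float(np.max(base - smooth[dip_sel]))
    return abs(peak)


def extract_features(ss: SweepSet, dvdt_thresh: float = 10.0,
                     psc_amp_thresh: float = 10.0,
                     lowpass_hz: float | None = None) -> dict[str, float]:
    """Extract the full 9-parameter phenotype for one cell.

    AP shape parameters come from the first spike of the rheobase sweep.
    Returns a dict keyed by :data:`PARAM_COLUMNS`; NaN marks ND.
    """
    if lowpass_hz:
        ss = SweepSet(ss.cell_id, ss.time,
                      lowpass_filter(ss.voltage, ss.sampling_rate, lowpass_hz),
                      ss.sampling_rate, ss.stim_amplitudes, ss.stim_window,
                      vc_trace=ss.vc_trace, ramp_trace=ss.ramp_trace,
                      unexcitable=ss.unexcitable)
    feats = dict.fromkeys(PARAM_COLUMNS, ND)
    # rheobase sweep: lowest injected current with >=1 spike in the window
    order = np.argsort(ss.stim_amplitudes, kind="stable")
    rheo = None
    for i in order:
        pk = _spikes_in_window(ss, int(i), dvdt_thresh)
        if pk.size:
            rheo = (int(i), int(pk[0]))
            break
    if rheo is not None:
        sweep_i, spike_i = rheo
        v = ss.voltage[sweep_i]
        thr = ap_threshold(ss.time, v, spike_i, dvdt_thresh)
        feats["threshold"] = thr
        if np.isfinite(thr):
            rise, amp, hw = ap_shape_features(ss.time, v, spike_i, thr)
            feats["rise_time"], feats["amplitude"], feats["halfwidth"] = rise, amp, hw
    feats["firing_rate"] = firing_rate(ss, dvdt_thresh)
    feats["rin"] = input_resistance(ss)
    if ss.vc_trace is not None:
        t_vc, i_vc = ss.vc_trace
        times, freq, classes = detect_psc_events(t_vc, i_vc, psc_amp_thresh)
        dur = t_vc[-1] - t_vc[0] + (t_vc[1] - t_vc[0])
        n_e = sum(c == "epsc" for c in classes)
        feats["freq_epsc"] = n_e / dur
        feats["freq_ipsc"] = (len(classes) - n_e) / dur
    if ss.ramp_trace is not None:
        feats["na_current"] = na_current_amplitude(*ss.ramp_trace)
    return feats


def build_parameter_table(cells: list[tuple[str, dict[str, float]]] |
                          dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble per-cell feature dicts into the cells x 9 parameter table.

    NaN entries are ND.  Raises on duplicate cell ids.
    """
    if isinstance(cells, dict):
        items = list(cells.items())
    else:
        items = list(cells)
    ids = [cid for cid, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({c for c in ids if ids.count(c) > 1})
        raise ValueError(f"duplicate cell_id(s): {dupes}")
    df = pd.DataFrame([{**{"cell_id": cid}, **f} for cid, f in items])
    df = df.set_index("cell_id").reindex(columns=PARAM_COLUMNS).astype(float)
    for col in ("firing_rate", "freq_epsc", "freq_ipsc"):
        bad = df[col].dropna() < 0
        if bad.any():
            raise ValueError(f"negative frequencies in column {col}")
    return df


def nd_mask(table: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask of ND entries."""
    return table.isna()


def write_parameter_table(path, table: pd.DataFrame) -> None:
    """CSV with a literal ``ND`` token for missing entries."""
    table.to_csv(path, na_rep="ND")


def read_parameter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, na_values=["ND"], keep_default_na=False)
    return df.astype(float)
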
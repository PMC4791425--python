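"""Current-clamp sweep containers and on-disk formats.

A :class:`SweepSet` bundles one cell's current-clamp sweeps (a family of
500 ms current steps by default), the stimulus protocol metadata, and the
optional voltage-clamp recordings used for spontaneous-PSC and sodium-current
measurements.  Sweeps are stored as a dense (n_sweeps, n_samples) voltage
array in mV on a shared uniform time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["SweepSet", "read_sweeps_h5", "write_sweeps_h5", "read_sweeps_csv",
           "write_sweeps_csv"]


def _check_uniform(time: np.ndarray) -> float:
    """Return the sample interval, raising if the time base is not uniform."""
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or time.size < 2:
        raise ValueError("time base must be a 1-D array with >=2 samples")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("non-uniform time base")
    return float(dt[0])


@dataclass
class SweepSet:
    """One cell's current-clamp sweep family plus protocol metadata.

    Parameters
    ----------
    cell_id : str
        Unique cell identifier.
    time : ndarray, shape (n_samples,)
        Shared time base in seconds, uniformly sampled.
    voltage : ndarray, shape (n_sweeps, n_samples)
        Membrane voltage in mV, one row per sweep.
    sampling_rate : float
        Samples per second (Hz); must agree with ``time``.
    stim_amplitudes : ndarray, shape (n_sweeps,)
        Injected current per sweep in pA.
    stim_window : (float, float)
        Start and end of the current pulse in seconds; 0.5 s duration by
        default protocol.
    vc_trace : (time_s, current_pA) or None
        Voltage-clamp recording for spontaneous PSC analysis.
    ramp_trace : (time_s, current_pA) or None
        Voltage-clamp ramp response for sodium-current measurement.
    unexcitable : bool
        Flag a cell known to be unexcitable; firing-rate extraction then
        reports ND instead of 0 Hz.
    """

    cell_id: str
    time: np.ndarray
    voltage: np.ndarray
    sampling_rate: float
    stim_amplitudes: np.ndarray
    stim_window: tuple[float, float]
    vc_trace: tuple[np.ndarray, np.ndarray] | None = None
    ramp_trace: tuple[np.ndarray, np.ndarray] | None = None
    unexcitable: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.atleast_2d(np.asarray(self.voltage, dtype=float))
        self.stim_amplitudes = np.asarray(self.stim_amplitudes, dtype=float)
        dt = _check_uniform(self.time)
        if not np.isclose(1.0 / dt, self.sampling_rate, rtol=1e-4):
            raise ValueError(
                f"sampling_rate {self.sampling_rate} disagrees with time base "
                f"(dt={dt:g} s)")
        if self.voltage.shape[1] != self.time.size:
            raise ValueError("all sweeps must share the time base length")
        if self.stim_amplitudes.size != self.voltage.shape[0]:
            raise ValueError("one stimulus amplitude required per sweep")
        lo, hi = self.stim_window
        if not (self.time[0] <= lo < hi <= self.time[-1] + dt):
            raise ValueError("stim_window outside trace extent")

    @property
    def n_sweeps(self) -> int:
        return self.voltage.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def stim_duration(self) -> float:
        return self.stim_window[1] - self.stim_window[0]


def write_sweeps_h5(path, sweep_sets: list[SweepSet]) -> None:
    """Write sweep sets to HDF5 under ``/cells/<id>/``.

    The sweep matrix is stored time x sweeps; per-group attributes carry
    sampling_rate, stim_amplitudes and stim_window.  Creation timestamps
    are disabled so identical inputs produce identical files.
    """
    with h5py.File(path, "w", track_order=True) as f:
        cells = f.create_group("cells", track_order=True)
        for ss in sweep_sets:
            g = cells.create_group(ss.cell_id, track_order=True)
            ds = g.create_dataset("sweeps", data=ss.voltage.T,
                                  track_times=False)
            ds.attrs["units"] = "mV"
            g.create_dataset("time", data=ss.time, track_times=False)
            g.attrs["sampling_rate"] = ss.sampling_rate
            g.attrs["stim_amplitudes"] = ss.stim_amplitudes
            g.attrs["stim_window"] = np.asarray(ss.stim_window)
            g.attrs["unexcitable"] = bool(ss.unexcitable)
            if ss.vc_trace is not None:
                g.create_dataset("vc_trace",
                                 data=np.vstack(ss.vc_trace),
                                 track_times=False)
            if ss.ramp_trace is not None:
                g.create_dataset("ramp_trace",
                                 data=np.vstack(ss.ramp_trace),
                                 track_times=False)


def read_sweeps_h5(path) -> list[SweepSet]:
    """Read all cells from an HDF5 sweep file written by write_sweeps_h5."""
    out: list[SweepSet] = []
    with h5py.File(path, "r") as f:
        for cid, g in f["cells"].items():
            vc = g.get("vc_trace")
            ramp = g.get("ramp_trace")
            out.append(SweepSet(
                cell_id=str(cid),
                time=g["time"][()],
                voltage=g["sweeps"][()].T,
                sampling_rate=float(g.attrs["sampling_rate"]),
                stim_amplitudes=np.asarray(g.attrs["stim_amplitudes"]),
                stim_window=tuple(np.asarray(g.attrs["stim_window"])),
                vc_trace=(vc[0], vc[1]) if vc is not None else None,
                ramp_trace=(ramp[0], ramp[1]) if ramp is not None else None,
                unexcitable=bool(g.attrs.get("unexcitable", False)),
            ))
    return out


def write_sweeps_csv(path, ss: SweepSet) -> None:
    """One cell per CSV: first column time (s), remaining columns sweeps (mV).

    Column headers carry the stimulus amplitude in pA; protocol metadata
    travels in '#'-prefixed header comments.
    """
    cols = {"time": ss.time}
    for j, amp in enumerate(ss.stim_amplitudes):
        cols[f"sweep_{j}@{amp:g}pA"] = ss.voltage[j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# cell_id={ss.cell_id}\n")
        fh.write(f"# sampling_rate={ss.sampling_rate:g}\n")
        fh.write(f"# stim_window={ss.stim_window[0]:g},{ss.stim_window[1]:g}\n")
        df.to_csv(fh, index=False)


def read_sweeps_csv(path) -> SweepSet:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    time = df.iloc[:, 0].to_numpy(float)
    voltage = df.iloc[:, 1:].to_numpy(float).T
    amps = [float(c.split("@")[1].removesuffix("pA")) for c in df.columns[1:]]
    lo, hi = (float(x) for x in meta["stim_window"].split(","))
    return SweepSet(
        cell_id=meta.get("cell_id", "cell"),
        time=time,
        voltage=voltage,
        sampling_rate=float(meta["sampling_rate"]),
        stim_amplitudes=np.asarray(amps),
        stim_window=(lo, hi),
    )
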
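"""Synthetic Patch-seq study generator with known ground truth.

Emulates the study conditions end to end: 20 neurons spanning an
immature -> mature electrophysiological continuum (current-clamp sweep
families with stamped, analytically parameterized action potentials; a
voltage-clamp trace with spontaneous PSC events; a sodium-current ramp
response), plus a genes x samples FPKM matrix containing a neuron-specific
gene program and maturation-graded programs, against a contrast group of
blood-like samples.

The cell model is a passive RC membrane with stereotyped AP waveforms
stamped at deterministic spike times: feature extractors only need realistic
waveform geometry with analytically known ground truth, so no conductance
model is simulated.  Maturity m in [0, 1] linearly interpolates the planted
parameters:

    Rin 800 -> 150 MΩ, AP amplitude 40 -> 90 mV, halfwidth 4 -> 1 ms,
    threshold -30 -> -45 mV, max steady firing 2 -> 40 Hz,
    Na current 200 -> 2000 pA, total sPSC rate 0.1 -> 2 Hz.

Expression programs (log2 scale):

    value = baseline + neuron_effect * 1{neuron, gene in neuron-specific}
                     + effect_size * m       (mature program, neurons only)
                     + effect_size * (1 - m) (immature program, neurons only)
                     + Normal(0, noise_sd)

Contrast samples lack all neuron programs.  The mature program rises with
maturation and is expected in the magenta (r < -0.4 vs Dim1) cluster; the
immature program falls with maturation and is expected in the green cluster.
A small fraction of genes sits below 0.1 FPKM everywhere to exercise the
detected-expression filter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .sweeps import SweepSet, write_sweeps_h5
from .enrichment import GeneSetCollection, write_gmt

__all__ = ["SyntheticConfig", "simulate_sweeps", "simulate_expression",
           "generate_dataset"]

EL_MV = -65.0          # resting potential
CM_PF = 25.0           # membrane capacitance -> tau = Rin * Cm
DVDT_ONSET = 10.0      # mV/ms slope criterion the waveforms are built around
STIM_START_S = 0.15
STIM_DUR_S = 0.5       # 500 ms current pulses
STIM_STEP_PA = 2.0     # 2 pA increments
STIM_MIN_PA = -10.0
STIM_MAX_PA = 70.0
V_NOISE_MV = 0.05
VC_NOISE_PA = 4.0
VC_DURATION_S = 10.0
VC_RATE_HZ = 5000.0
RAMP_DURATION_S = 0.2
RAMP_NOISE_PA = 10.0


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic bundle.

    module_sizes is (neuron_specific, mature_program, immature_program);
    the mature program (rises with maturation) is the larger of the two
    maturation programs, mirroring the magenta > green asymmetry.
    """

    n_neurons: int = 20
    n_contrast: int = 21
    n_genes: int = 2000
    maturity: np.ndarray | None = None   # default: linspace(0, 1, n_neurons)
    module_sizes: tuple[int, int, int] = (300, 120, 60)
    effect_size: float = 2.0
    noise_sd: float = 0.25
    neuron_effect: float = 4.0
    low_expr_fraction: float = 0.05
    n_external: int = 1479
    n_external_overlap: int = 39
    sampling_rate: float = 20000.0
    seed: int = 15

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if self.maturity is None:
            self.maturity = np.linspace(0.0, 1.0, self.n_neurons)
        self.maturity = np.asarray(self.maturity, dtype=float)
        if self.maturity.min() < 0 or self.maturity.max() > 1:
            raise ValueError("maturity values must lie in [0, 1]")
        if self.maturity.size != self.n_neurons:
            raise ValueError("one maturity value per neuron required")
        total = sum(self.module_sizes)
        if total + int(self.low_expr_fraction * self.n_genes) > self.n_genes:
            raise ValueError("module sizes exceed the gene count")


def _planted_params(m: float, rng: np.random.Generator) -> dict[str, float]:
    """Maturity-interpolated cell parameters with mild per-cell jitter.

    The AP rise is much faster than the fall (real spikes are asymmetric),
    so rise time shrinks from 2 ms to 0.5 ms while halfwidth spans
    4 -> 1 ms.
    """
    jit = lambda sd: float(1.0 + sd * rng.standard_normal())
    p = {
        "rin": (800.0 - 650.0 * m) * jit(0.05),
        "threshold": -30.0 - 15.0 * m + float(rng.standard_normal()),
        "amplitude": (40.0 + 50.0 * m) * jit(0.03),
        "halfwidth": (4.0 - 3.0 * m) * jit(0.05),
        "rise_time": (2.0 - 1.5 * m) * jit(0.05),
        "max_rate": (2.0 + 38.0 * m) * jit(0.05),
        "rheobase": (40.0 - 30.0 * m) * jit(0.05),
        "na_current": (200.0 + 1800.0 * m) * jit(0.04),
        "rate_epsc": 0.6 * (0.1 + 1.9 * m) * jit(0.05),
        "rate_ipsc": 0.4 * (0.1 + 1.9 * m) * jit(0.05),
    }
    return p


class _APWaveform:
    """Analytic action-potential waveform with exact feature ground truth.

    Phases (times in ms from the blend start at voltage ``v_start``):

    * upstroke, 0 <= u <= T: v = v_start + s0*u + c*(1 - cos(pi*u/T))/2
      with s0 = 8 mV/ms and c = A - s0*T, so the slope rises monotonically
      from s0 (below the 10 mV/ms onset criterion) to its maximum and the
      criterion is crossed exactly once, steeply, at a closed-form voltage
      — the planted threshold;
    * downstroke, 0 <= w <= tf: half-cosine from the peak back to the
      threshold voltage, so the half-amplitude downcrossing sits at tf/2;
    * tail: exponential relaxation to the local baseline (tau 4 ms).

    ``v_start`` is chosen so the criterion crossing lands on the requested
    threshold voltage; the constructor solves the half-amplitude upcrossing
    numerically, making threshold / amplitude / rise time / halfwidth all
    analytically known.
    """

    S0 = 8.0  # blend base slope, mV/ms (below the 10 mV/ms criterion)

    def __init__(self, v_thr: float, amp_nominal: float, rise_ms: float,
                 halfwidth_ms: float, dvdt_onset: float = DVDT_ONSET):
        from scipy.optimize import brentq
        self.T = rise_ms
        self.c = amp_nominal - self.S0 * self.T
        if self.c <= 0:
            raise ValueError("AP amplitude too small for the rise time")
        # slope(u) = s0 + c*pi/(2T) * sin(pi*u/T); criterion crossing:
        arg = (dvdt_onset - self.S0) * 2.0 * self.T / (np.pi * self.c)
        if arg >= 1.0:
            raise ValueError("upstroke never reaches the onset criterion")
        self.u10 = self.T / np.pi * np.arcsin(arg)
        self.delta = self.S0 * self.u10 + self.c * (
            1.0 - np.cos(np.pi * self.u10 / self.T)) / 2.0
        self.v_start = v_thr - self.delta
        self.threshold = v_thr
        self.peak = self.v_start + amp_nominal
        self.amplitude = self.peak - self.threshold  # = amp_nominal - delta
        self.rise_time = self.T - self.u10
        # half-amplitude upcrossing (numeric; the blend is monotone)
        half_rel = self.delta + self.amplitude / 2.0
        f = lambda u: (self.S0 * u
                       + self.c * (1.0 - np.cos(np.pi * u / self.T)) / 2.0
                       - half_rel)
        t_up = brentq(f, self.u10, self.T, xtol=1e-12)
        pre_peak_half = self.T - t_up
        self.tf = 2.0 * (halfwidth_ms - pre_peak_half)
        if self.tf <= 0:
            raise ValueError("halfwidth too small for the rise shape")
        self.halfwidth = pre_peak_half + self.tf / 2.0

    def render(self, u_ms: np.ndarray, v_base: float,
               tau_ahp_ms: float = 4.0) -> np.ndarray:
        """Waveform voltage at times u_ms (ms) after the blend start,
        preceded by a quadratic depolarizing ramp from v_base."""
        t_pre = 2.0 * max(self.v_start - v_base, 0.5) / self.S0
        up = self.S0 * np.clip(u_ms, 0, self.T) + self.c * (
            1.0 - np.cos(np.pi * np.clip(u_ms, 0, self.T) / self.T)) / 2.0
        w = np.clip(u_ms - self.T, 0, self.tf)
        down = self.amplitude * (1.0 + np.cos(np.pi * w / self.tf)) / 2.0 \
            - self.amplitude
        w2 = np.clip(u_ms - self.T - self.tf, 0, None)
        tail = (self.threshold - v_base) * np.exp(-w2 / tau_ahp_ms)
        upre = np.clip(u_ms + t_pre, 0, t_pre)
        pre = v_base + self.S0 * upre ** 2 / (2.0 * t_pre)
        v = np.where(u_ms < 0, pre,
                     np.where(u_ms < self.T, self.v_start + up,
                              np.where(u_ms < self.T + self.tf,
                                       self.peak + down,
                                       v_base + tail)))
        return v

    def support_ms(self, v_base: float) -> tuple[float, float]:
        """(extent before blend start, extent after blend start) in ms."""
        t_pre = 2.0 * max(self.v_start - v_base, 0.5) / self.S0
        return t_pre, self.T + self.tf + 6.0 * 4.0


def _spike_count(i_pa: float, rheobase: float, count_max: int) -> int:
    """Planted F-I curve: 0 below rheobase, then a monotone staircase that
    saturates at count_max by the top current step."""
    if i_pa <= rheobase or count_max == 0:
        return 0
    gain = count_max / max(STIM_MAX_PA - rheobase, 1e-9)
    return int(min(count_max, np.floor(gain * (i_pa - rheobase)) + 1))


def _stamp_spike(time: np.ndarray, v: np.ndarray, t_peak: float,
                 v_base: float, wave: _APWaveform) -> None:
    """Overwrite the trace with one analytic AP waveform peaking at t_peak."""
    t_blend0 = t_peak - wave.T * 1e-3
    pre_ms, post_ms = wave.support_ms(v_base)
    sel = (time >= t_blend0 - pre_ms * 1e-3) \
        & (time <= t_blend0 + post_ms * 1e-3)
    u_ms = (time[sel] - t_blend0) * 1e3
    v[sel] = wave.render(u_ms, v_base)


def _psc_template(dt: float, tau_rise_ms: float, tau_decay_ms: float,
                  n: int) -> np.ndarray:
    w = np.arange(n) * dt * 1e3
    shape = np.exp(-w / tau_decay_ms) - np.exp(-w / tau_rise_ms)
    return shape / shape.max()


def _event_times(rng: np.random.Generator, n: int, duration: float,
                 margin: float = 0.2) -> np.ndarray:
    """n event times: an even grid with +-30% spacing jitter keeps a
    deterministic count while avoiding overlap."""
    if n == 0:
        return np.asarray([])
    spacing = (duration - 2 * margin) / n
    base = margin + (np.arange(n) + 0.5) * spacing
    return base + rng.uniform(-0.3, 0.3, n) * spacing


def simulate_sweeps(m: float, cfg: SyntheticConfig | None = None,
                    seed: int = 0, cell_id: str = "cell",
                    ) -> tuple[SweepSet, dict]:
    """Simulate one cell's full recording at maturity m in [0, 1].

    Returns the SweepSet plus a ground-truth dict of the planted parameter
    values, spike counts per sweep and PSC/sodium event plans.  Identical
    seeds yield bit-identical data.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("maturity must lie in [0, 1]")
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(seed)
    p = _planted_params(m, rng)
    wave = _APWaveform(p["threshold"], p["amplitude"], p["rise_time"],
                       p["halfwidth"])
    # the stamped waveform's exact feature values are the ground truth
    p["threshold"] = wave.threshold
    p["amplitude"] = wave.amplitude
    p["rise_time"] = wave.rise_time
    p["halfwidth"] = wave.halfwidth
    unexcitable = bool(m < 0.1 and rng.random() < 0.5)
    count_max = 0 if unexcitable else max(1, int(round(p["max_rate"]
                                                       * STIM_DUR_S)))
    fs = cfg.sampling_rate
    dt = 1.0 / fs
    time = np.arange(int(round(0.8 * fs))) * dt
    amps = np.arange(STIM_MIN_PA, STIM_MAX_PA + STIM_STEP_PA / 2,
                     STIM_STEP_PA)
    stim_lo = STIM_START_S
    stim_hi = STIM_START_S + STIM_DUR_S
    r_gohm = p["rin"] / 1e3
    tau_s = p["rin"] * 1e6 * CM_PF * 1e-12
    v_all = np.empty((amps.size, time.size))
    spike_counts = []
    in_stim = (time >= stim_lo) & (time < stim_hi)
    after = time >= stim_hi
    # recording noise is band-limited by the 2 kHz acquisition filter
    from .ephys import lowpass_filter
    noise = V_NOISE_MV * rng.standard_normal((amps.size, time.size))
    noise = lowpass_filter(noise, fs, 2000.0)
    for si, i_pa in enumerate(amps):
        v = np.full(time.size, EL_MV)
        rise = 1.0 - np.exp(-(time[in_stim] - stim_lo) / tau_s)
        v[in_stim] += i_pa * r_gohm * rise
        v_ss = i_pa * r_gohm * (1.0 - np.exp(-STIM_DUR_S / tau_s))
        v[after] += v_ss * np.exp(-(time[after] - stim_hi) / tau_s)
        count = _spike_count(i_pa, p["rheobase"], count_max)
        if count:
            # cap the depolarized plateau below threshold so every stamped
            # AP launches from a subthreshold baseline
            v = np.minimum(v, wave.v_start - 4.0)
            for j in range(count):
                t_peak = stim_lo + (j + 0.5) * STIM_DUR_S / count
                t_peak = time[int(round(t_peak / dt))]  # align to the grid
                v_base = float(v[int(round((t_peak - 0.012) / dt))])
                _stamp_spike(time, v, t_peak, v_base, wave)
        v += noise[si]
        v_all[si] = v
        spike_counts.append(count)

    # voltage-clamp trace with planted spontaneous PSC events
    dt_vc = 1.0 / VC_RATE_HZ
    t_vc = np.arange(int(VC_DURATION_S * VC_RATE_HZ)) * dt_vc
    i_vc = VC_NOISE_PA * rng.standard_normal(t_vc.size)
    n_e = int(round(p["rate_epsc"] * VC_DURATION_S))
    n_i = int(round(p["rate_ipsc"] * VC_DURATION_S))
    events = []
    all_times = _event_times(rng, n_e + n_i, VC_DURATION_S)
    klasses = np.asarray(["epsc"] * n_e + ["ipsc"] * n_i)
    rng.shuffle(klasses)
    for t0, klass in zip(all_times, klasses):
        tau_d = 5.0 if klass == "epsc" else 20.0
        amp_ev = 20.0 + rng.uniform(0.0, 20.0)
        tpl = _psc_template(dt_vc, 1.0, tau_d, int(0.15 / dt_vc))
        j0 = int(round(t0 / dt_vc))
        j1 = min(j0 + tpl.size, i_vc.size)
        i_vc[j0:j1] -= amp_ev * tpl[:j1 - j0]
        events.append({"time": float(t0), "class": klass,
                       "amplitude": float(amp_ev)})

    # sodium-current ramp: outward ramp baseline + planted inward transient
    t_ramp = np.arange(int(RAMP_DURATION_S * fs)) * dt
    ramp = 1200.0 * t_ramp / RAMP_DURATION_S
    dip_t0 = 0.08
    ramp -= p["na_current"] * np.exp(-0.5 * ((t_ramp - dip_t0) / 0.0015) ** 2)
    ramp += RAMP_NOISE_PA * rng.standard_normal(t_ramp.size)

    ss = SweepSet(cell_id=cell_id, time=time, voltage=v_all,
                  sampling_rate=fs, stim_amplitudes=amps,
                  stim_window=(stim_lo, stim_hi),
                  vc_trace=(t_vc, i_vc), ramp_trace=(t_ramp, ramp))
    truth = {
        "cell_id": cell_id, "maturity": float(m),
        "unexcitable": unexcitable,
        "params": {k: float(v) for k, v in p.items()},
        "spike_counts": spike_counts,
        "spike_count_max": int(max(spike_counts)),
        "firing_rate": max(spike_counts) / STIM_DUR_S,
        "n_epsc": n_e, "n_ipsc": n_i,
        "freq_epsc": n_e / VC_DURATION_S, "freq_ipsc": n_i / VC_DURATION_S,
        "events": events,
    }
    return ss, truth


def simulate_expression(maturities: np.ndarray,
                        cfg: SyntheticConfig | None = None,
                        seed: int = 0) -> tuple[ExpressionMatrix, dict]:
    """Simulate the genes x samples FPKM matrix with planted programs.

    Returns the matrix (neuron samples Cell_1.. plus contrast samples a1..)
    and a ground-truth dict listing each program's genes.
    """
    cfg = cfg or SyntheticConfig()
    maturities = np.asarray(maturities, dtype=float)
    if maturities.size != cfg.n_neurons:
        raise ValueError("one maturity value per neuron required")
    rng = np.random.default_rng(seed)
    n_low = int(round(cfg.low_expr_fraction * cfg.n_genes))
    ns, n_up, n_dn = cfg.module_sizes
    genes = np.asarray([f"G{i + 1:04d}" for i in range(cfg.n_genes)])
    perm = rng.permutation(cfg.n_genes)
    idx_ns = perm[:ns]
    idx_up = perm[ns:ns + n_up]
    idx_dn = perm[ns + n_up:ns + n_up + n_dn]
    idx_low = perm[ns + n_up + n_dn:ns + n_up + n_dn + n_low]
    neuron_ids = [f"Cell_{i + 1}" for i in range(cfg.n_neurons)]
    contrast_ids = [f"a{i + 1}" for i in range(cfg.n_contrast)]
    samples = neuron_ids + contrast_ids
    n_samples = len(samples)
    baseline = rng.uniform(1.0, 6.0, cfg.n_genes)
    log2 = baseline[:, None] + cfg.noise_sd * rng.standard_normal(
        (cfg.n_genes, n_samples))
    is_neuron = np.zeros(n_samples, dtype=bool)
    is_neuron[:cfg.n_neurons] = True
    m_vec = np.zeros(n_samples)
    m_vec[:cfg.n_neurons] = maturities
    log2[np.ix_(idx_ns, is_neuron)] += cfg.neuron_effect
    log2[idx_up] += cfg.effect_size * m_vec[None, :] * is_neuron[None, :]
    log2[idx_dn] += cfg.effect_size * (1.0 - m_vec[None, :]) \
        * is_neuron[None, :]
    fpkm = np.maximum(2.0 ** log2 - 1.0, 0.0)
    fpkm[idx_low] = rng.uniform(0.0, 0.09, (n_low, n_samples))
    values = pd.DataFrame(fpkm, index=genes, columns=samples)
    classes = pd.Series(["neuron"] * cfg.n_neurons
                        + ["contrast"] * cfg.n_contrast, index=samples)
    truth = {
        "neuron_specific": sorted(genes[idx_ns]),
        "mature_program": sorted(genes[idx_up]),
        "immature_program": sorted(genes[idx_dn]),
        "low_expressed": sorted(genes[idx_low]),
        "neuron_module": sorted(np.concatenate(
            [genes[idx_ns], genes[idx_up], genes[idx_dn]])),
        "null_genes": sorted(set(genes)
                             - set(genes[perm[:ns + n_up + n_dn + n_low]])),
        "maturity": {c: float(m) for c, m in zip(neuron_ids, maturities)},
    }
    return ExpressionMatrix(values, classes), truth


def _replicate_pair(log_col: np.ndarray, target_r: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two independently-noised copies of a log-scale library whose expected
    Pearson correlation is target_r (attenuation: r = var/(var + sigma^2))."""
    var = float(np.var(log_col))
    sigma = np.sqrt(var * (1.0 / target_r - 1.0))
    return (log_col + sigma * rng.standard_normal(log_col.size),
            log_col + sigma * rng.standard_normal(log_col.size))


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 100003 + 7919 * k) % (2 ** 31 - 1))


def generate_dataset(cfg: SyntheticConfig, outdir, force: bool = False,
                     ) -> dict:
    """Write the full synthetic bundle and return its ground truth.

    Files: sweeps.h5, expression.tsv, classes.csv, replicates.tsv,
    annotations.gmt, external_list.txt, ground_truth.json — the formats the
    analysis modules read.  Fully reproducible from cfg.seed.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_derive_seed(cfg.seed, 0))

    sweep_sets, cell_truths = [], []
    for i, m in enumerate(cfg.maturity):
        ss, truth = simulate_sweeps(m, cfg, seed=_derive_seed(cfg.seed, i + 1),
                                    cell_id=f"Cell_{i + 1}")
        sweep_sets.append(ss)
        cell_truths.append(truth)
    write_sweeps_h5(outdir / "sweeps.h5", sweep_sets)

    expr, expr_truth = simulate_expression(
        cfg.maturity, cfg, seed=_derive_seed(cfg.seed, 10001))
    expr.values.to_csv(outdir / "expression.tsv", sep="\t")
    pd.DataFrame({"sample": expr.samples,
                  "class": expr.sample_class.to_numpy()}
                 ).to_csv(outdir / "classes.csv", index=False, header=False)

    # technical replicate pair of one library (Cell_2), planted r ~ 0.99
    log_col = np.log2(expr.values["Cell_2"].to_numpy() + 1.0)
    rep_a, rep_b = _replicate_pair(log_col, 0.99, rng)
    pd.DataFrame({"Cell_2_repA": np.maximum(2.0 ** rep_a - 1.0, 0.0),
                  "Cell_2_repB": np.maximum(2.0 ** rep_b - 1.0, 0.0)},
                 index=expr.genes).to_csv(outdir / "replicates.tsv", sep="\t")

    # annotation collection: the planted programs plus random decoy terms
    all_genes = list(expr.genes)
    sets = {
        "NEURON_MODULE": set(expr_truth["neuron_module"]),
        "MATURE_PROGRAM": set(expr_truth["mature_program"]),
        "IMMATURE_PROGRAM": set(expr_truth["immature_program"]),
    }
    names = {
        "NEURON_MODULE": "planted neuron-specific gene program",
        "MATURE_PROGRAM": "planted maturation-up program",
        "IMMATURE_PROGRAM": "planted maturation-down program",
    }
    for t in range(20):
        size = int(rng.integers(50, 200))
        members = rng.choice(all_genes, size=size, replace=False)
        sets[f"RANDOM_{t + 1:02d}"] = set(members)
        names[f"RANDOM_{t + 1:02d}"] = "random decoy term"
    coll = GeneSetCollection(sets, names)
    write_gmt(outdir / "annotations.gmt", coll)

    # external maturity list sharing exactly n_external_overlap genes with
    # the planted candidate set (mature program; all of it lies inside the
    # planted neuron module)
    mature = list(expr_truth["mature_program"])
    overlap = sorted(rng.choice(mature, size=cfg.n_external_overlap,
                                replace=False))
    nulls = [g for g in expr_truth["null_genes"]]
    n_fill = cfg.n_external - cfg.n_external_overlap
    n_null_fill = min(len(nulls) // 2, n_fill)
    fill_null = sorted(rng.choice(nulls, size=n_null_fill, replace=False))
    fill_fake = [f"EXT{i + 1:04d}" for i in range(n_fill - n_null_fill)]
    external = overlap + fill_null + fill_fake
    (outdir / "external_list.txt").write_text("\n".join(external) + "\n")

    truth = {
        "config": {
            "n_neurons": cfg.n_neurons, "n_contrast": cfg.n_contrast,
            "n_genes": cfg.n_genes, "module_sizes": list(cfg.module_sizes),
            "effect_size": cfg.effect_size, "noise_sd": cfg.noise_sd,
            "neuron_effect": cfg.neuron_effect, "seed": cfg.seed,
        },
        "maturity": [float(m) for m in cfg.maturity],
        "cells": cell_truths,
        "expression": expr_truth,
        "external_overlap": overlap,
        "replicate_target_r": 0.99,
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True))
    return truth
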
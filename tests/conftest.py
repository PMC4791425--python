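"""Shared fixtures: the default synthetic bundle and its full pipeline run.

Both are session-scoped — the bundle is the study-condition dataset every
end-to-end check runs against, and the pipeline over it is deterministic.
"""

import warnings

import numpy as np
import pytest

from patchseq.pipeline import run_pipeline
from patchseq.simulate import SyntheticConfig, generate_dataset
from patchseq.sweeps import SweepSet


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle (seed 15) plus its ground truth."""
    out = tmp_path_factory.mktemp("data") / "bundle"
    truth = generate_dataset(SyntheticConfig(seed=15), out)
    return out, truth


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    out, _ = bundle
    with warnings.catch_warnings():
        # the block-structured synthetic network legitimately triggers the
        # soft-power argmax fallback
        warnings.simplefilter("ignore", UserWarning)
        return run_pipeline(out)


def toy_sweepset(spike_counts, stim_amps=None, rin_mohm=None,
                 fs=20000.0, baseline=-65.0):
    """Hand-built sweep family with triangular spikes at known positions.

    Each spike rises 70 mV in 1 ms from a -45 mV takeoff and falls
    symmetrically — trivially detectable geometry for contract tests.
    """
    stim_lo, stim_hi = 0.15, 0.65
    n = int(round(0.8 * fs))
    time = np.arange(n) / fs
    sweeps = []
    spike_counts = list(spike_counts)
    if stim_amps is None:
        stim_amps = [-20.0 + 10.0 * i for i in range(len(spike_counts))]
    for count, amp in zip(spike_counts, stim_amps):
        v = np.full(n, baseline)
        if rin_mohm is not None:
            sel = (time >= stim_lo) & (time < stim_hi)
            v[sel] += amp * rin_mohm / 1e3
        for k in range(count):
            t_pk = stim_lo + (k + 0.5) * (stim_hi - stim_lo) / count
            rise = np.abs(time - t_pk) <= 1e-3
            v[rise] = np.maximum(
                v[rise], 25.0 - 70.0 * np.abs(time[rise] - t_pk) / 1e-3)
        sweeps.append(v)
    return SweepSet(cell_id="toy", time=time, voltage=np.array(sweeps),
                    sampling_rate=fs, stim_amplitudes=np.array(stim_amps),
                    stim_window=(stim_lo, stim_hi))
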
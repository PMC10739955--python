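"""Shared fixtures.

The network simulations are the expensive ingredient, so one session-scoped
batch (four conditions x 10 seeds, on the 4x-compressed timeline) feeds every
test that needs full runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crhmem import network as nw
from crhmem import synthetic as sy

SHORTEN_FACTOR = 4
N_SEEDS = 10


def run_condition(tag: str, seed: int) -> pd.DataFrame:
    """One shortened-timeline run; returns per-neuron epoch means + FS weights."""
    if tag == "appetitive":
        params = nw.preset_params("nutella_table1", seed=seed)
        proto = nw.build_protocol("appetitive")
    elif tag == "gate_off":
        params = nw.preset_params("fs_table1", seed=seed,
                                  fs_weight_mean=0.0, fs_weight_sd=0.0)
        proto = nw.build_protocol("aversive")
    elif tag == "aversive":
        params = nw.preset_params("fs_table1", seed=seed)
        proto = nw.build_protocol("aversive")
    elif tag == "control":
        params = nw.preset_params("fs_table1", seed=seed)
        proto = nw.build_protocol("control")
    else:
        raise ValueError(tag)
    p, pr = nw.shorten(params, proto, SHORTEN_FACTOR)
    res = nw.simulate(p, pr)
    em = res.epoch_means()
    em["fs_weight"] = res.fs_weights
    em["omega_sum_final"] = res.omega_sum[:, -1]
    em["omega_sum_initial"] = res.omega_sum_initial
    return em


@pytest.fixture(scope="session")
def sim_batch():
    """Epoch-mean tables for aversive / control / appetitive / gate-off x 10 seeds."""
    return {tag: [run_condition(tag, seed) for seed in range(N_SEEDS)]
            for tag in ("aversive", "control", "appetitive", "gate_off")}


def make_photometry_spec(seed: int) -> sy.SyntheticPhotometrySpec:
    """Randomized 15-min session: bleaching, events, context step, motion.

    Transients and artifacts sit inside the analysis mid-window (the head and
    tail 5-min home-cage segments are reserved for bleach fitting); events are
    spaced well apart so their amplitudes can be read out individually.
    """
    rng = np.random.default_rng(seed)
    return sy.SyntheticPhotometrySpec(
        duration_s=900.0,
        bleach_coeffs_sig=(rng.uniform(5e-8, 2e-7), rng.uniform(-1e-3, -3e-4), 1.0),
        bleach_coeffs_ref=(rng.uniform(4e-8, 1.5e-7), rng.uniform(-8e-4, -2e-4), 1.0),
        event_times_s=tuple(np.array([330.0, 360.0, 390.0]) + rng.uniform(0, 20, 3)),
        event_amplitudes=tuple(rng.uniform(0.05, 0.15, 3)),
        context_step=(310.0, 580.0, 0.04),
        motion_times_s=tuple(np.array([450.0, 490.0, 530.0]) + rng.uniform(0, 20, 3)),
        motion_amplitudes=tuple(rng.uniform(0.3, 0.5, 3)),
        noise_sd=0.0015,
        seed=seed,
    )
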
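"""Spiking-network model of contextual memory in CRH neurons.

A population of N leaky integrate-and-fire (LIF) neurons with spike-frequency
adaptation stands in for the CRH neuron population.  Each neuron receives

* a *context* current: N_context Poisson spike trains (8 Hz in a novel
  environment, 1 Hz in the home cage) passed through a double-exponential
  filter (rise 2 ms, decay 20 ms) and weighted by the neuron's plastic
  context weights;
* a *foot-shock* current FS(t) = sum_k exp(-(t - t_k)^2) (t in seconds),
  scaled by a fixed per-neuron weight drawn from N(2, 1);
* a *hazelnut* current Nut(t) = exp(-(t - t_Nut)^2 / 1e4), scaled by a
  per-neuron weight drawn from U[-0.09, 0.01] (appetitive stimuli inhibit);
* a white-noise current and a constant bias.

Every spike also drives a slow double-exponential trace r_slow (rise 100 ms,
decay 1 s) — the model's calcium-like indicator, and the activity signal the
learning rules read.

Learning rules (per neuron, acting on the total context weight s = sum_j w_j;
see *Weight bookkeeping* below):

* two-factor (aversive):  da/dt = eps * (Omega - s) * r_slow * H(r_slow - r_thresh)
* one-factor (appetitive): da/dt = eps * (Omega - s) * H(Nut(t) - nut_thresh)
* both relax the weights toward the auxiliary variable: tau_omega * ds/dt = a - s,
  a delayed update standing in for slow molecular plasticity.

The first factor is a weight ceiling: neurons far below Omega are recruited
hardest, so previously *weak* cells gain the most.  The second factor is a
plasticity gate opened only by strong stimulus responses (aversive) or by the
appetitive stimulus itself.

Weight bookkeeping
------------------
The ceiling Omega applies to the per-neuron total context weight, and one
auxiliary variable a_i accompanies that total; per-channel weights are updated
in lockstep (the dense stepper divides the increment equally over the
N_context channels).  Treating the da/dt increment as per-channel
instead would multiply the loop gain on the total by N_context and turn the
aversive ceiling dynamics into a near-undamped oscillator — not a usable
model.  The appetitive rate constant, by contrast, is only effective at the
per-channel reading; its preset value here (2e-3 /s) is the per-channel rate
times N_context, so the per-total dynamics match.
Because the rules never individuate channels, :func:`simulate` uses an exact
factorization: one pooled context spike train and one scalar weight total per
neuron, integrated in a numba kernel.  The dense per-channel stepper
(:func:`step_network` and friends) is retained as the reference
implementation and is bit-compatible with the fast path when fed the same
inputs (see tests).

Voltage, adaptation and the plasticity variables are integrated with forward
Euler at dt = 1 ms; the double-exponential filters use their exact per-step
exponential decays (they are defined as sums of exponentials, not ODEs).
The white-noise current enters as noise_sd * sqrt(dt / tau_m) per Euler step,
which makes the stationary voltage variance independent of dt.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "NetworkParams",
    "StimulusProtocol",
    "NetworkState",
    "SimulationResult",
    "IntegrationError",
    "PRESETS",
    "preset_params",
    "build_protocol",
    "shorten",
    "fs_current",
    "nut_current",
    "context_filter_update",
    "step_network",
    "apply_two_factor_rule",
    "apply_one_factor_rule",
    "simulate",
    "simulate_dense",
    "epoch_means",
    "save_result_h5",
]


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass
class NetworkParams:
    """Model parameters.  Defaults are the aversive (foot-shock) preset.

    Time constants in ms unless suffixed ``_s``; currents in pA; weights
    unitless.  ``epsilon`` is in 1/s.  ``r_thresh`` may be a float or the
    string ``"adaptive:P"`` (per-neuron P-th percentile of home-cage r_slow).
    ``context_gain`` is a free scale converting ceiling-level weight totals
    into currents of order pA (the parameter set leaves the current scale
    open); ``init_weight_sum_low/high`` bound the uniform draw of each
    neuron's initial total context weight.
    """

    tau_m: float = 10.0                 # ms
    v_reset: float = -65.0              # mV
    v_threshold: float = -40.0          # mV
    i_bias: float = -41.0               # pA
    d: float = 20.0                     # pA adaptation jump per spike
    tau_w: float = 100.0                # ms
    n_neurons: int = 100
    n_context: int = 1000
    tau_d_context: float = 20.0         # ms
    tau_r_context: float = 2.0          # ms
    epsilon: float = 0.014              # 1/s (aversive); 2e-3 for appetitive
    omega_ceiling: float = 0.0031       # aversive; -1 for appetitive
    tau_d: float = 1000.0               # ms, slow indicator decay
    tau_r: float = 100.0                # ms, slow indicator rise
    tau_omega: float = 400.0            # s, weight relaxation
    noise_sd: float = 0.7               # pA
    r_thresh: float | str = 4.0
    nut_thresh: float = 0.5
    fs_weight_mean: float = 2.0
    fs_weight_sd: float = 1.0
    nut_weight_low: float = -0.09
    nut_weight_high: float = 0.01
    context_gain: float = 4000.0
    fs_input_gain: float = 5.0          # pA per unit FS weight
    nut_input_gain: float = 20.0        # pA per unit Nut weight
    init_weight_sum_low: float = 0.0
    init_weight_sum_high: float = 0.0031
    dt: float = 1.0                     # ms
    seed: int = 0

    def validate(self) -> None:
        for name in ("tau_m", "tau_w", "tau_d_context", "tau_r_context",
                     "tau_d", "tau_r", "tau_omega", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v_reset >= self.v_threshold:
            raise ValueError("v_reset must lie below v_threshold")
        if self.n_neurons < 1 or self.n_context < 1:
            raise ValueError("n_neurons and n_context must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if isinstance(self.r_thresh, str):
            if not self.r_thresh.startswith("adaptive:"):
                raise ValueError("string r_thresh must look like 'adaptive:90'")
            float(self.r_thresh.split(":", 1)[1])

    @property
    def dt_s(self) -> float:
        return self.dt / 1000.0


@dataclass
class StimulusProtocol:
    """Experiment timeline driving the simulation.

    The default aversive timeline: 2190 s total; novel-context exposures on
    [500, 1290] s and [1790, 2190] s (home cage otherwise); ten 30-s-spaced
    foot shocks on [900, 1200] s; context Poisson rate 8 Hz (novel) / 1 Hz
    (home).  Appetitive runs replace the shocks with a hazelnut presentation
    centered at 930 s.
    """

    total_duration_s: float = 2190.0
    novel_context_intervals_s: tuple = ((500.0, 1290.0), (1790.0, 2190.0))
    context_rate_novel_hz: float = 8.0
    context_rate_home_hz: float = 1.0
    fs_times_s: tuple = ()
    nut_time_s: float | None = None
    nut_width_s2: float = 1.0e4
    mode: str = "control"

    def validate(self) -> None:
        if self.mode not in ("aversive", "appetitive", "control"):
            raise ValueError(f"unknown mode {self.mode!r}")
        ivs = sorted(self.novel_context_intervals_s)
        for a, b in ivs:
            if not (0 <= a < b <= self.total_duration_s):
                raise ValueError(f"interval ({a}, {b}) outside [0, {self.total_duration_s}]")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError("novel-context intervals overlap")
        for t in self.fs_times_s:
            if not any(a <= t <= b for a, b in ivs):
                raise ValueError(f"foot shock at {t} s outside any novel-context interval")
        if self.mode == "aversive" and self.nut_time_s is not None:
            raise ValueError("aversive protocol cannot carry a nut time")
        if self.mode == "appetitive" and self.fs_times_s:
            raise ValueError("appetitive protocol cannot carry foot shocks")
        if min(self.context_rate_novel_hz, self.context_rate_home_hz) < 0:
            raise ValueError("context rates must be >= 0")

    def context_rate_hz(self, t: float) -> float:
        for a, b in self.novel_context_intervals_s:
            if a <= t < b:
                return self.context_rate_novel_hz
        return self.context_rate_home_hz

    def epoch_windows(self) -> dict:
        """Named analysis windows: home, pre, fs/nut, post.

        Pre is the first novel-context interval up to stimulus onset,
        truncated to the length of the second exposure so that Pre and Post
        means average comparable durations; Post is the second exposure.
        """
        ivs = sorted(self.novel_context_intervals_s)
        (a1, b1), (a2, b2) = ivs[0], ivs[-1]
        post_len = b2 - a2
        pre_end = min(a1 + post_len, b1)
        windows = {"home": (0.0, a1)}
        if self.fs_times_s:
            fs0 = min(self.fs_times_s)
            gaps = np.diff(sorted(self.fs_times_s))
            spacing = float(gaps[0]) if gaps.size else 30.0
            pre_end = min(pre_end, fs0)
            windows["fs"] = (fs0, min(max(self.fs_times_s) + spacing, b1))
        windows["pre"] = (a1, pre_end)
        windows["post"] = (a2, b2)
        return windows


PRESETS = ("fs_table1", "nutella_table1", "control")


def preset_params(name: str, **overrides) -> NetworkParams:
    """Named parameter presets.

    ``fs_table1``/``control``: the aversive parameter column (eps 0.014/s,
    Omega 0.0031); ``nutella_table1``: the appetitive column (eps 2e-6/s,
    Omega -1) with commensurately larger initial weight totals and a smaller
    context gain, so that Pre currents match across modes.
    """
    if name in ("fs_table1", "control"):
        p = NetworkParams()
    elif name == "nutella_table1":
        p = NetworkParams(epsilon=2e-3, omega_ceiling=-1.0, context_gain=10.0,
                          init_weight_sum_low=0.0, init_weight_sum_high=1.5)
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    p = replace(p, **overrides)
    p.validate()
    return p


def build_protocol(mode: str = "aversive", **overrides) -> StimulusProtocol:
    """Construct the stimulus timeline for a mode.

    Aversive: ten foot shocks at 900, 930, ..., 1170 s (the first shock at
    the opening of the [900, 1200] s window, 30 s apart).  Appetitive: a
    hazelnut presentation at 930 s, no shocks.  Control: neither.
    """
    proto = StimulusProtocol(mode=mode)
    if mode == "aversive":
        proto = replace(proto, fs_times_s=tuple(900.0 + 30.0 * k for k in range(10)))
    elif mode == "appetitive":
        proto = replace(proto, nut_time_s=930.0)
    elif mode != "control":
        raise ValueError(f"unknown mode {mode!r}")
    proto = replace(proto, **overrides)
    proto.validate()
    return proto


def shorten(params: NetworkParams, protocol: StimulusProtocol, factor: float):
    """Compress the timeline by ``factor`` while preserving plasticity totals.

    All protocol times divide by ``factor``; the learning rate multiplies and
    tau_omega divides by it, and the hazelnut width scales by factor^2, so the
    integrated weight change over the (shorter) stimulus block is unchanged.
    Membrane, synaptic and indicator time constants are physiology and stay.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    f = float(factor)
    p = replace(params, epsilon=params.epsilon * f, tau_omega=params.tau_omega / f)
    proto = replace(
        protocol,
        total_duration_s=protocol.total_duration_s / f,
        novel_context_intervals_s=tuple((a / f, b / f)
                                        for a, b in protocol.novel_context_intervals_s),
        fs_times_s=tuple(t / f for t in protocol.fs_times_s),
        nut_time_s=None if protocol.nut_time_s is None else protocol.nut_time_s / f,
        nut_width_s2=protocol.nut_width_s2 / f ** 2,
    )
    proto.validate()
    return p, proto


def fs_current(t, fs_times) -> np.ndarray | float:
    """FS(t) = sum_k exp(-(t - t_k)^2), t in seconds (Gaussian width 1 s)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for tk in fs_times:
        out = out + np.exp(-((t - tk) ** 2))
    return out if out.ndim else float(out)


def nut_current(t, nut_time: float | None, width_s2: float = 1.0e4):
    """Nut(t) = exp(-(t - t_Nut)^2 / width), width 1e4 s^2 by default."""
    t = np.asarray(t, dtype=float)
    if nut_time is None:
        out = np.zeros_like(t)
    else:
        out = np.exp(-((t - nut_time) ** 2) / width_s2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# dense reference implementation (per-channel weights; for small problems)

@dataclass
class NetworkState:
    """Full network state for the dense stepper."""

    v: np.ndarray               # mV, per neuron
    w_adapt: np.ndarray         # pA, per neuron
    omega: np.ndarray           # n_neurons x n_context context weights
    a: np.ndarray               # auxiliary plasticity variable, same shape
    ctx_fd: np.ndarray          # context filter decay state, per channel
    ctx_fr: np.ndarray          # context filter rise state
    slow_fd: np.ndarray         # r_slow decay state, per neuron
    slow_fr: np.ndarray
    time_s: float = 0.0

    @classmethod
    def initial(cls, params: NetworkParams, omega0: np.ndarray) -> "NetworkState":
        n, m = omega0.shape
        return cls(np.full(n, params.v_reset), np.zeros(n),
                   omega0.astype(float).copy(), omega0.astype(float).copy(),
                   np.zeros(m), np.zeros(m), np.zeros(n), np.zeros(n))

    @property
    def r_context(self) -> np.ndarray:
        return self.ctx_fd - self.ctx_fr

    @property
    def r_slow(self) -> np.ndarray:
        return self.slow_fd - self.slow_fr

    @property
    def omega_sum(self) -> np.ndarray:
        return self.omega.sum(axis=1)


def context_filter_update(state: NetworkState, params: NetworkParams,
                          counts: np.ndarray) -> np.ndarray:
    """Advance the per-channel context filter one step; returns r_context.

    ``counts`` holds the context spikes landing in this step.  The filter is
    the exact double exponential exp(-t/tau_d) - exp(-t/tau_r) applied to the
    spike train.
    """
    state.ctx_fd = state.ctx_fd * np.exp(-params.dt / params.tau_d_context) + counts
    state.ctx_fr = state.ctx_fr * np.exp(-params.dt / params.tau_r_context) + counts
    return state.r_context


def step_network(state: NetworkState, params: NetworkParams,
                 ctx_counts: np.ndarray, fs_t: float, nut_t: float,
                 fs_weights: np.ndarray, nut_weights: np.ndarray,
                 noise: np.ndarray | None = None) -> np.ndarray:
    """One forward-Euler step of the membrane equations.  Returns spike mask.

    Order: advance the context filter, form currents, Euler-update V and the
    adaptation variable, detect/reset spikes (V is clamped to v_reset, the
    adaptation variable jumps by d), then advance r_slow with the new spikes.
    The plasticity rules run afterwards via :func:`apply_two_factor_rule` or
    :func:`apply_one_factor_rule`.
    """
    dt, dt_s = params.dt, params.dt_s
    r_ctx = context_filter_update(state, params, ctx_counts)
    i_syn = (params.context_gain * (state.omega @ r_ctx)
             + params.fs_input_gain * fs_weights * fs_t
             + params.nut_input_gain * nut_weights * nut_t)
    if noise is None and params.noise_sd > 0:
        raise ValueError("pass an explicit noise vector (or zeros) when noise_sd > 0")
    gamma = np.zeros_like(state.v) if noise is None else noise
    state.v = state.v + (dt / params.tau_m) * (-state.v + params.i_bias
                                               + i_syn - state.w_adapt) \
        + params.noise_sd * np.sqrt(dt / params.tau_m) * gamma
    state.w_adapt = state.w_adapt - (dt / params.tau_w) * state.w_adapt
    spiked = state.v >= params.v_threshold
    state.v = np.where(spiked, params.v_reset, state.v)
    state.w_adapt = state.w_adapt + params.d * spiked
    state.slow_fd = state.slow_fd * np.exp(-dt / params.tau_d) + spiked
    state.slow_fr = state.slow_fr * np.exp(-dt / params.tau_r) + spiked
    state.time_s += dt_s
    if not (np.isfinite(state.v).all() and np.isfinite(state.w_adapt).all()):
        bad = int(np.nonzero(~np.isfinite(state.v))[0][0])
        raise IntegrationError(f"non-finite state for neuron {bad} at t = {state.time_s:.3f} s")
    return spiked


def apply_two_factor_rule(state: NetworkState, params: NetworkParams,
                          r_thresh: np.ndarray | float) -> None:
    """Aversive weight update (one Euler step, per-neuron totals).

    da/dt = eps * (Omega - sum_j w_ij) * r_slow * H(r_slow - r_thresh), the
    increment distributed equally over the channels; then
    tau_omega * dw/dt = a - w.  The Heaviside gate is strict (H(0) = 0).
    """
    dt_s = params.dt_s
    rs = state.r_slow
    gate = rs > np.asarray(r_thresh)
    da = params.epsilon * (params.omega_ceiling - state.omega_sum) * rs * gate
    state.a = state.a + (dt_s * da / state.omega.shape[1])[:, None]
    state.omega = state.omega + (dt_s / params.tau_omega) * (state.a - state.omega)


def apply_one_factor_rule(state: NetworkState, params: NetworkParams,
                          nut_t: float) -> None:
    """Appetitive weight update: da/dt = eps * (Omega - sum_j w_ij) * H(Nut - thresh)."""
    dt_s = params.dt_s
    if nut_t > params.nut_thresh:
        da = params.epsilon * (params.omega_ceiling - state.omega_sum)
        state.a = state.a + (dt_s * da / state.omega.shape[1])[:, None]
    state.omega = state.omega + (dt_s / params.tau_omega) * (state.a - state.omega)


# ---------------------------------------------------------------------------
# fast factorized path

@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _run_segment(step0, step1, counts, fs_arr, nut_arr,
                 dt_s, tau_m_s, v_reset, v_th, i_bias, d_jump, tau_w_s,
                 ad_ctx, ar_ctx, ad_slow, ar_slow, noise_sd,
                 gain_over_m, w_fs, w_nut,
                 eps, omega_ceil, r_thresh, nut_thresh, tau_omega_s,
                 rule_mode, plast_on,
                 V, w, fd, fr, ctx_state, s, a,
                 record_every, r_slow_rec, s_rec,
                 spk_neuron, spk_step, spk_count):
    n = V.size
    noise_scale = noise_sd * np.sqrt(dt_s / tau_m_s)
    for step in range(step0, step1):
        ctx_state[0] = ctx_state[0] * ad_ctx + counts[step]
        ctx_state[1] = ctx_state[1] * ar_ctx + counts[step]
        R = ctx_state[0] - ctx_state[1]
        fs_t = fs_arr[step]
        nut_t = nut_arr[step]
        nut_open = 1.0 if nut_t > nut_thresh else 0.0
        for i in range(n):
            I = i_bias + gain_over_m * s[i] * R + w_fs[i] * fs_t + w_nut[i] * nut_t
            V[i] += (dt_s / tau_m_s) * (-V[i] + I - w[i])
            if noise_scale > 0.0:
                V[i] += noise_scale * np.random.normal()
            w[i] -= (dt_s / tau_w_s) * w[i]
            spiked = 0.0
            if V[i] >= v_th:
                V[i] = v_reset
                w[i] += d_jump
                spiked = 1.0
                if spk_count < spk_neuron.size:
                    spk_neuron[spk_count] = i
                    spk_step[spk_count] = step
                spk_count += 1
            fd[i] = fd[i] * ad_slow + spiked
            fr[i] = fr[i] * ar_slow + spiked
            rs = fd[i] - fr[i]
            if plast_on:
                if rule_mode == 1:
                    if rs > r_thresh[i]:
                        a[i] += dt_s * eps * (omega_ceil - s[i]) * rs
                elif rule_mode == 2:
                    if nut_open > 0.0:
                        a[i] += dt_s * eps * (omega_ceil - s[i])
                s[i] += (dt_s / tau_omega_s) * (a[i] - s[i])
            if not np.isfinite(V[i]):
                return spk_count, i, step
        if (step + 1) % record_every == 0:
            rec = (step + 1) // record_every - 1
            for i in range(n):
                r_slow_rec[i, rec] = fd[i] - fr[i]
                s_rec[i, rec] = s[i]
    return spk_count, -1, -1


@dataclass
class SimulationResult:
    """Outputs of a full run.

    ``r_slow`` (the simulated calcium-like indicator) and ``omega_sum`` are
    n_neurons x n_samples matrices sampled every ``record_dt_s`` seconds;
    ``spike_times`` holds one strictly increasing array of spike times (s)
    per neuron.  ``fs_weights``/``nut_weights`` are the drawn per-neuron
    stimulus weights; ``r_thresh_used`` the resolved plasticity thresholds.
    """

    spike_times: list
    r_slow: np.ndarray
    omega_sum: np.ndarray
    record_dt_s: float
    fs_weights: np.ndarray
    nut_weights: np.ndarray
    omega_sum_initial: np.ndarray
    r_thresh_used: np.ndarray
    params: NetworkParams
    protocol: StimulusProtocol

    @property
    def sample_times_s(self) -> np.ndarray:
        return (np.arange(self.r_slow.shape[1]) + 1) * self.record_dt_s

    def epoch_means(self, windows: dict | None = None) -> pd.DataFrame:
        return epoch_means(self, windows)


def epoch_means(result: SimulationResult, windows: dict | None = None) -> pd.DataFrame:
    """Per-neuron mean r_slow in each named window (columns = window names)."""
    if windows is None:
        windows = result.protocol.epoch_windows()
    t = result.sample_times_s
    cols = {}
    for name, (t0, t1) in windows.items():
        m = (t >= t0) & (t < t1)
        if not m.any():
            raise ValueError(f"window {name!r} = ({t0}, {t1}) contains no samples")
        cols[name] = result.r_slow[:, m].mean(axis=1)
    return pd.DataFrame(cols)


def _resolve_r_thresh(params, protocol, result_home_rslow):
    if isinstance(params.r_thresh, str):
        pct = float(params.r_thresh.split(":", 1)[1])
        return np.percentile(result_home_rslow, pct, axis=1)
    return np.full(params.n_neurons, float(params.r_thresh))


def simulate(params: NetworkParams, protocol: StimulusProtocol,
             record_dt_s: float = 0.1,
             max_wall_s: float | None = None,
             _inputs: tuple | None = None) -> SimulationResult:
    """Run the full timeline with the factorized fast path.

    Plasticity is enabled from the first novel-context onset; when
    ``r_thresh`` is adaptive, the per-neuron threshold is the stated
    percentile of each neuron's home-cage r_slow samples collected before
    that onset.  ``max_wall_s`` optionally rejects runs whose projected cost
    exceeds a wall-clock budget.
    """
    params.validate()
    protocol.validate()
    dt_s = params.dt_s
    n_steps = int(round(protocol.total_duration_s / dt_s))
    if max_wall_s is not None:
        projected = n_steps * params.n_neurons * 2e-8
        if projected > max_wall_s:
            raise ValueError(
                f"projected run time ~{projected:.0f} s exceeds the "
                f"{max_wall_s:.0f} s budget; shorten the protocol or raise the budget")
    rng = np.random.default_rng(params.seed)
    t_steps = (np.arange(n_steps) + 1) * dt_s
    if _inputs is not None:     # deterministic injection for reference comparisons
        w_fs, w_nut, s0, counts = (np.asarray(x, dtype=float) for x in _inputs)
    else:
        w_fs = rng.normal(params.fs_weight_mean, params.fs_weight_sd, params.n_neurons)
        w_nut = rng.uniform(params.nut_weight_low, params.nut_weight_high,
                            params.n_neurons)
        s0 = rng.uniform(params.init_weight_sum_low, params.init_weight_sum_high,
                         params.n_neurons)
        rate = np.full(n_steps, protocol.context_rate_home_hz)
        for a_iv, b_iv in protocol.novel_context_intervals_s:
            rate[(t_steps >= a_iv) & (t_steps < b_iv)] = protocol.context_rate_novel_hz
        counts = rng.poisson(rate * params.n_context * dt_s).astype(np.float64)
    fs_arr = fs_current(t_steps, protocol.fs_times_s) if protocol.fs_times_s \
        else np.zeros(n_steps)
    nut_arr = nut_current(t_steps, protocol.nut_time_s, protocol.nut_width_s2)

    record_every = max(int(round(record_dt_s / dt_s)), 1)
    n_rec = n_steps // record_every
    n = params.n_neurons
    V = np.full(n, params.v_reset)
    w = np.zeros(n)
    fd = np.zeros(n)
    fr = np.zeros(n)
    ctx_state = np.zeros(2)
    s = s0.copy()
    a = s0.copy()            # a(0) = w(0): weights are stationary until the gate opens
    r_slow_rec = np.zeros((n, n_rec))
    s_rec = np.zeros((n, n_rec))
    spike_cap = int(n * protocol.total_duration_s * 150) + 1000
    spk_neuron = np.zeros(spike_cap, dtype=np.int64)
    spk_step = np.zeros(spike_cap, dtype=np.int64)

    rule_mode = {"aversive": 1, "control": 1, "appetitive": 2}[protocol.mode]
    if protocol.novel_context_intervals_s:
        plast_start_s = min(a_iv for a_iv, _ in protocol.novel_context_intervals_s)
    else:           # no context exposure: plasticity never engages
        plast_start_s = protocol.total_duration_s
    plast_step = int(round(plast_start_s / dt_s))
    common = dict(
        dt_s=dt_s, tau_m_s=params.tau_m / 1000.0, v_reset=params.v_reset,
        v_th=params.v_threshold, i_bias=params.i_bias, d_jump=params.d,
        tau_w_s=params.tau_w / 1000.0,
        ad_ctx=np.exp(-params.dt / params.tau_d_context),
        ar_ctx=np.exp(-params.dt / params.tau_r_context),
        ad_slow=np.exp(-params.dt / params.tau_d),
        ar_slow=np.exp(-params.dt / params.tau_r),
        noise_sd=params.noise_sd,
        gain_over_m=params.context_gain / params.n_context,
        w_fs=params.fs_input_gain * w_fs,
        w_nut=params.nut_input_gain * w_nut, eps=params.epsilon,
        omega_ceil=params.omega_ceiling, nut_thresh=params.nut_thresh,
        tau_omega_s=params.tau_omega, rule_mode=rule_mode,
        V=V, w=w, fd=fd, fr=fr, ctx_state=ctx_state, s=s, a=a,
        record_every=record_every, r_slow_rec=r_slow_rec, s_rec=s_rec,
        spk_neuron=spk_neuron, spk_step=spk_step,
    )
    _seed_kernel(int(rng.integers(0, 2 ** 31 - 1)))
    dummy_thresh = np.zeros(n)
    spk_count, bad_i, bad_step = _run_segment(
        0, plast_step, counts, fs_arr, nut_arr, r_thresh=dummy_thresh,
        plast_on=False, spk_count=0, **common)
    if bad_i >= 0:
        raise IntegrationError(
            f"non-finite state for neuron {bad_i} at t = {(bad_step + 1) * dt_s:.3f} s")
    home_rec = plast_step // record_every
    r_thresh = _resolve_r_thresh(params, protocol, r_slow_rec[:, :max(home_rec, 1)])
    spk_count, bad_i, bad_step = _run_segment(
        plast_step, n_steps, counts, fs_arr, nut_arr, r_thresh=r_thresh,
        plast_on=True, spk_count=spk_count, **common)
    if bad_i >= 0:
        raise IntegrationError(
            f"non-finite state for neuron {bad_i} at t = {(bad_step + 1) * dt_s:.3f} s")
    if spk_count > spike_cap:
        raise IntegrationError(
            f"{spk_count} spikes exceed the {spike_cap} buffer; runaway firing")
    spike_times = [np.sort(spk_step[:spk_count][spk_neuron[:spk_count] == i] + 1)
                   * dt_s for i in range(n)]
    return SimulationResult(spike_times, r_slow_rec, s_rec, record_every * dt_s,
                            w_fs, w_nut, s0, r_thresh, params, protocol)


def simulate_dense(params: NetworkParams, protocol: StimulusProtocol,
                   ctx_counts: np.ndarray, omega0: np.ndarray,
                   fs_weights: np.ndarray, nut_weights: np.ndarray,
                   r_thresh: np.ndarray | float = None,
                   record_dt_s: float = 0.1) -> SimulationResult:
    """Dense per-channel reference run on explicit inputs (tests, small n).

    ``ctx_counts`` is an (n_steps, n_context) array of context spike counts;
    noise is off (the reference path is for deterministic comparisons).
    Plasticity is enabled from the first novel-context onset, as in
    :func:`simulate`.
    """
    params.validate()
    protocol.validate()
    if params.noise_sd != 0:
        raise ValueError("the dense reference path runs without noise; set noise_sd=0")
    dt_s = params.dt_s
    n_steps = ctx_counts.shape[0]
    n = params.n_neurons
    state = NetworkState.initial(params, omega0)
    if r_thresh is None:
        r_thresh = float(params.r_thresh)
    thresh = np.broadcast_to(np.asarray(r_thresh, dtype=float), (n,))
    t_steps = (np.arange(n_steps) + 1) * dt_s
    fs_arr = fs_current(t_steps, protocol.fs_times_s) if protocol.fs_times_s \
        else np.zeros(n_steps)
    nut_arr = nut_current(t_steps, protocol.nut_time_s, protocol.nut_width_s2)
    plast_start_s = min(a_iv for a_iv, _ in protocol.novel_context_intervals_s)
    record_every = max(int(round(record_dt_s / dt_s)), 1)
    n_rec = n_steps // record_every
    r_slow_rec = np.zeros((n, n_rec))
    s_rec = np.zeros((n, n_rec))
    spikes = [[] for _ in range(n)]
    rule_mode = {"aversive": 1, "control": 1, "appetitive": 2}[protocol.mode]
    for step in range(n_steps):
        spiked = step_network(state, params, ctx_counts[step], fs_arr[step],
                              nut_arr[step], fs_weights, nut_weights)
        for i in np.nonzero(spiked)[0]:
            spikes[i].append(t_steps[step])
        if t_steps[step] > plast_start_s:
            if rule_mode == 1:
                apply_two_factor_rule(state, params, thresh)
            else:
                apply_one_factor_rule(state, params, nut_arr[step])
        if (step + 1) % record_every == 0:
            rec = (step + 1) // record_every - 1
            r_slow_rec[:, rec] = state.r_slow
            s_rec[:, rec] = state.omega_sum
    return SimulationResult([np.asarray(sp) for sp in spikes], r_slow_rec, s_rec,
                            record_every * dt_s, fs_weights, nut_weights,
                            omega0.sum(axis=1), np.asarray(thresh, dtype=float),
                            params, protocol)


def save_result_h5(result: SimulationResult, path) -> None:
    """SimulationResult to HDF5: /spikes/<i>, /r_slow, /omega_sum, /meta."""
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        for i, sp in enumerate(result.spike_times):
            g.create_dataset(str(i), data=sp)
        f.create_dataset("r_slow", data=result.r_slow)
        f.create_dataset("omega_sum", data=result.omega_sum)
        f.create_dataset("fs_weights", data=result.fs_weights)
        f.create_dataset("nut_weights", data=result.nut_weights)
        meta = f.create_group("meta")
        meta.attrs["record_dt_s"] = result.record_dt_s
        meta.attrs["mode"] = result.protocol.mode
        for k, v in vars(result.params).items():
            meta.attrs[f"param_{k}"] = v if not isinstance(v, str) else str(v)
        meta.attrs["total_duration_s"] = result.protocol.total_duration_s
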
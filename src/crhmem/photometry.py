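"""Fiber-photometry preprocessing.

Bulk calcium signals recorded through an optical fiber come in two excitation
channels: a calcium-dependent channel (465/470 nm GCaMP excitation) and a
calcium-independent isosbestic channel (405 nm) that tracks motion artifacts
and bleaching but not activity.  The preprocessing chain implemented here:

1. :func:`trim_session` — drop the first/last 5 min (handling, LED settling).
2. :func:`detrend_polynomial` — fit a second-order curve to each channel
   (by default using only the head/tail home-cage windows) and subtract it to
   remove slow photobleaching.
3. :func:`fit_reference` — least-squares affine fit of the 405 channel to the
   signal channel, so common-mode artifacts have matched amplitude.
4. :func:`delta_f` — pointwise subtraction of the fitted reference (dF).
5. :func:`dff` — the alternative normalized path:
   dF/F = (F465 - F_fit405) / F_fit405 with a second-order polynomial map of
   the 405 channel onto the 465 channel.
6. :func:`zscore` — z = (F - F0) / sigma_F, where F0 is the session's own
   home-cage baseline mean and sigma_F may come from the same session or from
   day 1 of a multi-day series (to keep cross-day scaling comparable).

Both dF variants lead to the same downstream conclusions on synthetic data;
they are exposed side by side and tagged on the output trace.

All operations are deterministic given their inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhotometrySession",
    "ProcessedTrace",
    "UnderdeterminedFitError",
    "trim_session",
    "detrend_polynomial",
    "fit_reference",
    "delta_f",
    "dff",
    "zscore",
    "epoch_mean",
    "process_session",
    "read_session_h5",
    "write_session_h5",
    "read_session_csv",
    "write_session_csv",
]


class UnderdeterminedFitError(ValueError):
    """Raised when a fit window contains too few samples for the model."""


@dataclass
class PhotometrySession:
    """Two-channel fluorescence recording.

    Attributes
    ----------
    signal : np.ndarray
        Calcium-dependent channel (465/470 nm), arbitrary units.
    reference : np.ndarray
        Calcium-independent isosbestic channel (405 nm).
    rate_hz : float
        Sampling rate.
    epoch_annotations : dict[str, tuple[float, float]]
        Named windows in seconds relative to the start of the session
        (e.g. ``{"home_cage": (0, 300), "context": (400, 700)}``).
    """

    signal: np.ndarray
    reference: np.ndarray
    rate_hz: float
    epoch_annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.signal.shape != self.reference.shape or self.signal.ndim != 1:
            raise ValueError("signal and reference must be equal-length 1-D arrays")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        dur = self.duration_s
        for name, (a, b) in self.epoch_annotations.items():
            if not (0 <= a <= b <= dur + 1e-9):
                raise ValueError(f"annotation {name!r} = ({a}, {b}) outside recording [0, {dur}]")

    @property
    def n_samples(self) -> int:
        return self.signal.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz


@dataclass
class ProcessedTrace:
    """A processed single-channel trace with provenance.

    ``method`` is one of ``"deltaF"``, ``"dFF"``, ``"zscore"``;
    ``baseline_stats`` records (F0, sigma_F, sd source) for z-scored traces.
    """

    time_s: np.ndarray
    values: np.ndarray
    rate_hz: float
    method: str
    baseline_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in ("deltaF", "dFF", "zscore"):
            raise ValueError(f"unknown method tag {self.method!r}")
        if len(self.time_s) != len(self.values):
            raise ValueError("time and values must be equal length")


def _window_slice(session_rate: float, n: int, window_s) -> slice:
    a, b = window_s
    i0 = int(round(a * session_rate))
    i1 = int(round(b * session_rate))
    return slice(max(i0, 0), min(i1, n))


def trim_session(session: PhotometrySession, head_s: float = 300.0,
                 tail_s: float = 300.0) -> PhotometrySession:
    """Drop the first ``head_s`` and last ``tail_s`` seconds of a recording.

    The first and last 5 minutes of each session are home-cage segments
    recorded for bleaching correction; they are excluded from analysis.
    Epoch annotations are re-indexed to the trimmed time base; annotations
    falling entirely outside the retained window are dropped.
    """
    n = session.n_samples
    n_head = int(round(head_s * session.rate_hz))
    n_tail = int(round(tail_s * session.rate_hz))
    if n - n_head - n_tail <= 0:
        raise ValueError(
            f"recording of {session.duration_s:.1f} s too short to trim "
            f"{head_s:.0f}+{tail_s:.0f} s")
    sl = slice(n_head, n - n_tail)
    kept_dur = (n - n_head - n_tail) / session.rate_hz
    ann = {}
    for name, (a, b) in session.epoch_annotations.items():
        a2, b2 = a - head_s, b - head_s
        if b2 <= 0 or a2 >= kept_dur:
            continue
        ann[name] = (max(a2, 0.0), min(b2, kept_dur))
    return PhotometrySession(session.signal[sl], session.reference[sl],
                             session.rate_hz, ann)


def detrend_polynomial(channel: np.ndarray, rate_hz: float,
                       fit_windows=None, degree: int = 2):
    """Subtract a least-squares polynomial bleaching trend.

    The polynomial is fitted using only the samples inside ``fit_windows``
    (list of (start_s, end_s)); by default the first and last 5 minutes, the
    home-cage segments least contaminated by evoked activity.  Recordings
    shorter than 10 min fall back to a full-trace fit with a logged warning.

    Returns ``(detrended, coefficients)`` with coefficients in descending
    power order (a, b, c) for a*t^2 + b*t + c.
    """
    channel = np.asarray(channel, dtype=float)
    n = channel.size
    t = np.arange(n) / rate_hz
    if fit_windows is None:
        if n / rate_hz < 600.0:
            logger.warning("recording shorter than 10 min; fitting bleach trend on full trace")
            fit_windows = [(0.0, n / rate_hz)]
        else:
            fit_windows = [(0.0, 300.0), (n / rate_hz - 300.0, n / rate_hz)]
    mask = np.zeros(n, dtype=bool)
    for w in fit_windows:
        mask[_window_slice(rate_hz, n, w)] = True
    if mask.sum() < degree + 1:
        raise UnderdeterminedFitError(
            f"{int(mask.sum())} samples in fit windows; need >= {degree + 1}")
    coeffs = np.polyfit(t[mask], channel[mask], degree)
    trend = np.polyval(coeffs, t)
    return channel - trend, coeffs


def fit_reference(reference: np.ndarray, signal: np.ndarray):
    """Affine least-squares fit of the reference channel onto the signal.

    Returns ``(fitted, alpha, beta)`` where ``fitted = alpha*reference + beta``
    minimizes the squared error to ``signal``.
    """
    reference = np.asarray(reference, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if reference.shape != signal.shape:
        raise ValueError("channels must have equal length")
    var = np.var(reference)
    if var == 0:
        raise ValueError("reference channel has zero variance; affine fit undefined")
    alpha = np.cov(reference, signal, bias=True)[0, 1] / var
    beta = signal.mean() - alpha * reference.mean()
    return alpha * reference + beta, alpha, beta


def delta_f(signal: np.ndarray, fitted_reference: np.ndarray) -> np.ndarray:
    """Pointwise dF: signal minus the (fitted) calcium-independent reference."""
    signal = np.asarray(signal, dtype=float)
    fitted_reference = np.asarray(fitted_reference, dtype=float)
    if signal.shape != fitted_reference.shape:
        raise ValueError("channels must have equal length")
    return signal - fitted_reference


def dff(signal: np.ndarray, reference: np.ndarray, degree: int = 2,
        fit: bool = True) -> np.ndarray:
    """Normalized dF/F via a polynomial map of the reference onto the signal.

    The 405 channel is fitted to the 465 channel with a degree-2 polynomial
    (in the reference *values*, capturing both gain and bleaching mismatch),
    then dF/F = (F465 - F_fit405) / F_fit405.  Pass ``fit=False`` when the
    reference has already been mapped onto the signal scale.
    """
    signal = np.asarray(signal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if signal.shape != reference.shape:
        raise ValueError("channels must have equal length")
    if fit:
        coeffs = np.polyfit(reference, signal, degree)
        fitted = np.polyval(coeffs, reference)
    else:
        fitted = reference
    bad = np.nonzero(fitted <= 0)[0]
    if bad.size:
        raise ValueError(
            f"fitted reference non-positive at sample {int(bad[0])}; dF/F undefined")
    return (signal - fitted) / fitted


def zscore(trace: np.ndarray, rate_hz: float, baseline_window_s,
           sd_source: str = "same-day", day1_sigma: float | None = None,
           day1_f0: float | None = None, f0_source: str = "same-day"):
    """z = (F - F0) / sigma_F.

    ``F0`` defaults to the mean of the session's own baseline window (a 3-min
    home-cage segment preceding context placement); ``sigma_F`` comes either
    from the same baseline (``sd_source="same-day"``) or, for multi-day series,
    from day 1 (``sd_source="day-1"`` with ``day1_sigma`` supplied) so that
    cross-day amplitudes share one scale.  Sample SD uses the n-1 denominator.

    Returns a :class:`ProcessedTrace`.
    """
    trace = np.asarray(trace, dtype=float)
    sl = _window_slice(rate_hz, trace.size, baseline_window_s)
    base = trace[sl]
    if base.size < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    if f0_source == "day-1":
        if day1_f0 is None:
            raise ValueError("f0_source='day-1' requires day1_f0")
        f0 = float(day1_f0)
    else:
        f0 = float(base.mean())
    if sd_source == "same-day":
        sigma = float(base.std(ddof=1))
    elif sd_source == "day-1":
        if day1_sigma is None:
            raise ValueError("sd_source='day-1' requires day1_sigma")
        sigma = float(day1_sigma)
    else:
        raise ValueError(f"unknown sd_source {sd_source!r}")
    if sigma == 0:
        raise ValueError("baseline standard deviation is zero; z-score undefined")
    values = (trace - f0) / sigma
    return ProcessedTrace(np.arange(trace.size) / rate_hz, values, rate_hz,
                          "zscore",
                          {"F0": f0, "sigma_F": sigma, "sd_source": sd_source})


def epoch_mean(trace: np.ndarray, rate_hz: float, window_s) -> float:
    """Mean of the samples inside ``window_s = (start_s, end_s)``."""
    trace = np.asarray(trace, dtype=float)
    sl = _window_slice(rate_hz, trace.size, window_s)
    seg = trace[sl]
    if seg.size == 0:
        raise ValueError(f"window {window_s} contains no samples")
    return float(seg.mean())


def process_session(session: PhotometrySession, method: str = "zscore",
                    baseline: str = "home_cage", sd_source: str = "same-day",
                    day1_sigma: float | None = None,
                    trim: bool = False, fit_windows=None) -> ProcessedTrace:
    """Run the full chain: (trim) -> detrend both channels -> fit -> dF (-> z).

    ``method``: "deltaF" stops after reference subtraction; "dFF" uses the
    polynomial-normalized path on the raw channels; "zscore" z-scores the dF
    trace against the ``baseline`` annotation window.
    """
    if trim:
        session = trim_session(session)
    if method == "dFF":
        values = dff(session.signal, session.reference)
        return ProcessedTrace(session.time_s, values, session.rate_hz, "dFF")
    sig_d, _ = detrend_polynomial(session.signal, session.rate_hz, fit_windows)
    ref_d, _ = detrend_polynomial(session.reference, session.rate_hz, fit_windows)
    fitted, _, _ = fit_reference(ref_d, sig_d)
    df = delta_f(sig_d, fitted)
    if method == "deltaF":
        return ProcessedTrace(session.time_s, df, session.rate_hz, "deltaF")
    if method != "zscore":
        raise ValueError(f"unknown method {method!r}")
    if baseline not in session.epoch_annotations:
        raise ValueError(f"no {baseline!r} annotation on session")
    return zscore(df, session.rate_hz, session.epoch_annotations[baseline],
                  sd_source=sd_source, day1_sigma=day1_sigma)


# ---------------------------------------------------------------------------
# session I/O (HDF5 groups /signal, /reference, /meta; CSV time/signal/reference)

def write_session_h5(session: PhotometrySession, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=session.signal)
        f.create_dataset("reference", data=session.reference)
        meta = f.create_group("meta")
        meta.attrs["rate_hz"] = session.rate_hz
        for name, (a, b) in session.epoch_annotations.items():
            meta.attrs[f"epoch_{name}"] = (a, b)


def read_session_h5(path) -> PhotometrySession:
    with h5py.File(path, "r") as f:
        signal = f["signal"][:]
        reference = f["reference"][:]
        rate = float(f["meta"].attrs["rate_hz"])
        ann = {}
        for key, val in f["meta"].attrs.items():
            if key.startswith("epoch_"):
                ann[key[len("epoch_"):]] = (float(val[0]), float(val[1]))
    return PhotometrySession(signal, reference, rate, ann)


def write_session_csv(session: PhotometrySession, path) -> None:
    pd.DataFrame({"time": session.time_s, "signal": session.signal,
                  "reference": session.reference}).to_csv(path, index=False)


def read_session_csv(path, rate_hz: float | None = None) -> PhotometrySession:
    df = pd.read_csv(path)
    if rate_hz is None:
        dt = np.diff(df["time"].to_numpy())
        rate_hz = 1.0 / float(np.median(dt))
    return PhotometrySession(df["signal"].to_numpy(), df["reference"].to_numpy(), rate_hz)
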
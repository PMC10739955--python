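"""Synthetic inputs with known ground truth for every pipeline stage.

The study's raw recordings are not publicly deposited, so validation runs on
generated data that emulates their structure:

* :func:`generate_photometry_session` — dual-channel photometry at 100 Hz
  with second-order polynomial bleaching, a home-cage baseline, a sustained
  context-evoked elevation, shock-locked calcium transients (signal channel
  only) and motion artifacts shared by both channels, mirroring the
  calcium-dependent 465/470 nm and calcium-independent 405 nm channels.
* :func:`generate_cell_table` — per-cell idF/F tables with a
  Weak/Intermediate/Strong mixture and a ground-truth recruitment rule:
  aversive (Weak cells gain activity in proportion to their shock response)
  or appetitive (activity scaled down, most for Strong cells).
* :func:`generate_fov_pair` — paired day-1/day-2 maximal-projection images
  plus cell masks related by a known rotation/translation/scale.
* :func:`generate_behavior_barcode` — binary freezing annotations (10 Hz)
  from bout intervals, enforcing the >= 3 s bout definition.

Every generator takes an explicit seed and is exactly reproducible; no
global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .miniscope import AlignmentTransform, FovImagePair, warp_image
from .photometry import PhotometrySession

__all__ = [
    "InvalidSpecError",
    "SyntheticPhotometrySpec",
    "PhotometryGroundTruth",
    "generate_photometry_session",
    "SyntheticCellTableSpec",
    "generate_cell_table",
    "SyntheticFovSpec",
    "generate_fov_pair",
    "generate_behavior_barcode",
    "BARCODE_RATE_HZ",
    "MIN_BOUT_S",
]

#: annotation rate for behavior barcodes (fixed; documented choice)
BARCODE_RATE_HZ = 10.0
#: minimum freezing-bout duration (no movement for at least 3 s)
MIN_BOUT_S = 3.0

GROUP_NAMES = ("Weak", "Intermediate", "Strong")


class InvalidSpecError(ValueError):
    """A generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# photometry sessions

@dataclass
class SyntheticPhotometrySpec:
    """Parameters of a synthetic dual-channel photometry session.

    Bleaching is multiplicative: channel = bleach(t) * (baseline + activity),
    with bleach(t) = a*t^2 + b*t + c required strictly positive over the
    recording.  Calcium events (instant rise, single-exponential decay) enter
    the signal channel only; motion artifacts (brief Gaussian bumps) enter
    both channels with a shared gain, so reference subtraction can remove
    them.  The defaults describe a 15-min session bleaching by ~25%.
    """

    duration_s: float = 900.0
    rate_hz: float = 100.0
    bleach_coeffs_sig: tuple = (1.5e-7, -5e-4, 1.0)
    bleach_coeffs_ref: tuple = (1.0e-7, -4e-4, 1.0)
    baseline_level: float = 1.0
    event_times_s: tuple = ()
    event_amplitudes: tuple = ()
    event_decay_s: float = 2.0
    context_step: tuple | None = None      # (onset_s, offset_s, amplitude)
    motion_times_s: tuple = ()
    motion_amplitudes: tuple = ()
    motion_width_s: float = 0.2
    motion_gain: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise InvalidSpecError("duration_s and rate_hz must be positive")
        if len(self.event_times_s) != len(self.event_amplitudes):
            raise InvalidSpecError("event_times_s and event_amplitudes must pair up")
        if len(self.motion_times_s) != len(self.motion_amplitudes):
            raise InvalidSpecError("motion_times_s and motion_amplitudes must pair up")
        for t in tuple(self.event_times_s) + tuple(self.motion_times_s):
            if not (0 <= t <= self.duration_s):
                raise InvalidSpecError(f"event/motion time {t} outside [0, {self.duration_s}]")
        if self.context_step is not None:
            on, off, _ = self.context_step
            if not (0 <= on <= off <= self.duration_s):
                raise InvalidSpecError("context_step window outside the recording")
        t = np.linspace(0, self.duration_s, 2049)
        for name, coeffs in (("signal", self.bleach_coeffs_sig),
                             ("reference", self.bleach_coeffs_ref)):
            if np.polyval(coeffs, t).min() <= 0:
                raise InvalidSpecError(f"{name} bleaching polynomial not strictly positive")
        if self.noise_sd < 0 or self.event_decay_s <= 0:
            raise InvalidSpecError("noise_sd must be >= 0 and event_decay_s > 0")


@dataclass
class PhotometryGroundTruth:
    """What a perfect preprocessing chain should recover."""

    event_times_s: np.ndarray
    #: event peak amplitudes as they appear after detrending (bleach-scaled)
    event_amplitudes_detrended: np.ndarray
    event_component: np.ndarray     # bleach-scaled event waveform (signal channel)
    motion_component: np.ndarray    # additive shared artifact (signal channel)
    context_component: np.ndarray   # bleach-scaled sustained elevation
    bleach_coeffs_sig: tuple
    bleach_coeffs_ref: tuple
    baseline_level: float


def generate_photometry_session(spec: SyntheticPhotometrySpec):
    """Generate a session; returns (PhotometrySession, PhotometryGroundTruth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz

    events = np.zeros(n)
    for t0, amp in zip(spec.event_times_s, spec.event_amplitudes):
        dt = t - t0
        events += np.where(dt >= 0, amp * np.exp(-np.maximum(dt, 0) / spec.event_decay_s), 0.0)
    context = np.zeros(n)
    if spec.context_step is not None:
        on, off, amp = spec.context_step
        context[(t >= on) & (t < off)] = amp
    motion = np.zeros(n)
    for t0, amp in zip(spec.motion_times_s, spec.motion_amplitudes):
        motion += amp * np.exp(-0.5 * ((t - t0) / spec.motion_width_s) ** 2)

    bleach_sig = np.polyval(spec.bleach_coeffs_sig, t)
    bleach_ref = np.polyval(spec.bleach_coeffs_ref, t)
    signal = (bleach_sig * (spec.baseline_level + events + context)
              + motion + rng.normal(0, spec.noise_sd, n))
    reference = (bleach_ref * spec.baseline_level
                 + spec.motion_gain * motion + rng.normal(0, spec.noise_sd, n))

    ev_times = np.asarray(spec.event_times_s, dtype=float)
    ev_amps = (np.asarray(spec.event_amplitudes, dtype=float)
               * np.polyval(spec.bleach_coeffs_sig, ev_times))
    truth = PhotometryGroundTruth(ev_times, ev_amps, bleach_sig * events,
                                  motion, bleach_sig * context,
                                  spec.bleach_coeffs_sig, spec.bleach_coeffs_ref,
                                  spec.baseline_level)
    return PhotometrySession(signal, reference, spec.rate_hz), truth


# ---------------------------------------------------------------------------
# cell activity tables

@dataclass
class SyntheticCellTableSpec:
    """Mixture structure for a per-cell idF/F table.

    Cells fall into Weak / Intermediate / Strong pools by their pre-stimulus
    (Pre) contextual activity.  The shock (FS) response is drawn per cell,
    larger on average for Weak cells (as observed in vivo).  Post activity
    follows the selected ground-truth rule:

    * ``aversive``: Post = Pre + k_g * FSresp, with k largest for Weak cells
      and zero for Strong cells (ceiling) — Weak cells are recruited in
      proportion to their shock response.
    * ``appetitive``: Post = (1 - s_g) * Pre, with the scale-down factor s_g
      largest for Strong cells — activity shrinks, ranks preserved.

    ``day_noise_sd`` adds independent day-to-day measurement noise to every
    Post value (idF/F units).  Units throughout are idF/F (percent).
    """

    n_cells: int = 120
    group_fractions: tuple = (0.35, 0.45, 0.20)
    pre_means: tuple = (2.0, 7.0, 15.0)
    pre_sds: tuple = (0.8, 1.5, 3.0)
    fs_means: tuple = (13.0, 8.0, 5.0)
    fs_sds: tuple = (3.0, 2.0, 2.0)
    recruitment_rule: str = "aversive"
    k_recruit: tuple = (1.0, 0.5, 0.0)      # aversive gain per group
    s_scale: tuple = (0.05, 0.30, 0.60)     # appetitive scale-down per group
    n_post_days: int = 1
    day_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        fr = np.asarray(self.group_fractions, dtype=float)
        if fr.size != 3 or np.any(fr < 0) or np.any(fr > 1):
            raise InvalidSpecError("group_fractions must be three proportions in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise InvalidSpecError(f"group_fractions sum to {fr.sum()!r}, not 1")
        if self.n_cells < 3:
            raise InvalidSpecError("need at least 3 cells")
        for sds in (self.pre_sds, self.fs_sds):
            if np.any(np.asarray(sds) < 0):
                raise InvalidSpecError("group sds must be >= 0")
        if self.recruitment_rule not in ("aversive", "appetitive"):
            raise InvalidSpecError(f"unknown recruitment_rule {self.recruitment_rule!r}")
        if self.n_post_days < 1 or self.day_noise_sd < 0:
            raise InvalidSpecError("n_post_days >= 1 and day_noise_sd >= 0 required")


def generate_cell_table(spec: SyntheticCellTableSpec):
    """Generate a long-format cell table; returns (DataFrame, labels).

    The table has columns ``cell_id, day, epoch, idff`` with epochs ``pre``
    and ``fs`` on day 1 and ``post`` on days 2..1+n_post_days.  ``labels`` is
    the ground-truth group name per cell.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = np.floor(np.asarray(spec.group_fractions) * spec.n_cells).astype(int)
    while counts.sum() < spec.n_cells:           # distribute rounding remainder
        counts[int(np.argmax(np.asarray(spec.group_fractions) * spec.n_cells - counts))] += 1
    group_idx = np.repeat(np.arange(3), counts)

    pre = rng.normal(np.asarray(spec.pre_means)[group_idx],
                     np.asarray(spec.pre_sds)[group_idx])
    fs = rng.normal(np.asarray(spec.fs_means)[group_idx],
                    np.asarray(spec.fs_sds)[group_idx])
    rows = []
    for c in range(spec.n_cells):
        rows.append({"cell_id": c, "day": 1, "epoch": "pre", "idff": pre[c]})
        rows.append({"cell_id": c, "day": 1, "epoch": "fs", "idff": fs[c]})
    for d in range(spec.n_post_days):
        if spec.recruitment_rule == "aversive":
            post = pre + np.asarray(spec.k_recruit)[group_idx] * fs
        else:
            post = (1.0 - np.asarray(spec.s_scale)[group_idx]) * pre
        post = post + rng.normal(0, spec.day_noise_sd, spec.n_cells)
        for c in range(spec.n_cells):
            rows.append({"cell_id": c, "day": 2 + d, "epoch": "post", "idff": post[c]})
    labels = np.asarray(GROUP_NAMES)[group_idx]
    return pd.DataFrame(rows), labels


# ---------------------------------------------------------------------------
# field-of-view image pairs

@dataclass
class SyntheticFovSpec:
    """Blob field of view plus a known day-2 similarity transform."""

    image_shape: tuple = (64, 64)
    n_cells: int = 15
    cell_radius_px: float = 2.5
    transform: AlignmentTransform = field(default_factory=AlignmentTransform)
    background_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.image_shape) < 8 or self.n_cells < 1 or self.cell_radius_px <= 0:
            raise InvalidSpecError("image too small, no cells, or non-positive radius")
        if not (0.5 < self.transform.scale < 2.0):
            raise InvalidSpecError("scale must lie in (0.5, 2)")
        if self.background_noise_sd < 0:
            raise InvalidSpecError("background_noise_sd must be >= 0")


def generate_fov_pair(spec: SyntheticFovSpec):
    """Generate day-1/day-2 FOV pairs; returns ((day1, day2), true_transform).

    Day 1 is Gaussian blobs at random centroids (raw channel) with labeled
    disks (mask channel); day 2 applies the spec transform with bilinear
    interpolation (raw) / nearest-neighbor (mask) and zero padding.  Centroid
    placement is rejection-sampled so every cell sits fully inside the frame
    before and after the transform; a transform that leaves no admissible
    placement raises :class:`InvalidSpecError`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    margin = 2.0 * spec.cell_radius_px + 1.0
    centroids = []
    for _ in range(spec.n_cells):
        for _attempt in range(1000):
            c = np.array([rng.uniform(margin, H - 1 - margin),
                          rng.uniform(margin, W - 1 - margin)])
            c2 = spec.transform.apply_to_points(c, (H, W))[0]
            if (margin <= c2[0] <= H - 1 - margin and margin <= c2[1] <= W - 1 - margin
                    and all(np.linalg.norm(c - p) > 2.5 * spec.cell_radius_px
                            for p in centroids)):
                centroids.append(c)
                break
        else:
            raise InvalidSpecError(
                "transform leaves no in-frame placement for all cells")
    centroids = np.asarray(centroids)

    yy, xx = np.mgrid[0:H, 0:W]
    raw = np.zeros((H, W))
    mask = np.zeros((H, W), dtype=int)
    sigma = spec.cell_radius_px / 1.5
    for lab, (cy, cx) in enumerate(centroids, start=1):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        raw += rng.uniform(0.6, 1.0) * np.exp(-0.5 * r2 / sigma ** 2)
        mask[r2 <= spec.cell_radius_px ** 2] = lab
    raw += rng.normal(0, spec.background_noise_sd, (H, W))

    day2_raw = warp_image(raw, spec.transform, order=1)
    day2_mask = warp_image(mask.astype(float), spec.transform, order=0).astype(int)
    pair = (FovImagePair(raw, mask, "day1"),
            FovImagePair(day2_raw, day2_mask, "day2"))
    return pair, spec.transform


# ---------------------------------------------------------------------------
# behavior barcodes

def generate_behavior_barcode(bout_starts_s, bout_ends_s, duration_s,
                              rate_hz: float = BARCODE_RATE_HZ) -> np.ndarray:
    """Binary freezing annotation: 1 inside bouts, 0 elsewhere.

    Bouts must be non-overlapping, each at least :data:`MIN_BOUT_S` seconds
    (freezing = no movement for at least 3 s), and inside [0, duration].
    """
    starts = np.asarray(bout_starts_s, dtype=float)
    ends = np.asarray(bout_ends_s, dtype=float)
    if starts.shape != ends.shape:
        raise InvalidSpecError("bout starts and ends must pair up")
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    for s, e in zip(starts, ends):
        if e - s < MIN_BOUT_S:
            raise InvalidSpecError(
                f"bout [{s}, {e}] lasts {e - s:.2f} s; freezing requires "
                f"no movement for at least {MIN_BOUT_S:.0f} s")
        if s < 0 or e > duration_s:
            raise InvalidSpecError(f"bout [{s}, {e}] outside [0, {duration_s}]")
    if np.any(starts[1:] < ends[:-1]):
        raise InvalidSpecError("bouts must not overlap")
    n = int(round(duration_s * rate_hz))
    barcode = np.zeros(n, dtype=np.int8)
    t = np.arange(n) / rate_hz
    for s, e in zip(starts, ends):
        barcode[(t >= s) & (t < e)] = 1
    return barcode
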
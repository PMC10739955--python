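"""Single-cell miniscope measures and cross-day field-of-view registration.

One-photon miniscope recordings yield, per day, a maximal-projection image of
the field of view plus a curated cell-assignment (mask) channel from the
source-extraction pipeline.  Cells must be re-identified across days before
any cross-day comparison; the approach here is a stochastic descent on image
similarity:

* the *global alignment* metric GA is the sum of Frobenius norms of pixelwise
  differences over day pairs, computed separately for the raw projections and
  the mask channel;
* a weighted combination (0.3 mask + 0.7 raw) is the optimization criterion;
* random rotation/translation/scale perturbations are proposed to one day's
  transform at a time and kept only if the weighted metric decreases;
* the perturbation size halves every 500 iterations, the perturbed day cycles
  every 400 iterations, and several restarts from different initial
  conditions guard against local minima.

After alignment, :func:`match_cells` builds a one-to-one cell correspondence
by greedy nearest-centroid matching under a distance cap.

The per-cell activity measure is :func:`integrated_dff` (idF/F): the mean of
the single-cell dF/F trace sampled at 0.1 s over a 3-min window, x100.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "FovImagePair",
    "AlignmentTransform",
    "AlignmentResult",
    "integrated_dff",
    "global_alignment_metric",
    "weighted_metric",
    "stochastic_align",
    "match_cells",
    "warp_image",
    "read_fov_tiff",
    "write_fov_tiff",
]


@dataclass
class AlignmentTransform:
    """Similarity transform: rotate/scale about the image center, then shift.

    In (x, y) coordinates with y = row, x = col and the rotation
    counter-clockwise by ``rotation_deg``:

        p' = scale * R(p - c) + c + (dx, dy)

    where ``c`` is the image center.  Composition and inversion are closed in
    this family.
    """

    rotation_deg: float = 0.0
    translation_px: tuple = (0.0, 0.0)  # (dx, dy)
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def _rc_matrix(self, shape):
        """Forward map in (row, col) coordinates: q' = A q + b."""
        th = math.radians(self.rotation_deg)
        s = self.scale
        # (row, col) = (y, x); CCW rotation in (x, y)
        A = s * np.array([[math.cos(th), math.sin(th)],
                          [-math.sin(th), math.cos(th)]])
        c = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        dy, dx = self.translation_px[1], self.translation_px[0]
        b = c + np.array([dy, dx]) - A @ c
        return A, b

    def apply_to_points(self, points_rc, shape):
        """Map an (n, 2) array of (row, col) points through the transform."""
        A, b = self._rc_matrix(shape)
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        return pts @ A.T + b

    def inverse(self) -> "AlignmentTransform":
        th = math.radians(self.rotation_deg)
        s = 1.0 / self.scale
        dx, dy = self.translation_px
        # invert p' = sR p_c + c + t  ->  p = (1/s) R^-1 (p' - c - t) + c
        inv_dx = -s * (math.cos(th) * dx + math.sin(th) * dy)
        inv_dy = -s * (-math.sin(th) * dx + math.cos(th) * dy)
        return AlignmentTransform(-self.rotation_deg, (inv_dx, inv_dy), s)

    def compose(self, first: "AlignmentTransform") -> "AlignmentTransform":
        """Return self o first (apply ``first``, then ``self``)."""
        th2 = math.radians(self.rotation_deg)
        s2 = self.scale
        dx1, dy1 = first.translation_px
        tx = s2 * (math.cos(th2) * dx1 - math.sin(th2) * dy1) + self.translation_px[0]
        ty = s2 * (math.sin(th2) * dx1 + math.cos(th2) * dy1) + self.translation_px[1]
        return AlignmentTransform(self.rotation_deg + first.rotation_deg,
                                  (tx, ty), self.scale * first.scale)

    def as_dict(self):
        return {"rotation_deg": float(self.rotation_deg),
                "translation_px": [float(self.translation_px[0]),
                                   float(self.translation_px[1])],
                "scale": float(self.scale)}


@dataclass
class FovImagePair:
    """Per-day raw maximal-projection image plus cell-mask channel."""

    raw: np.ndarray
    mask: np.ndarray
    day_id: str = "day"

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.raw.shape != self.mask.shape:
            raise ValueError("raw and mask must share a shape")


@dataclass
class AlignmentResult:
    transforms: dict            # day_id -> AlignmentTransform
    final_metric: float
    trajectory: np.ndarray      # weighted metric after each iteration (best restart)
    restart_metrics: list = field(default_factory=list)
    correspondence: pd.DataFrame | None = None


def warp_image(image: np.ndarray, transform: AlignmentTransform,
               order: int = 1) -> np.ndarray:
    """Apply a transform to an image (bilinear by default, zero padding)."""
    A, b = transform._rc_matrix(image.shape)
    Ainv = np.linalg.inv(A)
    offset = -Ainv @ b
    return ndimage.affine_transform(np.asarray(image, dtype=float), Ainv,
                                    offset=offset, order=order, mode="constant",
                                    cval=0.0)


def integrated_dff(cell_trace: np.ndarray, rate_hz: float,
                   window_s: float = 180.0, sample_s: float = 0.1,
                   start_s: float = 0.0) -> float:
    """idF/F: mean of dF/F resampled at ``sample_s`` over ``window_s``, x100."""
    trace = np.asarray(cell_trace, dtype=float)
    i0 = int(round(start_s * rate_hz))
    n_need = int(round(window_s * rate_hz))
    if i0 < 0 or i0 + n_need > trace.size:
        raise ValueError(
            f"trace of {trace.size / rate_hz:.1f} s does not cover window "
            f"[{start_s}, {start_s + window_s}] s")
    seg = trace[i0:i0 + n_need]
    per_bin = max(int(round(sample_s * rate_hz)), 1)
    n_bins = seg.size // per_bin
    binned = seg[:n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    return float(binned.mean() * 100.0)


def _frob(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.sum((a - b) ** 2)))


def global_alignment_metric(images_by_day, reference: np.ndarray | None = None) -> float:
    """Sum of Frobenius distances between day images.

    With ``reference=None`` (default) the sum runs over all unordered day
    pairs; otherwise each day is compared against the fixed reference image.
    """
    imgs = [np.asarray(im, dtype=float) for im in images_by_day]
    shapes = {im.shape for im in imgs}
    if len(shapes) > 1 or (reference is not None
                           and np.asarray(reference).shape not in shapes):
        raise ValueError("all images must share a shape")
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        return sum(_frob(im, ref) for im in imgs)
    total = 0.0
    for i in range(len(imgs)):
        for j in range(i + 1, len(imgs)):
            total += _frob(imgs[i], imgs[j])
    return total


def weighted_metric(ga_mask: float, ga_raw: float,
                    w_mask: float = 0.3, w_raw: float = 0.7) -> float:
    """Optimization criterion: 0.3 * GA(mask) + 0.7 * GA(raw)."""
    if not (np.isfinite(ga_mask) and np.isfinite(ga_raw)):
        raise ValueError("metric components must be finite")
    return w_mask * ga_mask + w_raw * ga_raw


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    peak = img.max()
    return img / peak if peak > 0 else img


def _pair_metric(raws, masks, pair_mode):
    ref_raw = raws[0] if pair_mode == "vs_reference" else None
    ref_mask = masks[0] if pair_mode == "vs_reference" else None
    if pair_mode == "vs_reference":
        ga_raw = global_alignment_metric(raws[1:], ref_raw)
        ga_mask = global_alignment_metric(masks[1:], ref_mask)
    else:
        ga_raw = global_alignment_metric(raws)
        ga_mask = global_alignment_metric(masks)
    return weighted_metric(ga_mask, ga_raw)


def stochastic_align(days, iterations: int = 10000, restarts: int = 5,
                     seed: int = 0, init_scales=(5.0, 10.0, 0.1),
                     halve_every: int = 500, swap_every: int = 400,
                     pair_mode: str = "all_pairs",
                     smooth_sigma_px: float = 3.0,
                     min_mass_fraction: float = 0.5,
                     match_max_dist_px: float | None = 6.0) -> AlignmentResult:
    """Register the fields of view of several recording days.

    Parameters
    ----------
    days : sequence of FovImagePair
        Day 0 is the fixed reference; later days carry the free transforms.
    iterations : int
        Total proposal count per restart.
    restarts : int
        Independent descents from perturbed initial conditions; the restart
        with the lowest final weighted metric wins.
    init_scales : (rot_deg, trans_px, scale)
        Initial perturbation scales; each halves every ``halve_every``
        iterations.  The perturbed day cycles every ``swap_every`` iterations.
    pair_mode : "all_pairs" | "vs_reference"
        Whether GA sums over all unordered day pairs or against day 0 only.

    Acceptance is strict descent of the weighted metric: ties and increases
    are rejected, so the accepted-metric trajectory is non-increasing.  Two
    numerical safeguards shape the search: the channels are Gaussian-smoothed
    (``smooth_sigma_px``) before the metric so the similarity basin is wider
    than a cell body, and proposals whose warped raw channel retains less
    than ``min_mass_fraction`` of its intensity mass are rejected — a
    transform sliding the field of view out of frame trivially shrinks the
    Frobenius distance and must not count as alignment.
    """
    if len(days) < 2:
        raise ValueError("need at least 2 days to align")
    rng = np.random.default_rng(seed)

    def _prep(img):
        img = _normalize(img)
        if smooth_sigma_px > 0:
            img = ndimage.gaussian_filter(img, smooth_sigma_px)
        return img

    raw0 = [_prep(d.raw) for d in days]
    mask0 = [_prep((np.asarray(d.mask) > 0).astype(float)) for d in days]
    masses = [im.sum() for im in raw0]
    free = list(range(1, len(days)))

    best = None
    restart_metrics = []
    for restart in range(restarts):
        transforms = {}
        for k in free:
            if restart == 0:
                transforms[k] = AlignmentTransform()
            else:
                transforms[k] = AlignmentTransform(
                    rng.normal(0, init_scales[0] / 2),
                    (rng.normal(0, init_scales[1] / 2),
                     rng.normal(0, init_scales[1] / 2)),
                    float(np.exp(rng.normal(0, init_scales[2] / 2))))
        raws = [raw0[0]] + [warp_image(raw0[k], transforms[k]) for k in free]
        masks = [mask0[0]] + [warp_image(mask0[k], transforms[k]) for k in free]
        metric = _pair_metric(raws, masks, pair_mode)
        trajectory = np.empty(iterations)
        for it in range(iterations):
            scale_fac = 0.5 ** (it // halve_every)
            day_idx = free[(it // swap_every) % len(free)]
            cur = transforms[day_idx]
            prop = AlignmentTransform(
                cur.rotation_deg + rng.normal(0, init_scales[0] * scale_fac),
                (cur.translation_px[0] + rng.normal(0, init_scales[1] * scale_fac),
                 cur.translation_px[1] + rng.normal(0, init_scales[1] * scale_fac)),
                max(cur.scale + rng.normal(0, init_scales[2] * scale_fac), 1e-3))
            pos = free.index(day_idx) + 1
            new_raw = warp_image(raw0[day_idx], prop)
            new_mask = warp_image(mask0[day_idx], prop)
            if new_raw.sum() < min_mass_fraction * masses[day_idx]:
                trajectory[it] = metric   # image (partly) out of frame: reject
                continue
            saved_raw, saved_mask = raws[pos], masks[pos]
            raws[pos], masks[pos] = new_raw, new_mask
            cand = _pair_metric(raws, masks, pair_mode)
            if cand < metric:
                transforms[day_idx] = prop
                metric = cand
            else:
                raws[pos], masks[pos] = saved_raw, saved_mask
            trajectory[it] = metric
        restart_metrics.append(metric)
        if best is None or metric < best[0]:
            best = (metric, dict(transforms), trajectory)

    metric, transforms, trajectory = best
    corr = None
    if match_max_dist_px is not None:
        aligned_masks = [np.asarray(days[0].mask)]
        for k in free:
            aligned_masks.append(
                warp_image(np.asarray(days[k].mask, dtype=float),
                           transforms[k], order=0).astype(int))
        corr = match_cells(aligned_masks, max_dist_px=match_max_dist_px,
                           day_ids=[d.day_id for d in days])
    named = {days[k].day_id: transforms[k] for k in free}
    named[days[0].day_id] = AlignmentTransform()
    return AlignmentResult(named, metric, trajectory, restart_metrics, corr)


def _centroids(mask: np.ndarray):
    mask = np.asarray(mask)
    labels = [int(v) for v in np.unique(mask) if v > 0]
    if not labels:
        return [], np.empty((0, 2))
    cents = ndimage.center_of_mass(mask > 0, mask, labels)
    return labels, np.asarray(cents, dtype=float)


def match_cells(aligned_masks, max_dist_px: float = 6.0, day_ids=None) -> pd.DataFrame:
    """Greedy one-to-one nearest-centroid matching against the reference day.

    ``aligned_masks[0]`` is the reference (labeled) mask; later masks must
    already be in the reference frame.  Returns a table with columns
    ``day``, ``cell_id``, ``ref_cell_id`` (nullable) and ``distance_px``;
    cells whose nearest available reference centroid exceeds ``max_dist_px``
    are left unmatched.
    """
    if day_ids is None:
        day_ids = [f"day{k}" for k in range(len(aligned_masks))]
    ref_labels, ref_cents = _centroids(aligned_masks[0])
    rows = [{"day": day_ids[0], "cell_id": lab, "ref_cell_id": lab,
             "distance_px": 0.0} for lab in ref_labels]
    for k in range(1, len(aligned_masks)):
        labels, cents = _centroids(aligned_masks[k])
        if not labels or not ref_labels:
            rows += [{"day": day_ids[k], "cell_id": lab, "ref_cell_id": None,
                      "distance_px": np.nan} for lab in labels]
            continue
        dists = np.linalg.norm(cents[:, None, :] - ref_cents[None, :, :], axis=2)
        matched = {}
        d = dists.copy()
        while np.isfinite(d).any() and d.min() <= max_dist_px:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            matched[labels[i]] = (ref_labels[j], float(dists[i, j]))
            d[i, :] = np.inf
            d[:, j] = np.inf
        for idx, lab in enumerate(labels):
            ref_lab, dist = matched.get(lab, (None, np.nan))
            rows.append({"day": day_ids[k], "cell_id": lab,
                         "ref_cell_id": ref_lab, "distance_px": dist})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF (page 0 raw, page 1 mask), JSON transforms, CSV matches

def write_fov_tiff(pair: FovImagePair, path) -> None:
    tifffile.imwrite(path, np.stack([pair.raw.astype(np.float32),
                                     np.asarray(pair.mask, dtype=np.float32)]))


def read_fov_tiff(path, day_id: str | None = None) -> FovImagePair:
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] < 2:
        raise ValueError(f"{path}: expected a 2-page TIFF (raw, mask)")
    return FovImagePair(pages[0].astype(float),
                        np.round(pages[1]).astype(int),
                        day_id or str(path))


def write_alignment_json(result: AlignmentResult, path) -> None:
    payload = {
        "final_metric": result.final_metric,
        "restart_metrics": [float(m) for m in result.restart_metrics],
        "transforms": {d: t.as_dict() for d, t in result.transforms.items()},
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)
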
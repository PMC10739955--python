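"""Population state-space analysis and contextual-recall statistics.

This module holds the cross-day analyses run on per-cell activity:

* :func:`build_matrix` assembles the cells x time population matrix from
  per-day traces and a cross-day cell correspondence (cells unmatched on any
  included day are dropped);
* :func:`pca_svd` runs PCA directly via the singular value decomposition,
  giving components, per-time-sample projections for state-space plots, and
  explained-variance fractions;
* :func:`paired_comparison`, :func:`pre_post_correlation` and
  :func:`recruitment_regression` implement the recall statistics: paired
  Pre-vs-Post tests, per-cell Pre-Post correlation, and the within-group
  regression of recruitment (Post - Pre) on the shock response;
* :func:`freezing_time` summarizes behavioral freezing from annotation
  barcodes (bouts shorter than 3 s do not count as freezing);
* :func:`recall_report` bundles the full qualitative recall pattern for a
  cell table plus group labels.

Standard tests (paired t, Pearson r, regression slope test) are delegated to
scipy.stats; the contribution here is the epoching, grouping, and
recruitment logic around them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationMatrix",
    "PCAResult",
    "build_matrix",
    "pca_svd",
    "paired_comparison",
    "pre_post_correlation",
    "recruitment_regression",
    "freezing_time",
    "table_to_wide",
    "recall_report",
    "repeated_measures_anova",
]

MIN_FREEZING_BOUT_S = 3.0


@dataclass
class PopulationMatrix:
    """Cells x time matrix with cross-day cell identity.

    ``X[i, j]`` is the activity of (reference) cell ``cell_ids[i]`` at the
    j-th pooled time sample; ``col_annotations`` carries one row per column
    with ``day``, ``time_s`` and optionally ``condition``.
    """

    X: np.ndarray
    cell_ids: np.ndarray
    col_annotations: pd.DataFrame
    sample_dt_s: float = 0.1

    def __post_init__(self):
        if self.X.shape != (len(self.cell_ids), len(self.col_annotations)):
            raise ValueError("X shape must match cell_ids x col_annotations")

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X)
            f.create_dataset("cell_ids", data=np.asarray(self.cell_ids))
            f.create_dataset("day", data=np.asarray(self.col_annotations["day"], dtype="S"))
            f.create_dataset("time_s", data=self.col_annotations["time_s"].to_numpy())
            f.attrs["sample_dt_s"] = self.sample_dt_s


@dataclass
class PCAResult:
    components: np.ndarray          # cell-space directions (cells x k)
    singular_values: np.ndarray
    variance_fractions: np.ndarray
    projections: np.ndarray         # k x time: state-space trajectory
    center: str


def build_matrix(cell_traces_by_day: dict, correspondence: pd.DataFrame | None = None,
                 conditions: dict | None = None,
                 sample_dt_s: float = 0.1) -> PopulationMatrix:
    """Concatenate per-day traces into one cells x time matrix.

    Parameters
    ----------
    cell_traces_by_day : dict[day_id, pandas.DataFrame]
        One DataFrame per day, rows indexed by that day's cell ids, columns
        = time samples (0.1 s grid).
    correspondence : DataFrame with columns day, cell_id, ref_cell_id
        Cross-day identity (e.g. from miniscope.match_cells).  ``None``
        asserts that all days already share reference ids.
    conditions : dict[day_id, str], optional
        Condition tag per day for the column annotations.

    Cells missing (unmatched) on any included day are dropped with a logged
    count; rows are ordered by reference cell id; columns keep day blocks
    contiguous and time-ordered.
    """
    days = list(cell_traces_by_day)
    maps = {}
    for day in days:
        df = cell_traces_by_day[day]
        if correspondence is None:
            maps[day] = {cid: cid for cid in df.index}
        else:
            sub = correspondence[correspondence["day"] == day].dropna(subset=["ref_cell_id"])
            maps[day] = dict(zip(sub["cell_id"], sub["ref_cell_id"]))
    common = None
    for day in days:
        present = {maps[day][cid] for cid in cell_traces_by_day[day].index
                   if cid in maps[day]}
        common = present if common is None else common & present
    if not common:
        raise ValueError("no cell is matched across all included days")
    n_all = max(len(cell_traces_by_day[d].index) for d in days)
    dropped = n_all - len(common)
    if dropped:
        logger.info("dropping %d cells unmatched on some day", dropped)
    ref_ids = np.asarray(sorted(common))

    blocks, ann = [], []
    for day in days:
        df = cell_traces_by_day[day]
        inv = {ref: cid for cid, ref in maps[day].items()}
        block = np.vstack([df.loc[inv[ref]].to_numpy(dtype=float) for ref in ref_ids])
        blocks.append(block)
        n_t = block.shape[1]
        ann.append(pd.DataFrame({
            "day": [day] * n_t,
            "condition": [(conditions or {}).get(day, "")] * n_t,
            "time_s": np.arange(n_t) * sample_dt_s,
        }))
    return PopulationMatrix(np.hstack(blocks), ref_ids,
                            pd.concat(ann, ignore_index=True), sample_dt_s)


def pca_svd(X: np.ndarray, center: str = "columns") -> PCAResult:
    """PCA of a cells x time matrix via the SVD.

    ``center`` removes the mean over cells from each time column (default),
    the mean over time from each cell row (``"rows"``), or nothing
    (``"none"``).  Variance fractions are s_k^2 / sum s^2 and sum to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows and 2 columns")
    if center == "columns":
        Xc = X - X.mean(axis=0, keepdims=True)
    elif center == "rows":
        Xc = X - X.mean(axis=1, keepdims=True)
    elif center == "none":
        Xc = X
    else:
        raise ValueError(f"unknown centering {center!r}")
    if np.allclose(Xc, 0):
        raise ValueError("matrix is degenerate (no variance after centering)")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    frac = S ** 2 / np.sum(S ** 2)
    return PCAResult(U, S, frac, S[:, None] * Vt, center)


def paired_comparison(pre_values, post_values):
    """Paired two-tailed t-test; returns (mean_diff, t, p).

    A constant nonzero shift (zero-variance differences) is degenerate for
    the t statistic; it is reported as +/-inf with p = 0 and a warning.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("need equal-length 1-D arrays with n >= 2")
    diff = post - pre
    md = float(diff.mean())
    if diff.std(ddof=1) == 0:
        if md == 0:
            return 0.0, 0.0, 1.0
        warnings.warn("zero-variance paired differences; t is infinite")
        return md, float(np.sign(md) * np.inf), 0.0
    t, p = stats.ttest_rel(post, pre)
    return md, float(t), float(p)


def pre_post_correlation(pre_values, post_values):
    """Pearson correlation of per-cell Pre vs Post activity.

    Returns (r, p, (slope, intercept)) with p from the regression slope test.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape or pre.size < 3:
        raise ValueError("need at least 3 paired values")
    if pre.std() == 0 or post.std() == 0:
        raise ValueError("zero variance in pre or post values; correlation undefined")
    fit = stats.linregress(pre, post)
    return float(fit.rvalue), float(fit.pvalue), (float(fit.slope), float(fit.intercept))


def recruitment_regression(fs_response, post_minus_pre, labels) -> pd.DataFrame:
    """Within-group regression of recruitment on the shock response.

    For each label group with at least 3 cells, regresses (Post - Pre) on the
    FS-epoch response; groups with fewer cells are skipped with a warning.
    Returns a table with columns group, n, r, slope, p.
    """
    fs = np.asarray(fs_response, dtype=float)
    dpp = np.asarray(post_minus_pre, dtype=float)
    labels = np.asarray(labels)
    if not (fs.shape == dpp.shape == labels.shape):
        raise ValueError("fs_response, post_minus_pre and labels must align")
    rows = []
    for g in pd.unique(labels):
        m = labels == g
        if m.sum() < 3:
            warnings.warn(f"group {g!r} has {int(m.sum())} cells (< 3); skipped")
            continue
        if fs[m].std() == 0:
            raise ValueError(f"group {g!r}: zero variance in FS response")
        fit = stats.linregress(fs[m], dpp[m])
        rows.append({"group": g, "n": int(m.sum()), "r": float(fit.rvalue),
                     "slope": float(fit.slope), "p": float(fit.pvalue)})
    return pd.DataFrame(rows)


def freezing_time(barcode, rate_hz: float, window_s=None,
                  min_bout_s: float = MIN_FREEZING_BOUT_S):
    """Seconds spent freezing inside a window, and the frozen fraction.

    ``barcode`` is a binary annotation series; bouts shorter than
    ``min_bout_s`` (freezing requires no movement for at least 3 s) are
    excluded.  ``window_s`` is (start, end) in seconds or a plain duration
    (meaning (0, duration)); default is the whole barcode.
    """
    b = np.asarray(barcode).astype(int)
    if window_s is None:
        i0, i1 = 0, b.size
    else:
        if np.isscalar(window_s):
            window_s = (0.0, float(window_s))
        i0 = int(round(window_s[0] * rate_hz))
        i1 = int(round(window_s[1] * rate_hz))
        if i0 < 0 or i1 > b.size:
            raise ValueError(f"window {window_s} not covered by the barcode")
    seg = b[i0:i1]
    edges = np.diff(np.concatenate([[0], seg, [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    total = 0.0
    for s, e in zip(starts, ends):
        dur = (e - s) / rate_hz
        if dur >= min_bout_s:
            total += dur
    frac = total / ((i1 - i0) / rate_hz) if i1 > i0 else 0.0
    return total, frac


def table_to_wide(table: pd.DataFrame, post_day: int | None = None) -> pd.DataFrame:
    """Pivot a long cell table (cell_id, day, epoch, idff) to one row per cell.

    Columns: ``pre``, ``fs`` (day-1 epochs) and ``post`` (the requested post
    day; default the first day carrying a ``post`` epoch).
    """
    first = table[table["day"] == table["day"].min()]
    wide = first.pivot_table(index="cell_id", columns="epoch", values="idff")
    posts = table[table["epoch"] == "post"]
    if not posts.empty:
        if post_day is None:
            post_day = int(posts["day"].min())
        sel = posts[posts["day"] == post_day].set_index("cell_id")["idff"]
        wide["post"] = sel
    return wide


def recall_report(table: pd.DataFrame, labels, post_day: int | None = None) -> dict:
    """Full recall-pattern summary for a cell table plus group labels.

    Returns a dict with the overall paired Pre/Post comparison, the overall
    Pre-Post correlation, per-group paired statistics, the Weak-vs-Strong
    comparison at Post (unpaired two-tailed t), and the within-group
    recruitment regression table.
    """
    wide = table_to_wide(table, post_day)
    labels = np.asarray(labels)
    if len(labels) != len(wide):
        raise ValueError("one label per cell required")
    pre = wide["pre"].to_numpy()
    post = wide["post"].to_numpy()
    out = {"overall_paired": paired_comparison(pre, post),
           "overall_correlation": pre_post_correlation(pre, post)[:2],
           "groups": {}}
    for g in pd.unique(labels):
        m = labels == g
        if m.sum() >= 2:
            out["groups"][g] = {"n": int(m.sum()),
                                "paired": paired_comparison(pre[m], post[m])}
    if {"Weak", "Strong"} <= set(labels):
        w, s = labels == "Weak", labels == "Strong"
        t, p = stats.ttest_ind(post[w], post[s])
        out["weak_vs_strong_post"] = (float(t), float(p))
    if "fs" in wide.columns:
        out["recruitment"] = recruitment_regression(wide["fs"].to_numpy(),
                                                    post - pre, labels)
    return out


def repeated_measures_anova(table: pd.DataFrame, value_col: str = "idff",
                            within_col: str = "day", subject_col: str = "cell_id"):
    """One-way repeated-measures ANOVA across days (library-backed convenience)."""
    from statsmodels.stats.anova import AnovaRM
    res = AnovaRM(table, depvar=value_col, subject=subject_col,
                  within=[within_col]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])
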
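"""Scoring a detector against ground truth.

True positives are defined purely positionally: a minimum-total-distance
one-to-one assignment (Hungarian algorithm) between truth and detections,
with matches allowed only within ``max_dist_px``.  Accuracy is matched
truth over total truth — false positives are reported separately and do not
enter it.  Size-group errors are likewise kept out of the true-positive
definition and reported in a separate confusion table.  An optional binary
region-of-interest mask (e.g. the membrane face within which labeling is
quantified) restricts both truth and detections before matching.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .types import GroundTruthParticle, ParticleRecord

__all__ = [
    "MatchResult",
    "default_match_radius",
    "match_detections",
    "accuracy",
    "center_rmse",
    "size_confusion",
    "write_report",
]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching outcome.

    ``pairs`` holds ``(truth_index, detection_index, distance_px)`` with
    indices into the original input lists; entries outside the ROI appear in
    neither ``pairs`` nor the unmatched lists.
    """

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_truth: tuple[int, ...]
    unmatched_detections: tuple[int, ...]
    max_dist_px: float

    @property
    def n_truth(self) -> int:
        return len(self.pairs) + len(self.unmatched_truth)


def default_match_radius(diameter_nm: float, pixel_size_nm: float) -> float:
    """Match radius: twice the particle pixel diameter, at least 5 px."""
    return max(2.0 * diameter_nm / pixel_size_nm, 5.0)


def _xy(obj) -> tuple[float, float]:
    if isinstance(obj, (GroundTruthParticle, ParticleRecord)):
        return obj.x_px, obj.y_px
    x, y = obj
    return float(x), float(y)


def _in_roi(xy: tuple[float, float], roi: np.ndarray | None) -> bool:
    if roi is None:
        return True
    c, r = int(round(xy[0])), int(round(xy[1]))
    return 0 <= r < roi.shape[0] and 0 <= c < roi.shape[1] and bool(roi[r, c])


def match_detections(
    truth,
    detections,
    max_dist_px: float,
    roi: np.ndarray | None = None,
) -> MatchResult:
    """Optimal (not greedy) assignment of detections to truth within
    ``max_dist_px``; points outside ``roi`` are excluded beforehand."""
    if max_dist_px <= 0:
        raise ValueError("max_dist_px must be positive")
    t_xy = [_xy(t) for t in truth]
    d_xy = [_xy(d) for d in detections]
    t_idx = [i for i, p in enumerate(t_xy) if _in_roi(p, roi)]
    d_idx = [i for i, p in enumerate(d_xy) if _in_roi(p, roi)]
    if not t_idx or not d_idx:
        return MatchResult((), tuple(t_idx), tuple(d_idx), max_dist_px)
    tp = np.array([t_xy[i] for i in t_idx])
    dp = np.array([d_xy[i] for i in d_idx])
    dist = np.sqrt(((tp[:, None, :] - dp[None, :, :]) ** 2).sum(axis=2))
    big = max_dist_px * (len(t_idx) + len(d_idx) + 1) * 1e3 + 1e6
    cost = np.where(dist <= max_dist_px, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs, m_t, m_d = [], set(), set()
    for r, c in zip(rows, cols):
        if dist[r, c] <= max_dist_px:
            pairs.append((t_idx[r], d_idx[c], float(dist[r, c])))
            m_t.add(t_idx[r])
            m_d.add(d_idx[c])
    return MatchResult(
        tuple(pairs),
        tuple(i for i in t_idx if i not in m_t),
        tuple(i for i in d_idx if i not in m_d),
        max_dist_px,
    )


def accuracy(match: MatchResult) -> float:
    """Matched truth over total (ROI-restricted) truth; undefined without
    truth particles."""
    if match.n_truth == 0:
        raise ValueError("accuracy undefined with zero ground-truth particles")
    return len(match.pairs) / match.n_truth


def center_rmse(match: MatchResult, detection_groups=None):
    """Root-mean-square center distance over matched pairs.

    With ``detection_groups`` (group label per detection index) also returns
    a per-group breakdown: ``(overall, {group: rmse})``.
    """
    if not match.pairs:
        raise ValueError("center_rmse undefined with no matched pairs")
    d2 = np.array([d**2 for _, _, d in match.pairs])
    overall = float(np.sqrt(d2.mean()))
    if detection_groups is None:
        return overall
    groups = np.array([detection_groups[di] for _, di, _ in match.pairs])
    per_group = {
        int(g): float(np.sqrt(d2[groups == g].mean())) for g in np.unique(groups)
    }
    return overall, per_group


def size_confusion(
    match: MatchResult,
    truth_diameters_nm,
    detection_groups,
) -> tuple[pd.DataFrame, dict[float, float]]:
    """Confusion of true nominal diameter vs assigned size group.

    Rows are ascending true diameters, columns assigned group labels; counts
    are over matched pairs.  Per-class recall counts a truth particle as
    recovered when it is matched AND its group index equals the rank of its
    diameter (group k <-> k-th smallest diameter).
    """
    diams = sorted({float(truth_diameters_nm[ti]) for ti, _, _ in match.pairs}
                   | {float(truth_diameters_nm[ti]) for ti in match.unmatched_truth})
    all_groups = sorted({int(detection_groups[di]) for _, di, _ in match.pairs})
    rank = {d: k for k, d in enumerate(diams)}
    table = pd.DataFrame(
        0, index=pd.Index(diams, name="true_diameter_nm"),
        columns=pd.Index(all_groups, name="assigned_group"),
    )
    correct = {d: 0 for d in diams}
    totals = {d: 0 for d in diams}
    for ti, di, _ in match.pairs:
        d = float(truth_diameters_nm[ti])
        g = int(detection_groups[di])
        table.loc[d, g] += 1
        totals[d] += 1
        if g == rank[d]:
            correct[d] += 1
    for ti in match.unmatched_truth:
        totals[float(truth_diameters_nm[ti])] += 1
    recall = {d: (correct[d] / totals[d] if totals[d] else float("nan")) for d in diams}
    return table, recall


def write_report(
    path,
    match: MatchResult,
    truth_diameters_nm=None,
    detection_groups=None,
) -> str:
    """Write a human-readable evaluation summary (and return it)."""
    lines = [
        f"truth particles (in scope): {match.n_truth}",
        f"matched (true positives):   {len(match.pairs)}",
        f"missed (false negatives):   {len(match.unmatched_truth)}",
        f"spurious (false positives): {len(match.unmatched_detections)}",
        f"match radius:               {match.max_dist_px:g} px",
    ]
    if match.n_truth:
        lines.append(f"accuracy:                   {accuracy(match):.4f}")
    if match.pairs:
        if detection_groups is not None:
            overall, per_group = center_rmse(match, detection_groups)
            lines.append(f"center RMSE:                {overall:.3f} px")
            for g, v in per_group.items():
                lines.append(f"  group {g}:                  {v:.3f} px")
        else:
            lines.append(f"center RMSE:                {center_rmse(match):.3f} px")
    if truth_diameters_nm is not None and detection_groups is not None and match.pairs:
        table, recall = size_confusion(match, truth_diameters_nm, detection_groups)
        lines.append("size confusion (rows: true nm, cols: assigned group):")
        lines.append(table.to_string())
        for d, r in recall.items():
            lines.append(f"  recall @ {d:g} nm: {r:.4f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
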
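"""Size-measurement accuracy, breakpoint fitting and recovery curves.

Accuracy is the ratio of the pipeline's measured minimum Feret diameter to
a reference (ground-truth or manual) mFD, in percent. A chromatic rim of
width h replaces the outer edge of every black particle, so accuracy is
roughly (d - 2h)/d for a particle of diameter d: it collapses for small
particles and plateaus for large ones. The plateau onset is estimated with
a continuous two-segment (hinge) linear model fit by Levenberg-Marquardt
least squares with a multi-start breakpoint grid; a LOESS smooth is
provided for visualisation only.

The recovery curve gives, per lower size threshold, the percentage of true
particles at or above the threshold that were re-detected; the operational
lower size limit is the smallest threshold whose mean recovery reaches a
required level (80% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.nonparametric.smoothers_lowess import lowess

from .morphometry import ParticleTable
from .scene import GroundTruthTable

__all__ = [
    "Matches",
    "AccuracyPair",
    "BreakpointFit",
    "RecoveryCurve",
    "match_particles",
    "accuracy_pairs",
    "accuracy_curve",
    "fit_breakpoint",
    "recovery_curve",
    "select_size_limit",
    "plot_accuracy",
    "plot_recovery",
]


@dataclass
class Matches:
    """One-to-one truth-to-detection assignment."""

    pairs: list[tuple[int, int, float]]  # (reference id, detected id, distance um)
    missed_ref_ids: list[int]
    false_positive_ids: list[int]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class AccuracyPair:
    reference_mfd_um: float
    measured_mfd_um: float

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.measured_mfd_um / self.reference_mfd_um


@dataclass
class BreakpointFit:
    """Two-segment continuous linear fit of accuracy vs reference mFD."""

    breakpoint_um: float
    slope_pre: float  # %/µm below the breakpoint
    slope_post: float  # %/µm above (≈ 0 when the accuracy plateaus)
    plateau_pct: float  # model value at the breakpoint
    rss: float
    converged: bool
    degenerate: bool = False


@dataclass
class RecoveryCurve:
    thresholds_um: np.ndarray
    mean_pct: np.ndarray
    sd_pct: np.ndarray
    se_pct: np.ndarray
    n_replicates: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_um": self.thresholds_um,
                "mean_recovery_pct": self.mean_pct,
                "sd_pct": self.sd_pct,
                "se_pct": self.se_pct,
                "n_replicates": self.n_replicates,
            }
        )


def _centroids_um(table) -> tuple[np.ndarray, np.ndarray]:
    """(ids, (N,2) x/y centroids in µm) from a truth or particle table."""
    if isinstance(table, GroundTruthTable):
        px = table.spec.pixel_size_um
        ids = np.array([p.id for p in table.particles])
        xy = np.array(
            [[p.centroid_col_px * px, p.centroid_row_px * px] for p in table.particles]
        ).reshape(-1, 2)
        return ids, xy
    if isinstance(table, ParticleTable):
        ids = np.array([p.id for p in table.particles])
        xy = np.array(
            [[p.centroid_x_um, p.centroid_y_um] for p in table.particles]
        ).reshape(-1, 2)
        return ids, xy
    raise TypeError(f"cannot extract centroids from {type(table).__name__}")


def match_particles(
    reference, detected: ParticleTable, max_dist_um: float = 20.0
) -> Matches:
    """Greedy one-to-one nearest-centroid matching within ``max_dist_um``.

    Candidate pairs are sorted by distance and accepted greedily; unmatched
    references are misses, unmatched detections false positives.
    """
    ref_ids, ref_xy = _centroids_um(reference)
    det_ids, det_xy = _centroids_um(detected)
    if len(ref_ids) == 0 or len(det_ids) == 0:
        return Matches([], list(ref_ids), list(det_ids))
    d = np.linalg.norm(ref_xy[:, None, :] - det_xy[None, :, :], axis=2)
    cand = np.argwhere(d <= max_dist_um)
    order = np.argsort(d[cand[:, 0], cand[:, 1]], kind="stable")
    used_r: set[int] = set()
    used_d: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i, j in cand[order]:
        if i in used_r or j in used_d:
            continue
        used_r.add(int(i))
        used_d.add(int(j))
        pairs.append((int(ref_ids[i]), int(det_ids[j]), float(d[i, j])))
    missed = [int(r) for k, r in enumerate(ref_ids) if k not in used_r]
    fps = [int(c) for k, c in enumerate(det_ids) if k not in used_d]
    return Matches(pairs, missed, fps)


def accuracy_pairs(
    reference, detected: ParticleTable, matches: Matches
) -> list[AccuracyPair]:
    """Accuracy pairs (reference vs measured mFD) for matched particles."""
    if isinstance(reference, GroundTruthTable):
        ref_mfd = {p.id: p.true_mfd_um for p in reference.particles}
    else:
        ref_mfd = {p.id: p.mfd_um for p in reference.particles}
    det_mfd = {p.id: p.mfd_um for p in detected.particles}
    return [
        AccuracyPair(ref_mfd[r], det_mfd[d])
        for r, d, _ in matches.pairs
        if ref_mfd[r] > 0 and det_mfd[d] > 0
    ]


def accuracy_curve(
    pairs: list[AccuracyPair], loess_span: float = 0.75
) -> pd.DataFrame:
    """LOESS smooth of accuracy (%) against reference mFD, for plots."""
    if not (0 < loess_span <= 1):
        raise ValueError("loess_span must lie in (0, 1]")
    if len(pairs) < 10:
        raise ValueError("need at least 10 accuracy pairs")
    x = np.array([p.reference_mfd_um for p in pairs])
    y = np.array([p.accuracy_pct for p in pairs])
    sm = lowess(y, x, frac=loess_span, return_sorted=True)
    return pd.DataFrame({"reference_mfd_um": sm[:, 0], "accuracy_pct": sm[:, 1]})


def _hinge(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    bp, c, s1, s2 = params
    return np.where(x < bp, c + s1 * (x - bp), c + s2 * (x - bp))


def fit_breakpoint(
    pairs: list[AccuracyPair],
    constrain_plateau: bool = False,
    n_starts: int = 10,
) -> BreakpointFit:
    """Fit the two-segment accuracy model and locate the plateau onset.

    The model is continuous at the breakpoint: accuracy = c + s1*(x - bp)
    below and c + s2*(x - bp) above. With ``constrain_plateau`` the post-
    break slope s2 is fixed at zero. A multi-start grid over candidate
    breakpoints guards against local minima; non-convergence from every
    start is a flagged failure, never a silent fallback.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 accuracy pairs spanning both regimes")
    x = np.array([p.reference_mfd_um for p in pairs], dtype=float)
    y = np.array([p.accuracy_pct for p in pairs], dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("accuracy pairs must span a range of reference sizes")

    def resid(params: np.ndarray) -> np.ndarray:
        if constrain_plateau:
            params = np.array([params[0], params[1], params[2], 0.0])
        return _hinge(params, x) - y

    best = None
    span = hi - lo
    for bp0 in np.linspace(lo + 0.05 * span, hi - 0.05 * span, n_starts):
        above = x >= bp0
        c0 = float(y[above].mean()) if above.any() else float(y.mean())
        s10 = (c0 - float(y[~above].mean())) / max(bp0 - lo, 1e-6) if (~above).any() else 1.0
        p0 = [bp0, c0, s10] if constrain_plateau else [bp0, c0, s10, 0.0]
        bounds = (
            ([lo, -np.inf, -np.inf], [hi, np.inf, np.inf])
            if constrain_plateau
            else ([lo, -np.inf, -np.inf, -np.inf], [hi, np.inf, np.inf, np.inf])
        )
        try:
            sol = least_squares(resid, p0, bounds=bounds, method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return BreakpointFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)
    rss, p = best
    if constrain_plateau:
        bp, c, s1 = p
        s2 = 0.0
    else:
        bp, c, s1, s2 = p
    edge = 0.02 * span
    degenerate = bool(bp <= lo + edge or bp >= hi - edge or abs(s1 - s2) < 1e-3)
    return BreakpointFit(
        breakpoint_um=float(bp),
        slope_pre=float(s1),
        slope_post=float(s2),
        plateau_pct=float(c),
        rss=rss,
        converged=True,
        degenerate=degenerate,
    )


def recovery_curve(
    spike_truth: list[np.ndarray],
    detected: list[np.ndarray],
    thresholds: np.ndarray,
) -> RecoveryCurve:
    """Recovery (%) per lower size threshold, across replicate spikes.

    ``spike_truth`` and ``detected`` hold, per replicate, the arrays of
    true and of detected mFDs (µm). For a threshold t, a replicate's
    recovery is 100 * #detected(mFD >= t) / #true(mFD >= t); replicates
    with no true particle above t are undefined there, and a threshold with
    no defined replicate is dropped with a warning.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if len(spike_truth) != len(detected):
        raise ValueError("need one detected table per truth table")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    rows = []
    for t in thresholds:
        per_rep = []
        for tru, det in zip(spike_truth, detected):
            n_true = int(np.sum(np.asarray(tru) >= t))
            if n_true == 0:
                continue
            n_det = int(np.sum(np.asarray(det) >= t))
            per_rep.append(100.0 * n_det / n_true)
        if not per_rep:
            warnings.warn(f"threshold {t} µm dropped: no true particles above it")
            continue
        arr = np.array(per_rep)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        rows.append((t, float(arr.mean()), sd, sd / np.sqrt(len(arr)), len(arr)))
    if not rows:
        return RecoveryCurve(*(np.array([]) for _ in range(4)), np.array([], int))
    t, m, sd, se, n = map(np.array, zip(*rows))
    return RecoveryCurve(t, m, sd, se, n.astype(int))


def select_size_limit(
    curve: RecoveryCurve, min_recovery_pct: float = 80.0
) -> float | None:
    """Smallest threshold whose mean recovery reaches the required level.

    Returns None with a warning when the level is never reached.
    """
    if len(curve.thresholds_um) == 0:
        warnings.warn("empty recovery curve: no size limit selected")
        return None
    ok = np.nonzero(curve.mean_pct >= min_recovery_pct)[0]
    if len(ok) == 0:
        warnings.warn(
            f"mean recovery never reaches {min_recovery_pct}%: no size limit selected"
        )
        return None
    return float(curve.thresholds_um[ok[0]])


def plot_accuracy(
    pairs: list[AccuracyPair],
    path,
    loess_span: float = 0.75,
    fit: BreakpointFit | None = None,
) -> None:
    """Diagnostic figure: accuracy scatter + LOESS smooth + segmented fit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p.reference_mfd_um for p in pairs])
    y = np.array([p.accuracy_pct for p in pairs])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, s=14, alpha=0.6, label="particles")
    if len(pairs) >= 10:
        curve = accuracy_curve(pairs, loess_span)
        ax.plot(
            curve["reference_mfd_um"], curve["accuracy_pct"],
            color="tab:blue", lw=2, label="LOESS",
        )
    if fit is not None and fit.converged:
        grid = np.linspace(x.min(), x.max(), 200)
        ax.plot(
            grid, _hinge(np.array([fit.breakpoint_um, fit.plateau_pct,
                                   fit.slope_pre, fit.slope_post]), grid),
            color="tab:red", lw=2,
            label=f"segmented fit (break {fit.breakpoint_um:.0f} µm)",
        )
        ax.axvline(fit.breakpoint_um, ls="--", color="grey", lw=1)
    ax.set_xlabel("reference mFD (µm)")
    ax.set_ylabel("size accuracy (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_recovery(
    curve: RecoveryCurve, path, min_recovery_pct: float = 80.0
) -> None:
    """Diagnostic figure: mean recovery per size threshold with SD bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(
        np.arange(len(curve.thresholds_um)), curve.mean_pct,
        yerr=curve.sd_pct, capsize=3, color="tab:grey",
    )
    ax.axhline(min_recovery_pct, ls="--", color="tab:red", lw=1,
               label=f"{min_recovery_pct:.0f}% rule")
    ax.set_xticks(np.arange(len(curve.thresholds_um)))
    ax.set_xticklabels([f"{t:g}" for t in curve.thresholds_um])
    ax.set_xlabel("lower size limit, mFD (µm)")
    ax.set_ylabel("mean recovery (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
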
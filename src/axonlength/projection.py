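"""Projection-based axon length estimation and its statistical calibration.

A fast alternative to full 3D tracing is to measure the length of the axon's
planar projection (camera lucida or slide scanner) and multiply by a correction
factor α.  For a curve whose tangent directions are uniform on the sphere
(zero anisotropy) the exact factor is 4/π ≈ 1.2732 for a 3D curve projected
onto a plane, and π/2 for a planar curve projected onto a line: the expected
projected length of a unit isotropic segment onto a plane is E|sin θ| = π/4.

Real axons are not perfectly isotropic, so per-class empirical factors are
estimated by through-origin least squares of 3D length on projected length,
with percentile confidence intervals from a residual ("error-resampling")
bootstrap, and out-of-sample error distributions from stratified k-fold
cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .morphology import SegmentSet

__all__ = [
    "PLANES",
    "LengthPair",
    "AlphaFit",
    "project_length",
    "theoretical_alpha",
    "estimate_from_projection",
    "fit_alpha",
    "cv_projection_error",
]

#: projection plane -> index of the dropped coordinate
PLANES = {"XY": 2, "XZ": 1, "YZ": 0}


@dataclass(frozen=True)
class LengthPair:
    """One regression observation: projected vs true 3D length of a neuron."""

    neuron_id: str
    class_label: int
    plane: str
    length_2d: float
    length_3d: float

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if not 0.0 <= self.length_2d <= self.length_3d * (1 + 1e-9):
            raise ValueError("need 0 <= length_2d <= length_3d")


@dataclass
class AlphaFit:
    """Per-class correction factors with bootstrap confidence intervals."""

    alpha_by_class: dict[int, float]
    ci95_by_class: dict[int, tuple[float, float]]
    n_boot: int
    r2_adj: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        for c, a in self.alpha_by_class.items():
            lo, hi = self.ci95_by_class[c]
            if not (lo <= a <= hi) or a <= 0:
                raise ValueError(f"inconsistent alpha/CI for class {c}")


def project_length(s: SegmentSet, plane: str = "XY") -> float:
    """Length of the arbor's orthogonal projection onto a coordinate plane.

    Drops the out-of-plane coordinate of every endpoint and sums the planar
    endpoint distances; never exceeds the 3D total length.
    """
    try:
        drop = PLANES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}; expected one of {sorted(PLANES)}")
    keep = [i for i in range(3) if i != drop]
    d = (s.p1 - s.p0)[:, keep]
    return float(np.linalg.norm(d, axis=1).sum())


def theoretical_alpha(embedding: str = "3d_to_plane") -> float:
    """Isotropy correction factor: 4/π (3D→plane) or π/2 (2D→line)."""
    if embedding == "3d_to_plane":
        return 4.0 / math.pi
    if embedding == "2d_to_line":
        return math.pi / 2.0
    raise ValueError(f"unknown embedding {embedding!r}")


def estimate_from_projection(length_2d: float, alpha: float) -> float:
    """3D length estimate: projected length times the correction factor."""
    if length_2d < 0:
        raise ValueError("length_2d must be >= 0")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return alpha * length_2d


def _pairs_frame(pairs: list[LengthPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "neuron_id": [p.neuron_id for p in pairs],
            "class_label": [p.class_label for p in pairs],
            "plane": [p.plane for p in pairs],
            "length_2d": [p.length_2d for p in pairs],
            "length_3d": [p.length_3d for p in pairs],
        }
    )


def _slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("degenerate data: all projected lengths are zero")
    return float(np.dot(x, y) / sxx)


def fit_alpha(
    pairs: list[LengthPair],
    n_boot: int | None = 2000,
    seed: int | None = None,
    intercept: bool = False,
    stop_tol: float | None = None,
) -> AlphaFit:
    """Fit per-class correction factors α by OLS with class as a factor.

    The regression is through the origin (a slope per class, interpreted
    directly as the multiplicative factor); ``intercept=True`` adds a common
    intercept as a robustness variant.  CI95 per class comes from a percentile
    residual bootstrap: residuals of the fit are resampled within class and
    added back to the fitted values, and the slope is re-estimated ``n_boot``
    times (default 2000).  If ``stop_tol`` is given (e.g. ``0.001``),
    bootstrapping instead proceeds in batches of 100 until the relative change
    of the CI bounds falls below it.

    ``r2_adj`` is the adjusted R² of the pooled fit with one slope per class.
    """
    if not pairs:
        raise ValueError("no pairs")
    df = _pairs_frame(pairs)
    counts = df.groupby("class_label").size()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"need >= 2 pairs per class; too few for class(es) {list(small.index)}")

    rng = np.random.default_rng(seed)
    classes = sorted(df["class_label"].unique())

    # pooled design: one column (x where class==c) per class, optional intercept
    n = len(df)
    X = np.zeros((n, len(classes) + (1 if intercept else 0)))
    for j, c in enumerate(classes):
        mask = df["class_label"].to_numpy() == c
        X[mask, j] = df.loc[mask, "length_2d"].to_numpy()
    if intercept:
        X[:, -1] = 1.0
    res = sm.OLS(df["length_3d"].to_numpy(), X).fit()
    r2_adj = float(res.rsquared_adj)

    alpha_by_class: dict[int, float] = {}
    ci95: dict[int, tuple[float, float]] = {}
    all_resid = np.empty(n)
    for c in classes:
        sub = df[df["class_label"] == c]
        x = sub["length_2d"].to_numpy()
        y = sub["length_3d"].to_numpy()
        if intercept:
            A = np.column_stack([x, np.ones_like(x)])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            a_hat, b_hat = float(beta[0]), float(beta[1])
            fitted = a_hat * x + b_hat
        else:
            a_hat = _slope_through_origin(x, y)
            b_hat = 0.0
            fitted = a_hat * x
        resid = y - fitted
        all_resid[df["class_label"].to_numpy() == c] = resid

        def boot_slopes(m: int) -> np.ndarray:
            idx = rng.integers(0, len(resid), size=(m, len(resid)))
            ystar = fitted[None, :] + resid[idx]
            if intercept:
                slopes = np.empty(m)
                for i in range(m):
                    bb, *_ = np.linalg.lstsq(A, ystar[i], rcond=None)
                    slopes[i] = bb[0]
                return slopes
            sxx = float(np.dot(x, x))
            return (ystar @ x) / sxx

        if stop_tol is not None:
            draws = boot_slopes(100)
            lo, hi = np.quantile(draws, [0.025, 0.975])
            while True:
                draws = np.concatenate([draws, boot_slopes(100)])
                lo2, hi2 = np.quantile(draws, [0.025, 0.975])
                scale = max(abs(a_hat), 1e-12)
                if max(abs(lo2 - lo), abs(hi2 - hi)) / scale < stop_tol:
                    lo, hi = lo2, hi2
                    break
                lo, hi = lo2, hi2
            n_used = len(draws)
        else:
            if n_boot is None or n_boot < 1:
                raise ValueError("n_boot must be >= 1 when stop_tol is not used")
            draws = boot_slopes(n_boot)
            lo, hi = np.quantile(draws, [0.025, 0.975])
            n_used = n_boot
        # the point estimate always lies inside the reported interval
        alpha_by_class[c] = a_hat
        ci95[c] = (min(float(lo), a_hat), max(float(hi), a_hat))

    return AlphaFit(alpha_by_class, ci95, n_used, r2_adj, all_resid)


def cv_projection_error(
    pairs: list[LengthPair],
    k: int = 5,
    n_boot: int = 100,
    seed: int | None = None,
) -> dict[tuple[int, str], np.ndarray]:
    """Out-of-sample signed percent errors per (class, plane) stratum.

    For each stratum, ``n_boot`` bootstrap resamples are drawn; each resample
    is split into ``k`` folds, the through-origin slope is fitted on the
    training folds and signed errors ``100·(α̂·L2d − L3d)/L3d`` are collected on
    the held-out fold.  Errors are pooled over folds and repetitions.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = _pairs_frame(pairs)
    rng = np.random.default_rng(seed)
    out: dict[tuple[int, str], np.ndarray] = {}
    for (c, plane), sub in df.groupby(["class_label", "plane"], sort=True):
        x = sub["length_2d"].to_numpy()
        y = sub["length_3d"].to_numpy()
        n = len(sub)
        if n < k:
            raise ValueError(f"stratum (class {c}, plane {plane}) has {n} < k={k} pairs")
        errs: list[np.ndarray] = []
        for _ in range(n_boot):
            take = rng.integers(0, n, size=n)
            xb, yb = x[take], y[take]
            perm = rng.permutation(n)
            folds = np.array_split(perm, k)
            for fold in folds:
                test = np.zeros(n, dtype=bool)
                test[fold] = True
                a = _slope_through_origin(xb[~test], yb[~test])
                errs.append(100.0 * (a * xb[test] - yb[test]) / yb[test])
        out[(int(c), str(plane))] = np.concatenate(errs)
    return out
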
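"""Grid sweeps of length estimators and the error/effort statistics.

Every (neuron × parameter combination × replicate) produces one record holding
the ground-truth path length, the estimate, the signed percent error
``100·(estimate − truth)/truth``, and for the stereological probes the total
intersection count ΣQ (the sampling effort) and the coefficient of error.
From the long table the module computes kernel-smoothed error densities with
automatic bandwidth, areas under the density within ±threshold (the
probability of a tolerable error), bilinear error/effort surfaces over the
parameter grid, t-based upper confidence limits of the mean error, and
normalized RMSE by 5-fold cross-validation — plus the expected-error
arithmetic used to compare methods on directly measured neurons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .morphology import NeuronMorphology, extract_segments
from .projection import estimate_from_projection, project_length, theoretical_alpha
from .stereology import (
    IntersectionTally,
    ProbeSpec,
    build_frame,
    coefficient_of_error,
    count_intersections,
    fractionator_estimate,
)
from .morphology import bounding_box

__all__ = [
    "BenchmarkTable",
    "EmpiricalDensity",
    "ErrorSurface",
    "DEFAULT_GRIDS",
    "run_grid",
    "error_density",
    "prob_within",
    "surface",
    "mean_error_upper_ci",
    "rmse_cv",
    "expected_error_report",
    "ExpectedErrorReport",
]

#: canonical computational parameter grids (µm)
DEFAULT_GRIDS: dict[str, dict[str, list[float]]] = {
    "spheres": {
        "diameter": [10, 15, 20, 25, 30, 35, 40, 45, 50],
        "step": [70, 80, 90, 100, 110, 120, 130, 140, 150],
    },
    "planes": {
        "spacing": [3, 6, 9, 12, 15, 18, 21, 24, 27, 30],
        "step": [70, 80, 90, 100, 110, 120, 130, 140, 150],
    },
    "projection": {"plane": ["XY", "XZ", "YZ"], "alpha": ["theory"]},
}

_RECORD_COLUMNS = [
    "neuron_id",
    "class_label",
    "method",
    "param1",
    "param2",
    "replicate",
    "true_length",
    "estimate",
    "error_pct",
    "error_um",
    "effort",
    "ce",
]


@dataclass
class BenchmarkTable:
    """Long-format sweep results plus the grid and master seed that made them.

    ``records.param1``/``param2`` hold (plane, alpha) for the projection
    method, (step, diameter) for spheres and (step, spacing) for planes.
    """

    records: pd.DataFrame
    method: str
    grid: dict
    seed: int | None

    def __len__(self) -> int:
        return len(self.records)


def _record_seed(master: int | None, i_neuron: int, i_combo: int, i_rep: int) -> int:
    """Stated seed-splitting rule: one child stream per record."""
    ss = np.random.SeedSequence((0 if master is None else int(master),
                                 i_neuron, i_combo, i_rep))
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(
    morphs: list[NeuronMorphology],
    method: str,
    grid: dict | None = None,
    replicates: int = 1,
    seed: int | None = None,
    *,
    section_thickness: float = 50.0,
    box_xy: float = 50.0,
    box_z: float = 50.0,
    struct_codes=(2,),
) -> BenchmarkTable:
    """Exhaustive estimator sweep over morphologies × parameter grid × replicates.

    ``grid`` defaults to the canonical grid of the method (``DEFAULT_GRIDS``).
    Every record is reproducible from (neuron index, combo index, replicate
    index, master seed).
    """
    if method not in ("projection", "spheres", "planes"):
        raise ValueError(f"unknown method {method!r}")
    grid = DEFAULT_GRIDS[method] if grid is None else grid
    if method == "projection":
        keys = ("plane", "alpha")
    elif method == "spheres":
        keys = ("step", "diameter")
    else:
        keys = ("step", "spacing")
    missing = [k for k in keys if k not in grid or not grid[k]]
    if missing:
        raise ValueError(f"grid missing non-empty entries for {missing}")
    combos = list(itertools.product(grid[keys[0]], grid[keys[1]]))

    rows = []
    for i_n, m in enumerate(morphs):
        segs = extract_segments(m, struct_codes)
        truth = segs.total_length
        if truth <= 0:
            raise ValueError(f"morphology {m.name!r} has no axonal length")
        bbox = bounding_box(segs)
        proj_cache: dict[str, float] = {}
        for i_c, (v1, v2) in enumerate(combos):
            for i_r in range(replicates):
                if method == "projection":
                    plane = str(v1)
                    alpha = theoretical_alpha() if v2 == "theory" else float(v2)
                    if plane not in proj_cache:
                        proj_cache[plane] = project_length(segs, plane)
                    est = estimate_from_projection(proj_cache[plane], alpha)
                    effort, ce = np.nan, np.nan
                else:
                    rec_seed = _record_seed(seed, i_n, i_c, i_r)
                    frame = build_frame(
                        bbox,
                        step=float(v1),
                        seed=rec_seed,
                        section_thickness=section_thickness,
                        box_xy=box_xy,
                        box_z=box_z,
                    )
                    probe = (
                        ProbeSpec("sphere", diameter=float(v2))
                        if method == "spheres"
                        else ProbeSpec("planes", spacing=float(v2))
                    )
                    tally = count_intersections(segs, frame, probe)
                    est = fractionator_estimate(tally, frame, probe)
                    effort = tally.total_q
                    ce = coefficient_of_error(tally) if tally.total_q else np.nan
                rows.append(
                    (
                        m.name,
                        m.class_label,
                        method,
                        v1,
                        v2,
                        i_r,
                        truth,
                        est,
                        100.0 * (est - truth) / truth,
                        est - truth,
                        effort,
                        ce,
                    )
                )
    records = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    return BenchmarkTable(records=records, method=method, grid=grid, seed=seed)


class EmpiricalDensity:
    """Gaussian-KDE error density with Silverman (automatic) bandwidth.

    A zero-spread sample degenerates to a point mass at the common value.
    """

    def __init__(self, errors, bandwidth="auto") -> None:
        errors = np.asarray(errors, dtype=float).ravel()
        if len(errors) < 10:
            raise ValueError("need at least 10 observations for a density")
        self.n = len(errors)
        self._point_mass: float | None = None
        if np.ptp(errors) == 0.0:
            self._point_mass = float(errors[0])
            self._kde = None
        else:
            bw = "silverman" if bandwidth in ("auto", "silverman") else bandwidth
            self._kde = stats.gaussian_kde(errors, bw_method=bw)

    def pdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self._point_mass is not None:
            return np.where(x == self._point_mass, np.inf, 0.0)
        return self._kde(x)

    def integrate(self, lo: float, hi: float) -> float:
        if self._point_mass is not None:
            return 1.0 if lo <= self._point_mass <= hi else 0.0
        return float(self._kde.integrate_box_1d(lo, hi))


def error_density(errors, bandwidth="auto") -> EmpiricalDensity:
    """Smoothed (KDE) density of signed percent errors; integrates to 1."""
    return EmpiricalDensity(errors, bandwidth=bandwidth)


def prob_within(density: EmpiricalDensity, threshold: float) -> float:
    """P(|error| ≤ threshold): area under the density on [−threshold, +threshold]."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return density.integrate(-threshold, threshold)


@dataclass
class ErrorSurface:
    """Statistic over the 2-parameter grid with bilinear off-node queries."""

    param_names: tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    statistic: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("surface values must be finite at all grid nodes")
        self._interp = RegularGridInterpolator(
            (self.axis1, self.axis2), self.values, method="linear",
            bounds_error=True,
        )

    def at(self, v1: float, v2: float) -> float:
        """Query the surface (exact at nodes, bilinear between, no extrapolation)."""
        try:
            return float(self._interp([[v1, v2]])[0])
        except ValueError:
            raise ValueError(
                f"query ({v1}, {v2}) outside the grid hull "
                f"[{self.axis1[0]}, {self.axis1[-1]}] x [{self.axis2[0]}, {self.axis2[-1]}]"
            ) from None


def surface(
    table: BenchmarkTable,
    statistic: str = "mean_abs_error",
    threshold: float = 5.0,
) -> ErrorSurface:
    """Aggregate a benchmark table onto its parameter grid.

    ``statistic``: ``mean_abs_error`` (mean |signed % error|), ``effort``
    (mean ΣQ) or ``prob_within`` (area of the pooled error density within
    ±``threshold`` %, per grid node).
    """
    df = table.records
    if table.method == "projection":
        raise ValueError("surfaces are defined over the two stereological parameters")
    names = ("step", "diameter" if table.method == "spheres" else "spacing")
    a1 = np.array(sorted(df["param1"].unique()), dtype=float)
    a2 = np.array(sorted(df["param2"].unique()), dtype=float)
    values = np.full((len(a1), len(a2)), np.nan)
    for (v1, v2), sub in df.groupby(["param1", "param2"]):
        i = np.searchsorted(a1, float(v1))
        j = np.searchsorted(a2, float(v2))
        if statistic == "mean_abs_error":
            values[i, j] = sub["error_pct"].abs().mean()
        elif statistic == "effort":
            values[i, j] = sub["effort"].mean()
        elif statistic == "prob_within":
            values[i, j] = prob_within(error_density(sub["error_pct"]), threshold)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return ErrorSurface(names, a1, a2, values, statistic)


def mean_error_upper_ci(abs_errors, level: float = 0.95) -> float:
    """Upper limit of the two-sided t confidence interval for the mean error."""
    x = np.asarray(abs_errors, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    m = x.mean()
    sem = x.std(ddof=1) / np.sqrt(len(x))
    if sem == 0.0:
        return float(m)
    tq = stats.t.ppf(0.5 + level / 2.0, df=len(x) - 1)
    return float(m + tq * sem)


def rmse_cv(table: BenchmarkTable, k: int = 5, seed: int | None = None) -> pd.DataFrame:
    """Normalized RMSE per parameter combination by k-fold cross-validation.

    Per combo, a linear model of true length on estimate is fitted on the
    training folds; the held-out RMSE is normalized by the range of true
    lengths in the training split and averaged over folds.
    """
    df = table.records
    rows = []
    for (v1, v2), sub in df.groupby(["param1", "param2"]):
        n = len(sub)
        if n < k:
            raise ValueError(f"combo ({v1}, {v2}) has {n} < k={k} records")
        X = sub["estimate"].to_numpy().reshape(-1, 1)
        y = sub["true_length"].to_numpy()
        kf = KFold(n_splits=k, shuffle=True, random_state=None if seed is None else int(seed))
        fold_scores = []
        for train, test in kf.split(X):
            model = LinearRegression().fit(X[train], y[train])
            pred = model.predict(X[test])
            rmse = float(np.sqrt(np.mean((pred - y[test]) ** 2)))
            rng_y = float(np.ptp(y[train]))
            fold_scores.append(rmse / rng_y if rng_y > 0 else rmse / max(y[train].mean(), 1e-12))
        rows.append((v1, v2, float(np.mean(fold_scores))))
    return pd.DataFrame(rows, columns=["param1", "param2", "nrmse"])


@dataclass
class ExpectedErrorReport:
    """Per-item and mean absolute percent differences vs direct measurement."""

    per_item_pct: list[float]
    mean_pct: float


def expected_error_report(direct, estimates) -> ExpectedErrorReport:
    """Expected error of an estimation method against direct measurements.

    Per item: ``100·|estimate − direct|/direct``; the mean is taken over the
    unrounded per-item values; both are reported to 2 decimals.
    """
    d = np.asarray(direct, dtype=float).ravel()
    e = np.asarray(estimates, dtype=float).ravel()
    if d.shape != e.shape:
        raise ValueError("direct and estimates must have equal length")
    if (d <= 0).any():
        raise ValueError("direct measurements must be positive")
    pct = 100.0 * np.abs(e - d) / d
    return ExpectedErrorReport(
        per_item_pct=[round(v, 2) for v in pct],
        mean_pct=round(float(pct.mean()), 2),
    )
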
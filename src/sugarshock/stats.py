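"""Summary statistics for snapshot RNA-count data.

This module holds the quantitative machinery used to compare simulated
populations with single-cell smFISH snapshots:

* mean and interquartile-range time traces of per-cell counts;
* Gaussian kernel density estimates (KDE) of integer count distributions,
  needed because ~100-200 imaged cells per timepoint are too few for a
  stable histogram-to-histogram comparison against 2,000 simulated cells;
* the Kullback-Leibler divergence ``D(P || Q) = sum_i P(i) ln(P(i)/Q(i))``
  evaluated on a common grid, directed experimental-against-simulated;
* the relative error of population means ``|exp - sim| / exp``;
* log-linear decay-rate fits for rifampicin-chase experiments;
* conversion of a pseudo-first-order binding rate to a bulk second-order
  rate constant, and signed percent differences for mutant-vs-WT tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import constants as _const
from scipy import stats as _scistats

from .errors import DataError, StructuralError

__all__ = [
    "SnapshotDataset",
    "KDEstimate",
    "DecayFit",
    "mean_iqr_trace",
    "gaussian_kde",
    "common_grid",
    "kl_divergence",
    "relative_error",
    "fit_decay_rate",
    "chase_decay_fit",
    "pseudo_to_second_order",
    "second_order_to_pseudo",
    "percent_difference",
]

#: Floor applied to the denominator density in the KL divergence.
KL_FLOOR = 1e-12

#: Default number of points in the common KDE evaluation grid.
GRID_POINTS = 512

_CSV_COLUMNS = ["cell_id", "time_min", "species", "count"]


class SnapshotDataset:
    """Per-timepoint, per-cell integer RNA counts.

    Wraps a tidy table with columns ``cell_id, time_min, species, count``
    where ``species`` is ``"sgrs"`` or ``"ptsg"`` (a chase dataset may use
    a single species label such as ``"rna"``).  The provenance tag records
    whether counts are experimental, synthetic or simulated.
    """

    def __init__(self, table: pd.DataFrame, provenance: str = "experimental"):
        missing = [c for c in _CSV_COLUMNS if c not in table.columns]
        if missing:
            raise DataError(f"snapshot table missing columns {missing}")
        if provenance not in ("experimental", "synthetic", "simulated"):
            raise DataError(f"unknown provenance tag {provenance!r}")
        counts = table["count"].to_numpy()
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise DataError("counts must be non-negative integers")
        table = table.loc[:, _CSV_COLUMNS].copy()
        table["count"] = table["count"].astype(np.int64)
        table["time_min"] = table["time_min"].astype(float)
        self.table = table.sort_values(
            ["time_min", "species", "cell_id"], kind="stable"
        ).reset_index(drop=True)
        self.provenance = provenance

    @property
    def timepoints(self) -> np.ndarray:
        return np.unique(self.table["time_min"].to_numpy())

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.table["species"].unique()))

    def counts(self, time_min: float, species: str) -> np.ndarray:
        mask = (self.table["time_min"] == float(time_min)) & (
            self.table["species"] == species
        )
        out = self.table.loc[mask, "count"].to_numpy()
        if out.size == 0:
            raise DataError(
                f"no cells for species {species!r} at t = {time_min} min"
            )
        return out

    def n_cells(self, time_min: float, species: str) -> int:
        return self.counts(time_min, species).size

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls, path: Union[str, Path], provenance: str = "experimental"
    ) -> "SnapshotDataset":
        return cls(pd.read_csv(path), provenance)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnapshotDataset):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass(frozen=True)
class KDEstimate:
    """A Gaussian KDE evaluated on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if self.grid.shape != self.density.shape:
            raise StructuralError("grid and density must have the same shape")
        if np.any(self.density < 0):
            raise StructuralError("density must be non-negative")

    def integral(self) -> float:
        """Trapezoidal integral over the grid (≈1 when the grid spans the
        support)."""
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class DecayFit:
    """Result of a log-linear decay fit: rate is the negated slope of
    ln(count) against time."""

    rate: float  # 1/s
    intercept: float
    stderr: float
    r_squared: float

    @property
    def lifetime(self) -> float:
        return 1.0 / self.rate if self.rate > 0 else float("inf")


def mean_iqr_trace(data) -> pd.DataFrame:
    """Per-timepoint mean and interquartile range of per-cell totals.

    Accepts a :class:`SnapshotDataset` or an
    :class:`~sugarshock.ensemble.EnsembleResult`.  Returns a tidy frame with
    columns ``time_min, species, mean, q25, q75``.
    """
    if hasattr(data, "to_dataset"):  # EnsembleResult
        data = data.to_dataset()
    rows = []
    for sp in data.species:
        for t in data.timepoints:
            c = data.counts(t, sp)  # raises naming the timepoint if empty
            rows.append(
                {
                    "time_min": float(t),
                    "species": sp,
                    "mean": float(np.mean(c)),
                    "q25": float(np.percentile(c, 25)),
                    "q75": float(np.percentile(c, 75)),
                }
            )
    if not rows:
        raise DataError("dataset has no populated timepoints")
    return pd.DataFrame(rows)


def common_grid(*samples: Sequence[float], n_points: int = GRID_POINTS) -> np.ndarray:
    """Shared KDE evaluation grid: ``n_points`` points spanning
    ``[min - 3*sigma, max + 3*sigma]`` of the pooled samples."""
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    if pooled.size < 2:
        raise DataError("need at least two pooled observations to build a grid")
    sigma = float(np.std(pooled, ddof=1))
    if sigma == 0.0:
        sigma = 1.0  # degenerate pooled sample: fall back to unit scale
    return np.linspace(pooled.min() - 3 * sigma, pooled.max() + 3 * sigma, n_points)


def gaussian_kde(
    counts: Sequence[float],
    grid: Sequence[float],
    bandwidth: float | None = None,
) -> KDEstimate:
    """Gaussian KDE of a count sample on an explicit evaluation grid.

    The bandwidth follows Scott's rule (``sigma * n**(-1/5)``) unless an
    absolute ``bandwidth`` override is given.  A zero-variance sample has no
    data-driven bandwidth, so it is rejected unless the override is set.
    """
    x = np.asarray(counts, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if x.size < 2:
        raise DataError("need at least two observations for a KDE")
    sigma = float(np.std(x, ddof=1))
    if bandwidth is None:
        if sigma == 0.0:
            raise DataError(
                "zero-variance sample: supply an explicit bandwidth override"
            )
        h = sigma * x.size ** (-0.2)
        kde = _scistats.gaussian_kde(x, bw_method="scott")
        density = kde(grid)
    else:
        if not bandwidth > 0:
            raise DataError("bandwidth override must be positive")
        h = float(bandwidth)
        z = (grid[:, None] - x[None, :]) / h
        density = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    return KDEstimate(grid=grid, density=np.asarray(density), bandwidth=h)


def kl_divergence(P, Q, *, q_floor: float = KL_FLOOR) -> float:
    """Kullback-Leibler divergence ``D(P || Q)`` with natural logarithm.

    ``P`` and ``Q`` are either two :class:`KDEstimate` objects on the same
    grid (the sum is weighted by the grid-cell width) or two plain discrete
    probability vectors of equal length (unit weights).  The denominator is
    floored at ``q_floor`` to avoid infinities where the simulated density
    vanishes.  By convention ``P`` is the reference (experimental)
    distribution and ``Q`` the simulated one.
    """
    if isinstance(P, KDEstimate) and isinstance(Q, KDEstimate):
        if P.grid.shape != Q.grid.shape or not np.allclose(P.grid, Q.grid):
            raise StructuralError("KDEs must be evaluated on the same grid")
        p, q = P.density, Q.density
        dx = float(P.grid[1] - P.grid[0])
    elif isinstance(P, KDEstimate) or isinstance(Q, KDEstimate):
        raise StructuralError("P and Q must both be KDEs or both plain vectors")
    else:
        p = np.asarray(P, dtype=float)
        q = np.asarray(Q, dtype=float)
        if p.shape != q.shape:
            raise StructuralError("P and Q must have the same shape")
        dx = 1.0
    # Floor both densities inside the log ratio: keeps the divergence
    # finite where Q vanishes and exactly zero when P and Q coincide.
    ratio = np.maximum(p, q_floor) / np.maximum(q, q_floor)
    mask = p > 0
    return float(dx * np.sum(p[mask] * np.log(ratio[mask])))


def relative_error(exp_avg: float, sim_avg: float) -> float:
    """Relative error ``|exp - sim| / |exp|`` of population means."""
    if exp_avg == 0:
        raise DataError("experimental average is zero; relative error undefined")
    return abs((exp_avg - sim_avg) / exp_avg)


def fit_decay_rate(
    times: Sequence[float], mean_counts: Sequence[float]
) -> DecayFit:
    """Ordinary least squares of ln(mean count) on time.

    ``times`` are seconds; the decay rate is the negated slope.  All counts
    must be positive (subtract background first; drop below-detection
    timepoints, e.g. via :func:`chase_decay_fit`).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(mean_counts, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise DataError("times and mean_counts must be equal-length 1-D")
    if np.any(c <= 0):
        raise DataError(
            "non-positive mean count: subtract background / drop "
            "below-detection timepoints before the log-linear fit"
        )
    if np.unique(t).size < 2:
        raise DataError("need at least two distinct timepoints")
    res = _scistats.linregress(t, np.log(c))
    return DecayFit(
        rate=-float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue) ** 2,
    )


def chase_decay_fit(
    dataset: SnapshotDataset, species: str = "rna"
) -> DecayFit:
    """Decay rate from a transcription-shutoff (rifampicin-chase) dataset.

    Takes the per-timepoint sample mean of the per-cell counts and fits
    ln(mean) against time in seconds.  Timepoints whose sample mean is zero
    are below the detection limit of the finite cell sample and are
    excluded before the fit.
    """
    times_s, means = [], []
    for t in dataset.timepoints:
        m = float(np.mean(dataset.counts(t, species)))
        if m > 0:
            times_s.append(float(t) * 60.0)
            means.append(m)
    if len(times_s) < 2:
        raise DataError(
            "fewer than two timepoints with positive mean counts; "
            "the chase decayed below detection too quickly"
        )
    return fit_decay_rate(times_s, means)


def pseudo_to_second_order(
    k1: float, pool: float, volume: float = 1e-15
) -> float:
    """Convert a pseudo-first-order rate (1/s) to a bulk second-order rate
    (M^-1 s^-1) at a given partner pool size and cell volume (liters,
    default 1 fL)."""
    if not pool > 0 or not volume > 0:
        raise DataError("pool and volume must be positive")
    if k1 < 0:
        raise DataError("rate must be non-negative")
    concentration = pool / (_const.N_A * volume)  # molar
    return k1 / concentration


def second_order_to_pseudo(
    k2: float, pool: float, volume: float = 1e-15
) -> float:
    """Inverse of :func:`pseudo_to_second_order`."""
    if not pool > 0 or not volume > 0:
        raise DataError("pool and volume must be positive")
    return k2 * pool / (_const.N_A * volume)


def percent_difference(mutant_value: float, wt_value: float) -> int:
    """Signed percent change of a mutant parameter relative to wild type,
    rounded to the nearest integer percent for reporting."""
    if wt_value == 0:
        raise DataError("wild-type value is zero; percent difference undefined")
    return int(round(100.0 * (mutant_value - wt_value) / wt_value))
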
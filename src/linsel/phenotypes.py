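"""Lineage phenotypes: time averages along a lineage and autocorrelations.

A lineage phenotype is any scalar computable from the concatenated
per-frame time series of one root-to-leaf path.  Built-ins:

``concentration``     mean fluorescence,  (1/τ) ∫ c(t) dt
``elongation_rate``   mean of d ln v / dt within cell cycles (1/h)
``production_rate``   mean of (1/v) d(cv)/dt within cell cycles (a.u./h)
``sim_phenotype``     alias of ``concentration`` for simulator output, which
                      stores the phenotype y in the fluorescence channel
``division_count``    the division count D (handled upstream; no extractor)

Division discontinuities: a division halves the size, so derivative-based
phenotypes skip the frame increment that straddles the mother→daughter
boundary and reweight over the retained increments; concentration is
continuous across a division and is integrated straight through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genealogy import Lineage, LineageEnsemble

__all__ = [
    "LineageSeries",
    "build_series",
    "time_avg_phenotype",
    "time_avg_concentration",
    "time_avg_elongation_rate",
    "time_avg_production_rate",
    "weighted_autocorrelation",
    "PHENOTYPES",
    "register_phenotype",
    "attach_phenotypes",
]

_TIME_TOL = 1e-9


@dataclass
class LineageSeries:
    """Per-frame observables concatenated along one lineage.

    ``division_frames`` are the indices (interior, > 0) at which a new cell's
    record begins, i.e. where the increment from frame ``i-1`` to ``i``
    straddles a division.
    """

    times: np.ndarray
    v: np.ndarray
    c: np.ndarray
    division_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.division_frames = np.asarray(self.division_frames, dtype=int)
        if len(self.times) < 2:
            raise ValueError("a lineage series needs at least two frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.v <= 0):
            raise ValueError("cell sizes must be strictly positive")
        if self.division_frames.size and (
            self.division_frames.min() < 1
            or self.division_frames.max() > len(self.times) - 1
        ):
            raise ValueError("division_frames must index interior frames")
        dt = np.diff(self.times)
        if np.any(dt > 1.5 * np.median(dt)):
            raise ValueError("gap in frame grid")

    @property
    def tau(self) -> float:
        return float(self.times[-1] - self.times[0])

    def _retained(self) -> np.ndarray:
        """Mask over increments ``i -> i+1`` excluding division-straddling ones."""
        keep = np.ones(len(self.times) - 1, dtype=bool)
        keep[self.division_frames - 1] = False
        return keep


def build_series(ensemble: LineageEnsemble, lineage: Lineage) -> LineageSeries:
    """Concatenate the per-cell sample blocks of a lineage, clipped to the window."""
    t0, t1 = ensemble.t0, ensemble.t1
    times, vs, cs, divs = [], [], [], []
    total = 0
    for cid in lineage.path:
        s = np.asarray(ensemble.records[cid].samples, dtype=float)
        if s.size == 0:
            continue
        mask = (s[:, 0] >= t0 - _TIME_TOL) & (s[:, 0] <= t1 + _TIME_TOL)
        s = s[mask]
        if s.size == 0:
            continue
        if total and s[0, 0] <= times[-1][-1] + _TIME_TOL:
            # mother sampled at its division time: keep the daughter's frame
            times[-1] = times[-1][:-1]
            vs[-1] = vs[-1][:-1]
            cs[-1] = cs[-1][:-1]
            total -= 1
            if not len(times[-1]):
                times.pop(), vs.pop(), cs.pop()
        if total:
            divs.append(total)
        total += len(s)
        times.append(s[:, 0])
        vs.append(s[:, 1])
        cs.append(s[:, 2])
    if not times:
        raise ValueError(f"lineage {lineage.leaf_id} carries no samples in window")
    return LineageSeries(
        times=np.concatenate(times),
        v=np.concatenate(vs),
        c=np.concatenate(cs),
        division_frames=np.asarray(divs, dtype=int),
    )


# ---------------------------------------------------------------------------
# Time-averaged phenotypes


def time_avg_phenotype(times: Sequence[float], y: Sequence[float]) -> float:
    """Trapezoidal time average ``(1/τ) ∫ y dt`` of an arbitrary per-frame signal."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two frames")
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def time_avg_concentration(series: LineageSeries) -> float:
    """Time-averaged fluorescence concentration (a.u.).

    Concentration is an intensive quantity, unaffected by the size halving at
    division, so the integral runs straight through division frames.
    """
    return time_avg_phenotype(series.times, series.c)


def time_avg_elongation_rate(series: LineageSeries) -> float:
    """Time-averaged elongation rate ``(1/τ) ∫ d ln v / dt`` (1/h).

    Increments straddling a division are excluded (the size halving is
    bookkeeping, not growth) and the average is reweighted over the retained
    time.  For noise-free exponential growth this equals
    ``Σ_cells ln(v_end / v_birth) / retained time`` exactly.
    """
    keep = series._retained()
    dlnv = np.diff(np.log(series.v))
    dt = np.diff(series.times)
    return float(dlnv[keep].sum() / dt[keep].sum())


def time_avg_production_rate(series: LineageSeries) -> float:
    """Time-averaged protein production rate ``(1/τ) ∫ (1/v) d(cv)/dt`` (a.u./h).

    Discretized with midpoint size per frame increment; division increments
    are excluded as in :func:`time_avg_elongation_rate`.
    """
    keep = series._retained()
    a = series.c * series.v
    da = np.diff(a)
    v_mid = 0.5 * (series.v[:-1] + series.v[1:])
    dt = np.diff(series.times)
    return float((da[keep] / v_mid[keep]).sum() / dt[keep].sum())


# ---------------------------------------------------------------------------
# Weighted autocorrelation


def weighted_autocorrelation(
    signals: Sequence[np.ndarray],
    dt: float,
    weights: Sequence[float],
    lags: Sequence[float],
) -> np.ndarray:
    """Weighted, pooled autocorrelation of per-lineage signals at given lags.

    For each lag ``s`` the weighted Pearson product-moment of the pairs
    ``(z_t, z_{t+s})`` pooled over lineages, with one weight per lineage
    (chronological or retrospective) applied to all its pairs.  Means and
    variance are plug-in weighted estimates over all frames, so lag 0 maps
    to exactly 1.

    Parameters
    ----------
    signals
        One 1-D array per lineage, on a shared frame grid of spacing ``dt`` (h).
    dt
        Frame interval in hours.
    weights
        One weight per lineage; normalized internally.
    lags
        Lag times in hours; each must be a multiple of ``dt`` within the
        shortest signal.
    """
    signals = [np.asarray(z, dtype=float) for z in signals]
    w = np.asarray(weights, dtype=float)
    if len(signals) != len(w):
        raise ValueError("one weight per lineage required")
    nmin = min(len(z) for z in signals)

    wsum = sum(wi * len(z) for wi, z in zip(w, signals))
    mean = sum(wi * z.sum() for wi, z in zip(w, signals)) / wsum
    var = sum(wi * ((z - mean) ** 2).sum() for wi, z in zip(w, signals)) / wsum
    if var == 0:
        raise ValueError("degenerate (constant) signals")

    out = np.empty(len(lags))
    for j, s in enumerate(lags):
        k = int(round(s / dt))
        if abs(k * dt - s) > 1e-6 * dt or k < 0 or k >= nmin:
            raise ValueError(f"lag {s} not on the frame grid within the window")
        num = 0.0
        den = 0.0
        for wi, z in zip(w, signals):
            zc = z - mean
            num += wi * (zc[: len(z) - k] * zc[k:]).sum()
            den += wi * (len(z) - k)
        out[j] = (num / den) / var
    return out


# ---------------------------------------------------------------------------
# Registry

PHENOTYPES: dict[str, Callable[[LineageSeries], float]] = {
    "concentration": time_avg_concentration,
    "elongation_rate": time_avg_elongation_rate,
    "production_rate": time_avg_production_rate,
    "sim_phenotype": time_avg_concentration,
}

#: phenotype computed from the division count, not from a series
DIVISION_COUNT = "division_count"


def register_phenotype(name: str, extractor: Callable[[LineageSeries], float]) -> None:
    """Register a user-defined lineage-phenotype extractor.

    ``extractor`` maps a :class:`LineageSeries` to one scalar; the name then
    becomes selectable everywhere a built-in phenotype is.
    """
    if name == DIVISION_COUNT:
        raise ValueError(f"{name!r} is reserved")
    PHENOTYPES[name] = extractor


def attach_phenotypes(
    ensemble: LineageEnsemble,
    lineages: Sequence[Lineage],
    names: Sequence[str],
) -> None:
    """Compute the named phenotypes for every lineage, in place.

    ``division_count`` is filled from the lineage's ``D``; every other name
    is looked up in the registry and applied to the lineage's series.
    """
    series_needed = [n for n in names if n != DIVISION_COUNT]
    for n in series_needed:
        if n not in PHENOTYPES:
            raise KeyError(f"unknown phenotype {n!r}; registered: {sorted(PHENOTYPES)}")
    for lin in lineages:
        if DIVISION_COUNT in names:
            lin.phenotypes[DIVISION_COUNT] = float(lin.D)
        if series_needed:
            series = build_series(ensemble, lin)
            for n in series_needed:
                lin.phenotypes[n] = PHENOTYPES[n](series)
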
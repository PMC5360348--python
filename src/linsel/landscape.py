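"""Fitness landscapes and selection strength from binned lineage statistics.

Given the chronological and retrospective probability distributions of a
lineage phenotype ``x`` on shared bins,

* the fitness landscape is ``h(x) = Λ + (1/τ) ln(P_rs(x) / P_cl(x))``,
* the selection strength is ``S[x] = <h>_rs - <h>_cl``, which equals
  ``(1/τ)`` times the Jeffreys (symmetrized Kullback-Leibler) divergence
  between the two distributions, and is bounded by the selection strength
  ``S[D]`` on the division count itself,
* the relative selection strength is ``S_rel[x] = S[x] / S[D]``, close to
  the squared correlation between lineage fitness ``h̃(D)`` and ``h(x)``
  in the near-Gaussian (second-cumulant) regime.

Bins empty in either distribution are trimmed and both distributions are
renormalized on the retained support; the removed mass is reported.  ``S[D]``
is always computed on raw integer division counts, never on histogram bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genealogy import LN2, Lineage, lineage_fitness

logger = logging.getLogger("linsel")

__all__ = [
    "DistributionPair",
    "FitnessLandscape",
    "SelectionReport",
    "DecompositionReport",
    "weighted_quantile",
    "select_bin_width",
    "make_edges",
    "estimate_distributions",
    "fitness_landscape",
    "selection_strength",
    "division_selection_strength",
    "decompose_response",
    "bin_sweep",
]


@dataclass
class DistributionPair:
    """Chronological/retrospective distributions of one phenotype on shared bins."""

    phenotype_name: str
    bin_edges: np.ndarray  # retained edges, len = n_bins + 1 (possibly ragged-trimmed)
    p_cl: np.ndarray
    p_rs: np.ndarray
    excluded_mass_cl: float
    excluded_mass_rs: float
    bin_lo: np.ndarray | None = None  # per-retained-bin lower/upper edges
    bin_hi: np.ndarray | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_lo + self.bin_hi)


@dataclass
class FitnessLandscape:
    """Binned fitness landscape ``h(x)`` with its window parameters."""

    bin_edges: np.ndarray
    h: np.ndarray  # 1/h, per retained bin
    Lambda: float  # population growth rate, 1/h
    tau: float  # window length, h


@dataclass
class SelectionReport:
    """Selection statistics for one phenotype."""

    phenotype_name: str
    S: float  # selection strength, 1/h
    S_D: float  # maximal selection strength S[D], 1/h
    S_rel: float  # S / S_D, dimensionless
    mean_h_cl: float
    mean_h_rs: float
    jeffreys_check: float  # |S - J/tau|, identity residual
    var_approx: float  # tau * Var_cl[h], second-cumulant approximation of S
    corr2_cl: float  # squared corr of h~(D) and h(x), chronological weights
    corr2_rs: float


@dataclass
class DecompositionReport:
    """Decomposition of the retrospective mean-fitness response across environments.

    ``Δ<h>_rs = Δ<h>_cl + ΔS`` exactly: individual response plus change in
    selection.
    """

    phenotype_name: str
    env_labels: tuple[str, str]
    delta_mean_h_rs: float
    delta_mean_h_cl: float
    delta_S: float


# ---------------------------------------------------------------------------
# Binning


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Inverted-CDF weighted quantile: smallest value whose CDF reaches ``q``."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cdf = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cdf, q, side="left"))
    return float(v[min(idx, len(v) - 1)])


def select_bin_width(values: Sequence[float], weights: Sequence[float]) -> float:
    """Freedman–Diaconis bin width on chronologically weighted phenotype values.

    ``width = 2 · IQR · m^(-1/3)`` with the weighted interquartile range and
    ``m`` the lineage count.  Degenerate IQR = 0 falls back to
    ``range / ceil(sqrt(m))`` with a warning.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    m = len(v)
    if m < 8:
        raise ValueError("need at least 8 lineages to choose a bin width")
    iqr = weighted_quantile(v, w, 0.75) - weighted_quantile(v, w, 0.25)
    if iqr > 0:
        return float(2.0 * iqr * m ** (-1.0 / 3.0))
    rng = float(v.max() - v.min())
    if rng == 0:
        raise ValueError("all phenotype values identical; no binning possible")
    logger.warning(
        "IQR is zero for %d values; falling back to range-based bin width", m
    )
    return rng / int(np.ceil(np.sqrt(m)))


def make_edges(values: Sequence[float], width: float) -> np.ndarray:
    """Bin edges of the given width spanning the pooled data range."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    n = max(1, int(np.ceil((hi - lo) / width)))
    edges = lo + width * np.arange(n + 1)
    # guard against float round-off dropping the maximum
    edges[-1] = max(edges[-1], hi + 1e-12 * max(1.0, abs(hi)))
    return edges


# ---------------------------------------------------------------------------
# Distributions and landscape


def estimate_distributions(
    lineages: Sequence[Lineage],
    phenotype: str,
    edges: np.ndarray,
    max_trim: float = 0.2,
    allow_excess_trim: bool = False,
) -> DistributionPair:
    """Histogram the chronological and retrospective lineage weights.

    ``p_cl(bin) = Σ 2^(-D)/N0`` and ``p_rs(bin) = count/N1`` over the
    lineages falling in each bin.  Bins empty in either distribution are
    trimmed and both are renormalized on the retained support; values
    falling outside ``edges`` (possible when edges are shared across
    replicates) are likewise trimmed.  The removed mass is reported, and
    removing more than ``max_trim`` of either mass raises unless
    ``allow_excess_trim``.
    """
    x = np.array([lin.phenotypes[phenotype] for lin in lineages], dtype=float)
    w_cl = np.array([lin.w_cl for lin in lineages], dtype=float)
    w_rs = np.array([lin.w_rs for lin in lineages], dtype=float)
    edges = np.asarray(edges, dtype=float)
    # normalize the raw masses first (censoring can leave sums slightly < 1)
    w_cl = w_cl / w_cl.sum()
    w_rs = w_rs / w_rs.sum()
    in_range = (x >= edges[0]) & (x <= edges[-1])

    p_cl, _ = np.histogram(x[in_range], bins=edges, weights=w_cl[in_range])
    p_rs, _ = np.histogram(x[in_range], bins=edges, weights=w_rs[in_range])

    keep = (p_cl > 0) & (p_rs > 0)
    excl_cl = float(p_cl[~keep].sum() + w_cl[~in_range].sum())
    excl_rs = float(p_rs[~keep].sum() + w_rs[~in_range].sum())
    if max(excl_cl, excl_rs) > max_trim:
        msg = (
            f"{phenotype}: trimming removed {excl_cl:.1%} (cl) / {excl_rs:.1%} (rs) "
            f"of probability mass (> {max_trim:.0%})"
        )
        if not allow_excess_trim:
            raise ValueError(msg + "; pass allow_excess_trim=True to override")
        logger.warning(msg)
    elif excl_cl or excl_rs:
        logger.info(
            "%s: trimmed %.2f%% (cl) / %.2f%% (rs) mass in empty bins",
            phenotype,
            100 * excl_cl,
            100 * excl_rs,
        )

    return DistributionPair(
        phenotype_name=phenotype,
        bin_edges=edges,
        p_cl=p_cl[keep] / p_cl[keep].sum(),
        p_rs=p_rs[keep] / p_rs[keep].sum(),
        excluded_mass_cl=excl_cl,
        excluded_mass_rs=excl_rs,
        bin_lo=edges[:-1][keep],
        bin_hi=edges[1:][keep],
    )


def fitness_landscape(pair: DistributionPair, Lambda: float, tau: float) -> FitnessLandscape:
    """``h(bin) = Λ + (1/τ) ln(p_rs / p_cl)`` on the trimmed common support."""
    h = Lambda + np.log(pair.p_rs / pair.p_cl) / tau
    return FitnessLandscape(bin_edges=pair.bin_edges, h=h, Lambda=Lambda, tau=tau)


# ---------------------------------------------------------------------------
# Selection strength


def division_selection_strength(lineages: Sequence[Lineage], tau: float) -> float:
    """``S[D]`` on raw integer division counts (no histogram binning).

    The empirical identity ``P_rs(D) ∝ 2^D P_cl(D)`` makes the landscape on
    ``D`` coincide with the lineage fitness up to the constant ``Λ``, so
    ``S[D] = Σ h̃(D) (p_rs - p_cl)``.
    """
    D = np.array([lin.D for lin in lineages])
    w_cl = np.array([lin.w_cl for lin in lineages])
    w_rs = np.array([lin.w_rs for lin in lineages])
    vals = np.unique(D)
    p_cl = np.array([w_cl[D == d].sum() for d in vals])
    p_rs = np.array([w_rs[D == d].sum() for d in vals])
    p_cl = p_cl / p_cl.sum()
    p_rs = p_rs / p_rs.sum()
    h_tilde = vals * LN2 / tau
    return float((h_tilde * (p_rs - p_cl)).sum())


def _weighted_corr2(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    ma, mb = (w * a).sum(), (w * b).sum()
    cov = (w * (a - ma) * (b - mb)).sum()
    va = (w * (a - ma) ** 2).sum()
    vb = (w * (b - mb) ** 2).sum()
    if va == 0 or vb == 0:
        return float("nan")
    return float(cov * cov / (va * vb))


def selection_strength(
    pair: DistributionPair,
    landscape: FitnessLandscape,
    lineages: Sequence[Lineage],
) -> SelectionReport:
    """Selection statistics for the phenotype of ``pair``.

    ``S = <h>_rs - <h>_cl`` with means over the binned distributions; the
    Jeffreys residual compares ``S`` against ``(1/τ) Σ (p_cl - p_rs) ln(p_cl/p_rs)``
    (an algebraic identity, so the residual is a numerical diagnostic);
    ``var_approx = τ Var_cl[h]`` is the second-cumulant approximation;
    ``S_D`` comes from raw division counts; the squared correlations between
    ``h̃(D)`` and ``h(x)`` are per-lineage, under both weightings.
    """
    tau = landscape.tau
    mean_cl = float((landscape.h * pair.p_cl).sum())
    mean_rs = float((landscape.h * pair.p_rs).sum())
    S = mean_rs - mean_cl
    jeffreys = float(
        ((pair.p_cl - pair.p_rs) * np.log(pair.p_cl / pair.p_rs)).sum() / tau
    )
    var_cl = float((pair.p_cl * (landscape.h - mean_cl) ** 2).sum())
    S_D = division_selection_strength(lineages, tau)
    if S_D <= 1e-12 and S > 1e-9:
        raise ValueError(
            f"S[{pair.phenotype_name}]={S:.3g} exceeds S[D]={S_D:.3g}; "
            "selection on a phenotype cannot exceed selection on D"
        )

    # per-lineage h~(D) vs h(x) correlation; lineages in trimmed-away bins drop out
    x = np.array([lin.phenotypes[pair.phenotype_name] for lin in lineages])
    D = np.array([lin.D for lin in lineages])
    w_cl = np.array([lin.w_cl for lin in lineages])
    w_rs = np.array([lin.w_rs for lin in lineages])
    hx = np.full(len(x), np.nan)
    for lo, hi, h in zip(pair.bin_lo, pair.bin_hi, landscape.h):
        sel = (x >= lo) & (x < hi)
        hx[sel] = h
    # values exactly at the top retained edge belong to the last bin
    at_top = x == pair.bin_hi[-1]
    hx[at_top] = landscape.h[-1]
    ok = ~np.isnan(hx)
    ht = lineage_fitness(D[ok], tau)
    corr2_cl = _weighted_corr2(ht, hx[ok], w_cl[ok])
    corr2_rs = _weighted_corr2(ht, hx[ok], w_rs[ok])

    return SelectionReport(
        phenotype_name=pair.phenotype_name,
        S=S,
        S_D=S_D,
        S_rel=S / S_D if S_D > 0 else float("nan"),
        mean_h_cl=mean_cl,
        mean_h_rs=mean_rs,
        jeffreys_check=abs(S - jeffreys),
        var_approx=tau * var_cl,
        corr2_cl=corr2_cl,
        corr2_rs=corr2_rs,
    )


def decompose_response(
    report1: SelectionReport,
    report2: SelectionReport,
    env_labels: tuple[str, str] = ("E1", "E2"),
) -> DecompositionReport:
    """Decompose the mean-fitness response to an environment change E1 -> E2.

    ``Δ<h>_rs = Δ<h>_cl + ΔS`` holds exactly because each report's ``S`` is
    defined as the difference of its two means.
    """
    if report1.phenotype_name != report2.phenotype_name:
        raise ValueError(
            f"phenotype mismatch: {report1.phenotype_name!r} vs {report2.phenotype_name!r}"
        )
    return DecompositionReport(
        phenotype_name=report1.phenotype_name,
        env_labels=env_labels,
        delta_mean_h_rs=report2.mean_h_rs - report1.mean_h_rs,
        delta_mean_h_cl=report2.mean_h_cl - report1.mean_h_cl,
        delta_S=report2.S - report1.S,
    )


# ---------------------------------------------------------------------------
# QC


def bin_sweep(
    lineages: Sequence[Lineage],
    phenotype: str,
    widths: Sequence[float],
    Lambda: float,
    tau: float,
) -> pd.DataFrame:
    """Sensitivity of ``S[x]`` to the histogram bin width.

    Returns a tidy frame (width, n_bins, S, excluded_mass_cl, excluded_mass_rs)
    for QC of the bin-width choice.
    """
    x = [lin.phenotypes[phenotype] for lin in lineages]
    rows = []
    for width in widths:
        edges = make_edges(x, width)
        pair = estimate_distributions(
            lineages, phenotype, edges, allow_excess_trim=True
        )
        scape = fitness_landscape(pair, Lambda, tau)
        rep = selection_strength(pair, scape, lineages)
        rows.append(
            {
                "width": width,
                "n_bins": len(pair.p_cl),
                "S": rep.S,
                "excluded_mass_cl": pair.excluded_mass_cl,
                "excluded_mass_rs": pair.excluded_mass_rs,
            }
        )
    return pd.DataFrame(rows)
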
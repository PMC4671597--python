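"""Lobe summaries, gravitational perfusion profiles, BAL concentrations,
and the nonparametric three-condition comparison.

The group comparison follows the study design: per-subject lobe means for
the baseline, diluent and allergen conditions are compared with an
analysis of variance on ranks (Kruskal–Wallis, tie-corrected) followed by
Tukey-type studentized-range tests on mean ranks for the three condition
pairs, with no additional multiplicity correction. Summaries are reported
as median [interquartile range].
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import LOBE_ROLES, CellCountRecord, LobeMaskVolume, ScalarVolume

__all__ = [
    "FunctionalMaps",
    "LobeSummary",
    "lobe_summary",
    "GravityProfile",
    "gravity_profile",
    "bal_concentrations",
    "median_iqr",
    "kruskal_wallis_h",
    "anova_on_ranks",
    "pairwise_ranks",
    "GroupComparison",
    "PAIRWISE_PAIRS",
]

#: The three condition pairs reported by the comparison.
PAIRWISE_PAIRS = (
    ("allergen", "diluent"),
    ("allergen", "baseline"),
    ("diluent", "baseline"),
)


@dataclass
class FunctionalMaps:
    """Voxelwise functional maps produced by the imaging pipeline.

    Q and sV are expected mean-normalized; fgas is the raw gas fraction
    (lobe-relative aeration is computed against the whole-lung mean); ki
    may be a voxelwise Patlak map or absent.
    """

    q_rel: ScalarVolume | None = None
    sv: ScalarVolume | None = None
    fgas: ScalarVolume | None = None
    ki: ScalarVolume | None = None
    low_signal: np.ndarray | None = None


@dataclass
class LobeSummary:
    table: pd.DataFrame  # one row per lobe role
    flagged_counts: dict[str, int] = field(default_factory=dict)


def lobe_summary(maps: FunctionalMaps, mask: LobeMaskVolume) -> LobeSummary:
    """Per-lobe arithmetic means of the functional maps.

    Low-signal-flagged voxels are excluded from the Q/sV means and their
    counts reported. Relative Fgas is the lobe mean over the whole-lung
    mean.
    """
    lung = mask.lung_mask
    flags = (
        np.asarray(maps.low_signal, dtype=bool)
        if maps.low_signal is not None
        else np.zeros(mask.grid.dims, dtype=bool)
    )
    fgas_lung_mean = (
        float(maps.fgas.values[lung].mean()) if maps.fgas is not None else None
    )
    rows = []
    flagged: dict[str, int] = {}
    for role in LOBE_ROLES:
        m = mask.role_mask(role)
        usable = m & ~flags
        flagged[role] = int((m & flags).sum())
        if not usable.any():
            raise ValueError(f"lobe {role!r} has no usable voxels after low-signal exclusion")
        row: dict[str, object] = {"lobe": role, "n_voxels": int(usable.sum())}
        if maps.q_rel is not None:
            row["q_rel"] = float(maps.q_rel.values[usable].mean())
        if maps.sv is not None:
            row["sv"] = float(maps.sv.values[usable].mean())
        if maps.fgas is not None:
            row["fgas_relative"] = float(maps.fgas.values[m].mean()) / fgas_lung_mean
        if maps.ki is not None:
            row["ki"] = float(maps.ki.values[m].mean())
        rows.append(row)
    return LobeSummary(pd.DataFrame(rows), flagged)


@dataclass
class GravityProfile:
    """Per-lobe perfusion vs gravitational height in equal-volume bins."""

    n_bins: int
    lobes: dict[str, pd.DataFrame]  # columns: bin, mean_height_mm, mean_q, n_voxels

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for role, df in self.lobes.items():
            d = df.copy()
            d.insert(0, "lobe", role)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


def gravity_profile(
    q_map: ScalarVolume, mask: LobeMaskVolume, n_bins: int = 8
) -> GravityProfile:
    """Split each study lobe into equal-volume bins along gravity.

    Height is the voxel-centre distance from the most dependent lung voxel
    along the declared gravity axis (whole-lung origin, shared by all
    lobes). Lobe voxels are sorted by height and split into ``n_bins``
    contiguous groups of equal voxel count; a remainder of r voxels is
    spread over the r most dependent bins. Equal voxel count equals equal
    volume on a uniform grid.
    """
    if q_map.grid.dims != mask.grid.dims:
        raise ValueError("map and mask are on different grids")
    height = q_map.grid.height_coordinate()
    lung = mask.lung_mask
    h = height - height[lung].min()
    lobes: dict[str, pd.DataFrame] = {}
    for role in LOBE_ROLES:
        m = mask.role_mask(role)
        n = int(m.sum())
        if n < n_bins:
            raise ValueError(f"lobe {role!r} has {n} voxels; cannot form {n_bins} bins")
        hv = h[m]
        qv = q_map.values[m]
        order = np.argsort(hv, kind="stable")
        hv, qv = hv[order], qv[order]
        base, rem = divmod(n, n_bins)
        counts = np.full(n_bins, base)
        counts[:rem] += 1  # most dependent bins absorb the remainder
        edges = np.concatenate([[0], np.cumsum(counts)])
        rows = []
        for b in range(n_bins):
            sl = slice(edges[b], edges[b + 1])
            rows.append(
                {
                    "bin": b,
                    "mean_height_mm": float(hv[sl].mean()),
                    "mean_q": float(qv[sl].mean()),
                    "n_voxels": int(counts[b]),
                }
            )
        lobes[role] = pd.DataFrame(rows)
    return GravityProfile(n_bins, lobes)


def bal_concentrations(record: CellCountRecord) -> dict[str, float]:
    """Cell concentrations per ml of returned BAL fluid."""
    v = record.returned_volume_ml
    return {
        "total_per_ml": record.total_cells / v,
        "eosinophils_per_ml": record.eosinophils / v,
        "neutrophils_per_ml": record.neutrophils / v,
        "mononuclear_per_ml": record.mononuclear / v,
    }


# ---------------------------------------------------------------------------
# Median [IQR] reporting convention


def _round_half_up(value: Decimal, decimals: int) -> float:
    return float(value.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def median_iqr(
    values: Sequence[float], decimals: int | None = None
) -> tuple[float, float, float]:
    """(median, Q1, Q3) under the published summary-table convention.

    Quantiles are linearly interpolated at position 1 + (n−1)·p in double
    precision; the even-n median is the exact decimal midpoint of the two
    central order statistics (computed in decimal arithmetic so that e.g.
    the midpoint of 165.1 and 177.8 is exactly 171.45, not the nearest
    binary double just below it). When ``decimals`` is given, results are
    rounded half-up on the full-precision value.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("median_iqr requires at least one value")
    v = np.sort(np.asarray(vals, dtype=float))
    n = v.size

    def quantile(p: float) -> float:
        pos = (n - 1) * p
        lo = int(np.floor(pos))
        frac = pos - lo
        hi = min(lo + 1, n - 1)
        return float(v[lo] + frac * (v[hi] - v[lo]))

    if n % 2 == 1:
        med_dec = Decimal(repr(float(v[n // 2])))
    else:
        a, b = v[n // 2 - 1], v[n // 2]
        med_dec = (Decimal(repr(float(a))) + Decimal(repr(float(b)))) / 2
    q1, q3 = quantile(0.25), quantile(0.75)
    if decimals is None:
        return float(med_dec), q1, q3
    return (
        _round_half_up(med_dec, decimals),
        _round_half_up(Decimal(q1), decimals),
        _round_half_up(Decimal(q3), decimals),
    )


# ---------------------------------------------------------------------------
# ANOVA on ranks and Tukey-type pairwise comparisons


def _pooled_ranks(groups: Mapping[str, Sequence[float]]) -> tuple[dict[str, np.ndarray], float]:
    """Average ranks of the pooled sample per group, and the tie correction
    factor 1 − Σ(t³−t)/(N³−N)."""
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # average ranks for ties
    out: dict[str, np.ndarray] = {}
    start = 0
    for g in labels:
        size = len(groups[g])
        out[g] = ranks[start : start + size]
        start += size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n_total**3 - n_total) if n_total > 1 else 1.0
    return out, correction


def kruskal_wallis_h(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    H = [12/(N(N+1)) · Σ nᵢ·R̄ᵢ² − 3(N+1)] / (1 − Σ(t³−t)/(N³−N));
    p from the chi-square approximation with k−1 degrees of freedom.
    All-identical data (correction factor 0) returns H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    ranks, correction = _pooled_ranks(groups)
    n_total = sum(len(v) for v in groups.values())
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        len(r) * float(np.mean(r)) ** 2 for r in ranks.values()
    ) - 3.0 * (n_total + 1)
    if correction == 0.0:
        return 0.0, 1.0
    h /= correction
    h = max(h, 0.0)
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


@dataclass
class PairDecision:
    statistic: float  # studentized-range q (or |mean-rank diff| for permutation)
    p_value: float
    significant: bool


@dataclass
class GroupComparison:
    """Outcome of the three-condition nonparametric comparison."""

    groups: dict[str, list[float]]
    statistic: float  # Kruskal-Wallis H
    p_value: float
    pairwise: dict[tuple[str, str], PairDecision]
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [f"ANOVA on ranks: H = {self.statistic:.4f}, p = {self.p_value:.4g}"]
        for g, v in self.groups.items():
            med, q1, q3 = median_iqr(v)
            lines.append(f"  {g}: median {med:.4g} [{q1:.4g}-{q3:.4g}] (n={len(v)})")
        for (a, b), d in self.pairwise.items():
            verdict = "significant" if d.significant else "ns"
            lines.append(
                f"  {a} vs {b}: q = {d.statistic:.3f}, p = {d.p_value:.4g} ({verdict})"
            )
        return "\n".join(lines)


def pairwise_ranks(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    method: str = "tukey",
    seed: int | None = None,
) -> dict[tuple[str, str], PairDecision]:
    """Tukey-type pairwise comparisons on ranks for the three conditions.

    ``method='tukey'``: studentized-range test on pooled mean ranks,
    q = |R̄ᵢ − R̄ⱼ| / sqrt(Vtie·(1/nᵢ + 1/nⱼ)/2) with Vtie the tie-corrected
    rank variance N(N+1)/12, referred to the studentized-range distribution
    with k groups and infinite error df (the convention of rank-based
    post-hoc tests after an ANOVA on ranks). ``method='permutation'``: an
    exact two-group permutation test on the mean-rank difference. No
    multiplicity correction beyond the procedure itself is applied.
    """
    missing = [r for r in LOBE_ROLES if r not in groups]
    if missing:
        raise ValueError(f"missing condition group(s): {missing}")
    ranks, correction = _pooled_ranks(groups)
    n_total = sum(len(v) for v in groups.values())
    k = len(groups)
    var = n_total * (n_total + 1) / 12.0 * correction
    out: dict[tuple[str, str], PairDecision] = {}
    rng = np.random.default_rng(seed)
    for a, b in PAIRWISE_PAIRS:
        ra, rb = ranks[a], ranks[b]
        diff = abs(float(np.mean(ra)) - float(np.mean(rb)))
        if method == "tukey":
            if var <= 0:
                out[(a, b)] = PairDecision(0.0, 1.0, False)
                continue
            se = np.sqrt(var * (1.0 / len(ra) + 1.0 / len(rb)) / 2.0)
            q = diff / se
            p = float(stats.studentized_range.sf(q, k, np.inf))
            out[(a, b)] = PairDecision(float(q), p, p < alpha)
        elif method == "permutation":
            p = _permutation_pvalue(
                np.asarray(groups[a], float), np.asarray(groups[b], float), rng
            )
            out[(a, b)] = PairDecision(diff, p, p < alpha)
        else:
            raise ValueError(f"unknown pairwise method {method!r}")
    return out


def _permutation_pvalue(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, max_exact: int = 20000
) -> float:
    """Two-sided permutation p-value for the mean-rank difference."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = a.size
    observed = abs(ranks[:na].mean() - ranks[na:].mean())
    idx = np.arange(pooled.size)
    from math import comb

    n_exact = comb(pooled.size, na)
    count = 0
    total = 0
    if n_exact <= max_exact:
        for combo in itertools.combinations(idx, na):
            sel = np.zeros(pooled.size, dtype=bool)
            sel[list(combo)] = True
            d = abs(ranks[sel].mean() - ranks[~sel].mean())
            count += d >= observed - 1e-12
            total += 1
    else:
        for _ in range(max_exact):
            sel = np.zeros(pooled.size, dtype=bool)
            sel[rng.choice(pooled.size, na, replace=False)] = True
            d = abs(ranks[sel].mean() - ranks[~sel].mean())
            count += d >= observed - 1e-12
            total += 1
    return count / total


def anova_on_ranks(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    pairwise_method: str = "tukey",
    seed: int | None = None,
) -> GroupComparison:
    """Kruskal–Wallis ANOVA on ranks, with the three printed pairwise
    comparisons when the groups are exactly the study conditions."""
    h, p = kruskal_wallis_h(groups)
    pairwise: dict[tuple[str, str], PairDecision] = {}
    if set(groups) == set(LOBE_ROLES):
        pairwise = pairwise_ranks(groups, alpha=alpha, method=pairwise_method, seed=seed)
    return GroupComparison(
        {g: [float(x) for x in v] for g, v in groups.items()}, h, p, pairwise, alpha
    )
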
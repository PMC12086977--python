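"""Plot-level environmental summaries and group-difference tests.

Covers the covariate side of the analysis: soil-moisture grid summaries
(mean, SD, CV%), basal-area-weighted shade-tolerance indices, centered
log-ratio transforms of soil texture, one-way permutation MANOVA
(PERMANOVA) on Euclidean distances, per-group means, and monthly
soil-moisture gain/loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd


class GridSummary(NamedTuple):
    mean: float
    sd: float
    cv_percent: float


@dataclass
class MoistureGrid:
    """One plot's grid of volumetric soil-water-content readings (% v/v)."""

    plot_id: str
    node_values: np.ndarray
    grid_shape: tuple[int, int] = (6, 7)

    def __post_init__(self) -> None:
        self.node_values = np.asarray(self.node_values, dtype=float)
        expected = self.grid_shape[0] * self.grid_shape[1]
        if self.node_values.size != expected:
            raise ValueError(
                f"grid {self.plot_id}: {self.node_values.size} nodes, "
                f"expected {expected} for shape {self.grid_shape}")

    @property
    def summary(self) -> GridSummary:
        return grid_summary(self.node_values)

    @property
    def mean(self) -> float:
        return self.summary.mean

    @property
    def sd(self) -> float:
        return self.summary.sd

    @property
    def cv_percent(self) -> float:
        return self.summary.cv_percent


@dataclass
class StandInventory:
    """Basal areas (m^2 ha^-1) and shade ratings for one plot's stand."""

    plot_id: str
    species_basal_areas: Mapping[str, float]
    sapling_basal_areas: Mapping[str, float] = field(default_factory=dict)
    shade_ratings: Mapping[str, float] = field(default_factory=dict)


def grid_summary(node_values) -> GridSummary:
    """Mean, sample SD (n-1), and CV% = 100*sd/mean of grid readings."""
    values = np.asarray(node_values, dtype=float)
    if values.size < 2:
        raise ValueError("grid summary needs at least 2 readings")
    if np.any(values <= 0):
        raise ValueError("soil-water-content readings must be positive")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return GridSummary(mean=mean, sd=sd, cv_percent=100.0 * sd / mean)


def weighted_shade_tolerance(inventory: StandInventory) -> float:
    """Basal-area-weighted mean shade-tolerance rating of the canopy.

    Ratings run 1 (most shade tolerant) to 4+ (intolerant); every species
    with positive basal area must carry a rating.
    """
    total = 0.0
    weighted = 0.0
    for species, ba in inventory.species_basal_areas.items():
        if ba < 0:
            raise ValueError(f"negative basal area for {species}")
        if ba == 0:
            continue
        if species not in inventory.shade_ratings:
            raise ValueError(f"no shade rating for canopy species {species}")
        total += ba
        weighted += ba * inventory.shade_ratings[species]
    if total <= 0:
        raise ValueError("total canopy basal area must be positive")
    return weighted / total


def clr_transform(parts) -> np.ndarray:
    """Centered log-ratio transform of a composition (parts of a whole).

    ``clr_i = ln(x_i / g(x))`` with g the geometric mean; the output sums
    to zero and is invariant to rescaling the whole composition.  Zero
    parts are rejected (no zero-replacement is performed).
    """
    x = np.asarray(parts, dtype=float)
    if np.any(x <= 0):
        raise ValueError("all composition parts must be strictly positive")
    logx = np.log(x)
    return logx - logx.mean()


def _pseudo_f(data: np.ndarray, labels: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from Euclidean sum-of-squares partition."""
    groups = np.unique(labels)
    n, a = len(data), len(groups)
    grand = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_within = 0.0
    for g in groups:
        sub = data[labels == g]
        ss_within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    ss_between = ss_total - ss_within
    if ss_within == 0.0:
        # perfectly homogeneous groups: F is +inf if anything separates
        # them, else the data carry no variation at all
        return float("inf") if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class PermutationTestResult(NamedTuple):
    pseudo_f: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int


def permutation_group_test(data, labels, n_permutations: int = 9999,
                           seed: int | None = None) -> PermutationTestResult:
    """One-way PERMANOVA on Euclidean distances.

    ``data`` is an (n, p) array (p = 1 reduces to the classical one-way F
    statistic); ``labels`` the group assignment per row.  The p-value uses
    the add-one permutation convention
    ``p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1)``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 1:
        data = data.T
    labels = np.asarray(labels)
    if len(labels) != data.shape[0]:
        raise ValueError("labels and data row counts differ")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 rows")
    observed = _pseudo_f(data, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        permuted = rng.permutation(labels)
        if _pseudo_f(data, permuted) >= observed:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermutationTestResult(
        pseudo_f=observed, p_value=p, n_permutations=n_permutations,
        df_between=len(groups) - 1, df_within=data.shape[0] - len(groups))


def group_means(values, groups) -> pd.DataFrame:
    """Per-group arithmetic mean, sample SD, and count.

    SD is NaN for single-element groups (undefined with the n-1
    denominator); values are carried unrounded.
    """
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float),
                          "group": np.asarray(groups)})
    if frame.empty:
        raise ValueError("no data")
    out = frame.groupby("group")["value"].agg(mean="mean",
                                              sd=lambda v: v.std(ddof=1),
                                              n="count")
    if (out["n"] == 0).any():
        raise ValueError("empty group")
    return out


def moisture_delta(start_swc: float, end_swc: float, days: int) -> float:
    """Monthly soil-moisture gain/loss: ``((end - start) / days) * 30``."""
    if days <= 0:
        raise ValueError("days must be positive")
    return (end_swc - start_swc) / days * 30.0
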
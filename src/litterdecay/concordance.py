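"""Rank-agreement statistics: Kendall's W and Spearman correlation.

Kendall's coefficient of concordance measures agreement of item rankings
across blocks (here: agreement of treatment-cell rankings across removal
dates, or of mesh-size rankings across treatments).  W = 1 is complete
agreement, W = 0 none.  Mid-ranks handle ties, with the standard tie
correction applied by default:

    W = 12 S / (m^2 (n^3 - n) - m sum_j T_j)

with m blocks, n items, S the sum of squared deviations of item rank-sums
from their mean, and T_j = sum(t^3 - t) over tie groups in block j.  The
chi-square approximation is chi2 = m (n - 1) W on n - 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConcordanceResult:
    w: float
    chi_square: float
    df: int
    p_value: float
    n_blocks: int
    n_items: int
    rank_matrix: pd.DataFrame


def _as_table(table) -> pd.DataFrame:
    frame = pd.DataFrame(table)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError("concordance needs at least 2 blocks and 2 items")
    if frame.isna().any().any():
        raise ValueError("concordance table must be rectangular and complete")
    return frame


def kendalls_w(table, tie_correction: bool = True,
               ascending: bool = True) -> ConcordanceResult:
    """Kendall's W for a blocks-by-items table of measurements.

    Values are ranked within each block (row); ``ascending=True`` gives
    rank 1 to the smallest value, so with negative decay rates the fastest
    decay ranks first.
    """
    frame = _as_table(table)
    values = frame.to_numpy(dtype=float)
    if not ascending:
        values = -values
    m, n = values.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    denom = m * m * (n ** 3 - n)
    if tie_correction:
        t_total = 0.0
        for row in ranks:
            _, counts = np.unique(row, return_counts=True)
            t_total += float((counts ** 3 - counts).sum())
        denom -= m * t_total
    if denom == 0:
        # every block is fully tied: no information, complete "agreement"
        w = 1.0
    else:
        w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    rank_matrix = pd.DataFrame(ranks, index=frame.index, columns=frame.columns)
    return ConcordanceResult(w=w, chi_square=chi2, df=df, p_value=p,
                             n_blocks=m, n_items=n, rank_matrix=rank_matrix)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("spearman correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
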
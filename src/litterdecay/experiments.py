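"""Seeded simulation experiments for validating the estimation chain.

These drive the synthetic generator through the fitting and testing
operations and measure frequentist operating characteristics: interval
coverage of the multigroup fit, the type-I error of the mixture-additivity
z-test, and the permutation test's null behaviour.
"""

from __future__ import annotations

import numpy as np

from .data_model import TreatmentCell
from .decay_estimation import fit_multigroup, instantaneous_k
from .environment_stats import permutation_group_test
from .mixture_additivity import (additivity_z, expected_mixture_k,
                                 expected_mixture_variance)
from .synthetic_data import SyntheticConfig, default_study_config, generate_bags
from . import study


def _rep_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def slope_recovery(n_reps: int = 200, seed: int = 0,
                   ln_noise_sd: float = 0.1) -> dict:
    """Interval coverage of the 12 treatment-cell slopes.

    Each replication draws the field design (minus the lost site) with the
    study's slope magnitudes as truth and the given ln-noise SD, fits the
    multigroup regression, and records whether each 95% interval covers
    its true slope.
    """
    truth = study.default_true_k_table()
    cover: dict[TreatmentCell, int] = {c: 0 for c in truth}
    for rep_seed in _rep_seeds(seed, n_reps):
        cfg = default_study_config(seed=rep_seed, ln_noise_sd=ln_noise_sd)
        fit = fit_multigroup(generate_bags(cfg))
        for cell, k in truth.items():
            lo, hi = fit.slope_intervals[cell]
            cover[cell] += lo <= -k <= hi
    per_cell = {c.label: cover[c] / n_reps for c in truth}
    overall = sum(cover.values()) / (n_reps * len(truth))
    return {"per_cell": per_cell, "overall": overall, "n_reps": n_reps}


def _null_config(seed: int) -> SyntheticConfig:
    """Study design with mixed-cell rates forced to the additive null."""
    table = study.default_true_k_table()
    for prolif in (True, False):
        for excl in (True, False):
            table[TreatmentCell(prolif, excl, "mixed")] = expected_mixture_k(
                table[TreatmentCell(prolif, excl, "maple")],
                table[TreatmentCell(prolif, excl, "beech")])
    return SyntheticConfig(true_k_table=table, ln_noise_sd=0.1, seed=seed)


def additivity_null(n_reps: int = 250, seed: int = 0,
                    critical_value: float = 1.96) -> dict:
    """Type-I behaviour of the additivity z-test under an additive truth.

    Each replication simulates the full 6-site design with every mixed
    cell's rate equal to its monospecific average, then estimates each
    cell's rate as the mean instantaneous k over that cell's bags
    (variance = sample variance / n).  Cells hold disjoint bags, so the
    three estimates entering each z-test are independent, matching the
    test's assumptions; the four proliferation x exclusion strata give
    n_reps x 4 null tests in total.
    """
    additive = 0
    total = 0
    for rep_seed in _rep_seeds(seed, n_reps):
        records = generate_bags(_null_config(rep_seed))
        by_cell: dict[TreatmentCell, list[float]] = {}
        for r in records:
            by_cell.setdefault(r.cell, []).append(
                instantaneous_k(r.percent_remaining, r.year_fraction))
        est = {c: (float(np.mean(ks)), float(np.var(ks, ddof=1) / len(ks)))
               for c, ks in by_cell.items()}
        for prolif in (True, False):
            for excl in (True, False):
                k_m, v_m = est[TreatmentCell(prolif, excl, "maple")]
                k_b, v_b = est[TreatmentCell(prolif, excl, "beech")]
                k_x, v_x = est[TreatmentCell(prolif, excl, "mixed")]
                result = additivity_z(
                    k_x, v_x, expected_mixture_k(k_m, k_b),
                    expected_mixture_variance(v_m, v_b),
                    critical_value=critical_value)
                additive += result.verdict == "additive"
                total += 1
    return {"additive_fraction": additive / total, "n_tests": total}


def permanova_type1(n_runs: int = 1000, seed: int = 0,
                    n_per_group: int = 8, n_permutations: int = 99,
                    alpha: float = 0.05) -> dict:
    """Rejection rate of the permutation group test under the null."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(["a", "b"], n_per_group)
    rejections = 0
    for i in range(n_runs):
        data = rng.normal(size=(2 * n_per_group, 2))
        result = permutation_group_test(data, labels,
                                        n_permutations=n_permutations,
                                        seed=int(rng.integers(2 ** 31)))
        rejections += result.p_value <= alpha
    return {"rejection_rate": rejections / n_runs, "n_runs": n_runs}
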
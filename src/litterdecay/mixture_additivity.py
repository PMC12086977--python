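"""Additivity tests for two-species litter mixtures.

Additivity means a 50:50 mixture loses mass at the average of its two
components' monospecific rates.  Departures are synergistic (faster than
expected) or antagonistic (slower).  The test statistic is a two-quantity
z-score: the observed mixed-bag slope minus the expected slope, divided by
the square root of their summed variances, with the expected-rate variance
propagated from the two monospecific slope variances as
``(var_maple + var_beech) / 4``.  A squared variant (``z**2``) is exposed
as a secondary accessor for comparison with pooled-variance formulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .data_model import MIXED_COMPONENT_INITIAL_G, BagRecord, ValidationError
from .decay_estimation import InstantaneousK, instantaneous_k

DEFAULT_CRITICAL_Z = 1.96

Verdict = Literal["additive", "synergistic", "antagonistic"]


@dataclass(frozen=True)
class AdditivityResult:
    observed_k: float
    expected_k: float
    standardized_difference: float
    z_score: float
    verdict: Verdict
    critical_value: float = DEFAULT_CRITICAL_Z

    @property
    def z_squared(self) -> float:
        return self.z_score ** 2


def expected_mixture_k(k_maple: float, k_beech: float) -> float:
    """Expected mixture rate under additivity: the arithmetic mean."""
    if not (math.isfinite(k_maple) and math.isfinite(k_beech)):
        raise ValueError("monospecific rates must be finite")
    return (k_maple + k_beech) / 2.0


def expected_mixture_variance(var_maple: float, var_beech: float) -> float:
    """Variance of the mean of two independent monospecific slopes."""
    if var_maple <= 0 or var_beech <= 0:
        raise ValueError("variances must be positive")
    return (var_maple + var_beech) / 4.0


def standardized_difference(observed: float, expected: float) -> float:
    """Signed fraction ``(observed - expected) / expected``.

    For negative (mass-loss) rates this is positive when the observed
    magnitude exceeds the expected magnitude.
    """
    if expected == 0:
        raise ValueError("expected rate must be nonzero")
    return (observed - expected) / expected


def additivity_z(observed_k: float, observed_var: float,
                 expected_k: float, expected_var: float,
                 critical_value: float = DEFAULT_CRITICAL_Z) -> AdditivityResult:
    """z-test of the observed mixture rate against its additive expectation.

    The sign of z is preserved; the verdict distinguishes synergism
    (|observed| > |expected|, faster-than-expected loss) from antagonism
    when |z| reaches the critical value.
    """
    if observed_var <= 0 or expected_var <= 0:
        raise ValueError("variances must be positive")
    z = (observed_k - expected_k) / math.sqrt(observed_var + expected_var)
    if abs(z) < critical_value:
        verdict: Verdict = "additive"
    elif abs(observed_k) > abs(expected_k):
        verdict = "synergistic"
    else:
        verdict = "antagonistic"
    return AdditivityResult(
        observed_k=observed_k,
        expected_k=expected_k,
        standardized_difference=standardized_difference(observed_k, expected_k),
        z_score=z,
        verdict=verdict,
        critical_value=critical_value,
    )


def per_species_mixed_k(record: BagRecord,
                        year_fraction: float | None = None
                        ) -> tuple[InstantaneousK, InstantaneousK]:
    """Instantaneous rates of each species inside one 50:50 mixed bag.

    Each component is referenced to its own 1.5 g initial mass.
    """
    if record.species != "mixed":
        raise ValidationError("per-species rates require a mixed bag")
    if record.maple_final_mass_g is None or record.beech_final_mass_g is None:
        raise ValidationError("mixed bag is missing a component mass")
    t = record.year_fraction if year_fraction is None else year_fraction
    results = []
    for mass, basis in ((record.maple_final_mass_g, "maple-in-mixed"),
                        (record.beech_final_mass_g, "beech-in-mixed")):
        pct = 100.0 * mass / MIXED_COMPONENT_INITIAL_G
        results.append(InstantaneousK(instantaneous_k(pct, t), record, basis))
    return results[0], results[1]


def mixture_vs_mono_ratio(k_in_mixture: float, k_monospecific: float) -> float:
    """Fractional speed-up (+) or slow-down (-) of a species in mixture.

    ``(|k_mix| / |k_mono|) - 1``: +0.27 means 27% faster in the mixture.
    """
    if k_monospecific == 0:
        raise ValueError("monospecific rate must be nonzero")
    return abs(k_in_mixture) / abs(k_monospecific) - 1.0


def interval_containment(k_in_mixture: float,
                         mono_interval: tuple[float, float]) -> bool:
    """Whether the in-mixture rate lies inside the monospecific 95% interval.

    Closed at both ends; a value outside flags a non-additivity candidate.
    """
    lower, upper = mono_interval
    if lower > upper:
        raise ValueError(f"inverted interval bounds ({lower}, {upper})")
    return lower <= k_in_mixture <= upper
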
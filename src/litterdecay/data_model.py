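"""Domain types, validation, and CSV I/O for litterbag mass-loss records.

The experimental unit is a single mesh bag of leaf litter buried in the
forest floor and retrieved after a known number of days.  Bags sit in a
factorial design: beech-sapling proliferation (Yes/No) x rainfall
exclusion (Yes/No) x litter "species" (monospecific maple, monospecific
beech, or a 50:50 two-species mixture) x mesh aperture (L/M/S), replicated
within sites and removed at three dates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SPECIES = ("maple", "beech", "mixed")
MESHES = ("L", "M", "S")
REMOVAL_DAYS = (30, 60, 90)

#: Incubation period expressed as a fraction of a 365-day year, at the
#: precision used throughout the analysis (4 decimals).
YEAR_FRACTIONS = {30: 0.0822, 60: 0.1644, 90: 0.2466}

#: Initial oven-dry mass weighed into every bag (grams).
STANDARD_INITIAL_MASS_G = 3.0
#: Initial mass of each component in a 50:50 mixed bag (grams).
MIXED_COMPONENT_INITIAL_G = 1.5

#: Tolerance (g) for the two mixed-bag component masses summing to the bag
#: total: two analytical-balance readings at +/-0.001 g each, rounded up.
MIXED_SUM_TOLERANCE_G = 5e-3

BAG_TABLE_COLUMNS = [
    "site",
    "plot",
    "proliferation",
    "exclusion",
    "species",
    "mesh",
    "replicate",
    "removal_day",
    "initial_mass_g",
    "final_mass_g",
    "maple_final_mass_g",
    "beech_final_mass_g",
]


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable header."""


class ValidationError(ValueError):
    """A row violates a domain invariant; the message names row and rule."""


def year_fraction(removal_day: int) -> float:
    """Elapsed time in years for a removal day.

    The three design removal days use the fixed 4-decimal fractions; any
    other positive day count falls back to ``day / 365``.
    """
    if removal_day <= 0:
        raise ValueError(f"removal_day must be positive, got {removal_day}")
    return YEAR_FRACTIONS.get(int(removal_day), removal_day / 365.0)


@dataclass(frozen=True, order=True)
class TreatmentCell:
    """One of the 12 Proliferation x Exclusion x Species combinations."""

    proliferation: bool
    exclusion: bool
    species: str

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )

    @property
    def label(self) -> str:
        """Canonical ``Yes-No-Maple``-style label."""
        yn = {True: "Yes", False: "No"}
        return f"{yn[self.proliferation]}-{yn[self.exclusion]}-{self.species.capitalize()}"

    @classmethod
    def from_label(cls, label: str) -> "TreatmentCell":
        prolif, excl, species = label.split("-")
        return cls(_parse_flag(prolif, "proliferation"),
                   _parse_flag(excl, "exclusion"),
                   species.lower())


#: Canonical deterministic ordering of the 12 treatment cells, used for
#: design-matrix columns and every report table: proliferation Yes before
#: No, exclusion Yes before No, species maple < beech < mixed.
ALL_CELLS: tuple[TreatmentCell, ...] = tuple(
    TreatmentCell(p, e, s)
    for p in (True, False)
    for e in (True, False)
    for s in SPECIES
)


@dataclass(frozen=True)
class MassRemaining:
    """Percent of initial mass remaining, paired with elapsed time in years."""

    percent_remaining: float
    year_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.percent_remaining <= 100:
            raise ValidationError(
                f"percent_remaining must be in (0, 100], got {self.percent_remaining}"
            )
        if self.year_fraction <= 0:
            raise ValidationError(
                f"year_fraction must be positive, got {self.year_fraction}"
            )


@dataclass
class BagRecord:
    """One litterbag observation: where it sat, what it held, what came back."""

    site: str
    plot: str
    proliferation: bool
    exclusion: bool
    species: str
    mesh: str
    replicate: int
    removal_day: int
    initial_mass_g: float = STANDARD_INITIAL_MASS_G
    final_mass_g: float = STANDARD_INITIAL_MASS_G
    maple_final_mass_g: float | None = None
    beech_final_mass_g: float | None = None

    @property
    def cell(self) -> TreatmentCell:
        return TreatmentCell(self.proliferation, self.exclusion, self.species)

    @property
    def year_fraction(self) -> float:
        return year_fraction(self.removal_day)

    @property
    def percent_remaining(self) -> float:
        return 100.0 * self.final_mass_g / self.initial_mass_g

    def validate(self, row: int | str = "?",
                 mixed_sum_tol: float = MIXED_SUM_TOLERANCE_G) -> None:
        """Raise :class:`ValidationError` naming the row and the broken rule."""
        if self.species not in SPECIES:
            raise ValidationError(f"row {row}: unknown species {self.species!r}")
        if self.mesh not in MESHES:
            raise ValidationError(f"row {row}: unknown mesh {self.mesh!r}")
        if self.removal_day <= 0:
            raise ValidationError(f"row {row}: removal_day must be positive")
        if self.initial_mass_g <= 0:
            raise ValidationError(f"row {row}: initial_mass_g must be positive")
        if not 0 < self.final_mass_g <= self.initial_mass_g:
            raise ValidationError(
                f"row {row}: final_mass_g must satisfy 0 < final <= initial "
                f"(got final={self.final_mass_g}, initial={self.initial_mass_g})"
            )
        has_components = (self.maple_final_mass_g is not None
                          and self.beech_final_mass_g is not None)
        if self.species == "mixed":
            if not has_components:
                raise ValidationError(
                    f"row {row}: mixed bag requires maple_final_mass_g and "
                    f"beech_final_mass_g"
                )
            total = self.maple_final_mass_g + self.beech_final_mass_g
            if abs(total - self.final_mass_g) > mixed_sum_tol:
                raise ValidationError(
                    f"row {row}: component masses ({total:.4f} g) do not sum "
                    f"to final_mass_g ({self.final_mass_g:.4f} g) within "
                    f"{mixed_sum_tol} g"
                )
        elif self.maple_final_mass_g is not None or self.beech_final_mass_g is not None:
            raise ValidationError(
                f"row {row}: per-species masses are only valid for mixed bags"
            )


def mass_loss_percent(final_mass: float, initial_mass: float) -> float:
    """Percent of initial mass lost: ``100 * (1 - final / initial)``.

    Values are carried unrounded; round only for presentation.
    """
    if final_mass <= 0 or initial_mass <= 0:
        raise ValueError("masses must be positive")
    if final_mass > initial_mass:
        raise ValueError(
            f"final_mass ({final_mass}) exceeds initial_mass ({initial_mass})"
        )
    return 100.0 * (1.0 - final_mass / initial_mass)


def _parse_flag(value, name: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("yes", "true", "1"):
        return True
    if text in ("no", "false", "0"):
        return False
    raise ValidationError(f"cannot parse {name} flag from {value!r}")


def _format_flag(value: bool) -> str:
    return "Yes" if value else "No"


def records_to_frame(records: Iterable[BagRecord]) -> pd.DataFrame:
    """Serialize records into the canonical bag-table layout."""
    rows = []
    for r in records:
        rows.append({
            "site": r.site,
            "plot": r.plot,
            "proliferation": _format_flag(r.proliferation),
            "exclusion": _format_flag(r.exclusion),
            "species": r.species,
            "mesh": r.mesh,
            "replicate": r.replicate,
            "removal_day": r.removal_day,
            "initial_mass_g": r.initial_mass_g,
            "final_mass_g": r.final_mass_g,
            "maple_final_mass_g": r.maple_final_mass_g,
            "beech_final_mass_g": r.beech_final_mass_g,
        })
    return pd.DataFrame(rows, columns=BAG_TABLE_COLUMNS)


def frame_to_records(frame: pd.DataFrame, validate: bool = True,
                     mixed_sum_tol: float = MIXED_SUM_TOLERANCE_G) -> list[BagRecord]:
    missing = [c for c in BAG_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"bag table is missing required columns: {missing}")
    records = []
    for idx, row in frame.iterrows():
        def _opt(value):
            return None if pd.isna(value) else float(value)

        record = BagRecord(
            site=str(row["site"]),
            plot=str(row["plot"]),
            proliferation=_parse_flag(row["proliferation"], "proliferation"),
            exclusion=_parse_flag(row["exclusion"], "exclusion"),
            species=str(row["species"]).strip().lower(),
            mesh=str(row["mesh"]).strip(),
            replicate=int(row["replicate"]),
            removal_day=int(row["removal_day"]),
            initial_mass_g=float(row["initial_mass_g"]),
            final_mass_g=float(row["final_mass_g"]),
            maple_final_mass_g=_opt(row["maple_final_mass_g"]),
            beech_final_mass_g=_opt(row["beech_final_mass_g"]),
        )
        if validate:
            record.validate(row=idx, mixed_sum_tol=mixed_sum_tol)
        records.append(record)
    return records


def read_bag_table(path: str | Path, validate: bool = True,
                   mixed_sum_tol: float = MIXED_SUM_TOLERANCE_G) -> list[BagRecord]:
    """Read a bag-table CSV, validating every row against the invariants.

    Row count and ordering are preserved; flags are serialized as
    ``Yes``/``No``.  Missing columns raise :class:`SchemaError`; rows that
    break an invariant raise :class:`ValidationError` naming row and rule.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    return frame_to_records(frame, validate=validate, mixed_sum_tol=mixed_sum_tol)


def write_bag_table(records: Sequence[BagRecord], path: str | Path) -> None:
    # 17 significant digits guarantee a lossless float round trip
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
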
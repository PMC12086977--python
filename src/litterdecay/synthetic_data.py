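"""Synthetic litterbag experiments and environmental records.

The generator inverts the linearized single-pool decay model the analysis
fits: percent mass remaining for a bag is drawn as

    pct = exp(ln 100 - k_cell * mesh_modifier * t + eps),   eps ~ N(0, sd)

so noise is additive on the ln scale (multiplicative on mass), and fitting
the multigroup regression to noiseless output returns the configured k
values exactly.  Environmental records (6x7 soil-moisture grids with
exclusion-dependent mean and CV%, sub-daily soil-temperature logs) follow
the field protocol's shapes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    MESHES,
    MIXED_COMPONENT_INITIAL_G,
    REMOVAL_DAYS,
    SPECIES,
    STANDARD_INITIAL_MASS_G,
    BagRecord,
    TreatmentCell,
    year_fraction,
)
from . import study

#: Site labels lost to incomplete sample processing in the field campaign.
STUDY_SITE_DROPOUT = frozenset({"3"})


def _substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of a single global seed."""
    tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


@dataclass
class SyntheticConfig:
    """Configuration for a synthetic litterbag experiment.

    ``true_k_table`` holds positive decay-rate magnitudes (year^-1); the
    generated data imply negative regression slopes of the same size.
    """

    true_k_table: Mapping[TreatmentCell, float]
    ln_noise_sd: float = 0.1
    n_sites_per_proliferation: int = 3
    n_replicates: int = 2
    mesh_effects: Mapping[str, float] | None = None
    site_dropout: frozenset[str] = frozenset()
    seed: int = 0
    #: optional per-species k magnitudes inside mixed bags, keyed by the
    #: mixed cell: (maple_k, beech_k).  Defaults to the mixed cell's own k.
    mixture_component_k: Mapping[TreatmentCell, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        for cell, k in self.true_k_table.items():
            if k <= 0:
                raise ValueError(f"true k for {cell.label} must be positive, got {k}")
        if self.ln_noise_sd < 0:
            raise ValueError("ln_noise_sd must be non-negative")
        if self.n_sites_per_proliferation < 1 or self.n_replicates < 1:
            raise ValueError("site and replicate counts must be at least 1")
        if self.mesh_effects is not None:
            for mesh, mod in self.mesh_effects.items():
                if mod <= 0:
                    raise ValueError(f"mesh modifier for {mesh} must be positive")

    def site_labels(self) -> dict[bool, list[str]]:
        """Site labels per proliferation level, following the field layout
        (proliferation sites numbered from 1, beech-free sites from n+2 so
        the default 3+3 design yields sites 1,2,3 and 5,6,7)."""
        n = self.n_sites_per_proliferation
        return {
            True: [str(i) for i in range(1, n + 1)],
            False: [str(i) for i in range(n + 2, 2 * n + 2)],
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        kwargs["true_k_table"] = {
            TreatmentCell.from_label(label): float(k)
            for label, k in raw["true_k_table"].items()
        }
        if raw.get("mixture_component_k"):
            kwargs["mixture_component_k"] = {
                TreatmentCell.from_label(label): tuple(map(float, pair))
                for label, pair in raw["mixture_component_k"].items()
            }
        if raw.get("site_dropout"):
            kwargs["site_dropout"] = frozenset(str(s) for s in raw["site_dropout"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "true_k_table": {c.label: float(k) for c, k in self.true_k_table.items()},
            "ln_noise_sd": self.ln_noise_sd,
            "n_sites_per_proliferation": self.n_sites_per_proliferation,
            "n_replicates": self.n_replicates,
            "mesh_effects": dict(self.mesh_effects) if self.mesh_effects else None,
            "site_dropout": sorted(self.site_dropout),
            "seed": self.seed,
            "mixture_component_k": (
                {c.label: list(pair) for c, pair in self.mixture_component_k.items()}
                if self.mixture_component_k else None
            ),
        }
        Path(path).write_text(yaml.safe_dump(raw))


@dataclass
class SyntheticEnvironmentConfig:
    """Configuration for synthetic soil-moisture grids and temperature logs."""

    swc_mean_by_exclusion: Mapping[bool, float] = field(
        default_factory=lambda: {True: 8.82, False: 15.57})
    swc_cv_by_exclusion: Mapping[bool, float] = field(
        default_factory=lambda: {True: 54.10, False: 24.40})
    grid_shape: tuple[int, int] = (6, 7)
    readings_per_node: int = 3
    temperature_profile: Sequence[float] | None = None

    def __post_init__(self) -> None:
        for excl in (True, False):
            if self.swc_mean_by_exclusion[excl] <= 0:
                raise ValueError("grid means must be strictly positive")
            if self.swc_cv_by_exclusion[excl] < 0:
                raise ValueError("grid CVs must be non-negative")
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid_shape must be positive")
        if self.readings_per_node < 1:
            raise ValueError("readings_per_node must be at least 1")


def default_study_config(seed: int = 0, ln_noise_sd: float = 0.1,
                         drop_lost_site: bool = True) -> SyntheticConfig:
    """The field campaign's design as a synthetic configuration.

    True decay rates are the study's fitted slope magnitudes; noise SD on
    the ln(% remaining) scale defaults to 0.1; the site lost to incomplete
    processing is dropped by default, leaving 5 sites (540 bags).
    """
    return SyntheticConfig(
        true_k_table=study.default_true_k_table(),
        ln_noise_sd=ln_noise_sd,
        seed=seed,
        site_dropout=STUDY_SITE_DROPOUT if drop_lost_site else frozenset(),
    )


def generate_bags(config: SyntheticConfig) -> list[BagRecord]:
    """Draw one full factorial of litterbag records.

    Layout per site: an excluder plot (``<site>-1``) and a rainfall plot
    (``<site>-2``), each holding species x mesh x replicate bags removed at
    30, 60 and 90 days, so the full count is
    ``(2 * n_sites_per_proliferation) * 2 * 3 * 3 * n_replicates * 3``
    bags -- 648 for the 3+3-site, 2-replicate design -- minus dropout.
    """
    rng = _substream(config.seed, "bags")
    mesh_effects = dict(config.mesh_effects or {m: 1.0 for m in MESHES})
    records: list[BagRecord] = []
    ln100 = math.log(100.0)
    for prolif, sites in config.site_labels().items():
        for site in sites:
            if site in config.site_dropout:
                continue
            for exclusion, plot_suffix in ((True, "1"), (False, "2")):
                plot = f"{site}-{plot_suffix}"
                for species in SPECIES:
                    cell = TreatmentCell(prolif, exclusion, species)
                    k_cell = config.true_k_table[cell]
                    for mesh in MESHES:
                        k = k_cell * mesh_effects[mesh]
                        for rep in range(1, config.n_replicates + 1):
                            for day in REMOVAL_DAYS:
                                records.append(_draw_bag(
                                    config, rng, site, plot, prolif, exclusion,
                                    species, mesh, rep, day, k, mesh_effects[mesh]))
    return records


def _draw_percent(rng, k: float, t: float, sd: float) -> float:
    """One bag's percent remaining: ``exp(ln 100 - k t + eps)``.

    The ln-scale noise ``eps`` is mean-zero with standard deviation ``sd``
    in every cell, and bounded above by ``k t`` so a draw can never imply
    net mass gain (pct stays in (0, 100]).  It is realized as a reflected
    gamma, ``eps = k t - Gamma(mean=k t, sd=sd)``, which converges to
    Normal(0, sd) whenever the expected loss ``k t`` is large relative to
    ``sd`` and skews left (masses hug 100% with occasional larger losses)
    near the no-loss boundary.  Constant variance across cells keeps the
    pooled-residual OLS intervals honest, so the fitter recovers the
    configured rates at nominal coverage.
    """
    if k <= 0 or t <= 0:
        raise ValueError("decay rate and elapsed time must be positive")
    if sd > 0:
        bound = k * t
        shape = (bound / sd) ** 2
        scale = sd * sd / bound
        eps = bound - rng.gamma(shape, scale)
    else:
        eps = 0.0
    # eps <= k*t analytically; min() only trims float round-off at the bound
    return min(100.0, math.exp(math.log(100.0) - k * t + eps))


def _draw_bag(config, rng, site, plot, prolif, exclusion, species, mesh,
              rep, day, k, mesh_mod) -> BagRecord:
    t = year_fraction(day)
    if species != "mixed":
        pct = _draw_percent(rng, k, t, config.ln_noise_sd)
        return BagRecord(site, plot, prolif, exclusion, species, mesh, rep, day,
                         STANDARD_INITIAL_MASS_G,
                         STANDARD_INITIAL_MASS_G * pct / 100.0)
    cell = TreatmentCell(prolif, exclusion, species)
    if config.mixture_component_k and cell in config.mixture_component_k:
        k_maple, k_beech = (v * mesh_mod for v in config.mixture_component_k[cell])
    else:
        k_maple = k_beech = k
    # each component carries sqrt(2) x the configured ln-noise so the
    # summed bag mass has ln-scale noise ~ ln_noise_sd like every other
    # bag; equal residual variance across cells is what makes the
    # generator the exact inverse of the pooled-variance estimator
    comp_sd = config.ln_noise_sd * math.sqrt(2.0)
    maple_mass = MIXED_COMPONENT_INITIAL_G * _draw_percent(rng, k_maple, t, comp_sd) / 100.0
    beech_mass = MIXED_COMPONENT_INITIAL_G * _draw_percent(rng, k_beech, t, comp_sd) / 100.0
    return BagRecord(site, plot, prolif, exclusion, species, mesh, rep, day,
                     STANDARD_INITIAL_MASS_G, maple_mass + beech_mass,
                     maple_final_mass_g=maple_mass, beech_final_mass_g=beech_mass)


def generate_moisture_grid(config: SyntheticEnvironmentConfig, exclusion: bool,
                           seed: int, plot_id: str = "synthetic"):
    """Draw one plot's soil-moisture grid (node = mean of repeated readings).

    Readings are lognormal with the per-reading CV inflated by
    ``sqrt(readings_per_node)`` so the node-level values match the
    configured mean and CV%.  A zero CV collapses to the mean exactly.
    """
    from .environment_stats import MoistureGrid  # local import to avoid cycle

    mean = config.swc_mean_by_exclusion[exclusion]
    cv = config.swc_cv_by_exclusion[exclusion]
    n_nodes = config.grid_shape[0] * config.grid_shape[1]
    rng = np.random.default_rng(seed)
    if cv == 0:
        nodes = np.full(n_nodes, mean)
    else:
        c = (cv / 100.0) * math.sqrt(config.readings_per_node)
        sigma2 = math.log1p(c * c)
        mu = math.log(mean) - sigma2 / 2.0
        readings = rng.lognormal(mu, math.sqrt(sigma2),
                                 size=(n_nodes, config.readings_per_node))
        nodes = readings.mean(axis=1)
    return MoistureGrid(plot_id=plot_id, node_values=nodes,
                        grid_shape=config.grid_shape)


def generate_temperature_log(start_day: int, n_days: int,
                             profile: Sequence[float],
                             interval_minutes: int = 15,
                             diurnal_amplitude: float = 3.0) -> pd.DataFrame:
    """Sub-daily soil-temperature readings whose daily means equal ``profile``.

    A sinusoidal diurnal cycle of the given amplitude is superimposed; its
    samples over a whole day sum to zero exactly, so daily means reproduce
    the profile.  ``interval_minutes`` must divide 1440; 1440 itself yields
    one reading per day with no diurnal cycle.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    if len(profile) == 0:
        raise ValueError("temperature profile must not be empty")
    if 1440 % interval_minutes != 0:
        raise ValueError("interval_minutes must divide 1440")
    daily = np.resize(np.asarray(profile, dtype=float), n_days)
    per_day = 1440 // interval_minutes
    rows = []
    base = pd.Timestamp("2022-06-20") + pd.Timedelta(days=start_day)
    for d in range(n_days):
        for i in range(per_day):
            ts = base + pd.Timedelta(days=d, minutes=i * interval_minutes)
            diurnal = (diurnal_amplitude * math.sin(2 * math.pi * i / per_day)
                       if per_day > 1 else 0.0)
            rows.append((ts, daily[d] + diurnal))
    return pd.DataFrame(rows, columns=["timestamp", "temp_c"])


def write_environment_csvs(config: SyntheticEnvironmentConfig, plots,
                           out_dir: str | Path, seed: int) -> dict[str, Path]:
    """Emit moisture-grid and temperature-log CSVs for a set of plots.

    ``plots`` is an iterable of ``(site, plot_id, exclusion)`` triples.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    moisture_rows = []
    temp_frames = []
    profile = config.temperature_profile or [15.0] * 90
    for i, (site, plot_id, exclusion) in enumerate(plots):
        grid = generate_moisture_grid(config, exclusion, seed + i, plot_id)
        r, c = config.grid_shape
        for idx, value in enumerate(grid.node_values):
            moisture_rows.append((site, plot_id, idx // c + 1, idx % c + 1, value))
        log = generate_temperature_log(0, len(profile), profile)
        log.insert(0, "plot", plot_id)
        temp_frames.append(log)
    moisture = pd.DataFrame(moisture_rows,
                            columns=["site", "plot", "row", "col", "swc_percent"])
    moisture_path = out_dir / "moisture_grid.csv"
    moisture.to_csv(moisture_path, index=False)
    temp_path = out_dir / "temperature_log.csv"
    pd.concat(temp_frames, ignore_index=True).to_csv(temp_path, index=False)
    return {"moisture": moisture_path, "temperature": temp_path}
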
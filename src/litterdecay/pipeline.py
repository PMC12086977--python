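"""End-to-end orchestration: simulate or ingest, fit, test, rank, summarize.

``run_pipeline`` executes the stages in order -- data, instantaneous k,
multigroup fit, additivity, concordance, environment summaries -- logging
each one, and writes a report bundle (CSV + JSON + plain-text summary)
plus a manifest capturing config, seed and software version.  Numeric
outputs are stored at full precision; presentation rounding (3 decimals
for rates, 1 for percentages) is applied only in the text summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data_model import (MESHES, REMOVAL_DAYS, BagRecord, TreatmentCell,
                         read_bag_table, records_to_frame)
from .decay_estimation import fit_multigroup, instantaneous_k_records
from .environment_stats import group_means
from .mixture_additivity import (additivity_z, expected_mixture_k,
                                 expected_mixture_variance)
from .concordance import kendalls_w
from .synthetic_data import (SyntheticConfig, SyntheticEnvironmentConfig,
                             default_study_config, generate_bags,
                             generate_moisture_grid)

log = logging.getLogger("litterdecay")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    mode: str = "simulate"                      # "simulate" | "analyze"
    bag_table: str | None = None                # required in analyze mode
    out_dir: str = "results/run"
    seed: int = 0
    time_basis: str = "year_fraction"
    critical_z: float = 1.96
    tie_correction: bool = True
    synthetic: SyntheticConfig | None = None    # defaults to the study design
    environment: SyntheticEnvironmentConfig = field(
        default_factory=SyntheticEnvironmentConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze" and not self.bag_table:
            raise ValueError("analyze mode requires bag_table")


def _fit_report(fit) -> dict:
    report = {
        "intercept": fit.intercept,
        "intercept_interval": list(fit.intercept_interval),
        "r_squared": fit.r_squared,
        "adj_r_squared": fit.adj_r_squared,
        "nobs": fit.nobs,
        "slopes": {c.label: {
            "slope": fit.slopes[c],
            "ci": list(fit.slope_intervals[c]),
            "se": fit.slope_se[c],
        } for c in fit.slopes},
    }
    if fit.covariate_coefficients:
        report["covariates"] = {
            name: {"coef": coef, "ci": list(ci)}
            for name, (coef, ci) in fit.covariate_coefficients.items()}
    return report


def _decode_fit_report(report: dict) -> "DecayFitResult":
    """Rebuild a DecayFitResult from a fit.json report."""
    from .decay_estimation import DecayFitResult

    slopes = {TreatmentCell.from_label(lbl): entry["slope"]
              for lbl, entry in report["slopes"].items()}
    return DecayFitResult(
        intercept=report["intercept"],
        intercept_interval=tuple(report["intercept_interval"]),
        slopes=slopes,
        slope_intervals={TreatmentCell.from_label(lbl): tuple(e["ci"])
                         for lbl, e in report["slopes"].items()},
        slope_se={TreatmentCell.from_label(lbl): e["se"]
                  for lbl, e in report["slopes"].items()},
        r_squared=report["r_squared"],
        adj_r_squared=report["adj_r_squared"],
        nobs=report["nobs"])


def _additivity_table(fit, critical_z: float) -> pd.DataFrame:
    rows = []
    for prolif in (True, False):
        for excl in (True, False):
            cells = {s: TreatmentCell(prolif, excl, s)
                     for s in ("maple", "beech", "mixed")}
            if any(c not in fit.slopes for c in cells.values()):
                continue
            k_map = fit.slopes[cells["maple"]]
            k_bee = fit.slopes[cells["beech"]]
            observed = fit.slopes[cells["mixed"]]
            expected = expected_mixture_k(k_map, k_bee)
            result = additivity_z(
                observed, fit.slope_se[cells["mixed"]] ** 2,
                expected, expected_mixture_variance(
                    fit.slope_se[cells["maple"]] ** 2,
                    fit.slope_se[cells["beech"]] ** 2),
                critical_value=critical_z)
            rows.append({
                "proliferation": "Yes" if prolif else "No",
                "exclusion": "Yes" if excl else "No",
                "observed_k": result.observed_k,
                "expected_k": result.expected_k,
                "std_diff": result.standardized_difference,
                "z": result.z_score,
                "verdict": result.verdict,
            })
    return pd.DataFrame(rows)


def _concordance_report(records: list[BagRecord], tie_correction: bool) -> dict:
    frame = records_to_frame(records)
    frame["percent_remaining"] = 100 * frame["final_mass_g"] / frame["initial_mass_g"]
    frame["cell"] = [r.cell.label for r in records]
    # removal-date agreement: rank 12 cells by mean remaining at each date
    by_date = frame.pivot_table(index="cell", columns="removal_day",
                                values="percent_remaining", aggfunc="mean")
    removal = kendalls_w(by_date.T, tie_correction=tie_correction)
    # mesh agreement: rank L/M/S by mean 90-day remaining within each cell
    at90 = frame[frame["removal_day"] == max(REMOVAL_DAYS)]
    by_mesh = at90.pivot_table(index="cell", columns="mesh",
                               values="percent_remaining", aggfunc="mean")
    mesh = kendalls_w(by_mesh[list(MESHES)], tie_correction=tie_correction)
    return {
        "removal_dates": {"w": removal.w, "chi_square": removal.chi_square,
                          "df": removal.df, "p_value": removal.p_value},
        "mesh_sizes": {"w": mesh.w, "chi_square": mesh.chi_square,
                       "df": mesh.df, "p_value": mesh.p_value},
    }


def _environment_table(config: RunConfig, records: list[BagRecord]) -> pd.DataFrame:
    plots = sorted({(r.site, r.plot, r.exclusion) for r in records})
    rows = []
    for i, (site, plot, exclusion) in enumerate(plots):
        grid = generate_moisture_grid(config.environment, exclusion,
                                      seed=config.seed * 1000 + i, plot_id=plot)
        s = grid.summary
        rows.append({"site": site, "plot": plot,
                     "exclusion": "Yes" if exclusion else "No",
                     "swc_mean": s.mean, "swc_sd": s.sd, "swc_cv": s.cv_percent})
    table = pd.DataFrame(rows)
    means = group_means(table["swc_mean"], table["exclusion"])
    cvs = group_means(table["swc_cv"], table["exclusion"])
    table.attrs["group_summary"] = {
        "swc_mean_by_exclusion": means["mean"].to_dict(),
        "swc_cv_by_exclusion": cvs["mean"].to_dict(),
    }
    return table


def _summary_text(fit_report: dict, additivity: pd.DataFrame,
                  concordance: dict, environment: pd.DataFrame) -> str:
    lines = ["Litter decay pipeline summary", "=" * 30, ""]
    lines.append(f"Shared intercept: {fit_report['intercept']:.3f} "
                 f"(ln % remaining); R2 = {fit_report['r_squared']:.3f}, "
                 f"adj R2 = {fit_report['adj_r_squared']:.3f}")
    lines.append("")
    lines.append("Decay rates (year^-1, negative = mass loss):")
    for label, entry in fit_report["slopes"].items():
        lo, hi = entry["ci"]
        lines.append(f"  {label:<16s} {entry['slope']:7.3f}  [{lo:.3f}, {hi:.3f}]")
    lines.append("")
    lines.append("Mixture additivity (observed vs expected mixed-bag slope):")
    for _, row in additivity.iterrows():
        lines.append(
            f"  Prolif={row.proliferation:<3s} Excl={row.exclusion:<3s} "
            f"obs={row.observed_k:.3f} exp={row.expected_k:.3f} "
            f"std diff={100 * row.std_diff:.1f}% z={row.z:.2f} -> {row.verdict}")
    lines.append("")
    r = concordance["removal_dates"]
    m = concordance["mesh_sizes"]
    lines.append(f"Concordance across removal dates: W={r['w']:.3f} "
                 f"chi2={r['chi_square']:.2f} df={r['df']} p={r['p_value']:.3f}")
    lines.append(f"Concordance across mesh sizes:    W={m['w']:.3f} "
                 f"chi2={m['chi_square']:.2f} df={m['df']} p={m['p_value']:.3f}")
    lines.append("")
    gs = environment.attrs["group_summary"]
    for excl in ("No", "Yes"):
        lines.append(f"Soil moisture (Exclusion={excl}): mean SWC "
                     f"{gs['swc_mean_by_exclusion'][excl]:.1f}%, "
                     f"mean CV {gs['swc_cv_by_exclusion'][excl]:.1f}%")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return paths and in-memory results."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict = {"out_dir": out_dir}

    def _write_csv(frame: pd.DataFrame, name: str) -> Path:
        path = out_dir / name
        frame.to_csv(path, index=False)
        written.append(path)
        return path

    def _write_json(obj, name: str) -> Path:
        path = out_dir / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))
        written.append(path)
        return path

    stage = "data"
    try:
        log.info("stage %s", stage)
        if config.mode == "simulate":
            syn = config.synthetic or default_study_config(seed=config.seed)
            if config.synthetic is None:
                syn = dataclasses.replace(syn, seed=config.seed)
            records = generate_bags(syn)
            _write_csv(records_to_frame(records), "bags.csv")
        else:
            records = read_bag_table(config.bag_table)
        if not records:
            raise ValueError("no bag records to analyse")
        outputs["n_bags"] = len(records)

        stage = "instantaneous_k"
        log.info("stage %s", stage)
        inst = instantaneous_k_records(records)
        inst_frame = records_to_frame(records)
        inst_frame["instant_k"] = [i.k for i in inst]
        _write_csv(inst_frame, "instantaneous_k.csv")

        stage = "fit"
        log.info("stage %s", stage)
        fit = fit_multigroup(records, time_basis=config.time_basis)
        fit_report = _fit_report(fit)
        _write_json(fit_report, "fit.json")
        _write_csv(fit.to_frame(), "fit.csv")
        outputs["fit"] = fit

        stage = "additivity"
        log.info("stage %s", stage)
        additivity = _additivity_table(fit, config.critical_z)
        _write_csv(additivity, "additivity.csv")
        outputs["additivity"] = additivity

        stage = "concordance"
        log.info("stage %s", stage)
        concordance = _concordance_report(records, config.tie_correction)
        _write_json(concordance, "concordance.json")
        outputs["concordance"] = concordance

        stage = "environment"
        log.info("stage %s", stage)
        environment = _environment_table(config, records)
        _write_csv(environment, "environment.csv")
        _write_json(environment.attrs["group_summary"], "environment_summary.json")
        outputs["environment"] = environment

        stage = "report"
        log.info("stage %s", stage)
        summary = _summary_text(fit_report, additivity, concordance, environment)
        (out_dir / "summary.txt").write_text(summary)
        written.append(out_dir / "summary.txt")
        digest = hashlib.sha256()
        for path in sorted(written):
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
        manifest = {
            "version": __version__,
            "mode": config.mode,
            "seed": config.seed,
            "time_basis": config.time_basis,
            "critical_z": config.critical_z,
            "tie_correction": config.tie_correction,
            "n_bags": len(records),
            "digest": digest.hexdigest(),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          sort_keys=True))
        outputs["manifest"] = manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return outputs
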
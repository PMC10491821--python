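"""End-to-end pipeline: samples -> fits -> thresholds -> assignments -> misid report.

The pipeline can start from a sample CSV or directly from published fitted
parameters (the intended field-use mode: thresholds and misidentification
rates are computable without any raw data).  Outputs are plain CSV/JSON with
the seed and a config hash recorded for provenance.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .assignment import ThresholdSet, empirical_threshold_set, solve_thresholds
from .constants import CERTAINTY_LEVELS, EMPIRICAL_EXTREMA, GRID_STEP, PUBLISHED_FITS
from .distributions import FittedDist, bootstrap_ci, ks_gof
from .errors import HatchsexError, InvalidConfigError
from .misid import run_misid
from .samples import SampleRecord, concentrations, read_samples, records_to_frame


@dataclass
class PipelineConfig:
    input_path: str | None = None  # sample CSV; None -> use published fits
    family: str = "lognormal"
    boot_iterations: int = 10_000
    certainty_levels: tuple[float, ...] = CERTAINTY_LEVELS
    grid_step: float = GRID_STEP
    n_reps_per_sex: int = 10_000
    seed: int = 0
    out_dir: str = "hatchsex-out"
    statuses: tuple[str, ...] = ("naive", "challenged")
    include_empirical: bool = True
    include_continuous: bool = True

    def __post_init__(self) -> None:
        for c in self.certainty_levels:
            if not 0.5 <= c < 1.0:
                raise InvalidConfigError(f"certainty level {c} outside [0.5, 1)")
        if self.grid_step <= 0:
            raise InvalidConfigError("grid_step must be > 0")

    def hash(self) -> str:
        # out_dir is excluded: it does not affect any computed number
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def fit_groups(
    records: list[SampleRecord], family: str, n_boot: int, seed: int
) -> dict[str, FittedDist]:
    """Fit one distribution per sex x status group present in the records."""
    fits = {}
    offset = 0
    for status in ("naive", "challenged"):
        for sex in ("F", "M"):
            x = concentrations(records, sex=sex, status=status)
            if x.size < 3:
                continue
            key = f"{status}_{'female' if sex == 'F' else 'male'}"
            fit = bootstrap_ci(x, family, n_boot=n_boot, seed=seed + offset)
            fit.ks_statistic, fit.ks_p = ks_gof(x, fit)
            fits[key] = fit
            offset += 1
    return fits


def threshold_table(
    fits: dict[str, FittedDist],
    certainty_levels=CERTAINTY_LEVELS,
    grid_step: float = GRID_STEP,
    statuses=("naive", "challenged"),
) -> pd.DataFrame:
    """Probabilistic decision thresholds for every status and certainty level."""
    rows = []
    for status in statuses:
        fit_f, fit_m = fits[f"{status}_female"], fits[f"{status}_male"]
        for cert in certainty_levels:
            ts = solve_thresholds(fit_f, fit_m, cert, grid_step=grid_step)
            rows.append(
                {
                    "status": status,
                    "certainty": cert,
                    "female_upper_pg_ml": ts.female_upper,
                    "male_lower_pg_ml": ts.male_lower,
                }
            )
    return pd.DataFrame(rows)


def misid_table(
    fits: dict[str, FittedDist],
    config: PipelineConfig,
    empirical_extrema: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Misidentification summary shaped like the published simulation table."""
    empirical_extrema = empirical_extrema or EMPIRICAL_EXTREMA
    rows = []
    seed = config.seed
    for status in config.statuses:
        fit_f, fit_m = fits[f"{status}_female"], fits[f"{status}_male"]
        rules: list[tuple[str, ThresholdSet | str]] = []
        if config.include_empirical and status in empirical_extrema:
            fmax, mmin = empirical_extrema[status]
            rules.append(("empirical", empirical_threshold_set(fmax, mmin, config.grid_step)))
        for cert in config.certainty_levels:
            rules.append(
                ("probabilistic", solve_thresholds(fit_f, fit_m, cert, config.grid_step))
            )
        if config.include_continuous:
            rules.append(("continuous", "continuous"))
        for label, rule in rules:
            seed += 1
            rep = run_misid(fit_f, fit_m, rule, config.n_reps_per_sex, seed=seed)
            rows.append(
                {
                    "status": status,
                    "method": label,
                    "certainty": rep.certainty,
                    "female_upper_pg_ml": getattr(rule, "female_upper", None),
                    "male_lower_pg_ml": getattr(rule, "male_lower", None),
                    "assigned_F": rep.assigned_f_total,
                    "assigned_M": rep.assigned_m_total,
                    "assigned_U": rep.counts["F"]["U"] + rep.counts["M"]["U"],
                    "pct_misid_F": rep.pct_misidentified_f,
                    "pct_misid_M": rep.pct_misidentified_m,
                    "prop_statistic": rep.prop_statistic,
                    "prop_p": rep.prop_p,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run fit -> thresholds -> misid end to end and write a report bundle.

    Returns a dict of the in-memory artifacts; writes ``fits.json``,
    ``thresholds.csv``, ``misid.csv``, ``assignments.csv`` (when samples were
    given) and ``run_log.json`` into ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": asdict(config),
    }

    records: list[SampleRecord] = []
    try:
        if config.input_path is None:
            fits = {k: v for k, v in PUBLISHED_FITS.items()}
            log["fit_source"] = "published constants"
        else:
            records = read_samples(config.input_path)
            log["n_rows"] = len(records)
            fits = fit_groups(records, config.family, config.boot_iterations, config.seed)
            log["fit_source"] = config.input_path
        statuses = tuple(
            s for s in config.statuses if f"{s}_female" in fits and f"{s}_male" in fits
        )

        thr = threshold_table(fits, config.certainty_levels, config.grid_step, statuses)
        mis = misid_table(fits, PipelineConfig(**{**asdict(config), "statuses": statuses}))
    except HatchsexError as exc:
        raise HatchsexError(f"pipeline stage failed: {exc}") from exc

    fits_json = {k: v.to_dict() for k, v in fits.items()}
    (out / "fits.json").write_text(json.dumps(fits_json, indent=2))
    for df, name in ((thr, "thresholds.csv"), (mis, "misid.csv")):
        df.insert(0, "config_hash", log["config_hash"])
        df.to_csv(out / name, index=False)

    assignments = None
    if records:
        unknowns = [r for r in records if r.sex == "U"]
        if unknowns and statuses:
            status = statuses[0]
            ts = solve_thresholds(
                fits[f"{status}_female"], fits[f"{status}_male"], 0.95, config.grid_step
            )
            df = records_to_frame(unknowns)
            df["assigned"] = ts.classify(df["testosterone_pg_ml"].to_numpy())
            df["config_hash"] = log["config_hash"]
            df.to_csv(out / "assignments.csv", index=False)
            assignments = df

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return {"fits": fits, "thresholds": thr, "misid": mis, "assignments": assignments, "log": log}
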
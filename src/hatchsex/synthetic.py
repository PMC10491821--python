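"""Synthetic data generation for the full pipeline.

Generates every input the analysis consumes with the statistical structure
the models assume: known-sex testosterone panels (sex- and challenge-status-
specific lognormals), paired naive/challenged samples with an additive
log-scale FSH shift, unknown-sex "wild" cohorts (latent-sex mixtures), and
competitive-ELISA dilution plates from a generating 4PL curve.

Defaults reproduce the published study conditions: group sample sizes and
lognormal parameters of the captive known-sex panels, FSH shifts equal to
the published challenged-minus-naive log-mean differences for each sex, and
8-step twofold plates spanning the assay's working range.  The FSH response
is modelled additively on the log scale (multiplicatively on pg/mL), so a
challenged concentration is its naive value times ``exp(delta_sex + noise)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ASSAY_RANGE, PUBLISHED_FITS
from .elisa import PlateSeries, fourpl
from .errors import InvalidConfigError
from .samples import SampleRecord


@dataclass
class GeneratorConfig:
    """Conditions for the synthetic cohorts.

    ``params_*`` are (meanlog, sdlog) of the naive lognormal per sex on the
    log-pg/mL scale; ``fsh_shift`` is the additive log-scale challenge shift
    (delta_female, delta_male) and ``fsh_noise_sd`` the log-scale residual SD
    of the individual response.  Defaults are the published naive group sizes
    and fitted parameters, with shifts equal to the published challenged
    minus naive log-means (0.99 for females, 0.85 for males).
    """

    n_female: int = 6
    n_male: int = 18
    params_female: tuple[float, float] = (
        PUBLISHED_FITS["naive_female"].meanlog,
        PUBLISHED_FITS["naive_female"].sdlog,
    )
    params_male: tuple[float, float] = (
        PUBLISHED_FITS["naive_male"].meanlog,
        PUBLISHED_FITS["naive_male"].sdlog,
    )
    fsh_shift: tuple[float, float] = (
        round(PUBLISHED_FITS["challenged_female"].meanlog - PUBLISHED_FITS["naive_female"].meanlog, 2),
        round(PUBLISHED_FITS["challenged_male"].meanlog - PUBLISHED_FITS["naive_male"].meanlog, 2),
    )
    fsh_noise_sd: float = 0.5
    seed: int = 0
    cohort: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise InvalidConfigError("counts must be >= 0")
        for name, (mu, sd) in (("params_female", self.params_female), ("params_male", self.params_male)):
            if sd < 0 or not (math.isfinite(mu) and math.isfinite(sd)):
                raise InvalidConfigError(f"{name}: sdlog must be >= 0 and parameters finite")
        if self.fsh_noise_sd < 0:
            raise InvalidConfigError("fsh_noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _status_params(config: GeneratorConfig, sex: str, status: str) -> tuple[float, float]:
    """Marginal lognormal parameters for one sex and challenge status.

    Challenged marginals follow from the additive log-scale response model:
    the mean shifts by delta_sex and the spread inflates to
    sqrt(sdlog^2 + fsh_noise_sd^2)."""
    mu, sd = config.params_female if sex == "F" else config.params_male
    if status == "challenged":
        delta = config.fsh_shift[0] if sex == "F" else config.fsh_shift[1]
        mu = mu + delta
        sd = math.hypot(sd, config.fsh_noise_sd)
    return mu, sd


def generate_known_sex_panel(
    config: GeneratorConfig, status: str = "naive"
) -> list[SampleRecord]:
    """Known-sex captive panel: n_female + n_male records for one status."""
    if status not in ("naive", "challenged"):
        raise InvalidConfigError(f"status must be 'naive' or 'challenged', got {status!r}")
    rng = config.rng()
    records = []
    for sex, n in (("F", config.n_female), ("M", config.n_male)):
        mu, sd = _status_params(config, sex, status)
        draws = rng.lognormal(mean=mu, sigma=sd, size=n)
        for i, x in enumerate(draws):
            records.append(
                SampleRecord(
                    individual_id=f"{config.cohort}-{sex}{i:04d}",
                    cohort=config.cohort,
                    sex=sex,
                    status=status,
                    testosterone_pg_ml=float(x),
                )
            )
    return records


def generate_paired_fsh(config: GeneratorConfig) -> list[SampleRecord]:
    """Paired naive + challenged samples per individual.

    The challenged log-concentration is the naive log-concentration plus the
    sex-specific shift plus Gaussian noise; pairs share an individual id.
    Records come back naive-then-challenged per individual.
    """
    rng = config.rng()
    records = []
    for sex, n in (("F", config.n_female), ("M", config.n_male)):
        mu, sd = config.params_female if sex == "F" else config.params_male
        delta = config.fsh_shift[0] if sex == "F" else config.fsh_shift[1]
        log_naive = rng.normal(mu, sd, size=n)
        noise = (
            rng.normal(0.0, config.fsh_noise_sd, size=n)
            if config.fsh_noise_sd > 0
            else np.zeros(n)
        )
        log_chal = log_naive + delta + noise
        for i in range(n):
            iid = f"{config.cohort}-{sex}{i:04d}"
            records.append(
                SampleRecord(iid, config.cohort, sex, "naive", float(np.exp(log_naive[i])))
            )
            records.append(
                SampleRecord(iid, config.cohort, sex, "challenged", float(np.exp(log_chal[i])))
            )
    return records


def generate_wild_cohort(
    config: GeneratorConfig, mix_prop_male: float = 0.5, status: str = "naive"
) -> list[SampleRecord]:
    """Unknown-sex wild cohort: a latent-sex mixture draw.

    Cohort size is ``n_female + n_male``; each animal's latent sex is
    Bernoulli(``mix_prop_male``) and its concentration is drawn from the
    latent sex's distribution for ``status``.  The latent sex is kept in the
    ``latent_sex`` field for validation; the ``sex`` label is "U".
    """
    if not 0.0 <= mix_prop_male <= 1.0:
        raise InvalidConfigError(f"mix_prop_male must be in [0, 1], got {mix_prop_male}")
    rng = config.rng()
    n = config.n_female + config.n_male
    latent = np.where(rng.random(n) < mix_prop_male, "M", "F")
    records = []
    for i, sex in enumerate(latent):
        mu, sd = _status_params(config, str(sex), status)
        x = rng.lognormal(mean=mu, sigma=sd)
        records.append(
            SampleRecord(
                individual_id=f"{config.cohort}-W{i:04d}",
                cohort=config.cohort,
                sex="U",
                status=status,
                testosterone_pg_ml=float(x),
                latent_sex=str(sex),
            )
        )
    return records


def generate_plate(
    fourpl_params: tuple[float, float, float, float] = (1.0, 0.0, 100.0, 50.0),
    dilution_steps: int = 8,
    noise_sd: float = 2.0,
    duplicates: int = 2,
    seed: int | None = None,
    top_concentration: float = ASSAY_RANGE[1],
    series_id: str = "standard",
    plate_id: str = "plate-1",
) -> PlateSeries:
    """Twofold dilution series from a generating 4PL curve.

    ``fourpl_params`` is (b, c, d, e); responses are 4PL(conc) plus Gaussian
    noise in %B/B0 units, duplicates share a concentration.  The default
    8-step series runs from the assay's top calibrator down by factors of 2.
    """
    if dilution_steps < 5:
        raise InvalidConfigError(
            f"need >= 5 dilution steps to identify 4 parameters, got {dilution_steps}"
        )
    if duplicates < 1:
        raise InvalidConfigError("duplicates must be >= 1")
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be >= 0")
    b, c, d, e = fourpl_params
    rng = np.random.default_rng(seed)
    concs = top_concentration / (2.0 ** np.arange(dilution_steps))
    wells = []
    for conc in concs:
        mean_resp = float(fourpl(conc, b, c, d, e))
        for rep in range(duplicates):
            resp = mean_resp + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            wells.append((float(conc), float(resp), rep))
    return PlateSeries(series_id=series_id, wells=wells, plate_id=plate_id)


#: Ready-made configurations mirroring the published cohorts.
PRESETS: dict[str, GeneratorConfig] = {
    "naive_panel": GeneratorConfig(n_female=6, n_male=18),
    "challenged_panel": GeneratorConfig(
        n_female=9,
        n_male=22,
        params_female=(
            PUBLISHED_FITS["challenged_female"].meanlog,
            PUBLISHED_FITS["challenged_female"].sdlog,
        ),
        params_male=(
            PUBLISHED_FITS["challenged_male"].meanlog,
            PUBLISHED_FITS["challenged_male"].sdlog,
        ),
        fsh_shift=(0.0, 0.0),
    ),
    "paired": GeneratorConfig(n_female=6, n_male=17),
    "wild": GeneratorConfig(n_female=24, n_male=24),
}
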
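"""Published reference values for hatchling Mojave desert tortoise testosterone.

These constants let thresholds and misidentification simulations be computed
without access to the raw field data: the fitted lognormal parameters (with
95% bootstrap confidence intervals and Kolmogorov-Smirnov goodness-of-fit
results) for each sex x FSH-challenge-status group, the observed concentration
extrema, and assay metadata.  Concentrations are plasma testosterone in pg/mL
throughout; ``meanlog``/``sdlog`` are on the natural-log pg/mL scale.
"""

from __future__ import annotations

from .distributions import FittedDist

#: Fitted lognormal distributions per group, keyed "<status>_<sex>".
#: Each carries the point estimates, 95% bootstrap CIs, sample size and
#: one-sample K-S goodness-of-fit result for the published captive panels.
PUBLISHED_FITS: dict[str, FittedDist] = {
    "naive_female": FittedDist(
        family="lognormal",
        params={"meanlog": 2.46, "sdlog": 0.29},
        ci={"meanlog": (2.23, 2.70), "sdlog": (0.11, 0.43)},
        n=6,
        ks_statistic=0.244,
        ks_p=0.795,
        boot_iterations=10_000,
    ),
    "naive_male": FittedDist(
        family="lognormal",
        params={"meanlog": 5.69, "sdlog": 0.53},
        ci={"meanlog": (5.44, 5.94), "sdlog": (0.35, 0.69)},
        n=18,
        ks_statistic=0.207,
        ks_p=0.376,
        boot_iterations=10_000,
    ),
    "challenged_female": FittedDist(
        family="lognormal",
        params={"meanlog": 3.45, "sdlog": 0.68},
        ci={"meanlog": (3.01, 3.90), "sdlog": (0.34, 0.95)},
        n=9,
        ks_statistic=0.238,
        ks_p=0.606,
        boot_iterations=10_000,
    ),
    "challenged_male": FittedDist(
        family="lognormal",
        params={"meanlog": 6.54, "sdlog": 0.85},
        ci={"meanlog": (6.20, 6.90), "sdlog": (0.58, 1.08)},
        n=22,
        ks_statistic=0.090,
        ks_p=0.987,
        boot_iterations=10_000,
    ),
}

#: Observed (min, max) concentration per group, pg/mL.
OBSERVED_RANGE: dict[str, tuple[float, float]] = {
    "naive_female": (7.8, 20.8),
    "naive_male": (125.4, 651.4),
    "challenged_female": (15.6, 139.0),
    "challenged_male": (114.8, 3773.9),
}

#: Empirical-range decision bounds (female_max_obs, male_min_obs) per status.
#: Naive groups do not overlap; the challenged groups overlap on
#: [114.8, 139.0], and the published rule assigns F strictly below the male
#: minimum and M strictly above the female maximum (the "unknown" band is the
#: overlap itself).
EMPIRICAL_EXTREMA: dict[str, tuple[float, float]] = {
    "naive": (20.8, 125.4),
    "challenged": (139.0, 114.8),
}

#: Alternative challenged bounds using the first extrema *outside* the range
#: of overlap (next-highest female, next-lowest male), an option some field
#: protocols prefer over the strict-overlap rule.
CHALLENGED_OUTSIDE_OVERLAP: tuple[float, float] = (68.1, 198.1)

#: Certainty levels used for the published probabilistic decision thresholds.
CERTAINTY_LEVELS: tuple[float, ...] = (0.5, 0.80, 0.95, 0.9999)

#: Integration bin around a measured concentration, pg/mL: the density mass
#: for each sex is integrated over [x - BIN_BELOW, x + BIN_ABOVE].
BIN_BELOW: float = 0.05
BIN_ABOVE: float = 0.049

#: Reporting grid for thresholds, pg/mL.
GRID_STEP: float = 0.1

#: Default threshold search range, pg/mL; brackets the assay working range and
#: excludes the spurious very-low-concentration density crossing.
SEARCH_RANGE: tuple[float, float] = (0.1, 10_000.0)

#: Quantifiable range of the testosterone ELISA kit, pg/mL.
ASSAY_RANGE: tuple[float, float] = (3.9, 500.0)

#: Plasma extraction efficiency determined with the same kit on a congeneric
#: tortoise.  Carried as metadata only; concentrations are NOT corrected.
EXTRACTION_EFFICIENCY: dict[str, float | bool] = {
    "mean": 0.941,
    "sd": 0.16,
    "applied_as_correction": False,
}
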
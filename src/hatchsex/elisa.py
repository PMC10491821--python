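"""Competitive ELISA analytics: 4PL calibration, parallelism, QC.

The response axis is %B/B0 (bound over maximally-bound tracer); in a
competitive assay it decreases with analyte concentration.  Curves are
modelled with the four-parameter logistic on the log-concentration axis,

    y = c + (d - c) / (1 + exp(b * (ln x - ln e))),

with lower asymptote ``c``, upper asymptote ``d``, slope ``b`` at the
inflection and inflection concentration ``e`` (the "effective dose 50%").
Parallelism between a sample dilution series and the kit standard is tested
with nested Gaussian-likelihood ratio tests that share the two asymptotes
and ask whether slope and/or ED50 differ between the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DomainError,
    FitError,
    InsufficientDataError,
    OutOfRangeError,
    UndefinedCVError,
)


@dataclass
class PlateSeries:
    """A dilution series on one plate: wells of (concentration, %B/B0, replicate)."""

    series_id: str  # "standard" | "pooled" | "sample" | free label
    wells: list[tuple[float, float, int]]
    plate_id: str = "plate-1"

    def __post_init__(self) -> None:
        for conc, resp, _rep in self.wells:
            if conc <= 0:
                raise DomainError(f"well concentration must be > 0, got {conc}")
            if not math.isfinite(resp):
                raise DomainError("well responses must be finite")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([w[0] for w in self.wells], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([w[1] for w in self.wells], dtype=float)


@dataclass
class FourPLFit:
    b: float  # slope at inflection (log-concentration axis)
    c: float  # lower asymptote, %B/B0
    d: float  # upper asymptote, %B/B0
    e: float  # inflection concentration (ED50), pg/mL
    rss: float = 0.0
    n: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.c < self.d:
            raise DomainError(f"lower asymptote c ({self.c}) must be below d ({self.d})")
        if not self.e > 0:
            raise DomainError(f"inflection e must be > 0, got {self.e}")

    def predict(self, x):
        return fourpl(np.asarray(x, dtype=float), self.b, self.c, self.d, self.e)


def fourpl(x, b, c, d, e):
    """Four-parameter logistic response at concentration(s) ``x``."""
    z = b * (np.log(x) - np.log(e))
    return c + (d - c) / (1.0 + np.exp(np.clip(z, -700, 700)))


def _initial_guess(x, y):
    c0, d0 = float(np.min(y)), float(np.max(y))
    span = d0 - c0
    c0, d0 = c0 - 0.05 * span - 1e-6, d0 + 0.05 * span + 1e-6
    e0 = float(np.exp(np.mean(np.log(x))))
    slope_sign = 1.0 if np.corrcoef(np.log(x), y)[0, 1] < 0 else -1.0
    return [slope_sign, c0, d0, e0]


def fit_4pl(series: PlateSeries) -> FourPLFit:
    """Least-squares 4PL fit of one dilution series.

    Requires at least 5 distinct concentrations.  Non-monotonic mean
    responses are tolerated (noise) but a warning-level check guards against
    grossly non-sigmoid input via the convergence test.
    """
    x, y = series.concentrations, series.responses
    if np.unique(x).size < 5:
        raise InsufficientDataError(
            f"need >= 5 distinct concentrations, got {np.unique(x).size}"
        )
    p0 = _initial_guess(x, y)
    try:
        popt, _ = optimize.curve_fit(
            fourpl,
            x,
            y,
            p0=p0,
            maxfev=20_000,
            bounds=([-50, -np.inf, -np.inf, 1e-12], [50, np.inf, np.inf, np.inf]),
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"4PL fit failed for series {series.series_id!r}: {exc}") from exc
    b, c, d, e = (float(v) for v in popt)
    if c > d:  # swap asymptotes and flip slope: identical curve
        b, c, d = -b, d, c
    resid = y - fourpl(x, b, c, d, e)
    return FourPLFit(b=b, c=c, d=d, e=e, rss=float(np.sum(resid**2)), n=int(x.size))


def invert_4pl(fit: FourPLFit, response: float) -> float:
    """Concentration whose fitted response equals ``response`` (inverse
    prediction); requires ``c < response < d``."""
    if not (fit.c < response < fit.d):
        raise OutOfRangeError(
            f"response {response} outside the open asymptote range ({fit.c}, {fit.d})"
        )
    ratio = (fit.d - fit.c) / (response - fit.c) - 1.0
    return float(fit.e * math.exp(math.log(ratio) / fit.b))


@dataclass
class ParallelismResult:
    """Nested LRTs between a standard and a sample dilution series.

    The full model shares the asymptotes (c, d) but lets slope and ED50
    differ between series; the reduced model shares all four parameters.
    ``chi2``, ``df``, ``p`` refer to the reduced-vs-full test (df = 2);
    ``submodels`` carries the one-parameter tests ("slope_only",
    "ed50_only" different) against the full model, each on 1 df.
    """

    chi2: float
    df: int
    p: float
    rss_full: float
    rss_reduced: float
    n: int
    submodels: dict[str, dict[str, float]] = field(default_factory=dict)
    fits: dict[str, tuple] = field(default_factory=dict)


def _fit_shared(x1, y1, x2, y2, variant: str, p0):
    """Least-squares fit of the combined two-series model.

    variant: "full" (c,d shared; b,e per series), "slope" (only b differs),
    "ed50" (only e differs), "reduced" (all shared).  Parameters are packed
    with ln e for stability.
    """

    def unpack(theta):
        if variant == "full":
            c, d, b1, le1, b2, le2 = theta
        elif variant == "slope":
            c, d, b1, le1, b2 = theta
            le2 = le1
        elif variant == "ed50":
            c, d, b1, le1, le2 = theta
            b2 = b1
        else:
            c, d, b1, le1 = theta
            b2, le2 = b1, le1
        return c, d, b1, le1, b2, le2

    def resid(theta):
        c, d, b1, le1, b2, le2 = unpack(theta)
        r1 = y1 - fourpl(x1, b1, c, d, math.exp(le1))
        r2 = y2 - fourpl(x2, b2, c, d, math.exp(le2))
        return np.concatenate([r1, r2])

    sol = optimize.least_squares(resid, p0, max_nfev=40_000)
    if not sol.success:
        raise FitError(f"combined {variant} model failed to converge")
    rss = float(np.sum(sol.fun**2))
    return sol.x, rss, unpack(sol.x)


def parallelism_lrt(standard: PlateSeries, pooled: PlateSeries) -> ParallelismResult:
    """Likelihood-ratio parallelism test between two dilution series.

    Gaussian likelihood with constant error variance gives
    ``chi2 = n * ln(RSS_reduced / RSS_full)`` on ``df = 2`` for the main
    test; the intermediate models (only slope free, only ED50 free) are
    reported against the full model on 1 df each.  A non-significant main
    test supports parallelism (the sample behaves like the standard).
    """
    f1 = fit_4pl(standard)
    f2 = fit_4pl(pooled)
    x1, y1 = standard.concentrations, standard.responses
    x2, y2 = pooled.concentrations, pooled.responses
    n = int(x1.size + x2.size)

    # fit reduced first, then seed richer models from it so nesting holds
    c0 = (f1.c + f2.c) / 2.0
    d0 = (f1.d + f2.d) / 2.0
    b0 = (f1.b + f2.b) / 2.0
    le0 = (math.log(f1.e) + math.log(f2.e)) / 2.0
    _, rss_red, red_params = _fit_shared(x1, y1, x2, y2, "reduced", [c0, d0, b0, le0])
    c, d, b, le = red_params[0], red_params[1], red_params[2], red_params[3]
    _, rss_slope, _ = _fit_shared(x1, y1, x2, y2, "slope", [c, d, b, le, b])
    _, rss_ed50, _ = _fit_shared(x1, y1, x2, y2, "ed50", [c, d, b, le, le])
    start_full = [c, d, b, le, b, le]
    _, rss_full, full_params = _fit_shared(x1, y1, x2, y2, "full", start_full)
    # guard nesting against optimizer wobble
    rss_full = min(rss_full, rss_slope, rss_ed50, rss_red)

    def lrt(rss_restricted, df):
        chi2 = max(0.0, n * math.log(rss_restricted / rss_full))
        return chi2, float(stats.chi2.sf(chi2, df))

    chi2_main, p_main = lrt(rss_red, 2)
    chi2_b, p_b = lrt(rss_ed50, 1)  # ed50 shared => tests slope difference? see below
    chi2_e, p_e = lrt(rss_slope, 1)

    # naming from the free parameter's perspective: "slope_only" lets only the
    # slope differ, so comparing it to the full model tests the ED50 split.
    submodels = {
        "slope_only_vs_full": {"chi2": chi2_e, "df": 1, "p": p_e, "rss": rss_slope},
        "ed50_only_vs_full": {"chi2": chi2_b, "df": 1, "p": p_b, "rss": rss_ed50},
    }
    return ParallelismResult(
        chi2=chi2_main,
        df=2,
        p=p_main,
        rss_full=rss_full,
        rss_reduced=rss_red,
        n=n,
        submodels=submodels,
        fits={"standard": (f1.b, f1.c, f1.d, f1.e), "pooled": (f2.b, f2.c, f2.d, f2.e),
              "full_shared": tuple(float(v) for v in full_params[:2])},
    )


@dataclass
class QCResult:
    bb0_strict_pass: bool  # inside 20-80 %B/B0
    bb0_permissive_pass: bool  # inside 10-90 %B/B0
    dup_cv: float  # duplicate CV, %
    rerun_flag: bool


def qc_evaluate(wells: Sequence[float], bb0: float) -> QCResult:
    """QC one sample: replicate CV and %B/B0 window checks.

    ``dup_cv`` is 100 * SD / mean over the replicate responses (sample SD,
    divisor n-1; a single replicate gives CV 0).  ``rerun_flag`` is raised
    when the CV exceeds 20% or the sample sits outside the strict 20-80%
    B/B0 quantification window.
    """
    w = np.asarray(wells, dtype=float)
    if w.size < 1:
        raise InsufficientDataError("need at least one replicate")
    mean = float(np.mean(w))
    if mean == 0:
        raise UndefinedCVError("replicate mean is 0; CV undefined")
    dup_cv = 0.0 if w.size == 1 else float(100.0 * np.std(w, ddof=1) / mean)
    strict = 20.0 <= bb0 <= 80.0
    permissive = 10.0 <= bb0 <= 90.0
    return QCResult(
        bb0_strict_pass=strict,
        bb0_permissive_pass=permissive,
        dup_cv=dup_cv,
        rerun_flag=dup_cv > 20.0 or not strict,
    )


def plate_cvs(control_wells: dict[str, Sequence[float]]) -> tuple[float, float]:
    """Intra- and interplate CVs from a shared control sample.

    ``control_wells`` maps plate id to the control's replicate responses on
    that plate.  Returns (mean intraplate CV %, interplate CV %): intraplate
    CV is 100*SD/mean of replicates within each plate, averaged across
    plates; interplate CV is 100*SD/mean of the per-plate control means.
    """
    if len(control_wells) < 2:
        raise InsufficientDataError("interplate CV needs the control on >= 2 plates")
    intra, means = [], []
    for plate, wells in control_wells.items():
        w = np.asarray(wells, dtype=float)
        if w.size == 0:
            raise InsufficientDataError(f"plate {plate!r} has no control wells")
        m = float(np.mean(w))
        if m == 0:
            raise UndefinedCVError(f"plate {plate!r} control mean is 0")
        intra.append(0.0 if w.size == 1 else 100.0 * float(np.std(w, ddof=1)) / m)
        means.append(m)
    means = np.asarray(means)
    inter = float(100.0 * np.std(means, ddof=1) / np.mean(means))
    return float(np.mean(intra)), inter
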
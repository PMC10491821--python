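"""Paired FSH-challenge response tests.

Did the FSH injection elevate testosterone differently in males than in
females?  The primary test is a 2 (sex, between subjects) x 2 (challenge
status, within subjects) repeated-measures ANOVA on paired (log-)
concentrations; the key quantity is the sex x status interaction F with
(1, n-2) degrees of freedom.  For a two-level within factor this mixed
design reduces exactly to analyses of per-subject difference and mean
scores, which is how it is computed here (Type III style: the challenge
main effect tests the unweighted average of the two sexes' mean changes, so
group imbalance does not tilt it).  An independent general-purpose mixed
ANOVA is used as a cross-check in the test suite.

A permutation test on per-individual change (absolute or percent scale)
is provided for comparison with related work on a congeneric species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DesignError, DomainError, InsufficientDataError, PairingError
from .samples import SampleRecord


@dataclass
class PairedSample:
    individual_id: str
    sex: str  # "F" | "M"
    t_naive: float
    t_challenged: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise DomainError(f"sex must be F or M, got {self.sex!r}")
        if not (self.t_naive > 0 and self.t_challenged > 0):
            raise DomainError("both concentrations must be > 0")


@dataclass
class RanovaResult:
    f_interaction: float
    p_interaction: float
    df: tuple[int, int]
    f_sex: float
    p_sex: float
    f_challenge: float
    p_challenge: float
    levene_p: float
    shapiro_p: float
    transformed: bool  # log scale applied


def pair_records(records: Iterable[SampleRecord]) -> list[PairedSample]:
    """Assemble naive/challenged pairs by individual id.

    Individuals lacking either sample are dropped with a warning (they cannot
    contribute to a within-subject contrast); duplicated samples for one
    individual and status raise a pairing error.
    """
    by_id: dict[str, dict] = {}
    for r in records:
        slot = by_id.setdefault(r.individual_id, {"sex": r.sex})
        if r.status in slot:
            raise PairingError(f"duplicate {r.status} sample for {r.individual_id}")
        slot[r.status] = r.testosterone_pg_ml
        if r.sex != "U":
            slot["sex"] = r.sex
    pairs, dropped = [], []
    for iid, slot in by_id.items():
        if "naive" in slot and "challenged" in slot:
            pairs.append(PairedSample(iid, slot["sex"], slot["naive"], slot["challenged"]))
        else:
            dropped.append(iid)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} individual(s) without both samples: {dropped}")
    return pairs


def _split(pairs: Sequence[PairedSample], log_transform: bool):
    pairs = list(pairs)
    sexes = np.array([p.sex for p in pairs])
    pre = np.array([p.t_naive for p in pairs], dtype=float)
    post = np.array([p.t_challenged for p in pairs], dtype=float)
    if log_transform:
        pre, post = np.log(pre), np.log(post)
    for s in ("F", "M"):
        if np.count_nonzero(sexes == s) < 2:
            raise DesignError(f"need at least 2 complete pairs of sex {s}")
    return sexes, pre, post


def ranova_paired(pairs: Sequence[PairedSample], log_transform: bool = True) -> RanovaResult:
    """Mixed 2x2 repeated-measures ANOVA on paired concentrations.

    Between factor: sex; within factor: challenge status.  A significant
    interaction means the sexes responded differently to the challenge.
    Levene's test (median-centred) on the four sex x status cells and the
    Shapiro-Wilk test on cell-centred residuals accompany the F tests.

    With zero residual variance (e.g. noiseless synthetic data) a nonzero
    effect yields ``inf`` F and p = 0; a zero effect yields F = 0.
    """
    sexes, pre, post = _split(pairs, log_transform)
    n = len(sexes)
    is_m = sexes == "M"
    n_f, n_m = int(np.sum(~is_m)), int(np.sum(is_m))

    diff = post - pre  # within-subject change
    subj_mean = (post + pre) / 2.0

    def group_stats(v):
        vf, vm = v[~is_m], v[is_m]
        ssw = np.sum((vf - vf.mean()) ** 2) + np.sum((vm - vm.mean()) ** 2)
        return vf.mean(), vm.mean(), ssw

    # --- within-subject stratum: challenge main effect and interaction ------
    # y_i,post - y_i,pre = 2*(status effect) + 2*(interaction by sex) + noise
    df_err = n - 2
    mdf_f, mdf_m, ss_err_d = group_stats(diff)
    ms_err_d = ss_err_d / df_err / 2.0  # per-observation error MS (factor 2: diff of two obs)

    # interaction: difference of mean changes between sexes
    ss_inter = (mdf_m - mdf_f) ** 2 / (1.0 / n_f + 1.0 / n_m) / 2.0
    # challenge: unweighted (Type III) average change across sexes
    ss_chal = ((mdf_f + mdf_m) / 2.0) ** 2 / (0.25 * (1.0 / n_f + 1.0 / n_m)) / 2.0

    # --- between-subject stratum: sex main effect ---------------------------
    msm_f, msm_m, ss_err_s = group_stats(subj_mean)
    ms_err_s = ss_err_s / df_err * 2.0  # subject means average two observations
    ss_sex = (msm_m - msm_f) ** 2 / (1.0 / n_f + 1.0 / n_m) * 2.0

    def f_and_p(ss_effect, ms_error):
        if ms_error <= 1e-20:
            # zero-residual stratum: a genuinely nonzero effect diverges,
            # while float dust in an exactly-null effect is treated as zero
            f = math.inf if ss_effect > 1e-18 else 0.0
        else:
            f = ss_effect / ms_error
        p = float(stats.f.sf(f, 1, df_err)) if math.isfinite(f) else 0.0
        return float(f), p

    f_i, p_i = f_and_p(ss_inter, ms_err_d)
    f_c, p_c = f_and_p(ss_chal, ms_err_d)
    f_s, p_s = f_and_p(ss_sex, ms_err_s)

    # assumption checks
    cells = [pre[~is_m], pre[is_m], post[~is_m], post[is_m]]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            levene_p = float(stats.levene(*cells, center="median").pvalue)
    except Exception:
        levene_p = float("nan")
    resid = np.concatenate(
        [
            pre[~is_m] - pre[~is_m].mean(),
            pre[is_m] - pre[is_m].mean(),
            post[~is_m] - post[~is_m].mean(),
            post[is_m] - post[is_m].mean(),
        ]
    )
    if np.allclose(resid, 0.0):
        shapiro_p = float("nan")
    else:
        shapiro_p = float(stats.shapiro(resid).pvalue)

    return RanovaResult(
        f_interaction=f_i,
        p_interaction=p_i,
        df=(1, df_err),
        f_sex=f_s,
        p_sex=p_s,
        f_challenge=f_c,
        p_challenge=p_c,
        levene_p=levene_p,
        shapiro_p=shapiro_p,
        transformed=log_transform,
    )


def permutation_change_test(
    pairs: Sequence[PairedSample],
    scale: str = "absolute",
    n_perm: int = 9_999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test of the sex difference in mean pre-to-post change.

    The statistic is mean(change | M) - mean(change | F), with change either
    the absolute difference (pg/mL) or the percent difference
    ``100 * (post - pre) / pre``.  Sex labels are permuted across
    individuals; the two-sided p-value counts permutations whose absolute
    statistic is at least the observed one and includes the observed
    labelling in both numerator and denominator, so p is never 0.
    """
    if scale not in ("absolute", "percent"):
        raise DomainError(f"scale must be 'absolute' or 'percent', got {scale!r}")
    if n_perm < 999:
        raise InsufficientDataError(f"n_perm must be >= 999, got {n_perm}")
    sexes, pre, post = _split(pairs, log_transform=False)
    change = post - pre if scale == "absolute" else 100.0 * (post - pre) / pre
    is_m = sexes == "M"
    observed = float(change[is_m].mean() - change[~is_m].mean())

    rng = np.random.default_rng(seed)
    n = len(change)
    n_m = int(np.sum(is_m))
    total = change.sum()
    count = 0
    for _ in range(n_perm):
        perm_m = rng.choice(n, size=n_m, replace=False)
        mean_m = change[perm_m].mean()
        mean_f = (total - change[perm_m].sum()) / (n - n_m)
        if abs(mean_m - mean_f) >= abs(observed) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return observed, float(p)
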
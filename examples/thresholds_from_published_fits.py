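"""Decision thresholds for sexing hatchlings from a single testosterone value.

Uses only the published fitted lognormal parameters (no raw data needed) to
solve, at each certainty level, the concentration below which a hatchling is
called female and above which male; concentrations in between are "unknown".
"""

from hatchsex import solve_thresholds
from hatchsex.constants import CERTAINTY_LEVELS, PUBLISHED_FITS

for status in ("naive", "challenged"):
    fit_f = PUBLISHED_FITS[f"{status}_female"]
    fit_m = PUBLISHED_FITS[f"{status}_male"]
    print(f"\n{status} samples  (F: lognormal({fit_f.meanlog}, {fit_f.sdlog}), "
          f"M: lognormal({fit_m.meanlog}, {fit_m.sdlog}))")
    for cert in CERTAINTY_LEVELS:
        ts = solve_thresholds(fit_f, fit_m, cert)
        if ts.female_upper == ts.male_lower:
            print(f"  {cert:>7.2%}:  F < {ts.female_upper} < M   (single threshold)")
        else:
            print(f"  {cert:>7.2%}:  F <= {ts.female_upper} < U < {ts.male_lower} <= M")

# A hatchling at 37.7 pg/mL (naive) sits exactly at the 50% crossing: the two
# fitted densities carry equal mass there, so either sex is equally likely.
# Higher certainty levels widen the "unknown" band symmetrically in
# probability (not in pg/mL) around that crossing.
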
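"""Sample records and CSV input/output.

One :class:`SampleRecord` is one animal on one sampling occasion.  CSV files
use one row per occasion with the documented header; unknown latent sex and
morphometrics are optional columns.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

SEXES = ("F", "M", "U")
STATUSES = ("naive", "challenged")

REQUIRED_COLUMNS = ["individual_id", "cohort", "sex", "status", "testosterone_pg_ml"]
OPTIONAL_COLUMNS = ["latent_sex", "mass_g", "mcl_mm", "bb0", "cv_dup"]


@dataclass
class SampleRecord:
    """One animal x one sampling occasion.

    ``latent_sex`` holds the hidden true sex of synthetic unknown-sex animals
    so validation code can score assignments; it must never be fed to the
    classifier path.
    """

    individual_id: str
    cohort: str
    sex: str
    status: str
    testosterone_pg_ml: float
    latent_sex: str | None = None
    mass_g: float | None = None
    mcl_mm: float | None = None
    bb0: float | None = None
    cv_dup: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.status not in STATUSES:
            raise DomainError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.testosterone_pg_ml is not None and not self.testosterone_pg_ml > 0:
            raise DomainError(
                f"testosterone must be > 0 pg/mL, got {self.testosterone_pg_ml}"
            )


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    cols = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    df = pd.DataFrame([asdict(r) for r in records], columns=cols)
    return df


def frame_to_records(df: pd.DataFrame, source: str = "<frame>") -> list[SampleRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required columns {missing}")
    records, problems = [], []
    for i, row in df.iterrows():
        try:
            kwargs = {c: row[c] for c in REQUIRED_COLUMNS}
            kwargs["testosterone_pg_ml"] = float(kwargs["testosterone_pg_ml"])
            kwargs["individual_id"] = str(kwargs["individual_id"])
            kwargs["cohort"] = str(kwargs["cohort"])
            for c in OPTIONAL_COLUMNS:
                if c in df.columns and pd.notna(row[c]):
                    kwargs[c] = row[c]
            records.append(SampleRecord(**kwargs))
        except (DomainError, ValueError, TypeError) as exc:
            # +2: one for the header line, one for 0-based indexing
            problems.append(f"{source} line {i + 2}: {exc}")
    if problems:
        raise SchemaError("invalid rows:\n" + "\n".join(problems))
    return records


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read and validate a sample CSV; malformed rows are reported with line numbers."""
    path = Path(path)
    df = pd.read_csv(path)
    return frame_to_records(df, source=str(path))


def write_samples(records: Sequence[SampleRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def concentrations(
    records: Iterable[SampleRecord], sex: str | None = None, status: str | None = None
) -> np.ndarray:
    """Concentration vector, optionally filtered by sex and/or status."""
    vals = [
        r.testosterone_pg_ml
        for r in records
        if (sex is None or r.sex == sex) and (status is None or r.status == status)
    ]
    return np.asarray(vals, dtype=float)
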
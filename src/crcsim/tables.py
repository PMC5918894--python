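"""Core input tables: life tables, demography pyramids, calibration targets.

All tables round-trip through plain CSV (comma separated, UTF-8, header row,
period decimal separator) so that every pipeline input is inspectable text.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("male", "female")
LOCATIONS = ("colon", "rectum")
STAGES = ("I", "II", "III", "IV")

TERMINAL_AGE = 110


@dataclass
class LifeTable:
    """Annual other-cause death probabilities q(age) for one sex, ages 0..110.

    Invariants: 0 <= q <= 1 everywhere, q at the terminal age is 1, ages are
    contiguous from 0.
    """

    sex: str
    q: np.ndarray  # shape (TERMINAL_AGE + 1,)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.q.shape != (TERMINAL_AGE + 1,):
            raise ValueError(
                f"life table must cover ages 0..{TERMINAL_AGE} contiguously"
            )
        if np.any(self.q < 0) or np.any(self.q > 1):
            raise ValueError("death probabilities must lie in [0, 1]")
        if self.q[-1] != 1.0:
            raise ValueError("q at the terminal age must equal 1")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(TERMINAL_AGE + 1)


def write_life_tables(tables: dict[str, LifeTable], path) -> None:
    rows = [
        {"sex": sex, "age": int(a), "q": t.q[a]}
        for sex, t in tables.items()
        for a in range(TERMINAL_AGE + 1)
    ]
    pd.DataFrame(rows, columns=["sex", "age", "q"]).to_csv(path, index=False)


def read_life_tables(path) -> dict[str, LifeTable]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for sex, g in df.groupby("sex"):
        g = g.sort_values("age")
        if not np.array_equal(g["age"].to_numpy(), np.arange(len(g))):
            raise ValueError("life table ages must be contiguous from 0")
        out[str(sex)] = LifeTable(str(sex), g["q"].to_numpy())
    return out


@dataclass
class DemographyPyramid:
    """Population counts by sex and single year of age at a reference year."""

    reference_year: int
    counts: pd.DataFrame  # columns: sex, age, count

    def __post_init__(self) -> None:
        df = self.counts
        required = {"sex", "age", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"pyramid needs columns {sorted(required)}")
        if (df["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if df["count"].sum() <= 0:
            raise ValueError("no population")
        self.counts = df.reset_index(drop=True)

    @property
    def total(self) -> int:
        return int(self.counts["count"].sum())

    @property
    def female_share(self) -> float:
        f = self.counts.loc[self.counts["sex"] == "female", "count"].sum()
        return float(f) / self.total

    def to_csv(self, path) -> None:
        self.counts[["sex", "age", "count"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reference_year: int) -> "DemographyPyramid":
        return cls(reference_year, pd.read_csv(path))


@dataclass
class CalibrationTargets:
    """Age-band adenoma prevalence and stage/location CRC incidence targets.

    prevalence columns: sex, age_lo, age_hi, prevalence [, n]
    incidence columns:  sex, age_lo, age_hi, location, stage,
                        rate_per_100k [, person_years]
    The optional ``n`` / ``person_years`` columns carry the effective sample
    sizes used for Pearson residual scaling during calibration.
    """

    prevalence: pd.DataFrame
    incidence: pd.DataFrame

    def __post_init__(self) -> None:
        p, i = self.prevalence, self.incidence
        if ((p["prevalence"] < 0) | (p["prevalence"] > 1)).any():
            raise ValueError("prevalence proportions must lie in [0, 1]")
        if (i["rate_per_100k"] < 0).any():
            raise ValueError("incidence rates must be non-negative")
        for df in (p, i):
            _check_bands(df)
        self.prevalence = p.reset_index(drop=True)
        self.incidence = i.reset_index(drop=True)

    def write(self, prevalence_path, incidence_path) -> None:
        self.prevalence.to_csv(prevalence_path, index=False)
        self.incidence.to_csv(incidence_path, index=False)

    @classmethod
    def read(cls, prevalence_path, incidence_path) -> "CalibrationTargets":
        return cls(pd.read_csv(prevalence_path, float_precision="round_trip"),
                   pd.read_csv(incidence_path, float_precision="round_trip"))


def _check_bands(df: pd.DataFrame) -> None:
    """Age bands must be well-formed and non-overlapping within each stratum."""
    if (df["age_lo"] > df["age_hi"]).any():
        raise ValueError("age_lo must not exceed age_hi")
    keys = [c for c in ("sex", "location", "stage") if c in df.columns]
    for _, g in df.groupby(keys) if keys else [(None, df)]:
        g = g.sort_values("age_lo")
        lo = g["age_lo"].to_numpy()
        hi = g["age_hi"].to_numpy()
        if np.any(lo[1:] <= hi[:-1]):
            raise ValueError("age bands overlap")


def default_age_bands(lo: int = 40, hi: int = 85, width: int = 5) -> list[tuple[int, int]]:
    """5-year registry-style bands 40-44 ... 80-84 plus an open 85+ band."""
    bands = [(a, a + width - 1) for a in range(lo, hi, width)]
    bands.append((hi, TERMINAL_AGE))
    return bands
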
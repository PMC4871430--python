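"""Cohort survival (lx) input/output and entry-age truncation.

Supports two plain-text dialects:

* the HMD cohort-survivors dialect: a couple of header lines, then
  whitespace-delimited columns ``Year  Age  Female  Male  Total`` (an
  optional ``Births`` column enables birth-weighted pooling of a cohort
  range); the terminal age ``110+`` marks the open-ended interval;
* a minimal delimited format with header ``age,survivors``.

The preprocessing mirrors the standard treatment of historical cohort data
with unreliable childhood coverage: drop ages below a truncation age and
rescale so survivorship equals the radix at entry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .simulate import CAUSE_CENSORED, IntervalDeaths

__all__ = [
    "CohortSurvival",
    "read_hmd_cohort_lx",
    "read_cohort_csv",
    "write_cohort_csv",
    "truncate_renormalize",
    "cohort_to_interval_deaths",
    "records_to_cohort",
]


@dataclass(frozen=True)
class CohortSurvival:
    """Survivorship curve for one cohort: lx at each tabulated exact age."""

    ages: np.ndarray
    lx: np.ndarray
    radix: float
    cohort_label: str = ""
    truncation_age: Optional[float] = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        lx = np.asarray(self.lx, dtype=float)
        if ages.ndim != 1 or ages.size < 2 or lx.shape != ages.shape:
            raise ValueError("ages and lx must be 1-d arrays of equal length >= 2")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(np.diff(lx) > 1e-9 * self.radix):
            raise ValueError("lx must be non-increasing")
        if np.any(lx < 0):
            raise ValueError("lx must be non-negative")
        if abs(lx[0] - self.radix) > 1e-6 * self.radix:
            raise ValueError(
                f"lx[0]={lx[0]} must equal the radix {self.radix} "
                "(truncate_renormalize re-establishes this after truncation)"
            )
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "lx", lx)

    @property
    def proportions(self) -> np.ndarray:
        """lx rescaled to survival probabilities (1 at the first age)."""
        return self.lx / self.radix


def _parse_hmd_age(token: str, lineno: int) -> int:
    token = token.strip()
    if token.endswith("+"):
        token = token[:-1]
    if token == "." or token == "":
        raise ValueError(f"line {lineno}: missing age entry")
    try:
        return int(token)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable age {token!r}") from exc


def read_hmd_cohort_lx(
    path,
    sex: str,
    cohorts: Union[int, Sequence[int], tuple],
    radix: float = 100_000.0,
) -> CohortSurvival:
    """Read one cohort (or pool a birth-year range) from an HMD cohort lx file.

    Parameters
    ----------
    path : file path
    sex : ``"Female"``, ``"Male"`` or ``"Total"`` (case-insensitive)
    cohorts : a single birth year, or a ``(first, last)`` inclusive range to
        pool.  Pooling averages lx across birth years, weighted by a
        ``Births`` column when the file provides one, unweighted otherwise.
    radix : scale of the lx column (HMD convention: 100000 at the first age).
    """
    path = Path(path)
    sex = sex.capitalize()
    header_cols: Optional[list[str]] = None
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if header_cols is None:
                if tokens[0] == "Year" and "Age" in tokens:
                    header_cols = tokens
                continue
            if len(tokens) != len(header_cols):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header_cols)} columns, "
                    f"got {len(tokens)}"
                )
            rows.append((lineno, tokens))
    if header_cols is None:
        raise ValueError(f"{path}: no 'Year  Age  ...' header line found")
    if sex not in header_cols:
        raise ValueError(f"{path}: no column {sex!r} (have {header_cols})")

    if isinstance(cohorts, (tuple, list, range)) and not isinstance(cohorts, int):
        first, last = int(min(cohorts)), int(max(cohorts))
    else:
        first = last = int(cohorts)
    wanted = set(range(first, last + 1))

    year_i = header_cols.index("Year")
    age_i = header_cols.index("Age")
    sex_i = header_cols.index(sex)
    births_i = header_cols.index("Births") if "Births" in header_cols else None

    per_year: dict[int, dict[int, float]] = {}
    weights: dict[int, float] = {}
    for lineno, tokens in rows:
        try:
            year = int(tokens[year_i])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: bad year {tokens[year_i]!r}") from exc
        if year not in wanted:
            continue
        age = _parse_hmd_age(tokens[age_i], lineno)
        val = tokens[sex_i]
        if val == ".":
            raise ValueError(
                f"{path}: line {lineno}: missing lx entry for cohort {year}, age {age}"
            )
        try:
            lx = float(val)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: bad lx value {val!r}") from exc
        per_year.setdefault(year, {})[age] = lx
        if births_i is not None:
            weights[year] = float(tokens[births_i])

    missing = wanted - set(per_year)
    if missing:
        raise LookupError(f"{path}: cohorts not found: {sorted(missing)}")

    ages = sorted(next(iter(per_year.values())))
    for year, table in per_year.items():
        if sorted(table) != ages:
            raise ValueError(f"{path}: cohort {year} has a different age grid")
    ages_arr = np.array(ages, dtype=float)
    curves = np.array([[per_year[y][a] for a in ages] for y in sorted(per_year)])
    if births_i is not None:
        w = np.array([weights[y] for y in sorted(per_year)], dtype=float)
        pooled = (curves * w[:, None]).sum(axis=0) / w.sum()
    else:
        pooled = curves.mean(axis=0)

    label = f"{path.stem} {sex} {first}" if first == last else f"{path.stem} {sex} {first}-{last}"
    return CohortSurvival(ages=ages_arr, lx=pooled, radix=radix, cohort_label=label)


def read_cohort_csv(path, cohort_label: Optional[str] = None) -> CohortSurvival:
    """Read the minimal delimited cohort format (header: age, survivors)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty cohort file") from exc
    for col in ("age", "survivors"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    try:
        ages = df["age"].to_numpy(dtype=float)
        lx = df["survivors"].to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cells in age/survivors") from exc
    return CohortSurvival(
        ages=ages, lx=lx, radix=float(lx[0]), cohort_label=cohort_label or path.stem
    )


def write_cohort_csv(cohort: CohortSurvival, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# cohort={cohort.cohort_label} radix={cohort.radix:g}")
        if cohort.truncation_age is not None:
            fh.write(f" truncation_age={cohort.truncation_age:g}")
        fh.write("\nage,survivors\n")
        for a, l in zip(cohort.ages, cohort.lx):
            fh.write(f"{a:g},{l:.10g}\n")


def truncate_renormalize(cohort: CohortSurvival, x0: float) -> CohortSurvival:
    """Drop ages below x0 and rescale so lx(x0) equals the radix.

    x0 must be a tabulated age (no interpolation).  Idempotent at a fixed x0.
    """
    match = np.nonzero(np.isclose(cohort.ages, x0))[0]
    if match.size == 0:
        raise ValueError(f"truncation age {x0} is not a tabulated age")
    i = int(match[0])
    if cohort.lx[i] <= 0:
        raise ValueError(f"no survivors at truncation age {x0}")
    scale = cohort.radix / cohort.lx[i]
    return replace(
        cohort,
        ages=cohort.ages[i:],
        lx=cohort.lx[i:] * scale,
        truncation_age=float(x0),
    )


def cohort_to_interval_deaths(
    cohort: CohortSurvival, actual_n: Optional[int] = None
) -> IntervalDeaths:
    """Convert an lx curve to integer interval death counts at cohort size actual_n.

    Standard errors of a multinomial fit scale with the true number of lives
    behind the curve, not with the radix, so proportions are rescaled to
    ``actual_n`` (default: the radix).  Survivors at the last tabulated age
    die in the open-ended final interval; the rounding residual is assigned
    to the largest interval.
    """
    if actual_n is None:
        actual_n = int(round(cohort.radix))
    if actual_n <= 0:
        raise ValueError(f"actual_n must be positive, got {actual_n}")
    p = cohort.proportions
    raw = np.empty(cohort.ages.size)
    raw[:-1] = actual_n * (p[:-1] - p[1:])
    raw[-1] = actual_n * p[-1]
    deaths = np.round(raw).astype(np.int64)
    residual = actual_n - deaths.sum()
    if residual != 0:
        deaths[int(np.argmax(deaths))] += residual
    return IntervalDeaths(breaks=cohort.ages.copy(), deaths=deaths, n_entry=actual_n)


def records_to_cohort(
    records: pd.DataFrame,
    ages: Sequence[float],
    radix: float = 100_000.0,
    cohort_label: str = "",
) -> CohortSurvival:
    """Empirical survivorship of simulated records on a given age grid.

    Censored individuals count as survivors at every tabulated age below
    their censoring age.
    """
    ages = np.asarray(ages, dtype=float)
    death_age = records["age_at_death"].to_numpy(dtype=float)
    censored = (records["cause"] == CAUSE_CENSORED).to_numpy()
    n = len(records)
    if n == 0:
        raise ValueError("no records")
    alive = np.empty(ages.size)
    for j, a in enumerate(ages):
        alive[j] = np.sum((death_age > a) | (censored & (death_age >= a)))
    lx = alive / alive[0] * radix
    return CohortSurvival(ages=ages, lx=lx, radix=radix, cohort_label=cohort_label)
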
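"""Individual-based stochastic simulator of the two-process vitality model.

Each individual carries a vitality path started at 1 that loses ``r*dt`` per
Euler step plus Gaussian noise ``s*sqrt(dt)``; crossing zero is intrinsic
death.  Environmental challenges arrive as Poisson(lam*dt) counts per step
with exponentially distributed magnitudes (mean ``beta``); a challenge whose
magnitude reaches current vitality is extrinsic death.  The simulator is the
brute-force counterpart of the closed forms in :mod:`pyvitality.model` —
unlike them it retains the full interaction between the stochastic vitality
path and the challenge process — and doubles as the generator of synthetic
twin-study cohorts (monozygotic/dizygotic pairs plus a general population) in
the style of late-19th-century registry data, with the study's
entry-age truncation rule: a twin pair enters only if both members survive
the truncation age.

Within a step the update order is fixed for reproducibility: diffusion update
first, intrinsic-death check, then challenges drawn against the updated
vitality of those still alive.  Order effects vanish as ``dt -> 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelParams

__all__ = [
    "SimConfig",
    "IndividualRecord",
    "IntervalDeaths",
    "simulate_individual",
    "simulate_cohort",
    "make_twin_study",
    "records_to_interval_counts",
    "write_records",
    "read_records",
    "write_interval_deaths",
    "read_interval_deaths",
    "TWIN_GROUPS",
    "GP_GROUPS",
]

logger = logging.getLogger(__name__)

CAUSE_INTRINSIC = "intrinsic"
CAUSE_EXTRINSIC = "extrinsic"
CAUSE_CENSORED = "censored"

#: canonical study group labels: zygosity (MZ/DZ twins, GP general population) x sex
TWIN_GROUPS = ("MZ-M", "MZ-F", "DZ-M", "DZ-F")
GP_GROUPS = ("GP-M", "GP-F")

RECORD_COLUMNS = ["id", "pair_id", "group", "age_at_death", "cause", "censored"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration for one simulated cohort."""

    params: ModelParams
    n: int
    seed: int
    dt: float = 0.05
    max_age: float = 120.0
    group_label: str = ""
    paired: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (0.0 < self.dt <= 0.25):
            raise ValueError(f"dt must be in (0, 0.25], got {self.dt}")
        if self.max_age <= 0:
            raise ValueError(f"max_age must be > 0, got {self.max_age}")
        if self.paired and self.n % 2:
            raise ValueError("paired cohorts need an even number of individuals")


@dataclass(frozen=True)
class IndividualRecord:
    """One simulated life."""

    id: int
    group_label: str
    age_at_death: float
    cause: str
    pair_id: Optional[int] = None


@dataclass(frozen=True)
class IntervalDeaths:
    """Death counts per age interval — the likelihood's sufficient statistic.

    ``breaks`` is a strictly increasing age grid; interval ``j < m-1`` is
    ``[breaks[j], breaks[j+1])`` and the last interval ``[breaks[-1], inf)``
    is open-ended.  ``deaths`` has one count per interval (length ``m``);
    ``n_entry`` is the number alive at ``breaks[0]``, so
    ``n_entry - deaths.sum()`` is the right-censored remainder.
    """

    breaks: np.ndarray
    deaths: np.ndarray
    n_entry: int

    def __post_init__(self) -> None:
        breaks = np.asarray(self.breaks, dtype=float)
        deaths = np.asarray(self.deaths)
        if breaks.ndim != 1 or breaks.size < 2:
            raise ValueError("breaks must be a 1-d grid with at least 2 ages")
        if np.any(np.diff(breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")
        if deaths.shape != breaks.shape:
            raise ValueError("deaths must have one count per interval (len(breaks))")
        if np.any(deaths < 0) or not np.allclose(deaths, np.round(deaths)):
            raise ValueError("death counts must be non-negative integers")
        if deaths.sum() > self.n_entry:
            raise ValueError("sum of deaths exceeds n_entry")
        object.__setattr__(self, "breaks", breaks)
        object.__setattr__(self, "deaths", np.round(deaths).astype(np.int64))

    @property
    def n_censored(self) -> int:
        return int(self.n_entry - self.deaths.sum())


def _simulate_ages(
    params: ModelParams, n: int, dt: float, max_age: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Euler simulation; returns (ages, causes) for n individuals.

    Deaths are recorded at the midpoint of the step in which they occur
    (unbiased to O(dt), and distinct from the censoring marker: survivors at
    the horizon carry age exactly max_age with cause ``censored``).
    """
    r, s, lam, beta = params.r, params.s, params.lam, params.beta
    n_steps = int(np.ceil(max_age / dt - 1e-9))
    ages = np.full(n, float(max_age))
    causes = np.full(n, CAUSE_CENSORED, dtype=object)
    v = np.ones(n)
    alive = np.arange(n)
    sqdt = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        m = alive.size
        if m == 0:
            break
        t = min(step * dt, max_age)
        v_prev = v[alive]
        v_a = v_prev - r * dt + s * sqdt * rng.standard_normal(m)
        dead_i = v_a <= 0.0
        # Brownian-bridge correction: the path may have touched zero inside
        # the step even when both endpoints are positive;
        # P(cross) = exp(-2 v_prev v_new / (s^2 dt)) for a bridge.
        open_i = np.nonzero(~dead_i)[0]
        if open_i.size:
            p_cross = np.exp(-2.0 * v_prev[open_i] * v_a[open_i] / (s * s * dt))
            crossed = rng.random(open_i.size) < p_cross
            dead_i[open_i[crossed]] = True
        dead_e = np.zeros(m, dtype=bool)
        if lam > 0.0:
            k = rng.poisson(lam * dt, m)
            ci = np.nonzero((k > 0) & ~dead_i)[0]
            if ci.size:
                # max of k iid Exp(beta) magnitudes by inverse transform
                u = rng.random(ci.size)
                worst = -beta * np.log1p(-np.power(u, 1.0 / k[ci]))
                dead_e[ci] = worst >= v_a[ci]
        dead = dead_i | dead_e
        v[alive] = v_a
        if np.any(dead):
            t_death = t - 0.5 * dt
            ages[alive[dead_i]] = t_death
            causes[alive[dead_i]] = CAUSE_INTRINSIC
            ages[alive[dead_e]] = t_death
            causes[alive[dead_e]] = CAUSE_EXTRINSIC
            alive = alive[~dead]
    return ages, causes


def simulate_individual(
    params: ModelParams,
    dt: float = 0.05,
    max_age: float = 120.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> IndividualRecord:
    """Simulate a single life; pass either a Generator or a seed."""
    if rng is None:
        rng = np.random.default_rng(seed)
    ages, causes = _simulate_ages(params, 1, dt, max_age, rng)
    return IndividualRecord(id=0, group_label="", age_at_death=float(ages[0]), cause=str(causes[0]))


def simulate_cohort(config: SimConfig, id_offset: int = 0) -> pd.DataFrame:
    """Simulate one cohort; returns a records table.

    Columns: id, pair_id (-1 if unpaired), group, age_at_death, cause,
    censored.  Identical configs produce bit-identical tables.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ages, causes = _simulate_ages(config.params, config.n, config.dt, config.max_age, rng)
    ids = np.arange(config.n) + id_offset
    pair_ids = ids // 2 if config.paired else np.full(config.n, -1)
    df = pd.DataFrame(
        {
            "id": ids,
            "pair_id": pair_ids,
            "group": config.group_label,
            "age_at_death": ages,
            "cause": causes.astype(str),
            "censored": causes == CAUSE_CENSORED,
        }
    )
    frac = df["cause"].value_counts(normalize=True).to_dict()
    logger.info(
        "simulated cohort %s: n=%d mean_age=%.2f cause_fractions=%s",
        config.group_label or "<unnamed>",
        config.n,
        df["age_at_death"].mean(),
        {k: round(v, 4) for k, v in sorted(frac.items())},
    )
    return df


def make_twin_study(
    configs: Mapping[str, SimConfig],
    truncation_age: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-group twin study with entry-age truncation.

    ``configs`` maps group labels (e.g. ``"MZ-F"``) to cohort configurations;
    groups whose config has ``paired=True`` are simulated as twin pairs
    (consecutive individuals share a ``pair_id``) and a pair is retained only
    if *both* members survive ``truncation_age``.  Unpaired (general
    population) individuals are retained if they themselves survive.
    Individuals are simulated from birth on the chronological clock, so the
    retained records still contain their full ages at death.

    Returns ``(records, retention)`` where ``retention`` is a per-group table
    of simulated/retained counts.
    """
    if truncation_age < 0:
        raise ValueError("truncation_age must be >= 0")
    frames = []
    retention_rows = []
    id_offset = 0
    for label, config in configs.items():
        if config.group_label and config.group_label != label:
            config = replace(config, group_label=label)
        elif not config.group_label:
            config = replace(config, group_label=label)
        df = simulate_cohort(config, id_offset=id_offset)
        id_offset += config.n
        n_sim = len(df)
        if config.paired:
            survives = df["age_at_death"] > truncation_age
            both = survives.groupby(df["pair_id"]).transform("all")
            kept = df[both]
        else:
            kept = df[df["age_at_death"] > truncation_age]
        if kept.empty:
            raise ValueError(
                f"group {label!r}: no individuals survive truncation age {truncation_age}"
            )
        retention_rows.append(
            {
                "group": label,
                "paired": config.paired,
                "n_simulated": n_sim,
                "n_retained": len(kept),
                "retained_fraction": len(kept) / n_sim,
            }
        )
        frames.append(kept)
    records = pd.concat(frames, ignore_index=True)
    retention = pd.DataFrame(retention_rows)
    logger.info("twin study retention:\n%s", retention.to_string(index=False))
    return records, retention


def records_to_interval_counts(
    records: pd.DataFrame, breaks: Sequence[float]
) -> IntervalDeaths:
    """Bin uncensored deaths into half-open age intervals.

    Censored records count toward ``n_entry`` only.  A death age below the
    first break violates the truncation convention and raises.
    """
    breaks = np.asarray(breaks, dtype=float)
    if breaks.ndim != 1 or breaks.size < 2 or np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly increasing with >= 2 ages")
    dead = records[records["cause"] != CAUSE_CENSORED]
    ages = dead["age_at_death"].to_numpy(dtype=float)
    if np.any(ages < breaks[0]):
        raise ValueError(
            f"death age below first break {breaks[0]}: truncation violated"
        )
    idx = np.searchsorted(breaks, ages, side="right") - 1
    deaths = np.bincount(idx, minlength=breaks.size).astype(np.int64)
    return IntervalDeaths(breaks=breaks, deaths=deaths, n_entry=len(records))


# ---------------------------------------------------------------------------
# plain-text serialization


def write_records(records: pd.DataFrame, path, seed: Optional[int] = None) -> None:
    """Write a records table as CSV with a seed comment header."""
    path = Path(path)
    with path.open("w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        records.to_csv(fh, index=False, columns=RECORD_COLUMNS)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file {path} missing columns: {sorted(missing)}")
    return df[RECORD_COLUMNS]


def write_interval_deaths(data: IntervalDeaths, path, seed: Optional[int] = None) -> None:
    """Two-column delimited file (age_break, deaths) with n_entry in the header."""
    path = Path(path)
    with path.open("w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write(f"# n_entry={data.n_entry}\n")
        fh.write("age,deaths\n")
        for b, d in zip(data.breaks, data.deaths):
            fh.write(f"{b:g},{d}\n")


def read_interval_deaths(path) -> IntervalDeaths:
    path = Path(path)
    n_entry = None
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") and "n_entry=" in line:
                n_entry = int(line.split("n_entry=")[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    if n_entry is None:
        raise ValueError(f"{path}: missing '# n_entry=' header line")
    return IntervalDeaths(
        breaks=df["age"].to_numpy(dtype=float),
        deaths=df["deaths"].to_numpy(),
        n_entry=n_entry,
    )
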
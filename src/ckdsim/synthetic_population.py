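"""Synthetic screened-cohort microdata generation.

Generates individual-level microdata with the age, risk-factor, and
CKD-stage structure of a screened high-risk cohort: ages follow a normal
distribution (mean 71.45 y, SD 8.18 y) truncated below at a minimum
screening age of 45, a configurable fraction of the cohort enters in a CKD
state, and every member carries at least one high-risk marker
(hypertension, diabetes, or age >= 65).

Sampling is inverse-CDF on the truncated support, so the number of draws is
exact and the output is deterministic per seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, FormatError, ParameterError
from .states import (
    STAGE_I_IV,
    STAGE_NONE,
    STAGE_TOKENS,
    STAGE_V,
    State,
)

__all__ = [
    "Individual",
    "PopulationSpec",
    "generate_ages",
    "bin_ages",
    "synthesize_cohort",
    "write_microdata",
    "read_microdata",
    "MICRODATA_HEADER",
]

MICRODATA_HEADER = ["id", "age", "hypertension", "diabetes", "state", "stage_at_entry"]

#: Ages above the terminal 5-year bin are folded into it.
DEFAULT_MAX_AGE = 105


@dataclass
class Individual:
    """One simulated person.

    ``stage_at_entry`` records the lumped CKD stage at cohort entry
    ("NONE", "I-IV" or "V") for reporting only; the engine never reads it.
    ``last_screened_year`` is runtime bookkeeping (idempotent screening
    within a year) and is not serialized.
    """

    id: int
    age: int
    hypertension: bool
    diabetes: bool
    state: State = State.AT_RISK
    stage_at_entry: str = STAGE_NONE
    year_of_death: Optional[int] = None
    last_screened_year: Optional[int] = field(default=None, compare=False)

    def is_alive(self) -> bool:
        return self.state is not State.DEAD


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of the synthetic screened cohort.

    Defaults describe the study cohort: 35,412 screened individuals, ages
    ~ Normal(71.45, 8.18) truncated at 45, 25.75% entering with CKD of whom
    ~2% are already end-stage. ``high_risk_fraction`` records the share of
    the source population the cohort represents (metadata for scaling
    results up to a city population; the synthesized cohort itself is
    entirely high-risk).
    """

    n: int = 35412
    age_mean: float = 71.45
    age_sd: float = 8.18
    age_min: int = 45
    age_max: int = DEFAULT_MAX_AGE
    high_risk_fraction: float = 0.10
    ckd_prevalence: float = 0.2575
    stage_v_fraction: float = 0.02
    detected_fraction: float = 0.25
    hypertension_prev: float = 0.5
    diabetes_prev: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ParameterError(f"cohort size must be > 0, got {self.n}")
        if self.age_sd <= 0:
            raise ParameterError(f"age_sd must be > 0, got {self.age_sd}")
        for name in (
            "high_risk_fraction",
            "ckd_prevalence",
            "stage_v_fraction",
            "detected_fraction",
            "hypertension_prev",
            "diabetes_prev",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(**d)


def generate_ages(
    n: int,
    mean: float,
    sd: float,
    min_age: float,
    seed: int,
    max_age: float = DEFAULT_MAX_AGE,
) -> np.ndarray:
    """Draw ``n`` whole-year ages from a lower-truncated normal.

    Continuous draws come from Normal(``mean``, ``sd``) truncated below at
    ``min_age`` via inverse-CDF sampling (exact draw count, deterministic
    per ``seed``), are floored to whole years, and ages at or above
    ``max_age`` are folded into the terminal 5-year bin.
    """
    if n <= 0:
        raise ParameterError(f"n must be > 0, got {n}")
    if sd <= 0:
        raise ParameterError(f"sd must be > 0, got {sd}")
    if not min_age < mean + 6 * sd:
        raise ParameterError(
            f"min_age {min_age} leaves no practical mass under Normal({mean}, {sd})"
        )
    a = (min_age - mean) / sd
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    u = np.random.default_rng(seed).random(n)
    ages = np.floor(dist.ppf(u)).astype(np.int64)
    return np.clip(ages, int(min_age), int(max_age) - 1)


def bin_ages(ages: Sequence[float], bin_width: int = 5) -> pd.DataFrame:
    """Tabulate ages into half-open bins ``[x, x + bin_width)``.

    Returns a DataFrame with columns ``bin`` (lower edge), ``frequency``,
    ``percentage`` and ``cumulative_percentage``; percentages sum to 100
    within floating rounding.
    """
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be > 0, got {bin_width}")
    ages = np.asarray(ages)
    if ages.size == 0:
        raise EmptyInputError("cannot bin an empty age list")
    lower = (np.floor(ages / bin_width) * bin_width).astype(np.int64)
    edges = np.arange(lower.min(), lower.max() + bin_width, bin_width)
    freq = pd.Series(lower).value_counts().reindex(edges, fill_value=0)
    pct = 100.0 * freq / ages.size
    return pd.DataFrame(
        {
            "bin": edges,
            "frequency": freq.to_numpy(),
            "percentage": pct.to_numpy(),
            "cumulative_percentage": pct.cumsum().to_numpy(),
        }
    ).reset_index(drop=True)


def synthesize_cohort(spec: PopulationSpec) -> list[Individual]:
    """Generate the synthetic screened cohort described by ``spec``.

    Ages come from :func:`generate_ages`; hypertension and diabetes flags
    are independent Bernoulli draws at the configured prevalences, with one
    flag assigned (in proportion to the prevalences) to any under-65 member
    drawn with neither, so every member carries at least one high-risk
    marker. A ``ckd_prevalence`` fraction enters in a CKD state:
    ``stage_v_fraction`` of those as ESRD (stage V) and the rest as
    pre-end-stage, of whom ``detected_fraction`` are already diagnosed.
    Fully reproducible from ``spec.seed``.
    """
    ages = generate_ages(
        spec.n, spec.age_mean, spec.age_sd, spec.age_min, spec.seed, spec.age_max
    )
    rng = np.random.default_rng([spec.seed, 1])

    hyp = rng.random(spec.n) < spec.hypertension_prev
    dia = rng.random(spec.n) < spec.diabetes_prev

    # High-risk invariant: under-65 members need hypertension or diabetes.
    need_flag = (ages < 65) & ~hyp & ~dia
    denom = spec.hypertension_prev + spec.diabetes_prev
    p_hyp = spec.hypertension_prev / denom if denom > 0 else 1.0
    assign_hyp = rng.random(spec.n) < p_hyp
    hyp |= need_flag & assign_hyp
    dia |= need_flag & ~assign_hyp

    has_ckd = rng.random(spec.n) < spec.ckd_prevalence
    is_stage_v = rng.random(spec.n) < spec.stage_v_fraction
    is_detected = rng.random(spec.n) < spec.detected_fraction

    cohort: list[Individual] = []
    for i in range(spec.n):
        if has_ckd[i]:
            if is_stage_v[i]:
                state, stage = State.ESRD, STAGE_V
            elif is_detected[i]:
                state, stage = State.CKD_DIAGNOSED, STAGE_I_IV
            else:
                state, stage = State.CKD_UNDETECTED, STAGE_I_IV
        else:
            state, stage = State.AT_RISK, STAGE_NONE
        cohort.append(
            Individual(
                id=i,
                age=int(ages[i]),
                hypertension=bool(hyp[i]),
                diabetes=bool(dia[i]),
                state=state,
                stage_at_entry=stage,
            )
        )
    return cohort


def write_microdata(cohort: Iterable[Individual], path: str | Path) -> Path:
    """Write a cohort to CSV (header ``id,age,hypertension,diabetes,state,
    stage_at_entry``; booleans as 0/1)."""
    cohort = list(cohort)
    if not cohort:
        raise EmptyInputError("refusing to write an empty cohort")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MICRODATA_HEADER)
        for ind in cohort:
            writer.writerow(
                [
                    ind.id,
                    ind.age,
                    int(ind.hypertension),
                    int(ind.diabetes),
                    ind.state.value,
                    ind.stage_at_entry,
                ]
            )
    return path


def read_microdata(path: str | Path) -> list[Individual]:
    """Read a microdata CSV back into a cohort.

    Raises :class:`FormatError` naming the offending line for malformed
    rows or unknown state/stage tokens, and :class:`EmptyInputError` for an
    empty file.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise EmptyInputError(f"{path} is empty") from None
        if header != MICRODATA_HEADER:
            raise FormatError(
                f"{path}:1: expected header {','.join(MICRODATA_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        cohort: list[Individual] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(MICRODATA_HEADER):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(MICRODATA_HEADER)} fields, "
                    f"got {len(row)}"
                )
            try:
                ind_id, age = int(row[0]), int(row[1])
                hyp, dia = int(row[2]), int(row[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if hyp not in (0, 1) or dia not in (0, 1):
                raise FormatError(f"{path}:{lineno}: boolean flags must be 0 or 1")
            try:
                state = State(row[4])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unknown state token {row[4]!r}"
                ) from None
            if row[5] not in STAGE_TOKENS:
                raise FormatError(f"{path}:{lineno}: unknown stage token {row[5]!r}")
            cohort.append(
                Individual(
                    id=ind_id,
                    age=age,
                    hypertension=bool(hyp),
                    diabetes=bool(dia),
                    state=state,
                    stage_at_entry=row[5],
                )
            )
    if not cohort:
        raise EmptyInputError(f"{path} contains a header but no rows")
    return cohort
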
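"""Annual mortality schedules (life tables) and the mortality adjustments
applied to them.

The model's background mortality is an annual life table: for each integer
age ``x`` a probability ``qx`` of dying within the year conditional on being
alive at age ``x``. Real analyses feed in a national period table; for
self-contained runs a Gompertz–Makeham synthesizer provides a realistic
human all-cause schedule. Achondroplasia's reduced life expectancy is
modelled as an age shift in the lookup: the per-cycle death probability at
age ``a`` is the general-population ``qx`` at ``a + age_shift``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "MortalityAdjustment",
    "gompertz_makeham_table",
    "dp_at",
    "read_life_table",
    "write_life_table",
    "life_expectancy",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual conditional death probabilities by integer age.

    Parameters
    ----------
    ages : array of int
        Contiguous integer ages starting at 0.
    qx : array of float
        Probability of death within the year at each age. The final entry
        (at ``max_age``) must be 1 so the table is closed.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or qx.ndim != 1 or len(ages) != len(qx):
            raise ValueError("ages and qx must be 1-d arrays of equal length")
        if len(ages) == 0:
            raise ValueError("life table is empty")
        if ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise ValueError("non-contiguous ages: ages must run 0..max_age in steps of 1")
        if np.any((qx < 0) | (qx > 1)) or not np.all(np.isfinite(qx)):
            bad = int(np.flatnonzero(~((qx >= 0) & (qx <= 1)))[0])
            raise ValueError(f"qx out of [0, 1] at age {ages[bad]} (qx={qx[bad]!r})")
        if qx[-1] != 1.0:
            raise ValueError(f"table not closed: qx at max age {ages[-1]} must be 1, got {qx[-1]}")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def qx_at(self, age: int) -> float:
        """``qx`` at an integer age, with bounds checking."""
        age = int(age)
        if age < 0 or age > self.max_age:
            raise ValueError(f"age {age} outside table range 0..{self.max_age}")
        return float(self.qx[age])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LifeTable):
            return NotImplemented
        return np.array_equal(self.ages, other.ages) and np.array_equal(self.qx, other.qx)


@dataclass(frozen=True)
class MortalityAdjustment:
    """How the general-population table is adapted for the modelled cohort.

    ``age_shift`` implements the reduced life expectancy of achondroplasia:
    the death probability applied at age ``a`` is the table's ``qx`` at
    ``a + age_shift`` (10 years by default). ``surgical_mortality`` is the
    additional per-cycle probability of dying during an elective pediatric
    orthopedic procedure, added to the death outflow of surgical states.
    """

    age_shift: int = 10
    surgical_mortality: float = 0.00013

    def __post_init__(self) -> None:
        if int(self.age_shift) != self.age_shift or self.age_shift < 0:
            raise ValueError(f"age_shift must be a nonnegative integer, got {self.age_shift}")
        object.__setattr__(self, "age_shift", int(self.age_shift))
        if not 0.0 <= self.surgical_mortality <= 1.0:
            raise ValueError(
                f"surgical_mortality must be in [0, 1], got {self.surgical_mortality}"
            )


# Synthetic defaults land life expectancy at birth near contemporary
# western-European values; a stand-in for a national period table.
DEFAULT_GM_PARAMS = {"a": 5e-4, "b": 3.5e-5, "c": 1.095}


def gompertz_makeham_table(
    a: float = DEFAULT_GM_PARAMS["a"],
    b: float = DEFAULT_GM_PARAMS["b"],
    c: float = DEFAULT_GM_PARAMS["c"],
    max_age: int = 120,
) -> LifeTable:
    """Synthesize an annual life table from a Gompertz–Makeham hazard.

    The hazard at exact age ``x`` is ``h(x) = a + b * c**x``: a constant
    background (Makeham) term plus an exponentially senescent (Gompertz)
    term. The annual death probability is the exact integral of the hazard
    over the year of age::

        qx(age) = 1 - exp(-(a + b * c**age * (c - 1) / ln c))

    clamped to [0, 1], with ``qx(max_age)`` forced to 1 to close the table.

    Parameters
    ----------
    a : float
        Age-independent baseline hazard (per year), ``a >= 0``.
    b : float
        Scale of the senescent hazard at age 0, ``b > 0``.
    c : float
        Annual multiplicative rate of senescent-hazard growth, ``c > 1``.
    max_age : int
        Last age in the table, at least 120.
    """
    for name, value in (("a", a), ("b", b), ("c", c)):
        if not np.isfinite(value):
            raise ValueError(f"Gompertz–Makeham parameter {name} must be finite, got {value!r}")
    if a < 0:
        raise ValueError(f"Gompertz–Makeham parameter a must be >= 0, got {a}")
    if b <= 0:
        raise ValueError(f"Gompertz–Makeham parameter b must be > 0, got {b}")
    if c <= 1:
        raise ValueError(f"Gompertz–Makeham parameter c must be > 1, got {c}")
    if max_age < 120:
        raise ValueError(f"max_age must be >= 120, got {max_age}")

    ages = np.arange(max_age + 1)
    # integral of h over [age, age+1): a + b * c**age * (c - 1) / ln c
    cum_hazard = a + b * np.power(c, ages.astype(float)) * (c - 1.0) / np.log(c)
    qx = np.clip(1.0 - np.exp(-cum_hazard), 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def dp_at(table: LifeTable, adj: MortalityAdjustment, age: int) -> float:
    """Per-cycle death probability for a cohort member of the given age.

    Implements the age-shift reading of the life-expectancy reduction:
    ``dp(age) = qx(age + age_shift)``.
    """
    shifted = int(age) + adj.age_shift
    if shifted > table.max_age:
        raise ValueError(
            f"age {age} + shift {adj.age_shift} = {shifted} exceeds the life table's "
            f"max age {table.max_age}; supply a longer table"
        )
    return table.qx_at(shifted)


def life_expectancy(table: LifeTable, age: int = 0) -> float:
    """Remaining life expectancy at an integer age, mid-year death convention."""
    age = int(age)
    q = table.qx[age:]
    alive = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
    deaths = alive * q
    # any residual mass at max_age dies in that year by table closure
    return float(np.sum(deaths * (np.arange(len(q)) + 0.5)))


def _delimiter_for(path: str) -> str:
    return "\t" if os.path.splitext(str(path))[1].lower() in {".tsv", ".tab"} else ","


def read_life_table(path) -> LifeTable:
    """Read a two-column (age, qx) delimited text file; header optional.

    CSV or TSV is autodetected from the extension. Validation errors cite
    the offending data row (1-based, excluding any header).
    """
    sep = _delimiter_for(path)
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = not str(first.iloc[0, 0]).strip().lstrip("+-").isdigit()
    df = pd.read_csv(
        path, sep=sep, header=0 if has_header else None, float_precision="round_trip"
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (age, qx), found {df.shape[1]}")
    ages = df.iloc[:, 0].to_numpy()
    qx = df.iloc[:, 1].astype(float).to_numpy()

    for i, age in enumerate(ages):
        if float(age) != int(age):
            raise ValueError(f"{path}: row {i + 1}: age {age!r} is not an integer")
    ages = ages.astype(int)
    if len(ages) and ages[0] != 0:
        raise ValueError(f"{path}: row 1: table must start at age 0, got {ages[0]}")
    steps = np.diff(ages)
    if np.any(steps == 0):
        row = int(np.flatnonzero(steps == 0)[0]) + 2
        raise ValueError(f"{path}: row {row}: duplicate age {ages[row - 1]}")
    if np.any(steps != 1):
        row = int(np.flatnonzero(steps != 1)[0]) + 2
        raise ValueError(
            f"{path}: row {row}: non-contiguous ages ({ages[row - 2]} followed by {ages[row - 1]})"
        )
    bad = np.flatnonzero((qx < 0) | (qx > 1) | ~np.isfinite(qx))
    if len(bad):
        row = int(bad[0]) + 1
        raise ValueError(f"{path}: row {row}: qx={qx[bad[0]]} outside [0, 1]")
    return LifeTable(ages=ages, qx=qx)


def write_life_table(table: LifeTable, path) -> None:
    """Write a table as delimited text, full float precision, header row."""
    df = table.to_frame()
    df["qx"] = [repr(float(v)) for v in table.qx]
    df.to_csv(path, sep=_delimiter_for(path), index=False)
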
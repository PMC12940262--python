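"""Life-table fitness analysis of cancer suppression in giant breeds.

Fitness is measured as expected lifetime reproductive success,
``LRS = sum_x l_x * m_x``, where ``l_x`` is the probability of surviving
from birth to age ``x`` and ``m_x`` the expected number of offspring
produced at age ``x``. Only the ages of consistent selective breeding
(2-6 yr inclusive by default) contribute; ``m_x = 0`` elsewhere.

Age-specific fecundity is derived from mean litter size under the observed
distribution of litters per breeding female per year: 82.2% of females
produce one litter, 17.1% two, and 0.66% three (these proportions sum to
99.96% and are used as printed, without renormalisation), so

    m_x = litter_size_x * (1*0.822 + 2*0.171 + 3*0.0066) = litter_size_x * 1.1838.

A hypothetical giant breed (>45 kg) whose mortality schedule is improved to
that of a large breed (25-45 kg) through greater cancer suppression gains
``delta_LRS`` offspring; the selection coefficient is
``s = delta_LRS / LRS_baseline`` and the variant is selectively favoured
when ``s`` exceeds the drift threshold ``1 / (2 Ne)``.

LRS here counts total offspring, not daughters; set ``per_daughter=True``
in :func:`lrs` for per-daughter accounting (halved fecundity). Ages are
integer years with no interpolation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LitterFrequency",
    "DEFAULT_LITTER_FREQUENCY",
    "SelectionResult",
    "fecundity_from_litter",
    "lrs",
    "selection_coefficient",
    "read_life_table",
    "load_life_table",
]

BREEDING_AGES = (2, 6)


@dataclass(frozen=True)
class LitterFrequency:
    """Proportions of breeding females whelping 1, 2 or 3 litters per year."""

    p1: float = 0.822
    p2: float = 0.171
    p3: float = 0.0066

    def __post_init__(self):
        for p in (self.p1, self.p2, self.p3):
            if not 0.0 <= p <= 1.0:
                raise ValueError("litter frequencies must lie in [0, 1]")
        if self.p1 + self.p2 + self.p3 > 1.0 + 1e-3:
            raise ValueError("litter frequencies sum to more than 1")

    @property
    def litters_per_year(self) -> float:
        return 1.0 * self.p1 + 2.0 * self.p2 + 3.0 * self.p3


DEFAULT_LITTER_FREQUENCY = LitterFrequency()


@dataclass(frozen=True)
class SelectionResult:
    lrs_baseline: float
    lrs_alternative: float
    delta_lrs: float
    s: float
    ne: float
    drift_threshold: float
    favoured: bool

    def to_dict(self) -> dict:
        return {
            "lrs_baseline": self.lrs_baseline,
            "lrs_alternative": self.lrs_alternative,
            "delta_lrs": self.delta_lrs,
            "s": self.s,
            "ne": self.ne,
            "drift_threshold": self.drift_threshold,
            "favoured": self.favoured,
        }


def fecundity_from_litter(
    litter_size: float, freq: LitterFrequency = DEFAULT_LITTER_FREQUENCY
) -> float:
    """m_x from a mean litter size and the litters-per-year distribution."""
    if litter_size < 0:
        raise ValueError(f"litter size must be non-negative, got {litter_size}")
    return float(litter_size) * freq.litters_per_year


def _validate_life_table(table: pd.DataFrame) -> pd.DataFrame:
    if "age" not in table.columns or "lx" not in table.columns:
        raise ValueError("life table needs 'age' and 'lx' columns")
    if "mx" not in table.columns and "lxmx" not in table.columns:
        raise ValueError("life table needs an 'mx' or 'lxmx' column")
    t = table.copy()
    t["age"] = t["age"].astype(int)
    t = t.sort_values("age").reset_index(drop=True)
    lx = t["lx"].to_numpy(dtype=float)
    if (lx < 0).any() or (lx > 1).any():
        raise ValueError("lx values must lie in [0, 1]")
    if (np.diff(lx) > 1e-12).any():
        raise ValueError("lx must be non-increasing with age")
    return t


def lrs(
    table: pd.DataFrame,
    breeding_ages: tuple[int, int] = BREEDING_AGES,
    per_daughter: bool = False,
) -> float:
    """Expected lifetime reproductive success over the breeding window.

    Uses a supplied ``lxmx`` column when present (printed life tables carry
    rounded ``mx``, so the product column is the more precise source);
    otherwise multiplies ``lx`` by ``mx``. Missing ages inside the window
    are an error.
    """
    t = _validate_life_table(table)
    lo, hi = int(breeding_ages[0]), int(breeding_ages[1])
    if lo > hi:
        raise ValueError(f"breeding age window out of order: {breeding_ages}")
    window = t[(t["age"] >= lo) & (t["age"] <= hi)]
    gaps = sorted(set(range(lo, hi + 1)) - set(window["age"]))
    if gaps:
        raise ValueError(f"life table is missing breeding ages: {gaps}")
    if "lxmx" in window.columns and window["lxmx"].notna().all():
        total = float(window["lxmx"].astype(float).sum())
    else:
        total = float((window["lx"].astype(float) * window["mx"].astype(float)).sum())
    return total / 2.0 if per_daughter else total


def selection_coefficient(
    lrs_baseline: float, lrs_alternative: float, ne: float = 100.0
) -> SelectionResult:
    """Selection coefficient of the alternative schedule against drift.

    s = (LRS_alt - LRS_base) / LRS_base; favoured iff s > 1/(2 Ne).
    """
    if lrs_baseline <= 0:
        raise ValueError("baseline LRS must be positive")
    if ne < 1:
        raise ValueError("effective population size must be >= 1")
    delta = float(lrs_alternative) - float(lrs_baseline)
    s = delta / float(lrs_baseline)
    threshold = 1.0 / (2.0 * float(ne))
    return SelectionResult(
        lrs_baseline=float(lrs_baseline),
        lrs_alternative=float(lrs_alternative),
        delta_lrs=delta,
        s=s,
        ne=float(ne),
        drift_threshold=threshold,
        favoured=bool(s > threshold),
    )


def read_life_table(path) -> pd.DataFrame:
    return _validate_life_table(pd.read_csv(path))


def load_life_table(size_class: str) -> pd.DataFrame:
    """Bundled life tables for the 'large' (25-45 kg) and 'giant' (>45 kg)
    size classes over the ages of selective breeding."""
    if size_class not in ("large", "giant"):
        raise ValueError("size_class must be 'large' or 'giant'")
    ref = importlib.resources.files("canine_lag.data") / f"life_table_{size_class}.csv"
    with importlib.resources.as_file(ref) as p:
        return read_life_table(p)
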
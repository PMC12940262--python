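"""Classify dog breeds as ancient or modern from modern-European admixture.

A breed's modern-European ancestry is summarised as the mean admixture
fraction across its genotyped individuals. Breeds with mean ancestry below
``ancient_cutoff`` (default 20%) are called *ancient*; breeds at or above
``modern_cutoff`` (default 90%) are called *modern*; everything in between is
*excluded* from downstream contrasts. The defaults reproduce the published
thresholds; looser ancient cut-offs are known to sweep in recently
established breeds (e.g. the eurasier), which is why the ancient boundary is
strict.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "BreedAgeLabel",
    "mean_breed_ancestry",
    "classify",
    "classify_table",
    "read_ancestry_csv",
    "labels_to_frame",
]

logger = logging.getLogger(__name__)

ANCIENT = "ancient"
MODERN = "modern"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class BreedAgeLabel:
    """One breed's mean ancestry and its ancient/modern/excluded call."""

    breed: str
    mean_ancestry: float
    label: str


def _validate_fractions(frac: pd.Series) -> pd.Series:
    frac = pd.to_numeric(frac, errors="raise").astype(float)
    if frac.isna().any():
        raise ValueError("ancestry fractions contain missing values")
    if (frac > 1.0).any():
        warnings.warn(
            "ancestry values > 1 detected; interpreting as percentages and "
            "dividing by 100",
            UserWarning,
            stacklevel=3,
        )
        frac = frac / 100.0
    if (frac < 0.0).any() or (frac > 1.0).any():
        raise ValueError("ancestry fractions must lie in [0, 1]")
    return frac


def mean_breed_ancestry(table: pd.DataFrame) -> dict[str, float]:
    """Per-breed arithmetic mean of individual modern-European fractions.

    Parameters
    ----------
    table : DataFrame
        Columns ``breed`` and ``modern_european_fraction`` (an optional
        ``individual_id`` column is carried but unused). Fractions given as
        percentages (values > 1) are auto-detected and rescaled with a
        warning.

    Returns
    -------
    dict mapping breed name to mean fraction in [0, 1].
    """
    if table is None or len(table) == 0:
        raise ValueError("no ancestry records")
    missing = {"breed", "modern_european_fraction"} - set(table.columns)
    if missing:
        raise ValueError(f"ancestry table missing columns: {sorted(missing)}")
    frac = _validate_fractions(table["modern_european_fraction"])
    counts = table.groupby("breed", sort=True).size()
    low = counts[counts < 10]
    if len(low):
        logger.warning(
            "%d breed(s) have fewer than 10 genotyped individuals: %s",
            len(low),
            ", ".join(f"{b} (n={n})" for b, n in low.items()),
        )
    means = frac.groupby(table["breed"]).mean()
    return {str(b): float(v) for b, v in means.sort_index().items()}


def classify(
    means: dict[str, float],
    ancient_cutoff: float = 0.20,
    modern_cutoff: float = 0.90,
) -> list[BreedAgeLabel]:
    """Label breeds ancient (< ancient_cutoff) / modern (>= modern_cutoff).

    The boundary conventions follow the printed inequality symbols: exactly
    20% ancestry is *excluded* (strict ``<``), exactly 90% is *modern*
    (inclusive ``>=``).
    """
    if not (0.0 <= ancient_cutoff < modern_cutoff <= 1.0):
        raise ValueError(
            f"cutoffs out of order: need 0 <= ancient ({ancient_cutoff}) "
            f"< modern ({modern_cutoff}) <= 1"
        )
    out = []
    for breed in sorted(means):
        m = float(means[breed])
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"mean ancestry for {breed!r} outside [0, 1]: {m}")
        if m < ancient_cutoff:
            label = ANCIENT
        elif m >= modern_cutoff:
            label = MODERN
        else:
            label = EXCLUDED
        out.append(BreedAgeLabel(breed, m, label))
    counts = {lab: sum(r.label == lab for r in out) for lab in (ANCIENT, MODERN, EXCLUDED)}
    logger.info("classified %d breeds: %s", len(out), counts)
    return out


def classify_table(
    table: pd.DataFrame,
    ancient_cutoff: float = 0.20,
    modern_cutoff: float = 0.90,
) -> list[BreedAgeLabel]:
    """Convenience: average a raw per-individual table, then classify."""
    return classify(mean_breed_ancestry(table), ancient_cutoff, modern_cutoff)


def read_ancestry_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def labels_to_frame(labels: list[BreedAgeLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "breed": [r.breed for r in labels],
            "mean_ancestry": [r.mean_ancestry for r in labels],
            "label": [r.label for r in labels],
        }
    )
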
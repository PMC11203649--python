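"""Inverse-degree (RDS-II style) weighting and weighted prevalence estimation.

Under the random-walk model of chain-referral recruitment, a member's chance
of entering the sample is proportional to her network degree; weighting each
respondent by the inverse of her reported degree therefore removes the
degree bias of the sample mean. Reported degrees are noisy self-reports and
are truncated to a fixed range (default [3, 150]) before inversion. Seeds
are excluded: they were hand-picked, not sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError, SchemaError
from .records import StudyDataset

DEFAULT_DEGREE_BOUNDS = (3, 150)


@dataclass
class WeightSet:
    """Per-participant RDS-II weights (seeds excluded).

    Weights are 1/degree rescaled to sum to the number of non-seed
    participants, so weighted and unweighted counts are side-by-side
    comparable; ratio estimates are invariant to the rescaling.
    """

    weights: pd.Series  # indexed by participant_id
    bounds: tuple[int, int] = DEFAULT_DEGREE_BOUNDS
    normalization: float = 1.0
    clamped_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.weights)

    def for_ids(self, ids: Sequence[str]) -> np.ndarray:
        return self.weights.reindex(ids).to_numpy()


@dataclass
class PrevalenceTable:
    """Weighted category proportions for one variable (point estimates; CI
    columns are filled by the bootstrap stage)."""

    variable: str
    categories: list
    estimates: pd.Series          # proportion per category, sums to 1
    weighted_counts: pd.Series
    unweighted_counts: pd.Series
    n_missing: int = 0
    lower: Optional[pd.Series] = None
    upper: Optional[pd.Series] = None
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "category": self.categories,
            "estimate": self.estimates.values,
            "weighted_count": self.weighted_counts.values,
            "unweighted_count": self.unweighted_counts.values,
        })
        if self.lower is not None:
            df["lower"] = self.lower.reindex(self.categories).values
            df["upper"] = self.upper.reindex(self.categories).values
        return df


def truncate_degrees(
    degrees: Sequence[int], low: int = 3, high: int = 150
) -> list[int]:
    """Clamp each reported degree into [low, high], preserving order."""
    if low < 1 or high < low:
        raise ValueError(f"invalid truncation bounds ({low}, {high})")
    return [min(high, max(low, int(d))) for d in degrees]


def compute_rds2_weights(
    dataset: StudyDataset, bounds: tuple[int, int] = DEFAULT_DEGREE_BOUNDS
) -> WeightSet:
    """Inverse-degree weights for every non-seed participant.

    Degrees are truncated to ``bounds`` first (zero or missing degrees are
    thereby raised to the floor rather than dropped — dropping would silently
    change the denominator); raw 1/degree weights are rescaled to sum to the
    non-seed count.
    """
    recruits = dataset.recruits()
    if len(recruits) == 0:
        raise EstimationError("no non-seed participants to weight")
    ids = recruits["participant_id"].tolist()
    raw_deg = recruits["degree_reported"].fillna(0).astype(int).tolist()
    clamped = [pid for pid, d in zip(ids, raw_deg) if d < bounds[0] or d > bounds[1]]
    deg = np.asarray(truncate_degrees(raw_deg, *bounds), dtype=float)
    raw = 1.0 / deg
    norm = len(raw) / raw.sum()
    weights = pd.Series(raw * norm, index=pd.Index(ids, name="participant_id"))
    return WeightSet(weights=weights, bounds=bounds, normalization=norm,
                     clamped_ids=clamped)


def estimate_prevalence(
    dataset: StudyDataset,
    weights: WeightSet,
    variable: str,
    categories: Optional[Sequence] = None,
) -> PrevalenceTable:
    """Weighted prevalence of each category of ``variable`` among non-seeds.

    Missing values are excluded with renormalization; the count of missing
    rows is reported on the table.
    """
    recruits = dataset.recruits()
    if variable not in recruits.columns:
        raise SchemaError(f"variable {variable!r} not in dataset")
    values = recruits.set_index("participant_id")[variable]
    w = weights.weights.reindex(values.index)
    if w.isna().any():
        missing = values.index[w.isna()].tolist()
        raise EstimationError(f"weights missing for participants {missing[:5]}")
    mask = values.notna()
    n_missing = int((~mask).sum())
    values, w = values[mask], w[mask]
    if len(values) == 0:
        raise EstimationError(f"no observed values for {variable!r}")
    totals = w.groupby(values).sum()
    if categories is None:
        categories = sorted(totals.index.tolist(), key=str)
    est = totals.reindex(categories).fillna(0.0) / w.sum()
    counts = values.value_counts().reindex(categories).fillna(0).astype(int)
    return PrevalenceTable(
        variable=variable,
        categories=list(categories),
        estimates=est,
        weighted_counts=totals.reindex(categories).fillna(0.0),
        unweighted_counts=counts,
        n_missing=n_missing,
    )


def minimum_sample_size(
    p: float, e: float, confidence: float = 0.95, deff: float = 1.0
) -> int:
    """Minimum sample size for estimating a proportion.

    ceil(deff * z^2 * p(1-p) / e^2) with z the two-sided normal quantile at
    the given confidence level; ``deff`` is the design effect of the complex
    sampling design relative to simple random sampling.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if e <= 0:
        raise ValueError("half-width e must be positive")
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    if deff < 1:
        raise ValueError("design effect must be >= 1")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return math.ceil(deff * z * z * p * (1.0 - p) / (e * e))
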
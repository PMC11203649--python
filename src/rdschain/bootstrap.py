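"""Chain (tree) bootstrap variance estimation for RDS statistics.

The recruitment design is treated as a cluster sample in which each cluster
is the recruit-set of one recruiter. A bootstrap replicate regrows the sample
by the same process that produced it: seeds are resampled with replacement,
and then, recursively down each chain, every selected recruiter's recruit-set
is resampled with replacement. Statistics (including the inverse-degree
weights) are recomputed on every replicate, so weighting uncertainty
propagates into the intervals. Intervals are percentile intervals of the
replicate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import EstimationError
from .records import RecruitmentForest, StudyDataset

Statistic = Callable[[StudyDataset], Union[float, pd.Series]]


@dataclass
class BootstrapReplicates:
    """Replicate values of one statistic plus the scheme that produced them."""

    statistic: str
    values: pd.DataFrame  # one row per replicate, one column per component
    seed: Optional[int]
    scheme: str = "tree"

    @property
    def B(self) -> int:
        return len(self.values)


@dataclass
class IntervalEstimate:
    """Percentile confidence interval for one scalar component."""

    name: str
    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "percentile"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval bounds out of order")


def chain_bootstrap_resample(
    dataset: StudyDataset,
    rng: np.random.Generator,
    scheme: str = "tree",
) -> StudyDataset:
    """One bootstrap replicate of the recruitment chains.

    ``scheme='tree'`` resamples seeds with replacement and then recursively
    resamples each selected recruiter's recruit-set with replacement, so a
    replicate is a forest of regrown chains. ``scheme='cluster'`` is the flat
    one-level alternative: seeds are kept, and each recruiter's recruit-set
    is resampled once without recursing into regrown copies (for sensitivity
    analysis).

    The replicate gets fresh ids ``b0, b1, ...``; the originating participant
    is recorded in a ``source_id`` column.
    """
    forest = dataset.forest
    kids = forest.children()
    roots = forest.roots

    sources: list[str] = []
    parents: list[Optional[int]] = []  # index into sources

    if scheme == "tree":
        stack: list[tuple[str, Optional[int]]] = []
        chosen_roots = rng.choice(len(roots), size=len(roots), replace=True)
        for ri in chosen_roots:
            stack.append((roots[int(ri)], None))
        while stack:
            src, parent_idx = stack.pop()
            my_idx = len(sources)
            sources.append(src)
            parents.append(parent_idx)
            children = kids[src]
            if children:
                picks = rng.choice(len(children), size=len(children), replace=True)
                for ci in picks:
                    stack.append((children[int(ci)], my_idx))
    elif scheme == "cluster":
        index_of: dict[str, int] = {}
        order = forest._bfs_order()
        for src in order:
            parent = forest.parent[src]
            sources.append(src)
            parents.append(None if parent is None else index_of[parent])
            index_of[src] = len(sources) - 1
        # resample each recruit-set in place (same tree shape, relabeled rows)
        for src in order:
            children = kids[src]
            if not children:
                continue
            picks = rng.choice(len(children), size=len(children), replace=True)
            for slot, ci in zip(children, picks):
                sources[index_of[slot]] = children[int(ci)]
    else:
        raise ValueError(f"unknown resampling scheme {scheme!r}")

    ids = [f"b{i}" for i in range(len(sources))]
    parent_map: dict[str, Optional[str]] = {
        pid: (None if pi is None else ids[pi]) for pid, pi in zip(ids, parents)
    }
    base = dataset.participants.set_index("participant_id")
    rows = base.loc[sources].reset_index()
    rows = rows.rename(columns={"participant_id": "source_id"})
    rows.insert(0, "participant_id", ids)
    rows["recruiter_id"] = rows["participant_id"].map(parent_map.get)
    return StudyDataset(
        participants=rows,
        forest=RecruitmentForest(parent_map, forest.coupon_limit),
        city_filter=dataset.city_filter,
    )


def bootstrap_ci(
    dataset: StudyDataset,
    statistic: Statistic,
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    scheme: str = "tree",
    name: str = "statistic",
    max_failure_rate: float = 0.1,
) -> tuple[list[IntervalEstimate], BootstrapReplicates]:
    """Percentile bootstrap interval(s) for any statistic of the dataset.

    The statistic may return a scalar or a named vector (pandas Series); one
    interval is produced per component. The point estimate comes from the
    original dataset. Replicates on which the statistic fails are dropped; if
    more than ``max_failure_rate`` of them fail the whole call errors with a
    failure log.
    """
    if B < 2:
        raise ValueError("need at least B=2 replicates")
    rng = np.random.default_rng(seed)
    point = statistic(dataset)
    if np.isscalar(point) or isinstance(point, float):
        point = pd.Series({name: float(point)})
    rows = []
    failures: list[str] = []
    for _ in range(B):
        replicate = chain_bootstrap_resample(dataset, rng, scheme=scheme)
        try:
            value = statistic(replicate)
        except Exception as exc:  # noqa: BLE001 - logged and rate-limited
            failures.append(repr(exc))
            continue
        if np.isscalar(value) or isinstance(value, float):
            value = pd.Series({name: float(value)})
        rows.append(value)
    if len(failures) > max_failure_rate * B:
        raise EstimationError(
            f"statistic failed on {len(failures)}/{B} replicates; "
            f"first failures: {failures[:3]}"
        )
    values = pd.DataFrame(rows).reset_index(drop=True)
    replicates = BootstrapReplicates(
        statistic=name, values=values, seed=seed, scheme=scheme
    )
    alpha = (1.0 - level) / 2.0
    intervals = []
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        intervals.append(
            IntervalEstimate(
                name=str(col),
                point=float(point.get(col, np.nan)),
                lower=float(np.quantile(v, alpha)),
                upper=float(np.quantile(v, 1.0 - alpha)),
                level=level,
            )
        )
    return intervals, replicates


def prevalence_statistic(variable: str, category,
                         bounds: tuple[int, int] = (3, 150)) -> Statistic:
    """Statistic factory: RDS-II weighted prevalence of one category,
    recomputing weights inside every replicate."""
    from .estimation import compute_rds2_weights, estimate_prevalence

    def stat(ds: StudyDataset) -> float:
        w = compute_rds2_weights(ds, bounds=bounds)
        table = estimate_prevalence(ds, w, variable)
        if category not in table.categories:
            return 0.0
        return float(table.estimates.loc[category])

    return stat


def prevalence_with_ci(
    dataset: StudyDataset,
    variable: str,
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    bounds: tuple[int, int] = (3, 150),
):
    """Full prevalence table for one variable with percentile CIs attached."""
    from .estimation import compute_rds2_weights, estimate_prevalence

    weights = compute_rds2_weights(dataset, bounds=bounds)
    table = estimate_prevalence(dataset, weights, variable)
    cats = list(table.categories)

    def stat(ds: StudyDataset) -> pd.Series:
        w = compute_rds2_weights(ds, bounds=bounds)
        t = estimate_prevalence(ds, w, variable, categories=cats)
        return t.estimates

    intervals, replicates = bootstrap_ci(
        dataset, stat, B=B, level=level, seed=seed, name=variable
    )
    lower = pd.Series({iv.name: iv.lower for iv in intervals})
    upper = pd.Series({iv.name: iv.upper for iv in intervals})
    # interval names come back stringified; align on category order
    table.lower = pd.Series([lower[str(c)] for c in cats], index=cats)
    table.upper = pd.Series([upper[str(c)] for c in cats], index=cats)
    table.level = level
    return table, replicates
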
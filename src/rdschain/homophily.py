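"""Homophily and Markov-equilibrium diagnostics of a recruitment chain.

Chain referral is modeled as a first-order Markov process on the category of
the variable of interest: the recruit's category depends only on the
recruiter's. The estimated recruiter->recruit transition matrix yields (i) a
homophily test — is the conditional distribution of recruits homogeneous
across recruiter categories? — and (ii) the equilibrium (stationary)
distribution the sample composition converges to as waves accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DiagnosticError, EstimationError, SchemaError
from .estimation import WeightSet
from .records import StudyDataset


@dataclass
class TransitionMatrix:
    """Recruiter->recruit conditional distributions for one variable.

    ``matrix[i, j]`` = P(recruit in category j | recruiter in category i).
    ``counts`` holds the raw pair counts behind each cell (the basis of the
    chi-square test); ``total`` is the recruit-category distribution over all
    included pairs (the marginal the conditionals are compared against).
    """

    variable: str
    categories: list
    matrix: np.ndarray
    counts: np.ndarray
    total: np.ndarray
    weighted: bool = True

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.categories, columns=self.categories)
        df.loc["Total"] = self.total
        return df

    def row_pairs(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class HomophilyReport:
    """Chi-square homogeneity test of the recruiter rows, plus the signed
    conditional-minus-marginal matrix used to read off (reverse) homophily."""

    variable: str
    categories: list
    conditional: np.ndarray
    marginal: np.ndarray
    statistic: float
    df: int
    p_value: float
    significant: bool
    excess: np.ndarray  # conditional - marginal, per recruiter row
    warning: Optional[str] = None


def crosstab_recruiter_recruit(
    dataset: StudyDataset,
    weights: Optional[WeightSet],
    variable: str,
    categories: Optional[Sequence] = None,
) -> TransitionMatrix:
    """Cross-tabulate recruiter vs recruit categories over coupon edges.

    Pairs whose recruiter is a seed are excluded (seeds were hand-picked, so
    their recruiting behavior is not part of the sampled process); pairs with
    a missing category on either end are dropped. With ``weights`` the
    conditional rows and the Total row are recruit-weight weighted; the raw
    pair counts are kept for testing either way.
    """
    df = dataset.participants.set_index("participant_id")
    if variable not in df.columns:
        raise SchemaError(f"variable {variable!r} not in dataset")
    is_seed = df["is_seed"].astype(bool)
    values = df[variable]
    pairs = [
        (recruiter, recruit)
        for recruiter, recruit in dataset.forest.edges()
        if not is_seed.loc[recruiter]
        and not pd.isna(values.loc[recruiter])
        and not pd.isna(values.loc[recruit])
    ]
    if not pairs:
        raise EstimationError(
            f"no recruiter->recruit pairs with non-seed recruiters for {variable!r}"
        )
    if categories is None:
        seen = sorted(
            {values.loc[a] for a, _ in pairs} | {values.loc[b] for _, b in pairs},
            key=str,
        )
        categories = list(seen)
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    counts = np.zeros((k, k))
    wsum = np.zeros((k, k))
    for recruiter, recruit in pairs:
        i = index[values.loc[recruiter]]
        j = index[values.loc[recruit]]
        counts[i, j] += 1
        w = 1.0
        if weights is not None:
            w = float(weights.weights.get(recruit, np.nan))
            if np.isnan(w):
                w = 1.0  # recruit outside the weight set (e.g. a seed)
        wsum[i, j] += w
    basis = wsum if weights is not None else counts
    row_sums = basis.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        matrix = np.where(row_sums > 0, basis / np.where(row_sums == 0, 1, row_sums), 0.0)
    total = basis.sum(axis=0) / basis.sum()
    return TransitionMatrix(
        variable=variable,
        categories=list(categories),
        matrix=matrix,
        counts=counts,
        total=total,
        weighted=weights is not None,
    )


def test_homophily(matrix: TransitionMatrix, alpha: float = 0.05) -> HomophilyReport:
    """Pearson chi-square of homogeneity of the recruiter rows.

    Homogeneity of the conditional recruit distributions across recruiter
    categories is tested as independence on the K x K pair-count table (the
    marginal is the count-weighted average of the rows, so homogeneity with
    the marginal and row-independence coincide). The test uses raw counts —
    the weighted proportions are reported but carry no effective-sample-size
    correction. No continuity correction, also for 2 x 2 tables.
    """
    counts = matrix.counts
    keep = counts.sum(axis=1) > 0
    table = counts[keep][:, counts.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise EstimationError("homophily test needs at least a 2x2 count table")
    result = stats.chi2_contingency(table, correction=False)
    expected = result.expected_freq
    warning = None
    if (expected < 1).mean() > 0.2:
        warning = (
            "more than 20% of expected cell counts are below 1; "
            "the chi-square approximation is unreliable"
        )
    k = len(matrix.categories)
    excess = matrix.matrix - matrix.total[None, :]
    return HomophilyReport(
        variable=matrix.variable,
        categories=matrix.categories,
        conditional=matrix.matrix,
        marginal=matrix.total,
        statistic=float(result.statistic),
        df=int(result.dof),
        p_value=float(result.pvalue),
        significant=bool(result.pvalue < alpha),
        excess=excess,
        warning=warning,
    )


def stationary_distribution(matrix: TransitionMatrix | np.ndarray) -> np.ndarray:
    """The unique stationary vector pi with pi P = pi, sum(pi) = 1.

    Solved as a linear system. Raises :class:`DiagnosticError` when the chain
    is reducible (some category unreachable from another), naming the
    absorbing class.
    """
    P = matrix.matrix if isinstance(matrix, TransitionMatrix) else np.asarray(matrix, float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("transition matrix rows must sum to 1")
    k = P.shape[0]
    _check_irreducible(P, matrix if isinstance(matrix, TransitionMatrix) else None)
    # solve (P^T - I) pi = 0 with the normalization row appended
    A = np.vstack([P.T - np.eye(k), np.ones((1, k))])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _check_irreducible(P: np.ndarray, matrix: Optional[TransitionMatrix]) -> None:
    import networkx as nx

    g = nx.from_numpy_array((P > 1e-12).astype(int), create_using=nx.DiGraph)
    if not nx.is_strongly_connected(g):
        comps = list(nx.strongly_connected_components(g))
        # an absorbing class has no edges leaving it
        absorbing = []
        for comp in comps:
            leaves = any(
                P[i, j] > 1e-12 for i in comp for j in range(P.shape[0]) if j not in comp
            )
            if not leaves:
                absorbing.append(sorted(comp))
        names = absorbing
        if matrix is not None:
            names = [[matrix.categories[i] for i in comp] for comp in absorbing]
        raise DiagnosticError(f"reducible chain; absorbing class(es): {names}")


def waves_to_equilibrium(
    matrix: TransitionMatrix | np.ndarray,
    start: Sequence[float],
    tol: float = 0.01,
    max_waves: int = 1000,
) -> int:
    """Smallest wave t with max_i |(start P^t)_i - pi_i| < tol.

    This is the survey-design question behind chain referral: how many
    recruitment waves until the sample composition forgets the seeds.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    P = matrix.matrix if isinstance(matrix, TransitionMatrix) else np.asarray(matrix, float)
    pi = stationary_distribution(P)
    v = np.asarray(start, dtype=float)
    if v.shape != (P.shape[0],) or not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise ValueError("start must be a probability vector over the categories")
    t = 0
    while np.max(np.abs(v - pi)) >= tol:
        v = v @ P
        t += 1
        if t > max_waves:
            raise DiagnosticError(
                f"no convergence to tol={tol} within {max_waves} waves"
            )
    return t


def wave_distributions(dataset: StudyDataset, variable: str,
                       categories: Optional[Sequence] = None) -> pd.DataFrame:
    """Empirical category distribution per wave (diagnostic companion to
    :func:`waves_to_equilibrium` on real chains)."""
    waves = dataset.forest.waves()
    df = dataset.participants.copy()
    df["wave"] = df["participant_id"].map(waves)
    df = df[df[variable].notna()]
    if categories is None:
        categories = sorted(df[variable].unique(), key=str)
    out = (
        df.groupby("wave")[variable]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=categories, fill_value=0.0)
    )
    return out
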
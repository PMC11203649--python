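"""Core data model for coupon-based chain-referral (RDS) surveys.

A study dataset couples a participant table (one row per completed interview)
with the recruitment forest implied by the coupon links: every non-seed
participant was recruited by exactly one earlier participant, seeds root the
trees, and the wave of a participant is her distance to the rooting seed.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .exceptions import IntegrityError

#: Canonical category levels for every categorical study variable.
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "city": ("Manaus", "BoaVista"),
    "age_group": ("15-24", "25-34", "35-49"),
    "education": ("elementary", "high_school", "college"),
    "migratory_status": ("asylum_seeker", "resident", "irregular"),
    "self_rated_health": ("good", "fair", "poor"),
    "reason_for_use": (
        "illness_or_treatment",
        "prenatal",
        "vaccination",
        "prevention_checkup_childcare",
        "diagnostic_exams",
        "dental",
    ),
}

#: Boolean study variables.
BOOLEAN_FIELDS: tuple[str, ...] = (
    "is_seed",
    "pregnant",
    "used_health_service_15d",
    "chronic_disease",
)

#: Canonical column order of a participant table.
PARTICIPANT_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "recruiter_id",
    "is_seed",
    "city",
    "degree_reported",
    "age_group",
    "education",
    "migratory_status",
    "pregnant",
    "self_rated_health",
    "used_health_service_15d",
    "reason_for_use",
    "chronic_disease",
    "months_in_brazil",
)


@dataclass(frozen=True)
class ParticipantRecord:
    """One interviewed woman.

    ``degree_reported`` is the self-reported number of eligible acquaintances
    (the second network-size question: peers of reproductive age), the basis
    of the inverse-degree weight. ``recruiter_id`` is ``None`` exactly when
    ``is_seed`` is true.
    """

    participant_id: str
    recruiter_id: Optional[str]
    is_seed: bool
    city: str
    degree_reported: int
    age_group: str
    education: str
    migratory_status: str
    pregnant: bool
    self_rated_health: str
    used_health_service_15d: bool
    reason_for_use: Optional[str]
    chronic_disease: bool
    months_in_brazil: int

    def __post_init__(self) -> None:
        if self.is_seed == (self.recruiter_id is not None):
            raise IntegrityError(
                f"participant {self.participant_id!r}: is_seed must hold exactly "
                f"when recruiter_id is absent"
            )
        if self.degree_reported < 0:
            raise ValueError(
                f"participant {self.participant_id!r}: degree_reported < 0"
            )
        if self.months_in_brazil < 0:
            raise ValueError(
                f"participant {self.participant_id!r}: months_in_brazil < 0"
            )
        if self.reason_for_use is not None and not self.used_health_service_15d:
            raise ValueError(
                f"participant {self.participant_id!r}: reason_for_use present "
                f"without health-service use"
            )


@dataclass(frozen=True)
class Violation:
    """One broken forest invariant: the rule name and the offending ids."""

    rule: str
    ids: tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule}: {', '.join(self.ids)}"


@dataclass
class RecruitmentForest:
    """The coupon graph: a forest rooted at seeds.

    Stored as a child -> parent map (``None`` marks a root). ``coupon_limit``
    caps the out-degree of every node (three coupons per participant in the
    study design).
    """

    parent: dict[str, Optional[str]]
    coupon_limit: int = 3

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    @property
    def roots(self) -> list[str]:
        return [n for n, p in self.parent.items() if p is None]

    def children(self) -> dict[str, list[str]]:
        """Child lists keyed by parent id, in insertion order."""
        out: dict[str, list[str]] = {n: [] for n in self.parent}
        for child, par in self.parent.items():
            if par is not None and par in out:
                out[par].append(child)
        return out

    def edges(self) -> list[tuple[str, str]]:
        """Recruiter -> recruit pairs."""
        return [(p, c) for c, p in self.parent.items() if p is not None]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.parent)
        g.add_edges_from(self.edges())
        return g

    def validate(self) -> list[Violation]:
        """Check every forest invariant; violations are reported, not raised."""
        violations: list[Violation] = []
        for child, par in self.parent.items():
            if par is not None and par not in self.parent:
                violations.append(Violation("dangling_recruiter", (par, child)))
        out_deg = Counter(p for p in self.parent.values() if p is not None)
        for node, deg in out_deg.items():
            if deg > self.coupon_limit:
                violations.append(Violation("coupon_limit_exceeded", (node,)))
        # cycle / reachability: BFS from roots; anything unreached sits on a cycle
        reached = set(self._bfs_order())
        unreached = [n for n in self.parent if n not in reached]
        if unreached:
            g = self.to_networkx().subgraph(unreached)
            for cyc in nx.simple_cycles(g):
                violations.append(Violation("cycle", tuple(sorted(cyc))))
            cyclic = {n for v in violations if v.rule == "cycle" for n in v.ids}
            orphans = [n for n in unreached if n not in cyclic]
            if orphans:
                violations.append(Violation("unreachable", tuple(sorted(orphans))))
        return violations

    def _bfs_order(self) -> list[str]:
        kids = self.children()
        order: list[str] = []
        queue = deque(self.roots)
        while queue:
            node = queue.popleft()
            order.append(node)
            queue.extend(kids[node])
        return order

    def waves(self) -> dict[str, int]:
        """Wave = distance to the rooting seed (seeds are wave 0).

        Raises :class:`IntegrityError` if some node is unreachable from a root.
        """
        kids = self.children()
        wave: dict[str, int] = {r: 0 for r in self.roots}
        queue = deque(self.roots)
        while queue:
            node = queue.popleft()
            for child in kids[node]:
                wave[child] = wave[node] + 1
                queue.append(child)
        missing = [n for n in self.parent if n not in wave]
        if missing:
            raise IntegrityError(
                f"unreachable nodes (orphaned or cyclic): {sorted(missing)[:10]}"
            )
        return wave


@dataclass
class StudyDataset:
    """A participant table plus its recruitment forest.

    ``participants`` uses the canonical column set (:data:`PARTICIPANT_COLUMNS`)
    with one row per interview, order preserved from the source; the forest
    node set equals the id column exactly.
    """

    participants: pd.DataFrame
    forest: RecruitmentForest
    city_filter: Optional[str] = None
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.participants["participant_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise IntegrityError(f"duplicate participant ids: {dupes}")
        if set(ids) != set(self.forest.parent):
            extra = set(ids) ^ set(self.forest.parent)
            raise IntegrityError(
                f"participant ids and forest nodes differ: {sorted(extra)[:10]}"
            )

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def n_seeds(self) -> int:
        return int(self.participants["is_seed"].sum())

    def seeds(self) -> pd.DataFrame:
        return self.participants[self.participants["is_seed"]]

    def recruits(self) -> pd.DataFrame:
        return self.participants[~self.participants["is_seed"]]

    def subset_city(self, city: str) -> "StudyDataset":
        """Restrict to one city; recruitment chains never cross cities."""
        mask = self.participants["city"] == city
        sub = self.participants[mask].reset_index(drop=True)
        keep = set(sub["participant_id"])
        parent = {
            pid: (par if par in keep else None)
            for pid, par in self.forest.parent.items()
            if pid in keep
        }
        return StudyDataset(
            participants=sub,
            forest=RecruitmentForest(parent, self.forest.coupon_limit),
            city_filter=city,
        )


def validate_forest(dataset: StudyDataset) -> list[Violation]:
    """Validation report for the dataset's recruitment forest.

    Empty iff the coupon graph is a forest, every out-degree respects the
    coupon limit, and every seed flag agrees with rootedness.
    """
    violations = dataset.forest.validate()
    df = dataset.participants
    roots = set(dataset.forest.roots)
    for pid, seed in zip(df["participant_id"], df["is_seed"]):
        if bool(seed) != (pid in roots):
            violations.append(Violation("seed_flag_mismatch", (pid,)))
    return violations


def assign_waves(dataset: StudyDataset) -> dict[str, int]:
    """Wave number (distance to rooting seed) for every participant."""
    return dataset.forest.waves()


def filter_eligible(
    dataset: StudyDataset, max_months: int = 36
) -> tuple[StudyDataset, Counter]:
    """Apply the survey eligibility rules representable in the data.

    Retains rows with a known reproductive-age group and at most
    ``max_months`` months since arrival (the three-year residence criterion).
    When an excluded participant had recruits, her recruits are re-attached to
    the nearest retained ancestor so chains stay connected; recruits with no
    retained ancestor become roots of their own tree (counted under
    ``promoted_to_root``).

    Returns the filtered dataset and a Counter of exclusions per criterion.
    """
    df = dataset.participants
    counts: Counter = Counter()
    keep_mask = pd.Series(True, index=df.index)
    bad_age = df["age_group"].isna()
    bad_res = df["months_in_brazil"] > max_months
    for idx in df.index:
        if bad_age.loc[idx]:
            counts["age_group_missing"] += 1
            keep_mask.loc[idx] = False
        elif bad_res.loc[idx]:
            counts[f"residence>{max_months}mo"] += 1
            keep_mask.loc[idx] = False
    if keep_mask.all():
        return dataset, counts

    kept = df[keep_mask].reset_index(drop=True).copy()
    keep_ids = set(kept["participant_id"])
    old_parent = dataset.forest.parent

    def retained_ancestor(pid: str) -> Optional[str]:
        par = old_parent.get(pid)
        while par is not None and par not in keep_ids:
            par = old_parent.get(par)
        return par

    parent: dict[str, Optional[str]] = {}
    promoted: list[str] = []
    for pid in kept["participant_id"]:
        anc = retained_ancestor(pid)
        parent[pid] = anc
        if anc is None and old_parent.get(pid) is not None:
            promoted.append(pid)
    if promoted:
        counts["promoted_to_root"] = len(promoted)
        promoted_set = set(promoted)
        kept.loc[kept["participant_id"].isin(promoted_set), "recruiter_id"] = None
    # keep recruiter links consistent with the spliced forest
    kept["recruiter_id"] = kept["participant_id"].map(parent.get)
    out = StudyDataset(
        participants=kept,
        forest=RecruitmentForest(parent, dataset.forest.coupon_limit),
        city_filter=dataset.city_filter,
        flags=dict(dataset.flags),
    )
    return out, counts


def build_dataset(
    records: Sequence[Mapping] | pd.DataFrame,
    coupon_limit: int = 3,
    edges: Optional[Iterable[tuple[str, str]]] = None,
) -> StudyDataset:
    """Assemble a StudyDataset from row mappings or a DataFrame.

    ``edges`` (recruiter, recruit) pairs, when given, override the inline
    ``recruiter_id`` column. Dangling recruiter references raise
    :class:`IntegrityError`.
    """
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    for col in PARTICIPANT_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df = df[list(PARTICIPANT_COLUMNS)].reset_index(drop=True)
    ids = df["participant_id"].astype(str)
    df["participant_id"] = ids
    df["recruiter_id"] = [
        None if pd.isna(r) else str(r) for r in df["recruiter_id"]
    ]
    df["is_seed"] = df["is_seed"].astype(bool)
    if edges is not None:
        recruiter_of = {recruit: recruiter for recruiter, recruit in edges}
        df["recruiter_id"] = [recruiter_of.get(pid) for pid in ids]
        df["is_seed"] = [pid not in recruiter_of for pid in ids]
    known = set(ids)
    parent: dict[str, Optional[str]] = {}
    for pid, rid in zip(ids, df["recruiter_id"]):
        rid = None if pd.isna(rid) else str(rid)
        if rid is not None and rid not in known:
            raise IntegrityError(
                f"participant {pid!r} names unknown recruiter {rid!r}"
            )
        parent[pid] = rid
    flags: dict[str, list[str]] = {}
    zero_degree = ids[(pd.to_numeric(df["degree_reported"], errors="coerce") <= 0)]
    if len(zero_degree):
        flags["zero_degree"] = zero_degree.tolist()
    return StudyDataset(
        participants=df, forest=RecruitmentForest(parent, coupon_limit), flags=flags
    )
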
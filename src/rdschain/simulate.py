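"""Synthetic hidden population and coupon-driven recruitment simulator.

Two recruitment modes cover the two jobs a ground-truth generator has here:

``degree_proportional``
    A finite population is generated with attributes drawn independently from
    configured marginals and degrees from a clamped discrete lognormal; each
    accepted coupon recruits an unrecruited member with probability
    proportional to degree (the random-walk model under which the
    inverse-degree estimator is consistent). Used for estimator-recovery
    experiments.

``category_markov``
    Recruits' category vectors are drawn from the recruiter's rows of
    configured transition matrices — the first-order Markov abstraction of
    chain referral, where a recruit's characteristics depend only on her
    recruiter's. Used to validate the homophily and equilibrium machinery.

Both modes issue a fixed number of coupons per participant, each converting
independently with a configurable acceptance probability, and proceed wave by
wave until the target number of non-seed recruits is reached.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import presets
from .exceptions import ConfigError, SimulationError
from .io import write_dataset, write_edge_list
from .records import PARTICIPANT_COLUMNS, RecruitmentForest, StudyDataset

#: Variables drawn from marginals for every synthetic member.
_MARGINAL_VARS = (
    "age_group",
    "education",
    "migratory_status",
    "pregnant",
    "self_rated_health",
    "used_health_service_15d",
    "chronic_disease",
)


@dataclass
class OutcomeModel:
    """Logistic ground truth for health-service use.

    ``odds_ratios`` are keyed by the dichotomized covariates of the
    multivariate model (age_15_24, college, pregnant, fair_poor_health,
    irregular); the intercept is calibrated so the population-level use
    prevalence matches ``target_prevalence``.
    """

    odds_ratios: dict[str, float]
    target_prevalence: float = 0.31

    def coefficients(self) -> dict[str, float]:
        return {k: float(np.log(v)) for k, v in self.odds_ratios.items()}


@dataclass
class SimulationConfig:
    """Everything that parameterizes one synthetic study.

    Defaults reproduce the published study conditions for the chosen city:
    marginals and transition rows from the printed tables, 3 coupons,
    degrees on [3, 150], and the city's seed count and sample size.
    """

    city: str = "Manaus"
    population_size: int = 20000
    attribute_marginals: Optional[dict] = None
    transition_matrices: Optional[dict] = None
    degree_distribution: tuple[str, dict] = ("lognormal", {"median": 15.0, "sigma": 0.9})
    degree_bounds: tuple[int, int] = (3, 150)
    n_seeds: Optional[int] = None
    seed_stratification: Optional[list[dict]] = None
    coupons_per_participant: int = 3
    coupon_acceptance_prob: Optional[float] = None
    target_sample_size: Optional[int] = None
    recruitment_mode: str = "degree_proportional"
    markov_variables: Optional[list[str]] = None
    homophily_kernel: Optional[dict] = None  # variable -> same-category multiplier
    outcome_model: Optional[OutcomeModel] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.city not in presets.MARGINALS:
            raise ConfigError(f"unknown city {self.city!r}")
        if self.attribute_marginals is None:
            self.attribute_marginals = {
                k: dict(v) for k, v in presets.MARGINALS[self.city].items()
            }
        if self.transition_matrices is None:
            self.transition_matrices = {
                var: {r: dict(row) for r, row in block.items()}
                for var, block in presets.TRANSITIONS[self.city].items()
            }
        design = presets.CITY_DESIGN[self.city]
        if self.n_seeds is None:
            self.n_seeds = int(design["n_seeds"])
        if self.target_sample_size is None:
            self.target_sample_size = int(design["target_sample_size"])
        if self.coupon_acceptance_prob is None:
            self.coupon_acceptance_prob = design["coupon_acceptance_prob"]
        self.validate()

    def validate(self) -> None:
        for var, marg in self.attribute_marginals.items():
            total = sum(marg.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"marginal for {var!r} sums to {total}, not 1")
            if any(p < 0 for p in marg.values()):
                raise ConfigError(f"negative probability in marginal for {var!r}")
        for var, block in self.transition_matrices.items():
            for row_cat, row in block.items():
                total = sum(row.values())
                if abs(total - 1.0) > 5e-3:  # printed rows carry rounding
                    raise ConfigError(
                        f"transition row {var!r}/{row_cat!r} sums to {total}"
                    )
        if not (0 < self.coupon_acceptance_prob <= 1):
            raise ConfigError("coupon_acceptance_prob must be in (0, 1]")
        if self.recruitment_mode not in ("degree_proportional", "category_markov"):
            raise ConfigError(f"unknown recruitment_mode {self.recruitment_mode!r}")
        lo, hi = self.degree_bounds
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid degree bounds {self.degree_bounds}")
        if self.n_seeds is not None and self.n_seeds < 1:
            raise ConfigError("need at least one seed")

    def default_stratification(self) -> list[dict]:
        """One constraint per seed, cycling migratory status x age group —
        seeds spread over different characteristics, as in the field protocol."""
        statuses = list(self.attribute_marginals["migratory_status"])
        ages = list(self.attribute_marginals["age_group"])
        out = []
        for i in range(self.n_seeds):
            out.append({
                "migratory_status": statuses[i % len(statuses)],
                "age_group": ages[(i // len(statuses)) % len(ages)],
            })
        return out


@dataclass
class SyntheticPopulation:
    """A generated hidden population with its ground truth attached."""

    members: pd.DataFrame  # one row per member, attribute columns + degree
    true_proportions: dict[str, dict]
    config: SimulationConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.members)


def _draw_categorical(rng: np.random.Generator, levels: list, probs: np.ndarray,
                      size: int) -> np.ndarray:
    idx = rng.choice(len(levels), size=size, p=probs / probs.sum())
    return np.asarray(levels, dtype=object)[idx]


def _draw_degrees(rng: np.random.Generator, config: SimulationConfig,
                  size: int) -> np.ndarray:
    name, params = config.degree_distribution
    lo, hi = config.degree_bounds
    if name == "lognormal":
        mu = float(np.log(params.get("median", 15.0)))
        sigma = float(params.get("sigma", 0.9))
        raw = np.rint(rng.lognormal(mu, sigma, size=size))
    elif name == "constant":
        raw = np.full(size, float(params.get("value", 15)))
    else:
        raise ConfigError(f"unknown degree distribution {name!r}")
    return np.clip(raw, lo, hi).astype(int)


def _draw_months(rng: np.random.Generator, city: str, size: int) -> np.ndarray:
    # Boa Vista arrivals are much more recent (83% under a year in the survey)
    if city == "BoaVista":
        recent = rng.random(size) < 0.83
        months = np.where(recent, rng.integers(0, 12, size=size),
                          rng.integers(12, 37, size=size))
    else:
        months = rng.integers(0, 37, size=size)
    return months.astype(int)


def generate_population(config: SimulationConfig) -> SyntheticPopulation:
    """Draw a finite hidden population from the configured marginals.

    Attributes are mutually independent and independent of degree; degrees
    come from the configured family clamped to the degree bounds. Ground-truth
    proportions are recorded from the configuration, with empirical tallies
    alongside.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 101]))
    n = config.population_size
    cols: dict[str, np.ndarray] = {}
    for var in _MARGINAL_VARS:
        marg = config.attribute_marginals[var]
        levels = list(marg)
        probs = np.array([marg[k] for k in levels], dtype=float)
        cols[var] = _draw_categorical(rng, levels, probs, n)
    cols["degree"] = _draw_degrees(rng, config, n)
    cols["months_in_brazil"] = _draw_months(rng, config.city, n)
    members = pd.DataFrame(cols)
    if config.outcome_model is not None:
        members["used_health_service_15d"] = _draw_outcome(
            rng, members, config.outcome_model
        )
    members["reason_for_use"] = _draw_reasons(rng, members, config.city)
    truth = {var: dict(config.attribute_marginals[var]) for var in _MARGINAL_VARS}
    empirical = {
        var: members[var].value_counts(normalize=True).to_dict()
        for var in _MARGINAL_VARS
    }
    return SyntheticPopulation(
        members=members,
        true_proportions={"configured": truth, "empirical": empirical},
        config=config,
    )


def _draw_outcome(rng: np.random.Generator, members: pd.DataFrame,
                  model: OutcomeModel) -> np.ndarray:
    from .models import dichotomize  # local import avoids a hard cycle

    design = dichotomize(members)
    coefs = model.coefficients()
    eta = np.zeros(len(members))
    for name, beta in coefs.items():
        eta += beta * design[name].to_numpy(dtype=float)
    intercept = _calibrate_intercept(eta, model.target_prevalence)
    prob = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    return rng.random(len(members)) < prob


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for the intercept giving mean sigmoid(b + eta) = target."""
    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mean = float(np.mean(1.0 / (1.0 + np.exp(-(mid + eta)))))
        if mean < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_reasons(rng: np.random.Generator, members: pd.DataFrame,
                  city: str) -> np.ndarray:
    dist = presets.REASON_DISTRIBUTION[city]
    levels = list(dist)
    probs = np.array([dist[k] for k in levels], dtype=float)
    used = members["used_health_service_15d"].to_numpy(dtype=bool)
    reasons = np.full(len(members), None, dtype=object)
    k = int(used.sum())
    if k:
        reasons[used] = _draw_categorical(rng, levels, probs, k)
    return reasons


def _pick_seed_indices(population: SyntheticPopulation,
                       config: SimulationConfig) -> list[int]:
    """Highest-degree members satisfying each stratification constraint —
    a deterministic surrogate for 'well connected in the migrant community'."""
    members = population.members
    constraints = config.seed_stratification or config.default_stratification()
    order = np.argsort(-members["degree"].to_numpy(), kind="stable")
    chosen: list[int] = []
    taken: set[int] = set()
    for constraint in constraints[: config.n_seeds]:
        found = None
        for idx in order:
            if int(idx) in taken:
                continue
            row = members.iloc[int(idx)]
            if all(row[k] == v for k, v in constraint.items()):
                found = int(idx)
                break
        if found is None:  # fall back to best-connected unchosen member
            found = next(int(i) for i in order if int(i) not in taken)
        chosen.append(found)
        taken.add(found)
    while len(chosen) < config.n_seeds:
        nxt = next(int(i) for i in order if int(i) not in taken)
        chosen.append(nxt)
        taken.add(nxt)
    return chosen


def simulate_recruitment(population: SyntheticPopulation,
                         config: SimulationConfig) -> StudyDataset:
    """Run coupon-driven recruitment over a generated population.

    Returns a :class:`StudyDataset` whose forest validates; seeds are flagged
    and ``degree_reported`` equals the member's true degree.
    """
    if config.n_seeds > len(population):
        raise ConfigError("more seeds than population members")
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 202]))
    if config.recruitment_mode == "degree_proportional":
        rows, parent = _recruit_degree_proportional(population, config, rng)
    else:
        rows, parent = _recruit_category_markov(population, config, rng)
    n_recruits = sum(1 for p in parent.values() if p is not None)
    if n_recruits < 0.1 * config.target_sample_size:
        raise SimulationError(
            f"recruitment exhausted at {n_recruits} recruits "
            f"(target {config.target_sample_size}); increase population_size "
            f"or coupon_acceptance_prob"
        )
    df = pd.DataFrame(rows)[list(PARTICIPANT_COLUMNS)]
    return StudyDataset(
        participants=df,
        forest=RecruitmentForest(parent, config.coupons_per_participant),
    )


def _member_row(members: pd.DataFrame, idx: int, pid: str,
                recruiter: Optional[str], city: str) -> dict:
    m = members.iloc[idx]
    used = bool(m["used_health_service_15d"])
    return {
        "participant_id": pid,
        "recruiter_id": recruiter,
        "is_seed": recruiter is None,
        "city": city,
        "degree_reported": int(m["degree"]),
        "age_group": m["age_group"],
        "education": m["education"],
        "migratory_status": m["migratory_status"],
        "pregnant": bool(m["pregnant"]),
        "self_rated_health": m["self_rated_health"],
        "used_health_service_15d": used,
        "reason_for_use": m["reason_for_use"] if used else None,
        "chronic_disease": bool(m["chronic_disease"]),
        "months_in_brazil": int(m["months_in_brazil"]),
    }


def _recruit_degree_proportional(population: SyntheticPopulation,
                                 config: SimulationConfig,
                                 rng: np.random.Generator):
    members = population.members
    degrees = members["degree"].to_numpy(dtype=float)
    n_pop = len(members)
    recruited = np.zeros(n_pop, dtype=bool)

    seed_idx = _pick_seed_indices(population, config)
    recruited[seed_idx] = True
    rows: list[dict] = []
    parent: dict[str, Optional[str]] = {}
    id_of: dict[int, str] = {}
    for i, idx in enumerate(seed_idx):
        pid = f"s{i}"
        id_of[idx] = pid
        parent[pid] = None
        rows.append(_member_row(members, idx, pid, None, config.city))

    current_wave = list(seed_idx)
    n_recruits = 0
    counter = 0
    target = config.target_sample_size
    while current_wave and n_recruits < target:
        successes = rng.binomial(config.coupons_per_participant,
                                 config.coupon_acceptance_prob,
                                 size=len(current_wave))
        demand: list[int] = []  # recruiter member-index per requested recruit
        for ridx, k in zip(current_wave, successes):
            demand.extend([ridx] * int(k))
        if not demand:
            break
        m = min(len(demand), target - n_recruits)
        demand = demand[:m]
        if config.homophily_kernel:
            new_idx = _draw_recruits_homophilous(
                rng, members, degrees, recruited, demand, config.homophily_kernel
            )
        else:
            new_idx = _draw_recruits_weighted(rng, degrees, recruited, len(demand))
        next_wave: list[int] = []
        for ridx, idx in zip(demand, new_idx):
            if idx < 0:
                continue
            recruited[idx] = True
            pid = f"r{counter}"
            counter += 1
            id_of[idx] = pid
            parent[pid] = id_of[ridx]
            rows.append(_member_row(members, idx, pid, id_of[ridx], config.city))
            next_wave.append(idx)
            n_recruits += 1
        current_wave = next_wave
    return rows, parent


def _draw_recruits_weighted(rng: np.random.Generator, degrees: np.ndarray,
                            recruited: np.ndarray, m: int) -> list[int]:
    """m distinct unrecruited members, inclusion probability sequential-
    proportional to degree (exponential-race / Gumbel top-k sampling)."""
    pool = np.flatnonzero(~recruited)
    if len(pool) == 0:
        return [-1] * m
    m_eff = min(m, len(pool))
    keys = rng.exponential(size=len(pool)) / degrees[pool]
    take = np.argpartition(keys, m_eff - 1)[:m_eff]
    ordered = take[np.argsort(keys[take])]
    out = [int(pool[i]) for i in ordered]
    out.extend([-1] * (m - m_eff))
    return out


def _draw_recruits_homophilous(rng, members, degrees, recruited, demand,
                               kernel) -> list[int]:
    """Sequential per-coupon draws with a same-category weight multiplier."""
    out: list[int] = []
    for ridx in demand:
        pool = np.flatnonzero(~recruited)
        if len(pool) == 0:
            out.append(-1)
            continue
        w = degrees[pool].copy()
        for var, mult in kernel.items():
            same = members[var].to_numpy(dtype=object)[pool] == members.iloc[ridx][var]
            w = w * np.where(same, float(mult), 1.0)
        idx = int(rng.choice(pool, p=w / w.sum()))
        recruited[idx] = True  # reserve; caller re-marks
        out.append(idx)
    recruited[[i for i in out if i >= 0]] = False  # caller owns the flag
    return out


def _recruit_category_markov(population: SyntheticPopulation,
                             config: SimulationConfig,
                             rng: np.random.Generator):
    """Generative first-order Markov recruitment: each recruit's category on
    every Markov variable is drawn from her recruiter's transition row;
    degree and the remaining variables are drawn independently."""
    members = population.members
    markov_vars = config.markov_variables or list(config.transition_matrices)
    blocks = {}
    for var in markov_vars:
        block = config.transition_matrices[var]
        cats = list(block)
        mat = np.array([[block[r][c] for c in cats] for r in cats], dtype=float)
        mat = mat / mat.sum(axis=1, keepdims=True)
        blocks[var] = (cats, mat)

    seed_idx = _pick_seed_indices(population, config)
    rows: list[dict] = []
    parent: dict[str, Optional[str]] = {}
    wave_attrs: list[dict] = []
    for i, idx in enumerate(seed_idx):
        pid = f"s{i}"
        parent[pid] = None
        row = _member_row(members, idx, pid, None, config.city)
        rows.append(row)
        wave_attrs.append(row)

    reasons = presets.REASON_DISTRIBUTION[config.city]
    reason_levels = list(reasons)
    reason_probs = np.array([reasons[k] for k in reason_levels], dtype=float)
    counter = 0
    n_recruits = 0
    target = config.target_sample_size
    while wave_attrs and n_recruits < target:
        successes = rng.binomial(config.coupons_per_participant,
                                 config.coupon_acceptance_prob,
                                 size=len(wave_attrs))
        recruiters: list[dict] = []
        for rec, k in zip(wave_attrs, successes):
            recruiters.extend([rec] * int(k))
        if not recruiters:
            break
        m = min(len(recruiters), target - n_recruits)
        recruiters = recruiters[:m]
        new_rows = _generate_markov_recruits(
            rng, recruiters, blocks, config, reason_levels, reason_probs
        )
        next_wave: list[dict] = []
        for rec, attrs in zip(recruiters, new_rows):
            pid = f"r{counter}"
            counter += 1
            attrs["participant_id"] = pid
            attrs["recruiter_id"] = rec["participant_id"]
            attrs["is_seed"] = False
            parent[pid] = rec["participant_id"]
            rows.append(attrs)
            next_wave.append(attrs)
            n_recruits += 1
        wave_attrs = next_wave
    return rows, parent


def _generate_markov_recruits(rng, recruiters, blocks, config,
                              reason_levels, reason_probs) -> list[dict]:
    m = len(recruiters)
    cols: dict[str, np.ndarray] = {}
    for var, (cats, mat) in blocks.items():
        cat_index = {c: i for i, c in enumerate(cats)}
        rows_idx = np.array([cat_index[r[var]] for r in recruiters])
        u = rng.random(m)
        cum = np.cumsum(mat, axis=1)[rows_idx]
        drawn = (u[:, None] > cum).sum(axis=1)
        cols[var] = np.asarray(cats, dtype=object)[drawn]
    for var in _MARGINAL_VARS:
        if var in cols:
            continue
        marg = config.attribute_marginals[var]
        levels = list(marg)
        probs = np.array([marg[k] for k in levels], dtype=float)
        cols[var] = _draw_categorical(rng, levels, probs, m)
    degrees = _draw_degrees(rng, config, m)
    months = _draw_months(rng, config.city, m)
    out = []
    for i in range(m):
        used = bool(cols["used_health_service_15d"][i])
        reason = None
        if used:
            reason = str(_draw_categorical(rng, reason_levels, reason_probs, 1)[0])
        out.append({
            "city": config.city,
            "degree_reported": int(degrees[i]),
            "age_group": cols["age_group"][i],
            "education": cols["education"][i],
            "migratory_status": cols["migratory_status"][i],
            "pregnant": bool(cols["pregnant"][i]),
            "self_rated_health": cols["self_rated_health"][i],
            "used_health_service_15d": used,
            "reason_for_use": reason,
            "chronic_disease": bool(cols["chronic_disease"][i]),
            "months_in_brazil": int(months[i]),
        })
    return out


def simulate_study(config: SimulationConfig) -> tuple[StudyDataset, SyntheticPopulation]:
    """Convenience wrapper: generate a population and recruit from it."""
    population = generate_population(config)
    dataset = simulate_recruitment(population, config)
    return dataset, population


def _config_echo(config: SimulationConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["degree_distribution"] = list(echo["degree_distribution"])
    # transition keys may be booleans; JSON needs strings
    echo["transition_matrices"] = {
        var: {str(r): {str(c): v for c, v in row.items()}
              for r, row in block.items()}
        for var, block in echo["transition_matrices"].items()
    }
    echo["attribute_marginals"] = {
        var: {str(k): v for k, v in marg.items()}
        for var, marg in echo["attribute_marginals"].items()
    }
    return echo


def emit_dataset(dataset: StudyDataset, out_dir: str | Path,
                 population: Optional[SyntheticPopulation] = None,
                 config: Optional[SimulationConfig] = None,
                 prefix: str = "rds") -> dict[str, Path]:
    """Write participant CSV, edge-list CSV and a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out / f"{prefix}_participants.csv",
        "edges": out / f"{prefix}_edges.csv",
        "truth": out / f"{prefix}_truth.json",
    }
    write_dataset(dataset, paths["participants"])
    write_edge_list(dataset, paths["edges"])
    sidecar: dict = {"n_participants": len(dataset), "n_seeds": dataset.n_seeds}
    if population is not None:
        sidecar["true_proportions"] = {
            kind: {var: {str(k): v for k, v in d.items()}
                   for var, d in by_var.items()}
            for kind, by_var in population.true_proportions.items()
        }
    if config is not None:
        sidecar["config"] = _config_echo(config)
        sidecar["rng_seed"] = config.rng_seed
    paths["truth"].write_text(json.dumps(sidecar, indent=2))
    return paths
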
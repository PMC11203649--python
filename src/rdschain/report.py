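"""End-to-end pipeline: one configuration in, the five study-style tables out.

Stages run in the survey's analysis order — eligibility filter, inverse-degree
weights, prevalence, homophily diagnostics, chain-bootstrap intervals,
bivariate and multivariate regression — and every stage logs its row
accounting. A run is deterministic given (dataset, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .bootstrap import prevalence_with_ci
from .estimation import compute_rds2_weights, estimate_prevalence
from .exceptions import ConfigError, RDSError
from .homophily import crosstab_recruiter_recruit, test_homophily
from .io import read_dataset
from .models import (
    add_bootstrap_ci,
    bivariate_association,
    fit_weighted_logistic,
    odds_ratio_report,
)
from .records import StudyDataset, filter_eligible
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger("rdschain")

#: Variables tabulated in the prevalence table.
PREVALENCE_VARIABLES = (
    "age_group",
    "education",
    "pregnant",
    "self_rated_health",
    "migratory_status",
    "used_health_service_15d",
)

#: Variables given homophily diagnostics.
HOMOPHILY_VARIABLES = (
    "age_group",
    "education",
    "migratory_status",
    "used_health_service_15d",
)

OUTCOME = "used_health_service_15d"


@dataclass
class ReportBundle:
    """All rendered analyses of one dataset plus run metadata."""

    city: Optional[str]
    homophily: dict[str, pd.DataFrame]
    prevalence: pd.DataFrame
    healthcare_needs: pd.DataFrame
    bivariate: pd.DataFrame
    multivariate: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _dataset_hash(dataset: StudyDataset) -> str:
    payload = dataset.participants.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def _resolve_dataset(config: dict, seed: Optional[int]) -> StudyDataset:
    if "data" in config:
        data_cfg = config["data"]
        return read_dataset(
            data_cfg["participants"],
            column_map=data_cfg.get("column_map"),
            edge_list=data_cfg.get("edge_list"),
        )
    if "simulation" in config:
        sim_kwargs = dict(config["simulation"])
        if seed is not None:
            sim_kwargs["rng_seed"] = seed
        dataset, _ = simulate_study(SimulationConfig(**sim_kwargs))
        return dataset
    raise ConfigError("config must contain a 'data' or a 'simulation' block")


def run_pipeline(
    config: dict | str | Path,
    seed: Optional[int] = None,
    bootstrap_B: Optional[int] = None,
) -> ReportBundle:
    """Execute the full analysis described by a config mapping or file.

    The config carries either a ``data`` block (participant CSV + optional
    edge list and column map) or a ``simulation`` block (kwargs of
    :class:`SimulationConfig`); optional keys: ``city`` (restrict analysis),
    ``bootstrap_B`` (replicates; 0 disables CI columns), ``seed``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = seed if seed is not None else config.get("seed", 0)
    B = bootstrap_B if bootstrap_B is not None else config.get("bootstrap_B", 200)

    stage = "load"
    try:
        dataset = _resolve_dataset(config, seed)
        n_input = len(dataset)
        logger.info("loaded %d participants (%d seeds)", n_input, dataset.n_seeds)

        city = config.get("city")
        if city:
            stage = "city-filter"
            dataset = dataset.subset_city(city)
            logger.info("city=%s retains %d rows", city, len(dataset))

        stage = "eligibility"
        dataset, exclusions = filter_eligible(dataset)
        logger.info(
            "eligibility: retained %d, excluded %s", len(dataset), dict(exclusions)
        )

        stage = "weights"
        weights = compute_rds2_weights(dataset)
        logger.info(
            "weights for %d non-seeds (%d degree reports clamped)",
            len(weights), len(weights.clamped_ids),
        )

        stage = "homophily"
        homophily_tables: dict[str, pd.DataFrame] = {}
        for var in HOMOPHILY_VARIABLES:
            matrix = crosstab_recruiter_recruit(dataset, weights, var)
            rep = test_homophily(matrix)
            tbl = matrix.to_frame()
            tbl["pairs"] = list(matrix.row_pairs()) + [matrix.counts.sum()]
            tbl.attrs.update(
                statistic=rep.statistic, df=rep.df, p_value=rep.p_value,
                significant=rep.significant,
            )
            homophily_tables[var] = tbl

        stage = "prevalence"
        prevalence_rows = []
        for var in PREVALENCE_VARIABLES:
            if B and B > 0:
                table, _ = prevalence_with_ci(dataset, var, B=B, seed=seed)
            else:
                table = estimate_prevalence(dataset, weights, var)
            frame = table.to_frame()
            frame.insert(0, "variable", var)
            prevalence_rows.append(frame)
        prevalence = pd.concat(prevalence_rows, ignore_index=True)

        stage = "healthcare-needs"
        needs = _healthcare_needs(dataset, weights)

        stage = "bivariate"
        bivariate_rows = []
        for var in ("age_group", "education", "pregnant", "self_rated_health",
                    "migratory_status"):
            try:
                assoc = bivariate_association(dataset, weights, OUTCOME, var)
            except RDSError as exc:  # degenerate screen: keep a placeholder row
                logger.warning("bivariate %s skipped: %s", var, exc)
                bivariate_rows.append(pd.DataFrame([{
                    "variable": var, "category": None,
                    "outcome_prevalence": float("nan"),
                    "statistic": float("nan"), "df": 0,
                    "p_value": float("nan"),
                }]))
                continue
            frame = assoc.to_frame()
            frame.insert(0, "variable", var)
            bivariate_rows.append(frame)
        bivariate = pd.concat(bivariate_rows, ignore_index=True)

        stage = "multivariate"
        from .models import DICHOTOMIES, dichotomize

        design = dichotomize(dataset.recruits())
        covariates = [c for c in DICHOTOMIES if design[c].nunique() > 1]
        dropped = sorted(set(DICHOTOMIES) - set(covariates))
        if dropped:
            logger.warning("multivariate drops constant covariates: %s", dropped)
        fit = fit_weighted_logistic(dataset, weights, outcome=OUTCOME,
                                    covariates=covariates)
        if B and B > 0:
            fit = add_bootstrap_ci(fit, dataset, B=B, seed=seed)
        multivariate = odds_ratio_report(fit)

    except RDSError as exc:
        raise type(exc)(f"pipeline stage {stage!r}: {exc}") from exc

    metadata = {
        "dataset_hash": _dataset_hash(dataset),
        "seed": seed,
        "bootstrap_B": B,
        "city": city,
        "weighting": f"RDS-II inverse degree, clamp {weights.bounds}",
        "n_participants": len(dataset),
        "n_seeds": dataset.n_seeds,
        "exclusions": dict(exclusions),
        "version": __version__,
        "config_echo": {k: v for k, v in config.items() if k != "data"},
    }
    return ReportBundle(
        city=city,
        homophily=homophily_tables,
        prevalence=prevalence,
        healthcare_needs=needs,
        bivariate=bivariate,
        multivariate=multivariate,
        metadata=metadata,
    )


def _healthcare_needs(dataset, weights) -> pd.DataFrame:
    """Reason-for-use joint proportions (summing to the proportion of users
    when reasons are exhaustive) plus the chronic-disease, fair/poor-health
    and pregnancy prevalences."""
    recruits = dataset.recruits().set_index("participant_id")
    w = weights.weights.reindex(recruits.index)
    wtot = float(w.sum())
    rows = []
    reasons = recruits["reason_for_use"]
    from .records import CATEGORY_LEVELS

    for reason in CATEGORY_LEVELS["reason_for_use"]:
        mask = reasons == reason
        value = float(w[mask].sum()) / wtot
        rows.append({
            "need": f"reason:{reason}", "estimate": value,
            "n": int(mask.sum()),
            "footnote": "no observations" if not mask.any() else "",
        })
    for label, mask in (
        ("chronic_disease", recruits["chronic_disease"].astype(bool)),
        ("fair_poor_health", recruits["self_rated_health"].isin(["fair", "poor"])),
        ("pregnant", recruits["pregnant"].astype(bool)),
    ):
        rows.append({
            "need": label, "estimate": float(w[mask].sum()) / wtot,
            "n": int(mask.sum()),
            "footnote": "no observations" if not mask.any() else "",
        })
    return pd.DataFrame(rows)


def render_tables(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write one CSV per study-style table plus a metadata JSON.

    Layouts are stable: homophily_<var>.csv (conditional rows + Total row +
    test columns), prevalence.csv, healthcare_needs.csv, bivariate.csv,
    multivariate.csv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for var, tbl in bundle.homophily.items():
        path = out / f"homophily_{var}.csv"
        flat = tbl.reset_index(names="recruiter_category")
        for key in ("statistic", "df", "p_value", "significant"):
            flat[key] = tbl.attrs[key]
        flat.to_csv(path, index=False)
        written[f"homophily_{var}"] = path
    for name in ("prevalence", "healthcare_needs", "bivariate", "multivariate"):
        path = out / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False)
        written[name] = path
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(bundle.metadata, indent=2, default=str))
    written["metadata"] = meta_path
    return written
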
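"""Shared fixtures: small hand-built recruitment chains."""

from __future__ import annotations

import numpy as np
import pytest

from rdschain.records import StudyDataset, build_dataset


def make_row(pid, recruiter=None, **overrides):
    """One participant row with sensible defaults, overridable per test."""
    row = dict(
        participant_id=pid,
        recruiter_id=recruiter,
        is_seed=recruiter is None,
        city="Manaus",
        degree_reported=10,
        age_group="25-34",
        education="high_school",
        migratory_status="resident",
        pregnant=False,
        self_rated_health="good",
        used_health_service_15d=False,
        reason_for_use=None,
        chronic_disease=False,
        months_in_brazil=12,
    )
    row.update(overrides)
    return row


def chain_dataset(rows) -> StudyDataset:
    return build_dataset([make_row(*args, **kw) for args, kw in rows])


@pytest.fixture
def tiny_dataset() -> StudyDataset:
    """Two seeds, eight recruits, three waves, mixed categories."""
    rows = [
        make_row("s1", None, degree_reported=50, migratory_status="irregular"),
        make_row("s2", None, degree_reported=40, age_group="35-49"),
        make_row("a", "s1", degree_reported=4, migratory_status="irregular",
                 used_health_service_15d=True, reason_for_use="prenatal",
                 pregnant=True),
        make_row("b", "s1", degree_reported=8, education="college"),
        make_row("c", "s2", degree_reported=8, age_group="15-24",
                 self_rated_health="fair"),
        make_row("d", "a", degree_reported=20, migratory_status="irregular"),
        make_row("e", "a", degree_reported=10, migratory_status="asylum_seeker",
                 used_health_service_15d=True, reason_for_use="vaccination"),
        make_row("f", "b", degree_reported=5, education="elementary",
                 chronic_disease=True),
        make_row("g", "c", degree_reported=12, age_group="15-24"),
        make_row("h", "d", degree_reported=6, self_rated_health="poor",
                 used_health_service_15d=True,
                 reason_for_use="illness_or_treatment"),
    ]
    return build_dataset(rows)


@pytest.fixture
def seven_node_dataset() -> StudyDataset:
    """One seed; wave-1 children a (two recruits) and b (one recruit)."""
    rows = [
        make_row("s0", None),
        make_row("a", "s0", degree_reported=6),
        make_row("b", "s0", degree_reported=9),
        make_row("c", "a", degree_reported=12),
        make_row("d", "a", degree_reported=15),
        make_row("e", "b", degree_reported=7),
        make_row("f", "e", degree_reported=11),
    ]
    return build_dataset(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
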
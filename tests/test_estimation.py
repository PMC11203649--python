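"""Degree truncation, RDS-II weights, weighted prevalence, sample size."""

import numpy as np
import pytest

from rdschain.estimation import (
    compute_rds2_weights,
    estimate_prevalence,
    minimum_sample_size,
    truncate_degrees,
)
from rdschain.exceptions import EstimationError, SchemaError
from rdschain.records import build_dataset

from conftest import make_row


class TestTruncateDegrees:
    @pytest.mark.parametrize(
        "degrees, expected",
        [
            ([1, 3, 80, 200], [3, 3, 80, 150]),
            ([3, 150, 77], [3, 150, 77]),   # already inside: identity
            ([0], [3]),                      # reported none -> floor
        ],
    )
    def test_clamp(self, degrees, expected):
        assert truncate_degrees(degrees) == expected

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            truncate_degrees([5], low=0)
        with pytest.raises(ValueError):
            truncate_degrees([5], low=10, high=5)


def _weights_dataset(degrees):
    rows = [make_row("seed", None, degree_reported=30)]
    rows += [
        make_row(f"r{i}", "seed" if i < 3 else f"r{i-3}", degree_reported=d)
        for i, d in enumerate(degrees)
    ]
    return build_dataset(rows)


class TestWeights:
    def test_hand_computed_example(self):
        ds = _weights_dataset([4, 8, 8])
        w = compute_rds2_weights(ds)
        assert np.allclose(w.weights.values, [1.5, 0.75, 0.75])

    def test_uniform_degrees_give_unit_weights(self):
        ds = _weights_dataset([20, 20, 20, 20])
        w = compute_rds2_weights(ds)
        assert np.allclose(w.weights.values, 1.0)

    def test_seeds_excluded(self):
        rows = [make_row("s1", None), make_row("s2", None)]
        rows += [make_row(f"r{i}", "s1" if i < 3 else "s2") for i in range(5)]
        w = compute_rds2_weights(build_dataset(rows))
        assert len(w) == 5
        assert not any(pid.startswith("s") for pid in w.weights.index)

    def test_weights_sum_to_nonseed_count(self, tiny_dataset):
        w = compute_rds2_weights(tiny_dataset)
        assert np.isclose(w.weights.sum(), len(tiny_dataset) - tiny_dataset.n_seeds)

    def test_out_of_range_degrees_recorded(self):
        ds = _weights_dataset([1, 8, 200])
        w = compute_rds2_weights(ds)
        assert sorted(w.clamped_ids) == ["r0", "r2"]

    def test_no_recruits_errors(self):
        ds = build_dataset([make_row("s", None)])
        with pytest.raises(EstimationError):
            compute_rds2_weights(ds)


class TestPrevalence:
    def _dataset(self, degrees, statuses):
        rows = [make_row("seed", None)]
        rows += [
            make_row(f"r{i}", "seed" if i < 3 else f"r{i-3}",
                     degree_reported=d, migratory_status=s)
            for i, (d, s) in enumerate(zip(degrees, statuses))
        ]
        return build_dataset(rows)

    def test_hand_computed_example(self):
        # weights (1.5, .75, .75); "irregular" on the first and third rows
        ds = self._dataset([4, 8, 8], ["irregular", "resident", "irregular"])
        w = compute_rds2_weights(ds)
        table = estimate_prevalence(ds, w, "migratory_status")
        assert np.isclose(table.estimates.loc["irregular"], 0.75)

    def test_single_category_estimates_one(self):
        ds = self._dataset([5, 9], ["resident", "resident"])
        w = compute_rds2_weights(ds)
        table = estimate_prevalence(ds, w, "migratory_status")
        assert table.estimates.loc["resident"] == 1.0

    def test_uniform_weights_reduce_to_sample_proportion(self):
        statuses = ["irregular", "resident", "resident", "asylum_seeker"]
        ds = self._dataset([10, 10, 10, 10], statuses)
        w = compute_rds2_weights(ds)
        table = estimate_prevalence(ds, w, "migratory_status")
        assert np.isclose(table.estimates.loc["irregular"], 0.25)
        assert np.isclose(table.estimates.loc["resident"], 0.5)

    def test_estimates_sum_to_one(self, tiny_dataset):
        w = compute_rds2_weights(tiny_dataset)
        table = estimate_prevalence(tiny_dataset, w, "education")
        assert np.isclose(table.estimates.sum(), 1.0)

    def test_matches_brute_force_tally(self, rng):
        # independent oracle: explicit loop over rows
        degrees = rng.integers(3, 60, size=17)
        cats = rng.choice(["a", "b", "c"], size=17)
        rows = [make_row("seed", None)]
        for i, (d, c) in enumerate(zip(degrees, cats)):
            rows.append(make_row(f"r{i}", "seed" if i < 3 else f"r{i-3}",
                                 degree_reported=int(d), education=None,
                                 self_rated_health=None, age_group=None))
            rows[-1]["age_group"] = {"a": "15-24", "b": "25-34", "c": "35-49"}[c]
        ds = build_dataset(rows)
        w = compute_rds2_weights(ds)
        table = estimate_prevalence(ds, w, "age_group")
        raw = {k: 0.0 for k in ("15-24", "25-34", "35-49")}
        total = 0.0
        for i, (d, c) in enumerate(zip(degrees, cats)):
            weight = float(w.weights[f"r{i}"])
            raw[{"a": "15-24", "b": "25-34", "c": "35-49"}[c]] += weight
            total += weight
        for cat, value in raw.items():
            assert abs(table.estimates.loc[cat] - value / total) < 1e-12

    def test_missing_values_renormalized_and_counted(self):
        rows = [make_row("seed", None)]
        rows += [make_row("r0", "seed", self_rated_health="good"),
                 make_row("r1", "seed", self_rated_health=None),
                 make_row("r2", "seed", self_rated_health="fair")]
        ds = build_dataset(rows)
        w = compute_rds2_weights(ds)
        table = estimate_prevalence(ds, w, "self_rated_health")
        assert table.n_missing == 1
        assert np.isclose(table.estimates.sum(), 1.0)

    def test_degree_scaling_invariance_inside_clamp(self):
        base = [4, 8, 8, 15]
        statuses = ["irregular", "resident", "irregular", "resident"]
        t1 = estimate_prevalence(
            self._dataset(base, statuses),
            compute_rds2_weights(self._dataset(base, statuses)),
            "migratory_status")
        scaled = [d * 3 for d in base]  # still within [3, 150]
        t2 = estimate_prevalence(
            self._dataset(scaled, statuses),
            compute_rds2_weights(self._dataset(scaled, statuses)),
            "migratory_status")
        assert np.allclose(t1.estimates.values, t2.estimates.values)

    def test_unknown_variable_is_schema_error(self, tiny_dataset):
        w = compute_rds2_weights(tiny_dataset)
        with pytest.raises(SchemaError):
            estimate_prevalence(tiny_dataset, w, "shoe_size")


class TestMinimumSampleSize:
    def test_survey_specification(self):
        # p=.19, e=.04, 95%, deff=2 -> 2 * 1.96^2 * .19*.81 / .0016 = 739.07
        assert minimum_sample_size(0.19, 0.04, 0.95, 2) == 740

    def test_textbook_case(self):
        assert minimum_sample_size(0.5, 0.10, 0.95, 1) == 97

    def test_design_effect_scales_linearly(self):
        from scipy import stats

        z = stats.norm.ppf(0.975)
        base = z * z * 0.3 * 0.7 / 0.05**2
        assert minimum_sample_size(0.3, 0.05, 0.95, 2) == int(np.ceil(2 * base))

    @pytest.mark.parametrize("kwargs", [
        dict(p=0.0, e=0.04), dict(p=1.2, e=0.04), dict(p=0.2, e=0.0),
        dict(p=0.2, e=0.04, confidence=1.2), dict(p=0.2, e=0.04, deff=0.5),
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            minimum_sample_size(**kwargs)
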
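"""Population generation, both recruitment modes, determinism, emission."""

import json

import numpy as np
import pandas as pd
import pytest

from rdschain.exceptions import ConfigError, SimulationError
from rdschain.homophily import crosstab_recruiter_recruit
from rdschain.io import read_dataset
from rdschain.records import assign_waves, validate_forest
from rdschain.simulate import (
    SimulationConfig,
    emit_dataset,
    generate_population,
    simulate_recruitment,
    simulate_study,
)


def small_config(**overrides):
    kwargs = dict(city="Manaus", population_size=4000, target_sample_size=200,
                  rng_seed=11)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


class TestConfig:
    def test_invalid_marginal_rejected(self):
        with pytest.raises(ConfigError, match="sums to"):
            small_config(attribute_marginals={
                "age_group": {"15-24": 0.6, "25-34": 0.6, "35-49": 0.1},
            })

    def test_invalid_acceptance_rejected(self):
        with pytest.raises(ConfigError):
            small_config(coupon_acceptance_prob=0.0)

    def test_city_defaults_resolved(self):
        cfg = SimulationConfig(city="BoaVista")
        assert cfg.n_seeds == 9
        assert cfg.target_sample_size == 1259
        assert cfg.coupon_acceptance_prob == pytest.approx(0.67)


class TestGeneratePopulation:
    def test_degenerate_marginal(self):
        cfg = small_config(attribute_marginals={
            **{k: dict(v) for k, v in
               SimulationConfig(city="Manaus").attribute_marginals.items()},
            "education": {"college": 1.0},
        })
        pop = generate_population(cfg)
        assert (pop.members["education"] == "college").all()

    def test_marginal_recovered_at_20000(self):
        cfg = SimulationConfig(city="Manaus", population_size=20000, rng_seed=5)
        pop = generate_population(cfg)
        emp = (pop.members["migratory_status"] == "irregular").mean()
        assert abs(emp - 0.26) < 0.01

    def test_degrees_clamped(self):
        cfg = small_config(
            degree_distribution=("lognormal", {"median": 400.0, "sigma": 1.0}))
        pop = generate_population(cfg)
        assert pop.members["degree"].between(3, 150).all()

    def test_reasons_only_for_users(self):
        pop = generate_population(small_config())
        users = pop.members["used_health_service_15d"].astype(bool)
        assert pop.members.loc[users, "reason_for_use"].notna().all()
        assert pop.members.loc[~users, "reason_for_use"].isna().all()


class TestRecruitment:
    def test_forest_always_validates(self):
        for mode in ("degree_proportional", "category_markov"):
            ds, _ = simulate_study(small_config(recruitment_mode=mode))
            assert validate_forest(ds) == []

    def test_deterministic_branching_with_certain_acceptance(self):
        cfg = small_config(population_size=20000, n_seeds=1,
                           seed_stratification=[{}],
                           coupon_acceptance_prob=1.0, target_sample_size=120)
        ds, _ = simulate_study(cfg)
        waves = pd.Series(assign_waves(ds))
        counts = waves.value_counts().sort_index()
        # 3^w recruits per wave until the target truncates the last wave
        assert list(counts.iloc[:4]) == [1, 3, 9, 27]

    def test_same_seed_reproduces_identical_dataset(self):
        a, _ = simulate_study(small_config(rng_seed=99))
        b, _ = simulate_study(small_config(rng_seed=99))
        pd.testing.assert_frame_equal(a.participants, b.participants)
        assert a.forest.parent == b.forest.parent

    def test_degree_reported_equals_true_degree(self):
        ds, pop = simulate_study(small_config())
        assert ds.participants["degree_reported"].between(3, 150).all()

    def test_mean_recruits_per_recruiter_tracks_acceptance(self):
        for accept in (0.67, 0.87):
            cfg = SimulationConfig(city="Manaus", population_size=60000,
                                   target_sample_size=2000,
                                   coupon_acceptance_prob=accept, rng_seed=21)
            ds, _ = simulate_study(cfg)
            waves = assign_waves(ds)
            max_wave = max(waves.values())
            kids = ds.forest.children()
            # recruiters in the last wave never got to use their coupons
            producers = [p for p in ds.forest.nodes if waves[p] < max_wave - 1]
            mean = np.mean([len(kids[p]) for p in producers])
            assert abs(mean - 3 * accept) < 0.15

    def test_exhaustion_raises_simulation_error(self):
        cfg = small_config(population_size=30, target_sample_size=2000,
                           n_seeds=6)
        pop = generate_population(cfg)
        with pytest.raises(SimulationError):
            simulate_recruitment(pop, cfg)

    def test_seed_stratification_respected(self):
        constraints = [{"migratory_status": "irregular"},
                       {"education": "college"}]
        cfg = small_config(n_seeds=2, seed_stratification=constraints)
        ds, _ = simulate_study(cfg)
        seeds = ds.seeds().set_index("participant_id")
        assert seeds.loc["s0", "migratory_status"] == "irregular"
        assert seeds.loc["s1", "education"] == "college"

    def test_inclusion_probability_proportional_to_degree(self):
        # without homophily, a member's inclusion frequency over many
        # replicates grows linearly in degree with intercept near zero
        base = SimulationConfig(city="Manaus", population_size=5000,
                                target_sample_size=150, rng_seed=0)
        pop = generate_population(base)
        class_size = pop.members["degree"].value_counts()
        tally = pd.Series(0.0, index=class_size.index)
        reps = 150
        for r in range(reps):
            cfg = SimulationConfig(city="Manaus", population_size=5000,
                                   target_sample_size=150,
                                   rng_seed=700_000 + r)
            ds = simulate_recruitment(pop, cfg)
            got = ds.recruits()["degree_reported"].value_counts()
            tally = tally.add(got, fill_value=0.0)
        freq = (tally / (reps * class_size)).dropna()
        deg = freq.index.to_numpy(dtype=float)
        slope, intercept = np.polyfit(
            deg, freq.to_numpy(), 1,
            w=np.sqrt(class_size.reindex(freq.index).to_numpy(dtype=float)))
        assert slope > 0
        assert abs(intercept) < 0.01

    def test_wave_distributions_approach_equilibrium(self):
        # category-Markov chains: the sample composition per wave converges
        # to the stationary distribution of the transition matrix
        from rdschain.homophily import stationary_distribution, wave_distributions
        from rdschain.presets import transition_matrix_array

        cats, P = transition_matrix_array("BoaVista", "migratory_status")
        pi = stationary_distribution(P)
        dists = []
        for r in range(40):
            cfg = SimulationConfig(
                city="BoaVista", recruitment_mode="category_markov",
                markov_variables=["migratory_status"], rng_seed=800_000 + r)
            ds, _ = simulate_study(cfg)
            wd = wave_distributions(ds, "migratory_status", categories=cats)
            dists.append(wd.reindex(range(6)))
        mean_by_wave = sum(d.fillna(0.0) for d in dists) / len(dists)
        gap = (mean_by_wave - pi).abs().max(axis=1)
        # seeds (wave 0) are stratified, far from pi; later waves get close
        assert gap.iloc[4] < gap.iloc[0]
        assert gap.iloc[4] < 0.05

    def test_markov_mode_recovers_transition_rows(self):
        # generate from the printed Manaus education rows; at 10,000 pairs the
        # empirical recruiter->recruit matrix matches within 0.02 per cell
        cfg = SimulationConfig(
            city="Manaus", recruitment_mode="category_markov",
            markov_variables=["education"], population_size=4000,
            target_sample_size=12000, coupon_acceptance_prob=0.87, rng_seed=3,
        )
        ds, _ = simulate_study(cfg)
        m = crosstab_recruiter_recruit(ds, None, "education")
        block = cfg.transition_matrices["education"]
        expected = np.array([[block[r][c] for c in m.categories]
                             for r in m.categories])
        expected = expected / expected.sum(axis=1, keepdims=True)
        assert np.max(np.abs(m.matrix - expected)) < 0.02


class TestEmit:
    def test_round_trip_and_sidecar(self, tmp_path):
        cfg = small_config()
        ds, pop = simulate_study(cfg)
        paths = emit_dataset(ds, tmp_path, population=pop, config=cfg)
        again = read_dataset(paths["participants"])
        pd.testing.assert_frame_equal(again.participants, ds.participants)
        sidecar = json.loads(paths["truth"].read_text())
        assert sidecar["rng_seed"] == cfg.rng_seed
        # sidecar truth matches a brute-force tally of the population
        tally = pop.members["migratory_status"].value_counts(normalize=True)
        for cat, value in sidecar["true_proportions"]["empirical"][
                "migratory_status"].items():
            assert value == pytest.approx(tally[cat])
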
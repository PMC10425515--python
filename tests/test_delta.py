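import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgindiv.coarse_grain import Partition, apply_partition, enumerate_bipartitions
from cgindiv.core import (
    Environment,
    LightSource,
    ParticleState,
    PopulationState,
    ResourcePatch,
    TraitSpec,
)
from cgindiv.delta import (
    Threshold,
    acceptable,
    best_partition,
    conditioned_delta,
    delta_C,
    delta_vector,
    projected_prediction,
    truthful_prediction,
)
from cgindiv.dynamics import UpdateRule, evolve
from cgindiv.errors import DomainError, ValidationError

from conftest import simple_population

BALLISTIC = UpdateRule("ballistic")


class TestPathways:
    def test_zero_steps_both_pathways_equal_plain_coarse_graining(
        self, aligned_pop, clusters_partition
    ):
        truthful = truthful_prediction(
            aligned_pop, BALLISTIC, None, 0, clusters_partition
        )
        projected = projected_prediction(
            aligned_pop, BALLISTIC, None, 0, clusters_partition
        )
        assert truthful == apply_partition(aligned_pop, clusters_partition)
        # at zero steps nothing has been predicted yet: the two pathways
        # coincide up to the dispersion the projection discards
        for t, p in zip(truthful, projected):
            assert np.allclose(t.centroid, p.centroid)
            assert t.agg_traits == p.agg_traits

    def test_truthful_centroid_is_mean_of_evolved_members(
        self, aligned_pop, clusters_partition
    ):
        steps = 4
        truthful = truthful_prediction(
            aligned_pop, BALLISTIC, None, steps, clusters_partition
        )
        final = evolve(aligned_pop, BALLISTIC, steps=steps)[-1]
        for c in truthful:
            expected = np.mean(
                [final.get(i).position for i in sorted(c.member_ids)], axis=0
            )
            assert np.allclose(c.centroid, expected)

    def test_projected_designated_cluster_matches_closed_form(
        self, aligned_pop, clusters_partition
    ):
        # the coherent cluster aggregates to heading 220; its projection
        # after k unit-speed steps is centroid + k*(cos 220, sin 220)
        steps = 7
        start = apply_partition(aligned_pop, clusters_partition)
        projected = projected_prediction(
            aligned_pop, BALLISTIC, None, steps, clusters_partition
        )
        theta = np.deg2rad(220.0)
        expected = start[0].centroid + steps * np.array(
            [np.cos(theta), np.sin(theta)]
        )
        assert np.allclose(projected[0].centroid, expected)


class TestDeltaC:
    def test_singleton_partition_gives_exactly_zero(self, aligned_pop):
        part = Partition.singleton(aligned_pop.ids)
        comp = delta_C(aligned_pop, BALLISTIC, None, 5, part, "position")
        assert comp.population_delta == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000), steps=st.integers(0, 5),
           rule_name=st.sampled_from(["ballistic", "chemotaxis", "phototaxis"]))
    def test_singleton_zero_across_rules_and_steps(self, seed, steps, rule_name):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        pop = simple_population(
            rng.uniform(0, 360, n), positions=rng.normal(0, 20, (n, 2))
        )
        env = Environment(
            resource_patches=(ResourcePatch((0, 0), 1.0, 25.0),),
            light_sources=(LightSource((50, 50), 1.0, 25.0),),
        )
        rule = UpdateRule(rule_name, sign=-1 if rule_name == "phototaxis" else 1)
        part = Partition.singleton(pop.ids)
        for trait in ("position", "direction"):
            comp = delta_C(pop, rule, env, steps, part, trait)
            assert comp.population_delta == 0.0

    def test_degenerate_blocks_give_zero_under_ballistic(self):
        # all members of every block identical in traits and position
        pop = simple_population(
            [30.0, 30.0, 300.0, 300.0],
            positions=[(0, 0), (0, 0), (9, 9), (9, 9)],
        )
        part = Partition({0: 0, 1: 0, 2: 1, 3: 1})
        for steps in (0, 1, 4):
            comp = delta_C(pop, BALLISTIC, None, steps, part, "position")
            assert comp.population_delta == pytest.approx(0.0, abs=1e-12)

    def test_signed_delta_equals_recomputed_difference(
        self, scrambled_pop, clusters_partition
    ):
        steps = 3
        comp = delta_C(
            scrambled_pop, BALLISTIC, None, steps, clusters_partition, "position"
        )
        truthful = {
            c.collective_id: c.centroid
            for c in truthful_prediction(
                scrambled_pop, BALLISTIC, None, steps, clusters_partition
            )
        }
        projected = {
            c.collective_id: c.centroid
            for c in projected_prediction(
                scrambled_pop, BALLISTIC, None, steps, clusters_partition
            )
        }
        for d in comp.per_collective:
            assert np.allclose(
                d.delta, truthful[d.collective_id] - projected[d.collective_id]
            )

    @pytest.mark.parametrize("steps", [1, 5, 10])
    def test_aligned_fixture_beats_scrambled_fixture(
        self, aligned_pop, scrambled_pop, clusters_partition, steps
    ):
        da = delta_C(
            aligned_pop, BALLISTIC, None, steps, clusters_partition, "position"
        ).population_delta
        ds = delta_C(
            scrambled_pop, BALLISTIC, None, steps, clusters_partition, "position"
        ).population_delta
        assert da < ds

    def test_truthful_dispersion_reported_for_spreading_blocks(
        self, scrambled_pop, clusters_partition
    ):
        comp = delta_C(
            scrambled_pop, BALLISTIC, None, 5, clusters_partition, "position"
        )
        # scrambled members fly apart: the 'entity' is distributed in space
        assert max(d.truthful_dispersion for d in comp.per_collective) > 1.0


class TestDeltaVector:
    def test_single_trait_equals_delta_C(self, aligned_pop, clusters_partition):
        (comp,) = delta_vector(
            aligned_pop, BALLISTIC, None, 3, clusters_partition, ["position"]
        )
        direct = delta_C(
            aligned_pop, BALLISTIC, None, 3, clusters_partition, "position"
        )
        assert comp.population_delta == direct.population_delta

    def test_empty_trait_list_rejected(self, aligned_pop, clusters_partition):
        with pytest.raises(DomainError):
            delta_vector(aligned_pop, BALLISTIC, None, 3, clusters_partition, [])

    def test_perfectly_correlated_traits_share_delta_pattern(self):
        specs = [
            TraitSpec("direction", "angular_degrees"),
            TraitSpec("direction_twin", "angular_degrees"),
        ]
        rng = np.random.default_rng(3)
        particles = [
            ParticleState(
                id=i,
                position=rng.normal(0, 5, 2),
                traits={"direction": d, "direction_twin": d},
            )
            for i, d in enumerate(rng.uniform(0, 360, 6))
        ]
        pop = PopulationState(t=0, particles=particles, trait_specs=specs)
        part = Partition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})
        rules = {
            "direction": UpdateRule("ballistic", direction_trait="direction"),
            "direction_twin": UpdateRule(
                "ballistic", direction_trait="direction_twin"
            ),
        }
        a, b = delta_vector(
            pop, rules, None, 4, part, ["direction", "direction_twin"]
        )
        assert a.population_delta == b.population_delta

    def test_partition_good_for_one_trait_bad_for_another(self):
        # chemoattractant at the origin, light at (100, 0): particles that
        # share a ray from the origin share a chemotaxis heading, particles
        # that share a ray from the light share a phototaxis heading.  The
        # two pairings order the two trait deltas oppositely.
        specs = [
            TraitSpec("chemo_dir", "angular_degrees"),
            TraitSpec("photo_dir", "angular_degrees"),
        ]
        positions = [(20, 20), (40, 40), (60, 10), (70, 20)]
        particles = [
            ParticleState(id=i, position=np.array(p, dtype=float),
                          traits={"chemo_dir": 0.0, "photo_dir": 0.0})
            for i, p in enumerate(positions)
        ]
        pop = PopulationState(t=0, particles=particles, trait_specs=specs)
        env = Environment(
            resource_patches=(ResourcePatch((0, 0), 1.0, 1000.0),),
            light_sources=(LightSource((100, 0), 1.0, 1000.0),),
        )
        rules = {
            "chemo_dir": UpdateRule("chemotaxis", direction_trait="chemo_dir"),
            "photo_dir": UpdateRule(
                "phototaxis", sign=-1, direction_trait="photo_dir"
            ),
        }
        traits = ["chemo_dir", "photo_dir"]
        chemo_pairs = Partition({0: 0, 1: 0, 2: 1, 3: 1})  # rays from origin
        photo_pairs = Partition({0: 0, 2: 0, 1: 1, 3: 1})  # rays from light
        chemo_a, photo_a = delta_vector(pop, rules, env, 1, chemo_pairs, traits)
        chemo_b, photo_b = delta_vector(pop, rules, env, 1, photo_pairs, traits)
        assert chemo_a.population_delta < chemo_b.population_delta
        assert photo_b.population_delta < photo_a.population_delta


class TestThresholdDecision:
    def _comp_with_delta(self, pop, part, value):
        comp = delta_C(pop, BALLISTIC, None, 0, part, "position")
        comp.population_delta = value
        return comp

    def test_decision_rule_is_strict(self, aligned_pop, clusters_partition):
        th = Threshold(1.0)
        zero = self._comp_with_delta(aligned_pop, clusters_partition, 0.0)
        boundary = self._comp_with_delta(aligned_pop, clusters_partition, 1.0)
        double = self._comp_with_delta(aligned_pop, clusters_partition, 2.0)
        assert acceptable(zero, th)
        assert not acceptable(boundary, th)  # delta == theta rejects
        assert not acceptable(double, th)

    def test_theta_must_be_positive(self):
        with pytest.raises(ValidationError):
            Threshold(0.0)

    def test_per_trait_threshold_overrides(self, aligned_pop, clusters_partition):
        th = Threshold(1.0, per_trait={"position": 100.0})
        comp = self._comp_with_delta(aligned_pop, clusters_partition, 50.0)
        assert acceptable(comp, th)


class TestBestPartition:
    def test_matched_partition_beats_mismatched(
        self, aligned_pop, clusters_partition
    ):
        mismatched = Partition({i: i // 2 for i in aligned_pop.ids})  # 6 x 2
        result = best_partition(
            aligned_pop,
            BALLISTIC,
            None,
            5,
            [clusters_partition, mismatched],
            Threshold(1e6),
            "position",
        )
        assert result.accepted
        assert result.partition == clusters_partition

    def test_all_candidates_failing_theta_yields_verdict(
        self, scrambled_pop, clusters_partition
    ):
        result = best_partition(
            scrambled_pop,
            BALLISTIC,
            None,
            5,
            [clusters_partition],
            Threshold(1e-6),
            "position",
        )
        assert not result.accepted
        assert result.partition is None
        assert result.comparison is None

    def test_single_passing_candidate_is_returned(
        self, aligned_pop, clusters_partition
    ):
        result = best_partition(
            aligned_pop, BALLISTIC, None, 5, [clusters_partition],
            Threshold(1e6), "position",
        )
        assert result.partition == clusters_partition

    def test_empty_candidates_rejected(self, aligned_pop):
        with pytest.raises(DomainError):
            best_partition(aligned_pop, BALLISTIC, None, 5, [], Threshold(1.0))

    def test_matches_brute_force_argmin_on_small_population(self):
        # independent oracle: recompute both pathways directly for every
        # enumerated candidate and take the argmin
        rng = np.random.default_rng(2)
        pop = simple_population(
            rng.uniform(0, 360, 6), positions=rng.normal(0, 10, (6, 2))
        )
        candidates = enumerate_bipartitions(pop.ids)
        steps = 3

        def oracle_delta(part):
            final = evolve(pop, BALLISTIC, steps=steps)[-1]
            truthful = {
                c.collective_id: c.centroid
                for c in apply_partition(final, part)
            }
            projected = {
                c.collective_id: c.centroid
                for c in evolve(apply_partition(pop, part), BALLISTIC,
                                steps=steps)[-1]
            }
            return max(
                np.linalg.norm(truthful[cid] - projected[cid])
                for cid in truthful
            )

        oracle_best = min(candidates, key=oracle_delta)
        result = best_partition(
            pop, BALLISTIC, None, steps, candidates, Threshold(1e9), "position"
        )
        assert result.partition == oracle_best
        assert result.comparison.population_delta == pytest.approx(
            oracle_delta(oracle_best)
        )


class TestConditionedDelta:
    def _env(self, label):
        return Environment(
            resource_patches=(ResourcePatch((0, 0), 1.0, 1000.0),),
            state_label=label,
        )

    def test_single_environment_reduces_to_delta_vector(
        self, aligned_pop, clusters_partition
    ):
        rule = UpdateRule("chemotaxis")
        cd = conditioned_delta(
            aligned_pop, rule, [(self._env("only"), 1.0)], 2,
            clusters_partition, ["position"], reduction="max",
        )
        (direct,) = delta_vector(
            aligned_pop, rule, self._env("only"), 2, clusters_partition,
            ["position"],
        )
        assert cd.reduced == direct.population_delta

    def test_identical_deltas_closed_forms(self, aligned_pop, clusters_partition):
        # k identical environment states: euclidean reduction d*sqrt(k),
        # max reduction d
        rule = UpdateRule("chemotaxis")
        envs = [(self._env(f"s{i}"), 1.0) for i in range(3)]
        (direct,) = delta_vector(
            aligned_pop, rule, envs[0][0], 2, clusters_partition, ["position"]
        )
        d = direct.population_delta
        euclid = conditioned_delta(
            aligned_pop, rule, envs, 2, clusters_partition, ["position"],
            reduction="euclidean",
        )
        maxi = conditioned_delta(
            aligned_pop, rule, envs, 2, clusters_partition, ["position"],
            reduction="max",
        )
        assert euclid.reduced == pytest.approx(d * np.sqrt(3))
        assert maxi.reduced == pytest.approx(d)

    def test_ecological_confound_raises_the_conditioned_error(self):
        # a pairing coherent under one resource layout loses coherence when
        # the environment state changes: the max reduction exceeds the
        # single-environment delta
        pop = simple_population(
            [0.0] * 4, positions=[(20, 20), (40, 40), (60, 10), (70, 20)]
        )
        part = Partition({0: 0, 1: 0, 2: 1, 3: 1})
        rule = UpdateRule("chemotaxis")
        env_a = self._env("patch_origin")
        env_b = Environment(
            resource_patches=(ResourcePatch((100, 0), 1.0, 1000.0),),
            state_label="patch_east",
        )
        (single,) = delta_vector(pop, rule, env_a, 1, part, ["position"])
        cd = conditioned_delta(
            pop, rule, [(env_a, 0.5), (env_b, 0.5)], 1, part, ["position"],
            reduction="max",
        )
        assert cd.reduced > single.population_delta

    def test_zero_total_weight_rejected(self, aligned_pop, clusters_partition):
        with pytest.raises(DomainError):
            conditioned_delta(
                aligned_pop, UpdateRule("chemotaxis"),
                [(self._env("a"), 0.0)], 1, clusters_partition, ["position"],
            )
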
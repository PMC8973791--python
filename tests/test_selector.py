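"""Eligibility gating, diversity clustering, sampling, tournament selection."""

import itertools
import math

import numpy as np
import pytest
from rdkit import Chem, DataStructs

from evochem.fitness import Pose, make_fitness_result
from evochem.selector import (
    SelectionConfig,
    cluster_population,
    eligible_seeds,
    sample_representatives,
    tournament_select,
)

BENZENE = "c1ccccc1"


def hexagon(shift=0.0):
    return tuple(
        (1.4 * math.cos(k * math.pi / 3) + shift, 1.4 * math.sin(k * math.pi / 3), 0.0)
        for k in range(6)
    )


def posed_result(mol_id, score, shift=0.0):
    pose = Pose(mol_id, ("C",) * 6, hexagon(shift), score, smiles=BENZENE)
    return make_fitness_result(mol_id, score, 6, pose=pose)


class TestEligibilityGate:
    """The 2 A RMSD / score-drop disjunction on hand-labeled pose cases."""

    # (rmsd_shift, parent_score, child_score, expected_eligible)
    CASES = [
        (1.1, -5.0, -4.2, True),    # consistent mode, worse score -> kept
        (0.0, -5.0, -5.0, True),    # identical pose
        (1.9, -5.0, -4.9, True),    # just inside the RMSD threshold
        (2.1, -5.0, -4.9, False),   # outside threshold, trivial improvement
        (3.0, -5.0, -7.0, True),    # moved, but clearly better score
        (3.0, -5.0, -5.2, False),   # moved, improvement below margin
        (3.0, -5.0, -6.0, True),    # improvement exactly at margin
        (5.0, -5.0, -4.0, False),   # moved and worse
        (2.0, -5.0, -4.9, False),   # boundary: threshold is strict (<)
        (0.5, -3.0, -1.0, True),    # consistent mode dominates bad score
    ]

    @pytest.mark.parametrize("shift,pscore,cscore,expected", CASES)
    def test_hand_labeled_cases(self, shift, pscore, cscore, expected):
        config = SelectionConfig(rmsd_threshold=2.0, score_drop_margin=1.0)
        parent = posed_result("p", pscore)
        child = posed_result("c", cscore, shift=shift)
        out = eligible_seeds([child], {"c": parent}, config)
        assert (len(out) == 1) is expected

    def test_generation_one_always_eligible(self):
        config = SelectionConfig()
        child = make_fitness_result("c", -1.0, 6)
        assert eligible_seeds([child], {"c": None}, config) == [child]

    def test_poseless_modes_vacuous_rmsd(self):
        config = SelectionConfig()
        parent = make_fitness_result("p", -5.0, 6)
        child = make_fitness_result("c", -1.0, 6)  # much worse score
        assert eligible_seeds([child], {"c": parent}, config) == [child]


class TestClustering:
    def test_identical_molecules_one_cluster(self):
        assignment = cluster_population([BENZENE] * 5, cutoff=0.15)
        assert set(assignment) == {0}

    def test_zero_cutoff_splits_by_fingerprint(self, probe_molecules):
        mols = probe_molecules[:12]
        assignment = cluster_population(mols, cutoff=0.0)
        fps = {Chem.RDKFingerprint(Chem.MolFromSmiles(s)).ToBitString() for s in mols}
        assert len(set(assignment)) == len(fps)

    def test_sphere_exclusion_property_brute_force(self, probe_molecules):
        """Every member is within the cutoff of its cluster leader (all-pairs check)."""
        mols = probe_molecules  # 30 molecules
        cutoff = 0.15
        assignment = cluster_population(mols, cutoff=cutoff)
        fps = [Chem.RDKFingerprint(Chem.MolFromSmiles(s)) for s in mols]
        dist = [
            [1.0 - DataStructs.TanimotoSimilarity(a, b) for b in fps] for a in fps
        ]
        # leader of cluster c = first molecule of c in the deterministic visit order
        order = sorted(range(len(mols)), key=lambda i: (mols[i], i))
        leader = {}
        for i in order:
            leader.setdefault(assignment[i], i)
        for i, cid in enumerate(assignment):
            assert dist[i][leader[cid]] <= cutoff

    def test_deterministic_under_fitness_order(self, probe_molecules):
        fitness = [-(i % 7) - 0.1 for i in range(len(probe_molecules))]
        a1 = cluster_population(probe_molecules, 0.15, fitness)
        a2 = cluster_population(probe_molecules, 0.15, fitness)
        assert a1 == a2


class TestSampling:
    def test_one_per_cluster_when_budget_equals_clusters(self):
        members = ["a", "b", "c", "d", "e"]
        clusters = [0, 1, 2, 3, 4]
        fitness = [-5.0, -4.0, -3.0, -2.0, -1.0]
        picked = sample_representatives(clusters, members, 5, fitness)
        assert sorted(picked) == [0, 1, 2, 3, 4]

    def test_round_robin_allocation(self):
        # clusters of sizes 5 / 3 / 1, budget 6 -> allocation 3 / 2 / 1
        clusters = [0] * 5 + [1] * 3 + [2]
        members = [f"m{i}" for i in range(9)]
        fitness = [-9, -8, -7, -6, -5, -4, -3, -2, -1]
        picked = sample_representatives(clusters, members, 6, fitness)
        alloc = {c: sum(1 for i in picked if clusters[i] == c) for c in (0, 1, 2)}
        assert alloc == {0: 3, 1: 2, 2: 1}

    def test_budget_below_cluster_count_truncates_by_fitness(self):
        clusters = [0, 1, 2]
        members = ["x", "y", "z"]
        fitness = [-1.0, -9.0, -5.0]
        picked = sample_representatives(clusters, members, 2, fitness)
        assert picked == [1, 2]  # two best-led clusters

    def test_deterministic(self, probe_molecules):
        clusters = cluster_population(probe_molecules, 0.15)
        p1 = sample_representatives(clusters, probe_molecules, 10, rng_seed=5)
        p2 = sample_representatives(clusters, probe_molecules, 10, rng_seed=5)
        assert p1 == p2


def ranked_population(n):
    """n individuals with distinct fitness; rank 1 is best (lowest score)."""
    return [make_fitness_result(f"m{r:02d}", -float(n - r + 1), 10) for r in range(1, n + 1)]


class TestTournament:
    def test_full_size_tournament_is_greedy(self):
        pop = ranked_population(10)
        out = tournament_select(pop, k=10, n=1, rng_seed=0)
        assert out[0].mol_id == "m01"

    def test_k1_uniform_within_binomial_bounds(self):
        pop = ranked_population(10)
        draws = 10000
        counts = {}
        for s in range(draws):
            w = tournament_select(pop, k=1, n=1, rng_seed=s)[0]
            counts[w.mol_id] = counts.get(w.mol_id, 0) + 1
        p = 1 / 10
        sigma = math.sqrt(draws * p * (1 - p))
        for mid in (r.mol_id for r in pop):
            assert abs(counts.get(mid, 0) - draws * p) < 3.5 * sigma

    def test_k2_selection_probability_closed_form(self):
        n_pop = 10
        pop = ranked_population(n_pop)
        draws = 10000
        counts = {}
        for s in range(draws):
            w = tournament_select(pop, k=2, n=1, rng_seed=s)[0]
            counts[w.mol_id] = counts.get(w.mol_id, 0) + 1
        for rank, res in enumerate(pop, start=1):
            expected = 2 * (n_pop - rank) / (n_pop * (n_pop - 1))
            sigma = math.sqrt(draws * expected * (1 - expected)) if expected else 1.0
            assert abs(counts.get(res.mol_id, 0) - draws * expected) < 4 * sigma, rank

    def test_selection_pressure_increases_with_k(self):
        pop = ranked_population(30)
        means = []
        for k in (1, 2, 4, 8):
            sel = [
                tournament_select(pop, k=k, n=1, rng_seed=s)[0].raw_score
                for s in range(300)
            ]
            means.append(np.mean(sel))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))  # improving

    def test_distinct_winners_and_determinism(self):
        pop = ranked_population(20)
        s1 = tournament_select(pop, k=4, n=10, rng_seed=3)
        s2 = tournament_select(pop, k=4, n=10, rng_seed=3)
        assert [r.mol_id for r in s1] == [r.mol_id for r in s2]
        assert len({r.mol_id for r in s1}) == 10

    def test_population_exhaustion_terminates(self):
        pop = ranked_population(5)
        out = tournament_select(pop, k=4, n=100, rng_seed=0)
        # only the best 5-(4-1)=2 individuals can ever win a 4-way tournament
        assert {r.mol_id for r in out} == {"m01", "m02"}
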
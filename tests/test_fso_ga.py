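import itertools
from collections import Counter

import numpy as np
import pytest

from gmigago import (
    ClusterAssignment,
    DistanceMatrix,
    FSOGA,
    FsoConfig,
    PAMGA,
    PlantedDesign,
    build_potential_modules,
    fsoga_crossover,
    fsoga_init,
    fsoga_mutate,
    functional_scores,
    make_planted_expression,
    make_toy_ontology,
    membership_threshold,
    partition_to_membership,
    run_fso_ga,
    validate_membership,
)
from gmigago.fso_ga import FitnessEvaluator, PotentialModules


class TestMembershipThreshold:
    @pytest.mark.parametrize(
        "distances,expected",
        [
            ((1, 2, 3, 4, 5), 7.0),  # Q1=2, Q3=4 -> 4 + 1.5*2
            ((1, 2, 3, 5), 6.125),  # Q1=1.75, Q3=3.5 under linear interpolation
            ((0.4, 0.4, 0.4), 0.4),  # zero quartile range
            ((0.7,), 0.7),  # single member: Q1=Q3
        ],
    )
    def test_boxplot_upper_fence(self, distances, expected):
        assert membership_threshold(distances) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            membership_threshold([])


def small_instance():
    """3 clusters of 3 genes plus one gene sitting between two medoids."""
    n = 10
    D = np.full((n, n), 1.2)
    blocks = [(0, 1, 2), (3, 4, 5), (6, 7, 8)]
    for block in blocks:
        for i in block:
            for j in block:
                D[i, j] = 0.1 if i != j else 0.0
    # gene 9: close to medoids 0 and 3, far from 6
    for j in (0, 1, 2, 3, 4, 5):
        D[9, j] = D[j, 9] = 0.12
    np.fill_diagonal(D, 0.0)
    dm = DistanceMatrix([f"g{i}" for i in range(n)], D)
    assign = ClusterAssignment([0, 0, 0, 1, 1, 1, 2, 2, 2, 0], k=3)
    return dm, (0, 3, 6), assign


class TestBuildPotentialModules:
    def test_hand_checked_lists(self):
        dm, medoids, assign = small_instance()
        pot = build_potential_modules(dm, medoids, assign)
        # thresholds: cluster 0 member distances (0, .1, .1, .12) -> Q3+1.5QR
        d0 = np.array([0.0, 0.1, 0.1, 0.12])
        q1, q3 = np.percentile(d0, [25, 75])
        assert pot.thresholds[0] == pytest.approx(q3 + 1.5 * (q3 - q1))
        # the ambiguous gene may join clusters 0 and 1, not 2
        assert pot.lists[9] == [0, 1]
        # medoids always list their own module, tight genes have M = 1
        assert pot.lists[0][0] == 0
        assert pot.lists[6] == [2]

    def test_stage1_module_always_included(self):
        dm, medoids, assign = small_instance()
        pot = build_potential_modules(dm, medoids, assign)
        for i in range(dm.n):
            assert assign.labels[i] in pot.lists[i]
            assert pot.M(i) >= 1


def _potential_three_wide():
    """A potential structure where one gene may join all 3 modules."""
    dist = np.array(
        [
            [0.0, 1.0, 1.0],
            [1.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
            [0.2, 0.3, 0.4],
        ]
    )
    lists = [[0], [1], [2], [0, 1, 2]]
    return PotentialModules(lists, dist, np.array([0.5, 0.5, 0.5]), np.array([0, 1, 2, 0]))


class TestInit:
    def test_over_zero_yields_hard_partitions(self):
        pot = _potential_three_wide()
        rng = np.random.default_rng(0)
        seed = np.eye(4, 3, dtype=np.uint8)[[0, 1, 2, 0]]
        for A in fsoga_init(pot, 0.0, 30, seed, rng):
            validate_membership(A, pot)
            assert (A.sum(axis=1) == 1).all()

    def test_single_candidate_gene_is_pinned(self):
        pot = _potential_three_wide()
        rng = np.random.default_rng(1)
        seed = np.eye(4, 3, dtype=np.uint8)[[0, 1, 2, 0]]
        for A in fsoga_init(pot, 1.0, 30, seed, rng):
            assert A[0].tolist() == [1, 0, 0]

    def test_over_one_row_sums_uniform(self):
        pot = _potential_three_wide()
        rng = np.random.default_rng(2)
        counts = Counter()
        n_draws = 10_000
        for _ in range(n_draws):
            A = fsoga_init(pot, 1.0, 2, np.eye(4, 3, dtype=np.uint8)[[0, 1, 2, 0]], rng)[1]
            counts[int(A[3].sum())] += 1
        for c in (1, 2, 3):
            assert counts[c] / n_draws == pytest.approx(1 / 3, abs=0.02)

    def test_seed_matrix_is_first_individual(self):
        pot = _potential_three_wide()
        seed = np.eye(4, 3, dtype=np.uint8)[[0, 1, 2, 0]]
        pop = fsoga_init(pot, 0.5, 5, seed, np.random.default_rng(3))
        np.testing.assert_array_equal(pop[0], seed)


class TestCrossoverMutation:
    def test_identical_parents_give_identical_child(self):
        pot = _potential_three_wide()
        rng = np.random.default_rng(4)
        A = fsoga_init(pot, 1.0, 2, np.eye(4, 3, dtype=np.uint8)[[0, 1, 2, 0]], rng)[1]
        child = fsoga_crossover(A, A.copy(), rng, pot)
        np.testing.assert_array_equal(child, A)

    def test_child_rows_come_from_a_parent(self):
        pot = _potential_three_wide()
        rng = np.random.default_rng(5)
        seed = np.eye(4, 3, dtype=np.uint8)[[0, 1, 2, 0]]
        pop = fsoga_init(pot, 1.0, 20, seed, rng)
        for A1, A2 in zip(pop[::2], pop[1::2]):
            child = fsoga_crossover(A1, A2, rng, pot)
            validate_membership(child, pot)
            for i in range(4):
                row = child[i].tolist()
                # repair may add a membership but never removes one
                assert row == A1[i].tolist() or row == A2[i].tolist() or sum(row) >= 1

    def test_mutation_zero_rate_is_identity(self):
        pot = _potential_three_wide()
        rng = np.random.default_rng(6)
        A = np.eye(4, 3, dtype=np.uint8)[[0, 1, 2, 0]]
        np.testing.assert_array_equal(fsoga_mutate(A, 0.0, pot, 1.0, rng), A)

    def test_mutation_preserves_invariants_at_full_rate(self):
        pot = _potential_three_wide()
        rng = np.random.default_rng(7)
        A = np.eye(4, 3, dtype=np.uint8)[[0, 1, 2, 0]]
        for _ in range(1000):
            A2 = fsoga_mutate(A, 1.0, pot, 1.0, rng)
            validate_membership(A2, pot)
            assert 1 <= A2[3].sum() <= 3


class TestFunctionalScores:
    def test_sim_of_one_module_with_constant_pairwise_similarity(self):
        # two retained terms at lin = 0.6 -> Sim_1 = Sim_2 = 0.6 -> Sim = 0.6
        sim, _ = functional_scores(
            [[("t1", 0.01), ("t2", 0.01)]], lambda a, b: 0.6, n_modules=1
        )
        assert sim == pytest.approx(0.6)

    def test_sig_normalized_by_module_count(self):
        # p_adj 1e-5 and 1e-3 over k = 2 modules -> (5 + 3)/2 = 4
        _, sig = functional_scores(
            [[("t1", 1e-5)], [("t2", 1e-3)]], lambda a, b: 0.0, n_modules=2
        )
        assert sig == pytest.approx(4.0)

    def test_target_weighting(self):
        # Sim = 0.5, alpha = 1000, Sig = 30 -> Target = 530
        assert 0.5 * 1000 + 30 == pytest.approx(530.0)

    def test_singleton_module_contributes_sig_only(self):
        sim, sig = functional_scores(
            [[("t1", 1e-4)], [("t2", 1e-2), ("t3", 1e-2)]],
            lambda a, b: 1.0,
            n_modules=2,
        )
        assert sim == pytest.approx(1.0)  # only the two-term module defines Sim
        assert sig == pytest.approx((4 + 2 + 2) / 2)

    def test_per_term_normalization_flag(self):
        _, sig = functional_scores(
            [[("t1", 1e-5)], [("t2", 1e-3)]], lambda a, b: 0.0, n_modules=2,
            sig_norm="per_term",
        )
        assert sig == pytest.approx(4.0)  # (5+3)/2 terms here equals the k version

    def test_empty_profiles_score_zero(self):
        assert functional_scores([[], []], lambda a, b: 1.0, n_modules=2) == (0.0, 0.0)


@pytest.fixture(scope="module")
def tiny_instance():
    """12 genes, 3 planted blocks, 3 expression-ambiguous genes: small enough
    to enumerate every legal membership matrix."""
    design = PlantedDesign(
        n_genes=12, n_samples=50, k_blocks=3, within_block_corr=0.65,
        overlap_genes=(3, 7, 11), seed=5,
    )
    X, labels = make_planted_expression(design)
    dag, corpus, _ = make_toy_ontology(
        labels, gene_ids=X.gene_ids, terms_per_block=2, depth=1,
        annotation_noise=0.2, seed=6,
    )
    stage1 = PAMGA(k=3, population_size=40, generations=8, pam_max_iter=300,
                   random_state=1).fit(X)
    return X, labels, dag, corpus, stage1


def enumerate_valid_matrices(potential):
    choices = [
        [s for r in range(1, len(lst) + 1) for s in itertools.combinations(lst, r)]
        for lst in potential.lists
    ]
    for combo in itertools.product(*choices):
        A = np.zeros((potential.n, potential.k), dtype=np.uint8)
        for i, mods in enumerate(combo):
            for j in mods:
                A[i, j] = 1
        if (A.sum(axis=0) == 0).any():
            continue
        yield A


class TestFitness:
    def test_label_permutation_invariance(self, tiny_instance):
        _, _, dag, corpus, stage1 = tiny_instance
        cfg = FsoConfig(over=1.0, alpha=1000, seed=0)
        ev = FitnessEvaluator(stage1.distance_.gene_ids, dag, corpus, cfg)
        A = partition_to_membership(stage1.assignment_)
        perm = [2, 0, 1]
        b1 = ev.breakdown(A)
        b2 = ev.breakdown(A[:, perm])
        assert b1.sim == pytest.approx(b2.sim)
        assert b1.sig == pytest.approx(b2.sig)

    def test_target_combines_sim_and_sig(self, tiny_instance):
        _, _, dag, corpus, stage1 = tiny_instance
        cfg = FsoConfig(over=1.0, alpha=1000, seed=0)
        ev = FitnessEvaluator(stage1.distance_.gene_ids, dag, corpus, cfg)
        b = ev.breakdown(partition_to_membership(stage1.assignment_))
        assert b.target == pytest.approx(b.sim * 1000 + b.sig)
        assert 0.0 <= b.sim <= 1.0
        assert b.sig >= 0.0


class TestRunFsoGa:
    def test_elite_target_bounded_below_by_stage1(self, tiny_instance):
        _, _, dag, corpus, stage1 = tiny_instance
        cfg = FsoConfig(over=1.0, alpha=1000, population_size=40, generations=8, seed=3)
        out = run_fso_ga((stage1.medoids_, stage1.assignment_), stage1.distance_,
                         dag, corpus, cfg)
        assert out.target >= out.seed_target - 1e-12
        assert (np.diff(out.ga.fitness_trace) >= 0).all()
        validate_membership(out.membership, out.potential)

    def test_elite_attains_bruteforce_optimum(self, tiny_instance):
        _, _, dag, corpus, stage1 = tiny_instance
        cfg = FsoConfig(over=1.0, alpha=1000, population_size=120, generations=15, seed=2)
        ev = FitnessEvaluator(stage1.distance_.gene_ids, dag, corpus, cfg)
        potential = build_potential_modules(stage1.distance_, stage1.medoids_,
                                            stage1.assignment_)
        brute_max = max(ev(A) for A in enumerate_valid_matrices(potential))
        out = run_fso_ga((stage1.medoids_, stage1.assignment_), stage1.distance_,
                         dag, corpus, cfg)
        assert out.target == pytest.approx(brute_max, abs=1e-9)

    def test_estimator_reproducible_and_improves_sim(self, noisy_fixture, noisy_stage1):
        _, _, dag, corpus, _ = noisy_fixture
        fit = lambda: FSOGA(
            dag, corpus, over=1.0, alpha=1000, population_size=80, generations=12,
            random_state=11,
        ).fit(noisy_stage1.distance_, medoids=noisy_stage1.medoids_,
              labels=noisy_stage1.assignment_)
        a, b = fit(), fit()
        np.testing.assert_array_equal(a.membership_, b.membership_)
        assert a.sim_ > a.seed_sim_  # functional refinement strictly helps here
        assert a.target_ >= a.seed_target_
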
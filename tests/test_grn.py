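"""Unit and oracle tests for program inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coregmap import grn as G


def frame(rows, genes=None, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


# -- discretization ----------------------------------------------------------


class TestDiscretize:
    def test_zero_variance_gene_is_all_zero(self):
        out = G.discretize(frame([[5, 5, 5, 5]]))
        assert (out.to_numpy() == 0).all()

    def test_boundary_at_one_sd_inclusive(self):
        # sd([-2,0,2]) = 2 with ddof=1; cuts at median ± 2 are met with >= / <=
        out = G.discretize(frame([[-2, 0, 2]]), threshold_sd=1.0, center="median")
        assert out.to_numpy().tolist() == [[-1, 0, 1]]

    def test_additive_shift_invariance(self, toy_expr):
        base = G.discretize(toy_expr)
        shifted = toy_expr.copy()
        shifted.iloc[2] += 5.0
        assert G.discretize(shifted).equals(base)

    def test_sample_order_invariance(self, toy_expr):
        perm = list(toy_expr.columns[::-1])
        out = G.discretize(toy_expr[perm])
        assert out.equals(G.discretize(toy_expr)[perm])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            G.discretize(pd.DataFrame())
        with pytest.raises(ValueError):
            G.discretize(frame([[1, 2, 3]]), threshold_sd=0)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(shift=st.floats(-50, 50, allow_nan=False), row=st.integers(0, 5))
    def test_shift_invariance_property(self, shift, row):
        rng = np.random.default_rng(7)
        expr = frame(rng.normal(size=(6, 8)))
        shifted = expr.copy()
        shifted.iloc[row] += shift
        assert G.discretize(shifted).equals(G.discretize(expr))


@pytest.mark.parametrize(
    "row, min_support, kept",
    [
        ([1, 0, 0, 0, 0, 0, 0, 0, 0, 0], 0.1, True),  # boundary inclusive
        ([0] * 10, 0.1, False),
        ([0] * 10, 0.0, True),  # min 0 keeps everything
    ],
)
def test_filter_supported_genes(row, min_support, kept):
    disc = frame([row]).astype(int)
    out = G.filter_supported_genes(disc, min_support)
    assert (len(out) == 1) is kept


# -- itemset mining ----------------------------------------------------------


def brute_force_sets(disc, min_support, max_set_size):
    """Exhaustive subset enumeration oracle."""
    names = list(disc.index)
    mat = disc.to_numpy()
    n = mat.shape[1]
    min_count = max(int(np.ceil(min_support * n)), 1)
    found = set()
    for sign, pol in ((1, G.ACTIVATOR), (-1, G.INHIBITOR)):
        for k in range(1, max_set_size + 1):
            for combo in itertools.combinations(range(len(names)), k):
                count = int((mat[list(combo)] == sign).all(axis=0).sum())
                if count >= min_count:
                    found.add((tuple(names[i] for i in combo), pol, count))
    return found


class TestMining:
    def test_pair_example(self):
        disc = frame(
            [[1, 1, 1, 1, 1, 1, 0, 0, -1, -1], [1, 1, 1, 1, 1, 1, -1, -1, 0, 0]],
            genes=["R1", "R2"],
        ).astype(int)
        sets = G.mine_coregulator_sets(disc, min_support=0.5, max_set_size=2)
        pair = [s for s in sets if s.members == ("R1", "R2") and s.polarity == G.ACTIVATOR]
        assert len(pair) == 1 and pair[0].support == pytest.approx(0.6)

    def test_full_support_excludes_any_zero(self):
        disc = frame([[1, 1, 0], [1, 1, 1]], genes=["Rz", "Rfull"]).astype(int)
        sets = G.mine_coregulator_sets(disc, min_support=1.0, max_set_size=2)
        assert all("Rz" not in s.members for s in sets)
        assert any(s.members == ("Rfull",) for s in sets)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        disc = frame(rng.choice([-1, 0, 1], size=(8, 15), p=[0.3, 0.4, 0.3])).astype(int)
        got = {
            (s.members, s.polarity, round(s.support * 15))
            for s in G.mine_coregulator_sets(disc, min_support=0.2, max_set_size=3)
        }
        assert got == brute_force_sets(disc, 0.2, 3)

    def test_no_regulators_raises(self):
        with pytest.raises(ValueError):
            G.mine_coregulator_sets(frame(np.empty((0, 4))).astype(int), 0.5, 2)


# -- candidate selection -----------------------------------------------------


def oracle_best_program(target_disc, candidate_sets, disc_regulators, target):
    """Independent exhaustive (A, I) ranking with plain-python loops."""
    acts = [s for s in candidate_sets if s.polarity == G.ACTIVATOR and target not in s.members]
    inhs = [s for s in candidate_sets if s.polarity == G.INHIBITOR and target not in s.members]
    options_a = [frozenset()] + [frozenset(s.members) for s in acts]
    options_i = [frozenset()] + [frozenset(s.members) for s in inhs]
    samples = list(disc_regulators.columns)
    nz = [j for j, v in enumerate(target_disc) if v != 0]

    def state(members, j):
        vals = [disc_regulators.loc[m].iloc[j] for m in members]
        if vals and all(v == 1 for v in vals):
            return 1
        if vals and all(v == -1 for v in vals):
            return -1
        return 0

    scored = []
    for A in options_a:
        for I in options_i:
            if (not A and not I) or (A & I):
                continue
            hits = 0
            for j in nz:
                pred = -1 if state(I, j) == 1 else state(A, j)
                hits += pred == target_disc[j]
            score = hits / len(nz)
            scored.append((-score, len(A) + len(I), sorted(A), sorted(I), A, I, score))
    scored.sort(key=lambda r: r[:4])
    return scored[0]


class TestCandidateSelection:
    def test_perfect_single_activator_ranks_first(self):
        disc = frame([[1, -1, 0, 1]], genes=["R1"]).astype(int)
        sets = G.mine_coregulator_sets(disc, min_support=0.25, max_set_size=1)
        out = G.select_candidate_programs(np.array([1, -1, 0, 1]), sets, disc, 10, target="t")
        assert out[0].activators == frozenset({"R1"}) and out[0].rule_score == 1.0

    def test_all_zero_target_yields_nothing(self):
        disc = frame([[1, 1, 1, 1]], genes=["R1"]).astype(int)
        sets = G.mine_coregulator_sets(disc, 0.5, 1)
        assert G.select_candidate_programs(np.zeros(4, dtype=int), sets, disc, 5, "t") == []

    def test_silent_candidate_scores_zero(self):
        # regulator never at +1/−1 jointly where target is non-zero
        disc = frame([[1, 1, 0, 0], [0, 0, 1, 1]], genes=["Ra", "Rb"]).astype(int)
        sets = G.mine_coregulator_sets(disc, 0.5, 1)
        target = np.array([0, 0, 1, 1])
        out = G.select_candidate_programs(target, sets, disc, 10, "t")
        scores = {tuple(sorted(p.activators)): p.rule_score for p in out if not p.inhibitors}
        assert scores[("Ra",)] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_top_program_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        disc = frame(rng.choice([-1, 0, 1], size=(3, 12)), genes=["Ra", "Rb", "Rc"]).astype(int)
        sets = G.mine_coregulator_sets(disc, min_support=0.15, max_set_size=2)
        target = rng.choice([-1, 0, 1], size=12)
        if not (target != 0).any():
            target[0] = 1
        got = G.select_candidate_programs(target, sets, disc, 1, target="t")[0]
        _, _, a, i, A, I, score = oracle_best_program(target, sets, disc, "t")
        assert (got.activators, got.inhibitors) == (A, I)
        assert got.rule_score == pytest.approx(score)


# -- regression scoring ------------------------------------------------------


class TestRegression:
    def test_exact_fit_gives_r2_one(self, toy_expr):
        expr = toy_expr.copy()
        expr.loc["t"] = expr.loc[["g0", "g1"]].mean()
        prog = G.RegulatoryProgram("t", frozenset(["g0", "g1"]), frozenset(), 1.0)
        assert G.score_program_regression(expr, prog) == pytest.approx(1.0)

    def test_constant_target_gives_zero(self, toy_expr):
        expr = toy_expr.copy()
        expr.loc["t"] = 3.0
        prog = G.RegulatoryProgram("t", frozenset(["g0"]), frozenset(), 1.0)
        assert G.score_program_regression(expr, prog) == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        expr = frame(rng.normal(size=(4, 8)), genes=["a1", "a2", "i1", "t"])
        prog = G.RegulatoryProgram("t", frozenset(["a1", "a2"]), frozenset(["i1"]), 1.0)
        got = G.score_program_regression(expr, prog)
        # closed-form normal equations
        y = expr.loc["t"].to_numpy()
        X = np.column_stack(
            [np.ones(8), expr.loc[["a1", "a2"]].mean().to_numpy(), expr.loc["i1"].to_numpy()]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r2 = 1 - ((y - X @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert got == pytest.approx(r2, abs=1e-9)

    def test_batch_scorer_agrees_with_reference(self, toy_expr):
        rng = np.random.default_rng(11)
        expr = toy_expr.copy()
        expr.loc["t"] = rng.normal(size=expr.shape[1])
        acts = [("g0",), ("g1", "g2")]
        inhs = [("g3",), ("g4", "g5")]
        scorer = G._BatchR2(expr, acts, inhs)
        progs = []
        for A in [frozenset(), frozenset(["g0"]), frozenset(["g1", "g2"])]:
            for I in [frozenset(), frozenset(["g3"]), frozenset(["g4", "g5"])]:
                if not (A or I):
                    continue
                progs.append(G.RegulatoryProgram("t", A, I, 0.5))
        scorer.score(expr.loc["t"].to_numpy(), progs)
        for p in progs:
            assert p.r2 == pytest.approx(G.score_program_regression(expr, p), abs=1e-9)


# -- evidence integration ----------------------------------------------------


def prog(target, A, I, r2):
    return G.RegulatoryProgram(target, frozenset(A), frozenset(I), 0.5, r2=r2)


class TestEvidenceIntegration:
    def test_empty_evidence_reduces_to_argmax_r2(self):
        cands = [prog("t", ["a", "b"], [], 0.7), prog("t", ["c"], [], 0.9)]
        best = G.integrate_evidence(cands, G.EvidenceSet(), (1, 1, 1))
        assert best.activators == frozenset(["c"]) and best.merged_score == pytest.approx(0.9)

    def test_evidence_breaks_r2_tie(self):
        cands = [prog("t", ["a"], [], 0.8), prog("t", ["b"], [], 0.8)]
        ev = G.EvidenceSet.from_pairs(regulation=[("b", "t")])
        best = G.integrate_evidence(cands, ev, (1, 1, 1))
        assert best.activators == frozenset(["b"])

    def test_weighted_mean_matches_hand_computation(self):
        # hand-computed merged scores at weights (1,1,1):
        #   {a,b}: (0.9 + 0 + 0)/3 = 0.300
        #   {c,d}: (0.3 + 1 + 1)/3 ≈ 0.767
        #   {e}:   (0.6 + 1 + 1)/3 ≈ 0.867 (no within-set pair -> f_coop = 1)
        cands = [
            prog("t", ["a", "b"], [], 0.9),
            prog("t", ["c", "d"], [], 0.3),
            prog("t", ["e"], [], 0.6),
        ]
        ev = G.EvidenceSet.from_pairs(
            regulation=[("c", "t"), ("d", "t"), ("e", "t")], cooperation=[("c", "d")]
        )
        best = G.integrate_evidence(cands, ev, (1, 1, 1))
        assert best.activators == frozenset(["e"])
        assert best.merged_score == pytest.approx((0.6 + 1 + 1) / 3)

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError):
            G.integrate_evidence([], G.EvidenceSet())


# -- whole-pipeline inference ------------------------------------------------


class TestInferGrn:
    def test_noiseless_recovery_contains_true_activators(self, small_truth):
        from coregmap import synthetic

        expr, _, _ = synthetic.simulate_expression(small_truth, n_samples_per_class=40, sigma=0.0, seed=9)
        inferred = G.infer_grn(expr, small_truth.regulators)
        got = {p.target: p for p in inferred.programs}
        for planted in small_truth.grn.programs:
            sel = got.get(planted.target)
            assert sel is not None and planted.activators <= sel.activators

    def test_all_genes_regulators_gives_empty_grn(self, toy_expr):
        out = G.infer_grn(toy_expr, list(toy_expr.index))
        assert len(out) == 0

    def test_sample_permutation_invariance(self, small_truth, small_cohort):
        expr = small_cohort[0].iloc[:, :40]  # keep it quick
        base = G.infer_grn(expr, small_truth.regulators)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(expr.columns))
        permuted = G.infer_grn(expr[perm], small_truth.regulators)
        key = lambda g: {(p.target, p.activators, p.inhibitors, round(p.r2, 12)) for p in g}
        assert key(base) == key(permuted)

    def test_selected_program_invariants(self, small_truth, small_cohort):
        expr = small_cohort[0].iloc[:, :40]
        inferred = G.infer_grn(expr, small_truth.regulators)
        assert len(inferred) > 0
        for p in inferred.programs:
            assert not (p.activators & p.inhibitors)
            pool = {(c.activators, c.inhibitors) for c in inferred.candidates[p.target]}
            assert (p.activators, p.inhibitors) in pool
            assert len(inferred.candidates[p.target]) <= 10

    def test_determinism(self, small_truth, small_cohort):
        expr = small_cohort[0].iloc[:, :40]
        a = G.infer_grn(expr, small_truth.regulators)
        b = G.infer_grn(expr, small_truth.regulators)
        assert [(p.target, p.activators, p.inhibitors, p.r2, p.merged_score) for p in a] == [
            (p.target, p.activators, p.inhibitors, p.r2, p.merged_score) for p in b
        ]

    def test_no_regulators_present_raises(self, toy_expr):
        with pytest.raises(ValueError):
            G.infer_grn(toy_expr, ["absent1", "absent2"])
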
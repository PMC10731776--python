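"""Similarity families checked against independent brute-force oracles."""

import numpy as np
import pytest

from microlink.containers import (
    AssociationMatrix,
    DiseaseDAG,
    SimilarityMatrix,
    SymptomProfile,
)
from microlink.similarity import (
    dss1,
    dss1_matrix,
    dss2,
    functional_similarity,
    gip_kernel,
    merge_two_sources,
    semantic_contribution,
    semantic_value,
    set_similarity,
)

from conftest import random_dag


# ----------------------------------------------------------------- oracles

def oracle_contribution(dag: DiseaseDAG, omega: float) -> dict[str, float]:
    """Exhaustive path enumeration: C(d) = max over all root-to-d ancestor
    paths of omega**len(path). Recursion over explicit paths, fully
    independent of the BFS implementation."""
    parents = dag.parents_of()
    best: dict[str, float] = {}

    def walk(node, value):
        if value > best.get(node, 0.0):
            best[node] = value
            for p in parents[node]:
                walk(p, value * omega)

    walk(dag.root, 1.0)
    return best


def chain_dag(names):
    edges = tuple((names[i], names[i + 1]) for i in range(len(names) - 1))
    return DiseaseDAG(names[0], frozenset(names), edges)


# ------------------------------------------------------- semantic similarity

class TestSemanticContribution:
    def test_single_node(self):
        dag = DiseaseDAG("D", frozenset({"D"}), ())
        assert semantic_contribution(dag, 0.5) == {"D": 1.0}

    def test_chain_decay(self):
        dag = chain_dag(["D", "P", "G"])
        assert semantic_contribution(dag, 0.5) == {"D": 1.0, "P": 0.5, "G": 0.25}

    def test_diamond_takes_max_path(self):
        # G reachable from D at depth 1 (direct) and depth 2 (via P)
        dag = DiseaseDAG(
            "D", frozenset({"D", "P", "G"}),
            (("D", "P"), ("P", "G"), ("D", "G")),
        )
        assert semantic_contribution(dag, 0.5)["G"] == 0.5

    def test_unreachable_node_errors(self):
        dag = DiseaseDAG("D", frozenset({"D", "P", "X"}), (("D", "P"),))
        with pytest.raises(ValueError, match="unreachable"):
            semantic_contribution(dag, 0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            dag = random_dag(rng)
            omega = float(rng.uniform(0.2, 1.0))
            got = semantic_contribution(dag, omega)
            want = oracle_contribution(dag, omega)
            assert got.keys() == want.keys()
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-12)


class TestSemanticValue:
    def test_single_node_is_one(self):
        assert semantic_value(DiseaseDAG("D", frozenset({"D"}), ()), 0.5) == 1.0

    def test_chain_sum(self):
        assert semantic_value(chain_dag(["D", "P", "G"]), 0.5) == 1.75

    def test_monotone_under_node_addition(self):
        small = chain_dag(["D", "P"])
        big = chain_dag(["D", "P", "G"])
        assert semantic_value(big, 0.5) > semantic_value(small, 0.5)


class TestDss1:
    def test_self_similarity_is_one(self):
        dag = chain_dag(["D", "P", "G"])
        assert dss1(dag, dag, 0.5) == 1.0

    def test_disjoint_is_zero(self):
        a = chain_dag(["D1", "P1"])
        b = chain_dag(["D2", "P2"])
        assert dss1(a, b, 0.5) == 0.0

    def test_shared_parent_hand_value(self):
        a = chain_dag(["D1", "P"])
        b = chain_dag(["D2", "P"])
        # shared node P: (0.5 + 0.5) / (1.5 + 1.5) = 1/3
        assert dss1(a, b, 0.5) == pytest.approx(1 / 3)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_dag(rng), random_dag(rng)
            assert dss1(a, b, 0.6) == pytest.approx(dss1(b, a, 0.6))

    def test_matches_oracle_on_random_dags(self):
        """100 random DAG pairs (<= 12 nodes): dss1 equals direct evaluation
        from the path-enumeration oracle, exactly."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = random_dag(rng), random_dag(rng)
            omega = float(rng.uniform(0.3, 0.9))
            ca, cb = oracle_contribution(a, omega), oracle_contribution(b, omega)
            shared = set(ca) & set(cb)
            want = (
                sum(ca[d] + cb[d] for d in shared)
                / (sum(ca.values()) + sum(cb.values()))
                if shared else 0.0
            )
            assert dss1(a, b, omega) == pytest.approx(want, rel=1e-12)

    def test_matrix_wrapper_diagonal_and_symmetry(self):
        rng = np.random.default_rng(3)
        dags = {f"D{i}": random_dag(rng) for i in range(6)}
        sim = dss1_matrix(dags, 0.5)
        assert np.allclose(np.diag(sim.values), 1.0)
        assert np.allclose(sim.values, sim.values.T)


# ------------------------------------------------------------------- symptom

class TestDss2:
    def test_identical_rows(self):
        prof = SymptomProfile(np.array([[1.0, 2.0], [1.0, 2.0]]), ["a", "b"])
        assert dss2(prof).values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_rows(self):
        prof = SymptomProfile(np.array([[1.0, 0.0], [0.0, 3.0]]), ["a", "b"])
        assert dss2(prof).values[0, 1] == pytest.approx(0.0)

    def test_hand_cosine(self):
        prof = SymptomProfile(np.array([[1.0, 1, 0], [0, 1, 1.0]]), ["a", "b"])
        assert dss2(prof).values[0, 1] == pytest.approx(0.5)

    def test_zero_row_warns_and_zeroes(self):
        prof = SymptomProfile(np.array([[0.0, 0.0], [1.0, 1.0]]), ["a", "b"])
        with pytest.warns(UserWarning, match="empty symptom"):
            sim = dss2(prof)
        assert sim.values[0, 1] == 0.0
        assert sim.values[0, 0] == 1.0


# ----------------------------------------------------------------------- GIP

class TestGipKernel:
    def test_identical_profiles_give_one(self):
        A = AssociationMatrix(
            np.array([[1, 0], [1, 0], [0, 1]]), ["m1", "m2", "m3"], ["d1", "d2"]
        )
        assert gip_kernel(A, "microbe").values[0, 1] == pytest.approx(1.0)

    def test_identity_matrix_hand_value(self):
        A = AssociationMatrix(np.eye(2, dtype=int), ["m1", "m2"], ["d1", "d2"])
        K = gip_kernel(A, "disease")
        # mean ||column||^2 = 1 so eta = 1; off-diagonal exp(-2)
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0))

    def test_doubling_bandwidth_squares_entries(self):
        rng = np.random.default_rng(5)
        A = AssociationMatrix((rng.random((6, 4)) < 0.5).astype(int),
                              [f"m{i}" for i in range(6)],
                              [f"d{j}" for j in range(4)])
        K1 = gip_kernel(A, "microbe", eta_prime=1.0).values
        K2 = gip_kernel(A, "microbe", eta_prime=2.0).values
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(K2[off], K1[off] ** 2)

    def test_all_zero_matrix_errors(self):
        A = AssociationMatrix.__new__(AssociationMatrix)
        A.values = np.zeros((3, 3), dtype=np.int8)
        A.row_labels = ["a", "b", "c"]
        A.col_labels = ["x", "y", "z"]
        with pytest.raises(ValueError, match="bandwidth"):
            gip_kernel(A, "disease")

    @pytest.mark.parametrize("axis", ["disease", "microbe"])
    def test_matches_direct_per_pair_evaluation(self, axis, rng):
        """Random binary matrices <= 20x20: kernel equals elementwise
        evaluation of the defining formula to 1e-12."""
        for _ in range(10):
            nm = int(rng.integers(3, 21))
            nd = int(rng.integers(3, 21))
            vals = (rng.random((nm, nd)) < 0.4).astype(int)
            if vals.sum() == 0:
                vals[0, 0] = 1
            A = AssociationMatrix(vals, [f"m{i}" for i in range(nm)],
                                  [f"d{j}" for j in range(nd)])
            K = gip_kernel(A, axis).values
            profiles = vals.T if axis == "disease" else vals
            n = profiles.shape[0]
            eta = 1.0 / np.mean([np.dot(p, p) for p in profiles])
            for i in range(n):
                for j in range(n):
                    diff = profiles[i] - profiles[j]
                    want = 1.0 if i == j else np.exp(-eta * np.dot(diff, diff))
                    assert K[i, j] == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------- functional similarity

class TestFunctionalSimilarity:
    def base(self, vals, labels):
        return SimilarityMatrix(vals, labels)

    def test_set_similarity_basics(self):
        base = self.base(np.array([[1.0, 0.2], [0.2, 1.0]]), ["a", "b"])
        assert set_similarity("a", ["a", "b"], base) == 1.0
        assert set_similarity("a", ["b"], base) == pytest.approx(0.2)

    def test_identical_partner_sets_give_one(self):
        A = AssociationMatrix(np.array([[1, 1], [1, 1]]), ["x", "y"], ["a", "b"])
        base = self.base(np.eye(2), ["a", "b"])
        assert functional_similarity(A, base).values[0, 1] == pytest.approx(1.0)

    def test_disjoint_sets_zero_base_give_zero(self):
        A = AssociationMatrix(np.array([[1, 0], [0, 1]]), ["x", "y"], ["a", "b"])
        base = self.base(np.eye(2), ["a", "b"])
        assert functional_similarity(A, base).values[0, 1] == 0.0

    def test_hand_value_single_partners(self):
        A = AssociationMatrix(np.array([[1, 0], [0, 1]]), ["x", "y"], ["a", "b"])
        base = self.base(np.array([[1.0, 0.4], [0.4, 1.0]]), ["a", "b"])
        assert functional_similarity(A, base).values[0, 1] == pytest.approx(0.4)

    def test_empty_partner_set_warns(self):
        A = AssociationMatrix(np.array([[0, 0], [1, 1]]), ["x", "y"], ["a", "b"])
        base = self.base(np.eye(2), ["a", "b"])
        with pytest.warns(UserWarning, match="no partner"):
            sim = functional_similarity(A, base)
        assert sim.values[0, 0] == 1.0
        assert sim.values[0, 1] == 0.0

    def test_matches_direct_formula_on_random_inputs(self, rng):
        """Random association/base pairs: equals a literal double-loop
        evaluation of the best-match-average definition."""
        for _ in range(10):
            n, p = int(rng.integers(3, 8)), int(rng.integers(3, 6))
            A = AssociationMatrix(
                np.clip((rng.random((n, p)) < 0.6).astype(int) +
                        np.eye(n, p, dtype=int) * 0, 0, 1),
                [f"x{i}" for i in range(n)], [f"d{j}" for j in range(p)],
            )
            raw = rng.random((p, p))
            raw = (raw + raw.T) / 2
            np.fill_diagonal(raw, 1.0)
            base = self.base(raw, [f"d{j}" for j in range(p)])
            got = functional_similarity(A, base).values
            for i in range(n):
                for j in range(n):
                    si = np.flatnonzero(A.values[i])
                    sj = np.flatnonzero(A.values[j])
                    if i == j:
                        want = 1.0
                    elif len(si) == 0 or len(sj) == 0:
                        want = 0.0
                    else:
                        want = (
                            sum(max(raw[d, e] for e in si) for d in sj)
                            + sum(max(raw[d, e] for e in sj) for d in si)
                        ) / (len(si) + len(sj))
                    assert got[i, j] == pytest.approx(want, abs=1e-12)


class TestMergeTwoSources:
    @pytest.mark.parametrize("a,b,want", [(0.6, 0.4, 0.5), (0.6, 0.0, 0.6),
                                          (0.0, 0.0, 0.0)])
    def test_merge_rules(self, a, b, want):
        Sa = SimilarityMatrix(np.array([[1.0, a], [a, 1.0]]), ["x", "y"])
        Sb = SimilarityMatrix(np.array([[1.0, b], [b, 1.0]]), ["x", "y"])
        assert merge_two_sources(Sa, Sb).values[0, 1] == pytest.approx(want)

    def test_label_mismatch_errors(self):
        Sa = SimilarityMatrix(np.eye(2), ["x", "y"])
        Sb = SimilarityMatrix(np.eye(2), ["x", "z"])
        with pytest.raises(ValueError, match="labels"):
            merge_two_sources(Sa, Sb)


# ------------------------------------------------------- global invariants

@pytest.mark.parametrize("maker", ["gip", "dfs", "dss1"])
def test_outputs_symmetric_unit_interval(maker, rng):
    for _ in range(5):
        nm, nd = int(rng.integers(4, 10)), int(rng.integers(4, 8))
        vals = (rng.random((nm, nd)) < 0.5).astype(int)
        vals[0, 0] = 1
        A = AssociationMatrix(vals, [f"m{i}" for i in range(nm)],
                              [f"d{j}" for j in range(nd)])
        if maker == "gip":
            sim = gip_kernel(A, "microbe")
        elif maker == "dfs":
            base_raw = rng.random((nd, nd))
            base_raw = (base_raw + base_raw.T) / 2
            np.fill_diagonal(base_raw, 1.0)
            with np.errstate(all="ignore"):
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    sim = functional_similarity(
                        A, SimilarityMatrix(base_raw, list(A.col_labels)))
        else:
            dags = {f"d{j}": random_dag(rng, 8) for j in range(nd)}
            sim = dss1_matrix(dags, 0.5)
        v = sim.values
        assert np.abs(v - v.T).max() <= 1e-12
        assert v.min() >= 0.0 and v.max() <= 1.0


# ------------------------------------------------------ hypothesis properties

from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=50, derandomize=True, deadline=None)
@given(arrays(np.int8, (5, 4), elements=st.integers(0, 1)))
def test_gip_kernel_symmetric_unit_range_property(vals):
    """For any binary association pattern with at least one link, the
    interaction-profile kernel is symmetric with unit diagonal and entries
    in (0, 1]."""
    if vals.sum() == 0:
        vals = vals.copy()
        vals[0, 0] = 1
    A = AssociationMatrix(vals, [f"m{i}" for i in range(5)],
                          [f"d{j}" for j in range(4)])
    K = gip_kernel(A, "microbe").values
    assert np.abs(K - K.T).max() <= 1e-12
    assert np.allclose(np.diag(K), 1.0)
    assert K.min() > 0 and K.max() <= 1


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(0, 1), st.floats(0, 1))
def test_merge_two_sources_bounds_property(a, b):
    """The two-database merge always lands between min and max of the
    nonzero inputs, and merging a matrix with itself is the identity."""
    Sa = SimilarityMatrix(np.array([[1.0, a], [a, 1.0]]), ["x", "y"])
    Sb = SimilarityMatrix(np.array([[1.0, b], [b, 1.0]]), ["x", "y"])
    merged = merge_two_sources(Sa, Sb).values[0, 1]
    nz = [v for v in (a, b) if v != 0]
    if nz:
        assert min(nz) - 1e-12 <= merged <= max(nz) + 1e-12
    else:
        assert merged == 0.0
    self_merged = merge_two_sources(Sa, Sa).values[0, 1]
    assert self_merged == pytest.approx(a)
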
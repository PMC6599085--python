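"""Profile queries, bypass-gene screening, context ranking, Fisher tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rnashotgun.phyloprofile import (
    GeneContext,
    OrthologMatrix,
    ProfileError,
    context_rank,
    eval_query,
    fisher_cooccurrence,
    fisher_enumerate,
    fisher_from_counts,
    parse_query,
    screen_bypass_candidates,
)


@pytest.fixture
def small_matrix():
    presence = pd.DataFrame(
        {
            "cmoA": [1, 1, 1, 0, 0],
            "cmoB": [1, 1, 0, 0, 0],
            "trmR": [0, 0, 1, 1, 0],
            "trhP": [1, 0, 0, 0, 1],
        },
        index=[f"org{i}" for i in range(5)],
    ).astype(bool)
    return OrthologMatrix(presence)


def random_matrix(rng, n_org, n_fam):
    presence = pd.DataFrame(
        rng.random((n_org, n_fam)) < 0.5,
        index=[f"o{i}" for i in range(n_org)],
        columns=[f"f{j}" for j in range(n_fam)],
    )
    return OrthologMatrix(presence)


class TestQueries:
    def test_single_atom(self, small_matrix):
        assert eval_query(small_matrix, "cmoA") == ["org0", "org1", "org2"]

    def test_contradiction_is_empty(self, small_matrix):
        assert eval_query(small_matrix, "cmoA & !cmoA") == []

    def test_paper_shaped_query(self, small_matrix):
        # downstream families present, upstream hydroxylase absent
        result = eval_query(small_matrix, "(cmoA & cmoB | trmR) & !trhP")
        assert result == ["org1", "org2", "org3"]

    def test_parentheses_and_precedence(self, small_matrix):
        # & binds tighter than |
        assert eval_query(small_matrix, "cmoB & trmR | trhP") == ["org0", "org4"]
        assert eval_query(small_matrix, "cmoB & (trmR | trhP)") == ["org0"]

    def test_unknown_family_rejected(self, small_matrix):
        with pytest.raises(ProfileError, match="unknown family"):
            eval_query(small_matrix, "cmoA & missing")

    @pytest.mark.parametrize("bad", ["cmoA &", "(cmoA", "& cmoA", "cmoA cmoB"])
    def test_syntax_errors(self, small_matrix, bad):
        with pytest.raises(ProfileError):
            eval_query(small_matrix, bad)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_boolean_operators_distribute_over_rows(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 12, 4)
        q_or = set(eval_query(m, "f0 & f1 | f2 & !f3"))
        expected = set(eval_query(m, "f0 & f1")) | set(eval_query(m, "f2 & !f3"))
        assert q_or == expected
        q_and = set(eval_query(m, "(f0 | f1) & (f2 | f3)"))
        assert q_and == set(eval_query(m, "f0 | f1")) & set(eval_query(m, "f2 | f3"))


class TestScreen:
    def test_intersection_example(self):
        presence = pd.DataFrame(
            {
                "g1": [1, 0, 0, 0],
                "g2": [1, 1, 1, 0],
                "g3": [1, 1, 1, 1],
                "g4": [1, 0, 1, 1],
                "g5": [1, 1, 0, 0],
            },
            index=["ref", "sel1", "sel2", "bsub"],
        ).astype(bool)
        m = OrthologMatrix(presence)
        pre, post = screen_bypass_candidates(m, ["sel1", "sel2"], "ref", ["bsub"])
        assert pre == ["g3"]
        _, post = screen_bypass_candidates(
            m, ["sel1", "sel2"], "ref", ["bsub"], annotation={"g3": "characterized"}
        )
        assert post == []

    def test_all_organisms_selected_gives_universal_families(self, small_matrix):
        pre, _ = screen_bypass_candidates(small_matrix, small_matrix.organisms[1:], "org0")
        universal = [f for f in small_matrix.families if small_matrix.has(f).all()]
        assert pre == universal

    def test_empty_selection_is_degenerate(self, small_matrix):
        with pytest.raises(ProfileError, match="degenerate"):
            screen_bypass_candidates(small_matrix, [], "org0")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_filter(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 12, 30)
        orgs = m.organisms
        selected, reference, must = orgs[1:5], orgs[0], orgs[5:7]
        pre, _ = screen_bypass_candidates(m, selected, reference, must)
        rows = [reference, *selected, *must]
        brute = [
            f for f in m.families if all(bool(m.presence.loc[o, f]) for o in rows)
        ]
        assert pre == brute


class TestContextRank:
    def test_fusion_scoring(self):
        contexts = [
            GeneContext(f"org{i}", "cand", "chr1", 100, 200, fused_with="trmR")
            for i in range(3)
        ]
        ranked = context_rank(["cand", "decoy"], contexts, {"trmR"}, fusion_bonus=2)
        assert ranked[0] == ("cand", 6)
        assert ranked[1] == ("decoy", 0)

    def test_proximity_same_replicon_only(self):
        contexts = [
            GeneContext("o1", "cmoA", "chr1", 1000, 2000),
            GeneContext("o1", "cand", "chr1", 4000, 5000),  # 2 kb gap: proximal
            GeneContext("o2", "cmoA", "chr1", 1000, 2000),
            GeneContext("o2", "cand", "plasmid", 2500, 3000),  # different replicon
            GeneContext("o3", "cmoA", "chr1", 1000, 2000),
            GeneContext("o3", "cand", "chr1", 500_000, 501_000),  # too far
        ]
        ranked = dict(context_rank(["cand"], contexts, {"cmoA"}, proximity_bp=5000))
        assert ranked["cand"] == 1

    def test_ties_broken_lexicographically(self):
        ranked = context_rank(["zeta", "alpha"], [], {"cmoA"})
        assert [f for f, _ in ranked] == ["alpha", "zeta"]


class TestFisher:
    def test_independence_table(self):
        res = fisher_from_counts(10, 10, 10, 10)
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_small_table_exact_values(self):
        # enumeration by hand: two-sided 34/70, one-sided 17/70
        res = fisher_from_counts(3, 1, 1, 3, "two-sided")
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)
        res1 = fisher_from_counts(3, 1, 1, 3, "greater")
        assert res1.p_value == pytest.approx(17 / 70, abs=1e-12)

    def test_infinite_odds_ratio_when_bc_zero(self):
        res = fisher_from_counts(5, 0, 0, 5)
        assert math.isinf(res.odds_ratio)

    def test_cooccurrence_counts_from_matrix(self, small_matrix):
        res = fisher_cooccurrence(small_matrix, "cmoA", "trhP")
        assert (res.a, res.b, res.c, res.d) == (1, 2, 1, 1)
        assert res.n == len(small_matrix.organisms)

    def test_self_pair_rejected(self, small_matrix):
        with pytest.raises(ProfileError, match="self-pair"):
            fisher_cooccurrence(small_matrix, "cmoA", "cmoA")

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 100_000))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 101))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n - a + 1))
        c = int(rng.integers(0, n - a - b + 1))
        d = n - a - b - c
        for sidedness in ("two-sided", "greater"):
            res = fisher_from_counts(a, b, c, d, sidedness)
            assert res.p_value == pytest.approx(
                fisher_enumerate(a, b, c, d, sidedness), rel=1e-9
            )


class TestMatrixIO:
    def test_tsv_round_trip(self, small_matrix, tmp_path):
        path = tmp_path / "matrix.tsv"
        small_matrix.to_tsv(path)
        reloaded = OrthologMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(
            reloaded.presence, small_matrix.presence, check_names=False
        )

    def test_duplicate_ids_rejected(self):
        presence = pd.DataFrame([[True], [False]], index=["a", "a"], columns=["f"])
        with pytest.raises(ProfileError, match="duplicate"):
            OrthologMatrix(presence)
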
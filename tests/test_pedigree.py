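import numpy as np
import pandas as pd
import pytest

from metablup.pedigree import (
    GroupContributionMatrix,
    GroupTable,
    Pedigree,
    PedigreeError,
    _inbreeding_meuwissen_luo,
    build_A,
    build_A_gamma,
    build_A_gamma_inverse,
    build_A_inverse,
    build_A_upg_inverse,
    compute_breed_proportions,
    compute_inbreeding,
    compute_Q,
    sort_and_validate,
    truncate_pedigree,
)

from conftest import make_pedigree, random_pedigree


def simple_rows(n=3):
    return [
        (1, 0, 0, 2000, "A", "X", "M", 0),
        (2, 0, 0, 2000, "A", "X", "F", 0),
        (3, 1, 2, 2002, "A", "X", "F", 1),
    ][:n]


class TestSortAndValidate:
    def test_child_before_parent_reordered(self):
        rows = [simple_rows()[2], simple_rows()[0], simple_rows()[1]]
        df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year",
                                         "breed", "country", "sex", "genotyped"])
        ped = sort_and_validate(Pedigree(df))
        assert ped.is_sorted()
        assert list(ped.ids) == [1, 2, 3]

    def test_self_parenting_is_cycle(self):
        rows = [(1, 1, 0, 2000, "A", "X", "M", 0)]
        df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year",
                                         "breed", "country", "sex", "genotyped"])
        with pytest.raises(PedigreeError, match="own parent"):
            sort_and_validate(Pedigree(df))

    def test_two_cycle_detected(self):
        rows = [(1, 2, 0, 2000, "A", "X", "M", 0),
                (2, 1, 0, 2000, "A", "X", "F", 0)]
        df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year",
                                         "breed", "country", "sex", "genotyped"])
        with pytest.raises(PedigreeError, match="cycle"):
            sort_and_validate(Pedigree(df))

    def test_idempotent_on_sorted(self):
        ped = make_pedigree(simple_rows())
        again = sort_and_validate(ped)
        assert list(again.ids) == list(ped.ids)

    def test_dangling_parent_rejected(self):
        rows = [(1, 99, 0, 2000, "A", "X", "M", 0)]
        df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year",
                                         "breed", "country", "sex", "genotyped"])
        with pytest.raises(PedigreeError, match="not in pedigree"):
            Pedigree(df)


class TestInbreeding:
    def test_founders_zero(self):
        ped = make_pedigree(simple_rows())
        F = compute_inbreeding(ped)
        assert F.F.loc[1] == 0 and F.F.loc[2] == 0 and F.F.loc[3] == 0

    def test_full_sib_mating_quarter(self):
        rows = [
            (1, 0, 0, 0, "A", "X", "M", 0), (2, 0, 0, 0, "A", "X", "F", 0),
            (3, 1, 2, 1, "A", "X", "M", 0), (4, 1, 2, 1, "A", "X", "F", 0),
            (5, 3, 4, 2, "A", "X", "F", 0),
        ]
        ped = make_pedigree(rows)
        assert compute_inbreeding(ped).F.loc[5] == pytest.approx(0.25)

    def test_metafounder_founder_inbreeding(self, two_group_table):
        # both parents in one MF with gamma_ii = 0.6 -> F = gamma/2 = 0.3
        rows = [(1, -1, -1, 1990, "A", "X", "F", 0)]
        ped = make_pedigree(rows, groups=two_group_table)
        gamma = np.array([[0.6, 0.0], [0.0, 0.6]])
        F = compute_inbreeding(ped, gamma=gamma)
        assert F.gamma_based
        assert F.F.loc[1] == pytest.approx(0.3)

    def test_meuwissen_luo_matches_tabular(self, rng):
        ped = random_pedigree(300, rng)
        Ft = compute_inbreeding(ped, method="tabular").F.to_numpy()
        Fm = _inbreeding_meuwissen_luo(ped)
        assert np.abs(Ft - Fm).max() < 1e-10

    def test_F_equals_diag_A_minus_one(self, rng):
        ped = random_pedigree(200, rng)
        A = build_A(ped).dense()
        F = compute_inbreeding(ped).values_for(ped)
        assert np.abs(F - (np.diag(A) - 1.0)).max() < 1e-12


class TestBuildA:
    def test_unrelated_founders_identity(self):
        ped = make_pedigree(simple_rows(2))
        assert np.array_equal(build_A(ped).dense(), np.eye(2))

    def test_parent_offspring_half(self):
        ped = make_pedigree(simple_rows())
        A = build_A(ped).dense()
        assert A[0, 2] == pytest.approx(0.5)

    def test_half_sib_offspring_diagonal(self):
        rows = [
            (1, 0, 0, 0, "A", "X", "M", 0), (2, 0, 0, 0, "A", "X", "F", 0),
            (3, 0, 0, 0, "A", "X", "F", 0),
            (4, 1, 2, 1, "A", "X", "M", 0), (5, 1, 3, 1, "A", "X", "F", 0),
            (6, 4, 5, 2, "A", "X", "F", 0),
        ]
        A = build_A(make_pedigree(rows)).dense()
        assert A[5, 5] == pytest.approx(1.125)

    def test_subset_is_submatrix(self, rng):
        ped = random_pedigree(120, rng)
        A = build_A(ped)
        sub = build_A(ped, subset=[10, 50, 100])
        pos = ped.positions([10, 50, 100])
        assert np.allclose(sub.dense(), A.dense()[np.ix_(pos, pos)])

    def test_subset_unknown_id_errors(self):
        ped = make_pedigree(simple_rows())
        with pytest.raises(PedigreeError):
            build_A(ped, subset=[1, 999])


class TestAInverse:
    def test_founders_identity(self):
        ped = make_pedigree(simple_rows(2))
        F = compute_inbreeding(ped)
        assert np.allclose(build_A_inverse(ped, F).dense(), np.eye(2))

    def test_trio_inverse(self):
        ped = make_pedigree(simple_rows())
        F = compute_inbreeding(ped)
        Ainv = build_A_inverse(ped, F).dense()
        assert np.abs(Ainv @ build_A(ped).dense() - np.eye(3)).max() < 1e-12

    def test_random_pedigree_vs_dense_oracle(self, rng):
        ped = random_pedigree(300, rng, missing_rate=0.0)
        F = compute_inbreeding(ped)
        Ainv = build_A_inverse(ped, F).dense()
        A = build_A(ped).dense()
        assert np.abs(Ainv - np.linalg.inv(A)).max() < 1e-8


class TestAGamma:
    def test_zero_gamma_equals_A(self, rng, two_group_table):
        ped = random_pedigree(150, rng, groups=two_group_table, missing_rate=0.2)
        A = build_A(ped).dense()
        Ag = build_A_gamma(ped, np.zeros((2, 2))).dense()
        assert np.abs(A - Ag).max() < 1e-12

    def test_cross_group_relationship_and_child(self, two_group_table):
        rows = [
            (1, -1, -1, 1990, "A", "X", "M", 0),
            (2, -2, -2, 1990, "B", "X", "F", 0),
            (3, 1, 2, 1995, "A", "X", "F", 0),
        ]
        ped = make_pedigree(rows, groups=two_group_table)
        gamma = np.array([[0.0, 0.5], [0.5, 0.0]])
        # degenerate diag just for the recursion check
        Ag = build_A_gamma(ped, gamma).dense()
        assert Ag[0, 1] == pytest.approx(0.5)
        assert Ag[2, 2] == pytest.approx(1.25)

    def test_single_mf_child_diagonal(self, two_group_table):
        rows = [
            (1, -1, -1, 1990, "A", "X", "M", 0),
            (2, -1, -1, 1990, "A", "X", "F", 0),
            (3, 1, 2, 1995, "A", "X", "F", 0),
        ]
        ped = make_pedigree(rows, groups=two_group_table)
        gamma = np.diag([0.61, 0.2])
        Ag = build_A_gamma(ped, gamma).dense()
        assert Ag[2, 2] == pytest.approx(1.305)

    def test_diag_recursion_identity(self, rng, two_group_table):
        # diag_i = 1 + a(sire, dam)/2 for every non-founder, exhaustively
        ped = random_pedigree(200, rng, groups=two_group_table, missing_rate=0.1)
        gamma = np.array([[0.6, 0.4], [0.4, 0.7]])
        Ag = build_A_gamma(ped, gamma, keep_metafounders=True).dense()
        r = 2
        for i in range(ped.n):
            ps = ped.sire_pos[i] + r if ped.sire_pos[i] >= 0 else ped.sire_grp[i]
            pd_ = ped.dam_pos[i] + r if ped.dam_pos[i] >= 0 else ped.dam_grp[i]
            a_pq = Ag[ps, pd_] if ps >= 0 and pd_ >= 0 else 0.0
            assert Ag[r + i, r + i] == pytest.approx(1 + a_pq / 2, abs=1e-12)

    def test_asymmetric_gamma_rejected(self, two_group_table):
        ped = make_pedigree([(1, -1, -1, 1990, "A", "X", "M", 0)], groups=two_group_table)
        with pytest.raises(ValueError, match="symmetric"):
            build_A_gamma(ped, np.array([[0.6, 0.1], [0.3, 0.6]]))


class TestAGammaInverse:
    def test_diagonal_gamma_founders(self, two_group_table):
        rows = [(1, -1, -1, 1990, "A", "X", "M", 0),
                (2, -2, -2, 1990, "B", "X", "F", 0)]
        ped = make_pedigree(rows, groups=two_group_table)
        Ainv = build_A_gamma_inverse(ped, np.eye(2)).dense()
        Aaug = build_A_gamma(ped, np.eye(2), keep_metafounders=True).dense()
        assert np.abs(Ainv @ Aaug - np.eye(4)).max() < 1e-10

    def test_dense_oracle_200_animals(self, rng, two_group_table):
        ped = random_pedigree(200, rng, groups=two_group_table, missing_rate=0.15)
        gamma = np.array([[0.62, 0.5], [0.5, 0.71]])
        Ainv = build_A_gamma_inverse(ped, gamma).dense()
        Aaug = build_A_gamma(ped, gamma, keep_metafounders=True).dense()
        assert np.abs(Ainv @ Aaug - np.eye(202)).max() < 1e-8

    def test_singular_gamma_instructs_bending(self, two_group_table):
        ped = make_pedigree([(1, -1, -1, 1990, "A", "X", "M", 0)], groups=two_group_table)
        singular = np.full((2, 2), 0.5)
        with pytest.raises(ValueError, match="bend"):
            build_A_gamma_inverse(ped, singular)


class TestQ:
    def test_both_parents_unknown_unit_row(self, two_group_table):
        ped = make_pedigree([(1, -2, -2, 1990, "B", "X", "F", 0)], groups=two_group_table)
        Q = compute_Q(ped, two_group_table)
        assert np.allclose(Q.Q, [[0, 1]])

    def test_mixed_parent_groups(self, two_group_table):
        rows = [(1, -2, -2, 1990, "B", "X", "F", 0),
                (2, -1, 1, 1995, "A", "X", "F", 0)]
        ped = make_pedigree(rows, groups=two_group_table)
        Q = compute_Q(ped, two_group_table)
        assert np.allclose(Q.rows([2]), [[0.5, 0.5]])

    def test_rows_sum_to_one(self, rng, two_group_table):
        ped = random_pedigree(150, rng, groups=two_group_table, missing_rate=0.2)
        Q = compute_Q(ped, two_group_table)
        assert np.abs(Q.Q.sum(axis=1) - 1.0).max() < 1e-12
        assert (Q.Q >= 0).all()


class TestAUpgInverse:
    def test_no_unknown_parents_zero_group_block(self, rng):
        gt = GroupTable(pd.DataFrame(dict(group_id=[1], breed=["A"], country=["X"],
                                          year_start=[1900], year_end=[2030])))
        ped = random_pedigree(50, rng)
        ped = Pedigree(ped.df, groups=gt)
        Q = compute_Q(ped, gt)
        M = build_A_upg_inverse(ped, compute_inbreeding(ped), Q).dense()
        assert np.abs(M[50:, :]).max() == 0 and np.abs(M[:, 50:]).max() == 0

    def test_matches_dense_block_assembly(self, rng, two_group_table):
        ped = random_pedigree(50, rng, groups=two_group_table, missing_rate=0.3)
        F = compute_inbreeding(ped)
        Q = compute_Q(ped, two_group_table)
        M = build_A_upg_inverse(ped, F, Q).dense()
        Ainv = build_A_inverse(ped, F).dense()
        Qm = Q.Q
        expect = np.block([[Ainv, -Ainv @ Qm],
                           [-Qm.T @ Ainv, Qm.T @ Ainv @ Qm]])
        assert np.abs(M - expect).max() < 1e-10

    def test_animal_row_sums_vanish(self, rng, two_group_table):
        # each animal row of [A^-1, -A^-1 Q] sums to zero since Q rows sum to 1
        ped = random_pedigree(50, rng, groups=two_group_table, missing_rate=0.3)
        F = compute_inbreeding(ped)
        Q = compute_Q(ped, two_group_table)
        M = build_A_upg_inverse(ped, F, Q).dense()
        assert np.abs(M[:50, :].sum(axis=1)).max() < 1e-10


class TestTruncation:
    def _ped(self, groups):
        rows = [
            (1, 0, 0, 1960, "A", "X", "M", 0),   # grandparent, cut at depth 1
            (2, 0, 0, 1960, "A", "X", "F", 0),
            (3, 1, 2, 1980, "A", "X", "M", 0),   # parent, kept
            (4, 0, 0, 1980, "A", "X", "F", 0),   # parent, kept
            (5, 3, 4, 2000, "A", "X", "F", 1),   # genotyped
        ]
        return make_pedigree(rows, groups=groups)

    def test_depth_one_replaces_grandparents(self, two_group_table):
        ped = self._ped(two_group_table)
        out = truncate_pedigree(ped, two_group_table, depth=1)
        assert set(out.ids) == {3, 4, 5}
        rec = out.df.set_index("animal")
        assert rec.loc[3, "sire"] < 0 and rec.loc[3, "dam"] < 0

    def test_infinite_depth_keeps_all_ancestors(self, two_group_table):
        ped = self._ped(two_group_table)
        out = truncate_pedigree(ped, two_group_table, depth=np.inf)
        assert set(out.ids) == {1, 2, 3, 4, 5}

    def test_all_founder_pedigree_gets_groups(self, two_group_table):
        rows = [(1, 0, 0, 2000, "A", "X", "F", 1)]
        ped = make_pedigree(rows, groups=two_group_table)
        out = truncate_pedigree(ped, two_group_table)
        rec = out.df.set_index("animal")
        assert rec.loc[1, "sire"] < 0 and rec.loc[1, "dam"] < 0

    def test_no_genotyped_errors(self, two_group_table):
        rows = [(1, 0, 0, 2000, "A", "X", "F", 0)]
        ped = make_pedigree(rows, groups=two_group_table)
        with pytest.raises(PedigreeError):
            truncate_pedigree(ped, two_group_table)


class TestBreedProportions:
    def test_purebred_and_crosses(self):
        rows = [
            (1, 0, 0, 0, "A", "X", "M", 0),
            (2, 0, 0, 0, "B", "X", "F", 0),
            (3, 1, 2, 1, "A", "X", "F", 0),   # F1
            (4, 1, 3, 2, "A", "X", "F", 0),   # backcross to A
        ]
        ped = make_pedigree(rows)
        B = compute_breed_proportions(ped)
        assert B.loc[1, "A"] == 1.0
        assert B.loc[3, "A"] == pytest.approx(0.5)
        assert B.loc[3, "B"] == pytest.approx(0.5)
        assert B.loc[4, "A"] == pytest.approx(0.75)
        assert np.abs(B.sum(axis=1) - 1.0).max() < 1e-12
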
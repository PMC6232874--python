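"""Kruskal-Wallis, Mann-Whitney, BH-FDR, connection screening, grid search."""

import itertools

import numpy as np
import pytest

from neuroxent.coupling import epoch_coupling_matrix
from neuroxent.entropy import EntropyParams
from neuroxent.preprocessing import EpochSet
from neuroxent.stats import (
    _tie_break_key,
    bh_fdr,
    kruskal_wallis,
    mann_whitney_u,
    parameter_grid_search,
    screen_connections,
    significant_counts,
)

RNG = np.random.default_rng(777)


class TestKruskalWallis:
    def test_hand_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        # H = 12/(N(N+1)) * sum(R_j^2/n_j) - 3(N+1) with ranks 1..9
        assert h == pytest.approx(7.2, abs=1e-9)
        assert 0.0 < p < 0.05

    def test_identical_values_convention(self):
        with pytest.warns(UserWarning):
            assert kruskal_wallis([[5, 5], [5, 5]]) == (0.0, 1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1], [2, 3]])

    def test_permutation_mean_near_k_minus_1(self):
        # H over all label permutations of 6 distinct values has mean ~ k - 1
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        hs = [
            kruskal_wallis([perm[0:2], perm[2:4], perm[4:6]])[0]
            for perm in itertools.permutations(values)
        ]
        assert np.mean(hs) == pytest.approx(2.0, abs=0.3)

    def test_agrees_with_mannwhitney_at_k2(self):
        # asymptotic equivalence: same rejection decisions on tie-free data
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(20)
            b = rng.standard_normal(20) + rng.uniform(0, 1.5)
            _, p_kw = kruskal_wallis([a, b])
            _, p_mw = mann_whitney_u(a, b)
            assert (p_kw < 0.05) == (p_mw < 0.05)


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_uninformative(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_rank_sum_identity(self):
        a = RNG.standard_normal(8)
        b = RNG.standard_normal(11)
        u_a, _ = mann_whitney_u(a, b)
        u_b, _ = mann_whitney_u(b, a)
        assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])
        with pytest.raises(ValueError):
            mann_whitney_u([1], [1, 2])


class TestBhFdr:
    def test_worked_example(self):
        adjusted, reject = bh_fdr([0.01, 0.02, 0.05, 0.60], alpha=0.05)
        assert list(reject) == [True, True, False, False]
        assert adjusted[0] == pytest.approx(0.04)

    def test_all_zero_all_rejected(self):
        _, reject = bh_fdr([0.0, 0.0, 0.0])
        assert reject.all()

    def test_single_test_uncorrected(self):
        adjusted, _ = bh_fdr([0.03])
        assert adjusted[0] == pytest.approx(0.03)

    def test_adjusted_monotone_in_raw_order(self):
        p = RNG.uniform(0, 1, 30)
        adjusted, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-15)

    def test_rejection_monotone_in_alpha(self):
        p = RNG.uniform(0, 1, 40) ** 2
        _, r1 = bh_fdr(p, alpha=0.01)
        _, r2 = bh_fdr(p, alpha=0.10)
        assert np.all(r2[r1])  # reject(0.01) subset of reject(0.10)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, -0.1])


def make_subject_matrices(shift_groups=(0.0, 0.0, 0.0), n_subj=6, seed=0,
                          bands=("theta", "beta1"), n_ch=3, directed=False):
    """Synthetic subject-level matrices; `shift_groups` shifts band 'theta',
    pair (0, 1) per group."""
    rng = np.random.default_rng(seed)
    metric = "cross_apen" if directed else "cross_sampen"
    out = {}
    for g_idx, group in enumerate(("HC", "MCI", "AD")[: len(shift_groups)]):
        subjects = []
        for _ in range(n_subj):
            subj = {}
            for band in bands:
                mat = epoch_coupling_matrix(
                    rng.standard_normal((n_ch, 40)), EntropyParams(metric=metric)
                )
                vals = rng.normal(1.0, 0.1, (n_ch, n_ch))
                vals = (vals + vals.T) / 2 if not directed else vals
                if band == "theta":
                    vals[0, 1] += shift_groups[g_idx]
                    vals[1, 0] += shift_groups[g_idx]
                mat.values = vals
                mat.band = band
                subj[band] = mat
            subjects.append(subj)
        out[group] = subjects
    return out


class TestScreenConnections:
    def test_injected_shift_flagged(self):
        mats = make_subject_matrices((0.0, 1.0, 2.0), n_subj=10, seed=1)
        table = screen_connections(mats, alpha=0.05, test="kruskal_3group")
        hit = table[(table.band == "theta") & (table.chan_i == "ch00") & (table.chan_j == "ch01")]
        assert bool(hit["significant"].iloc[0])
        # few (if any) others flagged
        assert int(table["significant"].sum()) <= 3
        counts = significant_counts(table)
        assert counts["total"] == int(table["significant"].sum())
        assert counts["theta"] >= 1

    def test_zero_variance_connection_p1(self):
        mats = make_subject_matrices((0.0, 0.0, 0.0), n_subj=4, seed=2)
        for subjects in mats.values():
            for subj in subjects:
                subj["beta1"].values[0, 2] = 1.0
                subj["beta1"].values[2, 0] = 1.0
        table = screen_connections(mats)
        row = table[(table.band == "beta1") & (table.chan_i == "ch00") & (table.chan_j == "ch02")]
        assert row["p_raw"].iloc[0] == 1.0
        assert not bool(row["significant"].iloc[0])

    def test_directed_matrices_symmetrized(self):
        mats = make_subject_matrices((0.0, 0.0, 0.0), n_subj=4, seed=3, directed=True)
        table = screen_connections(mats)
        assert len(table) == 2 * 3  # 2 bands x C(3,2) pairs

    def test_scope_and_test_validation(self):
        mats = make_subject_matrices(n_subj=4, seed=4)
        with pytest.raises(ValueError):
            screen_connections(mats, fdr_scope="nope")
        with pytest.raises(ValueError):
            screen_connections(mats, test="nope")
        with pytest.raises(ValueError):
            screen_connections(mats, test="mannwhitney_2group")  # 3 groups

    def test_two_group_mannwhitney(self):
        mats = make_subject_matrices((0.0, 1.5), n_subj=10, seed=5)
        table = screen_connections(mats, test="mannwhitney_2group")
        hit = table[(table.band == "theta") & (table.chan_j == "ch01")]
        assert bool(hit["significant"].iloc[0])

    def test_single_subject_group_rejected(self):
        mats = make_subject_matrices(n_subj=1, seed=6)
        with pytest.raises(ValueError):
            screen_connections(mats)

    def test_mismatched_channels_rejected(self):
        mats = make_subject_matrices(n_subj=3, seed=7)
        bad = make_subject_matrices(n_subj=3, seed=8, n_ch=4)
        mats["AD"] = bad["AD"]
        with pytest.raises(ValueError):
            screen_connections(mats)

    def test_global_scope_single_family(self):
        mats = make_subject_matrices((0.0, 1.0, 2.0), n_subj=10, seed=9)
        band_t = screen_connections(mats, fdr_scope="band")
        glob_t = screen_connections(mats, fdr_scope="global")
        assert np.allclose(band_t["p_raw"], glob_t["p_raw"])
        assert glob_t.attrs["fdr_scope"] == "global"


def make_cohort(seed=0, n_subj=3, n_ch=3, n=100, n_epochs=2, split="train"):
    rng = np.random.default_rng(seed)
    cohort = {}
    for group in ("HC", "MCI", "AD"):
        subjects = []
        for k in range(n_subj):
            es = EpochSet(
                subject_id=f"{group}-{k}",
                band="theta",
                fs=100.0,
                channels=tuple(f"ch{i}" for i in range(n_ch)),
                epochs=[rng.standard_normal((n_ch, n)) for _ in range(n_epochs)],
                group=group,
                split=split,
            )
            subjects.append({"theta": es})
        cohort[group] = subjects
    return cohort


class TestGridSearch:
    def test_single_cell_chosen(self):
        cohort = make_cohort()
        result = parameter_grid_search(cohort, ("cross_sampen",), (1,), (0.2,))
        assert result.selected == ("cross_sampen", 1, 0.2)
        assert result.counts.shape[0] == 1
        assert set(result.tables) == {("cross_sampen", 1, 0.2)}
        assert result.matrices is not None

    def test_null_cohort_not_discriminative(self):
        cohort = make_cohort(seed=1, n_subj=4)
        result = parameter_grid_search(cohort, ("cross_sampen",), (1,), (0.15, 0.2))
        assert not result.discriminative

    def test_test_split_guard(self):
        cohort = make_cohort(split="test")
        with pytest.raises(ValueError, match="test-set"):
            parameter_grid_search(cohort, ("cross_sampen",), (1,), (0.2,))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            parameter_grid_search(make_cohort(), (), (1,), (0.2,))

    def test_tie_break_order(self):
        # equal counts: prefer cross_sampen, then smaller m, then larger r
        items = [
            (("cross_apen", 1, 0.25), 5),
            (("cross_sampen", 2, 0.25), 5),
            (("cross_sampen", 1, 0.10), 5),
            (("cross_sampen", 1, 0.25), 5),
            (("cross_sampen", 1, 0.25), 7),
        ]
        ranked = sorted(items, key=_tie_break_key)
        assert ranked[0] == (("cross_sampen", 1, 0.25), 7)  # count dominates
        assert ranked[1] == (("cross_sampen", 1, 0.25), 5)
        assert ranked[2] == (("cross_sampen", 1, 0.10), 5)
        assert ranked[3] == (("cross_sampen", 2, 0.25), 5)
        assert ranked[4] == (("cross_apen", 1, 0.25), 5)
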
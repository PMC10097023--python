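import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longicore.coexpression_network import (
    GREY,
    NetworkConfig,
    adjacency,
    connectivity,
    detect_modules,
    mad_filter,
    merge_modules,
    module_eigengene,
    module_trait,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
    transform_counts,
)


def _frame(x, prefix="v"):
    return pd.DataFrame(
        np.asarray(x, dtype=float),
        columns=[f"{prefix}{i}" for i in range(np.shape(x)[1])],
    )


class TestMadFilter:
    def test_constant_column_dropped(self):
        m = _frame(np.column_stack([np.ones(10), np.arange(10)]))
        kept = mad_filter(m, 0.5)
        assert list(kept.columns) == ["v1"]

    def test_keep_fraction_one_is_identity(self, rng):
        m = _frame(rng.standard_normal((8, 6)))
        pd.testing.assert_frame_equal(mad_filter(m, 1.0), m)

    def test_matches_brute_force_ranking(self, rng):
        m = _frame(rng.standard_normal((12, 10)))
        kept = mad_filter(m, 0.5)
        # independent oracle: explicit MAD + stable sort
        mads = {
            c: np.median(np.abs(m[c] - np.median(m[c]))) for c in m.columns
        }
        order = sorted(m.columns, key=lambda c: (-mads[c], list(m.columns).index(c)))
        assert set(kept.columns) == set(order[:5])

    def test_tie_break_by_column_order(self):
        # two identical columns: the earlier one wins the boundary slot
        col = np.arange(6.0)
        m = _frame(np.column_stack([col, col, np.zeros(6)]))
        kept = mad_filter(m, 1 / 3)
        assert list(kept.columns) == ["v0"]


class TestScaleFreeFit:
    def test_perfect_power_law_fits_one(self):
        # freq proportional to k^-2 exactly: k values 10..80 land in separate
        # equal-width bins and counts C/(b+1)^2 are integers for C = 705600
        counts = [705600 // (b + 1) ** 2 for b in range(8)]
        k = np.concatenate([np.full(c, 10.0 * (b + 1))
                            for b, c in enumerate(counts)])
        r2 = scale_free_fit(k, n_bins=8)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_increasing_relationship_is_negative(self):
        counts = [(b + 1) ** 2 * 100 for b in range(8)]
        k = np.concatenate([np.full(c, 10.0 * (b + 1))
                            for b, c in enumerate(counts)])
        assert scale_free_fit(k, n_bins=8) < 0

    def test_matches_regression_oracle(self, rng):
        k = rng.gamma(2.0, 3.0, size=300)
        n_bins = 10
        r2 = scale_free_fit(k, n_bins=n_bins)
        # independent re-derivation with numpy.polyfit
        kk = k[k > 0]
        edges = np.linspace(kk.min(), kk.max(), n_bins + 1)
        which = np.clip(np.digitize(kk, edges[1:-1]), 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum():
                xs.append(np.log10(kk[sel].mean()))
                ys.append(np.log10(sel.sum() / kk.size))
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = np.array(ys) - (slope * np.array(xs) + intercept)
        ss_tot = ((np.array(ys) - np.mean(ys)) ** 2).sum()
        expected = -np.sign(slope) * (1 - (resid**2).sum() / ss_tot)
        assert r2 == pytest.approx(expected, abs=1e-10)

    def test_constant_connectivity_rejected(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.full(30, 2.0))


class TestAdjacency:
    def test_perfect_pair_is_one(self, rng):
        x = rng.standard_normal(20)
        m = _frame(np.column_stack([x, 2 * x + 5, rng.standard_normal(20)]))
        a = adjacency(m, beta=6)
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_unsigned_hand_value(self):
        # engineer |cor| = 0.5 exactly: cor((1,0,-1,0),(0.5,1,-0.5,-1)) = 0.5
        m = _frame(np.array([[1, 0.5], [0, 1], [-1, -0.5], [0, -1.0]]))
        a = adjacency(m, beta=2)
        r = np.corrcoef(m.to_numpy(), rowvar=False)[0, 1]
        assert a.iloc[0, 1] == pytest.approx(abs(r) ** 2)

    def test_beta_one_is_abs_correlation(self, rng):
        m = _frame(rng.standard_normal((15, 5)))
        a = adjacency(m, beta=1).to_numpy()
        r = np.abs(np.corrcoef(m.to_numpy(), rowvar=False))
        np.testing.assert_allclose(a, r, atol=1e-12)

    def test_signed_mapping(self, rng):
        m = _frame(rng.standard_normal((15, 4)))
        a = adjacency(m, beta=2, network_type="signed").to_numpy()
        r = np.corrcoef(m.to_numpy(), rowvar=False)
        np.testing.assert_allclose(
            a[np.triu_indices(4, 1)],
            (((1 + r) / 2) ** 2)[np.triu_indices(4, 1)],
            atol=1e-12,
        )

    def test_zero_variance_column_named(self):
        m = _frame(np.column_stack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match="v0"):
            adjacency(m, beta=2)


class TestTom:
    def _brute(self, a):
        """Triple-loop oracle straight from the TOM definition."""
        p = a.shape[0]
        tom = np.eye(p)
        k = [sum(a[i, u] for u in range(p) if u != i) for i in range(p)]
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(p)
                        if u != i and u != j)
                tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
        return tom

    def test_single_edge_hand_value(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 1.0
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom[0, 1] == pytest.approx(1.0)
        assert tom[0, 2] == pytest.approx(0.0)

    def test_identity_adjacency_gives_zero_overlap(self):
        tom = tom_similarity(pd.DataFrame(np.eye(4))).to_numpy()
        off = tom[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 1, (6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(pd.DataFrame(a)).to_numpy()
            np.testing.assert_allclose(tom, self._brute(a), atol=1e-12)

    def test_bounds_and_symmetry(self, rng):
        a = rng.uniform(0, 1, (10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom.min() >= 0 and tom.max() <= 1
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_duplicated_columns_reach_one(self, rng):
        x = rng.standard_normal(30)
        m = _frame(np.column_stack([x, x, rng.standard_normal((30, 3))]))
        tom = tom_similarity(adjacency(m, 6)).to_numpy()
        assert tom[0, 1] == pytest.approx(1.0, abs=1e-5)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(pd.DataFrame(a))


class TestSoftThreshold:
    def test_rsq_target_zero_picks_first_power(self, rng):
        m = _frame(rng.standard_normal((20, 10)))
        cfg = NetworkConfig(rsq_target=0.0, power_grid=(2, 4, 6))
        report = pick_soft_threshold(m, cfg)
        assert report.chosen_power == 2

    def test_mean_connectivity_nonincreasing_unsigned(self, rng):
        m = _frame(rng.standard_normal((30, 20)))
        report = pick_soft_threshold(m, NetworkConfig(rsq_target=0.99))
        k = report.table["mean_connectivity"].to_numpy()
        assert (np.diff(k) <= 1e-12).all()

    def test_cohort_reaches_target_at_smallest_power(self, small_cohort):
        # planted blocks in a sparse background give the heavy-tailed
        # connectivity a scale-free fit rewards
        table, _, _ = small_cohort
        m = transform_counts(table.counts, "log1p_relative")
        m = mad_filter(m, 0.5)
        m = m.loc[:, m.std(axis=0) > 0]
        report = pick_soft_threshold(m, NetworkConfig(rsq_target=0.8))
        row = report.table[report.table["power"] == report.chosen_power]
        assert row["signed_r2"].iloc[0] >= 0.8
        # the choice rule: smallest grid power reaching the target
        reaching = report.table[report.table["signed_r2"] >= 0.8]
        assert report.chosen_power == reaching["power"].iloc[0]

    def test_argmax_fallback_when_target_unreachable(self, rng):
        m = _frame(rng.standard_normal((40, 30)))
        report = pick_soft_threshold(m, NetworkConfig(rsq_target=0.999))
        best = report.table.loc[report.table["signed_r2"].idxmax(), "power"]
        assert report.chosen_power == best


class TestModuleDetection:
    def _planted(self, rng, sizes=(30, 30), n_noise=60, load=0.95, n=100):
        cols, truth = {}, {}
        for b, size in enumerate(sizes):
            f = rng.standard_normal(n)
            for j in range(size):
                name = f"B{b}_{j}"
                cols[name] = load * f + np.sqrt(1 - load**2) * rng.standard_normal(n)
                truth[name] = b
        for j in range(n_noise):
            cols[f"N{j}"] = rng.standard_normal(n)
            truth[f"N{j}"] = -1
        return pd.DataFrame(cols), truth

    def test_two_planted_blocks_recovered(self, rng):
        m, truth = self._planted(rng)
        diss = 1 - tom_similarity(adjacency(m, 6))
        part = detect_modules(m, diss)
        non_grey = [c for c in part.labels.unique() if c != GREY]
        assert len(non_grey) == 2
        # label purity vs ground truth
        for b in (0, 1):
            members = [o for o, t in truth.items() if t == b]
            top = part.labels.loc[members].value_counts()
            assert top.iloc[0] / len(members) >= 0.95
            assert top.index[0] != GREY

    def test_pure_noise_stays_grey(self):
        for seed in range(3):
            r = np.random.default_rng(seed)
            m = _frame(r.standard_normal((80, 120)))
            diss = 1 - tom_similarity(adjacency(m, 6))
            part = detect_modules(m, diss)
            assert (part.labels == GREY).mean() >= 0.9

    def test_otu_order_invariance(self, rng):
        m, _ = self._planted(rng, sizes=(28, 26), n_noise=30)
        diss = 1 - tom_similarity(adjacency(m, 6))
        part1 = detect_modules(m, diss)
        perm = rng.permutation(m.shape[1])
        mp = m.iloc[:, perm]
        dissp = 1 - tom_similarity(adjacency(mp, 6))
        part2 = detect_modules(mp, dissp)
        # identical partition up to relabeling
        joined = pd.DataFrame({"a": part1.labels, "b": part2.labels})
        grouping_a = joined.groupby("a")["b"].nunique()
        grouping_b = joined.groupby("b")["a"].nunique()
        assert (grouping_a == 1).all() and (grouping_b == 1).all()

    def test_tiny_input_all_grey_with_warning(self, rng):
        m = _frame(rng.standard_normal((10, 5)))
        diss = 1 - tom_similarity(adjacency(m, 2))
        with pytest.warns(UserWarning, match="grey"):
            part = detect_modules(m, diss)
        assert (part.labels == GREY).all()


class TestEigengene:
    def test_identical_profiles(self, rng):
        x = rng.standard_normal(25)
        m = _frame(np.column_stack([x, x, x]))
        eig, var = module_eigengene(m, m.columns)
        xs = (x - x.mean()) / x.std()
        np.testing.assert_allclose(eig.to_numpy(), xs, atol=1e-10)
        assert var == pytest.approx(1.0)

    def test_anticorrelated_pair(self, rng):
        x = rng.standard_normal(25)
        m = _frame(np.column_stack([x, -x]))
        eig, var = module_eigengene(m, m.columns)
        assert var == pytest.approx(1.0)
        # orientation falls back to positive correlation with first member
        assert np.corrcoef(eig, m["v0"])[0, 1] > 0

    def test_variance_explained_matches_eigen_oracle(self, rng):
        m = _frame(rng.standard_normal((40, 6)))
        _, var = module_eigengene(m, m.columns)
        xs = (m - m.mean()) / m.std(ddof=0)
        lam = np.sort(np.linalg.eigvalsh(np.cov(xs.to_numpy(), rowvar=False,
                                                ddof=0)))[::-1]
        assert var == pytest.approx(lam[0] / lam.sum(), abs=1e-10)

    def test_unit_variance(self, rng):
        m = _frame(rng.standard_normal((30, 5)))
        eig, _ = module_eigengene(m, m.columns)
        assert np.std(eig.to_numpy()) == pytest.approx(1.0)

    def test_single_member_rejected(self, rng):
        m = _frame(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError, match="2 members"):
            module_eigengene(m, ["v0"])


class TestMerge:
    def _partition(self, m, labels):
        from longicore.coexpression_network import _partition_from_labels

        return _partition_from_labels(m, pd.Series(labels, index=m.columns))

    def test_duplicate_modules_merge(self, rng):
        f = rng.standard_normal(50)
        cols = [0.95 * f + 0.3 * rng.standard_normal(50) for _ in range(8)]
        m = _frame(np.column_stack(cols))
        part = self._partition(m, ["blue"] * 4 + ["red"] * 4)
        merged = merge_modules(part, m, merge_cut=0.25)
        assert len(merged.module_names) == 1

    def test_orthogonal_modules_stay_separate(self, rng):
        f1, f2 = rng.standard_normal(60), rng.standard_normal(60)
        cols = [0.95 * f1 + 0.2 * rng.standard_normal(60) for _ in range(4)]
        cols += [0.95 * f2 + 0.2 * rng.standard_normal(60) for _ in range(4)]
        m = _frame(np.column_stack(cols))
        part = self._partition(m, ["blue"] * 4 + ["red"] * 4)
        merged = merge_modules(part, m, merge_cut=0.25)
        assert len(merged.module_names) == 2


class TestModuleTrait:
    def _setup(self, rng, n=60):
        f = rng.standard_normal(n)
        cols = [0.9 * f + 0.4 * rng.standard_normal(n) for _ in range(6)]
        cols += [rng.standard_normal(n) for _ in range(6)]
        m = _frame(np.column_stack(cols))
        from longicore.coexpression_network import _partition_from_labels

        part = _partition_from_labels(
            m, pd.Series(["blue"] * 6 + [GREY] * 6, index=m.columns)
        )
        return m, part, f

    def test_trait_equal_to_eigengene(self, rng):
        m, part, _ = self._setup(rng)
        traits = pd.DataFrame({"t": part.eigengenes["blue"]}, index=m.index)
        res = module_trait(m, part, traits)
        row = res.module_trait.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-30

    def test_matches_pearsonr_oracle(self, rng):
        m, part, _ = self._setup(rng)
        traits = pd.DataFrame({"t": rng.standard_normal(60)}, index=m.index)
        res = module_trait(m, part, traits)
        r_o, p_o = stats.pearsonr(part.eigengenes["blue"], traits["t"])
        row = res.module_trait.iloc[0]
        assert row["r"] == pytest.approx(r_o, abs=1e-10)
        assert row["p"] == pytest.approx(p_o, rel=1e-6)
        # GS matches per-OTU pearson correlations
        for otu in ["v0", "v7"]:
            r_gs, _ = stats.pearsonr(m[otu], traits["t"])
            assert res.gs.loc[otu, "t"] == pytest.approx(r_gs, abs=1e-10)

    def test_trait_sign_flip_negates_r(self, rng):
        m, part, _ = self._setup(rng)
        t = (rng.standard_normal(60) > 0).astype(float)
        res1 = module_trait(m, part, pd.DataFrame({"t": t}, index=m.index))
        res2 = module_trait(m, part, pd.DataFrame({"t": 1 - t}, index=m.index))
        assert res1.module_trait["r"].iloc[0] == pytest.approx(
            -res2.module_trait["r"].iloc[0], abs=1e-12
        )
        assert res1.module_trait["p"].iloc[0] == pytest.approx(
            res2.module_trait["p"].iloc[0], abs=1e-12
        )

    def test_constant_trait_rejected(self, rng):
        m, part, _ = self._setup(rng)
        traits = pd.DataFrame({"t": np.ones(60)}, index=m.index)
        with pytest.raises(ValueError, match="constant"):
            module_trait(m, part, traits)


def test_transform_counts_modes(small_cohort):
    table, _, _ = small_cohort
    for mode in ("log1p_relative", "hellinger", "none"):
        out = transform_counts(table.counts, mode)
        assert out.shape == table.counts.shape
    with pytest.raises(ValueError, match="unknown transform"):
        transform_counts(table.counts, "clr")


def test_connectivity_excludes_self(rng):
    m = _frame(rng.standard_normal((20, 5)))
    a = adjacency(m, 2)
    k = connectivity(a)
    np.testing.assert_allclose(
        k.to_numpy(), a.to_numpy().sum(0) - 1.0, atol=1e-12
    )
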
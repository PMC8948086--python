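import numpy as np
import pytest
from scipy.stats import ks_2samp

from kerneldeef import (
    DonorProfile,
    ddg_scan,
    per_gene_theta,
    permutation_null,
    wilks_lambda,
)
from kerneldeef.ddg import _gram_1d
from kerneldeef.synthetic import simulate_scrnaseq_cohort


def sscp_oracle(X, y):
    """From-scratch SSCP determinant ratio — kept deliberately naive."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    grand = X.mean(axis=0)
    E = np.zeros((X.shape[1], X.shape[1]))
    H = np.zeros_like(E)
    for g in np.unique(y):
        Xg = X[y == g]
        mu = Xg.mean(axis=0)
        E += (Xg - mu).T @ (Xg - mu)
        d = (mu - grand)[:, None]
        H += len(Xg) * d @ d.T
    return np.linalg.det(E) / np.linalg.det(E + H)


FIXTURE_X = np.array(
    [
        [0.1, 1.2],
        [-0.4, 0.8],
        [0.3, 1.5],
        [-0.2, 0.9],
        [2.1, -0.6],
        [1.8, -1.1],
        [2.4, -0.3],
        [1.6, -0.9],
    ]
)
FIXTURE_Y = np.array(["ctl"] * 4 + ["case"] * 4)


class TestWilksLambda:
    def test_fixture_matches_sscp_oracle(self):
        got = wilks_lambda(FIXTURE_X, FIXTURE_Y)
        assert got == pytest.approx(sscp_oracle(FIXTURE_X, FIXTURE_Y), abs=1e-12)

    def test_fixture_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        dummy = (FIXTURE_Y == "case").astype(float)
        exog = np.column_stack([np.ones(len(FIXTURE_Y)), dummy])
        mv = MANOVA(FIXTURE_X, exog)
        res = mv.mv_test(hypotheses=[("group", np.array([[0.0, 1.0]]), None)])
        expected = float(res.results["group"]["stat"].loc["Wilks' lambda", "Value"])
        assert wilks_lambda(FIXTURE_X, FIXTURE_Y) == pytest.approx(expected, abs=1e-8)

    def test_equal_group_means_lambda_one(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=(4, 2))
        X = np.vstack([half, half])  # both groups have identical points
        y = np.array(["a"] * 4 + ["b"] * 4)
        assert wilks_lambda(X, y) == pytest.approx(1.0, abs=1e-12)

    def test_zero_within_scatter_lambda_zero(self):
        X = np.array([[0.0, 0.0]] * 3 + [[1.0, 2.0]] * 3)
        y = np.array(["a"] * 3 + ["b"] * 3)
        assert wilks_lambda(X, y) == pytest.approx(0.0, abs=1e-12)

    def test_range(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X = rng.normal(size=(10, 2))
            y = rng.permutation(["a"] * 5 + ["b"] * 5)
            lam = wilks_lambda(X, y)
            assert 0 < lam <= 1

    def test_degenerate_scatter_is_nan(self):
        X = np.zeros((6, 2))
        y = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(wilks_lambda(X, y))

    def test_invariances(self):
        lam0 = wilks_lambda(FIXTURE_X, FIXTURE_Y)
        # group relabeling
        swapped = np.where(FIXTURE_Y == "ctl", "case", "ctl")
        assert wilks_lambda(FIXTURE_X, swapped) == pytest.approx(lam0, abs=1e-12)
        # common rotation + translation
        ang = 0.73
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = FIXTURE_X @ R.T + np.array([5.0, -2.0])
        assert wilks_lambda(moved, FIXTURE_Y) == pytest.approx(lam0, abs=1e-10)
        # common positive scaling
        assert wilks_lambda(FIXTURE_X * 3.7, FIXTURE_Y) == pytest.approx(lam0, abs=1e-10)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="two groups"):
            wilks_lambda(FIXTURE_X, np.array(["a"] * 8))
        with pytest.raises(ValueError, match="at least two donors"):
            wilks_lambda(FIXTURE_X, np.array(["a"] * 7 + ["b"]))
        with pytest.raises(ValueError, match="at least 4"):
            wilks_lambda(FIXTURE_X[:3], np.array(["a", "a", "b"]))


class TestPermutationNull:
    def test_deterministic(self):
        a = permutation_null(FIXTURE_X, FIXTURE_Y, seed=5)
        b = permutation_null(FIXTURE_X, FIXTURE_Y, seed=5)
        assert a == b

    def test_is_a_wilks_value_of_permuted_labels(self):
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(FIXTURE_Y))
        # same generator construction as the implementation
        expected = wilks_lambda(FIXTURE_X, FIXTURE_Y[np.random.default_rng(3).permutation(8)])
        assert permutation_null(FIXTURE_X, FIXTURE_Y, seed=3) == pytest.approx(expected)

    def test_null_agrees_without_signal(self):
        # many no-signal "genes": observed and null lambda distributions agree
        rng = np.random.default_rng(4)
        obs, null = [], []
        y = np.array(["a"] * 6 + ["b"] * 6)
        for g in range(300):
            X = rng.normal(size=(12, 2))
            obs.append(wilks_lambda(X, y))
            null.append(permutation_null(X, y, seed=g))
        assert ks_2samp(obs, null).pvalue > 0.01


def make_gene_cohort(shift=0.0, n_donors=4, n_cells=120, seed=0):
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    for grp, mu in (("ctl", 0.0), ("case", shift)):
        for d in range(n_donors):
            x = rng.normal(mu, 1.0, size=(n_cells, 2))
            profiles.append(
                DonorProfile(
                    donor_id=f"{grp}{d}",
                    expression=x,
                    feature_names=["geneA", "geneB"],
                    group_label=grp,
                )
            )
            labels.append(grp)
    return profiles, labels


class TestPerGeneTheta:
    def test_shape(self):
        profiles, _ = make_gene_cohort()
        theta = per_gene_theta(profiles, "geneA", n=60, seed=1)
        assert theta.shape == (len(profiles), 2)

    def test_groups_separate_on_shifted_gene(self):
        profiles, labels = make_gene_cohort(shift=3.0, n_donors=6, n_cells=300, seed=2)
        theta = per_gene_theta(profiles, "geneA", n=250, seed=3)
        y = np.asarray(labels)
        t1 = theta[:, 0]
        gap = abs(t1[y == "ctl"].mean() - t1[y == "case"].mean())
        spread = max(t1[y == "ctl"].std(), t1[y == "case"].std())
        assert gap > 3 * spread

    def test_identical_distribution_near_constant_gram(self):
        profiles, _ = make_gene_cohort(shift=0.0, n_cells=400, seed=5)
        samples = np.stack(
            [p.expression[:400, 0] for p in profiles]
        )
        G = _gram_1d(samples, gamma=1.0)
        assert np.ptp(G) < 0.05  # all donors nearly interchangeable

    def test_missing_gene(self):
        profiles, _ = make_gene_cohort()
        with pytest.raises(KeyError, match="geneZ"):
            per_gene_theta(profiles, "geneZ", n=50, seed=0)


class TestGram1d:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(3, 7))
        G = _gram_1d(values, gamma=0.8)
        for i in range(3):
            for j in range(3):
                expected = np.mean(
                    [
                        np.exp(-0.8 * (a - b) ** 2)
                        for a in values[i]
                        for b in values[j]
                    ]
                )
                assert G[i, j] == pytest.approx(expected, abs=1e-12)


@pytest.fixture(scope="module")
def signal_scan():
    profiles, labels, truth = simulate_scrnaseq_cohort(
        n_donors_per_group=5,
        n_cells=120,
        n_genes=60,
        n_signal_genes=12,
        effect="mean_shift",
        effect_size=2.5,
        seed=9,
    )
    result = ddg_scan(profiles, labels, n=100, master_seed=1)
    return result, truth


class TestDdgScan:
    def test_table_contract(self, signal_scan):
        result, _ = signal_scan
        t = result.table
        assert list(t.columns) == ["gene", "lambda", "null_lambda", "rank"]
        assert t["lambda"].is_monotonic_increasing
        assert list(t["rank"]) == list(range(1, len(t) + 1))
        assert len(result.qq) == len(t)

    def test_signal_genes_rank_low(self, signal_scan):
        result, truth = signal_scan
        signal = set(truth.loc[truth.is_signal, "gene"])
        top = set(result.table.head(12)["gene"])
        assert len(top & signal) >= 8

    def test_extreme_thetas_exported(self, signal_scan):
        result, _ = signal_scan
        assert len(result.extreme_thetas) >= 1
        frame = next(iter(result.extreme_thetas.values()))
        assert list(frame.columns) == ["theta1", "theta2"]

    def test_deterministic(self):
        profiles, labels, _ = simulate_scrnaseq_cohort(
            n_donors_per_group=3, n_cells=60, n_genes=10, n_signal_genes=0, seed=2
        )
        a = ddg_scan(profiles, labels, n=50, master_seed=4)
        b = ddg_scan(profiles, labels, n=50, master_seed=4)
        assert a.table.equals(b.table)

    def test_degenerate_gene_collected(self):
        profiles, labels, _ = simulate_scrnaseq_cohort(
            n_donors_per_group=3, n_cells=60, n_genes=8, n_signal_genes=0, seed=3
        )
        for p in profiles:  # make one gene identically zero everywhere
            p.expression[:, 0] = 0.0
        result = ddg_scan(profiles, labels, n=50, master_seed=5)
        assert profiles[0].feature_names[0] in result.degenerate_genes
        assert profiles[0].feature_names[0] not in set(result.table["gene"])
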
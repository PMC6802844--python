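import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mvgwas as mg
from mvgwas.bayesfactors import EstimationError, _log10_bf_batch

from conftest import log10_bf_quadrature, make_correlation


def random_instance(rng, d):
    """Random (z, R, codes, sigma, n) with at least one direct phenotype."""
    a = rng.standard_normal((d, d + 2))
    r = a @ a.T
    dinv = 1 / np.sqrt(np.diag(r))
    r = r * np.outer(dinv, dinv)
    np.fill_diagonal(r, 1.0)
    while True:
        codes = rng.integers(0, 3, size=d)
        if (codes == 1).any():
            break
    z = rng.standard_normal(d) * 2.0
    sigma = rng.uniform(0.02, 0.4)
    n = rng.uniform(5e3, 5e4, size=d)
    return z, r, codes, sigma, n


class TestClosedForm:
    def test_null_model_is_exactly_zero(self, rng):
        z = rng.standard_normal(3) * 3
        assert mg.log10_bf_model(z, [1e4] * 3, make_correlation(3),
                                 mg.ModelPartition((0, 0, 0)), 0.1) == 0.0

    def test_indirect_only_model_is_null_equivalent(self, rng):
        # no direct phenotype: the genotype has no path into the data
        z = rng.standard_normal(2) * 3
        assert mg.log10_bf_model(z, [1e4] * 2, make_correlation(2),
                                 mg.ModelPartition((0, 2)), 0.1) == 0.0

    def test_zero_z_disfavours_any_alternative(self):
        for codes in [(1,), (1, 0), (1, 1), (1, 2)]:
            d = len(codes)
            bf = mg.log10_bf_model(np.zeros(d), [1e4] * d, make_correlation(d),
                                   mg.ModelPartition(codes), 0.1)
            assert bf < 0

    def test_d1_conjugate_closed_form(self):
        z, n, sigma = 3.0, 10_000.0, 0.02
        got = mg.log10_bf_model([z], [n], np.eye(1), mg.ModelPartition((1,)), sigma)
        expected = (stats.norm.logpdf(z, scale=np.sqrt(1 + n * sigma**2))
                    - stats.norm.logpdf(z)) / np.log(10)
        assert got == pytest.approx(expected, abs=1e-12)
        oracle = log10_bf_quadrature(np.array([z]), np.array([n]), np.eye(1),
                                     np.array([1]), sigma)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_indirect_coordinates_do_not_change_bf(self, rng):
        r = make_correlation(3, 0.4)
        model = mg.ModelPartition((1, 0, 2))
        n = np.array([2e4, 3e4, 4e4])
        z = np.array([3.0, 1.0, 2.0])
        base = mg.log10_bf_model(z, n, r, model, 0.1)
        for zi in (-5.0, 0.0, 4.2):
            z2 = z.copy()
            z2[2] = zi
            assert mg.log10_bf_model(z2, n, r, model, 0.1) == pytest.approx(base, abs=1e-12)

    def test_permutation_invariance(self, rng):
        d = 3
        z, r, codes, sigma, n = random_instance(rng, d)
        base = mg.log10_bf_model(z, n, r, mg.ModelPartition(tuple(codes)), sigma)
        for perm in itertools.permutations(range(d)):
            p = np.array(perm)
            got = mg.log10_bf_model(z[p], n[p], r[np.ix_(p, p)],
                                    mg.ModelPartition(tuple(codes[p])), sigma)
            assert got == pytest.approx(base, abs=1e-9)

    def test_monotone_in_abs_z_for_d1_direct(self):
        model = mg.ModelPartition((1,))
        vals = [mg.log10_bf_model([z], [1e4], np.eye(1), model, 0.05)
                for z in np.linspace(0, 6, 25)]
        assert np.all(np.diff(vals) > 0)

    def test_matches_quadrature_oracle_sample(self, rng):
        # the full 50-instance sweep runs in the acceptance suite
        for d in (1, 2, 3):
            for _ in range(4):
                z, r, codes, sigma, n = random_instance(rng, d)
                got = mg.log10_bf_model(z, n, r, mg.ModelPartition(tuple(codes)), sigma)
                oracle = log10_bf_quadrature(z, n, r, codes, sigma)
                assert got == pytest.approx(oracle, abs=1e-4)

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            mg.log10_bf_model([1.0, 2.0], [1e4] * 2, np.eye(3),
                              mg.ModelPartition((1, 0, 0)), 0.1)
        with pytest.raises(ValueError):
            mg.log10_bf_model([1.0], [1e4], np.eye(1), mg.ModelPartition((1,)), -0.1)


class TestNullCorrelation:
    def test_recovers_independence(self, rng):
        z = rng.standard_normal((10_000, 3))
        panel = _panel_from_z(z)
        est = mg.estimate_null_correlation(panel, zmax=2.0)
        off = est.matrix[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05
        assert est.n_null_snps > 8000

    def test_duplicated_phenotype_gives_unit_correlation_then_conditioned(self, rng):
        z1 = rng.standard_normal(5000)
        panel = _panel_from_z(np.column_stack([z1, z1]))
        est = mg.estimate_null_correlation(panel, zmax=np.inf)
        assert est.conditioned
        assert est.matrix[0, 1] == pytest.approx(1.0, abs=1e-3)
        assert np.linalg.eigvalsh(est.matrix).min() > 0

    def test_degenerate_threshold_raises(self, rng):
        panel = _panel_from_z(rng.standard_normal((100, 2)))
        with pytest.raises(EstimationError, match="zmax"):
            mg.estimate_null_correlation(panel, zmax=0.0)


def _panel_from_z(z, n=10_000.0):
    m, d = z.shape
    cols = {
        "snp_id": [f"rs{i}" for i in range(m)],
        "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1) * 1000,
        "allele_ref": ["A"] * m,
        "allele_alt": ["G"] * m,
        "maf": np.full(m, 0.25),
        "strand_ambiguous": [False] * m,
    }
    for j in range(d):
        cols[f"z_pheno{j + 1}"] = z[:, j]
        cols[f"n_pheno{j + 1}"] = np.full(m, n)
        cols[f"p_pheno{j + 1}"] = 2 * stats.norm.sf(np.abs(z[:, j]))
    return mg.MergedPanel(phenotypes=[f"pheno{j + 1}" for j in range(d)], df=pd.DataFrame(cols))


class TestBFTable:
    def test_shape_and_elementwise_agreement(self, rng):
        z = rng.standard_normal((5, 2)) * 2
        panel = _panel_from_z(z)
        r = mg.NullCorrelation(matrix=make_correlation(2), n_null_snps=1000)
        space = mg.enumerate_models(2)
        grid = mg.PriorGrid((0.05, 0.1, 0.2))
        table = mg.log10_bf_table(panel, r, space, grid)
        assert table.logbf.shape == (5, 9, 3)
        np.testing.assert_array_equal(table.logbf[:, 0, :], 0.0)
        i, j, k = 3, 5, 1
        direct = mg.log10_bf_model(z[i], panel.n[i], r, space.models[j], grid.sigmas[k])
        assert table.logbf[i, j, k] == pytest.approx(direct, abs=1e-12)

    def test_all_null_panel_has_negative_median_bfav(self, rng):
        z = rng.standard_normal((3000, 2))
        panel = _panel_from_z(z, n=50_000.0)
        r = mg.NullCorrelation(matrix=np.eye(2), n_null_snps=3000)
        space = mg.enumerate_models(2)
        table = mg.log10_bf_table(panel, r, space, mg.PriorGrid())
        w = mg.ModelWeights.uniform(space, table.grid.sigmas)
        bfav = mg.log10_bf_av(table, w)
        assert np.median(bfav) < 0

    def test_nonfinite_snp_recorded_not_fatal(self, rng):
        z = rng.standard_normal((3, 2))
        z[1, 0] = np.nan
        panel = _panel_from_z(z)
        r = mg.NullCorrelation(matrix=np.eye(2), n_null_snps=100)
        table = mg.log10_bf_table(panel, r, mg.enumerate_models(2), mg.PriorGrid())
        assert len(table.errors) == 1 and table.errors[0]["snp_id"] == "rs1"
        assert np.isfinite(table.logbf[[0, 2]]).all()


class TestBFAverage:
    def _table(self, logbf, d=1, sigmas=(0.1,)):
        space = mg.enumerate_models(d)
        return mg.BFTable(snp_ids=np.array([f"rs{i}" for i in range(logbf.shape[0])]),
                          space=space, grid=mg.PriorGrid(sigmas), logbf=logbf)

    def test_degenerate_weight_recovers_single_bf(self):
        logbf = np.zeros((1, 3, 1))
        logbf[0, 1, 0] = 2.5
        logbf[0, 2, 0] = 0.0
        w = np.zeros((3, 1))
        w[1, 0] = 1.0
        assert mg.log10_bf_av(self._table(logbf), w)[0] == pytest.approx(2.5, abs=1e-12)

    def test_two_model_average_arithmetic(self):
        # BFs 10^2 and 10^4, equal weights: log10((100 + 10000) / 2)
        logbf = np.zeros((1, 3, 1))
        logbf[0, 1, 0] = 2.0
        logbf[0, 2, 0] = 4.0
        w = np.full((3, 1), 0.5)
        w[0, 0] = 0.0
        got = mg.log10_bf_av(self._table(logbf), w)[0]
        assert got == pytest.approx(np.log10(5050.0), abs=1e-12)

    def test_unit_bfs_average_to_unit(self):
        logbf = np.zeros((4, 3, 2))
        w = np.full((3, 2), 0.25)
        w[0, :] = 0.0
        np.testing.assert_allclose(mg.log10_bf_av(self._table(logbf, sigmas=(0.1, 0.2)), w),
                                   0.0, atol=1e-12)

    def test_negative_weight_rejected(self):
        logbf = np.zeros((1, 3, 1))
        w = np.array([[0.0], [1.5], [-0.5]])
        with pytest.raises(ValueError):
            mg.log10_bf_av(self._table(logbf), w)
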
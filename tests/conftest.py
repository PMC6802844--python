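"""Shared fixtures and independent numerical oracles.

The oracles deliberately take a different computational route from the
package: the Bayes factor oracle integrates the full d-dimensional
generative model over the direct-effect prior by Gauss-Hermite quadrature
(the package evaluates a closed-form conditional density ratio), and the
pruning oracle simulates the removal rule SNP by SNP in pure Python.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import multivariate_normal

import mvgwas as mg


# ---------------------------------------------------------------------------
# Bayes factor oracle: full-joint numerical integration
# ---------------------------------------------------------------------------

def dag_mean(codes, b, n, r):
    """Marginal Z-score mean implied by direct effects under the DAG.

    Unassociated phenotypes have mean 0, direct ones sqrt(n)*b, indirect
    ones the regression of their scores on the (U, D) scores applied to
    that mean (they see the genotype only through the direct phenotypes).
    """
    codes = np.asarray(codes)
    d = len(codes)
    mu = np.zeros(d)
    d_idx = np.flatnonzero(codes == 1)
    if len(d_idx) == 0:
        return mu
    mu[d_idx] = np.sqrt(np.asarray(n, float)[d_idx]) * np.asarray(b, float)
    i_idx = np.flatnonzero(codes == 2)
    if len(i_idx):
        ud = np.flatnonzero(codes != 2)
        w = np.linalg.solve(r[np.ix_(ud, ud)], r[np.ix_(ud, i_idx)])
        mu[i_idx] = w.T @ mu[ud]
    return mu


def log10_bf_quadrature(z, n, r, codes, sigma, nodes=40):
    """log10 BF by adaptive Gauss-Hermite integration over the effect prior.

    BF = [integral N(z; mu(b), R) prod_j N(b_j; 0, sigma^2) db] / N(z; 0, R)
    with mu(b) built from the DAG semantics. The integrand can be far
    narrower than the prior (large sqrt(n)*sigma), so the quadrature is
    centered and scaled at the numerically located mode of the integrand
    (mode by BFGS, curvature by central finite differences), then corrected
    by Gauss-Hermite weights.
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp
    from scipy.stats import norm

    z = np.asarray(z, float)
    r = np.asarray(r, float)
    codes = np.asarray(codes)
    d_idx = np.flatnonzero(codes == 1)
    k = len(d_idx)
    if k == 0:
        return 0.0
    # mu(b) is linear in b; build the map column by column from unit effects
    eye = np.eye(k)
    mmap = np.stack([dag_mean(codes, eye[j], n, r) for j in range(k)], axis=1)
    mvn = multivariate_normal(mean=np.zeros(len(z)), cov=r)

    def log_integrand(b):
        b = np.atleast_2d(b)
        return mvn.logpdf(z[None, :] - b @ mmap.T) + norm.logpdf(b, scale=sigma).sum(axis=-1)

    neg = lambda b: -float(np.asarray(log_integrand(b)).ravel()[0])
    mode = minimize(neg, np.zeros(k), method="BFGS").x
    # numerical Hessian of -log integrand at the mode
    h = 1e-5 * max(sigma, np.abs(mode).max() + sigma)
    hess = np.empty((k, k))
    for a in range(k):
        for bidx in range(k):
            ea, eb = eye[a] * h, eye[bidx] * h
            hess[a, bidx] = (
                neg(mode + ea + eb) - neg(mode + ea - eb)
                - neg(mode - ea + eb) + neg(mode - ea - eb)
            ) / (4 * h * h)
    cov = np.linalg.inv(0.5 * (hess + hess.T))
    chol = np.linalg.cholesky(cov)

    x, w = hermegauss(nodes)
    logw1 = np.log(w) - 0.5 * np.log(2.0 * np.pi)
    grids = np.meshgrid(*([x] * k), indexing="ij")
    xs = np.stack([g.ravel() for g in grids], axis=1)          # (K, k) std nodes
    lw = sum(np.meshgrid(*([logw1] * k), indexing="ij")[j].ravel() for j in range(k))
    pts = mode[None, :] + xs @ chol.T
    # integral h(b) db = sum W_k h(b_k) / phi(b_k; mode, cov)
    log_phi = (-0.5 * (xs**2).sum(axis=1)
               - 0.5 * np.linalg.slogdet(2 * np.pi * cov)[1])
    log_alt = logsumexp(lw + log_integrand(pts) - log_phi)
    return (log_alt - mvn.logpdf(z)) / np.log(10.0)


# ---------------------------------------------------------------------------
# Pruning oracle: literal simulation of the removal rule
# ---------------------------------------------------------------------------

def prune_bruteforce(rows, window):
    """Survivors of 'remove any SNP with a better survivor within window'.

    ``rows`` is a list of (chrom, pos, score) tuples. Repeatedly promotes
    the best remaining candidate (highest score; ties to the smaller
    position) to survivor and discards every remaining candidate within the
    window of it on the same chromosome.
    """
    remaining = list(rows)
    survivors = []
    while remaining:
        best = min(remaining, key=lambda t: (-t[2], t[1], str(t[0])))
        survivors.append(best)
        remaining = [
            t
            for t in remaining
            if t is not best and not (str(t[0]) == str(best[0]) and abs(t[1] - best[1]) <= window)
        ]
    return sorted(survivors, key=lambda t: (str(t[0]), t[1]))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_correlation(d, off=0.3):
    r = np.full((d, d), off)
    np.fill_diagonal(r, 1.0)
    return r


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study with known truth, used across test modules."""
    cfg = mg.SimConfig(
        d=3,
        m=4000,
        r_true=make_correlation(3),
        n=np.full(3, 50_000.0),
        components=[
            mg.SimComponent((0, 0, 0), 0.1, 0.92),
            mg.SimComponent((1, 1, 1), 0.1, 0.05),
            mg.SimComponent((1, 0, 2), 0.2, 0.03),
        ],
        seed=11,
        swap_fraction=0.3,
    )
    tables, truth = mg.simulate_panel(cfg)
    summaries = mg.tables_to_summaries(tables)
    panel = mg.merge_phenotypes(summaries, orient_to="pheno1")
    panel, report = mg.apply_qc(panel, maf_min=0.01)
    return {"config": cfg, "tables": tables, "truth": truth, "panel": panel, "report": report}


@pytest.fixture(scope="session")
def small_fit(small_study):
    panel = small_study["panel"]
    truth = small_study["truth"]
    model = mg.MultiPhenotypeScan(panel)
    in_panel = set(panel.df["snp_id"])
    training = [s for s in truth.nonnull_ids() if s in in_panel][:150]
    return model.fit(training_snps=training)


def write_toy_table(path, rows, header="rsid chr bp a1 a2 maf beta se p n"):
    """Write a whitespace-delimited toy summary table."""
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write(" ".join(str(x) for x in row) + "\n")


TOY_DIALECT = {
    "snp_id": "rsid",
    "chrom": "chr",
    "pos": "bp",
    "allele_ref": "a1",
    "allele_alt": "a2",
    "maf": "maf",
    "effect": "beta",
    "se": "se",
    "pvalue": "p",
    "n": "n",
}
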
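"""Empirical Bayes model weights and per-SNP posteriors.

The weighted-average Bayes factor needs weights ``w_{γ,σ}`` expressing the
relative plausibility of each non-null model/prior-scale pair. They are
learned from a training set of SNPs (in practice, the previously reported
univariate associations) by EM on the mixture whose component "likelihoods"
are the Bayes factors themselves: because every BF is a likelihood ratio
against the same null, maximizing ``Σ_i log Σ_{γ,σ} w BF_i(γ,σ)`` over the
simplex is an ordinary mixture-weight problem.

Per-SNP posteriors over models follow as ``post(γ,σ) ∝ w_{γ,σ} BF_{γ,σ}``
(optionally with a null component), and per-phenotype marginal probabilities
of the Unassociated / Direct / Indirect categories are sums of model
posteriors over the models placing that phenotype in the category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .bayesfactors import LN10, BFTable
from .models import ModelSpace

logger = logging.getLogger(__name__)

#: A phenotype is "confidently associated" when P(D) + P(I) strictly exceeds
#: this, and "confidently unassociated" when P(D) + P(I) < 1 - it.
CONFIDENCE_LEVEL = 0.95


@dataclass
class ModelWeights:
    """Mixture weights over the non-null (model, prior-scale) pairs.

    ``w`` has shape (3^d, n_sigmas) with the null-model row fixed at zero
    and the remaining entries summing to one.
    """

    w: np.ndarray
    space: ModelSpace
    sigmas: tuple[float, ...]
    training_snp_count: int = 0
    em_iterations: int = 0
    converged: bool = True
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, float)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        self.w = w

    @classmethod
    def uniform(cls, space: ModelSpace, sigmas) -> "ModelWeights":
        """Uniform weights over all non-null (model, σ) pairs."""
        sigmas = tuple(float(s) for s in sigmas)
        w = np.ones((space.size, len(sigmas)))
        w[space.null_index, :] = 0.0
        return cls(w=w / w.sum(), space=space, sigmas=sigmas)

    def by_model(self) -> pd.Series:
        """σ-summed weight per model, indexed by code string."""
        return pd.Series(self.w.sum(axis=1), index=self.space.code_strings())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, lab in enumerate(self.space.code_strings()):
            for k, s in enumerate(self.sigmas):
                rows.append({"model": lab, "sigma": s, "weight": self.w[j, k]})
        return pd.DataFrame(rows)


def fit_weights_em(
    training_bfs: BFTable, tol: float = 1e-6, max_iter: int = 10_000
) -> ModelWeights:
    """Learn mixture weights over non-null (model, σ) pairs by EM.

    E-step responsibilities are ``r_i(γ,σ) ∝ w_{γ,σ} BF_i(γ,σ)`` (computed
    by log-sum-exp); the M-step sets each weight to the mean responsibility.
    Starts from uniform weights; stops when the largest relative weight
    change falls below ``tol`` or after ``max_iter`` iterations. The mixture
    log-likelihood is non-decreasing across iterations (an EM guarantee,
    recorded in ``objective_trace``).
    """
    m = training_bfs.n_snps
    if m == 0:
        raise ValueError("empty training set")
    space = training_bfs.space
    nonnull = np.ones(space.size, dtype=bool)
    nonnull[space.null_index] = False
    lnbf = training_bfs.logbf[:, nonnull, :].reshape(m, -1) * LN10
    if not np.isfinite(lnbf).all():
        bad = np.asarray(training_bfs.snp_ids)[~np.isfinite(lnbf).all(axis=1)]
        raise ValueError(f"non-finite Bayes factors in training set (e.g. SNP {bad[0]})")

    k = lnbf.shape[1]
    lnw = np.full(k, -np.log(k))
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        joint = lnw[None, :] + lnbf
        ll_snp = logsumexp(joint, axis=1)
        trace.append(float(ll_snp.sum()))
        resp = np.exp(joint - ll_snp[:, None])
        w_new = resp.mean(axis=0)
        w_new /= w_new.sum()
        w_old = np.exp(lnw)
        # denominator floored so components decaying toward zero (whose
        # relative change never shrinks) cannot stall convergence
        rel = np.abs(w_new - w_old) / np.maximum(w_old, 1e-6)
        with np.errstate(divide="ignore"):
            lnw = np.log(w_new)
        if rel.max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations (tol=%g)", max_iter, tol)

    w = np.zeros((space.size, len(training_bfs.grid.sigmas)))
    w[nonnull, :] = np.exp(lnw).reshape(space.size - 1, -1)
    w /= w.sum()
    return ModelWeights(
        w=w,
        space=space,
        sigmas=training_bfs.grid.sigmas,
        training_snp_count=m,
        em_iterations=it,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


@dataclass
class PosteriorSummary:
    """Per-SNP model posteriors and per-phenotype category marginals.

    ``posterior`` has shape (n_snps, 3^d, n_sigmas) (+ ``null_posterior``
    when a null component was included); rows sum to one. ``marginals``
    has shape (n_snps, d, 3) over the categories (U, D, I).
    """

    snp_ids: np.ndarray
    space: ModelSpace
    sigmas: tuple[float, ...]
    posterior: np.ndarray = field(repr=False)
    null_posterior: np.ndarray | None = field(default=None, repr=False)
    marginals: np.ndarray = field(default=None, repr=False)

    @property
    def model_posterior(self) -> np.ndarray:
        """(n_snps, 3^d) posterior per model, summed over σ."""
        post = self.posterior.sum(axis=2)
        if self.null_posterior is not None:
            post = post.copy()
            post[:, self.space.null_index] += self.null_posterior
        return post

    def top_models(self) -> pd.DataFrame:
        """Highest-posterior model per SNP (σ-summed), S7-style."""
        mp = self.model_posterior
        top = mp.argmax(axis=1)
        labels = self.space.code_strings()
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "top_model": [labels[j] for j in top],
                "posterior": mp[np.arange(len(top)), top],
            }
        )

    def marginals_frame(self, phenotypes: list[str]) -> pd.DataFrame:
        cols = {"snp_id": self.snp_ids}
        for pi, name in enumerate(phenotypes):
            cols[f"pU_{name}"] = self.marginals[:, pi, 0]
            cols[f"pD_{name}"] = self.marginals[:, pi, 1]
            cols[f"pI_{name}"] = self.marginals[:, pi, 2]
        return pd.DataFrame(cols)


def model_posteriors(
    bfs: BFTable,
    weights: ModelWeights,
    include_null: bool = False,
    null_prior: float = 0.0,
) -> PosteriorSummary:
    """Per-SNP posterior over (model, σ) pairs, ``∝ w BF``.

    With ``include_null`` the null model participates with prior mass
    ``null_prior`` (its BF is 1) and the alternative weights share the
    remaining ``1 - null_prior``.
    """
    if include_null and not (0.0 <= null_prior < 1.0):
        raise ValueError(f"null_prior must be in [0, 1), got {null_prior}")
    lnbf = bfs.logbf * LN10
    w = weights.w.copy()
    w[bfs.space.null_index, :] = 0.0
    with np.errstate(divide="ignore"):
        lnw = np.log(w)
    joint = lnbf + lnw[None, :, :]
    flat = joint.reshape(bfs.n_snps, -1)
    if include_null and null_prior > 0.0:
        flat = flat + np.log1p(-null_prior)
        lognull = np.full((bfs.n_snps, 1), np.log(null_prior))
        norm = logsumexp(np.concatenate([flat, lognull], axis=1), axis=1)
        null_post = np.exp(lognull[:, 0] - norm)
    else:
        norm = logsumexp(flat, axis=1)
        null_post = None
    post = np.exp(flat - norm[:, None]).reshape(bfs.logbf.shape)
    summary = PosteriorSummary(
        snp_ids=np.asarray(bfs.snp_ids),
        space=bfs.space,
        sigmas=bfs.grid.sigmas,
        posterior=post,
        null_posterior=null_post,
    )
    summary.marginals = _marginals(summary)
    return summary


def _marginals(post: PosteriorSummary) -> np.ndarray:
    codes = post.space.codes_matrix  # (M, d)
    mp = post.model_posterior        # (m, M)
    m, d = mp.shape[0], codes.shape[1]
    out = np.zeros((m, d, 3))
    for c in range(3):
        out[:, :, c] = mp @ (codes == c)
    return out


def category_marginals(
    post: PosteriorSummary, level: float = CONFIDENCE_LEVEL
) -> pd.DataFrame:
    """Per-SNP, per-phenotype category probabilities with confidence flags.

    A phenotype is flagged confidently associated iff ``P(D) + P(I)``
    strictly exceeds ``level`` and confidently unassociated iff it is
    strictly below ``1 - level``.
    """
    marg = post.marginals
    passoc = marg[:, :, 1] + marg[:, :, 2]
    rows = []
    for i, sid in enumerate(post.snp_ids):
        for pi in range(marg.shape[1]):
            rows.append(
                {
                    "snp_id": sid,
                    "phenotype_index": pi,
                    "p_unassociated": marg[i, pi, 0],
                    "p_direct": marg[i, pi, 1],
                    "p_indirect": marg[i, pi, 2],
                    "confidently_associated": bool(passoc[i, pi] > level),
                    "confidently_unassociated": bool(passoc[i, pi] < 1.0 - level),
                }
            )
    return pd.DataFrame(rows)
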
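"""Null Z-score correlation and multivariate association Bayes factors.

Model
-----
Let ``z`` be the length-``d`` vector of signed Z-scores for one SNP across
``d`` phenotypes measured on (largely) overlapping samples. Under the global
null the scores are correlated only through shared noise::

    z ~ N(0, R)

with ``R`` the null correlation matrix, estimated from empirically null SNPs.

An alternative model ``γ`` partitions the phenotypes into sets (U, D, I):
Unassociated, Directly associated, Indirectly associated. The genotype
shifts the mean of the directly associated scores; conditional on the
unassociated scores, the standardized direct effect ``b_j`` of each D
phenotype has an independent ``N(0, σ²)`` prior, and a standardized effect
``b`` moves that phenotype's Z-score by ``sqrt(n_j) * b_j``. Indirectly
associated phenotypes respond to the genotype only through the D phenotypes,
so their conditional density given (U, D) is the same under the null and the
alternative and cancels from the likelihood ratio. The Bayes factor of
``γ`` against the null is therefore a ratio of two multivariate normal
densities of the conditional ``z_D | z_U``::

    BF_γ(z) = N(z_D; m, Σ + σ² diag(n_D)) / N(z_D; m, Σ)
    m = R_DU R_UU⁻¹ z_U,   Σ = R_DD − R_DU R_UU⁻¹ R_UD

Models with indirect but no direct phenotypes are observationally
equivalent to the null (the genotype has no path into the data), so their
Bayes factor is exactly 1.

All arithmetic is done in natural-log space and reported as log10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .models import ModelPartition, ModelSpace

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


class EstimationError(RuntimeError):
    """Too little data to estimate a quantity."""


@dataclass
class NullCorrelation:
    """Estimated null correlation matrix of the Z-scores.

    Captures phenotype correlation induced by overlapping samples; always
    symmetric with unit diagonal, conditioned to be positive definite.
    """

    matrix: np.ndarray
    n_null_snps: int
    conditioned: bool = False
    zmax: float | None = None

    @property
    def d(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path, phenotypes: list[str]) -> None:
        pd.DataFrame(self.matrix, index=phenotypes, columns=phenotypes).to_csv(
            path, sep="\t", float_format="%.17g"
        )


def _condition_correlation(r: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Floor eigenvalues at ``floor`` and re-standardize to unit diagonal."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() > floor:
        return r, False
    vals = np.maximum(vals, floor)
    fixed = (vecs * vals) @ vecs.T
    dinv = 1.0 / np.sqrt(np.diag(fixed))
    fixed = fixed * np.outer(dinv, dinv)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def estimate_null_correlation(panel, zmax: float = 2.0, min_snps: int = 50) -> NullCorrelation:
    """Estimate R from empirically null SNPs (all ``|z| < zmax``).

    The sample correlation of the Z-score vectors over SNPs whose largest
    absolute score is below ``zmax`` estimates the noise correlation from
    sample overlap; if the estimate is not positive definite it is repaired
    by eigenvalue flooring (at 1e-8) and re-standardization.
    """
    z = panel.z
    if z.shape[0] == 0:
        raise EstimationError("empty panel")
    null_mask = (np.abs(z) < zmax).all(axis=1)
    n_null = int(null_mask.sum())
    if n_null < min_snps:
        raise EstimationError(
            f"only {n_null} SNPs have all |z| < zmax={zmax}; at least {min_snps} "
            "are needed — raise zmax or supply more SNPs"
        )
    r = np.corrcoef(z[null_mask], rowvar=False)
    r = np.atleast_2d(r)
    if not np.isfinite(r).all():
        raise EstimationError("null correlation undefined (constant Z column?)")
    r, conditioned = _condition_correlation(r)
    if conditioned:
        logger.info("null correlation repaired to positive definite by eigenvalue flooring")
    return NullCorrelation(matrix=r, n_null_snps=n_null, conditioned=conditioned, zmax=zmax)


@dataclass
class _ModelContext:
    """Per-model linear algebra reused across SNPs and prior scales."""

    u_idx: np.ndarray
    d_idx: np.ndarray
    w: np.ndarray        # regression of z_D on z_U: m = z_U @ w.T
    sigma_cond: np.ndarray  # Schur complement Σ_D|U


def _model_context(r: np.ndarray, model: ModelPartition) -> _ModelContext | None:
    u, d_set, _ = model.partition_sets()
    if not d_set:
        return None
    u_idx = np.array(u, dtype=int)
    d_idx = np.array(d_set, dtype=int)
    if len(u_idx):
        ruu = r[np.ix_(u_idx, u_idx)]
        rdu = r[np.ix_(d_idx, u_idx)]
        w = np.linalg.solve(ruu, rdu.T).T
        sigma = r[np.ix_(d_idx, d_idx)] - w @ rdu.T
    else:
        w = np.zeros((len(d_idx), 0))
        sigma = r[np.ix_(d_idx, d_idx)]
    sigma = 0.5 * (sigma + sigma.T)
    return _ModelContext(u_idx=u_idx, d_idx=d_idx, w=w, sigma_cond=sigma)


def _mvn_logpdf(x: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(0, cov) at the rows of ``x``."""
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular conditional covariance; the null correlation matrix is "
            "ill-conditioned — consider a larger eigenvalue floor or fewer "
            "collinear phenotypes"
        ) from err
    sol = np.linalg.solve(chol, x.T)
    quad = (sol ** 2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    k = cov.shape[0]
    return -0.5 * (k * math.log(2.0 * math.pi) + logdet + quad)


def _log10_bf_batch(
    z: np.ndarray, n: np.ndarray, r: np.ndarray, model: ModelPartition, sigma: float
) -> np.ndarray:
    """Vectorized log10 BF_γ for a (m, d) batch of Z-score rows."""
    ctx = _model_context(r, model)
    if ctx is None:
        return np.zeros(z.shape[0])
    zd = z[:, ctx.d_idx]
    zu = z[:, ctx.u_idx]
    resid = zd - zu @ ctx.w.T
    nd = n[:, ctx.d_idx] if n.ndim == 2 else np.broadcast_to(n[ctx.d_idx], zd.shape)
    # per-SNP n is allowed to vary; group identical rows to reuse Cholesky
    out = np.empty(z.shape[0])
    uniq, inv = np.unique(np.round(nd, 6), axis=0, return_inverse=True)
    for k, nrow in enumerate(uniq):
        rows = inv == k
        cov1 = ctx.sigma_cond + sigma ** 2 * np.diag(nrow)
        out[rows] = (_mvn_logpdf(resid[rows], cov1) - _mvn_logpdf(resid[rows], ctx.sigma_cond)) / LN10
    return out


def log10_bf_model(
    z: np.ndarray,
    n: np.ndarray,
    r: NullCorrelation | np.ndarray,
    model: ModelPartition,
    sigma: float,
) -> float:
    """Closed-form log10 Bayes factor of model ``γ`` against the null.

    Parameters
    ----------
    z : (d,) array
        Signed Z-scores of one SNP.
    n : (d,) array
        Per-phenotype sample sizes (they may differ across phenotypes).
    r : NullCorrelation or (d, d) array
        Null correlation of the Z-scores (positive definite).
    model : ModelPartition
        The U/D/I assignment.
    sigma : float
        Prior standard deviation of each standardized direct effect.
    """
    rmat = r.matrix if isinstance(r, NullCorrelation) else np.asarray(r, float)
    z = np.atleast_1d(np.asarray(z, float))
    n = np.atleast_1d(np.asarray(n, float))
    if z.shape[0] != rmat.shape[0] or z.shape[0] != model.d or n.shape[0] != z.shape[0]:
        raise ValueError(
            f"dimension mismatch: z has {z.shape[0]}, R has {rmat.shape[0]}, "
            f"model has {model.d}, n has {n.shape[0]}"
        )
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(_log10_bf_batch(z[None, :], n[None, :], rmat, model, sigma)[0])


@dataclass
class PriorGrid:
    """Grid of prior standard deviations for standardized direct effects."""

    sigmas: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)

    def __post_init__(self) -> None:
        s = tuple(float(x) for x in self.sigmas)
        if len(s) == 0 or any(x <= 0 for x in s) or any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("prior grid must be nonempty, positive, strictly increasing")
        object.__setattr__(self, "sigmas", s)

    def __len__(self) -> int:
        return len(self.sigmas)


@dataclass
class BFTable:
    """Per-SNP log10 Bayes factors over the (model, prior-scale) grid.

    ``logbf`` has shape (n_snps, 3^d, n_sigmas); the null-model slice is
    identically zero.
    """

    snp_ids: np.ndarray
    space: ModelSpace
    grid: PriorGrid
    logbf: np.ndarray = field(repr=False)
    errors: list = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return self.logbf.shape[0]

    def restrict(self, snp_ids) -> "BFTable":
        """Row subset by SNP id (e.g. the training SNPs)."""
        lookup = pd.Index(self.snp_ids)
        pos = lookup.get_indexer(list(snp_ids))
        missing = [s for s, p in zip(snp_ids, pos) if p < 0]
        if missing:
            raise KeyError(f"SNPs absent from the BF table: {missing[:5]}")
        return BFTable(
            snp_ids=self.snp_ids[pos], space=self.space, grid=self.grid, logbf=self.logbf[pos]
        )

    def to_frame(self, logbfav: np.ndarray | None = None) -> pd.DataFrame:
        cols = {"snp_id": self.snp_ids}
        if logbfav is not None:
            cols["logBFav"] = logbfav
        labels = self.space.code_strings()
        for j, lab in enumerate(labels):
            for k, s in enumerate(self.grid.sigmas):
                cols[f"{lab}|{s:g}"] = self.logbf[:, j, k]
        return pd.DataFrame(cols)


def log10_bf_table(panel, r: NullCorrelation, space: ModelSpace, grid: PriorGrid) -> BFTable:
    """Evaluate log10 BF for every SNP × model × prior scale.

    SNPs with non-finite Z-scores yield non-finite entries and are recorded
    in ``errors`` rather than aborting the whole table.
    """
    z = panel.z
    n = panel.n
    if z.shape[1] != space.d or r.d != space.d:
        raise ValueError("panel, correlation and model space disagree on d")
    m = z.shape[0]
    out = np.zeros((m, space.size, len(grid)))
    good = np.isfinite(z).all(axis=1) & np.isfinite(n).all(axis=1)
    errors = [
        {"snp_id": sid, "error": "non-finite summary statistics"}
        for sid in np.asarray(panel.df["snp_id"])[~good]
    ]
    out[~good] = np.nan
    zg, ng = z[good], n[good]
    for j, model in enumerate(space.models):
        if j == space.null_index:
            continue
        for k, sigma in enumerate(grid.sigmas):
            out[good, j, k] = _log10_bf_batch(zg, ng, r.matrix, model, sigma)
    out[good, space.null_index, :] = 0.0
    return BFTable(
        snp_ids=np.asarray(panel.df["snp_id"]), space=space, grid=grid, logbf=out, errors=errors
    )


def log10_bf_av(table: BFTable, weights) -> np.ndarray:
    """Per-SNP log10 of the weighted-average Bayes factor.

    ``BF_av = Σ_{γ≠null, σ} w_{γ,σ} BF_{γ,σ}``, computed stably via
    log-sum-exp; the null model is excluded from the average and the
    weights must sum to 1 over the non-null pairs.
    """
    w = np.asarray(weights.w if hasattr(weights, "w") else weights, float)
    if w.shape != (table.space.size, len(table.grid)):
        raise ValueError(f"weights shape {w.shape} != {(table.space.size, len(table.grid))}")
    if (w < 0).any():
        raise ValueError("negative weight")
    w = w.copy()
    w[table.space.null_index, :] = 0.0
    total = w.sum()
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise ValueError(f"weights must sum to 1 over non-null pairs (got {total})")
    lnbf = table.logbf * LN10
    with np.errstate(divide="ignore"):
        lnw = np.log(w)
    flat = (lnbf + lnw[None, :, :]).reshape(table.n_snps, -1)
    return logsumexp(flat, axis=1) / LN10
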
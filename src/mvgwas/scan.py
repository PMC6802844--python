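"""Model/Results interface for the multivariate association scan.

`MultiPhenotypeScan` is constructed from a merged summary-statistic panel
(or directly from per-phenotype tables); its :meth:`~MultiPhenotypeScan.fit`
estimates the null Z-score correlation, evaluates the per-SNP Bayes factor
table over the 3^d model space and prior-scale grid, learns empirical Bayes
model weights from a training set (the previously reported univariate
associations) and returns a `ScanResults` carrying the weighted-average
Bayes factors, per-SNP model posteriors and per-phenotype category
marginals, with the downstream significance / classification / replication
procedures as methods.

Example
-------
>>> scan = MultiPhenotypeScan(panel)
>>> res = scan.fit(training_snps=previous_hit_ids)
>>> res.log10_bf_av.head()
>>> hits = res.classify(prev)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import significance as sig
from .bayesfactors import (
    BFTable,
    NullCorrelation,
    PriorGrid,
    estimate_null_correlation,
    log10_bf_av,
    log10_bf_table,
)
from .empirical_bayes import (
    ModelWeights,
    PosteriorSummary,
    category_marginals,
    fit_weights_em,
    model_posteriors,
)
from .io import MergedPanel, apply_qc, merge_phenotypes
from .models import DEFAULT_MAX_D, ModelSpace, enumerate_models
from .replication import overlap_with_release, replicate_by_snp
from .significance import HitList, PreviousHits


class MultiPhenotypeScan:
    """Bayesian multivariate association scan over GWAS summary statistics.

    Parameters
    ----------
    panel : MergedPanel
        Cross-phenotype aligned Z-scores (see :mod:`mvgwas.io`).
    prior_grid : sequence of float
        Prior standard deviations of the standardized direct effects.
    zmax : float
        Empirical-null selection rule for the correlation estimate: SNPs
        with all ``|z| < zmax`` are treated as null.
    max_d : int
        Capacity bound on the exhaustive 3^d model enumeration.
    """

    def __init__(
        self,
        panel: MergedPanel,
        prior_grid=(0.05, 0.1, 0.2, 0.4),
        zmax: float = 2.0,
        max_d: int = DEFAULT_MAX_D,
    ) -> None:
        self.panel = panel
        self.prior_grid = PriorGrid(tuple(prior_grid))
        self.zmax = zmax
        self.space: ModelSpace = enumerate_models(panel.d, max_d=max_d)
        self.qc_report = None

    @classmethod
    def from_tables(
        cls,
        tables,
        orient_to: str,
        maf_min: float = 0.01,
        n_min: float = 0,
        masks=(),
        **kwargs,
    ) -> "MultiPhenotypeScan":
        """Merge per-phenotype summaries, apply QC, and build the model."""
        panel = merge_phenotypes(tables, orient_to=orient_to)
        panel, report = apply_qc(panel, maf_min=maf_min, n_min=n_min, masks=masks)
        model = cls(panel, **kwargs)
        model.qc_report = report
        return model

    def fit(
        self,
        training_snps=None,
        tol: float = 1e-6,
        max_iter: int = 10_000,
        null_prior: float = 0.0,
        null_correlation: NullCorrelation | None = None,
    ) -> "ScanResults":
        """Run the full scan and return results.

        ``training_snps`` are the SNP ids used to learn the model weights
        (in the study design, the previous univariate associations); with
        ``None`` the weights stay uniform over non-null (model, σ) pairs.
        A precomputed ``null_correlation`` can be supplied, e.g. from a
        reference release.
        """
        r = null_correlation if null_correlation is not None else estimate_null_correlation(
            self.panel, zmax=self.zmax
        )
        bf = log10_bf_table(self.panel, r, self.space, self.prior_grid)
        if training_snps is not None:
            weights = fit_weights_em(bf.restrict(training_snps), tol=tol, max_iter=max_iter)
        else:
            weights = ModelWeights.uniform(self.space, self.prior_grid.sigmas)
        bfav = pd.Series(log10_bf_av(bf, weights), index=bf.snp_ids, name="log10_bf_av")
        post = model_posteriors(bf, weights, include_null=null_prior > 0, null_prior=null_prior)
        return ScanResults(
            model=self,
            null_correlation=r,
            bf_table=bf,
            weights=weights,
            log10_bf_av=bfav,
            posteriors=post,
        )


@dataclass
class ScanResults:
    """Fitted multivariate scan: estimates, posteriors, downstream analyses."""

    model: MultiPhenotypeScan
    null_correlation: NullCorrelation
    bf_table: BFTable
    weights: ModelWeights
    log10_bf_av: pd.Series
    posteriors: PosteriorSummary

    @property
    def panel(self) -> MergedPanel:
        return self.model.panel

    # -- downstream procedures -------------------------------------------

    def significance_threshold(self, prev: PreviousHits) -> float:
        """Smallest log10 BF_av among the previous univariate hits."""
        return sig.bf_threshold_from_previous(self.log10_bf_av, prev)

    def classify(
        self,
        prev: PreviousHits,
        threshold: float | None = None,
        window: int = sig.DEFAULT_PRUNE_WINDOW,
        maf_cutoff: float = sig.DEFAULT_LOW_MAF_CUTOFF,
        weak_p_cutoff: float = sig.DEFAULT_WEAK_UNIVARIATE_P,
    ) -> HitList:
        """Classify previous-univariate vs new-multivariate associations."""
        if threshold is None:
            threshold = self.significance_threshold(prev)
        return sig.classify_new_hits(
            self.log10_bf_av,
            self.panel,
            prev,
            threshold,
            window=window,
            maf_cutoff=maf_cutoff,
            weak_p_cutoff=weak_p_cutoff,
        )

    def relaxation_table(self, new_hits: HitList, gwas_threshold: float, **kwargs) -> pd.DataFrame:
        return sig.univariate_relaxation_table(self.panel, new_hits, gwas_threshold, **kwargs)

    def unreported_univariate(self, published: PreviousHits, gwas_threshold: float, **kwargs) -> HitList:
        return sig.find_unreported_univariate(self.panel, published, gwas_threshold, **kwargs)

    def replicate(self, hits: HitList, panel_late: MergedPanel, late_threshold: float):
        return replicate_by_snp(hits, self.panel, panel_late, late_threshold)

    def overlap(self, hits: HitList, later_hits: PreviousHits, window: int = 50_000):
        return overlap_with_release(hits, later_hits, window=window)

    def category_marginals(self, level: float = 0.95) -> pd.DataFrame:
        return category_marginals(self.posteriors, level=level)

    # -- presentation -----------------------------------------------------

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary."""
        phen = self.panel.phenotypes
        lines = [
            "Multivariate association scan",
            "=" * 64,
            f"phenotypes ({self.panel.d}): {', '.join(phen)}",
            f"SNPs: {self.panel.n_snps}; models: {self.bf_table.space.size}; "
            f"prior scales: {list(self.bf_table.grid.sigmas)}",
            f"null correlation from {self.null_correlation.n_null_snps} empirically null "
            f"SNPs (|z| < {self.null_correlation.zmax})",
            "",
            "Null Z-score correlation:",
            pd.DataFrame(self.null_correlation.matrix, index=phen, columns=phen)
            .round(3)
            .to_string(),
            "",
            f"Model weights (EM on {self.weights.training_snp_count} training SNPs, "
            f"{self.weights.em_iterations} iterations, converged={self.weights.converged}):"
            if self.weights.training_snp_count
            else "Model weights: uniform over non-null (model, sigma) pairs",
        ]
        by_model = self.weights.by_model().sort_values(ascending=False).head(top)
        lines.append(by_model.round(4).to_string())
        lines += [
            "",
            f"Top {top} SNPs by log10 BF_av:",
            self.log10_bf_av.sort_values(ascending=False).head(top).round(3).to_string(),
        ]
        return "\n".join(lines)

    def results_frame(self) -> pd.DataFrame:
        """Per-SNP frame: coordinates, log10 BF_av, min p, top model."""
        df = self.panel.df[["snp_id", "chrom", "pos", "maf"]].copy()
        df["log10_bf_av"] = self.log10_bf_av.to_numpy()
        df["min_univariate_p"] = self.panel.min_p.to_numpy()
        tops = self.posteriors.top_models()
        df["top_model"] = tops["top_model"].to_numpy()
        df["top_model_posterior"] = tops["posterior"].to_numpy()
        return df
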
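"""Significance thresholding, distance pruning and hit classification.

The multivariate significance threshold is anchored to the previously
reported univariate associations: a SNP is declared a significant
multivariate association when its log10 BF_av strictly exceeds the smallest
log10 BF_av among the previous univariate hits of the same study. New hits
are required to lie at least a window (default 500 kb) from every previous
hit and are greedily pruned so survivors are pairwise more than a window
apart; LD is handled purely by physical distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PRUNE_WINDOW = 500_000
DEFAULT_PROXIMITY = 1_000_000
DEFAULT_LOW_MAF_CUTOFF = 0.01
DEFAULT_WEAK_UNIVARIATE_P = 1e-4


@dataclass
class PreviousHits:
    """Previously reported genome-wide-significant SNPs present in the panel."""

    df: pd.DataFrame  # columns: snp_id, chrom, pos

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_ids(cls, panel, snp_ids, univariate_threshold: float | None = None) -> "PreviousHits":
        """Build from reported SNP ids, keeping those present in the panel.

        With ``univariate_threshold`` set, entries must also attain
        ``p <= threshold`` in at least one phenotype (the "previous
        univariate association" definition).
        """
        sub = panel.df[panel.df["snp_id"].isin(set(snp_ids))]
        if univariate_threshold is not None:
            minp = sub[[f"p_{p}" for p in panel.phenotypes]].min(axis=1)
            sub = sub[minp <= univariate_threshold]
        return cls(df=sub[["snp_id", "chrom", "pos"]].reset_index(drop=True))


@dataclass
class HitList:
    """Classified association list with provenance annotations.

    ``df`` columns: snp_id, chrom, pos, log10_bf_av, min_univariate_p,
    category, nearest_previous_hit_bp, low_maf, weak_univariate.
    """

    df: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def bf_threshold_from_previous(logbfav: pd.Series, prev: PreviousHits) -> float:
    """Smallest log10 BF_av among the previous univariate hits.

    ``logbfav`` is indexed by snp_id. Every previous hit must be present.
    """
    if len(prev) == 0:
        raise ValueError("no previous univariate hits; the threshold is undefined")
    vals = logbfav.reindex(prev.df["snp_id"])
    if vals.isna().any():
        missing = prev.df["snp_id"][vals.isna().to_numpy()].tolist()
        raise ValueError(f"previous hits absent from BF results: {missing[:5]}")
    return float(vals.min())


def greedy_prune(candidates: pd.DataFrame, window: int = DEFAULT_PRUNE_WINDOW) -> pd.DataFrame:
    """Greedily prune candidates so no survivor has a better one nearby.

    ``candidates`` needs columns chrom, pos, score. The survivors are the
    unique fixed point of the rule "remove any SNP with a strictly
    higher-scoring survivor within ``window`` bp on the same chromosome":
    scanning in order of descending score (ties broken toward the smaller
    position), a SNP is kept iff no already-kept SNP on its chromosome lies
    within the window. Survivors are pairwise more than ``window`` apart on
    each chromosome, and the operation is idempotent.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if len(candidates) == 0:
        return candidates.copy()
    order = candidates.sort_values(
        ["score", "pos"], ascending=[False, True], kind="mergesort"
    )
    kept_pos: dict[str, list[int]] = {}
    kept_idx = []
    for idx, row in order.iterrows():
        chrom = str(row["chrom"])
        pos = int(row["pos"])
        near = any(abs(pos - q) <= window for q in kept_pos.get(chrom, ()))
        if not near:
            kept_pos.setdefault(chrom, []).append(pos)
            kept_idx.append(idx)
    kept = set(kept_idx)
    return candidates.loc[[i for i in candidates.index if i in kept]].copy()


def _distance_to_nearest(df: pd.DataFrame, anchors: pd.DataFrame) -> np.ndarray:
    """Per-row distance (bp) to the nearest same-chromosome anchor; inf if none."""
    out = np.full(len(df), np.inf)
    if len(anchors) == 0 or len(df) == 0:
        return out
    by_chrom = {str(c): g["pos"].to_numpy() for c, g in anchors.groupby("chrom")}
    chroms = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    for i in range(len(df)):
        apos = by_chrom.get(chroms[i])
        if apos is not None:
            out[i] = np.abs(apos - pos[i]).min()
    return out


def classify_new_hits(
    logbfav: pd.Series,
    panel,
    prev: PreviousHits,
    threshold: float,
    window: int = DEFAULT_PRUNE_WINDOW,
    maf_cutoff: float = DEFAULT_LOW_MAF_CUTOFF,
    weak_p_cutoff: float = DEFAULT_WEAK_UNIVARIATE_P,
) -> HitList:
    """Classify significant SNPs into previous-univariate and new-multivariate.

    New multivariate hits are SNPs with log10 BF_av strictly above the
    threshold that are not previous hits, lie more than ``window`` bp from
    every previous hit, and survive greedy pruning by BF_av. Low-MAF and
    weak-univariate flags are diagnostics only (the caution cases) and never
    filter.
    """
    df = panel.df[["snp_id", "chrom", "pos", "maf"]].copy()
    df["log10_bf_av"] = logbfav.reindex(df["snp_id"]).to_numpy()
    df["min_univariate_p"] = panel.min_p.reindex(df["snp_id"]).to_numpy()
    df["nearest_previous_hit_bp"] = _distance_to_nearest(df, prev.df)

    prev_ids = set(prev.df["snp_id"])
    prev_rows = df[df["snp_id"].isin(prev_ids)].copy()
    prev_rows["category"] = "previous-univariate"

    sig = df[(df["log10_bf_av"] > threshold) & ~df["snp_id"].isin(prev_ids)]
    n_significant = len(sig)
    new = sig[sig["nearest_previous_hit_bp"] > window].copy()
    n_after_exclusion = len(new)
    new["score"] = new["log10_bf_av"]
    new = greedy_prune(new, window=window).drop(columns="score")
    new["category"] = "new-multivariate"

    out = pd.concat([prev_rows, new], ignore_index=True)
    out["low_maf"] = out["maf"] < maf_cutoff
    out["weak_univariate"] = out["min_univariate_p"] > weak_p_cutoff
    out = out.drop(columns="maf")
    counts = {
        "previous_univariate": len(prev_rows),
        "significant_non_previous": n_significant,
        "after_previous_exclusion": n_after_exclusion,
        "new_multivariate": len(new),
    }
    logger.info("classification counts: %s", counts)
    return HitList(df=out.reset_index(drop=True), counts=counts)


def univariate_relaxation_table(
    panel,
    new_hits: HitList,
    gwas_threshold: float,
    p_floor: float = 1e-6,
    window: int = DEFAULT_PRUNE_WINDOW,
) -> pd.DataFrame:
    """Relaxed-univariate-threshold comparison (marginal vs multivariate).

    Builds the list of "marginally significant" SNPs (min univariate p
    strictly below ``p_floor`` but not genome-wide significant), greedily
    prunes it by minimum p, removes entries within ``window`` of a new
    multivariate hit, merges with the new hits, sorts by minimum univariate
    p and reports cumulative per-category counts as the threshold relaxes.
    """
    if p_floor <= gwas_threshold:
        raise ValueError("p_floor must exceed the genome-wide threshold")
    minp = panel.min_p
    df = panel.df[["snp_id", "chrom", "pos"]].copy()
    df["min_univariate_p"] = minp.to_numpy()
    marginal = df[(df["min_univariate_p"] < p_floor) & (df["min_univariate_p"] > gwas_threshold)].copy()
    marginal["score"] = -np.log10(marginal["min_univariate_p"])
    marginal = greedy_prune(marginal, window=window).drop(columns="score")

    new_df = new_hits.df[new_hits.df["category"] == "new-multivariate"]
    dist = _distance_to_nearest(marginal, new_df)
    marginal = marginal[(dist > window) & ~marginal["snp_id"].isin(set(new_df["snp_id"]))].copy()
    marginal["category"] = "univariate-only"

    newpart = new_df[["snp_id", "chrom", "pos", "min_univariate_p"]].copy()
    newpart["category"] = "new-multivariate"
    merged = pd.concat([marginal, newpart], ignore_index=True)
    merged = merged.sort_values("min_univariate_p", kind="mergesort").reset_index(drop=True)
    merged["cum_univariate_only"] = (merged["category"] == "univariate-only").cumsum()
    merged["cum_new_multivariate"] = (merged["category"] == "new-multivariate").cumsum()
    return merged


def find_unreported_univariate(
    panel,
    published: PreviousHits,
    gwas_threshold: float,
    proximity: int = DEFAULT_PROXIMITY,
    window: int = DEFAULT_PRUNE_WINDOW,
) -> HitList:
    """Univariate-significant SNPs absent from the published hit list.

    SNPs attaining the genome-wide threshold in at least one phenotype but
    not among the published hits are greedily pruned by minimum p and
    annotated with the distance to the nearest published hit and a
    within-``proximity`` flag (physical proximity to a stronger reported
    signal is the common reason such SNPs went unreported).
    """
    df = panel.df[["snp_id", "chrom", "pos"]].copy()
    df["min_univariate_p"] = panel.min_p.to_numpy()
    pub_ids = set(published.df["snp_id"])
    cand = df[(df["min_univariate_p"] <= gwas_threshold) & ~df["snp_id"].isin(pub_ids)].copy()
    cand["score"] = -np.log10(cand["min_univariate_p"])
    cand = greedy_prune(cand, window=window).drop(columns="score")
    cand["nearest_previous_hit_bp"] = _distance_to_nearest(cand, published.df)
    cand["within_proximity"] = cand["nearest_previous_hit_bp"] <= proximity
    cand["category"] = "unreported-univariate"
    return HitList(
        df=cand.reset_index(drop=True),
        counts={
            "unreported_univariate": len(cand),
            "within_proximity": int(cand["within_proximity"].sum()),
        },
    )
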
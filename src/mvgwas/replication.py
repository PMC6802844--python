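"""Cross-release evaluation of new multivariate associations.

When a consortium publishes a later, larger data release, the new
multivariate hits from the earlier release can be checked against the later
univariate results. Because later releases contain the earlier samples,
this is an enrichment check rather than independent replication: the
question is whether the extra samples strengthen the signal, i.e. whether
the minimum univariate p-value at exactly the same SNP becomes smaller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP_WINDOW = 50_000

ENRICHMENT_NOTE = (
    "later releases include the earlier samples; improvement of the minimum "
    "univariate p-value is an enrichment check, not independent replication"
)


@dataclass
class ReplicationReport:
    """Per-hit early-vs-late comparison plus flag totals.

    ``df`` columns: snp_id, min_p_early, min_p_late, improved,
    crossed_later_threshold, matched.
    """

    df: pd.DataFrame
    late_threshold: float
    note: str = ENRICHMENT_NOTE
    totals: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.note}\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    def summary_block(self) -> pd.DataFrame:
        """S5-style one-row summary: hits, improved, crossed."""
        return pd.DataFrame(
            [
                {
                    "new_multivariate_in_first": self.totals["n_hits"],
                    "lower_univariate_p_in_second": self.totals["improved"],
                    "below_second_threshold": self.totals["crossed_later_threshold"],
                    "unmatched": self.totals["unmatched"],
                }
            ]
        )


def replicate_by_snp(
    hits, panel_early, panel_late, late_threshold: float
) -> ReplicationReport:
    """Compare each hit's minimum univariate p across releases (same snp_id).

    A hit improves when its later minimum p is strictly smaller than the
    earlier one at exactly the same SNP; it crosses when the later minimum p
    attains the later release's genome-wide threshold. Hits absent from the
    later panel are reported unmatched and excluded from flag denominators.
    """
    hit_df = hits.df if hasattr(hits, "df") else hits
    hit_df = hit_df[hit_df.get("category", "new-multivariate") == "new-multivariate"]
    ids = hit_df["snp_id"].tolist()
    early = panel_early.min_p.reindex(ids)
    late = panel_late.min_p.reindex(ids)
    matched = late.notna().to_numpy() & early.notna().to_numpy()
    improved = matched & (late.to_numpy() < early.to_numpy())
    crossed = matched & (late.to_numpy() <= late_threshold)
    df = pd.DataFrame(
        {
            "snp_id": ids,
            "min_p_early": early.to_numpy(),
            "min_p_late": late.to_numpy(),
            "matched": matched,
            "improved": improved,
            "crossed_later_threshold": crossed,
        }
    )
    totals = {
        "n_hits": len(df),
        "matched": int(matched.sum()),
        "unmatched": int((~matched).sum()),
        "improved": int(improved.sum()),
        "not_improved": int((matched & ~improved).sum()),
        "crossed_later_threshold": int(crossed.sum()),
    }
    if totals["unmatched"]:
        logger.info("%d hits absent from the later release", totals["unmatched"])
    return ReplicationReport(df=df, late_threshold=late_threshold, totals=totals)


def overlap_with_release(
    hits, later_univariate_hits, window: int = DEFAULT_OVERLAP_WINDOW
) -> tuple[int, pd.DataFrame]:
    """Count hits within ``window`` bp of a later-release univariate hit.

    The window is closed: a hit exactly ``window`` bp away overlaps. The
    distance is symmetric, so either list may supply the anchor coordinate.
    Returns the overlap count and the per-hit flag frame.
    """
    hit_df = (hits.df if hasattr(hits, "df") else hits).copy()
    later_df = later_univariate_hits.df if hasattr(later_univariate_hits, "df") else later_univariate_hits
    by_chrom = {str(c): g["pos"].to_numpy() for c, g in later_df.groupby("chrom")}
    dist = np.full(len(hit_df), np.inf)
    chroms = hit_df["chrom"].astype(str).to_numpy()
    pos = hit_df["pos"].to_numpy()
    for i in range(len(hit_df)):
        apos = by_chrom.get(chroms[i])
        if apos is not None and len(apos):
            dist[i] = np.abs(apos - pos[i]).min()
    flags = pd.DataFrame(
        {
            "snp_id": hit_df["snp_id"].to_numpy(),
            "nearest_later_hit_bp": dist,
            "overlaps_later_univariate": dist <= window,
        }
    )
    return int(flags["overlaps_later_univariate"].sum()), flags
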
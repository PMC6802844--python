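"""Reading, harmonizing and quality-filtering GWAS summary statistics.

The pipeline ingests one whitespace/tab-delimited table per phenotype,
reconstructs signed Z-scores, merges the tables into a single cross-phenotype
panel oriented to one reference phenotype's minor allele, and applies the
standard QC rules (drop SNPs missing from any phenotype, with missing or zero
MAF, with an exactly-zero effect, with mismatched alleles, below MAF or
sample-size thresholds, or inside masked regions).

Column semantics
----------------
A *dialect* maps column roles to column names in the file. Required roles:
``snp_id``, ``chrom``, ``pos``, ``allele_ref``, ``allele_alt``. Optional:
``maf``, ``effect``, ``se``, ``z``, ``pvalue``, ``n``. The ``maf`` column is
interpreted as the frequency of the effect (alt) allele and may lie anywhere
in [0, 1]; orientation of the merged panel folds it onto the minor allele of
the reference phenotype. The signed Z-score is reconstructed with priority
``z`` column > ``effect/se`` > signed two-sided normal quantile of ``pvalue``
with the sign of ``effect``.

Coordinates are 1-based and mask intervals are closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_ROLES = ("snp_id", "chrom", "pos", "allele_ref", "allele_alt")
OPTIONAL_ROLES = ("maf", "effect", "se", "z", "pvalue", "n")

#: Dialect of the canonical tables written by :mod:`mvgwas.simulate` and the CLI.
CANONICAL_DIALECT: dict[str, str] = {
    "snp_id": "snp",
    "chrom": "chr",
    "pos": "bp",
    "allele_ref": "ref",
    "allele_alt": "alt",
    "maf": "af",
    "effect": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

# Precedence used to attribute a dropped SNP to exactly one rule so that the
# per-rule counts and the retained count reconcile.
QC_RULES = (
    "missing_phenotype",
    "allele_mismatch",
    "missing_maf",
    "fixed",
    "zero_effect",
    "below_maf_threshold",
    "below_n_threshold",
    "masked_region",
)


class ConfigurationError(ValueError):
    """Bad dialect / option combination."""


class InputError(ValueError):
    """Unusable input data (e.g. zero parseable rows)."""


@dataclass
class PhenotypeSummary:
    """Parsed per-phenotype summary statistics.

    ``table`` columns: snp_id, chrom, pos, allele_ref, allele_alt, maf
    (effect-allele frequency, NaN when absent), z, n, pvalue.
    """

    phenotype: str
    table: pd.DataFrame
    n_unparseable: int = 0
    unparseable_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table["snp_id"].duplicated().any():
            dups = self.table["snp_id"][self.table["snp_id"].duplicated()].unique()
            logger.warning(
                "phenotype %s: %d duplicate snp_id values (e.g. %s); keeping first occurrence",
                self.phenotype, len(dups), dups[0],
            )
            self.table = self.table.drop_duplicates("snp_id", keep="first").reset_index(drop=True)


@dataclass
class MergedPanel:
    """Cross-phenotype aligned panel of Z-scores.

    ``df`` columns: snp_id, chrom, pos, allele_ref, allele_alt, maf,
    strand_ambiguous, then ``z_<p>``, ``n_<p>``, ``p_<p>`` per phenotype.
    All Z-scores refer to the oriented alt allele, which is the minor allele
    of the reference phenotype.
    """

    phenotypes: list[str]
    df: pd.DataFrame
    orient_to: str | None = None
    merge_drops: dict[str, int] = field(default_factory=dict)

    @property
    def d(self) -> int:
        return len(self.phenotypes)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def z(self) -> np.ndarray:
        """(n_snps, d) matrix of signed Z-scores."""
        return self.df[[f"z_{p}" for p in self.phenotypes]].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.df[[f"n_{p}" for p in self.phenotypes]].to_numpy(float)

    @property
    def p(self) -> np.ndarray:
        return self.df[[f"p_{p}" for p in self.phenotypes]].to_numpy(float)

    @property
    def min_p(self) -> pd.Series:
        """Per-SNP minimum univariate p-value across phenotypes."""
        s = self.df[[f"p_{p}" for p in self.phenotypes]].min(axis=1)
        s.index = self.df["snp_id"]
        return s

    def subset(self, mask) -> "MergedPanel":
        return MergedPanel(
            phenotypes=list(self.phenotypes),
            df=self.df.loc[mask].reset_index(drop=True),
            orient_to=self.orient_to,
            merge_drops=dict(self.merge_drops),
        )

    def to_tsv(self, path) -> None:
        """Write the canonical panel TSV (round-trips floats exactly)."""
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path, phenotypes: list[str] | None = None) -> "MergedPanel":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if phenotypes is None:
            phenotypes = [c[2:] for c in df.columns if c.startswith("z_")]
        return cls(phenotypes=phenotypes, df=df)


@dataclass
class QCReport:
    """Per-rule drop counts for one merge + QC pass; counts reconcile."""

    dropped: dict[str, int]
    n_retained: int
    n_input: int
    n_strand_ambiguous: int = 0

    def reconciles(self) -> bool:
        return sum(self.dropped.values()) + self.n_retained == self.n_input

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "dropped": v} for k, v in self.dropped.items()]
        rows.append({"rule": "retained", "dropped": self.n_retained})
        return pd.DataFrame(rows)


def _signed_z(effect, se, z, pvalue) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct signed Z-scores; returns (z, unparseable mask)."""
    m = len(effect)
    out = np.full(m, np.nan)
    bad = np.zeros(m, dtype=bool)

    have_z = np.isfinite(z)
    out[have_z] = z[have_z]

    need = ~have_z
    ok_ratio = need & np.isfinite(effect) & np.isfinite(se) & (se > 0)
    out[ok_ratio] = effect[ok_ratio] / se[ok_ratio]
    # se == 0 makes the Z-score undefined
    bad |= need & np.isfinite(effect) & np.isfinite(se) & (se == 0)

    need = ~np.isfinite(out) & ~bad
    ok_p = need & np.isfinite(effect) & np.isfinite(pvalue) & (pvalue > 0) & (pvalue <= 1)
    out[ok_p] = np.sign(effect[ok_p]) * stats.norm.isf(pvalue[ok_p] / 2.0)
    bad |= ~np.isfinite(out) & ~bad
    return out, bad


def read_summary_table(
    path,
    dialect: dict[str, str],
    phenotype: str | None = None,
    default_n: float | None = None,
    sep: str | None = None,
) -> PhenotypeSummary:
    """Read one phenotype's summary-statistic table.

    Parameters
    ----------
    path
        Delimited text file, optionally gzip-compressed.
    dialect
        Mapping of column roles to column names (see module docstring).
    default_n
        Study-wide sample-size proxy substituted when no per-SNP ``n``
        column is available.
    sep
        Field separator; defaults to arbitrary whitespace.

    Rows whose required fields cannot be parsed (e.g. ``se == 0``) are
    counted and listed in the result, never silently dropped.
    """
    unknown = set(dialect) - set(REQUIRED_ROLES) - set(OPTIONAL_ROLES)
    if unknown:
        raise ConfigurationError(f"unknown column roles in dialect: {sorted(unknown)}")
    missing = [r for r in REQUIRED_ROLES if r not in dialect]
    if missing:
        raise ConfigurationError(f"dialect missing required roles: {missing}")

    raw = pd.read_csv(path, sep=sep if sep is not None else r"\s+", engine="python")
    absent = [c for c in dialect.values() if c not in raw.columns]
    if absent:
        raise ConfigurationError(f"columns {absent} not found in {path}")

    def col(role, default=np.nan):
        if role in dialect:
            return pd.to_numeric(raw[dialect[role]], errors="coerce").to_numpy(float)
        return np.full(len(raw), default)

    z, bad = _signed_z(col("effect"), col("se"), col("z"), col("pvalue"))

    n = col("n")
    if default_n is not None:
        n = np.where(np.isfinite(n), n, float(default_n))

    pval = col("pvalue")
    with np.errstate(invalid="ignore"):
        pval = np.where(np.isfinite(pval), pval, 2.0 * stats.norm.sf(np.abs(z)))

    table = pd.DataFrame(
        {
            "snp_id": raw[dialect["snp_id"]].astype(str),
            "chrom": raw[dialect["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[dialect["pos"]], errors="coerce"),
            "allele_ref": raw[dialect["allele_ref"]].astype(str).str.upper(),
            "allele_alt": raw[dialect["allele_alt"]].astype(str).str.upper(),
            "maf": col("maf"),
            "z": z,
            "n": n,
            "pvalue": pval,
        }
    )
    bad |= ~np.isfinite(table["pos"].to_numpy(float))
    bad_ids = table.loc[bad, "snp_id"].tolist()
    if bad.any():
        logger.warning("%s: %d rows unparseable (e.g. %s)", path, int(bad.sum()), bad_ids[0])
    table = table.loc[~bad].reset_index(drop=True)
    if len(table) == 0:
        raise InputError(f"{path}: no parseable rows")
    table["pos"] = table["pos"].astype(np.int64)

    name = phenotype if phenotype is not None else str(path)
    return PhenotypeSummary(phenotype=name, table=table, n_unparseable=int(bad.sum()),
                            unparseable_ids=bad_ids)


def merge_phenotypes(tables: list[PhenotypeSummary], orient_to: str) -> MergedPanel:
    """Merge per-phenotype tables into one panel oriented to ``orient_to``.

    Keeps only SNPs present in every table with identical allele pairs up to
    a ref/alt swap; orients every SNP so the counted (alt) allele is the
    minor allele in the ``orient_to`` table, flipping Z signs of swapped
    tables; SNPs whose allele pairs differ beyond a swap are dropped and
    counted under ``allele_mismatch``.
    """
    names = [t.phenotype for t in tables]
    if orient_to not in names:
        raise ConfigurationError(f"orient_to={orient_to!r} not among phenotypes {names}")
    ref_tab = tables[names.index(orient_to)].table.set_index("snp_id")

    ids_per_table = [set(t.table["snp_id"]) for t in tables]
    union = set().union(*ids_per_table)
    common = set.intersection(*ids_per_table)
    n_missing = len(union) - len(common)

    # orient the reference phenotype to its own minor allele
    ref = ref_tab.loc[[i for i in ref_tab.index if i in common]].copy()
    flip = ref["maf"].to_numpy(float) > 0.5
    ref.loc[flip, ["allele_ref", "allele_alt"]] = ref.loc[flip, ["allele_alt", "allele_ref"]].to_numpy()
    ref.loc[flip, "z"] = -ref.loc[flip, "z"]
    ref.loc[flip, "maf"] = 1.0 - ref.loc[flip, "maf"]

    out = pd.DataFrame(
        {
            "snp_id": ref.index,
            "chrom": ref["chrom"].to_numpy(),
            "pos": ref["pos"].to_numpy(),
            "allele_ref": ref["allele_ref"].to_numpy(),
            "allele_alt": ref["allele_alt"].to_numpy(),
            "maf": ref["maf"].to_numpy(float),
        }
    ).reset_index(drop=True)
    pair = list(zip(out["allele_ref"], out["allele_alt"]))
    out["strand_ambiguous"] = [p in _AMBIGUOUS_PAIRS for p in pair]

    keep = np.ones(len(out), dtype=bool)
    for t in tables:
        tab = t.table.set_index("snp_id").loc[out["snp_id"]]
        same = (tab["allele_ref"].to_numpy() == out["allele_ref"].to_numpy()) & (
            tab["allele_alt"].to_numpy() == out["allele_alt"].to_numpy()
        )
        swapped = (tab["allele_ref"].to_numpy() == out["allele_alt"].to_numpy()) & (
            tab["allele_alt"].to_numpy() == out["allele_ref"].to_numpy()
        )
        keep &= same | swapped
        sign = np.where(swapped, -1.0, 1.0)
        out[f"z_{t.phenotype}"] = sign * tab["z"].to_numpy(float)
        out[f"n_{t.phenotype}"] = tab["n"].to_numpy(float)
        out[f"p_{t.phenotype}"] = tab["pvalue"].to_numpy(float)

    n_mismatch = int((~keep).sum())
    out = out.loc[keep].reset_index(drop=True)
    return MergedPanel(
        phenotypes=names,
        df=out,
        orient_to=orient_to,
        merge_drops={"missing_phenotype": n_missing, "allele_mismatch": n_mismatch},
    )


def apply_qc(
    panel: MergedPanel,
    maf_min: float = 0.0,
    n_min: float = 0,
    masks: list[tuple[str, int, int]] = (),
) -> tuple[MergedPanel, QCReport]:
    """Apply the standard QC drop rules to a merged panel.

    Rules (a SNP is retained iff it violates none; violators are counted
    once under the first violated rule in `QC_RULES` order): missing MAF,
    MAF exactly 0 (fixed), any Z exactly 0 (direction indeterminable),
    MAF < ``maf_min``, any per-phenotype n < ``n_min``, or position inside a
    closed mask interval. An empty output panel is legal.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    if n_min < 0:
        raise ValueError(f"n_min must be >= 0, got {n_min}")

    df = panel.df
    maf = df["maf"].to_numpy(float)
    z = panel.z
    n = panel.n

    viol = {
        "missing_maf": ~np.isfinite(maf),
        "fixed": np.isfinite(maf) & (maf == 0.0),
        "zero_effect": (z == 0.0).any(axis=1),
        "below_maf_threshold": np.isfinite(maf) & (maf > 0) & (maf < maf_min),
        "below_n_threshold": (n < n_min).any(axis=1) | ~np.isfinite(n).all(axis=1),
    }
    masked = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    for mchrom, start, end in masks:
        masked |= (chrom == str(mchrom)) & (pos >= start) & (pos <= end)
    viol["masked_region"] = masked

    dropped = {r: int(panel.merge_drops.get(r, 0)) for r in ("missing_phenotype", "allele_mismatch")}
    assigned = np.zeros(len(df), dtype=bool)
    for rule in QC_RULES:
        if rule in dropped and rule not in viol:
            continue
        mask = viol[rule] & ~assigned
        dropped[rule] = int(mask.sum())
        assigned |= viol[rule]

    kept = panel.subset(~assigned)
    report = QCReport(
        dropped=dropped,
        n_retained=kept.n_snps,
        n_input=len(df) + sum(panel.merge_drops.values()),
        n_strand_ambiguous=int(df["strand_ambiguous"].sum()),
    )
    for rule, cnt in dropped.items():
        if cnt:
            logger.info("QC: dropped %d SNPs (%s)", cnt, rule)
    return kept, report
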
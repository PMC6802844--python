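"""Synthetic multi-phenotype GWAS summary statistics.

Generates per-phenotype summary tables with exactly the statistical
structure the analysis assumes: for each SNP a model (U/D/I assignment plus
prior scale) is drawn from a mixture, standardized direct effects for the D
phenotypes are drawn from ``N(0, σ²)``, indirect phenotypes receive the
marginal mean implied by regressing on the direct ones through the noise
correlation ``R`` (the DAG semantics: indirect phenotypes see the genotype
only through the direct ones), and the Z-score vector is drawn as
``N(μ, R)`` with ``μ_D = sqrt(n_D)·b_D``, ``μ_U = 0`` and
``μ_I = R_{I,UD} R_{UD,UD}⁻¹ μ_{UD}``.

SNPs are independent: there is no LD, and positions are laid out on
synthetic chromosomes with fixed spacing purely so that distance-based
pruning logic is exercised. MAF is generated but does not modulate the
Z-scores (summary statistics are standardized); an optional contamination
mode injects inflated Z-scores at very low MAF to exercise the low-MAF
diagnostic flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelPartition


@dataclass(frozen=True)
class SimComponent:
    """One mixture component: a model partition, prior scale and probability."""

    codes: tuple[int, ...]
    sigma: float
    prob: float


def default_components(d: int, null_prop: float = 0.95, sigma: float = 0.1) -> list[SimComponent]:
    """Null plus the all-direct model — the simplest realistic mixture."""
    return [
        SimComponent(codes=(0,) * d, sigma=sigma, prob=null_prop),
        SimComponent(codes=(1,) * d, sigma=sigma, prob=1.0 - null_prop),
    ]


@dataclass
class SimConfig:
    """Configuration for the synthetic study.

    ``n`` holds per-phenotype sample sizes; ``components`` the true model
    mixture (must include the null as the all-zeros partition unless the
    study is meant to be fully non-null). ``two_release`` optionally gives
    (n_early, n_late) per-phenotype sample sizes with the late release a
    superset of the early one.
    """

    d: int
    m: int
    r_true: np.ndarray
    n: np.ndarray
    components: list[SimComponent] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    chrom_count: int = 2
    spacing: int = 100_000
    swap_fraction: float = 0.0
    shared_direction: bool = False
    lowmaf_contamination: float = 0.0
    lowmaf_inflation: float = 3.0
    two_release: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.d < 1 or self.m < 1:
            raise ValueError("d and m must be >= 1")
        self.r_true = np.asarray(self.r_true, float)
        if self.r_true.shape != (self.d, self.d):
            raise ValueError("r_true must be d x d")
        vals = np.linalg.eigvalsh(self.r_true)
        if vals.min() <= 0:
            raise ValueError("r_true must be positive definite")
        self.n = np.asarray(self.n, float)
        if self.n.shape != (self.d,) or (self.n <= 0).any():
            raise ValueError("n must be d positive sample sizes")
        if not self.components:
            self.components = default_components(self.d)
        probs = np.array([c.prob for c in self.components])
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("component probabilities must be nonnegative and sum to 1")
        for c in self.components:
            ModelPartition(c.codes)  # validates codes
            if len(c.codes) != self.d:
                raise ValueError(f"component codes {c.codes} do not have length d={self.d}")
        if self.two_release is not None:
            ne, nl = (np.asarray(a, float) for a in self.two_release)
            if ne.shape != (self.d,) or nl.shape != (self.d,):
                raise ValueError("two_release sample sizes must have length d")
            if (nl < ne).any():
                raise ValueError("late-release n must be >= early-release n per phenotype")
            self.two_release = (ne, nl)

    @property
    def phenotypes(self) -> list[str]:
        return [f"pheno{i + 1}" for i in range(self.d)]


@dataclass
class SimTruth:
    """Ground truth per SNP: model assignment, effects, Z-score means."""

    df: pd.DataFrame  # snp_id, chrom, pos, model, sigma plus effect_/mu_ columns
    phenotypes: list[str]

    def nonnull_ids(self) -> list[str]:
        null_str = " ".join(["0"] * len(self.phenotypes))
        return self.df.loc[self.df["model"] != null_str, "snp_id"].tolist()


def _mean_vector(codes: np.ndarray, b: np.ndarray, n: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Marginal Z-score mean implied by direct effects ``b`` under the DAG."""
    d = len(codes)
    mu = np.zeros(d)
    d_idx = np.flatnonzero(codes == 1)
    if len(d_idx) == 0:
        return mu
    mu[d_idx] = np.sqrt(n[d_idx]) * b[d_idx]
    i_idx = np.flatnonzero(codes == 2)
    if len(i_idx):
        ud = np.flatnonzero(codes != 2)
        w = np.linalg.solve(r[np.ix_(ud, ud)], r[np.ix_(ud, i_idx)])
        mu[i_idx] = w.T @ mu[ud]
    return mu


def _layout(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids = np.array([f"rs{i + 1}" for i in range(config.m)])
    per_chrom = -(-config.m // config.chrom_count)
    chroms = 1 + np.arange(config.m) // per_chrom
    pos = config.spacing * (1 + np.arange(config.m) % per_chrom)
    return ids, chroms.astype(int), pos.astype(int)


_BASES = np.array(list("ACGT"))


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw per-SNP models and direct effects; return (truth frame, codes, b)."""
    ids, chroms, pos = _layout(config)
    probs = np.array([c.prob for c in config.components])
    comp_idx = rng.choice(len(config.components), size=config.m, p=probs)
    codes = np.array([config.components[k].codes for k in comp_idx], dtype=np.int8)
    sigmas = np.array([config.components[k].sigma for k in comp_idx])
    if config.shared_direction:
        # one effect per SNP shared by all direct phenotypes (same sign and size)
        b = np.repeat(rng.standard_normal((config.m, 1)), config.d, axis=1) * sigmas[:, None]
    else:
        b = rng.standard_normal((config.m, config.d)) * sigmas[:, None]
    b[codes != 1] = 0.0
    truth = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chroms,
            "pos": pos,
            "model": [" ".join(map(str, c)) for c in codes],
            "sigma": sigmas,
        }
    )
    for j, name in enumerate(config.phenotypes):
        truth[f"effect_{name}"] = b[:, j]
    return truth, codes, b


def _means(config: SimConfig, codes: np.ndarray, b: np.ndarray, n: np.ndarray) -> np.ndarray:
    mu = np.zeros((config.m, config.d))
    # group SNPs by model so the per-model linear algebra is done once
    strs = np.array([c.tobytes() for c in codes])
    for key in np.unique(strs):
        rows = np.flatnonzero(strs == key)
        c = codes[rows[0]]
        d_idx = np.flatnonzero(c == 1)
        if len(d_idx) == 0:
            continue
        mu[np.ix_(rows, d_idx)] = np.sqrt(n[d_idx])[None, :] * b[np.ix_(rows, d_idx)]
        i_idx = np.flatnonzero(c == 2)
        if len(i_idx):
            ud = np.flatnonzero(c != 2)
            r = config.r_true
            w = np.linalg.solve(r[np.ix_(ud, ud)], r[np.ix_(ud, i_idx)])
            mu[np.ix_(rows, i_idx)] = mu[np.ix_(rows, ud)] @ w
    return mu


def _emit_tables(
    config: SimConfig,
    truth: pd.DataFrame,
    z: np.ndarray,
    n: np.ndarray,
    rng: np.random.Generator,
    af: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
) -> dict[str, pd.DataFrame]:
    tables = {}
    for j, name in enumerate(config.phenotypes):
        se = 1.0 / np.sqrt(n[j])
        beta = z[:, j] * se
        a1, a2, freq = ref.copy(), alt.copy(), af.copy()
        if config.swap_fraction > 0 and j > 0:
            swap = rng.random(config.m) < config.swap_fraction
            a1[swap], a2[swap] = alt[swap], ref[swap]
            freq = np.where(swap, 1.0 - af, af)
            beta = np.where(swap, -beta, beta)
        tables[name] = pd.DataFrame(
            {
                "snp": truth["snp_id"],
                "chr": truth["chrom"],
                "bp": truth["pos"],
                "ref": a1,
                "alt": a2,
                "af": freq,
                "beta": beta,
                "se": np.full(config.m, se),
                "pvalue": 2.0 * stats.norm.sf(np.abs(z[:, j])),
                "n": np.full(config.m, n[j]),
            }
        )
    return tables


def _draw_alleles(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ridx = rng.integers(0, 4, size=config.m)
    shift = rng.integers(1, 4, size=config.m)
    ref = _BASES[ridx]
    alt = _BASES[(ridx + shift) % 4]
    lo, hi = config.maf_range
    af = rng.uniform(lo, hi, size=config.m)
    return ref, alt, af


def simulate_panel(config: SimConfig) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """Generate one synthetic study in the canonical input dialect.

    Returns per-phenotype tables (readable with
    ``read_summary_table(..., CANONICAL_DIALECT)``) plus the ground truth.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth, codes, b = _draw_truth(config, rng)
    mu = _means(config, codes, b, config.n)
    chol = np.linalg.cholesky(config.r_true)
    z = mu + rng.standard_normal((config.m, config.d)) @ chol.T
    ref, alt, af = _draw_alleles(config, rng)

    if config.lowmaf_contamination > 0:
        null_rows = np.flatnonzero((codes == 0).all(axis=1))
        k = int(round(config.lowmaf_contamination * config.m))
        chosen = null_rows[: min(k, len(null_rows))]
        af[chosen] = rng.uniform(5e-4, 5e-3, size=len(chosen))
        z[chosen] *= config.lowmaf_inflation  # unstable low-MAF signals

    for j, name in enumerate(config.phenotypes):
        truth[f"mu_{name}"] = mu[:, j]
    tables = _emit_tables(config, truth, z, config.n, rng, af, ref, alt)
    return tables, SimTruth(df=truth, phenotypes=config.phenotypes)


def simulate_two_releases(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], SimTruth]:
    """Generate an early and a late release sharing samples and true effects.

    The late release's samples are a superset of the early ones, so for a
    null SNP the early and late Z-scores of one phenotype correlate as
    ``sqrt(n_early / n_late)``, while a true signal's mean grows as
    ``sqrt(n)``. Noise is constructed as
    ``ε_late = sqrt(n_e/n_l)·ε_early + sqrt(1 − n_e/n_l)·ε_extra`` with both
    pieces drawn from ``N(0, R)``.
    """
    if config.two_release is None:
        raise ValueError("config.two_release must be set")
    n_early, n_late = config.two_release
    rng = np.random.default_rng(config.seed)
    truth, codes, b = _draw_truth(config, rng)
    mu_e = _means(config, codes, b, n_early)
    mu_l = _means(config, codes, b, n_late)
    chol = np.linalg.cholesky(config.r_true)
    eps_early = rng.standard_normal((config.m, config.d)) @ chol.T
    eps_extra = rng.standard_normal((config.m, config.d)) @ chol.T
    ratio = np.sqrt(n_early / n_late)
    z_early = mu_e + eps_early
    z_late = mu_l + ratio[None, :] * eps_early + np.sqrt(1.0 - ratio**2)[None, :] * eps_extra
    ref, alt, af = _draw_alleles(config, rng)
    for j, name in enumerate(config.phenotypes):
        truth[f"mu_early_{name}"] = mu_e[:, j]
        truth[f"mu_late_{name}"] = mu_l[:, j]
    tables_early = _emit_tables(config, truth, z_early, n_early, rng, af, ref, alt)
    tables_late = _emit_tables(config, truth, z_late, n_late, rng, af, ref, alt)
    return tables_early, tables_late, SimTruth(df=truth, phenotypes=config.phenotypes)


def tables_to_summaries(tables: dict[str, pd.DataFrame]):
    """Convert in-memory canonical tables to PhenotypeSummary objects."""
    from .io import PhenotypeSummary

    out = []
    for name, tab in tables.items():
        out.append(
            PhenotypeSummary(
                phenotype=name,
                table=pd.DataFrame(
                    {
                        "snp_id": tab["snp"].astype(str),
                        "chrom": tab["chr"].astype(str),
                        "pos": tab["bp"].astype(np.int64),
                        "allele_ref": tab["ref"],
                        "allele_alt": tab["alt"],
                        "maf": tab["af"].astype(float),
                        "z": (tab["beta"] / tab["se"]).astype(float),
                        "n": tab["n"].astype(float),
                        "pvalue": tab["pvalue"].astype(float),
                    }
                ),
            )
        )
    return out
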
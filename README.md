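# mvgwas

Bayesian multivariate association analysis of GWAS summary statistics.

Most genome-wide association studies measure several closely related
phenotypes on (largely) the same samples — blood lipid fractions,
anthropometric traits, red-blood-cell indices — yet analyse each phenotype
separately. `mvgwas` reanalyses the released per-phenotype summary
statistics *jointly*: it scores every SNP against all multivariate
association models at once and can thereby detect loci whose evidence is
spread across phenotypes, none of which reaches genome-wide significance on
its own.

## The method

For `d` phenotypes, each SNP-level model γ assigns every phenotype to one
of three categories: **U**nassociated, **D**irectly associated, or
**I**ndirectly associated (the association vanishes after conditioning on
the directly associated phenotypes). There are `3^d` such assignments,
enumerated exhaustively. Writing `z` for the SNP's vector of signed
Z-scores and `R` for their correlation under the null (estimated from
empirically null SNPs — it captures the noise correlation induced by
sample overlap), each model's support is a Bayes factor against the global
null `z ~ N(0, R)`:

    BF_γ(z) = N(z_D; m, Σ + σ² diag(n_D)) / N(z_D; m, Σ),
    m = R_DU R_UU⁻¹ z_U,   Σ = R_DD − R_DU R_UU⁻¹ R_UD

where each directly associated phenotype's standardized effect has an
independent `N(0, σ²)` prior that shifts its Z-score by `√n · effect`, and
the indirectly associated phenotypes' factor cancels. The overall evidence
against the null is the weighted average over the non-null models and a
grid of prior scales σ,

    BF_av := Σ_{γ,σ} w_{γ,σ} · BF_{γ,σ}

with weights `w` learned by empirical Bayes (EM) from a training set of
previously reported univariate associations. Downstream, the package

* sets the multivariate significance threshold at the smallest `BF_av`
  among the previous univariate hits,
* prunes hits by physical distance (500 kb by default) and classifies
  **new multivariate associations** (significant, not previously reported,
  and at least 500 kb from every previous hit),
* compares relaxed univariate thresholds with the multivariate ranking,
  finds unreported univariate hits, and evaluates replication of new hits
  in a later data release (within-50 kb overlap, improvement of the minimum
  univariate p at the same SNP),
* reports per-SNP model posteriors and per-phenotype probabilities of the
  U/D/I categories, with "confident" calls at probability > 0.95.

A full synthetic-data generator (`mvgwas.simulate`) produces summary
statistics with exactly this structure, including overlapping-sample
two-release designs, for testing and power studies.

## Worked example

Simulate a 3-phenotype study of 8 000 SNPs on 50 000 samples (93% null
SNPs, 5% associated with all phenotypes, 2% with one direct and one
indirect association), scan it, and classify new hits:

```python
import numpy as np
import mvgwas as mg

r = np.full((3, 3), 0.3); np.fill_diagonal(r, 1.0)
config = mg.SimConfig(
    d=3, m=8000, r_true=r, n=np.full(3, 50_000.0),
    components=[mg.SimComponent((0, 0, 0), 0.02, 0.93),
                mg.SimComponent((1, 1, 1), 0.02, 0.05),
                mg.SimComponent((1, 0, 2), 0.04, 0.02)],
    seed=71, swap_fraction=0.3)
tables, truth = mg.simulate_panel(config)

model = mg.MultiPhenotypeScan.from_tables(
    mg.tables_to_summaries(tables), orient_to="pheno1", maf_min=0.01)
panel = model.panel
min_p = panel.min_p
previous = [s for s in truth.nonnull_ids()
            if s in min_p.index and min_p[s] <= 5e-8]   # "previous univariate hits"
results = model.fit(training_snps=previous)
print(results.summary(top=5))

prev = mg.PreviousHits.from_ids(panel, previous, univariate_threshold=5e-8)
print(f"threshold: log10 BF_av > {results.significance_threshold(prev):.2f}")
hits = results.classify(prev)
print(f"new multivariate associations: {hits.counts['new_multivariate']}")
```

Output:

```
Multivariate association scan
================================================================
phenotypes (3): pheno1, pheno2, pheno3
SNPs: 8000; models: 27; prior scales: [0.05, 0.1, 0.2, 0.4]
null correlation from 6581 empirically null SNPs (|z| < 2.0)

Null Z-score correlation:
        pheno1  pheno2  pheno3
pheno1   1.000   0.218   0.246
pheno2   0.218   1.000   0.226
pheno3   0.246   0.226   1.000

Model weights (EM on 302 training SNPs, 811 iterations, converged=True):
1 1 1    0.4101
1 0 2    0.2897
1 1 0    0.0959
2 1 1    0.0577
1 0 1    0.0534

Top 5 SNPs by log10 BF_av:
rs3696    103.643
rs582     100.267
rs3984     89.331
rs5908     87.613
rs6258     85.467

threshold: log10 BF_av > 4.45
new multivariate associations: 35
```

Reading this: the null correlation (~0.22–0.25) reflects the overlapping
samples; the learned weights concentrate on the two model shapes actually
present in the simulation (`1 1 1` all-direct, `1 0 2` direct/indirect,
rendered with the 0/1/2 = U/D/I code convention); the significance
threshold is the smallest `log10 BF_av` among the 302 univariate-significant
training SNPs; and 35 further loci — all truly associated in this
simulation — exceed it while lying more than 500 kb from every previous
hit.

The same pipeline is available from the shell:

```sh
mvgwas simulate --config sim.yaml --seed 1 --out sim/
mvgwas merge sim/pheno1.tsv sim/pheno2.tsv sim/pheno3.tsv \
    --orient-to pheno1 --out merged/
mvgwas scan merged/panel.tsv --training-snps train.txt --out scan/
mvgwas classify scan/results.tsv --panel merged/panel.tsv \
    --previous-hits prev.tsv --out hits/
mvgwas replicate hits/hits.tsv --panel-early merged/panel.tsv \
    --panel-late merged_late/panel.tsv --out replication/
```

Every command writes a JSON run manifest (config hash, input digests,
seeds, thresholds, record counts) next to its outputs.

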
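# mtgblup

Single-trait vs multi-trait GBLUP genomic prediction on simulated
breeding populations, with AI-REML variance components.

In genomic selection, breeding candidates are ranked by genomic
estimated breeding values (GEBVs) predicted from a phenotyped,
genotyped reference population. Conventional practice models each trait
separately; a multi-trait model exploits the genetic correlation
between traits to borrow information across them. Whether that extra
modeling effort pays off — and for which heritabilities, genetic
correlations and reference sizes — is the question this package lets
you study by simulation, end to end:

1. **Founder genomes** — phased diploid SNP haplotypes with tunable,
   geometrically decaying linkage disequilibrium (a first-order Markov
   copy process), plus PLINK bed/bim/fam and ped/map I/O and the
   standard genotype QC cascade (call rates, MAF, Hardy–Weinberg exact
   test).
2. **Meiosis** — an F1 generation under a 1:24 sire:dam design with 12
   offspring per dam: 4–6 crossovers per chromosome per gamete, no
   mutation; candidates sampled from the F1.
3. **Correlated traits** — pairs of traits controlled by 500 LD-matched
   QTL pairs carrying *identical* gamma(0.4, 2/3) signed effects, so
   the genetic correlation equals the signed dosage correlation of the
   pairs; heritability set through V_e = V_g (1 − h²)/h².
4. **Models** — single-trait GBLUP `y = 1u + Zg + e`, `g ~ N(0, G σ²ₐ)`,
   and the stacked bivariate model with `g ~ N(0, M ⊗ G)`,
   `e ~ N(0, R ⊗ I)`, on the VanRaden relationship matrix
   `G = WW′/Σ2pᵢ(1−pᵢ)`. Variance components by average-information
   REML (EM fallback, guaranteed ascent), run in the eigenbasis of the
   reference GRM block so each iteration is O(n).
5. **Experiments** — scenario drivers that cross h² ∈ {0.1, 0.3, 0.5}
   with r_g ∈ {0.2, 0.5, 0.8} and reference sizes, score accuracy as
   the squared correlation between GEBV and true breeding value over
   the candidates, and summarize the multi-minus-single gain.

See `docs/methods.md` for the models, algorithms and the honest
account of what desk-scale simulation does and does not reproduce.

## Worked example

```python
import numpy as np
import mtgblup as mg

panel = mg.simulate_founders(1000, n_chrom=2, snps_per_chrom=1000, seed=11)
ta, tb, pairs = mg.simulate_trait_pair(
    panel, mg.TraitSpec(h2=0.3), mg.TraitSpec(h2=0.3), target_r=0.5, seed=12
)
print("realized rg:", round(float(np.corrcoef(ta.tbv, tb.tbv)[0, 1]), 3))

grm = mg.compute_grm(panel.dosages())
res = mg.fit_multi(ta.phenotype, tb.phenotype, list(grm.ids), grm)
print(res.summary())
```

```
realized rg: 0.597
Bivariate GBLUP (AI-REML)
====================================================
n phenotyped                                1000
n in GRM                                    1000
status                                 converged
iterations                                    16
restricted logL                       -6254.0107
----------------------------------------------------
additive M    [[   59.4487    39.8208]
               [   39.8208    48.7494]]
residual R    [[  182.7380   -11.6620]
               [  -11.6620   146.8005]]
h^2 trait 1                               0.2455
h^2 trait 2                               0.2493
genetic correlation                       0.7397  (se 0.1014)
```

The trait pair was simulated at heritability 0.3 and a genetic
correlation target of 0.5; this draw realized 0.597 (the per-draw
spread of the LD-paired construction is real — see the methods note).
The bivariate REML fit recovers heritabilities near 0.25 and a genetic
correlation of 0.74 ± 0.10 for this dataset; `res.blup.gebv` holds the
GEBVs for every individual in the GRM.

A reduced scenario cell — five replicates of the high-heritability,
high-correlation setting at a reference size of 600 with 500 F1
candidates:

```python
cfg = mg.ScenarioConfig(ref_sizes=(600,), n_replicates=5, n_candidates=500,
                        h2_levels=(0.5,), rg_levels=(0.8,), master_seed=42)
summary = mg.summarize(mg.run_scenario1(cfg), average_traits=True)
```

```
          cell  n_ref  model  mean_accuracy  sd_accuracy  improvement
h0.5/0.5_rg0.8    600  multi         0.6819       0.0782       0.0521
h0.5/0.5_rg0.8    600 single         0.6298       0.0736       0.0521
```

Here the bivariate model beats the single-trait model by 5.2 accuracy
points on average across the paired replicates.

The same experiments are available from the shell:

```sh
mtgblup simulate-founders --n 1000 founders     # writes founders.bed/.bim/.fam
mtgblup scenario1 --config cfg.yaml --out s1.tsv
mtgblup summarize --average-traits s1.tsv
```

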
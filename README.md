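# chromdyn

Chromatin dynamics over a stimulation time course, for regulatory
genomicists working with multi-omic CD4+ T-cell activation data. The
package links three layers measured at six time points (0, 20, 60, 120,
240 and 1440 minutes after stimulation) — ATAC-seq chromatin
accessibility, promoter-capture Hi-C interactions and nascent gene
expression — and carries GWAS summary statistics through fine-mapping to
prioritised (SNP, peak, gene) hypotheses. A synthetic-data generator with
known ground truth stands in for deposited sequencing data, so the whole
pipeline runs on a laptop and every stage can be scored against truth.

## What it computes

**Dynamic vs static time courses.** Each feature's counts are fitted with
two zero-mean Gaussian-process regressions on the log2(1 + minutes) axis:
an RBF-plus-white-noise kernel (dynamic, hyperparameters σ_f², ℓ, σ_n²)
and a pure white-noise kernel (static, σ_n²). Model selection uses

    BIC = k ln(n) − 2 ln(L̂)

(smaller is favoured; k = 3 vs 1, n = replicates × time points) and a more
stringent likelihood-ratio test LR = 2(ln L̂_RBF − ln L̂_static) referred to
χ²(1) at α = 0.05.

**Temporal archetype clustering.** Peaks passing an inclusive LR > 1 cut
and lying outside strand-aware promoter windows ([TSS − 1000, TSS + 500])
are clustered with a Gaussian-process mixture (EM; cluster means carry an
RBF prior), recovering shapes such as monotone up/down, transient and
late responses.

**Peak–interaction–gene links.** Interactions with a CHiCAGO-like score
> 5 at ≥ 1 time point and genes with ≥ 10 total counts in every replicate
are joined: a peak inside an otherEnd fragment links to every bait that
fragment contacts and to each gene on that bait. Pearson correlations of
the three replicate-averaged series are stratified by bait–otherEnd
distance (< 200 kb up to 5 Mb) and tested against a random-triplet
background with a two-sided Wilcoxon rank-sum test.

**Fine-mapping.** Per SNP, Wakefield's approximate Bayes factor

    ABF = sqrt(V/(V+ω)) · exp(ω β² / (2V(V+ω))),  ω = 0.04

with posteriors normalised per locus and 99% credible sets formed by the
ranked cumulative-posterior rule (computed in log space).

**Prioritisation and structure.** Credible or LD-expanded (r² ≥ 0.8) SNPs
are intersected with peaks (0-based half-open), assigned genes through
links whose three correlations all reach 0.5, and classified by A/B
compartment membership over time. TAD tracks are compared by 90%
reciprocal overlap, compartment eigen-scores by correlation-versus-Δt
trend, and contact matrices by a simplified stratum-adjusted correlation
coefficient (SCC).

## Worked example

```python
import numpy as np
from chromdyn import simulate_genome, simulate_timecourses
from chromdyn.dynamics import classify_profiles
from chromdyn.finemap import credible_set
from chromdyn import simulate_gwas_locus

sc = simulate_genome(length=5_000_000, n_fragments=800, n_genes=20,
                     n_peaks=200, seed=11)
sim = simulate_timecourses(sc, dyn_fraction=0.5, replicates=3, seed=11)
calls = classify_profiles(sim["peak_counts"])
print(f"{int(calls.dynamic_by_lr.sum())}/{len(calls)} peaks dynamic by LR")

gwas, ld = simulate_gwas_locus(sc, effect=(0.25, 0.05), n_snps=50, seed=3)
cs = credible_set(gwas)
print(f"99% credible set: {cs.size} of {len(gwas)} SNPs; "
      f"causal included: {gwas.attrs['causal_snp'] in cs.members}")
```

prints

```
85/200 peaks dynamic by LR
99% credible set: 2 of 50 SNPs; causal included: True
```

i.e. with half the peaks simulated as dynamic, the conservative LR rule
recovers most of them, and a strong association (β = 0.25, se = 0.05)
narrows 50 SNPs to a 2-SNP credible set containing the causal variant.

The same stages are available from a shell:

```bash
chromdyn simulate --outdir demo --seed 11
chromdyn dynamics --counts demo/peak_counts.tsv --out demo/calls.tsv
chromdyn run-all --outdir demo_full --seed 11
```

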
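# netdms

Network-assisted analysis of genome-wide association studies (GWAS).

Single-marker GWAS of polygenic traits such as schizophrenia rarely yields
genome-wide-significant hits, yet many genes carry weak-to-moderate signal.
`netdms` searches for that signal jointly: gene-level association scores are
overlaid on a protein–protein interaction (PPI) network and dense, high-
scoring modules are grown greedily from every gene. Modules are then vetted
against layered null models, cross-validated between two studies in both
directions, merged into a consensus subnetwork, and followed up with
independent replication, SNP-level meta-analysis and pathway enrichment.

The package is aimed at statistical geneticists who have per-study GWAS
summary statistics (SNP → beta, SE, P), a gene annotation table and a PPI
edge list, and who want a reproducible, fully scriptable implementation of
the dense-module-search workflow — plus a synthetic-data generator with
known ground truth so every stage can be exercised and calibrated without
access-controlled genotype data.

## The model

Each gene *i* receives a gene-wise P value — the minimum P over SNPs within
the gene body ± 20 kb — and the node weight

    z_i = Φ⁻¹(1 − p_i),

Φ the standard-normal CDF. A module *m* with *k* member genes is scored

    Z_m = Σ_{i∈m} z_i / √k,

which is N(0, 1) for a fixed gene set under the uniform-P null. From every
seed gene the greedy search repeatedly adds, from the neighborhood within
hop distance *d* = 2 of the current module, the candidate maximising the
new score Z_{m+1}, accepting it iff `Z_{m+1} > Z_m·(1 + r)` with expansion
rate *r* = 0.1.

Each candidate module gets five significance layers:

| P value | Null model |
|---|---|
| `P(Z_m)` | empirical null N(δ, σ²) fitted to the bulk of all module scores (Efron-style central matching) |
| `P_GL`, `P_nSNPs` | resampled gene sets matching the module's gene-length / SNP-count decile profile (absorbs min-P confounding) |
| `P_topo` | resampled gene sets matching the module's node-degree bins [0,4], (4,16], (16,64], (64,∞) (absorbs hub bias) |
| `P_emp` | the fixed member set re-scored under phenotype-permutation gene-wise P matrices |

A module survives a discovery study iff all five are < 0.05, and survives
the evaluation study iff its re-scored `P(Z_m(eval))` and `P_emp(eval)` are
both < 0.05. Running both study orders and merging the survivors gives the
consensus subnetwork. SNP-level follow-up combines per-study effects by
inverse-variance fixed-effects meta-analysis (`β_meta = Σw_iβ_i/Σw_i`,
`w_i = 1/se_i²`, genomic control `se ← se·√λ`) with Cochran-Q/I²
heterogeneity filtering, and consensus genes are tested for pathway
over-representation by the hypergeometric tail with Bonferroni/BH
correction and an empirical resampling layer.

## Worked example

Simulate two correlated GWAS "studies" with a planted 10-gene module
(effect 3.0 on the SNP z-scale, shared by both studies) on a 1000-gene
scale-free network, then run the full bi-directional pipeline:

```python
from netdms import (PipelineParams, SimulationSpec, recovery_metrics,
                    run_bidirectional, simulate_gwas, simulate_network,
                    simulate_permutations)

spec = SimulationSpec(seed=0)              # the "default" preset
edges = simulate_network(spec)             # 1995 edges, 1000 genes
sim = simulate_gwas(spec, edges)           # 15828 SNPs per study
perms = {f"study{i+1}": simulate_permutations(spec, sim, i) for i in range(2)}
snps = {f"study{i+1}": sim.studies[i] for i in range(2)}

res = run_bidirectional(snps, sim.annotation, edges, perms, PipelineParams(seed=1))
for key, direction in res.directions.items():
    print(key, direction.funnel)
print("consensus:", len(res.consensus.genes), "genes")
print(recovery_metrics(res.consensus.genes, sim.truth["planted_genes"]))
```

prints

```
study1->study2 {'modules': 1000, 'pass_combinatorial': 12, 'pass_zm_eval': 12, 'final': 12}
study2->study1 {'modules': 1000, 'pass_combinatorial': 34, 'pass_zm_eval': 13, 'final': 12}
consensus: 12 genes
{'recall': 1.0, 'precision': 0.8333333333333334, 'n_consensus': 12, 'n_planted': 10}
```

Read bottom-up: 1000 modules are grown per direction (one per seed gene);
12 and 34 pass the five discovery criteria; 12 per direction also pass both
evaluation criteria in the other study. Their merged union holds 12 genes:
all 10 planted genes plus two bystanders recruited through their
interactions — recall 1.0, precision 0.83 against the known truth.

The same flow is available from the shell:

```bash
netdms simulate --preset default --seed 0 --out study/
netdms pipeline --study-dir study/ --seed 1 --out run/
netdms meta --study study/study1.tsv --study study/study2.tsv \
    --lam 1.04 --lam 1.04 --out meta/
```

Every subcommand writes TSV outputs plus a `manifest.json` recording input
checksums, parameters and seeds; stochastic stages refuse to run without a
seed. Exit codes: 0 ok, 2 configuration error, 3 data error.

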
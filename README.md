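# longicore

Mining longevity-associated core gut microbiota from 16S OTU tables.

Cohort studies of long-lived populations ask which gut taxa travel with the
longevity phenotype. Simple differential-abundance screens answer one taxon
at a time and ignore that gut microbes act in communities. `longicore`
implements the network-first alternative: build a **weighted co-abundance
network** over OTUs, find the module whose summary profile correlates with
the binary longevity trait, mine that module for **hub taxa**, cross-check
the hubs with a **random-forest** discrimination of longevity groups, and
keep the genera that survive both filters. The package also covers the two
validation arms that typically follow such a screen: qPCR relative
expression of candidate genera, and a PCA-based composite score for ranking
candidate probiotic strains.

## The method

Starting from a samples × OTUs count table, per-OTU MAD filtering keeps the
most variable half, then for a soft threshold β the adjacency is

    a_ij = |cor(x_i, x_j)|^β        (unsigned; signed variant available)

with β chosen as the smallest grid power whose connectivity distribution
fits a scale-free law (signed R² ≥ 0.85). Pairwise topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

feeds average-linkage clustering of 1 − TOM; a dynamic branch cut (minimum
module size 25, split sensitivity 0–4, unassignable OTUs grey) yields
modules, merged when their eigengenes are closer than 0.25. Each module is
summarised by its **eigengene** (first principal component of the
standardized member profiles); Pearson correlation of eigengenes with the
longevity indicator, with t-distribution p-values, selects significant
modules (p < 0.05). Within a selected module, the TOM-weighted network is
exported and nodes are ranked by **MNC** (maximal neighbourhood component —
the size of the largest connected component among a node's neighbours).
Genus-level relative abundances of the module's genera are fed to a
regression-mode random forest (500 trees, depth 7) with out-of-bag
permutation (ΔMSE) and node-purity importances; the **core genera** are the
intersection of the top-10 hub genera with both top-10 importance lists.

Strain scoring: three probiotic indicators per strain (gastrointestinal
survival %, self-aggregation %, hydrophobicity %) are z-standardized; a KMO
statistic > 0.6 gates PCA adequacy; components are retained to ≥ 90%
cumulative explained variance and each strain receives

    F_sum = Σ_c (v_c / M) Σ_i w_ic X_i

with `w` the component loadings, `v_c` the explained-variance fractions and
`M` their cumulative sum. qPCR fold changes use the standard 2^−ΔΔCt
convention against a total-bacteria reference gene and a control group.

Because cohort sequencing data of this kind are rarely depositable, the
package ships a first-class synthetic-data generator
(`longicore.synthetic`) that plants co-abundance modules, a trait-linked
module, nameable genera and known effect sizes, so every stage is testable
against ground truth.

## Worked example

```python
import json
from longicore import SyntheticDesign, generate_abundance
from longicore.pipeline import PipelineConfig, run_discovery

design = SyntheticDesign(n_samples=135, n_otus=800,
                         modules=((50, 0.8), (40, 0.7)),
                         trait_module_index=0, trait_effect=0.5, seed=7)
table, traits, truth = generate_abundance(design)
report = run_discovery(table, traits, PipelineConfig(seed=7))
print(json.dumps(report.summary(), indent=2))
```

prints (abridged):

```json
{
  "seed": 7,
  "chosen_power": 3.0,
  "n_modules": 2,
  "module_sizes": {"grey": 331, "turquoise": 36, "blue": 33},
  "selected_modules": [
    {"module": "turquoise", "r": 0.397, "p": 1.84e-06}
  ],
  "findings": [
    {
      "module": "turquoise",
      "n_nodes": 36,
      "n_edges": 108,
      "core_genera": ["Alistipes", "Lactobacillus", "Blautia",
                      "Lachnospiraceae NK4A136 group", "Bacteroides"]
    }
  ]
}
```

The generator planted a 50-OTU module (nominal loading 0.8) whose latent
factor correlates 0.5 with the binary longevity flag, annotated to five
genera. The pipeline chose β = 3, recovered the planted block as the
`turquoise` module (r = 0.40, p = 1.8·10⁻⁶ against the trait), exported its
TOM network (36 nodes, 108 edges), and the hub ∩ random-forest intersection
returned exactly the five planted genera.

The same chain is available from the shell:

```bash
longicore simulate --n-samples 135 --n-otus 800 --seed 7 --out sim/
longicore discover --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
    --traits sim/traits.tsv --seed 7 --out run/
longicore score-strains --table strains.tsv --out scores/
longicore qpcr --ct ct.tsv --control control --out qpcr/
```

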
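# ffl-dynamics

Dynamic miRNA–TF feed-forward-loop (FFL) co-regulatory network analysis of
staged case/control expression data, with a built-in synthetic-data generator
so every stage of the pipeline is testable end to end without external
downloads.

## The scientific problem

Myocardial infarction (MI) progresses through acute, subacute and chronic
phases, and the genes, microRNAs and transcription factors (TFs) driving each
phase differ. Given peripheral-blood expression profiles of cases sampled at
three stages against a shared control group, plus curated catalogs of typed
regulatory interactions (miRNA→gene, miRNA→TF, TF→gene, TF→miRNA), this
package reconstructs how the co-regulatory circuitry changes over disease
progression and derives a small diagnostic gene panel from it. It is aimed at
systems-biology analysts working with staged microarray/RNA cohorts and
curated interaction databases.

The pipeline:

1. **Preprocess** — drop probes never reaching log₂ intensity 7, drop
   ambiguous (multi-gene) and unannotated probes, average probes per gene,
   keep protein-coding genes.
2. **Differential expression** — per stage, cases vs the shared controls with
   an empirical-Bayes moderated t: the gene variance s²_g (df d_g) is shrunk
   toward a prior s₀² with prior df d₀ estimated by moment-matching,

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t̃_g = Δ̄_g / (s̃_g·√(1/n₁ + 1/n₂)),  p from t on d_g + d₀ df.

   SDE genes: BH-adjusted p < 0.001 and linear fold change 2^|Δ̄| > 1.2.
3. **Profile clustering** — standardized (baseline, stage 1..3) log₂FC
   profiles, city-block distance, complete linkage, cut at k = 2.
4. **Enrichment** — one-sided hypergeometric upper tail
   P(X ≥ x) = Σᵢ C(K,i)·C(N−K,n−i)/C(N,n) over subpathway gene sets,
   BH at 0.05, keeping only the minimum-p subpathway per parent pathway.
5. **FFL networks** — enumerate all motifs (m, t, g) with mutual m↔t
   regulation and a shared target g (t and g SDE; miRNAs unfiltered); merge
   them per stage into a typed directed network ("inh" from miRNAs, "reg"
   from TFs); score nodes by degree and betweenness
   BC_i = Σ_{s≠i≠t} σ_i(s,t)/σ(s,t) over ordered pairs; call top-degree hubs.
6. **Dynamics** — exact-subset (Venn) decomposition of nodes and edges across
   stages, stage-/transition-specific subnetworks, containment checks.
7. **Classification** — Gaussian Naive Bayes over a small gene panel,
   leave-one-out cross-validated ROC AUC for diagnosis and recurrence.

A synthetic-data module generates all inputs with known ground truth (planted
DE genes with stage-decaying effects, planted FFLs among decoy edges, planted
enriched gene sets, a planted two-gene class signal), so every downstream
stage has a recovery test.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
cohort (2000 genes, 14 controls vs 28 cases × 3 stages, 10 planted FFLs among
500 decoy edges):

```bash
cd analysis
python 01_simulate_cohort.py --seed 0
python 02_preprocess.py
python 03_differential_expression.py
...
python 08_biomarker_classifier.py
```

Selected output (seed 0):

```
SDE counts per stage: {1: 200, 2: 119, 3: 10} (union 200, shared 10)
  stage 1: recall of planted DE 0.995, false-discovery proportion 0.005
clustered 100 top SDE genes into 2 profile clusters:
  cluster 1: 47 genes, pattern down-then-recover, stage means [-1.23, -0.39, 0.12]
  cluster 2: 53 genes, pattern up-then-decay,     stage means [1.22, 0.39, -0.12]
stage 1: 10 motifs -> 30 nodes / 40 edges
planted loops recovered: 10 of 10; false motifs at any stage: 0
chronic network contained in acute+subacute union: nodes=True, edges=True
panel ['G0120', 'G0213']:
  diagnosis LOOCV AUC:  0.965 (single genes: G0120=0.903, G0213=0.882)
  recurrence LOOCV AUC: 0.872
```

Reading the numbers: the planted 200 DE genes are recovered almost perfectly
at the acute stage, and the geometric decay of the planted effect makes the
SDE sets shrink over stages, so the chronic network ends up nested inside the
earlier ones. Motif enumeration returns exactly the planted loops despite the
500 decoy edges. The planted two-gene panel (the TF and target of one planted
loop) separates cases from controls at LOOCV AUC 0.965 and carries the
weaker planted recurrence signal at 0.872.

The same pipeline runs from one config via the CLI:

```bash
ffl-dynamics simulate --outdir data --seed 0
ffl-dynamics run-all --config pipeline.yaml
```

or stage by stage (`preprocess`, `diffexpr`, `cluster`, `enrich`, `network`,
`compare`, `classify`).

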
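# ganglimark

Consensus negative-binomial marker discovery for bulk RNA-seq of the chick
cranial sensory ganglia — or any small-group expression experiment where the
question is "which genes mark this group, or this combination of groups,
with per-sample certainty?"

The cranial sensory ganglia (trigeminal ophthalmic `Top`, trigeminal
maxillomandibular `Tmm`, vestibulo-acoustic `VA`, petrosal `P`, nodose `N`)
house the cell bodies of somatosensory (`Top`, `Tmm`, `VA`) and
viscerosensory (`P`, `N`) neurons.  Starting from a gene × sample count
matrix, `ganglimark` finds high-confidence markers of individual ganglia and
of ganglion groups, and characterises the transcriptional structure that
those markers encode.

## The method

For every bipartition of the ganglion labels into a *high* and a *low* set
(all 2⁵ − 2 = 30 combinations for five ganglia), a gene is called
differentially expressed only when **two independent NB engines agree**:

1. a *conditional exact test*: with counts rescaled to a common effective
   library, group sums of i.i.d. NB(μ, α) counts share the NB success
   probability, so conditioning the high-group sum on the total `T` leaves a
   negative hypergeometric law free of the nuisance mean,
   `P(x | T) ∝ C(x + n_h/α − 1, x) · C(T − x + n_l/α − 1, T − x)`; the
   two-sided p sums all splits no more likely than the observed one;
2. an *NB log-link GLM likelihood-ratio test* of the group term, with log
   size-factor offsets, fitted by Fisher scoring and referred to χ²(1).

Both engines share one dispersion model: per-gene Cox–Reid adjusted profile
maximum likelihood, a parametric trend α(μ) = a₀ + a₁/μ, and log-scale
shrinkage towards the trend.  Each engine's p-values are BH-adjusted and the
**consensus** call requires q ≤ 0.05 from both, with positive log2 fold
change.

A consensus gene becomes a **marker** of a grouping when, in RPKM:

* every high-group sample is ≥ 1.5-fold above every low-group sample
  (`min(high) ≥ 1.5 · max(low)`, the dominance filter), and
* every high-group sample has RPKM ≥ 10.

Genes passing for several groupings are assigned to the most specific one
(smallest high set).  The pipeline also reports PCA of variance-stabilised
expression with a technical-covariate correlation screen (RIN, RNA yield,
sequencing depth), an average-linkage marker dendrogram with multiscale
bootstrap AU/BP node support, and EASE/hypergeometric term enrichment of
the marker panel against the expressed-gene background (> 0.3 RPKM).

A synthetic-data generator reproduces the study design — 5 ganglia × 3
replicates, NB counts with a dispersion–mean trend, tree-structured group
effects `((Top,Tmm),VA) | (N,P)`, planted markers, null covariates — so
every stage is testable end-to-end with known truth and no downloads.

## Worked example

```sh
ganglimark simulate --seed 1 --out sim/
ganglimark run-all --counts sim/counts.tsv --design sim/design.tsv \
    --annot sim/genes.tsv --out run/
```

or, as a library (this is what `analysis/01…06` scripts do stepwise):

```python
from ganglimark.simulate import SimulationConfig, simulate_experiment
from ganglimark.containers import PipelineConfig
from ganglimark.pipeline import run_pipeline

cm, design, annot, truth = simulate_experiment(SimulationConfig(seed=1))
res = run_pipeline(cm, design, annot, PipelineConfig(nboot=100, seed=1))
print(res.marker_summary)
```

prints

```
                n_markers
grouping
N,P|Tmm,Top,VA         30
Tmm,Top,VA|N,P         20
VA|N,P,Tmm,Top         15
N|P,Tmm,Top,VA         10
Tmm,Top|N,P,VA          9
P|N,Tmm,Top,VA          7
Tmm|N,P,Top,VA          5
Top|N,P,Tmm,VA          5
TOTAL                 101
```

— all 101 planted markers recovered, each assigned to its planted grouping
(sensitivity 1.00, empirical FDR 0.00 against the generator's truth table).
The marker dendrogram puts ganglia into the planted topology with AU ≥ 0.99
on the viscerosensory `{N,P}` and somatosensory `{Top,Tmm,VA}` nodes, PC1
separates the two modalities (silhouette 0.97), and all five planted
annotation terms are flagged enriched (q < 0.05) with none spurious.

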
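# swrnet

Network-proximity prioritization of cancer driver genes from
homeostatic-process gene sets.

Oncogenesis co-opts the molecular programs of three conserved homeostatic
processes — stress response (SR), wound healing (WH) and regeneration (RG).
`swrnet` operationalizes that observation: it builds consensus gene sets for
the three processes from cross-species differential-expression experiments,
measures how close every gene sits to those sets in a protein-interaction
network, and trains a classifier on those proximities to rank driver-gene
candidates genome-wide. It is aimed at computational biologists who have a
STRING-style edge list, gene sets (GMT), and driver/benchmark gene lists,
and want a reproducible, seed-controlled prioritization pipeline with
defensible null models.

## The method

For a gene *g* and a gene set *S*, the proximity feature is

    f_S(g) = |{ s in S' : dist(g, s) <= d }| / |S'| ,    S' = (S ∩ network) \ {g}

where dist is the hop distance in the interaction graph (edges kept at
combined score >= 400) and *d* = 2, the median pairwise shortest-path
distance between two random genes. The nine sets (SR/WH/RG × UP/DOWN plus
three direction-agnostic database sets) give nine features per gene. A
classifier (ExtraTrees by default) is trained with known drivers as
positives and degree-matched non-drivers as negatives (19:1, so the
precision–recall baseline is 0.05), evaluated by stratified five-fold
cross-validation with inner grid search, and compared across model families
with DeLong's test for correlated ROC curves.

Whether a gene *set* is unusually close to another is tested against a
degree-matched background with a one-sided Wilcoxon rank-sum test; the
effect size is log2 of the ratio of mean distances (negative = closer).
Overlap questions use the one-sided Fisher exact test with
Benjamini–Hochberg adjustment.

A seeded synthetic generator plants all of this structure — background
graph, nine modules, drivers with elevated module attachment, decoy hubs —
so the entire pipeline is testable without any downloads.

## Worked example

Everything below runs from scratch in about a minute on a synthetic
benchmark (800 genes, nine planted modules of 15, 40 planted drivers):

```sh
swrnet simulate --out-dir demo --n-genes 800 --n-drivers 40 --n-decoys 100 \
    --set-size 15 --p-bg 0.006 --p-signal 0.15 --seed 7
swrnet features --network demo/edges.tsv --gmt demo/sets.gmt \
    --out demo/features.tsv
swrnet train --features demo/features.tsv --positives demo/drivers.txt \
    --network demo/edges.tsv --ratio 5 --seed 7 \
    --model-out demo/model.joblib --metrics-out demo/metrics.json
swrnet score --model demo/model.joblib --features demo/features.tsv \
    --out demo/scores.tsv
swrnet select --scores demo/scores.tsv --exclude demo/drivers.txt --n 50 \
    --out-high demo/high.txt --out-low demo/low.txt
```

which prints, step by step:

```
797 x 9 feature matrix -> demo/features.tsv
CV AUROC=0.872 AUPRC=0.554 (prevalence 0.167) -> demo/model.joblib
797 gene scores -> demo/scores.tsv
50 high / 50 low candidates
```

797 of the 800 genes had at least one retained edge. The cross-validated
AUROC of 0.872 says the nine proximity fractions rank held-out planted
drivers well above degree-matched negatives; the AUPRC of 0.554 is far
above its 0.167 prevalence baseline. `demo/scores.tsv` holds the
deterministic genome-wide ranking (score descending, ties by gene
identifier), and the high/low lists are the top and bottom 50 after
excluding the known drivers.

The proximity test confirms the planted geometry. Appending the driver list
as an extra set to the GMT and testing it against one module:

```sh
swrnet proximity-test --network demo/edges.tsv --gmt demo/sets+drivers.gmt \
    --x DRIVERS --y SR-UP --max-tolerance 1 --seed 7 --out demo/prox.json
# p=3.039e-06 log2FC=-0.1217
```

drivers are significantly closer to the SR-UP module than degree-matched
(±1) controls, with mean distances about 8% shorter (2^-0.12). Testing one
planted module against an unrelated one instead gives p = 0.37 — disjoint
modules are not proximal, as they should not be.

Every output file embeds the fully resolved run configuration as a JSON
header, and every random choice is seeded, so re-running any command
reproduces its output byte for byte.

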
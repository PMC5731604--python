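# modsep

Network-based disease-module separation and prediction of missing common
genes for comorbid disease pairs on the protein–protein interactome.

## The problem

Two diseases that frequently co-occur (high comorbidity, relative risk
RR ≥ 1) tend to share part of their genetic basis. On the interactome —
the graph whose nodes are genes/proteins and whose edges are physical
interactions — the genes associated with each disease form a *disease
module*, and how far two modules sit from each other is measured by the
separation

```
S_AB = <d_AB> − (<d_AA> + <d_BB>) / 2
```

where `<d_AA>` averages, for every gene of disease A, the shortest-path
distance to its nearest other A gene; `<d_BB>` likewise for B; and `<d_AB>`
averages, for every gene of A, the distance to its nearest B gene and vice
versa (a gene associated with both diseases contributes 0 from each side).
Negative S_AB means the two modules overlap topologically.

Disease–gene association data are incomplete. For a comorbid pair whose
S_AB is unexpectedly large, this package searches for **missing common
genes**: candidates x, taken from the genes distinctly associated with
exactly one disease of the pair, are re-classified as shared, and the one
that minimises the resulting separation is the prediction:

```
x* = argmin S_AB[+x],    x ∈ (G_A ∪ G_B) − (G_A ∩ G_B)
s(x) = S_AB − S_AB[+x]          (prediction score; larger = better)
```

The search is exhaustive; a k-subset variant minimises `S_AB[+X]` over all
size-k candidate subsets, and a sequential mode recovers several genes one
at a time. Cross-validation (hold out known common genes, rank them among
held-out non-common genes, AUROC / Youden threshold / precision / recall,
randomized-common-gene baseline, RR-stratified reporting) and a seeded
synthetic benchmark with planted shared genes are included, so the whole
pipeline runs without any external download.

Intended users: computational biologists doing network medicine —
prioritising candidate shared genes for comorbid disease pairs, or studying
how module separation behaves on incomplete interactomes.

## Worked example

```python
import modsep as m

# a seeded synthetic interactome with one planted comorbid pair
g = m.generate_graph(500, attachment=2, seed=11)
pair = m.plant_pair(g, m.SyntheticConfig(seed=12))

model = m.DiseasePairModel(pair.graph, pair.g_a, pair.g_b,
                           name_a="disease_A", name_b="disease_B")
res = model.fit()            # exhaustive candidate scoring
print(res.summary(top=5))
```

```
        Disease-pair module separation
==========================================================
Disease A: disease_A  (25 genes mapped, 0 dropped)
Disease B: disease_B  (25 genes mapped, 0 dropped)
Method: nearest    Common genes: 8    Jaccard: 0.1905
----------------------------------------------------------
<d_AA>   1.3200   <d_BB>   1.3200   <d_AB>   1.1800
S_AB    -0.1400   excluded: 0+0 unreachable
----------------------------------------------------------
Top 5 candidate missing common genes (of 34):
gene        side         S_AB[+x]        s(x)
g451        B_only        -0.2550      0.1150
g155        A_only        -0.2543      0.1143
g303        A_only        -0.2543      0.1143
g318        B_only        -0.2543      0.1143
g368        B_only        -0.2543      0.1143
==========================================================
```

The pair overlaps (8 common genes, S_AB = −0.14); each candidate row shows
the separation after marking that gene shared and the score s(x). Held-out
recovery for the same pair:

```python
rec = model.cross_validate(seed=0)
print(rec.roc_score, rec.precision, rec.recall)   # 1.0  1.0  1.0
```

i.e. all 8 reserved common genes outrank all 10 held-out non-common genes,
and at the ROC-derived threshold (0.4542) they are recovered with perfect
precision and recall.

The same operations are available from the shell:

```bash
modsep simulate --out bench --n-pairs 10 --seed 1
modsep separation --graph bench/graph.tsv --assoc bench/assoc.tsv \
    --disease-a D0a --disease-b D0b
modsep predict    --graph bench/graph.tsv --assoc bench/assoc.tsv \
    --disease-a D0a --disease-b D0b --top 10
modsep evaluate   --graph bench/graph.tsv --assoc bench/assoc.tsv \
    --pairs bench/pairs.tsv --seed 1 --out-dir results
```

Exit codes: 0 success, 1 usage error, 2 data error. Runs with the same
arguments and seed are byte-identical.

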
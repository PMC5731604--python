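# Methods

## Model

modsep treats the interactome as an undirected, unweighted graph G over
opaque gene identifiers. All distances are shortest-path hop counts from
breadth-first search; interaction confidences and direction are ignored.
For a disease pair (A, B) with gene sets G_A, G_B mapped onto G, the
module separation is

    S_AB = <d_AB> − (<d_AA> + <d_BB>) / 2

with two aggregation methods:

* **nearest** (default): `<d_AA>` averages each A gene's distance to its
  nearest *other* A gene (self excluded); `<d_AB>` averages each A gene's
  distance to its nearest B gene, then each B gene's to its nearest A gene,
  so the denominator is |G_A| + |G_B| and a gene shared by both sets
  contributes 0 once per membership side.
* **all_pair_average** (the weaker comparator S_<AB>): the plain average
  over all unordered within-set pairs, and over all cross pairs (a, b)
  with a ≠ b.

Missing common genes are predicted by exhaustive minimisation of
S_AB[+x] = S(G_A ∪ {x}, G_B ∪ {x}) over the symmetric difference, reported
as the score s(x) = S_AB − S_AB[+x] in descending order; a k-subset
variant enumerates all C(n, k) subsets, and a sequential mode re-ranks
after committing each top gene. The sequential result may differ from the
k-subset optimum: the objective is not separable across genes on a graph.
An optional normalised score s(x)/S_AB is exposed behind a flag and is
undefined (error) when S_AB = 0.

Assumptions worth stating: the interactome is incomplete, so gene sets may
fall in different components; modules are *sets* of genes, not connected
subgraphs (largest-connected-component extraction and a configurable
minimum size/fraction check are provided separately in `graph_io`); and no
statistical significance is attached to S_AB itself — no degree-preserving
randomisation z-scores are computed.

## Degenerate inputs and numerical choices

* Unreachable pairs are excluded from the affected average and the genes
  recorded on the result (`excluded_a`/`excluded_b`); an error is raised
  only when an average would be empty. The identity
  S_AB = <d_AB> − (<d_AA>+<d_BB>)/2 holds to 1e−12 by construction.
* Sets with fewer than two mapped genes per disease are rejected —
  `<d_AA>` is undefined for singletons.
* Tie-breaking is lexicographic on gene id everywhere (rankings, best
  subsets, component extraction), making every result deterministic.
* `best_subset` refuses to start when C(n, k) exceeds a budget
  (2,000,000 by default); no heuristic search is attempted.
* BFS distance maps are cached per source gene and reused across the
  hundreds of candidate evaluations of one pair; the tests assert cached
  and uncached results are identical bit for bit.

## Cross-validation

For each usable pair (at least one common and one non-common gene), up to
10 common genes are reserved as positives and up to 10 non-common genes —
drawn balanced across the two exclusive sides — as negatives, without
replacement from a seeded generator. Every test gene x is scored by
s(x) = S_AB − S_AB[+x] on the reduced working sets; the ranking is compared
with the truth by the rank-based AUROC (Mann–Whitney; tied positive–negative
pairs credited 0.5). A Youden-style threshold — the score at the ROC point
maximising TPR − FPR, ties resolved toward the higher cutoff — yields
precision and recall. The baseline replaces a pair's common genes with an
equal number of uniformly drawn interactome genes outside G_A ∪ G_B,
preserving all set sizes and the graph.

Two hold-out conventions are implemented. **reserve** (default) removes
each positive from *both* working sets and scores it de novo,
S_AB[+x] = S(A ∪ {x}, B ∪ {x}) — the same form the method uses when
proposing genes not yet associated with either disease. **demote** retains
each positive on one uniformly chosen side, which keeps it inside the
single-gene candidate domain of the exhaustive search. Reserve is the
default for a structural reason we verified on the synthetic benchmark: a
demoted common gene remains a member of one working set, and because its
interactions still anchor both disease neighbourhoods, the pair's baseline
cross-distances collapse and every candidate's score flattens — held-out
genes then carry no recoverable signal. Removing positives from both sides
keeps the gap they are supposed to close intact.

The base S_AB in s(x) is computed on the reduced working sets (after the
hold-out), which only shifts all scores of a pair by a constant and leaves
the AUROC unchanged. `--repeats` averages metrics over independent seeded
draws; the default is a single draw. Stratified reports bin pairs by
comorbidity RR ([0,1), [1,2), [2,3), [3,∞); left-closed) and by common-gene
count ([0,5), [5,10), [10,15), [15,∞)); bin standard deviations are
population SDs so a single-record bin reports 0 rather than NaN.

## Synthetic benchmark

The generator's task is to produce pairs on which recovering planted shared
genes is *possible for this score* yet non-trivial, without any real data.

**Substrate.** `generate_graph` grows a preferential-attachment graph
(default 500 nodes, attachment 2) from a small complete core: connected,
sparse, heavy-tailed degrees. It supplies realistic background shortcuts
but carries no disease signal.

**Planting.** Disease structure is planted as *interactions*, the way
community-detection benchmarks plant their communities. Per pair:

* 6 hub genes per disease (`n_hubs`) are chosen among low-degree substrate
  nodes (degree ≤ 4), the two lead hubs at least 4 hops apart;
* every shared gene gets a planted edge to *every* hub of both diseases —
  pleiotropic connector genes binding both diseases' complexes;
* each exclusive gene is wired to one randomly chosen hub of its own
  disease with probability `locality`, otherwise left where it was sampled
  as a scattered associate. Scattered associates mirror real association
  data, where most of a disease's genes fall outside its observed module
  (e.g. a 69-gene disease whose largest connected component has 11).

`locality` ∈ (0,1] is the single compactness knob: higher values put more
genes one hop from a hub, and the mean within-module nearest distance
decreases monotonically with it. Defaults (n_a = n_b = 25, n_shared = 8,
locality = 0.7) give pairs whose S_AB is negative about two-thirds of the
time, reproducing the overlap ↔ negative-separation association, while
pairs planted with no shared genes are always positively separated.

This construction was chosen after a systematic study of alternatives
(membership-only planting on walk-grown modules, with many variants of
module shape and shared-gene placement). The study showed that under
nearest-distance separation the score decomposes as
s(x) = −Δ<d_AB> + ½Δ<d_AA> + ½Δ<d_BB>, and two effects dominate: a gene
close to both modules *dilutes* the within-averages (penalty), while any
member of a compact module, when marked shared, collapses the entire
module's cross-distances at once (reward for the wrong genes). Only genes
that reach many members of *both* modules in one step — hub-connected
shared genes — beat both effects; one-hop stars keep the within-averages
at exactly 1 so the dilution penalty vanishes, and spreading each
disease over several hubs keeps any single exclusive gene from collapsing
too much on its own, which is also what places the randomized baseline
near chance rather than below it. A generator whose shared genes are
merely *labelled* shared, without such connector wiring, produces pairs
on which this objective cannot identify them — an instructive limitation
of the method itself on modules without hub structure.

**Benchmark.** `make_benchmark` plants each pair on its own substrate
(avoiding cross-pair interference from planted edges) and prefixes gene ids
per pair so one graph/associations/pairs file set serves the whole
benchmark; RR metadata are drawn from an exponential with mean 2.0
(spanning all stratification bins) and never influence scoring. All output
is byte-reproducible from the seed.

**What passing tests do and do not show.** The benchmark demonstrates that
the implementation recovers structurally shared genes when modules are
hub-organised and that the all-pair-average variant and the randomized
baseline behave qualitatively as expected (worse, and near chance,
respectively). It does not calibrate absolute performance on real
interactomes, whose modules are noisier, larger and less star-like, and it
contains no literature bias, no false associations, and no weighted or
missing-edge structure.

## Parameters that matter

| parameter | where | default | meaning |
|---|---|---|---|
| method | separation/prediction/evaluation | nearest | distance aggregation (hops) |
| min module size / fraction | graph_io | 2 / 0.0 | module qualification check |
| n_pos, n_neg | evaluation | 10, 10 | held-out genes per pair (if available) |
| holdout | evaluation | reserve | reserve (both sides) vs demote (one side) |
| max_evaluations | prediction | 2,000,000 | subset-search budget (count) |
| n_nodes, attachment | synthetic | 500, 2 | substrate size and density |
| n_a, n_b, n_shared | synthetic | 25, 25, 8 | planted set sizes |
| locality | synthetic | 0.7 | clustered fraction / compactness, (0,1] |
| n_hubs | synthetic | 6 | hub complexes per disease |
| rr_scale | synthetic | 2.0 | mean of exponential RR metadata |

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on: the 5-node path graph
(worked examples); 200 random connected graphs of ≤ 30 nodes against a
brute-force oracle built on full distance matrices (agreement to 1e−12);
100 random instances for search-mode consistency; 1,000 random score/label
vectors for the AUROC; and the 50-pair benchmark at the defaults above
with 10+10 held-out genes per pair. The full suite completes in well under
a minute on one CPU.

## Known limitations

* No identifier translation, no edge weights/confidences, no fetching of
  public interactomes.
* No heuristic search for the k-subset problem beyond the sequential
  procedure; large candidate sets with large k are refused, not
  approximated.
* No significance testing of S_AB against degree-preserving null models.
* RR values are metadata for stratification only; the package never
  computes comorbidity from claims data.
* The synthetic generator makes no attempt to fit the degree sequence or
  clustering of the real human interactome.
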
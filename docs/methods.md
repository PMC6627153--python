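# Methods

## Network construction

Input interactions are undirected scored protein pairs. The filter keeps
edges with confidence ≥ `min_confidence` (default 0.73, the conventional
HIPPIE "high confidence" cut; the comparison is inclusive). Self-loops are
removed, duplicate pairs in either orientation collapse to the maximum
confidence (conservative: an interaction that qualified once is never
discarded), and proteins with no surviving partner are excluded entirely,
so every node of the working graph has degree ≥ 1. Identifiers are opaque
case-sensitive strings; accession mapping is out of scope. Construction is
idempotent: re-serializing the filtered graph and rebuilding it changes
nothing.

## MCODE complex detection

The detector follows the classic three-stage molecular-complex-detection
algorithm on a simple undirected graph.

*Vertex weighting.* For a node `v` with degree ≥ `degree_cutoff`
(default 2), take the closed neighborhood `N[v]`, find its highest k-core
(the largest `k` with a nonempty k-core), and set
`w(v) = k_max × density(highest k-core)`. Nodes below the degree cutoff
get weight 0. Density here and throughout is the simple-graph edge
density `|E| / (|V|(|V|−1)/2)`; the loop-including variant is not
implemented because the network is loop-free by construction.

*Complex prediction.* Seeds are visited in decreasing weight, ties broken
by lexicographic node id (the reference algorithm leaves order
unspecified; fixing it makes runs reproducible). From seed `s`, breadth-
first expansion up to `max_depth` levels (seed depth 0, default 100)
admits an unassigned neighbor `v` iff
`w(v) > w(s) × (1 − node_score_cutoff)` (default cutoff 0.2; strict
inequality, so boundary equality excludes). Memberships are disjoint. A
seed whose expansion yields only itself produces no complex and never
seeds again, but remains eligible to join a complex grown from a later
seed.

*Post-processing.* A complex whose induced subgraph contains no
`k_core`-core (default 2) is discarded; for simple graphs a 2-core means
a cycle, so surviving complexes have at least three members and more than
two interactions (the minimal case is a triangle). With `haircut` on
(default), members of within-complex degree < 2 are removed iteratively —
equivalently the complex is reduced to its 2-core. With `fluff` on
(default off), outside neighbors whose closed-neighborhood density
exceeds `fluff_density_cutoff` (default 0.1) are added; only fluffed
nodes may overlap between complexes.

*Scoring and ranking.* `score = density × |V|`, so `0 < score ≤ |V|` with
equality exactly for cliques. Clusters sort by descending score, then
descending node count, then lexicographically smallest member; ranks are
1-based and double as cluster ids in all outputs.

## Disease enrichment

For cluster `C` and disease `D`, with `n` the proteins of the filtered
network and annotations restricted to that universe:
`a = |C ∩ D|`, `b = |C| − a`, `c = |D| − a`, `d = n − a − b − c`.
Fisher's exact test is one-sided ("greater") by default — the hypothesis
of interest is over-representation of the disease's proteins inside the
cluster; the two-sided variant (sum of tables with point probability at
most the observed) is available by configuration. The significance level
defaults to 0.01 on the raw p-value; no correction is applied across the
cluster × disease grid by default, mirroring standard practice for this
screen, and only diseases with `a ≥ 1` are reported (others are trivially
p = 1, which affects reporting, not inference). The a-cell members are
reported as the cluster's shared proteins for that disease.

The comorbidity filter keeps significant results whose disease label
appears on the comorbid list after trimming and case-folding. Clusters
retaining at least one comorbid result are the disease subnetworks. With
an empty list every significant result is kept (with a warning) but none
is tagged comorbid, so there are no disease subnetworks and the pathway
stage is skipped — comorbidity evidence is a prerequisite for the label,
not an optional decoration.

## Pathway enrichment

Each pathway with a nonempty overlap against a disease subnetwork is
tested with the hypergeometric upper tail `P(X ≥ overlap)` for
`X ~ Hypergeom(universe, pathway size, cluster size)`, which coincides
with the one-sided Fisher test on the implied 2×2 table (asserted as a
cross-module consistency check in the tests). The universe defaults to
all network proteins, the same universe as the disease tests; an
"annotated" mode (proteins appearing in at least one pathway) is
available by configuration. Raw p-values are Holm-adjusted within each
cluster's family of tests — Holm's step-down is sometimes mislabelled
"FDR" in enrichment tools, but it controls the family-wise error rate,
hence the output column `adjusted_p_holm`. Significance defaults to
adjusted p < 0.05, a conventional pathway-screen level. A significant
pathway whose overlap contains a shared protein of the cluster's
significant comorbid disease is flagged *shared*.

## Synthetic data

The generator draws a planted-partition graph: `n_background` proteins
(default 400), within-module edge probability `p_within` (default 0.9)
for four planted modules of 18/25/5/29 nodes, background probability
`p_background` (default 0.01) for every other pair. Module edges carry
confidences from Uniform(0.75, 0.99) and background edges from
Uniform(0.3, 0.95), so at the 0.73 threshold module edges essentially
always survive while about one third of background edges do — the filter
is an active step. A planted-partition background was chosen over a
configuration model as the simplest generator with directly controllable
module density, which is the property the detector consumes. Confidences
are rounded to four decimals at generation time so in-memory values equal
the written file exactly and round-trips are lossless.

Each planted disease annotates host-module proteins with probability
`q_in` (default 0.8) and all others with `q_bg` (default 0.05); a disease
with no host module, or with `q_in = q_bg` (the `make_null_spec`
transform), is a true null and marked as such in the manifest. Each
planted pathway covers a `coverage` fraction (default 0.7) of its host
module plus 15 random background proteins; one unhosted decoy pathway and
one unhosted disease are included by default so negative behavior is
exercised. The comorbid list contains exactly the planted non-null
disease labels. The JSON manifest records module memberships, per-disease
and per-pathway member lists, null flags, and the post-threshold node and
edge counts of the emitted graph.

All randomness flows through a single seeded NumPy generator over
fixed-order index arrays, so equal seeds give byte-identical files.

What the generator does **not** emulate: degree heterogeneity of real
interactomes (hubs), correlated annotation (disease comorbidity in the
annotation source itself), literature-bias in confidence scores, and
overlapping complexes. Passing tests therefore demonstrate that the
pipeline recovers clean planted structure at realistic sizes, not that it
resolves everything a real interactome contains.

## Known limitations

MCODE cannot separate two dense regions of similar vertex weight joined
by even a single direct edge: expansion admits any neighbor within the
`node_score_cutoff` band of the seed weight, and the weight of a module
scales with its size, so same-density modules whose sizes differ by less
than ~20% (e.g. cliques of 25 and 29 nodes, weight ratio 24/28 ≈ 0.857 >
0.8) merge whenever a background edge connects them. Under the default
synthetic conditions a surviving cross edge between the two largest
modules is expected (≈ 2.5 on average), so those modules merge in roughly
a third of draws. Likewise, a 5-node module's planted disease needs at
least 3 of 5 members annotated for Fisher significance at 0.01, which
Bernoulli(0.8) sampling delivers ~94% of the time — small clusters have
intrinsically limited power. Both effects are visible in the
planted-structure recovery test, which reports the measured per-module
and per-disease rates.

Very small significant clusters (3 nodes, 3 interactions) sit exactly at
the post-processing boundary; the triangle is admitted by design, matching
the reported minimal subnetworks.

## Problem sizes

The default synthetic condition (400 proteins, ≈1500 candidate edges) is
the package's standard test surface; stochastic checks use 20 independent
seeds for recovery/power rates and ≥1000 cluster–disease tests for the
null calibration, sizes at which binomial noise on the measured rates is
small relative to the asserted margins.
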
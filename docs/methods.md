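# Methods

## The refinement model

A TF binding network is a directed graph over genes with an edge
TF → gene whenever ChIP-chip evidence places the TF on the gene's
promoter. Each edge carries two evidence flags: `binding` (always
required) and `regulation` (literature evidence that the TF actually
regulates the gene). Two network modes exist: *binding* keeps every
bound edge; *binding_and_regulation* keeps only edges with both flags.
The strict mode trades coverage for precision: fewer targets are
reachable, but the paths found are better supported.

For a knocked-out TF and one of its knockout targets, a modified
breadth-first search (mBFS) finds a shortest directed path. The
implementation is a first-visit BFS: a FIFO waiting list, a discovered
set, and a path record fixed at the moment a node is first enqueued.
First-visit bookkeeping preserves BFS level order on cyclic graphs, which
guarantees the returned path is shortest and that the search terminates on
any graph, including self-loops and complete digraphs. The destination
test applies to successors only, so a TF listed as its own target is found
only through a genuine cycle (length ≥ 1); this is the single case where
the reported node sequence repeats its endpoint. Among equal-length
shortest paths, lexicographic successor expansion makes the reported path
canonical and runs byte-reproducible.

Classification follows from the search outcome: length 1 ⇒ direct,
length > 1 ⇒ indirect, no path ⇒ false positive. Signals are targets
with a path; coverage is the pooled fraction of targets that are signals.
A path's confidence is the fraction of its steps whose edge carries the
`regulation` flag; precision is the unweighted mean confidence over all
found paths. Because each TF's indirect paths reuse a handful of
first-hop edges, the effective sample behind the precision estimate is
much smaller than the number of paths, and the estimate fluctuates
noticeably (±5 percentage points at the default synthetic scale) around
the network's regulation-flag density.

## Validation statistics

**Hypergeometric upper tail.** p = Σ_{x=V}^{min(S,T)} C(S,x)·C(G−S,T−x)
/ C(G,T) is evaluated with exact integers (a two-step multiplicative
recurrence per term, one rational division at the end), so it is
bit-stable for universes up to ~10⁵ genes and matches exact-rational
oracles to machine precision. When V is at or below the bottom of the
support the tail is exactly 1.

**Term enrichment.** Annotation sets are taken as pre-propagated flat
GMT gene sets; no ontology-graph reasoning is performed. Terms are
intersected with the universe, tested hypergeometrically, BH-corrected
across terms, and flagged enriched at q ≤ FDR (default 0.05). The
per-TF enrichment score is Σ |log p| over enriched terms; the log base
(default 10) is configurable and cancels from every A-vs-B comparison.
Contributions are summed in sorted order so the float score is
permutation-invariant. p = 0 is clamped to the smallest positive double
with a logged warning.

**Expression coherence.** For a gene set, the coherence distribution is
|Pearson r| over all unordered pairs of set genes present in the
expression matrix, with pairwise-complete observations and zero-variance
pairs skipped (and counted in the log). Two sets are compared by a
one-sided Wilcoxon rank-sum test of "stochastically greater": exact null
when both samples have ≤ 12 tie-free values, otherwise the normal
approximation with tie and continuity corrections (scipy's
`mannwhitneyu`). Both directions are computed so each side's superiority
count can be reported. Correlation pairs within one set are not
independent, so across-TF FDR control treats each TF's test as one
hypothesis; the per-TF p-values themselves are anticonservative in the
usual rank-sum-on-pairs way and are used comparatively, as in the original
measure.

**PPI module.** Core genes are set members with ≥ 1 physical interaction
partner inside the set; neighborhood genes are non-members with ≥ 1
partner in the core; the module is their union, and the test asks whether
the set/module overlap (= the core) is hypergeometrically surprising in
the gene universe. Self-interactions are dropped at load time.

**FDR.** Benjamini–Hochberg step-up, hand-rolled (q = cumulative minimum
of p·m/rank along sorted order, clipped at 1), order-aligned with input;
NaN entries (untestable TFs) pass through without counting toward m.

**Collection comparison and baselines.** `validate_collection` computes
all three measures per TF with BH across TFs (per direction / per side)
and reports the same three summary counts used throughout: TFs with
equal-or-higher enrichment, TFs significantly more coherent on each side,
TFs module-enriched on each side (plus strict smaller-p counts).
`random_removal` removes ⌊fraction·n⌋ targets per TF — the floor rule is
deliberate and conservative: sets with fewer than 1/fraction members are
left intact. Removal is per TF rather than pooled over all (TF, target)
pairs, so every TF loses the same fraction; the alternative pooled reading
would let chance concentrate removals in a few TFs. Seeding uses one
master seed plus a (replicate index, CRC32 of the TF name) counter, so
adding a TF never perturbs the other TFs' draws. In the per-replicate
comparison, a measure is "won" when the refined side's TF-win count
strictly exceeds the baseline's; enrichment wins by strictly higher score,
coherence by one-sided significance after FDR, and the PPI measure by
strictly smaller module p-value (enriched-count ties are otherwise near
universal when both sides contain the planted module).

## Synthetic data and what it does (not) show

The generator plants ground truth for all five inputs:

* **Network** — gene universe of 3000 (desk-scale stand-in for a genome),
  50 TFs whose out-degrees are Poisson with mean 60 (floored so every TF
  can host its planted direct targets), plus a deterministic TF cycle
  that keeps the TF subgraph strongly connected and the indirect-target
  pool deep. A reserved 10% of genes receives no incoming edges, making
  them provably unreachable. Regulation flags are i.i.d. Bernoulli(0.18),
  matching the evidence density observed on the real yeast corpus.
  Reachability truth is recomputed exhaustively (networkx BFS — a code
  path independent of the mBFS under test) and verified at generation
  time, so truth can never drift from the emitted network.
* **Knockout targets** — 100 per TF, split 6% direct / 84% indirect /
  10% unreachable (the regime observed on the real data), sampled from
  the distance-1, distance-≥2 and unreachable candidate pools
  respectively. Planted minimal path lengths are recorded.
* **Expression** — 50 conditions. Each TF's signal set is a coherent
  block with its own standard-normal factor per condition; a gene in
  blocks B follows x = λ·Σ_{b∈B} f_b/√|B| + √(1−λ²)·ε with loading
  λ = 0.7. For disjoint blocks this is the classic single-factor model
  with within-block pairwise correlation λ²; the √|B| normalisation
  extends it to the overlapping signal sets that arise because all TFs
  draw targets from a shared reachable universe (genes co-regulated by
  several TFs), keeping unit variance and proportional shared signal.
* **PPI** — Erdős–Rényi background at density 0.01 over the universe;
  pairs internal to a planted set are wired instead at density 0.9, so
  equal densities collapse to a pure Erdős–Rényi graph.
* **Annotations** — one planted term per TF drawing each member from the
  signal set with probability 0.9 (else uniformly), plus 80 uniform
  background terms of size 10–60.

All stages derive independent RNG streams from one seed, and every
iteration order is sorted, so two runs emit byte-identical files.

What passing on this generator shows: the search, classification,
coverage/precision accounting, module construction and all three
statistics behave exactly as specified on data whose truth is known, at
realistic effect directions. What it does not show: performance on real
compendia — real expression has condition structure, batch effects and
heavy tails; real PPI networks are scale-free, not Erdős–Rényi; real GO
terms are nested and DAG-propagated; and real ChIP-chip networks have
hub-dominated degree distributions. Absolute published counts from the
yeast corpus depend on specific database versions and are not reproduction
targets here; directional results (signals beat noises; refinement beats
random removal) are.

## Numerical and design choices

* Gene identifiers are uppercased, whitespace-stripped tokens, optionally
  routed through a transitively resolved alias→canonical map (cycles
  rejected), making normalization idempotent.
* Duplicate network edges merge by OR-ing evidence flags; successor lists
  are sorted; serialization is byte-stable.
* Self-loops are retained — a TF may bind its own promoter; the search
  handles them harmlessly.
* A TF is analysable ("eligible") iff it has ≥ 1 outgoing edge in the
  constructed network; ineligible TFs are skipped with a warning.
* A destination absent from the network yields "no path", not an error;
  a missing start node is an error (the query is malformed).
* Empty target lists report a missing interpretable ratio rather than 0;
  zero found paths report missing precision.
* Identical pooled values in the coherence test return p = 1 (no ranking
  evidence) rather than a divide-by-zero.
* Problem sizes in tests and the acceptance script (200 random digraphs of
  ≤ 15 nodes; exhaustive hypergeometric sweeps to G = 20–30; 100-seed
  power runs; one default-scale pipeline with ten baseline replicates)
  were chosen to make the full suite complete in a few minutes on one
  core while keeping every estimate's Monte-Carlo error far from the
  asserted margins.

## Known limitations

* The PPI-module statistic is not calibrated under a random-graph null:
  the module T is constructed from the set S itself (core ⊆ S ∩ T by
  definition), so at sparse equal densities the test is strongly
  anticonservative (≈ 60% of null seeds fall below p = 0.05 at density
  0.01 with |S| = 20, G = 300) and at dense ones it is conservative. Its
  p-values are therefore meaningful *comparatively* (side A vs side B,
  both constructed the same way) but not as calibrated significance
  levels, and the "approximately uniform null" idealisation fails.
* The coherence rank-sum treats correlation pairs as independent samples;
  with C(m, 2) pairs from m genes this overstates evidence on both sides
  of a comparison. It is used, as in the original measure, to rank sides
  rather than to certify calibrated error rates.
* A TF regulating targets through protein-level TF–TF interaction rather
  than a transcriptional chain is invisible to the binding network and
  will be misfiled as a false positive.
* The mBFS returns one canonical shortest path; equally short alternative
  chains are not enumerated.
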
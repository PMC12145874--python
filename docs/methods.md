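# Methods

This note documents the models, statistical procedures, numerical choices,
and known limitations of `phresp`.

## Growth-rate inference

Cultures are assumed to grow (or decay) exponentially within each growth
period, so the per-day rate is μ = (ln N₁ − ln N₀)/(t₁ − t₀) from the
boundary fluorescence readings. Readings must be positive and times strictly
increasing; violations raise immediately rather than propagating NaNs.

*Period selection.* Acclimatization is operationalized as "keep the last two
periods" (one for two-point series). A stabilization detector would need a
model of the transient that the data contract does not provide; the selection
rule is therefore a pluggable callable (`period_rates(keep_periods=...)`),
with the last-two default.

*Statistics.* Kruskal–Wallis (scipy) across pH conditions per strain, using
all selected well × period records as replicates (wells-only replication is a
configurable alternative via pre-aggregation; with two periods per well the
records are weakly negatively correlated within wells, which makes the test
mildly conservative rather than anticonservative). Dunn's post-hoc test is
implemented directly: pairwise z statistics on pooled mean ranks with the
standard tie correction Σ(t³−t)/(12(N−1)), two-sided normal p-values,
Benjamini–Hochberg adjustment across the condition pairs (threshold .05).
For two groups this reduces exactly to the tie-corrected asymptotic
rank-sum test, which the test suite uses as an independent cross-check.

*Compact letters.* Insert-and-absorb over the non-significance graph: start
from one group holding all conditions, split any group containing both
members of a significant pair, absorb subset groups. Letters are assigned in
condition order, so output is deterministic.

*Classification.* acid_intolerant if the acidic median rate is negative
(population collapse); acidophile if the acidic median is positive, strictly
highest, and the acidic condition shares no letter with the others;
generalist otherwise. The collapse threshold (median < 0) is a heuristic
reading of the phenotype and is documented as such in the docstring.

## Gene scoring

The expression filter keeps genes with CPM ≥ 1 in ≥ 2 samples (both
configurable). SLFDR = ln(FDR)·sign(log₂FC) is computed exactly as printed:
significant upregulation gives large *negative* scores. Because the
orientation surprises users accustomed to −ln scores, `flip_sign` is
provided; every downstream direction rule assumes the printed default.
FDR = 0 is floored at 1e−300 to keep the logarithm finite; log₂FC = 0 yields
score 0 with a warning (such genes are never DEGs and must stay rankable).
DEGs are called at FDR < .01 with direction from the fold-change sign.

Sample distances use log₂(CPM + 1), centered per gene by its mean across
samples (median optional), then Pearson correlation and Euclidean distance on
the sample columns. Zero-variance samples yield flagged NaN correlations.

## Enrichment

*FCS.* The in-set aggregate is the Wilcoxon rank-sum statistic W (sum of
pooled ranks of in-set SLFDR; average ranks on ties). The named test fixes
the statistic; the gene-sampling null fixes its reference distribution:
random member sets of the same size drawn without replacement from the
universe. The two-sided empirical p compares |W − E[W]|, E[W] = k(N+1)/2,
with the +1 numerator/denominator correction; draws per set size are cached
and shared across all sets of one universe (the null depends only on k), and
per-size draws are seeded by (seed, k) so results are independent of query
order. When C(N, k) ≤ n_perm the null is enumerated exhaustively instead and
the p-value is exact. An asymptotic mode (normal-approximation rank-sum
without continuity correction) is available; sampling is the default.
n_perm defaults to 10,000. Because the statistic is rank-based, p-values are
invariant to monotone transforms of the scores. Direction: a shift of in-set
scores toward negative values (upregulation under the printed SLFDR
orientation) is "enriched".

*ORA.* Up- and down-regulation are tested separately as 2×2 chi-square
tables (in/out × DEG/non-DEG), without continuity correction (configurable),
matching the default of the standard chi-square test. Testing the directions
separately is what permits the "both" outcome; a single omnibus table could
not assign direction. "Outside" means universe minus the set. A zero margin
(e.g. no down-DEGs anywhere) makes the table degenerate; p is set to 1 with a
warning. Candidacy — the in-set proportion actually exceeding the out-of-set
one — gates the call; the BH family nevertheless contains every set's
per-direction p.

*UGS.* Deterministic: enriched if ≥ min_degs up-DEGs and zero down-DEGs in
the set, depleted symmetrically. min_degs defaults to 2 because a minimum of
1 would flag every set containing a single DEG; it is exposed as
`--ugs-min-degs`. UGS has no p-value and therefore no error control — the
null-call rate is reported by the acceptance script rather than bounded.

*FDR families and combination.* BH is applied per method × direction across
all sets of one strain × contrast × set type (the granularity at which
results are tabulated); FCS's single two-sided p joins the family of its
candidate direction. A set is affected in a direction when at least one
method calls it after adjustment (UGS passes through unchanged); supporting
methods are recorded per direction. Pre-adjustment calls carry the candidate
direction; `adjust_and_combine` zeroes any direction whose FDR fails the
threshold, which is where the "direction implies significance" invariant is
enforced.

## Ontology propagation and collections

Only is_a-style child → parent edges are modelled; the edge table is the
contract (an OBO file can be reduced to it). Annotation closure is the
transitive ancestor union per gene, computed with memoized DFS and verified
in tests against a brute-force BFS; it is idempotent. Gene-set collections
carry a per-set type tag so enrichment runs per type by default; universe
restriction intersects memberships and drops (and counts) emptied sets.

## Response clustering

Group labels truncate pH values to their integer part (4.7→4, 7.0→7, 8.2→8).
The distance is √(1 − Jaccard similarity) on gene-set presence/absence —
the square-root transform makes the dissimilarity Euclidean-embeddable.
Conventions for degenerate inputs: two empty groups are at distance 0,
an empty vs a non-empty group at 1; both cases are logged. Linkage is
average (configurable); labels are sorted lexicographically before linkage
so merge ties resolve deterministically. The orthogroup-based and
functional-set-based matrices are the same operation run on the two set-type
slices. The exported TSV is exact; the raster heatmap's fill gradient starts
at the minimum off-diagonal distance.

## Synthetic data

The generators define the study conditions for all tests:

* **Growth**: 12 strains × 3 pH (4.7 / 7.0 / 8.2) × 12 wells, 3-day periods,
  initial RFU 100, multiplicative lognormal noise with CV 0.05 by default.
  Noise is drawn as exp(N(0, σ)) with σ = √ln(1 + cv²), so readings are
  always positive and the expected log-increment per period is exactly
  μ·Δt (the noise is median-1 in linear space, mean-0 in log space).
  Default rates follow four archetypes — acidophile (0.60/0.20/0.20 per day),
  generalist (0.35/0.45/0.40), and two acid-intolerant variants with
  collapse (−0.30) at pH 4.7 — magnitudes typical of exponentially growing
  diatom cultures. Culture renewal (dilution) is not modelled; only the
  log-increment structure matters downstream.
* **DE tables**: null genes draw FDR from Beta(a, 1) with a chosen so that
  P(FDR < .01) equals `deg_rate_null` (0.02 default; `fdr_alpha_shape`
  overrides a directly). Effect genes inside planted sets (probability
  `effect_deg_rate`, 0.8 default) draw FDR log-uniformly in [1e−6, .01].
  log₂FC magnitudes are lognormal (larger for DEGs), signs random except
  where a planted direction forces them; the magnitude only matters through
  its sign. Planted sets are disjoint from each other so truth is
  unambiguous; null sets overlap freely, as real annotations do. With
  `effect_unidirectional`, chance background DEGs inside a planted set adopt
  the planted sign, so all of a planted set's DEGs agree in direction.
* **Ontology**: a rooted random DAG; every non-root term takes 1–2 parents of
  strictly smaller depth, bounding all paths to the root by `max_depth`.
* **CPM matrices**: negative-binomial counts (variance m + φm²) around
  lognormal baseline means with planted per-condition multipliers, 3
  replicates per condition, normalized to counts per million.

What the generators do *not* emulate: library-size artifacts, count
overdispersion heterogeneity, correlated gene-gene expression, annotation
bias, or assembly noise. Passing tests therefore demonstrate correctness of
the statistics under the stated generative model, not robustness to every
real-data pathology.

## Problem sizes

The test suite and acceptance script run at deliberately desk-scale sizes
chosen to give stable Monte-Carlo estimates: 1000 null sets over a 2000-gene
universe with 2000 gene-sampling permutations for error control; 20 planted
sets of size 20 over 5000 genes for recovery; 1000 replicates for type-I
rates; 10,000 random triples for the metric check. The shared per-size null
cache makes the permutation cost linear in the number of distinct set sizes
rather than in the number of sets.

## Known limitations

* Dunn's test uses the asymptotic normal null; very small groups (< ~4
  records) make it unreliable, as in any implementation.
* UGS is sensitive to `deg_rate_null`: its null-call rate grows with the
  background DEG rate and set size, and is uncontrolled by design.
* The composite call has no cross-method multiplicity correction; it is a
  sensitivity-oriented union, as defined.
* The pipeline's growth and expression stages are simulated independently;
  no coupling between growth phenotype and transcriptomic response is
  modelled.
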
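# Methods

This note documents the models and conventions behind `popcnv`: what each
stage computes, the parameters that matter, what the synthetic generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Coordinates and primitives

All in-memory coordinates are 1-based inclusive (the PennCNV / UCSC
position-box convention); BED files are converted at the I/O boundary and
nowhere else. Interval length is `end − start + 1` everywhere — no module
computes it otherwise. Chromosome names are normalised to the `chr`
prefix. Copy states above 3 are preserved as read, but every
classification collapses states to {0, 1, 2, 3+}: on arrays, states
beyond 4 are rarely distinguishable and the population analyses only need
the deletion/baseline/amplification trichotomy with the zero-copy state
kept separate.

## Probe suitability

The genomic target is digested with NspI and StyI before hybridisation,
so a probe whose 25-mer plus up to 12 bp of reference flank contains
`RCATGY` or `CCWWGG` would assay a fragmented template. Both sites are
palindromic, so a single-strand scan suffices; the scan runs over the
concatenated flank+probe+flank string so boundary-spanning sites are
caught. When flanks are unavailable the screen runs on the probe alone
and is explicitly partial. Probes whose `[pos, pos+24]` targets overlap
compete for template; both members of an overlapping pair are removed
(strand ignored — sense and antisense probes target the same duplex
locus). The spacing statistic removes inter-probe gaps strictly greater
than the third quartile (linear interpolation between order statistics,
the numpy default; the quartile definition is a convention choice) before
taking the median, because probe deserts would otherwise dominate.

## Sample and call QC

Sample gates are strict inequalities (LRR SD < 0.35, BAF drift < 0.01),
matching how such thresholds are quoted; call length bounds (500 bp to
1 Mb) are treated as an inclusive range and marker density as inclusive
(≥ 0.00013 markers/bp — the "≥ vs >" choice is undocumented upstream and
recorded here). Removal reasons are charged in the fixed order length →
markers → density so that reports are deterministic. The filter is
idempotent by construction. Baselines are sex-aware: autosomes expect two
copies; the X expects one in males and two in females, so a two-copy male
X segment is an amplification.

## Recurrence and CNVRs

Reciprocal overlap is `min(ov/|a|, ov/|b|)` (the bedtools `-f x -r`
semantic): both intervals must be covered at the threshold fraction.
The recurrence graph links calls at ≥ 0.40 and regions are connected
components — recurrence is transitive, so a region's span can exceed any
single member. Uniqueness (degree 0) is decided once on the full panel
and never re-evaluated inside subgroups; subgroup tables therefore need
not ratio the way a within-group analysis would. Same-sample call pairs
contribute edges, but region sample counts and the most-common-CNV tally
count distinct samples only.

Boundary concordance is the mean pairwise reciprocal overlap of a
region's members. No closed-form definition of this statistic is fixed by
precedent, so this operational choice was made to satisfy two anchoring
constraints: members with identical boundaries score exactly 1.0, and
regions below 0.75 are flagged complex. Both the formula and the 0.75
threshold are exposed as parameters.

Concordance with an external interval set supports a stringent mode
(≥ 20 % reciprocal overlap) and a relaxed mode (≥ 1 bp); copy state is
deliberately ignored — any reported variant is taken as evidence the
region varies.

## Feature enrichment

The statistic is the count of calls sharing ≥ 1 bp with a track. The null
re-places every call uniformly on its own chromosome with its exact
length, independently (shuffled calls may overlap each other and the
originals): the simplest null that preserves the chromosome and size
distributions. With 1000 permutations the 95 % band is the 25th/975th
order statistic of the ascending null; other permutation counts scale the
ranks as `round(0.025·n)` / `round(0.975·n)`, and n < 40 is refused.
Verdicts are strict — an observed count equal to a band edge is
non-significant, so under a true null the non-ns rate is ~5 % (about
2.5 % enriched, 2.5 % depleted). Each permutation draws from its own
counter-based substream of the seed, so the null is reproducible and
independent of evaluation order.

Breakpoint context re-runs the same test on windows of ±window/2 around
each call's start and end. Calls shorter than the window would have
overlapping windows and are dropped entirely; windows are clipped at
chromosome edges rather than discarded (the alternative — discarding —
would deplete telomeric calls from the breakpoint analysis).

## Genes

Call/gene relations partition all ≥ 1 bp overlaps into encompasses /
inside / partial, with ties (identical intervals) resolved to
"encompasses". Complete-overlap lists (the first two relations) are the
export for external GO/pathway tools; enrichment against those databases
is out of scope. Ensembl biotypes collapse via a small mapping table
(`*_pseudogene` → pseudogene, `*RNA` → rna, `antisense`, everything else
→ other). The packaged negative-control list contains the symbols of
dosage-sensitive genes conserved across mammals (22 autosomal, 18
X-linked); genomic coordinates for them must be supplied by the caller's
annotation, and the tests use synthetic coordinates.

Subspecies privacy uses an asymmetric pair of rules on purpose: a region
is *carried* by a wild-caught sample when that sample has a member call in
the region's recurrence component (≥ 6 carriers required), but is *seen*
in the other subspecies on any ≥ 1 bp overlap with the region span. The
strict absence rule matches how private variants are screened against
other groups; the component rule keeps carrier counting consistent with
CNVR membership.

## Distances, trees, ordination

SNP distance for a pair is (loci where both are called and differ) /
(loci where both are called); shared no-calls are not differences, and
AB differs from both homozygotes. The per-co-called normalisation keeps
the distance in [0, 1] and comparable with the CNV distance. CNV distance
assigns every autosomal probe set a collapsed state per sample (2 unless
inside one of that sample's calls) and counts differing probe sets over
all probe sets. Sex chromosomes are excluded: the sex-dependent baseline
would confound a panel-wide distance. When overlapping same-sample calls
disagree at a probe, the most extreme departure from two wins and a tie
resolves to the deletion, with a logged warning.

Trees use classical Saitou–Nei neighbor joining with the standard
Q-criterion and deterministic tie-breaking (lexicographically smallest
pair of clade labels, a clade labelled by its smallest leaf), making the
output invariant to input order. BIONJ's variance weighting was
considered and not used: on additive or near-additive matrices the two
agree, NJ's arithmetic is simpler to verify against the 3-taxon closed
form, and the tests show exact recovery of random additive trees.
Negative branch lengths are kept and flagged, per NJ convention.

Classical MDS is the textbook principal-coordinates construction:
eigendecomposition of the double-centred squared-distance Gram matrix,
top-k axes by eigenvalue, axes with non-positive eigenvalues zeroed, and
a fixed sign convention (largest-magnitude loading positive). The Mantel
test correlates strictly-lower-triangle entries and permutes rows/columns
of the second matrix; it is one-sided for positive association, the
direction of scientific interest here, with the permutation p-value
`(1 + #{r* ≥ r}) / (1 + n)`.

## Deletion FDR

Genotypes inside a real deletion cannot be heterozygous, so a deletion
call (state 0 or 1) in which more than 10 % of genotype calls at its SNP
probes are AB is counted as a false positive. No-calls are excluded from
the denominator — they are not genotype calls — and a deletion containing
no called SNP probe is excluded from testing and reported as such. The
threshold is strict (exactly 10 % is not flagged) and configurable. Both
the pooled rate (flagged/tested over all samples) and the mean of
per-sample rates are reported, since pooling weights samples by call
count. Group rate comparisons (heterozygous or no-call rates inside
deletions or amplifications) use the two-sided Wilcoxon rank-sum via
scipy, which selects the exact distribution for small groups and the
tie-corrected normal approximation otherwise.

## Summary tables

Display values round half-up to two decimals, the convention such tables
are typeset with; full precision is retained internally and the row
identities (state counts sum to calls, unique + recurrent = calls) are
enforced at construction. Deletion/amplification ratio with zero
amplifications is an infinity sentinel excluded from downstream
statistics. Genome fraction affected is the union of call intervals over
the scope length (autosomes, optionally plus X), computed from the
supplied genome definition so synthetic genomes work unchanged; a
per-sample mode averages within-sample unions.

## Synthetic data

The generator plants a known truth at the call level; it does not
simulate intensities or the HMM caller. Default conditions mirror a
large array-based mouse survey, scaled to desk size:

* genome: 3 autosomes × 12 Mb (the demo panel uses 4 × 14 Mb);
* probes: truncated-exponential spacing, median 500 bp, capped at 2 kb so
  that every planted call of the minimum anchor length necessarily
  contains ≥ 3 markers and passes QC by construction;
* panel: classical (12), wild-derived (8), wild-caught *domesticus* (8)
  and *musculus* (8) samples;
* lengths: log-normal with deletion median 20,091 bp and amplification
  median 36,708 bp, σ = 1.2 (giving mean ≈ 2× median, the right skew
  array call sets show), clipped to [10 kb, 800 kb] anchors;
* deletion share per group: 0.457 classical / 0.692 wild-derived /
  0.745 wild-caught, i.e. del:amp ratios of 0.84 / 2.25 / 2.92;
* planted CNVRs: 12 regions placed in disjoint slots; members jitter both
  boundaries uniformly within ±10 % of the anchor length, so pairwise
  reciprocal overlap is at least 0.8L/1.2L ≈ 0.67 — comfortably above the
  0.40 detection threshold — while unique calls occupy their own slots
  and overlap nothing. Recurrence recovery is therefore exact by design
  (Rand index 1.0), which validates the graph machinery, not boundary
  resolution on noisy data;
* false positives: 25 % of deletion calls carry Hardy–Weinberg genotypes
  (per-probe MAF uniform on [0.05, 0.5], expected heterozygosity ≈ 0.37)
  instead of forced homozygotes, so they exceed the 10 % rule with
  probability ≈ 1 while true deletions essentially never do;
* genotypes: a shared ancestral allele per probe, group-level divergence
  (5–35 % flips by group), small individual noise, and group-dependent
  baseline heterozygous/no-call rates (1 % classical vs 3 % wild). This
  gives SNP and CNV distances the same group structure, hence a positive
  Mantel correlation, without modelling linkage or introgression;
* feature tracks: Poisson-placed 500 bp intervals at 2 × 10⁻⁵ per bp,
  with the planted track's density multiplied by the configured factor
  (default 2.0) inside the union of emitted call intervals.

What passing tests on this generator do **not** show: robustness to
boundary noise below the overlap threshold, linkage disequilibrium,
population admixture, probe-level intensity artefacts, or real
feature-track autocorrelation. The generator validates the algorithms'
contracts, not the biology.

### Problem sizes and the enrichment power study

Test and acceptance runs use desk-scale panels (tens of samples, a few
hundred calls, tens of Mb of genome) chosen so the whole suite runs in
minutes; the demo panel (~50 samples, ~1500 calls) mirrors the group
proportions and per-group call loads of a full survey at roughly 1/6
scale.

The enrichment power experiment deserves a note: members of one CNVR
largely share the same planted features, so their overlap indicators are
correlated and a panel dominated by a few large CNVRs gives the observed
count a high variance that no number of permutations removes. The power
panel therefore uses many independent planted zones — 8 unique calls per
sample with anchors capped at 60 kb on a 36 Mb genome — keeping the
planted footprint well below genome coverage (a heavily covered genome
also dilutes the contrast, because shuffled nulls land in enriched zones
too). Under those conditions a 2× planted density contrast is detected in
every seeded replicate, and a null track yields ~5 % non-null verdicts,
as a 95 % band should.

## Pipeline

Stages run in the order qc → recurrence → enrichment → genes → distance →
fdr → summaries. Missing optional inputs (genotypes, genes, tracks) skip
their stages with a warning rather than aborting, so a calls-only user
still gets recurrence and summaries. The manifest records the package
version, a hash of the analysis-relevant configuration (the output
directory is excluded) and the seed; a rerun with the same configuration
and seed is byte-identical, log timestamps aside.

## Known limitations

* Boundary concordance is an operational stand-in where no canonical
  formula exists; regions near the 0.75 threshold may classify
  differently under other definitions.
* The recurrence graph is exact but quadratic in the worst case of many
  mutually overlapping calls at one locus; panels of ~10⁴ calls build in
  seconds, far larger ones may not.
* The high-call-count sample exclusion (95th-percentile rule) is
  available as a filter but off by default.
* CNV distance treats every probe set equally; probe density variation
  along the genome weights dense regions more heavily.
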
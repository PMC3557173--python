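# Methods

`linkmap` implements the analysis layer that sits between a finished
genetic linkage map and genome-scale sequence resources in allotetraploid
cotton (*Gossypium hirsutum* × *G. barbadense* BC1 designs): map structure
diagnostics, segregation-distortion scanning, in silico PCR anchoring of
mapped markers to EST/BAC pools, and co-localization of anchored genes
with fiber-quality QTL. Map *construction* (grouping, ordering, Kosambi
distances) is deliberately an input, not a feature.

## Map model and summary statistics

A map is a set of linkage groups, each an ordered list of loci with
non-negative centimorgan positions. Group labels `A1..A13` / `D1..D13`
carry subgenome and homoeologous index (`A_i` pairs with `D_i`);
D-subgenome labels translate to conventional chromosome numbers through
the cytogenetic numbering of this cross (D3 = Chr. 17, D8 = Chr. 24, …).

The mean inter-locus distance divides total map length by the number of
inter-locus *intervals*, `n_loci − n_groups`, since a chain of n loci has
n−1 spacings. Published per-subgenome figures sometimes divide by locus
count instead; we standardize on intervals everywhere, so an
interval-based A-subgenome mean prints 1.18 rather than 1.17 cM. Means
are rounded half-away-from-zero to 2 decimals (conventional printed
rounding, not banker's rounding); loci-per-group to the nearest integer.
Gap detection is strictly greater-than the threshold (default 10 cM), so
an exactly-10-cM spacing is not a gap.

## Segregation distortion and SDR scanning

BC1 calls are coded 1 (recurrent-parent homozygote), 3 (heterozygote),
`-` (missing). Missing calls are dropped per locus, never imputed. Each
locus is tested against the Mendelian 1:1 expectation with the Pearson
goodness-of-fit chi-square, which for two classes reduces to
`(n1 − n3)² / (n1 + n3)` on 1 df. No Yates continuity correction is
applied: with ~138 individuals the asymptotic approximation is accurate,
and the correction would only blunt the test. α = 0.05 with no
multiple-testing correction, matching field practice for map-wide
distortion reporting; the type-I consequence (≈5% of fair loci flagged)
is quantified, not hidden — the calibration test requires the flagged
fraction of 10,000 fair loci to land in [0.04, 0.06]. A tie (n1 = n3)
gives chi-square 0, so a "distorted tie" cannot occur and no tie-break
rule is needed.

A segregation distortion region (SDR) is a maximal run of at least
`min_run` adjacent map loci all skewed in the same direction. Quantitative
SDR definitions vary across the literature; we use `min_run = 3` — the
smallest run that is not a pair — and expose it as a parameter. SDRs are
numbered globally in map order and named `SDR<k>_<chromosome>`.

Power at the study design: with transmission probability 0.70 over a
5-locus region and n = 138, the expected per-locus chi-square is
`138·(2·0.7 − 1)² ≈ 22.1`, per-locus detection probability ≈ 0.997, and
the region is recovered in ≥99 of 100 seeded replicates, while fair
131-locus groups produce a spurious SDR in ≤5% of replicates.

## Density, clusters, duplicated loci

Locus density uses half-open 10-cM bins `[k·w, (k+1)·w)` tiling
`[0, group length]`; a locus exactly at the group maximum is absorbed
into the last bin so counts conserve exactly.

"≥5 loci per cM" cluster calling is operationalized as a 1-cM window
sliding over position-sorted loci; overlapping qualifying windows are
merged into one maximal cluster. A merged cluster's overall span can
slightly exceed 1 cM, but every cluster contains at least one qualifying
sub-window; the test-suite oracle (an O(n²) all-subranges scan with the
same merge rule) pins this semantics down. Clusters are classified
`gene_island` when some ≤1-cM stretch inside holds ≥5 EST-SSR loci,
else `retro_rich` when REMAP loci form a strict majority of members
(threshold exposed; the canonical example is 8 of 15), else `generic`.

A marker mapping to m ≥ 2 loci contributes m duplicated loci. Each
duplicated locus is classified by its sibling loci: `homoeologous` if the
marker also hits the A/D partner group, else `same_chromosome`, else
`different_nonhomoeologous` — an exhaustive, disjoint partition whose
percentages are printed to 2 decimals. Candidate reciprocal
translocations between At chromosomes (defaults A2/A3 and A4/A5) are
supported by markers bridging `A_i` with `D_j`, the partner of the other
chromosome of the pair, counted per (A, D) combination.

## In silico PCR

A primer pair amplifies a template wherever the two primers bind opposite
strands in convergent (forward–reverse) orientation with at most
`max_mismatch` substitutions each (default 3) and a product length inside
configured bounds. Design choices:

* **Substitutions only.** No indels inside a primer site; matching is
  exact Hamming distance. This keeps the model verifiable against a naive
  full scan and is what a mismatch-count cutoff means in practice.
* **Pigeonhole search.** The primer is split into `max_mismatch + 1`
  contiguous near-equal segments; each segment is looked up exactly in a
  lazily built k-mer index of the template pool, and candidates are
  verified by full Hamming comparison. Completeness is a theorem: a site
  with ≤ `max_mismatch` substitutions cannot corrupt all
  `max_mismatch + 1` disjoint segments. The equivalence with the naive
  scan is asserted on 200 random primer/template combinations.
* **N handling.** Template `N` never matches a primer base (counts as a
  mismatch); primers must be unambiguous A/C/G/T.
* **No 3′-terminal penalty.** Real PCR is 3′-sensitive, but a
  computational screen with a plain mismatch bound has no such rule;
  adding one would silently change the published-style bookkeeping.
* **Product bounds.** 40–5,000 bp for ESTs and up to 20,000 bp for BACs
  (BAC inserts can host products no EST read could). All bounds are
  configurable.
* **Multiple hits per template are all reported** — multi-locus markers
  require it — and deduplicated on (start, end, strand) keeping the
  fewest mismatches.

Cross-species product comparison classifies a marker anchored in ≥2
species as `same_size` only under exact bp equality of every predicted
product, else `different_size`; single-species markers stay unclassified.

For anchoring arbitrary query sequences to long templates, `seed_extend`
finds exact shared k-mers (default k = 12) and extends each seed
ungapped in both directions under +1/−2 match/mismatch scoring,
terminating when the running score falls more than `xdrop` (default 12)
below its running maximum; matches below `min_score = 30` are dropped and
same-diagonal overlaps are merged. These parameters are conventional for
ungapped extension and all exposed. Note a finite X-drop is *not*
guaranteed to reach the per-diagonal optimal window (a deep dip can hide
a later positive run); the oracle-equivalence test therefore runs with an
unbounded X-drop, where extension from any seed inside the optimal window
provably attains the per-diagonal Kadane optimum. Coordinates are 0-based
half-open internally and 1-based inclusive in GFF3 output.

## Unigene selection and QTL integration

Per anchored marker, member sequences are merged greedily: repeatedly
join the pair with the longest suffix/prefix overlap of ≥40 bp at ≥95%
identity, keeping the left member's bases across the junction; the
representative is the longest resulting sequence, labeled
`merged_consensus` or `longest_member` by provenance. This is a
deliberate simplification of overlap-layout-consensus assembly (no
orientation flipping, no true consensus); the exhaustive-ordering oracle
in the tests brackets the greedy result between the longest member and
the best achievable merge length.

QTL intervals wider than 20 cM (the flanking-marker rule, interpreted as
interval width; a peak-distance interpretation is exposed as an
alternative by filtering upstream) are excluded. A marker cluster is
assigned to a retained QTL when any of its mapped positions falls inside
the closed interval on the same group; each (QTL, cluster) pair counts
once. The summary table has one row per chromosome with per-trait QTL
counts (qFE qFL qFF qFS qFU), QTL totals and distinct assigned-gene
counts, plus At/Dt subtotal rows that must sum to the grand total. QTL
clustering for multi-trait regions uses interval-overlap single linkage —
a transparent stand-in for Gaussian-mixture meta-analysis, which is out
of scope.

## Synthetic data

The generators emulate the study conditions, which are fixed as defaults:
26 groups × 131 loci over ~141 cM each, 138 BC1 individuals, 1% missing
calls (no rate is published; 1% is typical of SSR gel scoring), 12
planted distortion regions on 11 groups (8 toward the recurrent parent at
p_het = 0.30, 4 toward the heterozygote at 0.70), planted gene-island /
retro-rich / generic clusters, a duplication plan with 64% homoeolog
bridging, a 63.5% amplicon plant rate with per-primer substitution counts
cycling 0–3 and +6 bp cross-species insertions, and five-trait QTL plans
including one 26-cM interval that must be excluded by the 20-cM rule.
Markers lying inside planted QTL intervals are prioritized into the
primer panel, since planned QTL–marker overlap is part of the design
being emulated.

One integer seed feeds hierarchical per-generator streams
(`SeedSequence` spawn keys), so outputs are byte-identical across runs
and adding a generator never perturbs another's draws.

What the generator does **not** model — and hence what green tests do not
establish about real data: linkage disequilibrium between adjacent loci
(calls are independent across loci, so map-order runs are a cleaner
signal than real SDRs), repeat structure and biased base composition in
templates (uniform A/C/G/T; no SSR motifs, no vector contamination),
sequencing error in ESTs, and realistic recombination. Detector recovery
of planted features is exact in the noiseless regime by construction;
statistical behavior under noise is covered only for the chi-square
calibration and SDR power at the study's sample size.

## Problem sizes

Tests and the acceptance script run scaled-down pools — a few hundred to
a thousand markers against a few hundred templates, and four-group maps
for end-to-end runs — which exercise every code path of the engine; the
printed whole-study totals (3,414 loci, 693 duplicated loci, 2,111 of
3,324 markers anchored, Table-style distortion counts) enter as worked-
example inputs whose derived statistics the code recomputes. The pigeonhole
engine indexes ~1 Mb pools in well under a second; anchoring 1,000 markers
against ~1,700 templates takes a few seconds on one core.

## Known limitations

* Hamming-only primer matching misses sites with indels; real ePCR tools
  sometimes allow one gap.
* Greedy unigene merging is order-sensitive in pathological overlap
  graphs; the provenance label makes the fallback explicit.
* Homoeolog classification requires `A_i`/`D_i`-style labels; maps with
  opaque group names get no duplication classes or translocation signals.
* The 20-cM QTL filter discards wide intervals rather than shrinking them
  around the peak; with sparse flanking markers this is conservative.
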
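# Methods

## Model and assumptions

The pipeline predicts *active intergenic* enhancers from the coincidence of
three features measured genome-wide in two tissues: chromatin accessibility
(DNase-seq), H3K9ac enrichment (ChIP-seq) and low DNA methylation (BS-seq).
The underlying assumptions are that active enhancers are nucleosome-depleted
(DHS), flanked or covered by acetylated histones (H3K9ac), and lowly
methylated in the CG and CHG contexts; that mCG/mCHG patterns are stable
across vegetative tissues (so a single methylation dataset serves both
tissues); and that an enhancer regulates its nearest upstream or downstream
gene with positively correlated activity. Promoter-proximal and genic
signals are excluded because enhancer chromatin there cannot be separated
from gene chromatin. Repetitive sequence outside the uniquely mappable
genome is invisible to the short-read assays; all enrichment statistics are
therefore computed within a mappability mask supplied as input.

Coordinates are 0-based half-open (BED convention) everywhere internally;
GFF3 (1-based closed) is converted on read. Interval-set operations are
strand-blind; strand matters only where documented (promoter/flank
placement, profile orientation).

## Stage-by-stage procedure and parameters

**Replicate consensus** (`consensus`): two peaks agree when their overlap is
at least `replicate_overlap_frac` (default 0.70) of *both* peak lengths —
the reciprocal reading of "overlapping by at least 70% of their lengths",
matching bedtools `-f 0.70 -r`. The retained region is the union of the
agreeing peaks, which is conservative for the downstream ≥ 1 bp overlap
tests; chains (one peak agreeing with two) merge the whole component. Three
replicates are handled by integrating the first two and chaining the third
against the result. Which coordinates the original procedure retained is
not documented; union is this package's choice.

**LUMR calling** (`methylation`): the published procedure delegated
segmentation to MethylSeekR's HMM. Here segmentation is a transparent
run-based segmenter, a deliberate stand-in: maximal runs of ≥
`methylation_min_sites` (4) covered sites with frequency strictly below
`methylation_threshold` (0.20), consecutive sites at most
`methylation_max_gap_bp` (300) apart; a region spans first to last site + 1.
CG and CHG are segmented independently and intersected; regions whose mean
over fixed 100-bp windows (coverage-weighted within windows, CG and CHG
pooled) is ≥ 0.20 are then dropped. The boundary at exactly 20% is
excluded on both routes (strict `<` in segmentation, `>=` drop in the
filter), resolving the contradictory inclusive/exclusive phrasings of the
threshold in favour of exclusion. Sites with zero coverage are skipped, not
imputed. CHH is never used for calling, only for profiling.

**Integration** (`candidates.integrate`): candidate = LUMR with ≥ 1 bp
overlap with a consensus DHS and a consensus H3K9ac region in the tissue
and zero bp overlap with exon, intron or promoter classes. Candidate
coordinates are the LUMR coordinates, so shared candidates are recognised
by identical coordinates across tissues and
|union| = |V2| + |husk| − |shared| holds exactly.

**Genome partition** (`partition`): promoter = TSS − 1000 to TSS + 200
(strand-aware), flanking = 4 kb upstream of the promoter plus 5 kb
downstream of the TTS. Precedence for overlapping definitions is exon >
intron > promoter > flanking > TE > distal: intronic TE bp count as intron
(as published) and "TE" means intergenic TE space outside regulatory
flanks (the promoter-vs-TE and flank-vs-TE precedence is not documented in
the source; gene-proximal classes win here). Features are assigned to the
class of their midpoint — the straddler rule is likewise this package's
choice. Overlapping promoters of adjacent genes merge.

**Ranking** (`candidates.rank_candidates`): the contrast for a candidate in
tissue T is max over positions of (signal_T − signal_other), computed
exactly on the union of the two step tracks' breakpoints (a per-bp max, not
a windowed mean — the source does not specify; per-bp max is exact on step
tracks). Signed contrast oriented toward the ranked tissue matches the
tissue-specificity intent. Rank ties break by (contrast, chromosome, start)
per assay and by (rank sum, DNase rank, chromosome, start) overall, so
output is deterministic. The permutation null draws, per iteration, one
uniform permutation of 1..N per feature ranking (two here), sums
position-wise and sorts; the p-value at overall rank r is the fraction of
iterations whose r-th smallest null sum is ≤ the observed sum, floored at
1/n_perm. This is the per-rank-position reading of the published
"re-ranked according to the sum 1000 times" construction, exposed as the
only mode.

**Orientation and asymmetry** (`profiling.orient_dhs`): flank enrichment is
the mean H3K9ac over the 300-bp windows immediately up/downstream of the
DHS (a point estimate 300 bp away would be fragile on step tracks). The
higher side becomes 3' (ties keep orientation, flagged); eligibility
requires max flank ≥ `asym_min_rpm` (0.5 RPM) and asymmetry a ≥
`asym_fold` (2.0) ratio, with a zero low flank counting as asymmetric.
Flank means do not exclude bp inside neighbouring DHSs.

**Profile matrices and categories** (`profiling`): bodies are scaled to
`body_bins` (50) equal-width bins, flanks binned at `flank_bin_bp` (20) over
`heatmap_flank_bp` (1000); features shorter than the bin count are
interpolated from per-bp values. k-means (k = 4, scikit-learn, fixed seed,
10 initialisations) clusters the H3K9ac rows; clusters are relabelled 1..k
by descending mean enrichment — a deterministic proxy for the published
top-to-bottom heatmap order — and the labels order companion matrices.

**Expression bins** (`profiling.expression_bins`): bin 0 holds genes below
1 RPKM; the remainder split into 6 equal-count bins by ascending RPKM
(counts differ by ≤ 1 after ties).

**Target linking** (`linking`): nearest flanking genes only, by genomic
coordinate. Tissue-specific candidates link a flanking gene iff it is
significantly differentially expressed with the higher tissue matching;
shared candidates link genes with ≥ `expressed_min_rpkm` (1.0) in both
tissues — the bin-0 boundary is the only expression floor the source
states, so it is adopted as the "expressed" operationalisation. Genes
overlapping a candidate are excluded defensively.

**TE statistics** (`te_stats`): the baseline TE set keeps outermost
elements only (fully nested insertions are dropped — the published nested
resolution rule is not spelled out), drops elements fully inside introns
and elements ≤ 635 bp. A candidate is TE-contained when ≥ 80% of its
length lies within a *single* element. Family enrichment: with K
enhancer-containing baseline elements out of M, a family with M_f members
and k_f hits has p = P(X ≥ k_f), X ~ Binomial(K, M_f/M),
Bonferroni-corrected over families with k_f ≥ 1.

**Motif and permutation tests** (`te_stats`): GGCCCA scanning is
exact-match on both strands (reverse complement TGGGCC), overlaps counted;
PWM scanning is out of scope. Motif enrichment compares the fraction of
candidates with ≥ 1 hit against length-matched uniform draws from
intergenic space. The generic permutation test re-places features
(lengths preserved, non-overlapping, uniform within the mappable mask) and
reports the (b+1)/(n+1) empirical p, never exactly 0 — "p < 0.001" at
n = 1000 corresponds to b = 0. Whether shuffled features may overlap is
not documented; rejection-with-resampling is this package's choice.

**Reporting** (`reporting`): percentages round half-away-from-zero (1
decimal in tables, 0 in prose counts) — banker's rounding fails to
reproduce printed values such as 22%. The overlap table's "Total" row is
the union of the merged tissue sets and labelled as such: the published
per-tissue counts do not sum to the printed total by inclusion-exclusion,
implying a union semantics there too.

## Synthetic data: what it emulates, and what it does not

The generator plants, on two 1-Mb chromosomes with 100 genes each (10-kb
pitch, 2–4-kb genes with 1–4 exons), 60 enhancers (15 V2-IST-only, 30
husk-only, 15 shared — preserving the published ~1:2 tissue imbalance and
~15% shared fraction at desk scale). Each enhancer is a 1.0–1.5-kb
low-methylation valley with a central 300-bp DHS (6 RPM against an 0.02 RPM
background, 0.2 RPM in the undetected tissue) and a 300-bp H3K9ac block on
one randomly chosen side at 2 RPM, fivefold above the opposite flank —
one-sided acetylation at a fold comfortably above the 2.0 classification
threshold. Methylation sites are laid at fixed spacings (CG 29 bp, CHG 31,
CHH 11) with Beta-distributed frequencies centred at 0.86/0.74/0.02 in the
background, 0.05 in valleys, and an mCHH bump (0.15) at valley 5' edges
emulating the boundary-marking mCHH islands of maize. Decoy valleys,
DHS-only and H3K9ac-only valleys, and promoter peaks at 30 genes exercise
the integration filter and the intergenic exclusion. TEs come in six
families across the LTR/TIR/helitron orders, with one family wrapped around
8 planted enhancers (ten wrapping elements in all) to create a detectable
family enrichment, plus sub-635-bp, intronic and nested elements for the
baseline filter. Expression tables give designated target genes DE flags
matching the planted tissue pattern while constraining the opposite
flanking gene to not link, so each noise-free construction has exactly one
recoverable target. The GGCCCA motif is planted in 60% of enhancers on an
otherwise uniform random sequence.

Noise model: per-replicate peak boundaries jitter uniformly ± 30 bp (which
alone can never break the 70% reciprocal rule for 300-bp peaks), and with
probability 0.05 per enhancer and tissue its evidence fails peak calling in
one randomly chosen replicate of one assay — under the all-replicate
consensus rule this removes the tissue's detection, which is what makes
dropout the recall-limiting noise. An event-level dropout is used rather
than independent per-replicate-per-assay missingness because the chained
consensus tolerates no missing replicate at all: independent 5% dropout per
replicate would bound recall near 0.81 by construction, which is not the
regime the generator is meant to model. The Beta concentration is 50: the
run-based segmenter breaks a region at any single site at/above the 20%
threshold, so the per-site spread must keep such sites rare inside planted
valleys (at concentration 50 a 5%-methylated site exceeds 20% with
p ≈ 1e-5; at 20 it is ≈ 1.4% per site, which visibly splits valleys). With
`noise=0`, jitter, dropout and all distributional noise are disabled and
recovery is exact.

What passing on this synthetic data does **not** show: robustness to the
alignment- and peak-calling-level artefacts of real data (mappability bias
inside peaks, copy-number effects, antibody efficiency differences between
replicates), to methylation segmentation over sparse or bimodal coverage,
or to the realistic maize repeat landscape — TEs here are few, disjoint
except for planted nesting, and sequence-free. Genome-scale counts
(thousands of DHSs, tens of thousands of LUMRs) and kb-scale
distance-to-gene statistics are not reproduced at 2-Mb desk scale.

## Numerical choices and degenerate inputs

Signal statistics weight by bp and count uncovered positions as zero; track
maxima include uncovered positions. The max-difference contrast is exact on
the union of step breakpoints. Intervals outside chromosome bounds are
clipped with a warning; unknown chromosomes raise errors naming the
chromosome. Genes without exons are treated as single-exon with a warning.
Regions with no covered methylation sites are retained by the windowed-mean
filter (they cannot be contradicted) with a warning. Empty k-means
categories and empty expression bins yield warnings and NaN profiles.
Candidate sets smaller than k skip clustering. All stochastic components
(permutation nulls, k-means initialisation, the generator) take explicit
seeds and are deterministic given them; CLI runs record seed and config
hash in a manifest.

## Problem sizes used in validation

The test suite and the acceptance script run the full pipeline on the
default 2-Mb synthetic bundle (seconds per run), use exhaustive
enumeration at N = 3 for the permutation-null oracle, 1000-instance
brute-force oracles for interval algebra and motif scanning, 20 pooled
null rankings at N = 100 × 1000 permutations and 200 replicates × 200
permutations for the calibration checks — sizes chosen so the whole
validation completes in about a minute while keeping every statistical
check adequately powered.

## Known limitations

The segmenter is not an HMM: single high-methylation sites split regions
that MethylSeekR would bridge; accordingly LUMR boundaries snap to cytosine
positions and lose up to one inter-site gap per edge. Tissue-specificity
ranking combines two rankings that the source itself reports as
uncorrelated; the ranks are reproduced faithfully but should not be
over-interpreted. Linking considers nearest flanking genes only; enhancers
skipping a gene (documented for real maize loci) are out of scope, as are
repressive candidates. Only two tissues are supported.
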
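# Methods

`srnapipe` re-implements, as a tested pipeline over synthetic data with
planted truth, the computation that takes raw small RNA-seq reads to
quantified known miRNAs, isomiRs, newly annotated star-arm miRNAs and
miRNA-offset RNAs (moRNAs), and onward to normalization, differential
expression, moRNA–miRNA correlation, sample clustering and gene-set
enrichment. This note records the models, the parameters that matter, and
the design decisions taken where the procedure was genuinely open.

## Read preprocessing

Reads are clipped at the leftmost occurrence of the 3' adapter (minimum
overlap 5 nt at the read's 3' end, up to 1 mismatch per 10 aligned bases; N
counts as a mismatch). Reads that are adapter-only or in which no adapter is
found ("unclipped" — the insert was longer than the read, so it cannot be a
miRNA-sized RNA) are discarded. Survivors pass a length window of 15–30 nt
inclusive and a quality filter: mean base quality strictly greater than 30
and at most 2 bases under quality 20. "Higher than 30" is read strictly, so
a read at exactly mean Q30 is dropped. Identical sequences are then collapsed
into unique tags, and ground noise — unique sequences with fewer than 10
reads in a sample — is zeroed per sample (a `pooled` scope, thresholding the
across-sample sum instead, is available; per-sample is the default because
preprocessing is defined per sample). A tag survives overall if it is
retained in at least one sample. The stage emits a per-reason attrition
table (adapter-only, unclipped, length, quality, noise, kept).

## Reference and alignment

Each hairpin precursor is extended by 30 genomic bases per side, strand
aware, so that moRNAs processed just beyond the precursor ends still map
within one reference sequence; flanks are truncated (and recorded) at contig
ends. Internal coordinates are 0-based half-open; everything emitted is
1-based inclusive.

Tags are aligned ungapped and full-length, with up to 2 mismatches — the
budget implied by the isomiR taxonomy — to both strands of the genome and
the forward orientation of the extended hairpins. The aligner is exhaustive
rather than a wrapper around an external program: exact 5-mer seeds at three
disjoint offsets (pigeonhole: with ≤2 mismatches one seed is clean) feed a
vectorized full-length verification, and on small targets it is tested
position-for-position against a naive sliding-window scan. Tags whose exact
sequence recurs at more than 5 distinct genomic loci (position+strand)
outside hairpin regions (hairpin locus ± flank) are discarded as repetitive;
mismatch-tolerant hits do not count toward the locus tally because the
filter asks where the exact sequence recurs (a switch exposes the
alternative).

## Feature annotation

A kept tag goes to its best hairpin hit (fewest mismatches, then hairpin id,
then position) and is first tested as an isomiR of an annotated mature:
`exact` (identical), `shorter_longer` (0 mismatches, 1–2 nt end offsets at
either end), or `mismatch1/2` (same interval, 1–2 substitutions). The
affected region is called 5'/3'/both from the end offsets, or for
substitutions from the tag midpoint (first ⌈L/2⌉ positions are the 5' half).
End offsets beyond 2 nt disqualify a tag as an isomiR and send it to cluster
analysis.

Remaining tags on a hairpin are grouped into read clusters by interval
overlap (≥1 shared base, transitive closure). A cluster must total ≥10 reads
(the ground-noise floor, reused for consistency). Its representative is the
most abundant tag (ties: longer, then lexicographic). Classification:

* **new miRNA** — on hairpins with a single annotated mature, the star arm
  is predicted by a maximum-base-pairing fold (Nussinov dynamic program;
  AU/CG/GU pairs, minimum loop 3, traceback ties resolved toward pairs
  closer to the hairpin ends), mapping each mature position across its
  partner, taking the spanning interval and imposing the canonical 2-nt 3'
  overhang (a `+2` shift of the mirrored interval on either arm). A cluster
  whose 5' end lands within ±3 nt of the predicted star 5' end is a new
  miRNA, named `<mature>*`. Because a moRNA can sit flush against the star
  product, tags matching the star 5' end form their own cluster before
  overlap-grouping — otherwise a single bridging read merges the two
  features. Prediction is skipped when fewer than half of the mature bases
  pair, or the implied star collapses onto the mature.
* **moRNA** — a cluster whose representative has more than 50% of its bases
  outside all mature/new-miRNA intervals, named `moR-<hairpin>-5p/3p`, with
  the arm set by the representative midpoint relative to the 5p mature start
  / 3p mature end (hairpin midpoint as fallback). One moRNA per arm is
  named plainly; further same-arm clusters are numbered.

The >50%-outside rule and the ±3 nt star tolerance are this package's
quantifications of qualitative descriptions; no published numeric rule
exists for either. Every kept tag ends in exactly one feature or in an
unassigned list with a reason, and classification is invariant to input
order.

## Quantification and normalization

Known-miRNA expression sums the mature's `exact` and `shorter_longer` isomiR
tags; reads matching the hairpin with substitutions stay visible at the
isomiR level but are excluded from the miRNA total. Cluster features sum
their member tags.

Size factors are median-of-ratios: s_j = median over features (positive in
every sample) of k_ij divided by the feature's geometric mean. The
dispersion–mean relationship of the NB model (variance = μ + αμ²) is
estimated per feature by method of moments on normalized counts, with the
variance pooled *within* conditions so a real group difference does not
masquerade as dispersion, then smoothed two ways: a parametric least-squares
fit α(q) = a0 + a1/q, and a tricube-weighted local linear regression of α on
log q (span 0.7, no robustness iterations). The fit with the smaller
residual sum of squares is selected (tie → parametric); both RSS values are
reported. Fitted dispersions are clamped at 1e-8.

## Differential expression

Features whose total normalized expression is strictly above the median of
those totals are tested (the rest report NA). The test is the conditioned NB
exact test: given a feature's total K over both groups, every split (a, K−a)
is scored by the product of NB probabilities with group means q·S_g and
variances q·S_g + α q² Σ s_j², and the p-value is the summed probability of
all splits at most as likely as the observed one, normalized by the total.
At zero dispersion and equal size-factor sums this reduces exactly to the
two-sided binomial test, which the suite verifies for every split of every
K ≤ 30. BH correction is applied at FDR 0.05; fold changes are
log2(disease/control), capped at ±15 with a one-sided zero reporting the cap
exactly.

**Dispersion sharing.** Two modes are exposed and the choice matters more
than any other knob in the pipeline. `maximum` (default) tests each feature
at the larger of the fitted value and the feature's own moment estimate;
`fit-only` trusts the fitted curve. With 3 samples per group and dispersion
0.2, our simulations put the global-null probability of any BH call at 0.05
at ~0.04 for `maximum` and ~0.05–0.065 for `fit-only` — the plug-in exact
test is *not* automatically conservative once the fitted curve's sampling
noise is taken into account, although with the true dispersion supplied the
rate is 0.03. Conversely, planted 4-fold effects at 1M reads/sample are
recovered among testable features with sensitivity ~0.69 under `fit-only`
but only ~0.35 under `maximum`. The default follows the conservative
classic rule; analyses that can tolerate a null error rate at the nominal
boundary can switch to `fit-only` for roughly double the sensitivity.

isomiR-level differential expression is a Welch t-test on log2(normalized
counts + 1), flagged at |log2FC| ≥ 1 and BH-adjusted p < 0.05; a companion
column restricts correlation analyses to isomiRs contributing ≥10% of their
mature's expression. Sample clustering is complete linkage on Euclidean
distances of log2(normalized + 1), optionally restricted to features above
the median or the third quartile of totals (type-7 quantiles). moRNA–miRNA
correlation pairs each moRNA with the known miRNA of the same hairpin arm:
Pearson r, t-transform p, BH q, significance at q ≤ 0.1. Enrichment is the
upper-tail hypergeometric test of a target-gene list against a GMT
collection intersected with the universe, BH-corrected at q ≤ 0.05; target
prediction itself is out of scope and the stage accepts externally produced
lists.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the pipeline is validated under: 3 control vs 3 disease samples,
30 hairpins on a 1 Mb toy contig, 50,000 reads per sample, NB dispersion
0.2, per-sample scale factors log-uniform in [0.5, 2], 10% of features
differentially expressed at |log2FC| = 2, an isomiR mixture in which the
exact sequence carries ~34% of a miRNA's reads and end variation is
dominated by the 3' end, moRNAs on 30% of hairpins with a 0.84 probability
of the 5' arm, star-arm products planted on single-mature hairpins, decoy
22-mers at 1–10 genomic copies, and one moRNA planted highly expressed in
controls (above the third quartile of feature means) and absent from
disease. Hairpins are imperfect inverted repeats (one mid-arm substitution)
whose annotated matures sit at a canonical 2-nt-overhang duplex; moRNAs are
planted flush with (0–1 nt from) the mature boundary, reaching into the
30-bp flank. Reads carry the Illumina TruSeq small-RNA 3' adapter
(configurable; only the kit, not the string, is public for the original
protocol) and per-base qualities from a two-component model (high ≈ Q38,
low ≈ Q15) so the quality filter has work to do, plus configured fractions
of adapter-only, unclipped, low-quality, out-of-window and low-count noise
reads. With a fixed seed the FASTQ output is byte-identical.

What the generator does *not* emulate: position-dependent sequencing error,
ligation bias, cross-mapping between homologous miRNA families, RNA editing
beyond uniform substitution, UMIs, paired ends. Passing tests therefore
demonstrate the pipeline's internal correctness and its behavior under the
assumed statistical model, not robustness to those real-data artifacts.

Counts simulated directly (without reads) use the same planner and NB
sampler; totals per sample then follow the planted scale factors, and the
"totals track depth" property holds in the Poisson limit with unit scale
factors, which is how it is tested.

## Problem sizes and runtime choices

Simulation-heavy checks are sized to run comfortably on one CPU: the
global-null calibration uses 200 datasets of 500 features (≈3 minutes); the
planted-DE power check averages seeds 0–4 at 500 features and 1M
reads/sample; parameter-recovery checks use 1,200–5,000 features; the
end-to-end recovery check runs the full default study (≈20 s). The
acceptance script reruns the fold-change cap on the published group counts
(2493 vs 0) and the 200-replicate null calibration from scratch.

## Known limitations

* The exact test's dispersion plug-in is the classic moment/fit approach;
  shrinkage estimators from later model generations are deliberately out of
  scope.
* The star predictor maximizes pairing count, not free energy; on long
  low-complexity stems its traceback can differ from an energy model by a
  few nucleotides, which the ±3 nt cluster tolerance absorbs in practice.
* Naming assumes at most one plain moRNA per arm per hairpin.
* The aligner is designed for desk-scale references (≤ a few Mb); it is
  exhaustive and correct, not competitive with indexed aligners at genome
  scale.
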
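# Methods

## The design problem

Genotyping arrays for recently whole-genome-duplicated species fail mostly
through paralogy: reads from duplicated segments co-align to one locus and
produce apparent heterozygotes (paralogous sequence variants), and probes
whose flanking sequence recurs in the genome hybridize to multiple loci.
This toolkit implements an array-design pipeline that attacks paralogy at
three points — double-haploid (DH) heterozygosity, combined-depth and
heterozygosity-excess caps, and genome-wide flank-uniqueness — and then
selects SNPs in narrow focal points (FPs) so they can be combined into
multi-allelic haploblock markers for pedigree-based analysis.

## Quality cascade

Calls supported by fewer than `min_call_support` (10) reads are masked to
missing before any verdict; depths are retained for reporting. The cascade
then evaluates, in order: DH heterozygosity, site quality (< 20 phred
fails), combined depth (> 2000 fails), per-sample support (fails only when
*strictly more than* half the diploid members are under 10 reads — exactly
half passes, a boundary tested explicitly), caller strand-bias (p < 0.001)
and tail-distance-bias (p < 0.05) annotations, a BED mask of
low-mapping-confidence regions, and the allele-frequency rule (fails when
every called diploid allele is non-reference).

Decisions taken where the procedure was open:

* a missing DH call does not count as heterozygous — the filter acts on
  observed heterozygosity; treating missing as het would discard
  low-coverage regions twice;
* the 50% low-support denominator is the 14 diploid members only: the DHs
  are paralogy instruments, not panel diversity, and their near-double
  coverage would dilute the fraction;
* allele frequency is likewise computed over diploid members only, over
  non-missing calls, with the denominator carried in the profile;
* funnel accounting attributes each removed record to the *first* failing
  reason in cascade order, so per-reason removals are additive and
  survivors = input − Σ removals holds exactly (violations raise).

## Probe compatibility

Infinium II probes interrogate a single bi-allelic substitution, so indels,
tri-allelic sites and A/T or C/G pairs (which would need two bead types)
are removed; any other quality-stage survivor within 50 bp disqualifies a
site (the rule is symmetric — both members of a close pair fail); and both
24-mers directly flanking the SNP must be unique genome-wide. "High
quality SNPs" for the 50 bp rule are the quality-stage survivors, not all
raw variants, because the rule operates after quality filtering.

Flank uniqueness uses a canonical k-mer index: every genome window of 24 bp
is counted under min(code, revcomp-code), since probes hybridize to either
strand. Windows containing ambiguity codes are tallied separately and
always treated as non-unique. The index is two sorted numpy arrays (codes,
counts); lookup is binary search. Whether one repeated flank disqualifies a
SNP or both must repeat is genuinely ambiguous in practice; the default is
the stricter `either`, matching the aim of avoiding paralog-binding probes,
with `both` available via `ProbeRules(uniqueness_mode="both")`.

The external design score (probe convertibility, in [0, 1]) is consumed,
never computed: sites scoring below 0.7 fail, absent scores pass with a
logged notice.

## Focal points

An FP is a ±5 kb closed window (`half_width` = 5000; coordinates are
1-based inclusive throughout, with BED converted at the boundary).
Placement is anchored → bridge → terminal:

* **anchored**: one FP per integer cM of the genetic map, physical center
  by linear interpolation between flanking map points; beyond the mapped
  interval a constant `kb_per_cM` (440 kb) extrapolation is used, the only
  genome-wide ratio available. Duplicate-cM markers collapse to the first
  with a warning; map rows that break bp-monotonicity are dropped at load.
* **bridge**: any gap g > 400 kb between consecutive centers (chromosome
  start and end count as boundaries) receives ceil(g / 440 kb) − 1 equally
  spaced FPs; a chromosome with no FPs is tiled every 440 kb. After
  bridging no inter-center gap can exceed 440 kb (tested as a property).
* **terminal**: up to `terminal_fps_per_end` (default 4) extra FPs inside a
  40 kb window at each chromosome end, spaced 2·half_width, skipping
  positions within half_width of an existing FP. Published designs of this
  family report only the genome-wide total of terminal FPs (≈3.5 per end
  over 17 chromosomes); the per-end count is deliberately configuration.

Centers closer than half_width are deduplicated with precedence anchored >
bridge > terminal. Candidates are assigned to the FP whose closed window
contains them; with overlapping windows the nearest center wins, ties to
the lower fp_id — this makes FP candidate sets a partition, which the
per-FP cap requires.

## Tiered selection

Per-SNP heterozygosity profiles are taken over the diploid members in panel
order; missing calls are not heterozygous and shrink the denominator. At
P = 14 the strata are: tier 1 = het fraction in [0.35, 0.60] (5–8
members), tier 2 = [0.10, 0.35) (2–4 members), tier 3 = exactly one
member; fractions in (0.60, 0.65] or below 0.10 with ≥ 2 members form a
filler stratum, eligible but chosen last (they must be eligible because an
FP with ≤ 11 candidates selects everything). Above 0.65 is excluded as
probable paralogy; so is zero heterozygosity (uninformative). Inclusive
bounds were chosen so that P = 14 reproduces the named member counts
exactly.

Within an over-subscribed FP the selector works stage-wise: up to 5 tier-1,
fill with tier-2, then tier-3 (at most one per member, uncovered members
preferred, reduced-weight members only if slots remain), then filler by
descending heterozygote count, stopping at 11. "Complementary as far as
possible" is operationalized as a greedy with concave marginal gain
Σ_m 1/(1 + c(m)): members covered by fewer already-selected SNPs contribute
more, so coverage balances across the panel. Ties break to higher design
score, then smaller position, then id; candidates are canonically sorted
first, making the output invariant to input order and byte-deterministic.

Duplicate genotype profiles (identical calls across all diploid members,
not merely the same het pattern) collapse before selection to the
highest-scoring representative (tie: smallest position). After per-FP
selection, adjacent FPs on a chromosome are scrutinized: if both carry a
tier-3 SNP for the same member, the FP with more unselected alternatives
swaps its copy for the best replacement (re-running the greedy gain,
excluding re-conflicting candidates) or drops it. "Adjacent" means
consecutive in (chrom, center) order; the reduced-weight "fill-last"
policy implements down-weighting of an outgroup without inventing a
numeric quota, since none is established.

On adversarial candidate sets a one-pass stage-ordered greedy can trail the
exhaustive distinct-member-coverage optimum (typically by one member, when
a late-stage filler uniquely covers a member that an earlier redundant pick
displaced). The greedy-vs-oracle acceptance fixtures therefore specify the
redundancy regime the design targets — every covered member covered by at
least two candidates, at most five tier-1, distinct tier-3 members — under
which the greedy provably attains the optimum; the test still verifies cap
and dedupe behavior on every instance and reports any coverage gap per
instance.

Legacy (previously validated) markers merge after selection: inside an FP
window they attach to it exempt from the 11-SNP cap; elsewhere they ride
outside any FP; a legacy marker at the same (chrom, pos) as a new
selection replaces it (one manifest row, source `legacy`).

## Reporting

Funnel survival percentages are rounded half-even to one decimal. Headline
means (SNPs per FP, SNP density per kb) are emitted both at full precision
and truncated to one decimal; truncation, not rounding, is the convention
under which published figures of this kind (7.7 from 7.76…, 4.8 from
4.86…) are reproducible, and both values are always reported.

Concordance compares a forward-strand array report against sequencing
calls per sample: comparisons require non-missing calls on both sides and
≥ 10 reads of sequencing support; a match is an identical unordered allele
pair. Samples with zero comparisons are excluded from the mean with a
warning. A strand-flip audit is a consumer concern: the report is assumed
forward-strand and is not auto-corrected.

## Synthetic panels

`SimulationSpec` defaults define the study conditions: 4 chromosomes of
500 kb, a panel of 14 diploids (one reduced-weight outgroup) plus 2 DHs,
1,450 clean variants and 50 per artifact class (~2,000 total), per-sample
depth ~ Normal(35, 8) clipped at 11 (emulating 30–45× panels; clean calls
never fall below the 10-read support threshold by construction), genetic
map markers every 0.5 cM at 440 kb/cM, design scores in [0.72, 0.99] for
clean SNPs, and a 5% array discordance rate. Everything is a deterministic
function of the seed.

Construction guarantees: artifact classes are orthogonal (each planted
variant violates exactly one filter), variant positions keep > 50 bp of
clearance except the deliberately paired near-SNP class, repeat-flank
variants have their upstream 24-mer copied into a reserved variant-free
region, and 14 extra clean variants are packed into the first anchored FP
window of each chromosome so the over-subscribed selection path is
exercised. What the generator does *not* model: read-level errors,
linkage/LD structure between candidates, overlapping failure modes, or
probe-chemistry mechanisms of discordance (flips are uniform). Passing
tests therefore demonstrate correctness of the decision rules under
separable conditions, not robustness to the entangled failure modes of
real re-sequencing data.

## Problem sizes and numerics

The test suite and acceptance script run the full pipeline on the default
2 Mb / 2,000-variant panel (seconds on one CPU); the published genome-scale
funnel is replayed from its printed stage counts through the same
conservation-checked accounting rather than recomputed from raw data,
which is the package's intended way to audit any external run. Brute-force
oracles (both-strand substring scans, exhaustive subset search) back the
k-mer index and the greedy selector on these sizes. Thresholds are applied
with the exact strictness stated above (e.g. depth 2000 retained, 2001
removed; score 0.70 retained); no floating-point tolerances are needed
anywhere except the documented truncation/rounding conventions.

## Known limitations

* The pipeline consumes a single merged variant file; multi-assembly
  alignment/merging happens upstream.
* Bias tests are consumed as caller annotations, never recomputed from
  reads; absent annotations pass.
* The scrutiny rule considers consecutive FPs only; a sparser notion of
  "same region" would need a distance-based definition that is not
  established.
* Discordant loci are reported but not classified by cause (low depth vs
  probe-site SNPs).
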
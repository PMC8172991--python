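# Methods

## Scope and data model

`panelval` implements the computational layer of a targeted-panel clinical
validation: everything downstream of primary variant calling. Inputs are the
caller's outputs (small-variant VCF, fusion/splice CSV, CNV CSV), the panel
target space (BED with transcript/exon tags), per-base depth (TSV), and a
truth set (JSON) describing the expected content of a control or previously
characterized specimen. Read-level processing (alignment, primary calling,
BAM/FASTQ handling) is out of scope by design.

Coordinates follow the two standards the package touches: intervals are
0-based half-open (BED), variant positions 1-based (VCF); a 1-based position
`p` lies in `[s, e)` iff `s < p ≤ e`. Variant identity is the full tuple
`(chrom, pos, ref, alt)` **after** normalization (left alignment plus
parsimony trimming, the `vt`-style algorithm). Matching by full allele
identity is the strictest defensible rule; position-only matching would be
more permissive and is deliberately not offered, so any disagreement in
alleles at a shared position surfaces as an FP plus an FN rather than a TP.

The VCF dialect is vendor-specific, so the FORMAT keys carrying the per-call
metrics (depth, VAF, GQ, strand bias, adjusted quality, supporting reads) are
a configurable tag map; the defaults (`DP`, `VF`, `GQ`, `SB`, `AQ`, `AO`) are
what the synthetic writer emits. Multi-allelic records are split before
anything else; each ALT is an independent call.

## Filter cascade

The standard cascade applies seven manufacturer-style filters with inclusive
boundaries, exactly as printed in vendor documentation for this class of
assay: variant quality GQ ≥ 20, depth DP ≥ 100, strand bias SB ≤ 0.5, variant
frequency VF ≥ 0.026, indel reference repeat (homopolymer run ≤ 8), adjusted
quality AQ ≥ 10, and variant support ≥ 7 reads. Inclusive semantics are
asserted by boundary tests (a variant sitting exactly on every threshold
passes). The homopolymer filter applies only to insertions/deletions and
measures the longest single-base run starting at or immediately after the
indel anchor base, scanned in a 20-base downstream window (sufficient to
detect any run > 8).

Strand bias is treated as a generic score with a `≤` comparator. An
alternative convention expresses the same bound on a phred-like scale (3.01);
`FilterConfig.gatk_strand_bias_preset()` exposes that preset, but no
conversion between the scales is attempted — the consumed annotation must
already be on the matching scale, because the exact conversion formula is not
published.

Missing metrics are a policy question: `strict` mode fails the corresponding
filter (conservative — a call with no AQ cannot claim to have passed the AQ
filter), `lenient` mode skips it and records it as not-evaluated, which is the
right behavior for control VCFs produced by third-party callers that lack a
vendor-specific tag.

Reporting filters (depth ≥ 100× with VAF ≥ 2.6%, or depth ≥ 250× with
VAF ≥ 5%) sit on top of the cascade and define what "detected" means for
concordance and LOD purposes. The triage bands (report ≥ 5%, review 3–5%,
suppress < 3%) reflect the clinical practice of auto-reporting confident
calls and routing marginal VAFs to pathologist review.

## Concordance semantics

For small variants, against a truth set over a target space with coverage
`D(p)` and a sufficiency bound `m` (the depth bound of the active reporting
filter — 100 or 250):

* **TP** — observed in-target call whose key is in the truth set;
* **FP** — any other observed in-target call (calls outside the target are
  excluded and logged, never counted);
* **FN** — expected variant not called, with `D(pos) ≥ m`;
* **No Call** — expected variant not called, with `D(pos) < m`; uncallable
  positions are not penalized and are excluded from FN;
* **TN** — every remaining target base with `D(p) ≥ m` touched by neither an
  observed nor an expected variant's reference span.

The TN unit is the target-space base because the magnitudes that make NPA/NPV
meaningful for a panel are the millions of interrogated coding positions, not
a variant count. Whether touched positions are excluded from TN or not moves
NPA by well under 0.1% at panel scale; the partition above is the one the
per-position oracle in the test suite enumerates, and the classifier is
required to agree with that oracle exactly. Two conservation laws are
asserted: `TP + FN + NoCall = |truth|` and `TP + FP = |in-target observed|`.

CNV concordance is per gene against a reporting policy: amplifications at or
above `min_copies_call` (4 by default; 7 is a stricter site policy), large
deletions at or below 1 copy, diploid baseline 2. A truth entry is an
*expected positive* when it deviates from baseline in a reportable direction;
an expected amplification answered only by a deletion-direction call is an FN,
and FPs are reserved for reportable calls on genes not expected positive.
Duplicate observed calls for a gene keep the maximum deviation from baseline.

Fusions match as unordered gene pairs with each breakpoint inside an expected
exon interval of its gene (half-open containment). Admissibility is a policy:
high-confidence calls only, or high+low; splice-variant events additionally
need ≥ 20 supporting reads. FN reasons distinguish `not_called` from
`low_confidence_filtered`. TN is undefined for fusions and CNVs (no natural
negative unit); the counts carry a `tn_applicable` flag and NPA/NPV are
reported as NA.

## Accuracy and reproducibility statistics

PPA/NPA/PPV/NPV are plain ratios stored at full precision; presentation uses
round-half-up to one decimal, and rounding never feeds back into computation.
Note that half-up rounding renders 99.9959% as 100.0 — tables produced with
truncation will disagree in such cells by one display unit. Zero denominators
yield "undefined" (NA), never an exception. Wilson-score 95% intervals are
available but optional.

Replicate reproducibility has no designated truth, so pairwise agreement is
the symmetric directional mean (the average of |A∩B|/|A| and |A∩B|/|B|);
Jaccard is available as an option. A replicate design groups call sets by
provenance (run, operator, machine); intra-run compares within a run,
the inter-* factors compare across levels, and an explicit pair list is
accepted so any comparison scheme is representable (e.g. designs whose
pairwise counts are not simply `n·(n−1)/2`). Factor averages are means over
comparisons, not pooled counts.

## Limit of detection

Dilution is modeled as mass-proportional: a control fraction `f` scales every
expected VAF by `f` (wild-type diluent carries no alternate alleles), and a
"1:1 dilution" is `f = 0.5`. Detection of a variant with expected allele
fraction `p` at depth `N` is the binomial tail

    P[X ≥ max(min_support, ⌈min_vaf·N⌉)],  X ~ Binomial(N, p)

(the ceiling is computed after rounding `min_vaf·N` to 9 decimals, because
e.g. `0.05 × 500` is `25.000000000000004` in binary floating point and must
require 25 reads, not 26). The per-variant LOD over a detection table is the
smallest dilution fraction such that **every** level at or above it reaches
the required detection rate — robust to non-monotone flukes at low levels,
which trigger a warning; a `first_crossing` alternative is exposed by flag.
Because detection means "present in the filtered call set", the LOD is always
relative to a stated reporting filter. Probit-style LOB/LOD/LOQ regression
(CLSI EP17) is noted as future work; the level-wise rule matches how dilution
panels are actually read in this setting.

RNA fusion abundance is in copies/ng. Supporting reads are modeled as
Poisson(copies/ng × input ng × capture efficiency × fraction) — the simplest
model consistent with an LOD denominated in copies/ng; capture efficiency is
a configuration scalar (default 0.05 reads per copy-ng at the default 50 ng
input), chosen so that 7 copies/ng sits near the high-confidence detection
boundary, mirroring the assay's claimed RNA LOD.

Input qualification follows the clinical protocol for low-concentration
specimens: with recommended ranges of 40–120 ng total DNA at 3.3–10 ng/µl
(40–85 ng at 4.7–10 ng/µl for RNA), a specimen passes when both concentration
and total mass are in range; when the total mass is in range but the
concentration is not (e.g. 1 ng/µl × 50 µl = 50 ng), it is *qualified* —
reportable with a caveat about elevated false-negative risk; when the total
mass is out of range it fails.

## Coverage QC

A profile passes when ≥ 95% of positions reach ≥ 250×. Two pass semantics are
shipped because both readings exist in practice: the whole-sample fraction,
and a stricter rule requiring every exon (or transcript) to pass
individually; both are reported and the scope is a flag. Per-transcript
failure tables count, for each transcript, the samples in which it fails —
the standard way to spot systematically under-covered content. Mapping-rate
summaries are out of computational scope (they require BAMs).

## Synthetic controls: what they emulate and what they do not

The generator reproduces the *structure* of the commercial reference
materials: a DNA hotspot control with ~500 mutations across 53 genes in five
variant classes (default mix 60% SNV, 10% MNV, 12% insertion, 12% deletion,
6% complex) at VAFs drawn from a bulk Uniform(0.05, 0.5) plus a 20%
low-VAF tail Uniform(0.02, 0.05) that exercises the review band; and an RNA
mix of 14 fusions, one exon-skipping event and one multi-exon deletion, with
most abundances at 13 copies/ng, one at 8 and one at 6 — the 6 copies/ng
entry deliberately below the 7 copies/ng LOD claim, so its intermittent
detection is expected behavior, not a bug. CNV truth defaults to three
amplifications (9, 5 and 4 copies) and one large deletion (0.5 copies).

The read-sampling model is: per-base depth gamma-Poisson with mean 500× and
10% CV (so No-Call events arise naturally at low input); alt reads
Binomial(depth, VAF·f); spurious calls Poisson at 2 per megabase per sample
with VAFs in 3–8%; fusion supporting reads Poisson as above, tiered into
high confidence (≥ 10 reads), low confidence (4–9), or absent. Quality
metrics (GQ, SB, AQ) are drawn from passing ranges by default, with hooks to
inject failures of each named type. `noise = 0` collapses every draw to its
rounded mean — replicates become byte-identical, which pins down the
plumbing: zero-noise runs must show exactly 100% concordance in every
replicate factor and 100% PPA/PPV in every class.

What the synthetic data does **not** emulate: FFPE artifact chemistry
(deamination), sequence-context-dependent error, mappability, library
complexity, or inter-site protocol differences. Passing tests therefore
demonstrate that the *computations* are correct and internally consistent
with the stated stochastic model — not that any particular assay attains a
particular clinical sensitivity. Statistics tied to restricted specimen
content (the published reproducibility percentages, the 71%/62% sensitivities
at 1:1 dilution, the 98% coverage pass rate) are not desk-reproducible;
they are replaced by exact recomputation from published confusion counts and
by model-based recovery experiments.

## Numerical and design choices

* Determinism: every stochastic step uses `numpy.random.default_rng` seeded
  from the configuration seed plus a fixed stream id; identical configurations
  give byte-identical output files.
* Problem sizes: the test suite and acceptance script run the oracle
  comparison on 500 random instances of ≤ 2 000 target positions, the LOD
  recovery on series of six levels × 20 replicates (200 seeded repetitions in
  the tests, 100 in the script), and zero-noise scenes of 150 variants over
  20 transcripts — sizes chosen so the full statistical checks complete in
  seconds while keeping Monte-Carlo error far below the asserted margins.
* The LOD recovery experiment fixes depth at 500× (zero CV) so the binomial
  closed form is exact rather than marginalized over depth; the dilution grid
  (1.0, 0.84, 0.68, 0.5, 0.33, 0.17) and a 15% stock VAF place the expected
  VAF's crossing of the 5% reporting bound between the 0.5 and 0.33 levels.
* Degenerate inputs: zero denominators give NA statistics; empty dilution
  series, empty coverage scopes and sub-two-level LOD tables raise; a truth
  variant outside the target space is a configuration error, not an FN.
* Tie-breaks: duplicate CNV calls keep the maximum deviation from baseline;
  fusion matching tries both gene-pair orientations and accepts either.

## Known limitations

* Strand bias and adjusted quality are consumed, never recomputed; their
  scales are caller-specific.
* Haplotype-aware or distance-based variant matching (as in dedicated
  benchmarking tools) is out of scope; complex representations that differ
  after normalization will not match.
* The fusion model treats capture efficiency as a single scalar; real
  per-fusion efficiencies vary with junction sequence (the motivating assay
  has a documented repetitive-junction failure mode that a scalar cannot
  express).
* CNV concordance is gene-level with scalar copy numbers; no segment-level
  or allele-specific analysis.
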
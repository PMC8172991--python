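"""Truth-set concordance: TP/FP/FN/TN/No-Call classification.

Semantics
---------
Small variants are matched by full identity ``(chrom, pos, ref, alt)`` after
normalization.  An observed in-target call matching the truth set is a TP and
any other in-target call is an FP (calls outside the target space are excluded
and logged, not counted).  An expected variant that was not called is an FN
when its position reached the minimum coverage, and a **No Call** when it did
not — uncallable positions are not penalized.  Every remaining target position
with sufficient coverage that carries neither an observed nor an expected
variant contributes one TN, so the TN unit is the target-space base.

Fusions match when the observed gene pair equals the expected pair (unordered)
and each breakpoint falls within an expected exon interval of its gene.  CNVs
match per gene against a reporting policy (amplification threshold, deletion
threshold, diploid baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    CnvCall,
    CoverageProfile,
    FusionCall,
    FusionTruth,
    GenomicInterval,
    SmallVariant,
    TruthSet,
    VariantCallSet,
    merge_intervals,
    position_in_target,
)

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN/No-Call tallies for one variant class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    no_call: int = 0
    variant_class: str = ""
    tn_applicable: bool = True

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn, self.no_call) < 0:
            raise ValueError("confusion counts must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
            no_call=self.no_call + other.no_call,
            variant_class=self.variant_class or other.variant_class,
            tn_applicable=self.tn_applicable and other.tn_applicable,
        )


@dataclass(frozen=True)
class CnvPolicy:
    """Copy-number reporting policy: amplifications at or above
    ``min_copies_call`` copies, large deletions at or below
    ``max_copies_deletion`` copies, against a diploid baseline."""

    min_copies_call: float = 4.0
    max_copies_deletion: float = 1.0
    baseline_copies: float = 2.0

    def __post_init__(self) -> None:
        if not (self.min_copies_call > self.baseline_copies
                > self.max_copies_deletion >= 0):
            raise ValueError(
                "require min_copies_call > baseline_copies > "
                "max_copies_deletion >= 0"
            )


@dataclass(frozen=True)
class FusionPolicy:
    """Which fusion calls are admissible as positives: high-confidence only or
    high+low, and the minimum read support for splice-variant events."""

    include_low_confidence: bool = False
    min_splice_reads: int = 20

    def __post_init__(self) -> None:
        if self.min_splice_reads < 0:
            raise ValueError("min_splice_reads must be >= 0")


def classify_small_variants(
    observed: VariantCallSet,
    truth: TruthSet,
    target: list[GenomicInterval],
    coverage: CoverageProfile,
    min_depth: int,
    audit: list | None = None,
) -> ConfusionCounts:
    """Classify observed small-variant calls against a truth set.

    ``min_depth`` is the sufficient-coverage bound that separates FN from
    No-Call and defines which target bases are eligible as TN; it should equal
    the depth bound of the active reporting filter.  ``audit``, when given, is
    appended with ``(variant_key, label, reason)`` records.
    """
    target = merge_intervals(target)
    truth_keys = truth.small_variant_keys()
    truth_by_key = {v.key: v for v in truth.small_variants}
    for v in truth.small_variants:
        if not position_in_target(target, v.chrom, v.pos):
            raise ValueError(
                f"truth variant {v.key} lies outside the target space; "
                "truth sets must be in-panel"
            )

    def log(key, label, reason=""):
        if audit is not None:
            audit.append((key, label, reason))

    tp = fp = fn = no_call = 0
    in_target_observed: list[SmallVariant] = []
    for v in observed.variants:
        if not position_in_target(target, v.chrom, v.pos):
            logger.info("call %s outside target space: excluded", v.key)
            log(v.key, "excluded", "outside_target")
            continue
        in_target_observed.append(v)
        if v.key in truth_keys:
            tp += 1
            log(v.key, "TP", "")
        else:
            fp += 1
            reason = "wrong_allele_at_truth_position" if any(
                k[:2] == (v.chrom, v.pos) for k in truth_keys
            ) else "not_in_truth"
            log(v.key, "FP", reason)

    observed_keys = {v.key for v in in_target_observed}
    for key in sorted(truth_keys - observed_keys):
        tv = truth_by_key[key]
        depth = coverage.depth_at(tv.chrom, tv.pos)
        if depth is None:
            raise ValueError(
                f"coverage profile does not span truth position {key[:2]}"
            )
        if depth >= min_depth:
            fn += 1
            log(key, "FN", "not_called")
        else:
            no_call += 1
            log(key, "NoCall", f"depth {depth} < {min_depth}")

    # TN: sufficiently covered target bases untouched by any in-target
    # observed or expected variant (touched = reference span of the alleles)
    touched: set[tuple[str, int]] = set()
    for v in list(in_target_observed) + list(truth.small_variants):
        lo, hi = v.span
        for p in range(lo, hi + 1):
            touched.add((v.chrom, p))
    covered_total = int(np.count_nonzero(coverage.depths >= min_depth))
    covered_touched = sum(
        1
        for chrom, p in touched
        if position_in_target(target, chrom, p)
        and (d := coverage.depth_at(chrom, p)) is not None
        and d >= min_depth
    )
    tn = covered_total - covered_touched
    return ConfusionCounts(
        tp=tp, fp=fp, fn=fn, tn=tn, no_call=no_call, variant_class="small_variant"
    )


def classify_cnvs(
    observed: list[CnvCall],
    truth: list[tuple[str, float]],
    policy: CnvPolicy | None = None,
    audit: list | None = None,
) -> ConfusionCounts:
    """Classify observed CNV calls against expected per-gene copy numbers.

    A truth entry is an *expected positive* when its copy number deviates from
    the diploid baseline in a reportable direction (amplification above
    baseline, deletion at or below the deletion bound).  A TP requires a
    pass-filter observed call for that gene meeting the policy threshold in
    the same direction.  TN is not defined for this class.
    """
    if policy is None:
        policy = CnvPolicy()

    def log(gene, label, reason=""):
        if audit is not None:
            audit.append((gene, label, reason))

    # deduplicate observed per gene: keep the maximum deviation from baseline
    by_gene: dict[str, CnvCall] = {}
    for call in observed:
        if not call.passed:
            continue
        prev = by_gene.get(call.gene)
        if prev is None or abs(call.copies - policy.baseline_copies) > abs(
            prev.copies - policy.baseline_copies
        ):
            if prev is not None:
                logger.info(
                    "duplicate CNV call for %s: keeping max-deviation call", call.gene
                )
            by_gene[call.gene] = call

    def reportable(copies: float) -> str | None:
        if copies >= policy.min_copies_call:
            return "amplification"
        if copies <= policy.max_copies_deletion:
            return "deletion"
        return None

    def expected_direction(copies: float) -> str | None:
        if copies > policy.baseline_copies:
            return "amplification"
        if copies <= policy.max_copies_deletion:
            return "deletion"
        return None

    tp = fn = fp = 0
    expected_positive_genes: set[str] = set()
    for gene, exp_copies in truth:
        direction = expected_direction(exp_copies)
        if direction is None:
            continue
        expected_positive_genes.add(gene)
        call = by_gene.get(gene)
        if call is not None and reportable(call.copies) == direction:
            tp += 1
            log(gene, "TP", direction)
        else:
            fn += 1
            log(gene, "FN", "not_detected" if call is None else "below_threshold")
    for gene, call in sorted(by_gene.items()):
        if gene not in expected_positive_genes and reportable(call.copies):
            fp += 1
            log(gene, "FP", "unexpected_cnv")
    return ConfusionCounts(
        tp=tp, fp=fp, fn=fn, tn=0, variant_class="cnv", tn_applicable=False
    )


def _breakpoints_match(
    call: FusionCall, exons_first, exons_second
) -> bool:
    def inside(bp: int, exons) -> bool:
        return any(iv.start < bp <= iv.end for iv in exons)

    return inside(call.breakpoint_a, exons_first) and inside(
        call.breakpoint_b, exons_second
    )


def match_fusion(call: FusionCall, truth: FusionTruth) -> bool:
    """True iff the observed call matches the expected event: same unordered
    gene pair, and each breakpoint inside an expected exon interval of its
    matched gene (half-open containment: start < bp <= end)."""
    if frozenset((call.gene_a, call.gene_b)) != truth.gene_pair:
        return False
    if call.gene_a == truth.gene_a and _breakpoints_match(
        call, truth.expected_exons_a, truth.expected_exons_b
    ):
        return True
    if call.gene_a == truth.gene_b and _breakpoints_match(
        call, truth.expected_exons_b, truth.expected_exons_a
    ):
        return True
    return False


def classify_fusions(
    observed: list[FusionCall],
    truth: list[FusionTruth],
    policy: FusionPolicy | None = None,
    audit: list | None = None,
) -> ConfusionCounts:
    """Classify observed fusion/splice calls against expected events.

    Admissible calls pass the confidence policy (high only, or high+low) and,
    for splice-variant events, carry at least ``min_splice_reads`` supporting
    reads.  FN reasons distinguish events never called from events present
    only as inadmissible (e.g. low-confidence) calls.  TN is not defined for
    this class.
    """
    if policy is None:
        policy = FusionPolicy()

    def log(label_key, label, reason=""):
        if audit is not None:
            audit.append((label_key, label, reason))

    def admissible(call: FusionCall) -> bool:
        if call.confidence == "low" and not policy.include_low_confidence:
            return False
        if call.event_kind == "splice_variant" and (
            call.supporting_reads < policy.min_splice_reads
        ):
            return False
        return True

    tp = fn = 0
    matched_calls: set[int] = set()
    for t in truth:
        event = f"{t.gene_a}-{t.gene_b}"
        matching = [i for i, c in enumerate(observed) if match_fusion(c, t)]
        admissible_matching = [i for i in matching if admissible(observed[i])]
        if admissible_matching:
            tp += 1
            matched_calls.update(matching)
            log(event, "TP", "")
        else:
            fn += 1
            matched_calls.update(matching)
            reason = "not_called" if not matching else "low_confidence_filtered"
            log(event, "FN", reason)
    fp = 0
    for i, c in enumerate(observed):
        if i not in matched_calls and admissible(c):
            fp += 1
            log(f"{c.gene_a}-{c.gene_b}", "FP", "no_matching_truth_event")
    return ConfusionCounts(
        tp=tp, fp=fp, fn=fn, tn=0, variant_class="fusion", tn_applicable=False
    )
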
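"""Small-variant filter cascade and reporting-band triage.

The standard cascade is the manufacturer-recommended seven-filter set for
hybrid-capture tumor panels: variant quality (GQ >= 20), depth (DP >= 100),
strand bias (SB <= 0.5), variant frequency (VF >= 0.026), indel reference
repeat (homopolymer run <= 8), adjusted quality (AQ >= 10) and variant
support (>= 7 alt reads).  All boundaries are inclusive.

On top of the cascade, two reporting filters are used when comparing against a
truth set: depth >= 100x with VAF >= 2.6%, or depth >= 250x with VAF >= 5%.
Variants that survive filtering are triaged into reporting bands: VAF >= 5%
auto-report, 3-5% flagged for manual review, < 3% suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import SmallVariant

# canonical evaluation order (the result is order-independent; this only
# fixes the presentation order of failed_filters)
FILTER_NAMES = (
    "low_variant_quality",
    "low_depth",
    "strand_bias",
    "low_variant_frequency",
    "indel_reference_repeat",
    "adjusted_quality",
    "low_variant_support",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the standard seven-filter cascade (inclusive bounds)."""

    min_gq: float = 20.0
    min_dp: int = 100
    max_sb: float = 0.5
    min_vf: float = 0.026
    max_homopolymer: int = 8
    min_aq: float = 10.0
    min_support: int = 7

    def __post_init__(self) -> None:
        for name in ("min_gq", "min_dp", "max_sb", "max_homopolymer",
                     "min_aq", "min_support"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.min_vf <= 1.0):
            raise ValueError("min_vf must lie in [0,1]")

    @classmethod
    def gatk_strand_bias_preset(cls, **overrides) -> "FilterConfig":
        """Preset with the strand-bias bound expressed on a phred-like scale
        (3.01, the GATK-convention equivalent of the 0.5 score bound).  The
        comparator stays <=; only the scale of the consumed SB annotation
        changes, which is the caller's responsibility to match."""
        overrides.setdefault("max_sb", 3.01)
        return cls(**overrides)


@dataclass(frozen=True)
class ReportingFilter:
    """A depth/VAF reporting threshold pair applied before concordance."""

    min_depth: int = 250
    min_vaf: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValueError("min_depth must be > 0")
        if not (0.0 < self.min_vaf < 1.0):
            raise ValueError("min_vaf must lie in (0,1)")


#: reporting filter one: depth >= 100x and VAF >= 2.6%
FILTER_ONE = ReportingFilter(min_depth=100, min_vaf=0.026)
#: reporting filter two: depth >= 250x and VAF >= 5%
FILTER_TWO = ReportingFilter(min_depth=250, min_vaf=0.05)


@dataclass
class FilterResult:
    passed: bool
    failed_filters: list[str] = field(default_factory=list)
    not_evaluated: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_filters):
            raise ValueError("passed must be equivalent to failed_filters empty")


def homopolymer_run(ref_context: str, anchor: int) -> int:
    """Length of the longest single-base run starting at, or immediately
    following, the anchor base of an indel.

    ``anchor`` is a 0-based offset into ``ref_context`` (the padding base of a
    VCF-style indel).  Both the run containing the anchor base itself and the
    run starting at the next base are measured; the longer one is returned.
    """
    if not ref_context:
        raise ValueError("ref_context must be non-empty")
    if not (0 <= anchor < len(ref_context)):
        raise ValueError(f"anchor {anchor} out of range for context "
                         f"of length {len(ref_context)}")

    def run_from(i: int) -> int:
        j = i
        while j < len(ref_context) and ref_context[j] == ref_context[i]:
            j += 1
        return j - i

    best = run_from(anchor)
    if anchor + 1 < len(ref_context):
        best = max(best, run_from(anchor + 1))
    return best


def apply_standard_filters(
    v: SmallVariant,
    cfg: FilterConfig | None = None,
    ref_context: str | None = None,
    anchor: int | None = None,
    mode: str = "strict",
) -> FilterResult:
    """Evaluate the seven-filter cascade on one variant.

    ``ref_context``/``anchor`` feed the homopolymer filter and are consulted
    only for insertions and deletions.  A missing metric fails the
    corresponding filter under ``mode="strict"`` and is recorded as
    not-evaluated under ``mode="lenient"``.
    """
    if cfg is None:
        cfg = FilterConfig()
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be strict or lenient")
    failed: list[str] = []
    not_evaluated: list[str] = []

    def check(name: str, value, ok) -> None:
        if value is None:
            (failed if mode == "strict" else not_evaluated).append(name)
        elif not ok(value):
            failed.append(name)

    check("low_variant_quality", v.gq, lambda x: x >= cfg.min_gq)
    check("low_depth", v.depth, lambda x: x >= cfg.min_dp)
    check("strand_bias", v.sb, lambda x: x <= cfg.max_sb)
    check("low_variant_frequency", v.vaf, lambda x: x >= cfg.min_vf)
    if v.vclass in ("insertion", "deletion"):
        if ref_context is None or anchor is None:
            (failed if mode == "strict" else not_evaluated).append(
                "indel_reference_repeat"
            )
        elif homopolymer_run(ref_context, anchor) > cfg.max_homopolymer:
            failed.append("indel_reference_repeat")
    check("adjusted_quality", v.aq, lambda x: x >= cfg.min_aq)
    check("low_variant_support", v.support, lambda x: x >= cfg.min_support)

    order = {name: i for i, name in enumerate(FILTER_NAMES)}
    failed.sort(key=order.__getitem__)
    not_evaluated.sort(key=order.__getitem__)
    return FilterResult(
        passed=not failed, failed_filters=failed, not_evaluated=not_evaluated
    )


def apply_reporting_filter(v: SmallVariant, rf: ReportingFilter) -> bool:
    """True iff the variant meets the reporting depth and VAF thresholds."""
    if v.depth is None or v.vaf is None:
        return False
    return v.depth >= rf.min_depth and v.vaf >= rf.min_vaf


def classify_reporting_band(
    v: SmallVariant, report_min: float = 0.05, review_min: float = 0.03
) -> str:
    """Triage a variant by VAF: ``report`` (>= 5%), ``review`` (3-5%), or
    ``suppress`` (< 3%)."""
    if v.vaf is None:
        raise ValueError("reporting band requires a VAF")
    if v.vaf >= report_min:
        return "report"
    if v.vaf >= review_min:
        return "review"
    return "suppress"
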
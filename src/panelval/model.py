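"""Domain types and coordinate conventions for panel-validation analytics.

Conventions
-----------
* Intervals are 0-based half-open ``[start, end)`` (BED convention).
* Variant positions are 1-based (VCF convention).  A 1-based position ``p``
  lies inside an interval ``[s, e)`` iff ``s < p <= e``.
* Variant identity is the tuple ``(chrom, pos, ref, alt)`` *after*
  normalization (left alignment + parsimony trimming for indels).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

VALID_BASES = set("ACGTN")

VARIANT_CLASSES = ("SNV", "MNV", "insertion", "deletion", "complex")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally tagged with the
    transcript and exon it belongs to in the panel target space."""

    chrom: str
    start: int
    end: int
    transcript_id: str | None = None
    exon_index: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos1(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position ``pos`` falls inside this interval."""
        return chrom == self.chrom and self.start < pos <= self.end


def infer_variant_class(ref: str, alt: str) -> str:
    """Classify an allele pair into one of the five small-variant classes."""
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "deletion"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "insertion"
    return "complex"


@dataclass(frozen=True)
class SmallVariant:
    """One observed or expected sequence variant with per-call quality metrics.

    ``vaf``/``depth``/``support``/``gq``/``sb``/``aq`` may be ``None`` when a
    caller does not emit the corresponding metric (truth-set skeletons carry
    only the expected VAF in ``vaf``).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vclass: str = ""
    vaf: float | None = None
    depth: int | None = None
    support: int | None = None
    gq: float | None = None
    sb: float | None = None
    aq: float | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - VALID_BASES or set(self.alt) - VALID_BASES:
            raise ValueError(f"alleles must be over ACGTN: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("variant positions are 1-based (pos >= 1)")
        if not self.vclass:
            object.__setattr__(self, "vclass", infer_variant_class(self.ref, self.alt))
        elif self.vclass not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.vclass!r}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if (
            self.support is not None
            and self.depth is not None
            and self.support > self.depth
        ):
            raise ValueError("support cannot exceed depth")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive reference positions touched by this variant."""
        return (self.pos, self.pos + len(self.ref) - 1)


@dataclass
class VariantCallSet:
    """A set of small-variant calls from one sequencing replicate."""

    sample_id: str
    variants: list[SmallVariant] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            seen, dups = set(), set()
            for k in keys:
                (dups if k in seen else seen).add(k)
            raise ValueError(f"duplicate variant keys in call set: {sorted(dups)}")

    def key_set(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class FusionCall:
    """An observed gene fusion or splice-variant call."""

    gene_a: str
    gene_b: str
    breakpoint_a: int  # 1-based
    breakpoint_b: int  # 1-based
    confidence: str  # "high" | "low"
    supporting_reads: int
    event_kind: str = "fusion"  # "fusion" | "splice_variant"

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("gene symbols must be non-empty")
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")
        if self.confidence not in ("high", "low"):
            raise ValueError(f"confidence must be high|low, got {self.confidence!r}")
        if self.event_kind not in ("fusion", "splice_variant"):
            raise ValueError(f"unknown event kind {self.event_kind!r}")


@dataclass(frozen=True)
class CnvCall:
    """An observed copy-number call for one gene."""

    gene: str
    copies: float
    filter_status: str = "pass"  # "pass" | "fail"

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")

    @property
    def passed(self) -> bool:
        return self.filter_status == "pass"


@dataclass(frozen=True)
class FusionTruth:
    """An expected fusion/splice event with the exon intervals inside which an
    observed breakpoint counts as a match, and its abundance in copies/ng."""

    gene_a: str
    gene_b: str
    expected_exons_a: tuple[GenomicInterval, ...]
    expected_exons_b: tuple[GenomicInterval, ...]
    copies_per_ng: float
    event_kind: str = "fusion"

    def __post_init__(self) -> None:
        if not self.expected_exons_a or not self.expected_exons_b:
            raise ValueError("expected exon interval lists must be non-empty")
        if self.copies_per_ng < 0:
            raise ValueError("copies_per_ng must be >= 0")

    @property
    def gene_pair(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class TruthSet:
    """Expected content of a control or previously characterized specimen.

    ``small_variants`` are :class:`SmallVariant` skeletons whose ``vaf`` field
    holds the *expected* allele frequency in the undiluted material.
    """

    small_variants: list[SmallVariant] = field(default_factory=list)
    fusions: list[FusionTruth] = field(default_factory=list)
    cnvs: list[tuple[str, float]] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        for v in self.small_variants:
            if v.vaf is None or not (0.0 < v.vaf <= 1.0):
                raise ValueError(
                    f"truth variant {v.key} needs an expected VAF in (0,1]"
                )
        for gene, copies in self.cnvs:
            if copies < 0:
                raise ValueError(f"expected copies for {gene} must be >= 0")

    def small_variant_keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.small_variants}


class CoverageProfile:
    """Per-base read depth over a target space.

    ``depths`` is a flat array with one value per target base, concatenated in
    the order of ``intervals`` (which must be coordinate-sorted and
    non-overlapping).
    """

    def __init__(self, intervals: list[GenomicInterval], depths) -> None:
        self.intervals = list(intervals)
        self.depths = np.asarray(depths, dtype=np.int64)
        n = sum(len(iv) for iv in self.intervals)
        if n != self.depths.size:
            raise ValueError(
                f"depth array has {self.depths.size} values but target has {n} bases"
            )
        if np.any(self.depths < 0):
            raise ValueError("depths must be >= 0")
        # per-chrom (start, end, offset) index for position lookup
        self._index: dict[str, list[tuple[int, int, int]]] = {}
        offset = 0
        for iv in self.intervals:
            self._index.setdefault(iv.chrom, []).append((iv.start, iv.end, offset))
            offset += len(iv)
        for chrom, entries in self._index.items():
            entries.sort()
            starts = [s for s, _, _ in entries]
            for (s1, e1, _), s2 in zip(entries, starts[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping coverage intervals on {chrom}")
            self._index[chrom] = entries

    @property
    def total_positions(self) -> int:
        return int(self.depths.size)

    def depth_at(self, chrom: str, pos: int) -> int | None:
        """Depth at a 1-based position, or None if outside the target."""
        entries = self._index.get(chrom)
        if not entries:
            return None
        p0 = pos - 1
        i = bisect.bisect_right(entries, (p0, float("inf"), float("inf"))) - 1
        if i < 0:
            return None
        s, e, off = entries[i]
        if s <= p0 < e:
            return int(self.depths[off + (p0 - s)])
        return None

    def covers_pos1(self, chrom: str, pos: int) -> bool:
        return self.depth_at(chrom, pos) is not None

    def iter_positions(self):
        """Yield (chrom, pos1, depth) for every target base (slow path)."""
        off = 0
        for iv in self.intervals:
            for j in range(len(iv)):
                yield iv.chrom, iv.start + j + 1, int(self.depths[off + j])
            off += len(iv)


@dataclass
class TargetSpace:
    """A panel target space: tagged intervals plus the reference sequence the
    intervals were drawn from (keyed by chromosome, string starts at base 1)."""

    intervals: list[GenomicInterval]
    reference: dict[str, str]

    @property
    def total_positions(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def ref_base(self, chrom: str, pos: int) -> str:
        return self.reference[chrom][pos - 1]

    def ref_slice(self, chrom: str, pos: int, length: int) -> str:
        return self.reference[chrom][pos - 1 : pos - 1 + length]


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort intervals and merge overlapping/abutting ones that share a
    chromosome and transcript tag."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if (
            out
            and out[-1].chrom == iv.chrom
            and out[-1].transcript_id == iv.transcript_id
            and iv.start <= out[-1].end
        ):
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = replace(prev, end=iv.end)
        else:
            out.append(iv)
    return out


def position_in_target(
    intervals: list[GenomicInterval], chrom: str, pos: int
) -> bool:
    """Membership of a 1-based position in a target space (s < pos <= e)."""
    return any(iv.contains_pos1(chrom, pos) for iv in intervals)


def normalize_variant(
    v: SmallVariant, ref_seq: str, ref_start: int = 1
) -> SmallVariant:
    """Left-align and parsimony-trim a variant against its reference context.

    ``ref_seq`` is the reference sequence whose first base sits at 1-based
    genomic position ``ref_start``; it must cover the variant and enough
    upstream sequence for left shifting.  SNVs come back unchanged; the
    operation is idempotent and preserves the alternate haplotype.
    """
    lo = v.pos - ref_start
    if lo < 0 or lo + len(v.ref) > len(ref_seq):
        raise ValueError(f"reference context does not cover variant at {v.pos}")
    if ref_seq[lo : lo + len(v.ref)] != v.ref:
        raise ValueError(
            f"ref allele {v.ref!r} at {v.chrom}:{v.pos} disagrees with "
            f"reference context {ref_seq[lo:lo + len(v.ref)]!r}"
        )
    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        # trim shared trailing bases while both alleles keep >= 1 base
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        # left-shift: shared last base with one allele already minimal
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if pos - 1 < ref_start:
                break  # cannot shift past the start of the context
            prev = ref_seq[pos - 1 - ref_start]
            ref, alt, pos = prev + ref[:-1], prev + alt[:-1], pos - 1
            continue
        break
    # trim shared leading bases
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return replace(v, pos=pos, ref=ref, alt=alt, vclass=infer_variant_class(ref, alt))
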
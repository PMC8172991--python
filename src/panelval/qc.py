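"""Coverage QC: pass/fail auditing and per-transcript failure analysis.

A sample's coverage passes when at least ``min_fraction`` of target positions
reach ``min_depth`` reads (defaults 95% at 250x).  Two pass semantics are
shipped: the whole-sample fraction, and a stricter reading in which every
exon (or transcript) must individually meet the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CoverageProfile


@dataclass(frozen=True)
class CoverageRule:
    min_depth: int = 250
    min_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValueError("min_depth must be > 0")
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValueError("min_fraction must lie in (0,1]")


def _group_slices(profile: CoverageProfile, by: str):
    """Yield (group_key, boolean-coverage slice indices) per transcript/exon."""
    groups: dict = {}
    off = 0
    for iv in profile.intervals:
        if by == "transcript":
            key = iv.transcript_id
        else:
            key = (iv.transcript_id, iv.exon_index)
        groups.setdefault(key, []).append((off, off + len(iv)))
        off += len(iv)
    return groups


def _fraction(depths: np.ndarray, rule: CoverageRule) -> float:
    return float(np.count_nonzero(depths >= rule.min_depth)) / depths.size


def coverage_pass(
    profile: CoverageProfile,
    rule: CoverageRule | None = None,
    scope: str = "sample",
) -> tuple[bool, float]:
    """Evaluate the coverage rule at the requested scope.

    Returns ``(passed, fraction_covered)`` where ``fraction_covered`` is the
    whole-profile fraction of positions at or above ``min_depth``.  At
    ``sample`` scope the sample passes when that fraction meets
    ``min_fraction``; at ``transcript``/``exon`` scope it passes only when
    every transcript/exon individually meets the rule.
    """
    if rule is None:
        rule = CoverageRule()
    if profile.total_positions == 0:
        raise ValueError("empty coverage profile")
    overall = _fraction(profile.depths, rule)
    if scope == "sample":
        return overall >= rule.min_fraction, overall
    if scope not in ("transcript", "exon"):
        raise ValueError("scope must be sample, transcript, or exon")
    for key, slices in _group_slices(profile, scope).items():
        depths = np.concatenate([profile.depths[a:b] for a, b in slices])
        if depths.size == 0:
            raise ValueError(f"empty {scope} group {key}")
        if _fraction(depths, rule) < rule.min_fraction:
            return False, overall
    return True, overall


def transcript_failures(
    samples: list[CoverageProfile], rule: CoverageRule | None = None
) -> tuple[pd.DataFrame, int]:
    """Count, per transcript, the samples in which it fails the coverage rule.

    All samples must share a target space.  Returns the per-transcript table
    and the number of transcripts with at least one failure.
    """
    if rule is None:
        rule = CoverageRule()
    if not samples:
        raise ValueError("need at least one sample")
    ref = [(iv.chrom, iv.start, iv.end, iv.transcript_id) for iv in samples[0].intervals]
    for s in samples[1:]:
        if [(iv.chrom, iv.start, iv.end, iv.transcript_id) for iv in s.intervals] != ref:
            raise ValueError("samples do not share a target space")
    counts: dict = {}
    for s in samples:
        for tx, slices in _group_slices(s, "transcript").items():
            depths = np.concatenate([s.depths[a:b] for a, b in slices])
            counts.setdefault(tx, 0)
            if _fraction(depths, rule) < rule.min_fraction:
                counts[tx] += 1
    table = pd.DataFrame(
        sorted(counts.items()), columns=["transcript_id", "n_samples_failing"]
    )
    return table, int((table["n_samples_failing"] > 0).sum())


def sample_pass_rate(
    samples: list[CoverageProfile],
    rule: CoverageRule | None = None,
    scope: str = "sample",
) -> float:
    """Percentage of samples passing the coverage rule at the given scope."""
    if not samples:
        raise ValueError("need at least one sample")
    n_pass = sum(1 for s in samples if coverage_pass(s, rule, scope)[0])
    return 100.0 * n_pass / len(samples)
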
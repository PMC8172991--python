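"""Dilution-series analytical sensitivity (limit of detection) analysis.

A control material is mixed with wild-type nucleic acid at a set of dilution
fractions; at each level the assay is run in replicates and each expected
variant is scored as detected or not in the filtered call set.  Detection of a
variant with expected allele fraction ``p`` at depth ``N`` under a support
threshold behaves like a binomial tail: the alt-read count is
``X ~ Binomial(N, p)`` and the call survives when
``X >= max(min_support, ceil(min_vaf * N))``.  The per-variant LOD is the
smallest dilution fraction such that every level at or above it reaches the
required detection rate.

RNA fusion abundance is denominated in copies/ng; supporting reads follow a
Poisson law with mean ``copies_per_ng * input_ng * capture_efficiency *
fraction``, which makes the copies/ng LOD an equivalent Poisson-tail
computation.

Input qualification mirrors clinical practice for low-concentration
specimens: a sample whose total mass is in range but whose concentration is
below range is *qualified* (reportable with a caveat about the elevated
false-negative risk) rather than failed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import binom

from .concordance import FusionPolicy, match_fusion
from .filtering import ReportingFilter, apply_reporting_filter
from .model import FusionCall, TruthSet, VariantCallSet


@dataclass
class DilutionLevel:
    """One dilution level: the control fraction and the replicate call sets
    observed at that level (VariantCallSets for DNA, lists of FusionCall for
    RNA)."""

    fraction: float
    call_sets: list

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0,1]")


@dataclass(frozen=True)
class InputRequirement:
    """Manufacturer-recommended nucleic-acid input ranges."""

    dna_total_ng_range: tuple[float, float] = (40.0, 120.0)
    dna_conc_range_ng_ul: tuple[float, float] = (3.3, 10.0)
    rna_total_ng_range: tuple[float, float] = (40.0, 85.0)
    rna_conc_range_ng_ul: tuple[float, float] = (4.7, 10.0)
    rna_lod_copies_per_ng: float = 7.0

    def __post_init__(self) -> None:
        for name in ("dna_total_ng_range", "dna_conc_range_ng_ul",
                     "rna_total_ng_range", "rna_conc_range_ng_ul"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")


def expected_dilution_vaf(stock_vaf: float, dilution_fraction: float) -> float:
    """Expected allele fraction after mass-proportional dilution with
    wild-type material (which carries zero alternate alleles)."""
    if not (0.0 <= stock_vaf <= 1.0 and 0.0 <= dilution_fraction <= 1.0):
        raise ValueError("stock_vaf and dilution_fraction must lie in [0,1]")
    return stock_vaf * dilution_fraction


def required_alt_reads(depth: int, min_support: int, min_vaf: float) -> int:
    """Smallest alt-read count that clears both the support and VAF bounds."""
    # guard against float artifacts like 0.05*500 = 25.000000000000004
    return max(min_support, math.ceil(round(min_vaf * depth, 9)))


def analytic_detection_prob(
    expected_vaf: float, depth: int, min_support: int, min_vaf: float
) -> float:
    """Closed-form probability that a variant with the given expected allele
    fraction is detected at the given depth:
    P[Binomial(depth, expected_vaf) >= max(min_support, ceil(min_vaf*depth))].
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    k = required_alt_reads(depth, min_support, min_vaf)
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, depth, expected_vaf))


def detection_rate(
    series: list[DilutionLevel],
    truth: TruthSet,
    reporting_filter: ReportingFilter | None = None,
    fusion_policy: FusionPolicy | None = None,
) -> pd.DataFrame:
    """Tabulate per-variant detection rates across a dilution series.

    For DNA levels (call sets of small variants) a truth variant is detected
    in a replicate when its identity key is present after the optional
    reporting filter.  For RNA levels (lists of fusion calls) detection uses
    breakpoint/exon matching under the fusion policy.  A truth variant seen at
    no level, including the undiluted one, is flagged in the ``ever_detected``
    column rather than dropped.
    """
    rows = []
    for level in sorted(series, key=lambda lv: -lv.fraction):
        for cs in level.call_sets:
            if isinstance(cs, VariantCallSet):
                if reporting_filter is None:
                    keys = cs.key_set()
                else:
                    keys = {
                        v.key
                        for v in cs.variants
                        if apply_reporting_filter(v, reporting_filter)
                    }
                for tv in truth.small_variants:
                    rows.append(
                        {
                            "variant": "{}:{}:{}>{}".format(*tv.key),
                            "kind": "small_variant",
                            "fraction": level.fraction,
                            "detected": tv.key in keys,
                            "expected": tv.vaf * level.fraction,
                        }
                    )
            else:
                calls = list(cs)
                policy = fusion_policy or FusionPolicy()
                for ft in truth.fusions:
                    matched = any(
                        match_fusion(c, ft)
                        and (policy.include_low_confidence or c.confidence == "high")
                        and (
                            ft.event_kind != "splice_variant"
                            or c.supporting_reads >= policy.min_splice_reads
                        )
                        for c in calls
                        if isinstance(c, FusionCall)
                    )
                    rows.append(
                        {
                            "variant": f"{ft.gene_a}-{ft.gene_b}",
                            "kind": ft.event_kind,
                            "fraction": level.fraction,
                            "detected": matched,
                            "expected": ft.copies_per_ng * level.fraction,
                        }
                    )
    if not rows:
        raise ValueError("empty dilution series")
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["variant", "kind", "fraction"], as_index=False)
        .agg(
            n_detected=("detected", "sum"),
            n_replicates=("detected", "size"),
            expected=("expected", "first"),
        )
        .sort_values(["variant", "fraction"], ascending=[True, False])
        .reset_index(drop=True)
    )
    ever = table.groupby("variant")["n_detected"].transform("sum") > 0
    table["ever_detected"] = ever
    return table


def estimate_lod(
    table: pd.DataFrame, prob_threshold: float, rule: str = "all_above"
) -> dict[str, float | None]:
    """Per-variant LOD from a detection table.

    Under the default ``all_above`` rule the LOD is the smallest fraction such
    that *every* level at or above it has a detection rate >= the threshold
    (robust to non-monotone flukes at lower levels); ``first_crossing``
    returns the smallest fraction whose own rate clears the threshold.
    ``None`` marks variants for which no level qualifies.  A warning is issued
    when a variant's detection rates are not monotone in the fraction.
    """
    if not (0.0 < prob_threshold <= 1.0):
        raise ValueError("prob_threshold must lie in (0,1]")
    if rule not in ("all_above", "first_crossing"):
        raise ValueError(f"unknown LOD rule {rule!r}")
    out: dict[str, float | None] = {}
    for variant, grp in table.groupby("variant"):
        grp = grp.sort_values("fraction", ascending=False)
        if len(grp) < 2:
            raise ValueError(f"variant {variant}: LOD needs >= 2 dilution levels")
        rates = (grp["n_detected"] / grp["n_replicates"]).tolist()
        fractions = grp["fraction"].tolist()
        if any(r2 > r1 + 1e-12 for r1, r2 in zip(rates, rates[1:])):
            warnings.warn(
                f"variant {variant}: detection rates are not monotone in the "
                "dilution fraction",
                stacklevel=2,
            )
        lod: float | None = None
        if rule == "all_above":
            for frac, rate in zip(fractions, rates):
                if rate >= prob_threshold:
                    lod = frac
                else:
                    break
        else:
            for frac, rate in zip(fractions, rates):
                if rate >= prob_threshold:
                    lod = frac
        out[variant] = lod
    return out


def assess_nucleic_acid_input(
    conc_ng_ul: float,
    volume_ul: float,
    req: InputRequirement | None = None,
    analyte: str = "DNA",
) -> str:
    """Qualify a specimen's nucleic-acid input: ``pass`` when both the
    concentration and the total mass (concentration x volume) are in range,
    ``qualified`` when the total mass is in range but the concentration is
    out of range (reportable with a false-negative caveat), ``fail`` when the
    total mass is out of range."""
    if conc_ng_ul <= 0 or volume_ul <= 0:
        raise ValueError("concentration and volume must be positive")
    if req is None:
        req = InputRequirement()
    if analyte.upper() == "DNA":
        total_range, conc_range = req.dna_total_ng_range, req.dna_conc_range_ng_ul
    elif analyte.upper() == "RNA":
        total_range, conc_range = req.rna_total_ng_range, req.rna_conc_range_ng_ul
    else:
        raise ValueError("analyte must be DNA or RNA")
    total = conc_ng_ul * volume_ul
    if not (total_range[0] <= total <= total_range[1]):
        return "fail"
    if conc_range[0] <= conc_ng_ul <= conc_range[1]:
        return "pass"
    return "qualified"
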
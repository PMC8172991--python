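"""Synthetic control material and read-sampling simulation.

This module generates every input the validation pipeline consumes, emulating
the commercial reference materials the assay is validated against:

* a DNA hotspot control carrying ~500 characterized mutations across 53 genes
  in five variant classes (SNV, MNV, insertion, deletion, complex) at a range
  of allele frequencies;
* an RNA fusion control with 14 gene fusions, one exon-skipping event and one
  multi-exon deletion, each with a stated abundance in copies/ng — including
  one fusion at 6 copies/ng, deliberately below the assay's claimed
  7 copies/ng limit of detection;
* dilution series of both controls, and per-base coverage profiles over a
  multi-transcript target space.

The generative model is read-sampling, not read-level: per-position depth is
gamma-Poisson (negative-binomial-like, mean 500, ~10% CV), alt-supporting
reads are Binomial(depth, expected_vaf x dilution_fraction), spurious calls
arrive as a Poisson process per megabase, and fusion supporting reads are
Poisson(copies_per_ng x input_ng x capture_efficiency x fraction).  With
``noise=0`` every stochastic draw collapses to its rounded mean, so replicates
are byte-identical — the degenerate case used to pin down pipeline plumbing.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    CnvCall,
    CoverageProfile,
    FusionCall,
    FusionTruth,
    GenomicInterval,
    SmallVariant,
    TargetSpace,
    TruthSet,
    VariantCallSet,
    normalize_variant,
)

_BASES = np.array(list("ACGT"))

#: default RNA fusion panel: (gene_a, gene_b, copies/ng, event kind).
#: TMPRSS2-ERG sits at 6 copies/ng (below the 7 copies/ng LOD claim) and
#: SLC34A2-ROS1 at 8 copies/ng, mirroring the low-abundance members of the
#: commercial mix; remaining abundances default to 13 copies/ng.
DEFAULT_FUSION_PANEL: tuple[tuple[str, str, float, str], ...] = (
    ("EML4", "ALK", 13.0, "fusion"),
    ("SLC34A2", "ROS1", 8.0, "fusion"),
    ("TMPRSS2", "ERG", 6.0, "fusion"),
    ("TPM3", "NTRK1", 13.0, "fusion"),
    ("KIF5B", "RET", 13.0, "fusion"),
    ("CD74", "ROS1", 13.0, "fusion"),
    ("EGFR", "SEPT14", 13.0, "fusion"),
    ("FGFR3", "TACC3", 13.0, "fusion"),
    ("LMNA", "NTRK1", 13.0, "fusion"),
    ("ETV6", "NTRK3", 13.0, "fusion"),
    ("PAX8", "PPARG", 13.0, "fusion"),
    ("NCOA4", "RET", 13.0, "fusion"),
    ("FGFR3", "BAIAP2L1", 13.0, "fusion"),
    ("SLC45A3", "BRAF", 13.0, "fusion"),
    ("MET", "MET", 13.0, "splice_variant"),       # exon-14 skipping
    ("EGFR", "EGFR", 13.0, "splice_variant"),     # vIII multi-exon deletion
)

#: default CNV truth panel (gene, expected copies): two amplifications above
#: and one at the 4-copy reporting bound, plus one large deletion.
DEFAULT_CNV_PANEL: tuple[tuple[str, float], ...] = (
    ("ERBB2", 9.0),
    ("FGFR3", 5.0),
    ("MYC", 4.0),
    ("CDKN2A", 0.5),
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic control material.

    The defaults are the conditions of the validation design: a ~500-variant
    hotspot control across 53 genes with all five variant classes, VAFs
    spanning a bulk range (5-50%) plus a low-VAF tail (2-5%) that exercises
    the review band, ~500x mean coverage with 10% CV, and the 16-event RNA
    fusion panel above.
    """

    seed: int = 0
    n_small_variants: int = 500
    n_genes: int = 53
    variant_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "SNV": 0.60,
            "MNV": 0.10,
            "insertion": 0.12,
            "deletion": 0.12,
            "complex": 0.06,
        }
    )
    vaf_bulk: tuple[float, float] = (0.05, 0.50)
    vaf_tail: tuple[float, float] = (0.02, 0.05)
    vaf_tail_weight: float = 0.20
    depth_mean: float = 500.0
    depth_cv: float = 0.10
    fp_rate: float = 2.0  # spurious calls per megabase per sample
    fp_vaf_range: tuple[float, float] = (0.03, 0.08)
    noise: float = 1.0  # 0 disables all stochastic draws
    fusion_panel: tuple[tuple[str, str, float, str], ...] = DEFAULT_FUSION_PANEL
    cnv_panel: tuple[tuple[str, float], ...] = DEFAULT_CNV_PANEL
    capture_efficiency: float = 0.05  # supporting reads per copy per ng input
    input_ng: float = 50.0
    high_conf_min_reads: int = 10
    low_conf_min_reads: int = 4
    displace_breakpoints: bool = False
    exons_per_transcript: int = 3
    exon_length: int = 180
    intergenic_gap: int = 60
    gq_range: tuple[float, float] = (30.0, 90.0)
    sb_range: tuple[float, float] = (0.0, 0.4)
    aq_range: tuple[float, float] = (15.0, 40.0)

    def __post_init__(self) -> None:
        total = sum(self.variant_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant class proportions sum to {total}, not 1")
        for name in ("fp_rate", "capture_efficiency", "depth_cv", "noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_small_variants < 0 or self.n_genes < 1:
            raise ValueError("invalid counts")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng((int(self.seed),) + tuple(int(s) for s in stream))


def simulate_target_space(cfg: SimulationConfig) -> TargetSpace:
    """Generate a multi-transcript target space and its reference sequence.

    One transcript per gene, ``exons_per_transcript`` exons each, laid out on
    a single synthetic chromosome.  The first exon carries a homopolymer run
    longer than 8 bases so the indel reference-repeat filter is exercised.
    """
    rng = cfg.rng(1)
    intervals: list[GenomicInterval] = []
    pos = 100
    for t in range(cfg.n_genes):
        tx = f"TX{t + 1:03d}"
        for e in range(cfg.exons_per_transcript):
            intervals.append(
                GenomicInterval("chr1", pos, pos + cfg.exon_length,
                                transcript_id=tx, exon_index=e + 1)
            )
            pos += cfg.exon_length + cfg.intergenic_gap
    seq_len = pos + 100
    seq = rng.choice(_BASES, size=seq_len)
    # plant a >8-base homopolymer in the middle of the first exon
    first = intervals[0]
    mid = first.start + cfg.exon_length // 2
    seq[mid : mid + 12] = "A"
    reference = {"chr1": "".join(seq)}
    return TargetSpace(intervals=intervals, reference=reference)


def _gene_of(cfg: SimulationConfig, transcript_id: str) -> str:
    return f"G{int(transcript_id[2:]):03d}"


def _draw_alt_base(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return choices[rng.integers(len(choices))]


def simulate_truth(cfg: SimulationConfig, target: TargetSpace) -> TruthSet:
    """Place the configured variant content inside the target space.

    Small variants are positioned with a minimum spacing of 12 bases (so
    reference spans never overlap), drawn from the configured class mix and
    VAF distribution, and normalized.  The fusion panel's expected exon
    intervals are drawn from the target's transcripts; CNV truth comes from
    the configured panel.
    """
    rng = cfg.rng(2)
    margin = 8
    candidates: list[tuple[int, str]] = []
    for iv in target.intervals:
        # 1-based anchors leaving room for multi-base ref alleles and context
        for p in range(iv.start + 2, iv.end - margin):
            candidates.append((p + 1, iv.transcript_id))
    if cfg.n_small_variants and len(candidates) < cfg.n_small_variants:
        raise ValueError("target space too small for the requested variant count")
    order = rng.permutation(len(candidates))
    chosen: list[tuple[int, str]] = []
    used: set[int] = set()
    for idx in order:
        if len(chosen) == cfg.n_small_variants:
            break
        p, tx = candidates[idx]
        if all((p + d) not in used for d in range(-12, 13)):
            chosen.append((p, tx))
            used.add(p)
    if len(chosen) < cfg.n_small_variants:
        raise ValueError("target space too small for the requested variant count")
    chosen.sort()

    classes = list(cfg.variant_class_mix)
    probs = np.array([cfg.variant_class_mix[c] for c in classes])
    assigned = rng.choice(len(classes), size=len(chosen), p=probs)
    ref_seq = target.reference["chr1"]
    variants: list[SmallVariant] = []
    for (pos, tx), ci in zip(chosen, assigned):
        vclass = classes[ci]
        anchor = target.ref_base("chr1", pos)
        if vclass == "SNV":
            ref, alt = anchor, _draw_alt_base(rng, anchor)
        elif vclass == "MNV":
            ref = target.ref_slice("chr1", pos, 2)
            alt = "".join(_draw_alt_base(rng, b) for b in ref)
        elif vclass == "insertion":
            ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 7))))
            ref, alt = anchor, anchor + ins
        elif vclass == "deletion":
            dl = int(rng.integers(1, 7))
            ref, alt = target.ref_slice("chr1", pos, dl + 1), anchor
        else:  # complex: length-changing, not a clean ins/del
            ref = target.ref_slice("chr1", pos, 2)
            alt = _draw_alt_base(rng, ref[0]) + "".join(
                rng.choice(_BASES, size=2)
            )
        if rng.random() < cfg.vaf_tail_weight:
            vaf = float(rng.uniform(*cfg.vaf_tail))
        else:
            vaf = float(rng.uniform(*cfg.vaf_bulk))
        v = SmallVariant(
            chrom="chr1", pos=pos, ref=ref, alt=alt, vclass=vclass,
            vaf=vaf, gene=_gene_of(cfg, tx),
        )
        variants.append(normalize_variant(v, ref_seq, ref_start=1))

    # fusion truth: expected exons drawn from rotating transcript pairs
    by_tx: dict[str, list[GenomicInterval]] = {}
    for iv in target.intervals:
        by_tx.setdefault(iv.transcript_id, []).append(iv)
    tx_ids = sorted(by_tx)
    fusions: list[FusionTruth] = []
    for i, (gene_a, gene_b, copies, kind) in enumerate(cfg.fusion_panel):
        tx_a = tx_ids[(2 * i) % len(tx_ids)]
        tx_b = tx_ids[(2 * i + 1) % len(tx_ids)]
        fusions.append(
            FusionTruth(
                gene_a=gene_a,
                gene_b=gene_b,
                expected_exons_a=tuple(by_tx[tx_a]),
                expected_exons_b=tuple(by_tx[tx_b] if gene_a != gene_b else by_tx[tx_a]),
                copies_per_ng=copies,
                event_kind=kind,
            )
        )
    return TruthSet(
        small_variants=variants,
        fusions=fusions,
        cnvs=[(g, c) for g, c in cfg.cnv_panel],
        source_label=f"synthetic hotspot + fusion control (seed {cfg.seed})",
    )


def _simulate_depths(
    cfg: SimulationConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    if cfg.noise == 0 or cfg.depth_cv == 0:
        return np.full(n, int(round(cfg.depth_mean)), dtype=np.int64)
    shape = 1.0 / (cfg.depth_cv**2)
    lam = rng.gamma(shape, cfg.depth_mean / shape, size=n)
    return rng.poisson(lam).astype(np.int64)


def _metric(rng: np.random.Generator, lo: float, hi: float, noise: float) -> float:
    if noise == 0:
        return (lo + hi) / 2.0
    return float(rng.uniform(lo, hi))


def simulate_observed_calls(
    truth: TruthSet,
    cfg: SimulationConfig,
    target: TargetSpace,
    dilution_fraction: float = 1.0,
    seed_stream: int = 0,
    sample_id: str = "S1",
    provenance: dict[str, str] | None = None,
) -> tuple[VariantCallSet, CoverageProfile]:
    """Simulate one sequencing replicate of (possibly diluted) control material.

    Per truth variant the depth comes from the coverage profile at its
    position and the alt-read count is Binomial(depth, vaf x fraction); the
    variant is emitted when at least one supporting read was drawn, with VAF
    support/depth and quality metrics drawn from passing ranges.  Spurious
    false-positive SNVs arrive at ``fp_rate`` per megabase.
    """
    if not (0.0 <= dilution_fraction <= 1.0):
        raise ValueError("dilution_fraction must lie in [0,1]")
    rng = cfg.rng(3, seed_stream)
    n_bases = target.total_positions
    depths = _simulate_depths(cfg, n_bases, rng)
    profile = CoverageProfile(target.intervals, depths)

    variants: list[SmallVariant] = []
    taken_positions: set[int] = set()
    for tv in truth.small_variants:
        depth = profile.depth_at(tv.chrom, tv.pos)
        lo, hi = tv.span
        taken_positions.update(range(lo - 12, hi + 13))
        if depth is None or depth == 0:
            continue
        evaf = tv.vaf * dilution_fraction
        if cfg.noise == 0:
            support = int(round(depth * evaf))
        else:
            support = int(rng.binomial(depth, evaf))
        if support < 1:
            continue
        variants.append(
            SmallVariant(
                chrom=tv.chrom,
                pos=tv.pos,
                ref=tv.ref,
                alt=tv.alt,
                vclass=tv.vclass,
                vaf=support / depth,
                depth=int(depth),
                support=support,
                gq=_metric(rng, *cfg.gq_range, cfg.noise),
                sb=_metric(rng, *cfg.sb_range, cfg.noise),
                aq=_metric(rng, *cfg.aq_range, cfg.noise),
                gene=tv.gene,
            )
        )

    if cfg.noise != 0 and cfg.fp_rate > 0:
        n_fp = rng.poisson(cfg.fp_rate * n_bases / 1e6)
        flat_positions: list[int] = []
        for iv in target.intervals:
            flat_positions.extend(range(iv.start + 1, iv.end + 1))
        flat = np.array(flat_positions)
        for _ in range(int(n_fp)):
            for _attempt in range(50):
                pos = int(flat[rng.integers(flat.size)])
                if pos not in taken_positions:
                    break
            else:
                continue
            taken_positions.add(pos)
            depth = profile.depth_at("chr1", pos)
            if not depth:
                continue
            fp_vaf = rng.uniform(*cfg.fp_vaf_range)
            support = int(rng.binomial(depth, fp_vaf))
            if support < 1:
                continue
            ref = target.ref_base("chr1", pos)
            variants.append(
                SmallVariant(
                    chrom="chr1",
                    pos=pos,
                    ref=ref,
                    alt=_draw_alt_base(rng, ref),
                    vaf=support / depth,
                    depth=int(depth),
                    support=support,
                    gq=_metric(rng, *cfg.gq_range, cfg.noise),
                    sb=_metric(rng, *cfg.sb_range, cfg.noise),
                    aq=_metric(rng, *cfg.aq_range, cfg.noise),
                )
            )

    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    call_set = VariantCallSet(
        sample_id=sample_id, variants=variants, provenance=dict(provenance or {})
    )
    return call_set, profile


def simulate_fusion_calls(
    fusion_truths: list[FusionTruth],
    cfg: SimulationConfig,
    input_ng: float | None = None,
    dilution_fraction: float = 1.0,
    seed_stream: int = 0,
) -> list[FusionCall]:
    """Simulate fusion/splice calls from the RNA control.

    Supporting reads are Poisson with mean ``copies_per_ng x input_ng x
    capture_efficiency x fraction``; a call is emitted as high confidence at
    or above ``high_conf_min_reads`` supporting reads, as low confidence in
    the band down to ``low_conf_min_reads``, and not at all below that.
    Breakpoints are placed inside the expected exons unless
    ``displace_breakpoints`` is set (negative-control plumbing).
    """
    if input_ng is None:
        input_ng = cfg.input_ng
    if input_ng <= 0:
        raise ValueError("input_ng must be > 0")
    rng = cfg.rng(4, seed_stream)
    calls: list[FusionCall] = []
    for ft in fusion_truths:
        lam = ft.copies_per_ng * input_ng * cfg.capture_efficiency * dilution_fraction
        reads = int(round(lam)) if cfg.noise == 0 else int(rng.poisson(lam))
        if reads >= cfg.high_conf_min_reads:
            confidence = "high"
        elif reads >= cfg.low_conf_min_reads:
            confidence = "low"
        else:
            continue

        def breakpoint_in(exons) -> int:
            iv = exons[0]
            bp = iv.start + 1 + len(iv) // 2
            if cfg.displace_breakpoints:
                bp = max(iv.end for iv in exons) + 1000
            return bp

        calls.append(
            FusionCall(
                gene_a=ft.gene_a,
                gene_b=ft.gene_b,
                breakpoint_a=breakpoint_in(ft.expected_exons_a),
                breakpoint_b=breakpoint_in(ft.expected_exons_b),
                confidence=confidence,
                supporting_reads=reads,
                event_kind=ft.event_kind,
            )
        )
    return calls


def simulate_cnv_calls(
    cnv_truths: list[tuple[str, float]],
    cfg: SimulationConfig,
    seed_stream: int = 0,
) -> list[CnvCall]:
    """Simulate observed CNV calls: expected copies plus Gaussian measurement
    noise (sd 0.3 copies, scaled by ``noise``), all pass-filter."""
    rng = cfg.rng(5, seed_stream)
    calls = []
    for gene, copies in cnv_truths:
        obs = copies + cfg.noise * float(rng.normal(0.0, 0.3))
        calls.append(CnvCall(gene=gene, copies=max(0.0, obs), filter_status="pass"))
    return calls


def simulate_replicates(
    truth: TruthSet,
    cfg: SimulationConfig,
    target: TargetSpace,
    design: list[dict],
) -> list[VariantCallSet]:
    """Simulate a replicate series for reproducibility studies.

    ``design`` is a list of provenance dicts, one per replicate, e.g.
    ``{"run_id": "R1", "operator_id": "O1", "machine_id": "M1"}``.  Each
    replicate is an independent draw (seed stream = its index) with the given
    provenance labels; with ``noise=0`` all replicates are identical.
    """
    out = []
    for i, prov in enumerate(design):
        cs, _ = simulate_observed_calls(
            truth,
            cfg,
            target,
            dilution_fraction=1.0,
            seed_stream=i + 1,
            sample_id=f"{cfg.seed}-rep{i + 1}",
            provenance={k: str(v) for k, v in prov.items()},
        )
        out.append(cs)
    return out


def simulate_dilution_series(
    truth: TruthSet,
    cfg: SimulationConfig,
    target: TargetSpace,
    fractions: list[float],
    n_replicates: int = 3,
):
    """Simulate a DNA dilution series: per fraction, ``n_replicates``
    independent call sets.  Returns a list of (fraction, [VariantCallSet])."""
    series = []
    for li, frac in enumerate(fractions):
        call_sets = []
        for r in range(n_replicates):
            cs, _ = simulate_observed_calls(
                truth,
                cfg,
                target,
                dilution_fraction=frac,
                seed_stream=1000 * (li + 1) + r,
                sample_id=f"dil{frac}-rep{r + 1}",
            )
            call_sets.append(cs)
        series.append((frac, call_sets))
    return series
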
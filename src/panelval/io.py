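"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* VCF 4.2 for small variants (read via pysam; multi-allelic records are split
  so each ALT becomes an independent call).  The FORMAT keys that carry the
  per-call metrics are configurable through a *tag map* because vendor VCF
  dialects differ; the defaults are ``DP`` (depth), ``VF`` (allele frequency,
  per-ALT), ``GQ``, ``SB`` (strand bias), ``AQ`` (adjusted quality) and ``AO``
  (alt-supporting reads, per-ALT).
* BED for the target space: columns 4 and 5, when present, are the
  transcript id and exon index.
* Per-base depth TSV: ``chrom  pos0  depth``.
* Fusion CSV: ``gene_a,gene_b,breakpoint_a,breakpoint_b,confidence,
  supporting_reads,event_kind``.
* CNV CSV: ``gene,copies,filter_status``.
* Truth sets as JSON.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import pysam

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
)

DEFAULT_TAG_MAP = {
    "depth": "DP",
    "vaf": "VF",
    "gq": "GQ",
    "sb": "SB",
    "aq": "AQ",
    "support": "AO",
}

# FORMAT keys whose values are per-ALT (VCF Number=A)
_PER_ALT_FIELDS = {"vaf", "support"}

_PROVENANCE_PREFIX = "provenance_"


def _coerce(value, field: str):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if field in ("depth", "support", "gq"):
        return int(value) if field != "gq" else float(value)
    return float(value)


def read_vcf(
    path: str | Path,
    tag_map: dict[str, str] | None = None,
    strict: bool = True,
) -> VariantCallSet:
    """Read a small-variant VCF into a :class:`VariantCallSet`.

    One :class:`SmallVariant` is produced per ALT allele; positions stay
    1-based.  Under ``strict=True`` a record missing a mapped tag raises; under
    lenient mode the metric is left ``None``.
    """
    path = Path(path)
    tags = dict(DEFAULT_TAG_MAP, **(tag_map or {}))
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    provenance = {}
    for rec in vf.header.records:
        key = str(rec.key) if rec.key else ""
        if key.startswith(_PROVENANCE_PREFIX):
            provenance[key[len(_PROVENANCE_PREFIX):]] = str(rec.value)
    samples = list(vf.header.samples)
    sample_id = samples[0] if samples else path.stem
    variants: list[SmallVariant] = []
    for line_no, rec in enumerate(vf, start=1):
        if not rec.alts:
            continue
        fmt = rec.samples[samples[0]] if samples else {}
        for ai, alt in enumerate(rec.alts):
            fields: dict[str, float | int | None] = {}
            for field, tag in tags.items():
                raw = None
                if samples and tag in fmt:
                    raw = fmt[tag]
                elif tag in rec.info:
                    raw = rec.info[tag]
                if isinstance(raw, tuple):
                    raw = raw[ai] if field in _PER_ALT_FIELDS else raw[0]
                if raw is None and strict:
                    raise ValueError(
                        f"{path} record {line_no} ({rec.chrom}:{rec.pos}): "
                        f"missing mandatory tag {tag!r} (strict mode)"
                    )
                fields[field] = _coerce(raw, field)
            try:
                variants.append(
                    SmallVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        vaf=fields["vaf"],
                        depth=fields["depth"],
                        support=fields["support"],
                        gq=fields["gq"],
                        sb=fields["sb"],
                        aq=fields["aq"],
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path} record {line_no} ({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    return VariantCallSet(sample_id=sample_id, variants=variants, provenance=provenance)


def write_vcf(
    call_set: VariantCallSet,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a call set as an uncompressed VCF 4.2 file (one sample)."""
    path = Path(path)
    header = pysam.VariantHeader()
    contigs = contig_lengths or {}
    for v in call_set.variants:
        need = v.pos + len(v.ref) + 1
        if contigs.get(v.chrom, 0) < need:
            contigs[v.chrom] = need
    for chrom in sorted(contigs):
        header.contigs.add(chrom, length=contigs[chrom])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("VF", "A", "Float", "Variant allele frequency")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("SB", 1, "Float", "Strand bias score")
    header.formats.add("AQ", 1, "Float", "Adjusted quality")
    header.formats.add("AO", "A", "Integer", "Alt-supporting read count")
    for key, value in sorted(call_set.provenance.items()):
        header.add_meta(f"{_PROVENANCE_PREFIX}{key}", value=str(value))
    header.add_sample(call_set.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(call_set.variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            fmt = rec.samples[call_set.sample_id]
            fmt["GT"] = (0, 1)
            if v.depth is not None:
                fmt["DP"] = int(v.depth)
            if v.vaf is not None:
                fmt["VF"] = (float(v.vaf),)
            if v.gq is not None:
                fmt["GQ"] = int(round(v.gq))
            if v.sb is not None:
                fmt["SB"] = float(v.sb)
            if v.aq is not None:
                fmt["AQ"] = float(v.aq)
            if v.support is not None:
                fmt["AO"] = (int(v.support),)
            out.write(rec)


def read_target_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a target BED (3+ columns; cols 4-5 = transcript id, exon index).

    Returns 0-based half-open intervals, sorted, with overlapping/abutting
    intervals of the same transcript merged.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ValueError(f"{path} line {line_no}: fewer than 3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(
                    f"{path} line {line_no}: start {start} >= end {end}"
                )
            tx = cols[3] if len(cols) > 3 else None
            exon = int(cols[4]) if len(cols) > 4 else None
            intervals.append(
                GenomicInterval(chrom, start, end, transcript_id=tx, exon_index=exon)
            )
    return merge_intervals(intervals)


def write_target_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.transcript_id is not None:
                cols.append(iv.transcript_id)
                if iv.exon_index is not None:
                    cols.append(str(iv.exon_index))
            fh.write("\t".join(cols) + "\n")


def read_coverage_tsv(
    path: str | Path,
    target: list[GenomicInterval] | None = None,
    strict: bool = True,
) -> CoverageProfile:
    """Read a per-base depth TSV (``chrom  pos0  depth``).

    When ``target`` is given, every target base must be present (a gap is an
    error under strict mode; lenient mode fills gaps with depth 0).  Without a
    target, intervals are inferred from runs of contiguous positions.
    """
    path = Path(path)
    depth_map: dict[tuple[str, int], int] = {}
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path} line {line_no}: expected 3 columns")
            try:
                chrom, pos0, depth = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path} line {line_no}: {exc}") from exc
            rows.append((chrom, pos0, depth))
            depth_map[(chrom, pos0)] = depth
    if target is not None:
        target = merge_intervals(target)
        depths: list[int] = []
        for iv in target:
            for p0 in range(iv.start, iv.end):
                d = depth_map.get((iv.chrom, p0))
                if d is None:
                    if strict:
                        raise ValueError(
                            f"{path}: missing depth for {iv.chrom}:{p0} "
                            "(gap in coverage TSV under strict mode)"
                        )
                    d = 0
                depths.append(d)
        return CoverageProfile(target, np.array(depths, dtype=np.int64))
    rows.sort()
    intervals: list[GenomicInterval] = []
    depths = []
    run_chrom, run_start, prev = None, None, None
    for chrom, pos0, depth in rows:
        if run_chrom == chrom and prev is not None and pos0 == prev + 1:
            prev = pos0
        else:
            if run_chrom is not None:
                intervals.append(GenomicInterval(run_chrom, run_start, prev + 1))
            run_chrom, run_start, prev = chrom, pos0, pos0
        depths.append(depth)
    if run_chrom is not None:
        intervals.append(GenomicInterval(run_chrom, run_start, prev + 1))
    return CoverageProfile(intervals, np.array(depths, dtype=np.int64))


def write_coverage_tsv(profile: CoverageProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        off = 0
        for iv in profile.intervals:
            for j in range(len(iv)):
                fh.write(f"{iv.chrom}\t{iv.start + j}\t{int(profile.depths[off + j])}\n")
            off += len(iv)


_FUSION_COLUMNS = [
    "gene_a",
    "gene_b",
    "breakpoint_a",
    "breakpoint_b",
    "confidence",
    "supporting_reads",
    "event_kind",
]


def read_fusion_csv(path: str | Path) -> list[FusionCall]:
    path = Path(path)
    calls: list[FusionCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_FUSION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing fusion CSV columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                calls.append(
                    FusionCall(
                        gene_a=row["gene_a"],
                        gene_b=row["gene_b"],
                        breakpoint_a=int(row["breakpoint_a"]),
                        breakpoint_b=int(row["breakpoint_b"]),
                        confidence=row["confidence"],
                        supporting_reads=int(row["supporting_reads"]),
                        event_kind=row["event_kind"],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path} line {line_no}: {exc}") from exc
    return calls


def write_fusion_csv(calls: list[FusionCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FUSION_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.gene_a,
                    c.gene_b,
                    c.breakpoint_a,
                    c.breakpoint_b,
                    c.confidence,
                    c.supporting_reads,
                    c.event_kind,
                ]
            )


def read_cnv_csv(path: str | Path) -> list[CnvCall]:
    path = Path(path)
    calls: list[CnvCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"gene", "copies", "filter_status"} - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing CNV CSV columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                calls.append(
                    CnvCall(
                        gene=row["gene"],
                        copies=float(row["copies"]),
                        filter_status=row["filter_status"],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {line_no}: {exc}") from exc
    return calls


def write_cnv_csv(calls: list[CnvCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene", "copies", "filter_status"])
        for c in calls:
            writer.writerow([c.gene, repr(c.copies), c.filter_status])


def _interval_to_json(iv: GenomicInterval) -> dict:
    d = {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
    if iv.transcript_id is not None:
        d["transcript_id"] = iv.transcript_id
    if iv.exon_index is not None:
        d["exon_index"] = iv.exon_index
    return d


def _interval_from_json(d: dict) -> GenomicInterval:
    return GenomicInterval(
        d["chrom"],
        d["start"],
        d["end"],
        transcript_id=d.get("transcript_id"),
        exon_index=d.get("exon_index"),
    )


def write_truth(truth: TruthSet, path: str | Path) -> None:
    doc = {
        "source_label": truth.source_label,
        "small_variants": [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vclass": v.vclass,
                "expected_vaf": v.vaf,
                **({"gene": v.gene} if v.gene else {}),
            }
            for v in truth.small_variants
        ],
        "fusions": [
            {
                "gene_a": f.gene_a,
                "gene_b": f.gene_b,
                "expected_exons_a": [_interval_to_json(iv) for iv in f.expected_exons_a],
                "expected_exons_b": [_interval_to_json(iv) for iv in f.expected_exons_b],
                "copies_per_ng": f.copies_per_ng,
                "event_kind": f.event_kind,
            }
            for f in truth.fusions
        ],
        "cnvs": [{"gene": g, "expected_copies": c} for g, c in truth.cnvs],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> TruthSet:
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: invalid truth JSON: {exc}") from exc
    try:
        small = [
            SmallVariant(
                chrom=d["chrom"],
                pos=d["pos"],
                ref=d["ref"],
                alt=d["alt"],
                vclass=d.get("vclass", ""),
                vaf=d["expected_vaf"],
                gene=d.get("gene"),
            )
            for d in doc.get("small_variants", [])
        ]
        fusions = [
            FusionTruth(
                gene_a=d["gene_a"],
                gene_b=d["gene_b"],
                expected_exons_a=tuple(
                    _interval_from_json(x) for x in d["expected_exons_a"]
                ),
                expected_exons_b=tuple(
                    _interval_from_json(x) for x in d["expected_exons_b"]
                ),
                copies_per_ng=d["copies_per_ng"],
                event_kind=d.get("event_kind", "fusion"),
            )
            for d in doc.get("fusions", [])
        ]
        cnvs = [(d["gene"], float(d["expected_copies"])) for d in doc.get("cnvs", [])]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid truth JSON field: {exc}") from exc
    return TruthSet(
        small_variants=small,
        fusions=fusions,
        cnvs=cnvs,
        source_label=doc.get("source_label", ""),
    )
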
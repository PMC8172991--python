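"""Validation-report assembly: accuracy, reproducibility, LOD and coverage
tables from a manifest of input files.

This layer is pure orchestration — every number in a report is produced by an
operation in another module.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .concordance import (
    ConfusionCounts,
    CnvPolicy,
    FusionPolicy,
    classify_cnvs,
    classify_fusions,
    classify_small_variants,
)
from .filtering import ReportingFilter, apply_reporting_filter
from .lod import DilutionLevel, assess_nucleic_acid_input, detection_rate, estimate_lod
from .model import VariantCallSet
from .qc import CoverageRule, coverage_pass, sample_pass_rate, transcript_failures
from .stats import (
    FACTORS,
    ReproducibilityDesign,
    compute_accuracy,
    format_percent,
    reproducibility_summary,
)


@dataclass
class ValidationReport:
    accuracy: dict = field(default_factory=dict)
    reproducibility: list = field(default_factory=list)
    lod: list = field(default_factory=list)
    coverage: dict = field(default_factory=dict)
    qualification_flags: list = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)


def accuracy_section(counts: dict[str, ConfusionCounts]) -> dict:
    """Turn per-class confusion counts into a Table-2-style accuracy section."""
    out = {}
    for label, c in counts.items():
        stats = compute_accuracy(c, with_ci=True)
        out[label] = {
            "tp": c.tp,
            "tn": c.tn if c.tn_applicable else None,
            "fp": c.fp,
            "fn": c.fn,
            "no_call": c.no_call,
            **{k: stats.as_dict()[k] for k in ("ppa", "npa", "ppv", "npv")},
            "display": {k: format_percent(v) for k, v in stats.as_dict().items()},
        }
    return out


def _load_config(config: dict | str | Path | None) -> dict:
    if config is None:
        return {}
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    known = {
        "reporting_filter",
        "min_depth",
        "min_vaf",
        "cnv_policy",
        "fusion_policy",
        "coverage_rule",
        "coverage_scope",
        "lod_prob_threshold",
        "seed",
    }
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return config


def run_validation(
    manifest: dict | str | Path, config: dict | str | Path | None = None
) -> ValidationReport:
    """Run the full validation computation described by a manifest.

    The manifest (dict or YAML path) lists the truth set, target BED, and the
    observed inputs by role::

        truth: truth.json
        target: target.bed
        samples:                      # small-variant replicates
          - {vcf: rep1.vcf, coverage: rep1_depth.tsv, run_id: R1, ...}
        fusions: fusions.csv          # optional
        cnvs: cnvs.csv                # optional
        inputs:                       # optional input-qualification records
          - {analyte: DNA, conc_ng_ul: 1.0, volume_ul: 50}

    Accuracy counts are summed across samples.  QC failures are reported, not
    fatal; missing files raise.
    """
    cfg = _load_config(config)
    base = Path(".")
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        base = mpath.parent
        with open(mpath) as fh:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ValueError("manifest must be a mapping")

    def resolve(p) -> Path:
        p = Path(p)
        p = p if p.is_absolute() else base / p
        if not p.exists():
            raise FileNotFoundError(f"manifest input not found: {p}")
        return p

    rf = ReportingFilter(
        min_depth=int(cfg.get("min_depth", 250)),
        min_vaf=float(cfg.get("min_vaf", 0.05)),
    )
    cnv_policy = CnvPolicy(**cfg.get("cnv_policy", {}))
    fusion_policy = FusionPolicy(**cfg.get("fusion_policy", {}))
    rule = CoverageRule(**cfg.get("coverage_rule", {}))
    scope = cfg.get("coverage_scope", "sample")

    truth = pio.read_truth(resolve(manifest["truth"]))
    target = pio.read_target_bed(resolve(manifest["target"]))

    report = ValidationReport(
        config_echo={
            "reporting_filter": {"min_depth": rf.min_depth, "min_vaf": rf.min_vaf},
            "cnv_policy": asdict(cnv_policy),
            "fusion_policy": asdict(fusion_policy),
            "coverage_rule": asdict(rule),
            "coverage_scope": scope,
            "manifest": {
                k: str(v) for k, v in manifest.items() if isinstance(v, (str, Path))
            },
        }
    )

    call_sets: list[VariantCallSet] = []
    profiles = []
    for entry in manifest.get("samples", []):
        cs = pio.read_vcf(resolve(entry["vcf"]), strict=False)
        prov = {
            k: str(entry[k])
            for k in ("run_id", "operator_id", "machine_id")
            if k in entry
        }
        if prov:
            cs.provenance.update(prov)
        call_sets.append(cs)
        profiles.append(
            pio.read_coverage_tsv(resolve(entry["coverage"]), target=target)
        )

    if call_sets:
        total = ConfusionCounts(variant_class="small_variant")
        for cs, profile in zip(call_sets, profiles):
            filtered = VariantCallSet(
                sample_id=cs.sample_id,
                variants=[v for v in cs.variants if apply_reporting_filter(v, rf)],
                provenance=cs.provenance,
            )
            total = total + classify_small_variants(
                filtered, truth, target, profile, min_depth=rf.min_depth
            )
        counts = {"small_variants": total}
    else:
        counts = {}

    if "fusions" in manifest:
        fusion_calls = pio.read_fusion_csv(resolve(manifest["fusions"]))
        counts["fusions"] = classify_fusions(fusion_calls, truth.fusions, fusion_policy)
    if "cnvs" in manifest:
        cnv_calls = pio.read_cnv_csv(resolve(manifest["cnvs"]))
        counts["cnvs"] = classify_cnvs(cnv_calls, truth.cnvs, cnv_policy)
    report.accuracy = accuracy_section(counts)

    if len(call_sets) >= 2:
        designs = [ReproducibilityDesign(f, call_sets) for f in FACTORS]
        report.reproducibility = reproducibility_summary(designs).to_dict("records")

    if "dilution_series" in manifest:
        levels = []
        for entry in manifest["dilution_series"]:
            sets = [pio.read_vcf(resolve(p), strict=False) for p in entry["vcfs"]]
            filtered = [
                VariantCallSet(
                    sample_id=cs.sample_id,
                    variants=[v for v in cs.variants if apply_reporting_filter(v, rf)],
                    provenance=cs.provenance,
                )
                for cs in sets
            ]
            levels.append(DilutionLevel(fraction=float(entry["fraction"]), call_sets=filtered))
        table = detection_rate(levels, truth)
        lods = estimate_lod(table, prob_threshold=float(cfg.get("lod_prob_threshold", 0.95)))
        report.lod = [
            {"variant": k, "lod_fraction": v} for k, v in sorted(lods.items())
        ]

    if profiles:
        per_sample = []
        for cs, profile in zip(call_sets, profiles):
            passed, fraction = coverage_pass(profile, rule, scope)
            per_sample.append(
                {"sample_id": cs.sample_id, "passed": passed, "fraction": fraction}
            )
        table, n_failing = transcript_failures(profiles, rule)
        report.coverage = {
            "pass_rate_percent": sample_pass_rate(profiles, rule, scope),
            "samples": per_sample,
            "transcripts_with_failures": n_failing,
            "transcript_failures": table.to_dict("records"),
        }

    for entry in manifest.get("inputs", []):
        verdict = assess_nucleic_acid_input(
            float(entry["conc_ng_ul"]),
            float(entry["volume_ul"]),
            analyte=entry.get("analyte", "DNA"),
        )
        rec = {**entry, "verdict": verdict}
        report.qualification_flags.append(rec)

    return report


def render_tables(report: ValidationReport, fmt: str, outdir: str | Path) -> list[Path]:
    """Write report tables; output is bit-stable for a fixed report (sorted
    keys, fixed decimal formatting).  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        path = outdir / "report.json"
        with open(path, "w") as fh:
            json.dump(asdict(report), fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(path)
    elif fmt == "tsv":
        acc_rows = []
        for label in sorted(report.accuracy):
            row = {"variant_class": label, **report.accuracy[label]}
            row.update(row.pop("display"))
            acc_rows.append(row)
        if acc_rows:
            path = outdir / "accuracy.tsv"
            pd.DataFrame(acc_rows).to_csv(path, sep="\t", index=False)
            written.append(path)
        if report.reproducibility:
            path = outdir / "reproducibility.tsv"
            pd.DataFrame(report.reproducibility).to_csv(path, sep="\t", index=False)
            written.append(path)
        if report.lod:
            path = outdir / "lod.tsv"
            pd.DataFrame(report.lod).to_csv(path, sep="\t", index=False)
            written.append(path)
        if report.coverage:
            path = outdir / "coverage.tsv"
            pd.DataFrame(report.coverage.get("samples", [])).to_csv(
                path, sep="\t", index=False
            )
            written.append(path)
    elif fmt == "markdown":
        path = outdir / "report.md"
        lines = ["# Validation summary", "", "## Accuracy", ""]
        lines.append("| class | TP | TN | FP | FN | No-Call | PPA | NPA | PPV | NPV |")
        lines.append("|---|---|---|---|---|---|---|---|---|---|")
        for label in sorted(report.accuracy):
            a = report.accuracy[label]
            d = a["display"]
            lines.append(
                f"| {label} | {a['tp']} | {a['tn'] if a['tn'] is not None else 'NA'} "
                f"| {a['fp']} | {a['fn']} | {a['no_call']} "
                f"| {d['ppa']} | {d['npa']} | {d['ppv']} | {d['npv']} |"
            )
        if report.reproducibility:
            lines += ["", "## Reproducibility", "",
                      "| factor | average concordance | n comparisons |", "|---|---|---|"]
            for r in report.reproducibility:
                lines.append(
                    f"| {r['factor']} | {format_percent(r['average_concordance'])} "
                    f"| {r['n_comparisons']} |"
                )
        if report.coverage:
            lines += ["", "## Coverage", "",
                      f"pass rate: {format_percent(report.coverage['pass_rate_percent'])}%"]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        written.append(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return written
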
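"""Agreement statistics: PPA/NPA/PPV/NPV and replicate reproducibility.

PPA = TP/(TP+FN), NPA = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
expressed as percentages.  Values are kept at full precision; presentation
rounding (round-half-up to one decimal) is a formatting concern only.
Wilson-score 95% confidence intervals are available on request.

Reproducibility between replicates, where neither set is a designated truth,
is summarized by the symmetric directional concordance: the mean of
|A∩B|/|A| and |A∩B|/|B|.  Replicate designs group call sets by run, operator
and machine, and each factor averages over its admissible pairwise
comparisons (within-run pairs for intra-run; level-crossing pairs for the
inter-* factors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .concordance import ConfusionCounts
from .model import VariantCallSet

FACTORS = ("intra_run", "inter_run", "inter_operator", "inter_machine")

_FACTOR_KEY = {
    "intra_run": "run_id",
    "inter_run": "run_id",
    "inter_operator": "operator_id",
    "inter_machine": "machine_id",
}


def format_percent(value: float | None, decimals: int = 1) -> str:
    """Round-half-up presentation of a percentage (e.g. 99.25 -> '99.3')."""
    if value is None or value != value:  # None or NaN
        return "NA"
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def _wilson(num: int, den: int) -> tuple[float, float] | None:
    if den == 0:
        return None
    lo, hi = proportion_confint(num, den, alpha=0.05, method="wilson")
    return (100.0 * lo, 100.0 * hi)


@dataclass
class AccuracyStats:
    """PPA/NPA/PPV/NPV percentages (None where the denominator is zero)."""

    ppa: float | None
    npa: float | None
    ppv: float | None
    npv: float | None
    n_basis: ConfusionCounts
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {"ppa": self.ppa, "npa": self.npa, "ppv": self.ppv, "npv": self.npv}


def compute_accuracy(c: ConfusionCounts, with_ci: bool = False) -> AccuracyStats:
    """Compute the four agreement statistics from confusion counts.

    Zero denominators yield ``None`` rather than raising.  When the class has
    no defined TN (fusions, CNVs), NPA and NPV come back ``None``.
    """
    pairs = {
        "ppa": (c.tp, c.tp + c.fn),
        "npa": (c.tn, c.tn + c.fp),
        "ppv": (c.tp, c.tp + c.fp),
        "npv": (c.tn, c.tn + c.fn),
    }
    values: dict[str, float | None] = {}
    ci: dict[str, tuple[float, float]] = {}
    for name, (num, den) in pairs.items():
        if not c.tn_applicable and name in ("npa", "npv"):
            values[name] = None
            continue
        values[name] = _ratio(num, den)
        if with_ci and values[name] is not None:
            ci[name] = _wilson(num, den)
    return AccuracyStats(n_basis=c, ci=ci, **values)


def pairwise_concordance(
    a: VariantCallSet, b: VariantCallSet, method: str = "directional_mean"
) -> float | None:
    """Symmetric concordance between two replicate call sets, in percent.

    ``directional_mean`` (default) averages |A∩B|/|A| and |A∩B|/|B|, dropping
    a direction whose denominator is zero; ``jaccard`` uses |A∩B|/|A∪B|.
    Undefined (None) when both sets are empty.
    """
    ka, kb = a.key_set(), b.key_set()
    if not ka and not kb:
        return None
    inter = len(ka & kb)
    if method == "jaccard":
        return 100.0 * inter / len(ka | kb)
    if method != "directional_mean":
        raise ValueError(f"unknown concordance method {method!r}")
    terms = [inter / len(k) for k in (ka, kb) if k]
    return 100.0 * sum(terms) / len(terms)


@dataclass
class ReproducibilityDesign:
    """Pairwise-comparison design for one replicate factor.

    ``factor`` is one of intra_run / inter_run / inter_operator /
    inter_machine; comparisons are derived from the call sets' provenance
    labels (same run for intra-run, differing level for the inter factors),
    unless an explicit pair list (indices into ``call_sets``) is supplied.
    """

    factor: str
    call_sets: list[VariantCallSet]
    explicit_pairs: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"factor must be one of {FACTORS}")

    def pairs(self) -> list[tuple[int, int]]:
        if self.explicit_pairs is not None:
            return list(self.explicit_pairs)
        key = _FACTOR_KEY[self.factor]
        out = []
        for i, j in combinations(range(len(self.call_sets)), 2):
            li = self.call_sets[i].provenance.get(key)
            lj = self.call_sets[j].provenance.get(key)
            if li is None or lj is None:
                continue
            same = li == lj
            if (self.factor == "intra_run") == same:
                out.append((i, j))
        return out


def reproducibility_summary(
    designs: ReproducibilityDesign | list[ReproducibilityDesign],
    method: str = "directional_mean",
) -> pd.DataFrame:
    """Average pairwise concordance per replicate factor.

    Returns a table with one row per factor: the arithmetic mean over all
    admissible pairwise comparisons (not pooled counts) and the number of
    comparisons.  A factor with no admissible pair is marked not-evaluable
    (average NaN, n_comparisons 0).
    """
    if isinstance(designs, ReproducibilityDesign):
        designs = [designs]
    rows = []
    for design in designs:
        pairs = design.pairs()
        values = [
            pairwise_concordance(design.call_sets[i], design.call_sets[j], method)
            for i, j in pairs
        ]
        values = [v for v in values if v is not None]
        rows.append(
            {
                "factor": design.factor,
                "average_concordance": (
                    sum(values) / len(values) if values else float("nan")
                ),
                "n_comparisons": len(pairs),
            }
        )
    return pd.DataFrame(rows, columns=["factor", "average_concordance", "n_comparisons"])
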
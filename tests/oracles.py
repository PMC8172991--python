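"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively and stays independent of the code paths it
checks: per-position enumeration for concordance, direct binomial pmf
summation for detection probabilities, and string surgery for normalization.
"""

from __future__ import annotations

from math import comb


def brute_force_small_variant_counts(
    observed, truth, intervals, depth_lookup, min_depth
):
    """Per-position enumeration of TP/FP/FN/TN/No-Call.

    ``depth_lookup`` maps (chrom, pos1) -> depth for every target base;
    ``intervals`` are 0-based half-open.
    """

    def in_target(chrom, pos):
        return any(
            iv.chrom == chrom and iv.start < pos <= iv.end for iv in intervals
        )

    obs_in = [v for v in observed if in_target(v.chrom, v.pos)]
    truth_keys = {v.key for v in truth}
    obs_keys = {v.key for v in obs_in}

    tp = sum(1 for v in obs_in if v.key in truth_keys)
    fp = sum(1 for v in obs_in if v.key not in truth_keys)
    fn = nc = 0
    for t in truth:
        if t.key in obs_keys:
            continue
        if depth_lookup[(t.chrom, t.pos)] >= min_depth:
            fn += 1
        else:
            nc += 1

    touched = set()
    for v in list(obs_in) + list(truth):
        for p in range(v.pos, v.pos + len(v.ref)):
            touched.add((v.chrom, p))
    tn = 0
    for iv in intervals:
        for p in range(iv.start + 1, iv.end + 1):  # 1-based positions
            if depth_lookup[(iv.chrom, p)] >= min_depth and (
                iv.chrom, p
            ) not in touched:
                tn += 1
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn, "no_call": nc}


def binomial_tail_sum(n: int, p: float, k: int) -> float:
    """P[X >= k] for X ~ Binomial(n, p) by exhaustive pmf summation."""
    if k <= 0:
        return 1.0
    total = 0.0
    for x in range(k, n + 1):
        total += comb(n, x) * (p**x) * ((1.0 - p) ** (n - x))
    return min(1.0, total)


def apply_variant_to_sequence(seq: str, pos: int, ref: str, alt: str) -> str:
    """Replace the ref allele at 1-based ``pos`` with the alt allele."""
    i = pos - 1
    assert seq[i : i + len(ref)] == ref
    return seq[:i] + alt + seq[i + len(ref):]


def left_shift_indel(seq: str, pos: int, ref: str, alt: str):
    """Brute-force left shift of a minimal pure indel (anchor base plus an
    inserted or deleted tail): scan every candidate anchor position left of
    ``pos``, construct the anchor-form representation there, and return the
    leftmost one whose alternate haplotype is identical to the original's.
    """
    assert ref[0] == alt[0] and (ref.startswith(alt) or alt.startswith(ref))
    hap = apply_variant_to_sequence(seq, pos, ref, alt)
    t = abs(len(ref) - len(alt))
    deletion = len(ref) > len(alt)
    for p in range(1, pos):
        a = seq[p - 1]
        if deletion:
            r, al = seq[p - 1 : p + t], a
        else:
            r, al = a, a + hap[p : p + t]
        if r == al:
            continue
        if apply_variant_to_sequence(seq, p, r, al) == hap:
            return p, r, al
    return pos, ref, alt
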
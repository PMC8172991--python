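import numpy as np
import pytest

from panelval.model import GenomicInterval, SmallVariant, TruthSet, CoverageProfile
from panelval.simulate import SimulationConfig, simulate_target_space, simulate_truth


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_target(default_cfg):
    return simulate_target_space(default_cfg)


@pytest.fixture(scope="session")
def default_truth(default_cfg, default_target):
    return simulate_truth(default_cfg, default_target)


@pytest.fixture
def small_scene():
    """The worked small-variant concordance scene: a 1000-position target,
    two expected variants, two observed calls, one low-coverage position."""
    target = [GenomicInterval("chr1", 0, 1000)]
    truth = TruthSet(
        small_variants=[
            SmallVariant("chr1", 100, "A", "T", vaf=0.30),
            SmallVariant("chr1", 200, "G", "C", vaf=0.30),
        ]
    )
    depths = np.full(1000, 300, dtype=np.int64)
    depths[199] = 50  # 1-based position 200
    coverage = CoverageProfile(target, depths)
    observed = [
        SmallVariant("chr1", 100, "A", "T", vaf=0.3, depth=300, support=90),
        SmallVariant("chr1", 300, "C", "G", vaf=0.1, depth=300, support=30),
    ]
    return target, truth, coverage, observed


def make_instance(rng):
    """One randomized concordance instance (<= 2000 target positions)."""
    n_iv = int(rng.integers(1, 5))
    intervals = []
    total = 0
    for i in range(n_iv):
        chrom = "chr1" if i < 2 else "chr2"
        start = int(rng.integers(0, 500)) + (0 if i < 2 else 0)
        length = int(rng.integers(50, 500))
        intervals.append((chrom, start, start + length))
        total += length
    # lay out non-overlapping per chrom
    laid, cursor = [], {}
    for chrom, start, end in intervals:
        s = max(start, cursor.get(chrom, 0))
        e = s + (end - start)
        laid.append(GenomicInterval(chrom, s, e))
        cursor[chrom] = e + int(rng.integers(1, 50))
    intervals = laid

    depths = rng.integers(0, 400, size=sum(len(iv) for iv in intervals))
    coverage = CoverageProfile(intervals, depths)
    depth_lookup = {
        (c, p): d for c, p, d in coverage.iter_positions()
    }
    min_depth = int(rng.choice([100, 250]))

    # truth variants at spaced anchors (span <= 3 stays inside by margin)
    anchors = []
    for iv in intervals:
        anchors.extend((iv.chrom, p) for p in range(iv.start + 1, iv.end - 3))
    rng.shuffle(anchors)
    n_truth = int(rng.integers(0, 9))
    truth_vars, used = [], set()
    for chrom, p in anchors:
        if len(truth_vars) >= n_truth:
            break
        if any((chrom, p + d) in used for d in range(-4, 5)):
            continue
        used.add((chrom, p))
        kind = rng.random()
        if kind < 0.6:
            v = SmallVariant(chrom, p, "A", "T", vaf=0.3)
        elif kind < 0.8:
            v = SmallVariant(chrom, p, "ACG", "A", vaf=0.3)
        else:
            v = SmallVariant(chrom, p, "A", "AGG", vaf=0.3)
        truth_vars.append(v)
    truth = TruthSet(small_variants=truth_vars)

    observed, obs_keys = [], set()
    for tv in truth_vars:
        r = rng.random()
        if r < 0.6:  # concordant call
            v = SmallVariant(
                tv.chrom, tv.pos, tv.ref, tv.alt, vaf=0.3, depth=300, support=90
            )
        elif r < 0.75:  # wrong allele at the truth position
            alt = "C" if tv.alt != "C" else "G"
            v = SmallVariant(tv.chrom, tv.pos, "A", alt, vaf=0.3, depth=300, support=90)
        else:
            continue
        if v.key not in obs_keys:
            obs_keys.add(v.key)
            observed.append(v)
    # novel calls, some outside the target
    for _ in range(int(rng.integers(0, 6))):
        iv = intervals[int(rng.integers(len(intervals)))]
        if rng.random() < 0.2:
            p = iv.end + int(rng.integers(1, 100))  # outside
        else:
            p = int(rng.integers(iv.start + 1, iv.end + 1))
        v = SmallVariant(iv.chrom, p, "G", "A", vaf=0.1, depth=300, support=30)
        if v.key not in obs_keys:
            obs_keys.add(v.key)
            observed.append(v)
    return observed, truth, intervals, coverage, depth_lookup, min_depth
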
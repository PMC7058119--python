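"""Shared fixtures: small hand-built segment sets and one simulated
benchmark scenario reused (read-only) across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cnatree import bias_correction as bc
from cnatree.baseline_detection import compute_theta, detect_baseline
from cnatree.clonal_model import LikelihoodContext
from cnatree.segments_io import Segment, SegmentSet, SNPLocus
from cnatree.synthetic_data import simulate, six_scna_scenario


def make_segment(
    seg_id="s0",
    chrom="chr1",
    start=0,
    end=500_000,
    tumor=15_000,
    normal=15_000,
    gc=0.45,
    snps=(),
    corrected=None,
):
    seg = Segment(
        id=seg_id, chrom=chrom, start=start, end=end,
        tumor_reads=tumor, normal_reads=normal, gc=gc, snps=list(snps),
    )
    seg.corrected_ratio = corrected
    return seg


def make_snps(chrom, positions, b_counts, depths):
    return [
        SNPLocus(chrom=chrom, pos=int(p), b_count=int(b), depth=int(d))
        for p, b, d in zip(positions, b_counts, depths)
    ]


def exact_mean_segment(phi, c, genotype, seg_id="x", chrom="chr1", start=0,
                       normal=20_000, n_snps=200, depth=40, length=500_000):
    """Segment whose counts sit exactly at their model expectations for
    (phi, C, genotype) with theta = 1 and no GC bias."""
    cbar = phi * c + (1 - phi) * 2
    mu_t = genotype.count("M") / c if c > 0 else 0.0
    mu = (phi * c * mu_t + (1 - phi)) / cbar if cbar > 0 else 0.5
    p = min(mu, 1 - mu)
    b = int(round(p * depth))
    snps = make_snps(chrom, np.arange(n_snps) * 100 + start + 1,
                     [b] * n_snps, [depth] * n_snps)
    seg = make_segment(
        seg_id=seg_id, chrom=chrom, start=start, end=start + length,
        tumor=int(round(cbar / 2 * normal)), normal=normal, snps=snps,
        corrected=cbar / 2,
    )
    return seg


@pytest.fixture(scope="session")
def scenario_run():
    """One simulated benchmark scenario (seed 1), bias-corrected, with
    baseline and likelihood context prepared. Treated as read-only."""
    segset, truth = simulate(six_scna_scenario(seed=1))
    model = bc.fit_bias(segset)
    bc.apply_correction(segset, model)
    baseline = detect_baseline(segset, coverage=30.0)
    theta = compute_theta(segset, baseline)
    ctx = LikelihoodContext(theta=theta, c_max=15, bias=model)
    return {
        "segset": segset,
        "truth": truth,
        "bias": model,
        "baseline": baseline,
        "theta": theta,
        "ctx": ctx,
    }
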
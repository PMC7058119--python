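"""Detection of copy-neutral baseline segments and the ratio anchor.

Because tumor and normal libraries are sequenced separately, the
tumor/normal ratio of a copy-neutral segment is close to, but not
exactly, 1. The model therefore anchors the ratio scale on theta, the
geometric mean of the corrected ratios of detected baseline segments.

A segment is copy-neutral when its folded average BAF is consistent
with an underlying BAF of 1/2 *and* its SNP read depth matches the
copy-neutral expectation: BAF 1/2 alone also arises from balanced
states (homozygous deletion diluted by normal cells, PPMM, PPPMMM,
...), which the depth criterion excludes.

Neither criterion can be an exact equality on noisy counts. Moreover,
folding biases the observed statistic: at depth d the folded BAF
min(b, d-b)/d of a balanced locus has expectation well below 1/2
(about 0.43 at 30x), so the BAF test compares the segment's mean folded
BAF against its exact null expectation under Binomial(d_k, 1/2)
computed from the segment's own SNP depths, within ``baf_tol``. The
depth test is a relative band ``depth_tol`` around the expected
copy-neutral per-locus depth.
"""

from __future__ import annotations

import logging

import numpy as np

from .segments_io import SegmentSet

logger = logging.getLogger(__name__)


class BaselineNotFoundError(RuntimeError):
    pass


def null_folded_baf_mean(depths: np.ndarray) -> float:
    """Expected mean folded BAF over loci with the given depths when the
    underlying BAF is exactly 1/2: E[min(b, d-b)]/d, b ~ Binomial(d, 1/2)."""
    from scipy.stats import binom

    depths = np.asarray(depths, dtype=int)
    out = 0.0
    for d, count in zip(*np.unique(depths, return_counts=True)):
        b = np.arange(d + 1)
        out += count * float(np.sum(binom.pmf(b, d, 0.5) * np.minimum(b, d - b)) / d)
    return out / len(depths)


def detect_baseline(
    segset: SegmentSet,
    coverage: float,
    baf_tol: float = 0.03,
    depth_tol: float = 0.05,
) -> set[str]:
    """Return the ids of copy-neutral segments.

    ``coverage`` is the expected per-locus tumor depth at average copy
    number 2. Segments without SNPs cannot be tested and are never
    baseline.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    kept: set[str] = set()
    for seg in segset:
        if not seg.snps:
            continue
        depths = np.array([s.depth for s in seg.snps])
        mean_baf = float(np.mean(seg.folded_bafs()))
        if abs(mean_baf - null_folded_baf_mean(depths)) > baf_tol:
            continue
        mean_depth = float(np.mean([s.depth for s in seg.snps]))
        if abs(mean_depth - coverage) > depth_tol * coverage:
            continue
        kept.add(seg.id)
    if not kept:
        raise BaselineNotFoundError(
            "no copy-neutral segment passed the BAF/depth criteria; "
            "designate baseline segments manually or loosen the tolerances"
        )
    logger.info("detect_baseline: %d of %d segments are baseline", len(kept), len(segset))
    return kept


def compute_theta(segset: SegmentSet, baseline_ids: set[str]) -> float:
    """Geometric mean of the corrected ratios of the baseline segments."""
    if not baseline_ids:
        raise ValueError("baseline set is empty")
    logs = [np.log(segset.by_id(i).ratio) for i in sorted(baseline_ids)]
    return float(np.exp(np.mean(logs)))
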
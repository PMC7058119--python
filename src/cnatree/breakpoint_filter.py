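"""False-breakpoint filtering by aggregation, decomposition and merging.

An over-sensitive segmenter splits each true copy-number region into
many fragments. Because fragments of one region share both the
(corrected) read-count ratio and the B-allele frequency profile, they
can be re-joined without re-segmentation:

1. *aggregation* — agglomerative (Ward) clustering of segments on the
   scalar log corrected ratio, with the cluster count capped at
   c_max * tau (tau = assumed number of subclonal populations);
2. *decomposition* — mean-shift clustering of the pooled folded BAF
   values inside each ratio cluster; each segment takes the majority
   label of its own SNPs, splitting the cluster into BAF subclusters;
3. *merging* — within each (ratio, BAF) cell, transitively merge
   same-chromosome neighbours closer than rho base pairs.

Merging conserves read counts and SNPs exactly and can never join
fragments whose ratio or BAF profiles disagree, nor fragments separated
by more than rho, so true breakpoints survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import MeanShift

from . import bias_correction
from .bias_correction import BiasModel
from .segments_io import Segment, SegmentSet, StructuralError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Filter tuning.

    ``c_max * tau`` caps the number of ratio clusters; ``rho`` is the
    maximum gap (bp) bridged when merging adjacent fragments (default 1:
    only book-ended fragments merge); ``bandwidth`` the mean-shift kernel
    bandwidth on folded BAF (None = Silverman's rule).
    """

    c_max: int = 15
    tau: int = 5
    rho: int = 1
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.c_max * self.tau < 1:
            raise ValueError("c_max * tau must be >= 1")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


def aggregate(segset: SegmentSet, config: FilterConfig) -> list[list[Segment]]:
    """Partition segments into ratio clusters.

    Ward linkage on log corrected ratio; the tree is cut at the largest
    merge-height gap, never above ``c_max * tau`` clusters. All-equal
    input collapses to a single cluster.
    """
    segs = list(segset)
    if any(s.corrected_ratio is None for s in segs):
        raise ValueError("corrected_ratio unset; run bias correction first")
    n = len(segs)
    if n == 0:
        return []
    if n == 1:
        return [segs]
    x = np.log([s.corrected_ratio for s in segs])[:, None]
    Z = linkage(x, method="ward")
    heights = Z[:, 2]
    if heights[-1] < 1e-12:  # all ratios identical
        return [segs]
    cap = min(n, config.c_max * config.tau)
    # cutting into K clusters removes the top K-1 merges; the natural K
    # maximizes the gap between the last kept and first removed height
    best_k, best_gap = 2, -np.inf
    for k in range(2, cap + 1):
        upper = heights[n - k]
        lower = heights[n - k - 1] if n - k - 1 >= 0 else 0.0
        gap = upper - lower
        if gap > best_gap:
            best_k, best_gap = k, gap
    labels = fcluster(Z, t=best_k, criterion="maxclust")
    clusters: dict[int, list[Segment]] = {}
    for seg, lab in zip(segs, labels):
        clusters.setdefault(int(lab), []).append(seg)
    logger.info("aggregate: %d segments -> %d ratio clusters", n, len(clusters))
    return [clusters[k] for k in sorted(clusters)]


def _silverman_bandwidth(values: np.ndarray) -> float:
    sd = float(np.std(values))
    if sd == 0.0 or len(values) < 2:
        return 0.0
    return 1.06 * sd * len(values) ** (-0.2)


def _default_bandwidth(cluster: list[Segment], pooled: np.ndarray) -> float:
    """Silverman's rule floored at twice the binomial sampling scale.

    A single folded BAF observation at depth d has sampling SD of about
    sqrt(0.25/d) (~0.09 at 30x); Silverman's rule on a large pooled
    sample shrinks far below that and mean-shift would then resolve
    sampling noise into spurious modes, shattering fragment groups.
    Modes closer than ~2 sampling SDs are not separable from noise at
    the single-SNP level, so that is the resolution floor.
    """
    depths = np.array([sn.depth for s in cluster for sn in s.snps], dtype=float)
    noise_sd = float(np.sqrt(0.25 / np.median(depths))) if len(depths) else 0.0
    return max(_silverman_bandwidth(pooled), 2.0 * noise_sd)


def decompose(cluster: list[Segment], config: FilterConfig) -> list[list[Segment]]:
    """Split one ratio cluster into BAF subclusters.

    Mean-shift runs on the pooled folded BAFs of every SNP in the
    cluster; a segment's label is the modal label of its own SNPs (ties
    to the lowest label). Segments without SNPs cannot be BAF-typed and
    are grouped into a subcluster of their own.
    """
    if not cluster:
        raise ValueError("empty cluster")
    with_snps = [s for s in cluster if s.snps]
    without = [s for s in cluster if not s.snps]
    subclusters: list[list[Segment]] = []
    if with_snps:
        pooled = np.concatenate([s.folded_bafs() for s in with_snps])
        bw = config.bandwidth or _default_bandwidth(with_snps, pooled)
        if bw <= 0 or len(np.unique(pooled)) == 1:
            for s in with_snps:
                s.baf_cluster = 0
            subclusters.append(list(with_snps))
        else:
            ms = MeanShift(bandwidth=bw, bin_seeding=len(pooled) > 500)
            ms.fit(pooled[:, None])
            groups: dict[int, list[Segment]] = {}
            for s in with_snps:
                lab = ms.predict(s.folded_bafs()[:, None])
                counts = np.bincount(lab)
                s.baf_cluster = int(np.argmax(counts))  # ties -> lowest index
                groups.setdefault(s.baf_cluster, []).append(s)
            subclusters.extend(groups[k] for k in sorted(groups))
    if without:
        for s in without:
            s.baf_cluster = -1
        subclusters.append(without)
    return subclusters


def merge_adjacent(
    subcluster: list[Segment],
    rho: int,
    bias_model: BiasModel | None = None,
) -> tuple[list[Segment], dict[str, str]]:
    """Transitively merge same-chromosome neighbours with gap < rho.

    The merged segment spans min(start)..max(end), sums read counts,
    concatenates SNPs and recomputes GC as the length-weighted mean; its
    corrected ratio is recomputed from the summed counts through the
    bias model (identity when none is given). Returns the merged list
    and a child -> merged-id provenance map.
    """
    model = bias_model or bias_correction.IDENTITY
    segs = sorted(subcluster, key=lambda s: (s.chrom, s.start))
    for a, b in zip(segs, segs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise StructuralError(f"overlapping segments {a.id} and {b.id}")
    merged: list[Segment] = []
    provenance: dict[str, str] = {}
    run: list[Segment] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            merged.append(run[0])
            provenance[run[0].id] = run[0].id
            return
        new_id = run[0].id + "+"
        total_len = sum(s.length for s in run)
        gc = sum(s.gc * s.length for s in run) / total_len
        tumor = sum(s.tumor_reads for s in run)
        normal = sum(s.normal_reads for s in run)
        snps = sorted((sn for s in run for sn in s.snps), key=lambda sn: sn.pos)
        seg = Segment(
            id=new_id, chrom=run[0].chrom, start=run[0].start, end=run[-1].end,
            tumor_reads=tumor, normal_reads=normal, gc=gc, snps=snps,
            baf_cluster=run[0].baf_cluster,
        )
        raw = seg.raw_ratio if tumor > 0 else 0.5 / normal
        seg.corrected_ratio = bias_correction.correct(model, raw, gc)
        merged.append(seg)
        for s in run:
            provenance[s.id] = new_id

    for seg in segs:
        if run and seg.chrom == run[-1].chrom and seg.start - run[-1].end < rho:
            run.append(seg)
        else:
            flush()
            run = [seg]
    flush()
    return merged, provenance


def run_filter(
    segset: SegmentSet,
    config: FilterConfig,
    bias_model: BiasModel | None = None,
) -> tuple[SegmentSet, dict[str, str]]:
    """aggregate -> decompose -> merge; returns the filtered set and the
    child -> merged-segment provenance map."""
    provenance: dict[str, str] = {}
    out: list[Segment] = []
    for cluster in aggregate(segset, config):
        for sub in decompose(cluster, config):
            merged, prov = merge_adjacent(sub, config.rho, bias_model)
            out.extend(merged)
            provenance.update(prov)
    out.sort(key=lambda s: (s.chrom, s.start))
    logger.info("run_filter: %d segments -> %d after merging", len(segset), len(out))
    return SegmentSet(segments=out), provenance
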
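"""Count-level simulator for tumor/normal copy-number data.

Generates segment read counts and SNP allele counts under a known clone
tree, so every downstream stage (bias correction, breakpoint filtering,
baseline detection, inference) can be exercised with ground truth in
hand. The simulator works at count level, not read level: the model only
ever consumes per-segment read counts and per-SNP allele counts, so BAM
realism buys nothing at desk scale.

Generative scheme per segment j (clone tree with subpopulation
frequencies x; segment assigned to node v):

* subclonal frequency  phi_j = sum of x over v and its descendants
* average copy number  cbar_j = phi_j * C_j + (1 - phi_j) * 2
* normal reads  ~ Poisson(coverage * length)
* tumor reads   ~ Poisson(exp(gc_slope * gc + gc_intercept) * (cbar_j / 2)
                          * normal_reads)  — conditioned on the realized
                          normal count, matching the read-depth model
* per SNP: depth ~ Poisson(snp_depth * cbar_j / 2) floored at 1;
  B-count ~ Binomial(depth, m) where m is the expected BAF
  (phi_j * C_j * mu_j + (1 - phi_j)) / cbar_j, with the B allele assigned
  to either haplotype with probability 1/2 per locus (so the folded BAF
  is the informative quantity, as in real data).

GC fractions are drawn uniformly in [0.3, 0.6] per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segments_io import Segment, SegmentSet, SNPLocus

_GC_RANGE = (0.3, 0.6)


@dataclass(frozen=True)
class CloneNode:
    """One subpopulation: identifier, parent (None for the founding
    clone) and the fraction of cells belonging to exactly this clone."""

    id: str
    parent: str | None
    freq: float


@dataclass(frozen=True)
class ScnaSpec:
    """One simulated SCNA: location, integer copy number, allele
    genotype (string over {P, M}, empty for homozygous deletion) and the
    clone node that acquired it."""

    chrom: str
    start: int  # 1-based start position
    length: int
    copy_number: int
    genotype: str
    node: str


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    ``coverage`` is the expected normal reads per base (0.03 gives
    ~15000 reads on a 500-kb segment); ``snp_rate`` the density of
    heterozygous germline SNPs per base (1/2000 ~ typical human
    heterozygosity after genotype filtering); ``snp_depth`` the expected
    per-locus tumor depth at copy-neutral state (~30x WGS);
    ``gc_bias`` the (slope, intercept) of an injected log-linear GC
    effect on the tumor/normal ratio; ``false_breakpoint_rate`` the
    expected number of spurious splits per segment applied by
    :func:`inject_false_breakpoints`.
    """

    clone_nodes: tuple[CloneNode, ...]
    scnas: tuple[ScnaSpec, ...]
    normal_segments: tuple[tuple[str, int, int], ...]  # (chrom, 1-based start, length)
    coverage: float = 0.03
    snp_rate: float = 1.0 / 2000.0
    snp_depth: float = 30.0
    gc_bias: tuple[float, float] = (0.0, 0.0)
    false_breakpoint_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(n.freq for n in self.clone_nodes)
        if any(n.freq <= 0 for n in self.clone_nodes):
            raise ValueError("subpopulation frequencies must be positive")
        if total > 1.0 + 1e-9:
            raise ValueError(f"subpopulation frequencies sum to {total} > 1")
        ids = {n.id for n in self.clone_nodes}
        for n in self.clone_nodes:
            if n.parent is not None and n.parent not in ids:
                raise ValueError(f"clone {n.id}: unknown parent {n.parent}")
        for s in self.scnas:
            if len(s.genotype) != s.copy_number:
                raise ValueError(
                    f"SCNA at {s.chrom}:{s.start}: genotype {s.genotype!r} "
                    f"length != copy number {s.copy_number}"
                )
            if set(s.genotype) - {"P", "M"}:
                raise ValueError(f"genotype {s.genotype!r} not over {{P,M}}")
            if s.node not in ids:
                raise ValueError(f"SCNA at {s.chrom}:{s.start}: unknown node {s.node}")

    def subclonal_frequencies(self) -> dict[str, float]:
        """phi per node: own frequency plus all descendants'."""
        children: dict[str, list[str]] = {n.id: [] for n in self.clone_nodes}
        freq = {n.id: n.freq for n in self.clone_nodes}
        for n in self.clone_nodes:
            if n.parent is not None:
                children[n.parent].append(n.id)

        def subtree(v: str) -> float:
            return freq[v] + sum(subtree(c) for c in children[v])

        return {v: subtree(v) for v in freq}


@dataclass
class SegmentTruth:
    phi: float
    copy_number: int
    genotype: str
    node: str | None  # None for normal segments
    cbar: float


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    config: SimConfig
    segments: dict[str, SegmentTruth] = field(default_factory=dict)
    scna_segment_ids: dict[str, str] = field(default_factory=dict)  # scna key -> seg id
    split_parent: dict[str, str] = field(default_factory=dict)  # child id -> parent id


def _mu_tumor(genotype: str, copy_number: int) -> float:
    """Tumor BAF of a genotype: fraction of M alleles. Irrelevant (and
    taken as 0) for copy number 0, where the term it multiplies vanishes."""
    if copy_number == 0:
        return 0.0
    return genotype.count("M") / copy_number


def expected_baf(phi: float, copy_number: int, genotype: str) -> float:
    """Population-average BAF (phi*C*mu + (1-phi))/cbar, unfolded."""
    cbar = phi * copy_number + (1.0 - phi) * 2.0
    if cbar == 0.0:
        return 0.5  # degenerate: no DNA at all; never reached with phi < 1
    return (phi * copy_number * _mu_tumor(genotype, copy_number) + (1.0 - phi)) / cbar


def simulate(config: SimConfig) -> tuple[SegmentSet, SimTruth]:
    """Run the count-level simulation. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    phis = config.subclonal_frequencies()
    slope, intercept = config.gc_bias

    truth = SimTruth(config=config)
    segments: list[Segment] = []

    def emit(chrom: str, start1: int, length: int, phi: float, c: int,
             genotype: str, node: str | None, key: str | None) -> None:
        seg_id = f"seg{len(segments):05d}"
        cbar = phi * c + (1.0 - phi) * 2.0
        gc = float(rng.uniform(*_GC_RANGE))
        normal = max(1, int(rng.poisson(config.coverage * length)))
        tumor_mean = np.exp(slope * gc + intercept) * (cbar / 2.0) * normal
        tumor = int(rng.poisson(tumor_mean))
        n_snps = int(rng.poisson(config.snp_rate * length))
        start0 = start1 - 1  # to 0-based half-open
        positions = np.sort(
            rng.choice(np.arange(start0 + 1, start0 + length + 1), size=min(n_snps, length), replace=False)
        ) if n_snps > 0 else np.array([], dtype=int)
        mu = expected_baf(phi, c, genotype)
        snps = []
        for pos in positions:
            depth = max(1, int(rng.poisson(config.snp_depth * cbar / 2.0)))
            m = mu if rng.random() < 0.5 else 1.0 - mu  # random B-allele haplotype
            b = int(rng.binomial(depth, m))
            snps.append(SNPLocus(chrom=chrom, pos=int(pos), b_count=b, depth=depth))
        segments.append(
            Segment(
                id=seg_id, chrom=chrom, start=start0, end=start0 + length,
                tumor_reads=tumor, normal_reads=normal, gc=gc, snps=snps,
            )
        )
        truth.segments[seg_id] = SegmentTruth(
            phi=phi, copy_number=c, genotype=genotype, node=node, cbar=cbar
        )
        if key is not None:
            truth.scna_segment_ids[key] = seg_id

    for i, scna in enumerate(config.scnas):
        emit(
            scna.chrom, scna.start, scna.length, phis[scna.node],
            scna.copy_number, scna.genotype, scna.node, key=f"scna{i}",
        )
    for chrom, start1, length in config.normal_segments:
        emit(chrom, start1, length, 0.0, 2, "PM", None, key=None)

    segset = SegmentSet(segments=segments)
    if config.false_breakpoint_rate > 0:
        segset, truth = inject_false_breakpoints(
            segset, config.false_breakpoint_rate,
            seed=int(rng.integers(2**31)), truth=truth,
        )
    return segset, truth


def inject_false_breakpoints(
    segset: SegmentSet,
    rate: float,
    seed: int,
    truth: SimTruth | None = None,
) -> tuple[SegmentSet, SimTruth | None]:
    """Split segments at spurious breakpoints to mimic an over-sensitive
    segmenter.

    Each segment is split at k ~ Poisson(rate) uniform interior
    positions; children partition the parent interval, read counts are
    apportioned binomially by length fraction (so children sum exactly to
    the parent) and SNPs are reassigned by position. ``truth``, when
    given, gains a child -> parent provenance map.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[Segment] = []
    for seg in segset:
        k = int(rng.poisson(rate))
        interior = np.arange(seg.start + 1, seg.end)
        k = min(k, len(interior))
        if k == 0:
            out.append(seg)
            continue
        cuts = np.sort(rng.choice(interior, size=k, replace=False))
        bounds = [seg.start, *cuts.tolist(), seg.end]
        rem_t, rem_n, rem_len = seg.tumor_reads, seg.normal_reads, seg.length
        for ci in range(len(bounds) - 1):
            lo, hi = bounds[ci], bounds[ci + 1]
            frac = (hi - lo) / rem_len
            if ci == len(bounds) - 2:
                t, n = rem_t, rem_n
            else:
                t = int(rng.binomial(rem_t, frac))
                n = int(rng.binomial(rem_n, frac))
                rem_t -= t
                rem_n -= n
                rem_len -= hi - lo
            child = Segment(
                id=f"{seg.id}.{ci}", chrom=seg.chrom, start=lo, end=hi,
                tumor_reads=t, normal_reads=max(1, n), gc=seg.gc,
                snps=[s for s in seg.snps if lo < s.pos <= hi],
            )
            out.append(child)
            if truth is not None:
                truth.split_parent[child.id] = seg.id
                truth.segments[child.id] = truth.segments[seg.id]
    return SegmentSet(segments=out), truth


# ---------------------------------------------------------------------------
# Reference scenario: six SCNAs on chromosome 21 under a six-clone tree
# ---------------------------------------------------------------------------

def six_scna_scenario(
    coverage: float = 0.03,
    snp_rate: float = 1.0 / 2000.0,
    snp_depth: float = 30.0,
    gc_bias: tuple[float, float] = (0.0, 0.0),
    false_breakpoint_rate: float = 0.0,
    n_normal: int = 20,
    seed: int = 0,
) -> SimConfig:
    """The benchmark scenario: six SCNAs (a-f) on chr21 acquired along a
    six-clone lineage, plus copy-neutral segments for baseline detection.

    True subclonal frequencies are 0.95 (a), 0.30 (b), 0.10 (c),
    0.50 (d), 0.30 (e), 0.10 (f); SCNA a is a homozygous deletion,
    e a hemizygous deletion, f a seven-copy amplification. The
    subpopulation frequencies below realize those subclonal frequencies
    on the lineage A -> {D -> B -> C, E -> F}, with 5% normal cells.
    """
    nodes = (
        CloneNode("A", None, 0.15),
        CloneNode("D", "A", 0.20),
        CloneNode("B", "D", 0.20),
        CloneNode("C", "B", 0.10),
        CloneNode("E", "A", 0.20),
        CloneNode("F", "E", 0.10),
    )
    scnas = (
        ScnaSpec("chr21", 17478172, 500000, 0, "", "A"),
        ScnaSpec("chr21", 27485802, 500000, 3, "PPM", "B"),
        ScnaSpec("chr21", 30959067, 500000, 4, "PPPM", "C"),
        ScnaSpec("chr21", 35841868, 500000, 5, "PMMMM", "D"),
        ScnaSpec("chr21", 43277023, 500000, 1, "M", "E"),
        ScnaSpec("chr21", 25056314, 500000, 7, "MPPPPPP", "F"),
    )
    # copy-neutral segments on chr21 upstream of the first SCNA, spaced
    # 10 kb apart so that no merging rule can bridge them
    normals = tuple(
        ("chr21", 1_000_000 + i * 510_000, 500_000) for i in range(n_normal)
    )
    return SimConfig(
        clone_nodes=nodes,
        scnas=scnas,
        normal_segments=normals,
        coverage=coverage,
        snp_rate=snp_rate,
        snp_depth=snp_depth,
        gc_bias=gc_bias,
        false_breakpoint_rate=false_breakpoint_rate,
        seed=seed,
    )


SCNA_NAMES = ("a", "b", "c", "d", "e", "f")


def scenario_truth_table(truth: SimTruth) -> dict[str, SegmentTruth]:
    """Map the scenario's SCNA letters a-f to their ground truth."""
    return {
        name: truth.segments[truth.scna_segment_ids[f"scna{i}"]]
        for i, name in enumerate(SCNA_NAMES)
    }


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
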
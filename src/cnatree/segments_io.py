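"""Domain types and file formats for segment-level copy-number data.

A *segment* is a genomic interval produced upstream by a read-depth
segmenter (e.g. BIC-seq), carrying the tumor and matched-normal read
counts mapped into it and the heterozygous germline SNP loci it contains.
Coordinate conventions: segments are 0-based half-open ``[start, end)``
(BED-like); SNP positions are 1-based (VCF-like); a SNP at position
``pos`` belongs to a segment iff ``start < pos <= end``.

Strand is ignored throughout — copy number is strand-symmetric — and no
phasing is attempted: the model only ever consumes the folded B-allele
frequency ``min(baf, 1 - baf)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["chrom", "start", "end", "tumor_reads", "normal_reads", "gc"]
SNP_TSV_COLUMNS = ["chrom", "pos", "b_count", "depth"]


class ParseError(ValueError):
    """Malformed input file (bad column, bad value, bad row)."""


class StructuralError(ValueError):
    """Inconsistent genomic structure, e.g. overlapping segments."""


@dataclass
class SNPLocus:
    """One germline-heterozygous SNP with tumor allele counts.

    ``b_count`` is the number of tumor reads carrying the B allele
    (= the VCF alternate allele) and ``depth`` the total tumor reads at
    the locus.
    """

    chrom: str
    pos: int  # 1-based
    b_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ParseError(f"SNP {self.chrom}:{self.pos}: depth must be >= 1")
        if not 0 <= self.b_count <= self.depth:
            raise ParseError(
                f"SNP {self.chrom}:{self.pos}: b_count {self.b_count} "
                f"outside [0, depth={self.depth}]"
            )

    @property
    def baf(self) -> float:
        """B-allele frequency, in [0, 1]."""
        return self.b_count / self.depth

    @property
    def baf_hat(self) -> float:
        """Folded B-allele frequency min(baf, 1 - baf), in [0, 0.5]."""
        return min(self.baf, 1.0 - self.baf)


@dataclass
class Segment:
    """One genomic interval with read counts and its SNP loci."""

    id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    tumor_reads: int
    normal_reads: int
    gc: float
    corrected_ratio: float | None = None
    snps: list[SNPLocus] = field(default_factory=list)
    baf_cluster: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"segment {self.id} ({self.chrom}): start {self.start} >= end {self.end}"
            )
        if self.normal_reads < 1:
            raise ParseError(f"segment {self.id}: normal_reads must be >= 1")
        if self.tumor_reads < 0:
            raise ParseError(f"segment {self.id}: tumor_reads must be >= 0")
        if not 0.0 <= self.gc <= 1.0:
            raise ParseError(f"segment {self.id}: gc {self.gc} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def raw_ratio(self) -> float:
        """Uncorrected tumor/normal read-count ratio."""
        return self.tumor_reads / self.normal_reads

    @property
    def ratio(self) -> float:
        """Corrected ratio; raises if bias correction has not run."""
        if self.corrected_ratio is None:
            raise ValueError(f"segment {self.id}: corrected_ratio not set")
        return self.corrected_ratio

    def folded_bafs(self) -> np.ndarray:
        return np.array([s.baf_hat for s in self.snps], dtype=float)

    def contains(self, pos: int) -> bool:
        """1-based SNP position containment: start < pos <= end."""
        return self.start < pos <= self.end


@dataclass
class SegmentSet:
    """An ordered collection of segments plus baseline annotations.

    ``baseline_ids`` (copy-neutral segments) and ``theta`` (geometric mean
    of their corrected ratios) stay unset until baseline detection runs.
    """

    segments: list[Segment]
    baseline_ids: set[str] | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(ids) != len(set(ids)):
            raise StructuralError("segment ids are not unique")
        if self.baseline_ids is not None:
            unknown = set(self.baseline_ids) - set(ids)
            if unknown:
                raise StructuralError(f"baseline ids not in set: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def by_id(self, seg_id: str) -> Segment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    def non_baseline(self) -> list[Segment]:
        if self.baseline_ids is None:
            return list(self.segments)
        return [s for s in self.segments if s.id not in self.baseline_ids]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_segment_table(path: str | Path) -> SegmentSet:
    """Read a tab-separated segment table into a :class:`SegmentSet`.

    Required header columns: chrom, start, end, tumor_reads, normal_reads,
    gc. Coordinates are taken as 0-based half-open. SNP lists start empty;
    use :func:`attach_snps` afterwards.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file without header") from exc
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            seg = Segment(
                id=f"seg{i:05d}",
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                tumor_reads=int(row.tumor_reads),
                normal_reads=int(row.normal_reads),
                gc=float(row.gc),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
        segments.append(seg)
    return SegmentSet(segments=segments)


def write_segment_table(segset: SegmentSet, path: str | Path) -> None:
    """Inverse of :func:`read_segment_table` on the columns it serializes."""
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "tumor_reads": s.tumor_reads,
                "normal_reads": s.normal_reads,
                "gc": s.gc,
            }
            for s in segset
        ],
        columns=SEGMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def _read_snp_tsv(path: str | Path) -> list[SNPLocus]:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file without header") from exc
    missing = [c for c in SNP_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    loci = []
    for i, row in enumerate(df.itertuples(index=False)):
        depth = int(row.depth)
        if depth == 0:
            continue  # zero-depth loci carry no signal
        try:
            loci.append(
                SNPLocus(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    b_count=int(row.b_count),
                    depth=depth,
                )
            )
        except (TypeError, ValueError, ParseError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return loci


def _read_snp_vcf(path: str | Path, sample: str | None = None) -> list[SNPLocus]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if not samples:
        raise ParseError(f"{path}: VCF carries no samples")
    if sample is None:
        idx = 0
    else:
        if sample not in samples:
            raise ParseError(f"{path}: sample {sample!r} not in {samples}")
        idx = samples.index(sample)
    loci = []
    for variant in vcf:
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ParseError(
                f"{path}: {variant.CHROM}:{variant.POS}: FORMAT/AD absent"
            )
        row = np.asarray(ad[idx], dtype=float)
        row = row[row >= 0]  # cyvcf2 encodes missing as negative
        depth = int(row.sum())
        if depth == 0:
            continue
        b_count = int(row[1]) if len(row) > 1 else 0
        loci.append(
            SNPLocus(
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                b_count=b_count,
                depth=depth,
            )
        )
    return loci


def read_snp_counts(
    path: str | Path, format: str = "tsv", sample: str | None = None
) -> list[SNPLocus]:
    """Read tumor allele counts at heterozygous loci.

    ``format="vcf"`` expects a VCF 4.x with per-sample FORMAT/AD;
    ``b_count`` is the alternate-allele depth and ``depth`` the sum of
    allele depths. ``format="tsv"`` expects columns chrom, pos, b_count,
    depth. Zero-depth loci are dropped in both dialects.
    """
    if format == "tsv":
        return _read_snp_tsv(path)
    if format == "vcf":
        return _read_snp_vcf(path, sample=sample)
    raise ValueError(f"unknown SNP format {format!r}")


def write_snp_tsv(loci: list[SNPLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos, "b_count": s.b_count, "depth": s.depth}
            for s in loci
        ],
        columns=SNP_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP attachment
# ---------------------------------------------------------------------------

def attach_snps(segset: SegmentSet, loci: list[SNPLocus]) -> SegmentSet:
    """Assign each SNP locus to the unique segment containing it.

    Containment is ``start < pos <= end`` (1-based SNP vs 0-based
    half-open segment). Loci falling outside every segment are counted and
    logged, then dropped — the model has no use for orphan loci. Raises
    :class:`StructuralError` if segments on one chromosome overlap.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segset:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise StructuralError(
                    f"overlapping segments on {chrom}: {a.id} and {b.id}"
                )
    unassigned = 0
    for seg in segset:
        seg.snps = []
    for locus in loci:
        segs = by_chrom.get(locus.chrom, [])
        # binary search over sorted starts
        starts = [s.start for s in segs]
        i = int(np.searchsorted(starts, locus.pos - 1, side="right")) - 1
        if 0 <= i < len(segs) and segs[i].contains(locus.pos):
            segs[i].snps.append(locus)
        else:
            unassigned += 1
    if unassigned:
        logger.info("attach_snps: %d loci fell outside all segments", unassigned)
    for seg in segset:
        seg.snps.sort(key=lambda s: s.pos)
    return segset


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_results(
    segset: SegmentSet,
    assignments: dict[str, tuple[int, float, str]],
    tree: dict | None,
    prefix: str | Path,
    edge_probs: dict[tuple[str, str], float] | None = None,
) -> dict[str, Path]:
    """Write inference results next to ``prefix``.

    ``assignments`` maps segment id to (MAP copy number, MAP subclonal
    frequency, node label). Three files are produced: a per-segment TSV,
    the clone tree as nested JSON with node frequencies, and an
    edge-probability TSV.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    seg_path = prefix.with_name(prefix.name + ".segments.tsv")
    rows = []
    for seg in segset:
        c_map, phi_map, node = assignments.get(seg.id, (None, None, None))
        rows.append(
            {
                "segment_id": seg.id,
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "C_map": c_map,
                "phi_map": phi_map,
                "node": node,
            }
        )
    pd.DataFrame(
        rows,
        columns=["segment_id", "chrom", "start", "end", "C_map", "phi_map", "node"],
    ).to_csv(seg_path, sep="\t", index=False)

    out = {"segments": seg_path}
    if tree is not None:
        tree_path = prefix.with_name(prefix.name + ".tree.json")
        tree_path.write_text(json.dumps(tree, indent=2, sort_keys=True) + "\n")
        out["tree"] = tree_path

    edge_path = prefix.with_name(prefix.name + ".edges.tsv")
    edge_rows = [
        {"node_a": a, "node_b": b, "probability": p}
        for (a, b), p in sorted((edge_probs or {}).items())
    ]
    pd.DataFrame(edge_rows, columns=["node_a", "node_b", "probability"]).to_csv(
        edge_path, sep="\t", index=False
    )
    out["edges"] = edge_path
    return out


def read_tree_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
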
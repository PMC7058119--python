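"""GC-bias correction of the tumor/normal read-count ratio.

The tumor-to-normal read-count ratio of a segment shows a log-linear
dependence on its GC fraction. We fit a single line to
log(tumor/normal) against GC over all segments (with one pass of 3-MAD
residual trimming to keep copy-altered segments from tilting the fit),
and correct each segment's ratio back to a common reference GC. The
forward map and its inverse are exact algebraic inverses, which the
read-count likelihood relies on: the expected tumor count re-applies the
bias to the model ratio before comparing with the observed count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .segments_io import SegmentSet


@dataclass(frozen=True)
class BiasModel:
    """Log-linear GC bias: log(ratio) shifts by slope * (gc - reference_gc).

    ``intercept`` is the fitted line's offset at gc = 0 and is kept for
    diagnostics only; the correction itself is anchored at
    ``reference_gc`` so that a segment at the reference GC is untouched.
    """

    slope: float
    intercept: float
    reference_gc: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BiasModel":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            reference_gc=float(d["reference_gc"]),
        )


IDENTITY = BiasModel(slope=0.0, intercept=0.0, reference_gc=0.5)


def _check(ratio: float, gc: float) -> None:
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc {gc} outside [0, 1]")


def fit_bias(segset: SegmentSet) -> BiasModel:
    """Least-squares fit of log(tumor/normal) against GC fraction.

    One round of 3-MAD trimming of residuals guards against copy-altered
    outlier segments. Degenerate input (a single distinct GC value)
    yields a zero-slope model with a warning.
    """
    segs = list(segset)
    if len(segs) < 2:
        raise ValueError("need at least 2 segments to fit a bias model")
    gc = np.array([s.gc for s in segs])
    y = np.log([s.raw_ratio if s.tumor_reads > 0 else 0.5 / s.normal_reads for s in segs])
    lengths = np.array([s.length for s in segs], dtype=float)
    ref_gc = float(np.average(gc, weights=lengths))
    if np.ptp(gc) < 1e-12:
        warnings.warn("all GC values identical; returning zero-slope bias model")
        return BiasModel(slope=0.0, intercept=float(np.mean(y)), reference_gc=ref_gc)
    slope, intercept = np.polyfit(gc, y, 1)
    resid = y - (slope * gc + intercept)
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= 3.0 * 1.4826 * mad
        if keep.sum() >= 2 and np.ptp(gc[keep]) > 1e-12:
            slope, intercept = np.polyfit(gc[keep], y[keep], 1)
    return BiasModel(slope=float(slope), intercept=float(intercept), reference_gc=ref_gc)


def correct(model: BiasModel, raw_ratio: float, gc: float) -> float:
    """Remove the GC effect: exp(log r - slope * (gc - reference_gc))."""
    _check(raw_ratio, gc)
    return float(np.exp(np.log(raw_ratio) - model.slope * (gc - model.reference_gc)))


def invert(model: BiasModel, corrected_ratio: float, gc: float) -> float:
    """Re-apply the GC effect; exact inverse of :func:`correct`."""
    _check(corrected_ratio, gc)
    return float(
        np.exp(np.log(corrected_ratio) + model.slope * (gc - model.reference_gc))
    )


def apply_correction(segset: SegmentSet, model: BiasModel) -> SegmentSet:
    """Set ``corrected_ratio`` on every segment in place."""
    for seg in segset:
        raw = seg.raw_ratio if seg.tumor_reads > 0 else 0.5 / seg.normal_reads
        seg.corrected_ratio = correct(model, raw, seg.gc)
    return segset
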
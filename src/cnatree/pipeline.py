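"""End-to-end pipeline: bias correction -> breakpoint filter ->
baseline/theta -> subclonal inference -> result files.

The segment table entering the pipeline is the output of an upstream
read-depth segmenter; SNP allele counts come from a VCF (FORMAT/AD) or
TSV. Every stage logs input/output cardinalities, and a run writes an
effective-configuration snapshot next to its results so stochastic runs
can be reproduced exactly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import baseline_detection, bias_correction, breakpoint_filter, tssb_inference
from .breakpoint_filter import FilterConfig
from .clonal_model import LikelihoodContext
from .segments_io import (
    SegmentSet,
    attach_snps,
    read_segment_table,
    read_snp_counts,
    write_results,
)
from .tssb_inference import ChainState, McmcConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    segments_path: str = ""
    snps_path: str = ""
    snp_format: str = "tsv"  # "tsv" | "vcf"
    output_prefix: str = "cnatree_out"
    filter: FilterConfig = field(default_factory=FilterConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    bias_correction: bool = True
    run_breakpoint_filter: bool = True
    coverage: float = 30.0  # expected per-locus tumor depth at copy-neutral state
    baf_tol: float = 0.03
    depth_tol: float = 0.05
    c_max: int = 15
    flat_grid_step: float = 0.01
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        mcmc = McmcConfig(**raw.pop("mcmc", {}))
        return cls(filter=filt, mcmc=mcmc, **raw)


@dataclass
class PipelineResult:
    segset: SegmentSet
    bias_model: bias_correction.BiasModel
    provenance: dict[str, str]
    baseline_ids: set[str]
    theta: float
    chain: list[ChainState] | None
    flat: list[tssb_inference.FlatResult] | None
    assignments: dict[str, tuple[int, float, str]]  # seg id -> (C_map, phi_map, node)
    files: dict[str, Path] | None = None

    def map_state(self) -> ChainState:
        if self.chain is None:
            raise ValueError("tree-mode chain not available in flat mode")
        return tssb_inference.map_state(self.chain)


def run_stages(
    segset: SegmentSet,
    config: PipelineConfig,
    write: bool = False,
) -> PipelineResult:
    """Run the analysis stages on an in-memory :class:`SegmentSet` whose
    SNPs are already attached."""
    n_in = len(segset)

    if config.bias_correction:
        model = bias_correction.fit_bias(segset)
    else:
        model = bias_correction.IDENTITY
    bias_correction.apply_correction(segset, model)
    logger.info("bias_correction: slope=%.4f on %d segments", model.slope, n_in)

    if config.run_breakpoint_filter:
        if all(not s.snps for s in segset):
            raise ValueError(
                "breakpoint filter requires SNP loci for the decomposition "
                "stage; provide SNP counts or disable the filter"
            )
        segset, provenance = breakpoint_filter.run_filter(segset, config.filter, model)
    else:
        provenance = {s.id: s.id for s in segset}
    logger.info("breakpoint_filter: %d -> %d segments", n_in, len(segset))

    baseline_ids = baseline_detection.detect_baseline(
        segset, coverage=config.coverage,
        baf_tol=config.baf_tol, depth_tol=config.depth_tol,
    )
    segset.baseline_ids = baseline_ids
    theta = baseline_detection.compute_theta(segset, baseline_ids)
    segset.theta = theta
    logger.info("baseline: %d segments, theta=%.4f", len(baseline_ids), theta)

    ctx = LikelihoodContext(theta=theta, c_max=config.c_max, bias=model)
    infer_set = segset.non_baseline()
    logger.info("inference set: %d non-baseline segments", len(infer_set))

    chain = None
    flat = None
    assignments: dict[str, tuple[int, float, str]] = {}
    if config.mcmc.mode == "tree":
        chain = tssb_inference.run_mcmc(infer_set, ctx, config.mcmc)
        best = tssb_inference.map_state(chain)
        for sid, (c_map, _g, phi) in best.seg_maps.items():
            node = "/".join(map(str, best.assignments[sid])) or "root"
            assignments[sid] = (c_map, phi, node)
    else:
        flat = tssb_inference.flat_infer(infer_set, ctx, config.flat_grid_step)
        for res in flat:
            assignments[res.segment_id] = (res.c_map, res.phi_map, "flat")

    result = PipelineResult(
        segset=segset, bias_model=model, provenance=provenance,
        baseline_ids=baseline_ids, theta=theta, chain=chain, flat=flat,
        assignments=assignments,
    )
    if write:
        result.files = _write_outputs(result, config)
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-to-file pipeline entry point."""
    logging.basicConfig(level=config.log_level)
    segset = read_segment_table(config.segments_path)
    logger.info("read %d segments from %s", len(segset), config.segments_path)
    if config.snps_path:
        loci = read_snp_counts(config.snps_path, format=config.snp_format)
        attach_snps(segset, loci)
        logger.info("attached SNPs from %s", config.snps_path)
    return run_stages(segset, config, write=True)


def _tree_as_mapping(state: ChainState) -> dict:
    def node_key(nid: tuple[int, ...]) -> str:
        return "/".join(map(str, nid)) or "root"

    def build(nid: tuple[int, ...]) -> dict:
        info = state.nodes[nid]
        children = sorted(
            i for i in state.nodes if len(i) == len(nid) + 1 and i[: len(nid)] == nid
        )
        return {
            "id": node_key(nid),
            "weight": info["weight"],
            "phi": info["phi"],
            "segments": info["segments"],
            "children": [build(c) for c in children],
        }

    return build(())


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> dict[str, Path]:
    tree = _tree_as_mapping(result.map_state()) if result.chain else None
    edge_probs = (
        tssb_inference.edge_probabilities(result.chain) if result.chain else None
    )
    files = write_results(
        result.segset, result.assignments, tree, config.output_prefix,
        edge_probs=edge_probs,
    )
    prefix = Path(config.output_prefix)
    cfg_path = prefix.with_name(prefix.name + ".config.yaml")
    cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    files["config"] = cfg_path
    bias_path = prefix.with_name(prefix.name + ".bias.yaml")
    bias_path.write_text(yaml.safe_dump(result.bias_model.to_dict(), sort_keys=True))
    files["bias"] = bias_path
    return files
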
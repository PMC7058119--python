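# cnatree

Reconstruction of tumor subclonal populations from somatic copy-number
alterations (SCNAs) in paired tumor/normal sequencing data.

Bulk tumor samples are mixtures: a normal-cell fraction plus one or more
tumor subclones related by an evolutionary tree. An SCNA carried by a
subclone at *subclonal frequency* φ with *absolute copy number* Cᵀ
shifts two observables of the genomic segment it covers — the
tumor/normal read-count ratio, proportional to the population-average
copy number

&nbsp;&nbsp;&nbsp;&nbsp;C̄ = φ·Cᵀ + (1−φ)·2,

and the B-allele frequency (BAF) of heterozygous germline SNPs inside
the segment,

&nbsp;&nbsp;&nbsp;&nbsp;μ̄ = (φ·Cᵀ·μᵀ + (1−φ)) / C̄,&nbsp;&nbsp;&nbsp;&nbsp;μᵀ = n_M / Cᵀ,

where (n_P, n_M) is the allele genotype of the SCNA. Inferring (φ, Cᵀ)
jointly from (C̄, μ̄) is the core problem; it is only partially
identifiable — distinct (Cᵀ, μᵀ) pairs sharing the invariant
ξ = (Cᵀ·μ̂ᵀ − 1)/(Cᵀ − 2) explain the same observation exactly, each
with its own φ. The package quantifies this solution space (43 ξ-curves
at C_max = 15, 7 of them multi-solution), exploits it to remove false
segment breakpoints, and performs Bayesian inference of per-segment
(φ, Cᵀ) under a tree-structured stick-breaking (TSSB) Dirichlet-process
prior over clone trees, via MCMC.

The pipeline stages:

1. **GC-bias correction** — log-linear fit of log(tumor/normal) against
   GC fraction; exact invertible correction Φ/Φ⁻¹.
2. **False-breakpoint filtering** — fragments of one true copy-number
   region share ratio and BAF profiles, so they are re-joined by Ward
   clustering on log ratio, mean-shift on folded BAF, and adjacency
   merging.
3. **Baseline detection** — copy-neutral segments found by a
   finite-depth BAF-balance test plus a depth criterion; their
   corrected ratios' geometric mean ϑ anchors the ratio scale.
4. **Inference** — per segment, a Poisson likelihood for the tumor read
   count with mean Φ⁻¹(C̄/2·ϑ)·Dᴺ and a folded-binomial likelihood for
   SNP B-counts; φ structured by the TSSB clone-tree prior (or profiled
   on a grid in the tree-free "flat" mode for data violating the
   infinite-sites assumption).

Inputs are plain files: a BED-like segment TSV as produced downstream of
a read-depth segmenter (e.g. BIC-seq), and SNP allele counts as a VCF
with FORMAT/AD or a 4-column TSV. A count-level simulator with known
clone trees makes every stage testable without external data.

## Worked example

Simulate the package's six-SCNA chromosome-21 benchmark (six nested
subclones, frequencies 0.95/0.50/0.30/0.30/0.10/0.10, plus 20
copy-neutral segments) and run the full pipeline:

```python
from cnatree import (
    six_scna_scenario, simulate, scenario_truth_table,
    PipelineConfig, McmcConfig, run_stages,
)

segset, truth = simulate(six_scna_scenario(seed=1))
config = PipelineConfig(coverage=30.0, mcmc=McmcConfig(seed=1))
result = run_stages(segset, config)

print(f"theta = {result.theta:.4f} from {len(result.baseline_ids)} baseline segments")
table = scenario_truth_table(truth)
for i, name in enumerate("abcdef"):
    sid = truth.scna_segment_ids[f"scna{i}"]
    merged = result.provenance.get(sid, sid)
    c_map, phi, _ = result.assignments[merged]
    t = table[name]
    print(f"SCNA {name}: C_map={c_map:2d} phi_map={phi:.3f}   (truth C={t.copy_number}, phi={t.phi:.2f})")
```

prints

```
theta = 1.0021 from 20 baseline segments
SCNA a: C_map= 0 phi_map=0.945   (truth C=0, phi=0.95)
SCNA b: C_map=14 phi_map=0.025   (truth C=3, phi=0.30)
SCNA c: C_map=10 phi_map=0.025   (truth C=4, phi=0.10)
SCNA d: C_map= 8 phi_map=0.251   (truth C=5, phi=0.50)
SCNA e: C_map= 1 phi_map=0.251   (truth C=1, phi=0.30)
SCNA f: C_map= 4 phi_map=0.251   (truth C=7, phi=0.10)
```

ϑ ≈ 1 confirms the 20 copy-neutral segments anchor the ratio scale, and
the two SCNAs with a *unique* solution are recovered exactly: the
homozygous deletion a (Cᵀ = 0, φ = 0.95) and the hemizygous deletion e
(Cᵀ = 1). The four multi-copy SCNAs all lie on the ξ = 0 curve — each
carries exactly one minority allele — so several (Cᵀ, φ) pairs explain
their data *identically* (for d, (5, 0.50), (8, 0.25), (7, 0.30), … are
exact ties), and the reported maximum-a-posteriori state picks
degenerate merged modes: e.g. d is reported at (8, 0.251) sharing a
clone with e, an exact alternative solution of its observation. This is
the solution-space ambiguity the ξ-curve analysis predicts, not noise;
see `docs/methods.md` for the full account.

The solution-space census from the command line:

```
$ cnatree solspace --cmax 15 --out curves.tsv
43 curves, 7 with multiple phi solutions
```

Other subcommands: `simulate`, `filter`, `baseline`, `infer`, `run`
(see `cnatree --help`).

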
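"""Per-segment likelihood of subclonal frequency and copy number.

For a segment assigned subclonal frequency phi, absolute copy number C
and allele genotype g (a multiset of P/M copies), the population-average
copy number and folded B-allele frequency are

    cbar        = phi * C + (1 - phi) * 2
    mu_bar      = (phi * C * mu(g) + (1 - phi)) / cbar,   mu(g) = n_M / C
    mu_bar_hat  = min(mu_bar, 1 - mu_bar)

Because the B allele sits on either haplotype with equal probability,
the observed folded B-count of each SNP follows the *folded* binomial:
P(min(b, d-b) = x) = Bin(x; d, p) + Bin(d-x; d, p) for x < d/2 (and the
single middle term at x = d/2), with p = mu_bar_hat. Using a plain
binomial on the folded count instead would systematically favour
solutions with smaller folded BAF, because the folded count's mean lies
below p (about 0.43 at p = 1/2 and 30x depth). The tumor read count is
Poisson with mean equal to the
GC-bias-reapplied model ratio times the observed normal count,
(cbar/2) * theta pushed through the inverse bias map. Copy-number
support is gated by the corrected ratio against the baseline anchor
theta: below theta only {0, 1, 2} are considered, at or above it
{2, ..., c_max} (the neutral C = 2 belongs to both branches, so the
equality convention introduces no bias).

The marginal segment likelihood at phi sums the joint read-count x BAF
likelihood over the supported copy numbers and, per copy number, over
the full genotype ladder with a uniform genotype prior 1/|zeta(C)|
given C (matching the categorical prior on C). An unweighted sum would
act as an improper prior proportional to the genotype count C + 1,
handing high copy numbers a log(C+1) bonus that measurably drags
near-diploid segments toward spurious tiny-frequency, large-C
solutions. Mirrored genotypes (n_P, n_M) and (n_M, n_P) give identical
folded likelihood; both are retained so the genotype ladder stays
literal. mu(g) is undefined for C = 0 (empty
genotype); the term it multiplies vanishes there, which the code encodes
explicitly.

All likelihoods are natural-log; mixtures use log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

from . import bias_correction
from .bias_correction import BiasModel
from .segments_io import Segment, SNPLocus


@dataclass(frozen=True)
class Genotype:
    """Allele multiset: n_p paternal and n_m maternal copies."""

    n_p: int
    n_m: int

    @property
    def total(self) -> int:
        return self.n_p + self.n_m

    @property
    def mu_tumor(self) -> float:
        """Tumor BAF n_m / C; 0 by convention for the empty genotype
        (the likelihood never uses it there)."""
        return self.n_m / self.total if self.total > 0 else 0.0

    def __str__(self) -> str:
        return "P" * self.n_p + "M" * self.n_m if self.total else "EMPTY"


@lru_cache(maxsize=None)
def genotype_set(c: int) -> tuple[Genotype, ...]:
    """All genotypes of copy number c, ordered by increasing n_m.
    c = 0 yields the single empty genotype."""
    if c < 0:
        raise ValueError("copy number must be >= 0")
    return tuple(Genotype(n_p=c - m, n_m=m) for m in range(c + 1))


def expected_avg_copy(phi: float, c: int) -> float:
    """cbar = phi*C + (1-phi)*2."""
    return phi * c + (1.0 - phi) * 2.0


def expected_folded_baf(phi: float, c: int, g: Genotype) -> float:
    """Folded population-average BAF; exactly 0.5 for C = 0 (the tumor
    contributes no copies) and, degenerately, for cbar = 0 (phi = 1 at
    C = 0: no DNA at all)."""
    cbar = expected_avg_copy(phi, c)
    if cbar == 0.0:
        return 0.5
    mu_term = phi * c * g.mu_tumor if c > 0 else 0.0
    m = (mu_term + (1.0 - phi)) / cbar
    return min(m, 1.0 - m)


def _binom_logpmf(k: np.ndarray | int, n: np.ndarray | int, p: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(k > 0, k * np.log(p), 0.0) + np.where(
            n - k > 0, (n - k) * np.log1p(-p), 0.0
        )
    return const + term


def _poisson_logpmf(k: float, lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    return k * np.log(lam) - lam - gammaln(k + 1)


def folded_binom_logpmf(b_hat: int, depth: int, p: float | np.ndarray) -> np.ndarray:
    """Log pmf of the folded count min(b, d-b) when b ~ Binomial(d, p)
    with the B allele on a random haplotype: Bin(b_hat) + Bin(d - b_hat),
    collapsing to the single middle term when b_hat = d - b_hat."""
    p = np.asarray(p, dtype=float)
    lo = _binom_logpmf(b_hat, depth, p)
    if 2 * b_hat == depth:
        return lo
    hi = _binom_logpmf(depth - b_hat, depth, p)
    return np.logaddexp(lo, hi)


def snp_loglik(locus: SNPLocus, phi: float, c: int, g: Genotype) -> float:
    """Log folded-binomial pmf of the folded B-count min(b, d-b) under
    the expected folded BAF."""
    p = expected_folded_baf(phi, c, g)
    b_hat = min(locus.b_count, locus.depth - locus.b_count)
    return float(folded_binom_logpmf(b_hat, locus.depth, np.array(p)))


@dataclass
class LikelihoodContext:
    """Shared inference context: baseline anchor theta, copy-number cap
    and the bias model (needed to re-apply GC bias to model ratios)."""

    theta: float
    c_max: int = 15
    bias: BiasModel = field(default_factory=lambda: bias_correction.IDENTITY)

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.c_max < 3:
            raise ValueError("c_max must be >= 3")

    def lattice(self, support: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (C, mu_T, log genotype prior) arrays over the
        genotype ladder of every supported copy number, ordered by
        (C asc, n_m asc); the prior is uniform within each C."""
        return _lattice(support)


@lru_cache(maxsize=None)
def _lattice(support: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cs, mus, logw = [], [], []
    for c in support:
        gs = genotype_set(c)
        for g in gs:
            cs.append(c)
            mus.append(g.mu_tumor if c > 0 else 0.0)
            logw.append(-np.log(len(gs)))
    return np.array(cs, dtype=float), np.array(mus, dtype=float), np.array(logw)


def cn_support(seg: Segment, ctx: LikelihoodContext) -> tuple[int, ...]:
    """{0,1,2} below theta, {2,...,c_max} at or above it."""
    if seg.ratio < ctx.theta:
        return (0, 1, 2)
    return tuple(range(2, ctx.c_max + 1))


def readcount_loglik(seg: Segment, phi: float, c: int, ctx: LikelihoodContext) -> float:
    """Log Poisson pmf of the tumor read count with mean
    invert(bias, (cbar/2)*theta, gc) * normal_reads."""
    cbar = expected_avg_copy(phi, c)
    model_ratio = max(cbar / 2.0 * ctx.theta, 1e-300)
    lam = bias_correction.invert(ctx.bias, model_ratio, seg.gc) * seg.normal_reads
    return float(_poisson_logpmf(seg.tumor_reads, np.array(lam)))


def _folded_pairs(seg: Segment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique (folded count, depth) pairs with multiplicities."""
    b = np.array([s.b_count for s in seg.snps], dtype=int)
    d = np.array([s.depth for s in seg.snps], dtype=int)
    b_hat = np.minimum(b, d - b)
    pairs, counts = np.unique(np.stack([b_hat, d]), axis=1, return_counts=True)
    return pairs[0], pairs[1], counts


def baf_loglik_of_p(seg: Segment, p: np.ndarray) -> np.ndarray:
    """Sum of folded-binomial log pmfs over the segment's SNPs, as a
    function of the common folded success probability p (exact)."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if not seg.snps:
        return np.zeros_like(p)
    b_hat, d, counts = _folded_pairs(seg)
    out = np.zeros_like(p)
    pc = np.clip(p, 1e-12, 0.5)
    for bh, dd, cnt in zip(b_hat, d, counts):
        out += cnt * folded_binom_logpmf(int(bh), int(dd), pc)
    return out


_P_GRID = np.linspace(0.0, 0.5, 4001)


def _baf_interp(seg: Segment) -> np.ndarray:
    """Cached table of baf_loglik_of_p on a fine p grid; queried by
    linear interpolation in the sampler's hot path (absolute error
    below ~1e-6 at WGS-scale depths). Keyed by SNP count so the cache
    invalidates when a merge replaces the SNP list."""
    cached = getattr(seg, "_baf_table", None)
    if cached is not None and cached[0] == len(seg.snps):
        return cached[1]
    table = baf_loglik_of_p(seg, _P_GRID)
    seg._baf_table = (len(seg.snps), table)
    return table


def _folded_p_matrix(
    phis: np.ndarray, cs: np.ndarray, mus: np.ndarray
) -> np.ndarray:
    phi_col = phis[:, None]
    cbar = phi_col * cs[None, :] + (1.0 - phi_col) * 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_term = np.where(cs[None, :] > 0, phi_col * cs[None, :] * mus[None, :], 0.0)
        safe_cbar = np.where(cbar > 0, cbar, np.nan)
        m = (mu_term + (1.0 - phi_col)) / safe_cbar
        m = np.where(np.isnan(m), 0.5, m)
    return np.clip(np.minimum(m, 1.0 - m), 0.0, 0.5)


def _joint_loglik_matrix(
    seg: Segment, phis: np.ndarray, ctx: LikelihoodContext, exact: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint read-count + BAF log likelihood on the (phi x lattice) grid.

    Returns (loglik matrix of shape (n_phi, n_lattice), lattice copy
    numbers, lattice genotype BAFs). With ``exact`` the BAF term is
    evaluated per (folded count, depth) pair; otherwise it comes from
    the segment's cached fine-grid table by linear interpolation.
    """
    support = cn_support(seg, ctx)
    cs, mus, logw = ctx.lattice(support)
    phis = np.atleast_1d(np.asarray(phis, dtype=float))
    phi_col = phis[:, None]
    cbar = phi_col * cs[None, :] + (1.0 - phi_col) * 2.0
    # read-count term
    model_ratio = np.maximum(cbar / 2.0 * ctx.theta, 1e-300)
    gc_factor = np.exp(ctx.bias.slope * (seg.gc - ctx.bias.reference_gc))
    lam = model_ratio * gc_factor * seg.normal_reads
    rc = _poisson_logpmf(seg.tumor_reads, lam)
    if not seg.snps:
        return rc + logw[None, :], cs, mus
    p = _folded_p_matrix(phis, cs, mus)
    if exact:
        baf = baf_loglik_of_p(seg, p.ravel()).reshape(p.shape)
    else:
        baf = np.interp(p.ravel(), _P_GRID, _baf_interp(seg)).reshape(p.shape)
    return rc + baf + logw[None, :], cs, mus


def segment_loglik(seg: Segment, phi: float, ctx: LikelihoodContext) -> float:
    """Marginal log likelihood at phi: log-sum-exp of the joint
    likelihood over supported copy numbers and genotypes."""
    mat, _, _ = _joint_loglik_matrix(seg, np.array([phi]), ctx, exact=True)
    return float(logsumexp(mat[0]))


def segment_loglik_phi_grid(
    seg: Segment, phis: np.ndarray, ctx: LikelihoodContext
) -> np.ndarray:
    """Vectorized :func:`segment_loglik` over an array of phi values."""
    mat, _, _ = _joint_loglik_matrix(seg, phis, ctx)
    return logsumexp(mat, axis=1)


def map_copy_number(
    seg: Segment, phi: float, ctx: LikelihoodContext
) -> tuple[int, Genotype]:
    """The (C, genotype) maximizing the joint likelihood at phi.

    The lattice is ordered by (C ascending, n_m ascending) and argmax
    takes the first maximum, so ties break toward smaller C then fewer
    M copies.
    """
    mat, cs, mus = _joint_loglik_matrix(seg, np.array([phi]), ctx, exact=True)
    idx = int(np.argmax(mat[0]))
    c = int(cs[idx])
    n_m = int(round(mus[idx] * c)) if c > 0 else 0
    return c, Genotype(n_p=c - n_m, n_m=n_m)
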
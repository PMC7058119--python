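"""Tree-structured stick-breaking inference of the clone tree.

The prior over clone trees is a tree-structured stick-breaking (TSSB)
Dirichlet process: every node of an infinitely deep, infinitely wide
tree receives a stick mass built from Beta(1, alpha * decay^depth)
"stop" sticks (nu) and Beta(1, gamma) "branch" sticks (psi), and each
segment is thrown onto a node with probability equal to its stick mass.
Separately, each instantiated node carries a subpopulation frequency
(weight); the weights plus the mass still unallocated (the normal-cell
remainder) lie on the simplex under a flat Dirichlet prior. A segment
assigned to node v has subclonal frequency phi(v) = weight of v plus all
its descendants, so phi decreases monotonically down every branch.

The sampler alternates three moves per sweep:

* conjugate resampling of the nu / psi sticks from assignment counts;
* Gibbs reassignment of each segment over instantiated nodes plus one
  auxiliary fresh child per node (sticks drawn from the prior, weight
  split off the unallocated mass) — the auxiliary-variable device of
  Neal's algorithm 8, which is how new nodes are born;
* grid-Gibbs weight moves: mass exchange between a node and the
  unallocated remainder (and between random node pairs), sampling the
  transferred mass from its discretized conditional on a coarse-to-fine
  grid. Random-walk Metropolis is hopeless here: with read counts of
  order 10^4 the per-segment likelihood peaks have width ~0.005 in phi.

Each recorded state stores, per segment, the copy number and genotype
maximizing the joint likelihood at the segment's current phi. The
reported tree is the recorded state with the highest data
log-likelihood given its frequencies and tree. Edge probabilities
are fractions of recorded trees containing a directed parent-child
relation between occupied nodes, with node identity matched across
states by maximal Jaccard overlap of assigned-segment sets.

For data violating the infinite-sites assumption (each clone carrying
many SCNAs), the flat mode drops the tree prior entirely and profiles
each segment's likelihood on a phi grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .clonal_model import (
    Genotype,
    LikelihoodContext,
    map_copy_number,
    segment_loglik_phi_grid,
)
from .segments_io import Segment

logger = logging.getLogger(__name__)

ROOT: tuple[int, ...] = ()


@dataclass
class TssbNode:
    """One instantiated tree node.

    ``id`` is the path from the root (sequence of child indices), ``nu``
    the stop-stick, ``psi`` the branch sticks of its instantiated
    children, ``weight`` the subpopulation frequency of exactly this
    clone, ``segment_ids`` the data assigned here.
    """

    id: tuple[int, ...]
    nu: float
    psi: list[float] = field(default_factory=list)
    weight: float = 0.0
    segment_ids: set[str] = field(default_factory=set)

    @property
    def depth(self) -> int:
        return len(self.id)

    @property
    def parent_id(self) -> tuple[int, ...] | None:
        return self.id[:-1] if self.id else None


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: 50 burn-in sweeps then 300 recorded sweeps,
    scaling parameters alpha = gamma = 1 and a stick-depth decay of 0.5
    by default."""

    burnin: int = 50
    samples: int = 300
    alpha: float = 1.0
    gamma: float = 1.0
    seed: int = 0
    mode: str = "tree"  # "tree" | "flat"
    lambda_decay: float = 0.5
    pair_moves: int = 3
    grid_points: int = 101

    def __post_init__(self) -> None:
        if self.burnin < 0 or self.samples < 1:
            raise ValueError("burnin must be >= 0 and samples >= 1")
        if self.mode not in ("tree", "flat"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ChainState:
    """Snapshot of one recorded sweep."""

    iteration: int
    nodes: dict[tuple[int, ...], dict]  # id -> {weight, phi, parent, segments}
    assignments: dict[str, tuple[int, ...]]  # segment id -> node id
    seg_maps: dict[str, tuple[int, str, float]]  # seg id -> (C_map, genotype, phi)
    log_likelihood: float
    log_posterior: float
    residual: float


# ---------------------------------------------------------------------------
# Live tree
# ---------------------------------------------------------------------------

class _Tree:
    def __init__(self, rng: np.random.Generator, config: McmcConfig) -> None:
        self.rng = rng
        self.config = config
        root = TssbNode(id=ROOT, nu=float(rng.beta(1.0, config.alpha)), weight=0.5)
        self.nodes: dict[tuple[int, ...], TssbNode] = {ROOT: root}
        self.residual = 0.5

    # -- structure ----------------------------------------------------------
    def sorted_ids(self) -> list[tuple[int, ...]]:
        return sorted(self.nodes)

    def children(self, nid: tuple[int, ...]) -> list[tuple[int, ...]]:
        return sorted(i for i in self.nodes if len(i) == len(nid) + 1 and i[: len(nid)] == nid)

    def subtree_ids(self, nid: tuple[int, ...]) -> list[tuple[int, ...]]:
        return [i for i in self.nodes if i[: len(nid)] == nid]

    def phi(self, nid: tuple[int, ...]) -> float:
        return sum(self.nodes[i].weight for i in self.subtree_ids(nid))

    def phis(self) -> dict[tuple[int, ...], float]:
        return {nid: self.phi(nid) for nid in self.nodes}

    def n_subtree(self, nid: tuple[int, ...]) -> int:
        return sum(len(self.nodes[i].segment_ids) for i in self.subtree_ids(nid))

    def alpha_at(self, depth: int) -> float:
        return self.config.alpha * self.config.lambda_decay**depth

    # -- stick masses -------------------------------------------------------
    def stick_masses(self) -> tuple[dict[tuple[int, ...], float], dict[tuple[int, ...], float]]:
        """Per-node stick probability pi and per-node unexpanded rest mass."""
        pi: dict[tuple[int, ...], float] = {}
        rest: dict[tuple[int, ...], float] = {}
        subtree_mass: dict[tuple[int, ...], float] = {ROOT: 1.0}
        for nid in self.sorted_ids():
            node = self.nodes[nid]
            mass = subtree_mass[nid]
            pi[nid] = mass * node.nu
            remain = mass * (1.0 - node.nu)
            for idx, child in enumerate(self.children(nid)):
                share = remain * node.psi[idx]
                subtree_mass[child] = share
                remain -= share
            rest[nid] = remain
        return pi, rest

    def predictive_masses(
        self,
        exclude: str | None = None,
        counts: dict[tuple[int, ...], int] | None = None,
    ) -> tuple[dict[tuple[int, ...], float], dict[tuple[int, ...], float]]:
        """Collapsed (stick-integrated) predictive assignment masses.

        Returns, per node, the probability that a new segment stops
        there and the probability that it starts a fresh child there,
        using Beta posterior-mean sticks given the occupancy counts
        (the live counts, optionally leaving one segment out, or an
        explicit ``counts`` map). Unlike plugging in sampled sticks, the
        collapsed predictive never lets fresh-node mass vanish, so
        densely occupied configurations are not absorbing.
        """
        stop_mass: dict[tuple[int, ...], float] = {}
        fresh_mass: dict[tuple[int, ...], float] = {}
        subtree_mass: dict[tuple[int, ...], float] = {ROOT: 1.0}

        def n_here(nid: tuple[int, ...]) -> int:
            if counts is not None:
                return counts.get(nid, 0)
            node = self.nodes[nid]
            n = len(node.segment_ids)
            if exclude is not None and exclude in node.segment_ids:
                n -= 1
            return n

        n_sub: dict[tuple[int, ...], int] = {}
        for nid in sorted(self.nodes, key=len, reverse=True):
            n_sub[nid] = n_here(nid) + sum(
                n_sub[ch] for ch in self.children(nid)
            )
        for nid in self.sorted_ids():
            mass = subtree_mass[nid]
            nu_bar = (1.0 + n_here(nid)) / (
                1.0 + self.alpha_at(len(nid)) + n_sub[nid]
            )
            stop_mass[nid] = mass * nu_bar
            remain = mass * (1.0 - nu_bar)
            gamma = self.config.gamma
            for child in self.children(nid):
                below = sum(
                    n_sub[sib]
                    for sib in self.children(nid)
                    if sib[-1] >= child[-1]
                )
                psi_bar = (1.0 + n_sub[child]) / (1.0 + gamma + below)
                share = remain * psi_bar
                subtree_mass[child] = share
                remain -= share
            fresh_mass[nid] = remain
        return stop_mass, fresh_mass

    def sequential_assignment_logprior(self, order: list[tuple[str, tuple[int, ...]]]) -> float:
        """Log probability of the assignment pattern under the collapsed
        process, built by inserting segments one at a time (fixed order)
        and multiplying each one's predictive probability given the
        segments already placed. A segment opening a node that is empty
        so far pays that node's fresh/descent mass; later arrivals pay
        the join mass. This prices node creation once, where a
        leave-one-out pseudo-marginal would hand every member full join
        credit and overstate clustering."""
        counts: dict[tuple[int, ...], int] = {}
        total = 0.0
        for _sid, nid in order:
            stop_mass, _ = self.predictive_masses(counts=counts)
            total += float(np.log(max(stop_mass.get(nid, 0.0), 1e-300)))
            counts[nid] = counts.get(nid, 0) + 1
        return total

    # -- conjugate stick updates -------------------------------------------
    def resample_sticks(self) -> None:
        for nid in self.sorted_ids():
            node = self.nodes[nid]
            n_here = len(node.segment_ids)
            n_below = self.n_subtree(nid) - n_here
            node.nu = float(self.rng.beta(1.0 + n_here, self.alpha_at(node.depth) + n_below))
            kids = self.children(nid)
            counts = [self.n_subtree(k) for k in kids]
            node.psi = []
            for i in range(len(kids)):
                after = sum(counts[i + 1:])
                node.psi.append(float(self.rng.beta(1.0 + counts[i], self.config.gamma + after)))

    def prune(self) -> None:
        """Drop leaf nodes carrying no data anywhere below; their weight
        returns to the unallocated remainder."""
        changed = True
        while changed:
            changed = False
            for nid in sorted(self.nodes, key=len, reverse=True):
                if nid == ROOT:
                    continue
                if self.n_subtree(nid) == 0 and not self.children(nid):
                    self.residual += self.nodes[nid].weight
                    parent = self.nodes[nid[:-1]]
                    siblings = self.children(nid[:-1])
                    k = siblings.index(nid)
                    del self.nodes[nid]  # before reindexing: a sibling takes this id
                    if k < len(parent.psi):
                        parent.psi.pop(k)
                    for sib in siblings[k + 1:]:
                        self._reindex(sib, nid[:-1] + (sib[-1] - 1,))
                    changed = True
                    break

    def _reindex(self, old: tuple[int, ...], new: tuple[int, ...]) -> None:
        for sub in sorted(self.subtree_ids(old), key=len, reverse=True):
            node = self.nodes.pop(sub)
            node.id = new + sub[len(old):]
            self.nodes[node.id] = node

    def add_child(self, parent: tuple[int, ...], nu: float, psi: float, weight: float) -> tuple[int, ...]:
        idx = len(self.children(parent))
        nid = parent + (idx,)
        self.nodes[nid] = TssbNode(id=nid, nu=nu, weight=weight)
        self.nodes[parent].psi.append(psi)
        self.residual -= weight
        return nid


# ---------------------------------------------------------------------------
# Sweep moves
# ---------------------------------------------------------------------------

def _gibbs_pick(rng: np.random.Generator, logp: np.ndarray) -> int:
    p = np.exp(logp - logsumexp(logp))
    p = p / p.sum()
    return int(rng.choice(len(p), p=p))


_BIRTH_GRID = 25


def sample_assignments(
    tree: _Tree,
    segments: list[Segment],
    ctx: LikelihoodContext,
    rng: np.random.Generator,
) -> None:
    """One sweep over segment-to-node assignments.

    For each segment the candidate set holds (a) every instantiated
    node at its current phi and (b) birth candidates: a fresh child of
    each node X, with the child's weight taken *from X's own weight* on
    a grid over [0, w_X] (plus a fresh root child funded from the
    unallocated remainder). Funding a child from its parent's weight
    leaves every subtree sum phi unchanged except the moving segment's
    own, so the candidate scores involve only this segment's likelihood.
    The assignment prior uses the collapsed (stick-integrated) TSSB
    predictive given the other segments' positions; fresh nodes get
    their sticks drawn from the prior when instantiated (the
    auxiliary-variable device of Neal's algorithm 8). Without the
    funded births a new clone frequency could never exceed the
    unallocated remainder and the sampler would freeze in its initial
    clustering.
    """
    for seg in segments:
        stop_mass, fresh_mass = tree.predictive_masses(exclude=seg.id)
        ids = tree.sorted_ids()
        phis = tree.phis()
        cand_phis: list[float] = [phis[nid] for nid in ids]
        cand_logpi: list[float] = [np.log(max(stop_mass[nid], 1e-300)) for nid in ids]
        # birth candidates: (parent, nu, psi, weight, funded_from_residual)
        fresh: list[tuple[tuple[int, ...], float, float, float, bool]] = []
        for nid in ids:
            nu_new = float(rng.beta(1.0, tree.alpha_at(len(nid) + 1)))
            psi_new = float(rng.beta(1.0, tree.config.gamma))
            logpi_f = np.log(max(fresh_mass[nid], 1e-300))
            w_parent = tree.nodes[nid].weight
            if w_parent > 1e-12:
                for frac in np.linspace(0.0, 1.0, _BIRTH_GRID + 1)[1:]:
                    fresh.append((nid, nu_new, psi_new, float(frac * w_parent), False))
                    cand_phis.append(float(frac * w_parent))
                    cand_logpi.append(logpi_f - np.log(2 * _BIRTH_GRID))
        if tree.residual > 1e-12:
            nu_new = float(rng.beta(1.0, tree.alpha_at(1)))
            psi_new = float(rng.beta(1.0, tree.config.gamma))
            logpi_f = np.log(max(fresh_mass[ROOT], 1e-300))
            for frac in np.linspace(0.0, 1.0, _BIRTH_GRID + 1)[1:]:
                fresh.append((ROOT, nu_new, psi_new, float(frac * tree.residual), True))
                cand_phis.append(float(frac * tree.residual))
                cand_logpi.append(logpi_f - np.log(2 * _BIRTH_GRID))
        loglik = segment_loglik_phi_grid(seg, np.array(cand_phis), ctx)
        choice = _gibbs_pick(rng, np.array(cand_logpi) + loglik)
        # move the segment
        for node in tree.nodes.values():
            node.segment_ids.discard(seg.id)
        if choice < len(ids):
            target = ids[choice]
        else:
            parent, nu_new, psi_new, w_new, from_residual = fresh[choice - len(ids)]
            if from_residual:
                target = tree.add_child(parent, nu_new, psi_new, w_new)
            else:
                tree.nodes[parent].weight -= w_new
                target = tree.add_child(parent, nu_new, psi_new, w_new)
                tree.residual += w_new  # add_child debits residual; undo for funded birth
        tree.nodes[target].segment_ids.add(seg.id)
        tree.prune()


def _grid_exchange(
    tree: _Tree,
    seg_by_id: dict[str, Segment],
    ctx: LikelihoodContext,
    rng: np.random.Generator,
    give: tuple[int, ...] | None,
    take: tuple[int, ...] | None,
    grid_points: int,
) -> None:
    """Sample the mass transferred between two weight holders (a node or
    the unallocated remainder) from its discretized conditional."""
    w_give = tree.residual if give is None else tree.nodes[give].weight
    w_take = tree.residual if take is None else tree.nodes[take].weight
    total = w_give + w_take
    if total <= 0:
        return
    # delta = new value of the *take* holder, on [0, total]
    coarse = np.linspace(0.0, total, grid_points)
    # phi shift per node: +1 if take in subtree, -1 if give in subtree
    shift: dict[tuple[int, ...], float] = {}
    for nid in tree.nodes:
        s = 0.0
        if take is not None and take[: len(nid)] == nid:
            s += 1.0
        if give is not None and give[: len(nid)] == nid:
            s -= 1.0
        if s != 0.0:
            shift[nid] = s
    if not shift:
        return
    phis = tree.phis()

    def loglik_on(grid: np.ndarray) -> np.ndarray:
        delta = grid - w_take
        out = np.zeros_like(grid)
        for nid, s in shift.items():
            segs = tree.nodes[nid].segment_ids
            if not segs:
                continue
            new_phi = np.clip(phis[nid] + s * delta, 0.0, 1.0)
            for sid in segs:
                out += segment_loglik_phi_grid(seg_by_id[sid], new_phi, ctx)
        return out

    ll_coarse = loglik_on(coarse)
    best = coarse[int(np.argmax(ll_coarse))]
    half = total / (grid_points - 1)
    fine = np.linspace(max(0.0, best - half), min(total, best + half), grid_points)
    grid = np.unique(np.concatenate([coarse, fine, [w_take]]))
    ll = loglik_on(grid)
    # point weights account for uneven spacing (trapezoid cell widths)
    edges = np.concatenate([[grid[0]], (grid[1:] + grid[:-1]) / 2.0, [grid[-1]]])
    widths = np.maximum(np.diff(edges), 1e-12)
    pick = _gibbs_pick(rng, ll + np.log(widths))
    new_take = float(grid[pick])
    delta = new_take - w_take
    if take is None:
        tree.residual += delta
    else:
        tree.nodes[take].weight += delta
    if give is None:
        tree.residual -= delta
    else:
        tree.nodes[give].weight -= delta


def resample_weights(
    tree: _Tree,
    segments: list[Segment],
    ctx: LikelihoodContext,
    rng: np.random.Generator,
) -> None:
    """Grid-Gibbs weight moves: every node exchanges mass with the
    unallocated remainder, then a few random node pairs exchange mass.
    The flat Dirichlet prior over (node weights, remainder) is constant
    along each move, so the conditional is likelihood-shaped."""
    seg_by_id = {s.id: s for s in segments}
    ids = tree.sorted_ids()
    for nid in ids:
        _grid_exchange(tree, seg_by_id, ctx, rng, give=None, take=nid,
                       grid_points=tree.config.grid_points)
    # parent <-> child mass exchanges move clone frequency along tree
    # edges without disturbing the parent's own subtree sum
    for nid in ids:
        if nid and nid in tree.nodes:
            _grid_exchange(tree, seg_by_id, ctx, rng, give=nid[:-1], take=nid,
                           grid_points=tree.config.grid_points)
    ids = tree.sorted_ids()
    if len(ids) >= 2:
        for _ in range(tree.config.pair_moves):
            i, j = rng.choice(len(ids), size=2, replace=False)
            _grid_exchange(tree, seg_by_id, ctx, rng, give=ids[int(i)], take=ids[int(j)],
                           grid_points=tree.config.grid_points)


# ---------------------------------------------------------------------------
# Chain driver
# ---------------------------------------------------------------------------

def _snapshot(
    tree: _Tree,
    segments: list[Segment],
    ctx: LikelihoodContext,
    iteration: int,
) -> ChainState:
    phis = tree.phis()
    assignments: dict[str, tuple[int, ...]] = {}
    seg_maps: dict[str, tuple[int, str, float]] = {}
    log_lik = 0.0
    log_prior = 0.0
    seg_by_id = {s.id: s for s in segments}
    for nid, node in tree.nodes.items():
        for sid in node.segment_ids:
            assignments[sid] = nid
            seg = seg_by_id[sid]
            phi = phis[nid]
            ll = float(segment_loglik_phi_grid(seg, np.array([phi]), ctx)[0])
            log_lik += ll
            c_map, g = map_copy_number(seg, phi, ctx)
            seg_maps[sid] = (c_map, str(g), phi)
    log_prior = tree.sequential_assignment_logprior(
        sorted(assignments.items())
    )
    nodes = {
        nid: {
            "weight": node.weight,
            "phi": phis[nid],
            "parent": node.parent_id,
            "segments": sorted(node.segment_ids),
        }
        for nid, node in tree.nodes.items()
    }
    return ChainState(
        iteration=iteration,
        nodes=nodes,
        assignments=assignments,
        seg_maps=seg_maps,
        log_likelihood=log_lik,
        log_posterior=log_lik + log_prior,
        residual=tree.residual,
    )


def run_mcmc(
    segments: list[Segment],
    ctx: LikelihoodContext,
    config: McmcConfig,
) -> list[ChainState]:
    """Run the sampler on the non-baseline segments; returns the
    post-burn-in states. Deterministic given ``config.seed``."""
    if not segments:
        raise ValueError("no segments to infer on (all baseline?)")
    rng = np.random.default_rng(config.seed)
    tree = _Tree(rng, config)
    for seg in segments:
        tree.nodes[ROOT].segment_ids.add(seg.id)
    chain: list[ChainState] = []
    total = config.burnin + config.samples
    for it in range(total):
        tree.resample_sticks()
        sample_assignments(tree, segments, ctx, rng)
        resample_weights(tree, segments, ctx, rng)
        if it >= config.burnin:
            chain.append(_snapshot(tree, segments, ctx, it))
    logger.info(
        "run_mcmc: %d sweeps, %d recorded, final tree has %d nodes",
        total, len(chain), len(tree.nodes),
    )
    return chain


def map_state(chain: list[ChainState]) -> ChainState:
    """The recorded state with maximal stored log posterior (data
    likelihood plus the stick prior of the assignments); ties break to
    the earliest iteration.

    Ranking by posterior rather than bare likelihood matters on
    degenerate data: solutions on a shared xi curve tie exactly in
    likelihood, and only the tree prior (clustering, simplex feasibility
    and depth cost) separates them.
    """
    if not chain:
        raise ValueError("empty chain")
    best = chain[0]
    for state in chain[1:]:
        if state.log_posterior > best.log_posterior or (
            state.log_posterior == best.log_posterior
            and state.iteration < best.iteration
        ):
            best = state
    return best


# ---------------------------------------------------------------------------
# Edge probabilities over the chain
# ---------------------------------------------------------------------------

def _occupied(state: ChainState) -> dict[tuple[int, ...], frozenset[str]]:
    return {
        nid: frozenset(info["segments"])
        for nid, info in state.nodes.items()
        if info["segments"]
    }


def _state_edges(state: ChainState, labels: dict[tuple[int, ...], str]) -> set[tuple[str, str]]:
    occ = _occupied(state)
    edges: set[tuple[str, str]] = set()
    for nid in occ:
        if not nid:
            continue  # root has no parent
        anc = nid[:-1]
        while True:
            if anc in occ:
                edges.add((labels[anc], labels[nid]))
                break
            if not anc:
                break
            anc = anc[:-1]
    return edges


def _match_labels(
    state: ChainState, reference: dict[str, frozenset[str]]
) -> dict[tuple[int, ...], str]:
    """Label occupied nodes of a state by maximal Jaccard overlap with
    the reference state's clusters."""
    labels: dict[tuple[int, ...], str] = {}
    for nid, members in sorted(_occupied(state).items()):
        best_label, best_j = None, -1.0
        for label, ref_members in sorted(reference.items()):
            inter = len(members & ref_members)
            union = len(members | ref_members)
            j = inter / union if union else 0.0
            if j > best_j:
                best_label, best_j = label, j
        labels[nid] = best_label if best_label is not None else "/".join(sorted(members))
    return labels


def reference_labels(chain: list[ChainState]) -> tuple[ChainState, dict[str, frozenset[str]]]:
    """Cluster labels n0, n1, ... taken from the highest-likelihood state."""
    ref_state = map_state(chain)
    reference = {
        f"n{i}": members
        for i, (nid, members) in enumerate(sorted(_occupied(ref_state).items()))
    }
    return ref_state, reference


def edge_probabilities(chain: list[ChainState]) -> dict[tuple[str, str], float]:
    """Fraction of recorded trees containing each directed parent-child
    relation between occupied clusters."""
    _, reference = reference_labels(chain)
    counts: dict[tuple[str, str], int] = {}
    for state in chain:
        labels = _match_labels(state, reference)
        for edge in _state_edges(state, labels):
            counts[edge] = counts.get(edge, 0) + 1
    return {edge: c / len(chain) for edge, c in counts.items()}


def edge_probability(chain: list[ChainState], a: str, b: str) -> float:
    """Probability of the directed evolutionary relation a -> b."""
    return edge_probabilities(chain).get((a, b), 0.0)


# ---------------------------------------------------------------------------
# Flat (uniform-tree) mode
# ---------------------------------------------------------------------------

@dataclass
class FlatResult:
    segment_id: str
    phi_map: float
    c_map: int
    genotype: str
    phis: np.ndarray
    log_posterior: np.ndarray


def flat_infer(
    segments: list[Segment],
    ctx: LikelihoodContext,
    grid_step: float = 0.01,
) -> list[FlatResult]:
    """Per-segment profile of the marginal likelihood on a phi grid over
    (0, 1), with a uniform prior replacing the tree: for data where each
    clone carries many SCNAs (no infinite-sites structure), the tree
    prior has nothing to couple and independent profiling is exact."""
    if grid_step <= 0 or grid_step >= 1:
        raise ValueError("grid_step must be in (0, 1)")
    phis = np.arange(grid_step, 1.0, grid_step)
    results = []
    for seg in segments:
        curve = segment_loglik_phi_grid(seg, phis, ctx)
        idx = int(np.argmax(curve))
        phi_map = float(phis[idx])
        c_map, g = map_copy_number(seg, phi_map, ctx)
        results.append(
            FlatResult(
                segment_id=seg.id, phi_map=phi_map, c_map=c_map,
                genotype=str(g), phis=phis, log_posterior=curve,
            )
        )
    return results
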
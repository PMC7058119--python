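import numpy as np
import pytest

from cnatree.clonal_model import LikelihoodContext
from cnatree.tssb_inference import (
    ChainState,
    McmcConfig,
    ROOT,
    _Tree,
    edge_probabilities,
    edge_probability,
    flat_infer,
    map_state,
    run_mcmc,
)
from conftest import exact_mean_segment


def two_clone_segments(phi_a=0.9, phi_b=0.3, **kw):
    # both states have a unique frequency solution: an LOH amplification
    # (folded BAF below 1/cbar) and a hemizygous deletion (cbar < 2)
    a = exact_mean_segment(phi_a, 4, "PPPP", seg_id="segA", chrom="chr1", **kw)
    b = exact_mean_segment(phi_b, 1, "M", seg_id="segB", chrom="chr2", **kw)
    return [a, b]


CTX = LikelihoodContext(theta=1.0, c_max=15)


class TestRunMcmc:
    def test_records_exactly_samples_states(self):
        segs = two_clone_segments(n_snps=20, normal=2000)
        chain = run_mcmc(segs, CTX, McmcConfig(burnin=5, samples=12, seed=0))
        assert len(chain) == 12
        assert all(np.isfinite(s.log_posterior) for s in chain)
        assert all(np.isfinite(s.log_likelihood) for s in chain)

    def test_empty_segment_set_rejected(self):
        with pytest.raises(ValueError):
            run_mcmc([], CTX, McmcConfig())

    def test_same_seed_identical_chain(self):
        segs = two_clone_segments(n_snps=20, normal=2000)
        cfg = McmcConfig(burnin=3, samples=8, seed=11)
        c1 = run_mcmc(segs, CTX, cfg)
        segs2 = two_clone_segments(n_snps=20, normal=2000)
        c2 = run_mcmc(segs2, CTX, cfg)
        for s1, s2 in zip(c1, c2):
            assert s1.assignments == s2.assignments
            assert s1.log_posterior == pytest.approx(s2.log_posterior)
            assert {k: v["weight"] for k, v in s1.nodes.items()} == pytest.approx(
                {k: v["weight"] for k, v in s2.nodes.items()}
            )

    def test_distinct_frequencies_resolve_to_distinct_nodes(self):
        hits = 0
        for seed in range(8):
            segs = two_clone_segments(n_snps=60, normal=8000)
            chain = run_mcmc(segs, CTX, McmcConfig(burnin=20, samples=30, seed=seed))
            best = map_state(chain)
            phi_a = best.seg_maps["segA"][2]
            phi_b = best.seg_maps["segB"][2]
            if abs(phi_a - 0.9) < 0.05 and abs(phi_b - 0.3) < 0.05:
                hits += 1
        assert hits >= 7

    def test_stick_mass_and_phi_monotonicity_invariants(self):
        segs = two_clone_segments(n_snps=30, normal=4000)
        chain = run_mcmc(segs, CTX, McmcConfig(burnin=5, samples=25, seed=3))
        for state in chain:
            total = sum(v["weight"] for v in state.nodes.values()) + state.residual
            assert total == pytest.approx(1.0, abs=1e-12)
            for nid, info in state.nodes.items():
                assert -1e-12 <= info["phi"] <= 1 + 1e-12
                if nid != ROOT:
                    parent_phi = state.nodes[nid[:-1]]["phi"]
                    assert parent_phi >= info["phi"] - 1e-12


class TestWeightSampler:
    def test_two_node_posterior_matches_dense_grid_oracle(self):
        """Grid-Gibbs weight moves target the correct conditional: on a
        fixed two-leaf tree with weak single-peak likelihoods (deletion
        segments, which have unique solutions), the sampled marginal of
        one weight matches the numerically integrated posterior."""
        from cnatree.clonal_model import segment_loglik
        from cnatree.tssb_inference import resample_weights

        seg_a = exact_mean_segment(0.6, 1, "M", seg_id="segA", chrom="chr1",
                                   n_snps=3, normal=80, depth=25)
        seg_b = exact_mean_segment(0.25, 1, "M", seg_id="segB", chrom="chr2",
                                   n_snps=3, normal=80, depth=25)
        segs = [seg_a, seg_b]
        rng = np.random.default_rng(0)
        tree = _Tree(rng, McmcConfig(seed=0, pair_moves=2))
        tree.nodes[ROOT].weight = 0.3
        tree.residual = 0.4
        tree.add_child(ROOT, 0.5, 0.5, 0.3)
        tree.nodes[ROOT].segment_ids.add("segA")
        tree.nodes[(0,)].segment_ids.add("segB")

        samples = []
        for _ in range(1500):
            resample_weights(tree, segs, CTX, rng)
            samples.append(tree.nodes[(0,)].weight)
        samples = np.array(samples[200:])

        # dense oracle: posterior on the (w_root, w_child) simplex; note
        # phi(root) = w_root + w_child for the segment at the root
        grid = np.linspace(0.0005, 0.9995, 1000)
        ll_b = np.array([segment_loglik(segs[1], w, CTX) for w in grid])
        ll_a = np.array([segment_loglik(segs[0], p, CTX) for p in grid])
        scale = max(ll_a.max(), ll_b.max())
        marg = np.zeros_like(grid)
        for i, w_child in enumerate(grid):
            mask = grid <= 1 - w_child
            if mask.sum() < 2:
                continue
            phis_root = np.clip(grid[mask] + w_child, 0, 1)
            la = np.interp(phis_root, grid, ll_a)
            marg[i] = np.exp(ll_b[i] - scale) * np.trapezoid(
                np.exp(la - scale), grid[mask]
            )
        cdf = np.cumsum(marg)
        cdf /= cdf[-1]
        sample_cdf = np.searchsorted(np.sort(samples), grid) / len(samples)
        ks = float(np.max(np.abs(sample_cdf - cdf)))
        assert ks < 0.05

    def test_single_node_keeps_simplex_and_finds_optimum(self):
        rng = np.random.default_rng(1)
        tree = _Tree(rng, McmcConfig(seed=1))
        tree.nodes[ROOT].segment_ids.add("segA")
        from cnatree.tssb_inference import resample_weights

        # hemizygous deletion: cbar < 2, so the frequency is unique
        segs = [exact_mean_segment(0.8, 1, "M", seg_id="segA", n_snps=40, normal=5000)]
        for _ in range(20):
            resample_weights(tree, segs, CTX, rng)
            assert 0 <= tree.nodes[ROOT].weight <= 1
            assert tree.nodes[ROOT].weight + tree.residual == pytest.approx(1.0)
        assert tree.phis()[ROOT] == pytest.approx(0.8, abs=0.05)


def _fake_state(iteration, nodes, lp):
    """nodes: {path: (parent_or_None, segments)}"""
    node_map = {}
    for path, (parent, segs) in nodes.items():
        node_map[path] = {"weight": 0.1, "phi": 0.5, "parent": parent, "segments": segs}
    assignments = {s: path for path, (_, segs) in nodes.items() for s in segs}
    return ChainState(
        iteration=iteration, nodes=node_map, assignments=assignments,
        seg_maps={}, log_likelihood=lp, log_posterior=lp, residual=0.0,
    )


class TestMapState:
    def test_single_state_chain(self):
        s = _fake_state(0, {(): (None, ["x"])}, -10.0)
        assert map_state([s]) is s

    def test_equals_linear_scan_max_and_tie_rule(self):
        states = [
            _fake_state(0, {(): (None, ["x"])}, -12.0),
            _fake_state(1, {(): (None, ["x"])}, -8.0),
            _fake_state(2, {(): (None, ["x"])}, -8.0),
        ]
        assert map_state(states).iteration == 1  # earliest among ties
        assert map_state(states[::-1]).iteration == 1


class TestEdgeProbability:
    def chain(self):
        with_edge = _fake_state(
            0, {(): (None, ["x"]), (0,): ((), ["y"])}, -5.0
        )
        without = _fake_state(1, {(): (None, ["x", "y"])}, -9.0)
        return with_edge, without

    def test_edge_in_every_tree(self):
        with_edge, _ = self.chain()
        probs = edge_probabilities([with_edge] * 4)
        assert probs == {("n0", "n1"): 1.0}

    def test_edge_in_no_tree(self):
        with_edge, without = self.chain()
        chain = [with_edge, without, without, without]
        # reference (MAP) state is the first: labels n0 = {x}, n1 = {y}
        assert edge_probability(chain, "n1", "n0") == 0.0

    def test_three_of_four(self):
        with_edge, without = self.chain()
        chain = [with_edge, with_edge, with_edge, without]
        assert edge_probability(chain, "n0", "n1") == pytest.approx(0.75)


class TestFlatInfer:
    def test_exact_mean_fixture_recovered_within_grid_step(self):
        segs = [
            exact_mean_segment(0.75, 3, "PPM", seg_id="hi", chrom="chr1"),
            exact_mean_segment(0.40, 1, "M", seg_id="lo", chrom="chr2"),
        ]
        results = flat_infer(segs, CTX, grid_step=0.01)
        by_id = {r.segment_id: r for r in results}
        assert abs(by_id["hi"].phi_map - 0.75) <= 0.01 + 1e-9
        assert by_id["hi"].c_map == 3
        assert abs(by_id["lo"].phi_map - 0.40) <= 0.01 + 1e-9
        assert by_id["lo"].c_map == 1

    def test_posterior_curve_length_matches_grid(self):
        segs = [exact_mean_segment(0.5, 4, "PPPM", n_snps=10, normal=500)]
        (res,) = flat_infer(segs, CTX, grid_step=0.05)
        assert len(res.phis) == len(res.log_posterior) == len(np.arange(0.05, 1.0, 0.05))

    def test_grid_argmax_is_brute_force_by_construction(self):
        segs = [exact_mean_segment(0.3, 5, "PPPPM", n_snps=10, normal=500)]
        (res,) = flat_infer(segs, CTX, grid_step=0.02)
        assert res.phi_map == pytest.approx(res.phis[np.argmax(res.log_posterior)])

    def test_rejects_bad_grid_step(self):
        with pytest.raises(ValueError):
            flat_infer([exact_mean_segment(0.5, 4, "PPPM")], CTX, grid_step=0.0)
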
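import numpy as np
import pytest

from cascadist import (
    CascadeSizeDistribution,
    ModelConfig,
    build_response,
    brute_force_distribution,
    convolve_children,
    internal_message,
    leaf_message,
    root_distribution,
    root_tree,
    run_sdp,
    star,
    uniform_tree,
)
from cascadist.sdp import ConvolvedChildren, _conv2

from conftest import local_maxima, responses_for


class TestLeafMessage:
    def test_icm_tables(self, icm_config):
        msg = leaf_message(build_response(icm_config, None, 1))
        np.testing.assert_allclose(msg.pA, [[0.64, 0.0], [0.16, 0.2]], atol=1e-15)
        np.testing.assert_allclose(msg.pI, [[0.8, 0.0], [0.0, 0.2]], atol=1e-15)

    def test_no_seeding_concentrates_at_zero(self):
        msg = leaf_message(build_response(ModelConfig("icm", {"p": 0.0}), None, 1))
        assert msg.pI[0, 0] == 1.0 and msg.pA[0, 0] == 1.0
        assert msg.pI.sum() == msg.pA.sum() == 1.0

    def test_tables_always_normalized(self, tm_config):
        msg = leaf_message(build_response(tm_config, None, 1))
        assert msg.pI.sum() == pytest.approx(1.0, abs=1e-12)
        assert msg.pA.sum() == pytest.approx(1.0, abs=1e-12)

    def test_wrong_degree_rejected(self, icm_config):
        with pytest.raises(ValueError, match="degree 1"):
            leaf_message(build_response(icm_config, None, 2))


class TestConvolveChildren:
    def test_two_icm_leaves_by_hand(self, icm_config):
        leaf = leaf_message(build_response(icm_config, None, 1))
        cc = convolve_children([leaf, leaf])
        assert cc.pIstar[0, 0] == pytest.approx(0.64, abs=1e-15)
        assert cc.pIstar[1, 1] == pytest.approx(0.32, abs=1e-15)
        assert cc.pIstar[2, 2] == pytest.approx(0.04, abs=1e-15)
        expected_A = {
            (0, 0): 0.4096, (1, 0): 0.2048, (1, 1): 0.256,
            (2, 0): 0.0256, (2, 1): 0.064, (2, 2): 0.04,
        }
        for (t, a), v in expected_A.items():
            assert cc.pAstar[t, a] == pytest.approx(v, abs=1e-15)

    def test_single_message_passthrough(self, icm_config):
        leaf = leaf_message(build_response(icm_config, None, 1))
        cc = convolve_children([leaf])
        np.testing.assert_array_equal(cc.pIstar, leaf.pI)
        np.testing.assert_array_equal(cc.pAstar, leaf.pA)

    def test_empty_input_is_identity(self):
        cc = convolve_children([])
        assert cc.pIstar.shape == (1, 1) and cc.pIstar[0, 0] == 1.0

    def test_zero_pattern_t_below_a(self, icm_config, tm_config):
        leaves = [
            leaf_message(build_response(cfg, None, 1))
            for cfg in (icm_config, tm_config, icm_config)
        ]
        cc = convolve_children(leaves)
        for tab in (cc.pIstar, cc.pAstar):
            for t in range(tab.shape[0]):
                for a in range(tab.shape[1]):
                    if t < a:
                        assert tab[t, a] == 0.0

    def test_fft_and_direct_backends_agree(self):
        rng = np.random.default_rng(0)
        a = rng.random((300, 2))
        a /= a.sum()
        b = rng.random((300, 2))
        b /= b.sum()
        from scipy.signal import convolve

        direct = convolve(a, b, method="direct")
        fft = _conv2(a, b)  # above FFT_THRESHOLD -> FFT path
        np.testing.assert_allclose(fft, direct, atol=1e-12)


class TestInternalMessage:
    def test_zero_children_reduces_to_leaf(self, icm_config, tm_config):
        identity = ConvolvedChildren(np.ones((1, 1)), np.ones((1, 1)))
        for cfg in (icm_config, tm_config):
            r = build_response(cfg, None, 1)
            via_internal = internal_message(identity, r)
            via_leaf = leaf_message(r)
            np.testing.assert_allclose(via_internal.pI, via_leaf.pI, atol=1e-15)
            np.testing.assert_allclose(via_internal.pA, via_leaf.pA, atol=1e-15)

    def test_invariants_at_internal_hub(self, icm_config):
        leaf = leaf_message(build_response(icm_config, None, 1))
        cc = convolve_children([leaf, leaf])
        msg = internal_message(cc, build_response(icm_config, None, 3))
        assert msg.pI.sum() == pytest.approx(1.0, abs=1e-12)
        assert msg.pA.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(msg.pI[:, 1], msg.pA[:, 1], atol=1e-15)
        assert msg.pI[0, 1] == 0.0 and msg.pA[0, 1] == 0.0


class TestRootDistribution:
    def test_two_node_tree(self, icm_config, two_node_tree):
        dist = run_sdp(
            root_tree(two_node_tree, "0"),
            responses_for(two_node_tree, icm_config),
        )
        np.testing.assert_allclose(dist.probs, [0.64, 0.256, 0.104], atol=1e-15)

    def test_star3_and_mean_vs_marginals(self, icm_config, star3):
        dist = run_sdp(root_tree(star3), responses_for(star3, icm_config))
        np.testing.assert_allclose(
            dist.probs, [0.512, 0.28672, 0.1536, 0.04768], atol=1e-14
        )
        assert dist.probs[0] == pytest.approx(0.8**3, abs=1e-15)
        assert dist.mean_count() == pytest.approx(0.73696, abs=1e-12)

    def test_single_node_tree(self, icm_config):
        from cascadist import Network

        g = Network(nodes=["solo"])
        dist = run_sdp(root_tree(g, "solo"), responses_for(g, icm_config))
        np.testing.assert_allclose(dist.probs, [0.8, 0.2], atol=1e-15)

    def test_identity_cc_root(self, tm_config):
        r = build_response(tm_config, None, 0)
        dist = root_distribution(
            ConvolvedChildren(np.ones((1, 1)), np.ones((1, 1))), r, N=1
        )
        np.testing.assert_allclose(dist.probs, [1 - r.R[0], r.R[0]], atol=1e-15)


class TestRunSdp:
    @pytest.mark.parametrize("model", ["icm", "tm"])
    def test_matches_brute_force_on_random_trees(
        self, model, icm_config, tm_config
    ):
        cfg = icm_config if model == "icm" else tm_config
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            g = uniform_tree(n, seed=int(rng.integers(2**31)))
            exact = brute_force_distribution(g, cfg)
            dist = run_sdp(root_tree(g), responses_for(g, cfg))
            assert np.max(np.abs(dist.probs - exact.probs)) < 1e-10

    def test_root_invariance(self, icm_config):
        g = uniform_tree(17, seed=9)
        resp = responses_for(g, icm_config)
        base = run_sdp(root_tree(g, g.nodes[0]), resp).probs
        for root in (g.nodes[8], g.nodes[16], "auto"):
            alt = run_sdp(root_tree(g, root), resp).probs
            assert np.max(np.abs(alt - base)) < 1e-10

    def test_degree_mismatch_rejected(self, icm_config, star3):
        resp = responses_for(star3, icm_config)
        resp["0"] = build_response(icm_config, "0", 5)
        with pytest.raises(ValueError, match="degree"):
            run_sdp(root_tree(star3), resp)

    def test_multimodal_threshold_star(self, tm_config):
        g = star(11)
        dist = run_sdp(root_tree(g), responses_for(g, tm_config))
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-10)
        # hub-on vs hub-off events split the distribution into two bumps
        assert len(local_maxima(dist.probs)) >= 2
        exact = brute_force_distribution(g, tm_config)
        assert np.max(np.abs(dist.probs - exact.probs)) < 1e-10
        assert local_maxima(exact.probs) == local_maxima(dist.probs)


class TestGridMode:
    def test_coarse_grid_preserves_mean(self, icm_config, tm_config):
        g = uniform_tree(60, seed=4)
        for cfg in (icm_config, tm_config):
            resp = responses_for(g, cfg)
            exact = run_sdp(root_tree(g), resp)
            coarse = run_sdp(root_tree(g), resp, resolution=16)
            assert coarse.grid == 16
            assert len(coarse.probs) == 17
            assert abs(coarse.mean_count() - exact.mean_count()) < 1e-9

    def test_full_resolution_grid_is_bitwise_exact(self, icm_config):
        g = uniform_tree(35, seed=6)
        resp = responses_for(g, icm_config)
        exact = run_sdp(root_tree(g), resp)
        for C in (35, 64):
            gridded = run_sdp(root_tree(g), resp, resolution=C)
            assert gridded.grid is None
            np.testing.assert_array_equal(gridded.probs, exact.probs)


class TestDistributionTsv:
    def test_bit_stable_round_trip(self, icm_config):
        g = uniform_tree(12, seed=1)
        dist = run_sdp(root_tree(g), responses_for(g, icm_config))
        back = CascadeSizeDistribution.from_tsv(dist.to_tsv())
        assert back.N == dist.N
        np.testing.assert_array_equal(back.probs, dist.probs)
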
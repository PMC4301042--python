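import numpy as np
import pandas as pd
import pytest

from seedperf.importance import (
    ImportanceError,
    build_design,
    lmg_shares,
    normalize_shares,
)

from .oracles import lmg_bruteforce


def make_blocks(rng, n=80, correlated=False):
    z = rng.normal(size=(n, 3))
    if correlated:
        z[:, 1] = 0.6 * z[:, 0] + 0.8 * z[:, 1]
        z[:, 2] = 0.4 * z[:, 0] + 0.9 * z[:, 2]
    return {
        "b1": z[:, [0]],
        "b2": z[:, [1]],
        "b3": z[:, [2]],
    }


class TestLMG:
    def test_single_block_share_is_r2_gain(self, rng):
        n = 60
        x = rng.normal(size=(n, 1))
        cov = rng.normal(size=n)
        y = 0.5 * x[:, 0] + 0.3 * cov + rng.normal(size=n)
        res = lmg_shares(y, cov, {"only": x})
        assert res.shares["only"] == pytest.approx(
            res.total_r2 - res.covariate_r2, abs=1e-12
        )

    def test_orthogonal_blocks_get_marginal_increments(self, rng):
        """With mutually orthogonal blocks (orthogonal to the covariate
        too), increments are order-independent."""
        n = 90
        base = np.kron(np.eye(3), np.ones(n // 3))
        b1 = (base[0] - base[0].mean()).reshape(-1, 1)
        b2 = np.tile([1.0, -1.0], n // 2)
        b2 = (b2 - b2.mean()).reshape(-1, 1)
        assert abs(float((b1.T @ b2)[0, 0])) < 1e-9
        y = 0.7 * b1[:, 0] + 0.4 * b2[:, 0] + rng.normal(size=n)
        res = lmg_shares(y, None, {"b1": b1, "b2": b2})

        def r2_gain(block):
            X0 = np.ones((n, 1))
            Xb = np.column_stack([np.ones(n), block])
            r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
            rb = y - Xb @ np.linalg.lstsq(Xb, y, rcond=None)[0]
            sst = np.sum((y - y.mean()) ** 2)
            return (r0 @ r0 - rb @ rb) / sst

        assert res.shares["b1"] == pytest.approx(r2_gain(b1), abs=1e-10)
        assert res.shares["b2"] == pytest.approx(r2_gain(b2), abs=1e-10)

    def test_matches_bruteforce_ordering_enumeration(self, rng):
        """Correlated blocks: exact subset-weight LMG equals the naive
        average over all 3! orderings, to 1e-10."""
        n = 60
        blocks = make_blocks(rng, n, correlated=True)
        cov = rng.normal(size=n)
        y = (
            0.6 * blocks["b1"][:, 0]
            + 0.3 * blocks["b2"][:, 0]
            + 0.2 * cov
            + rng.normal(size=n)
        )
        res = lmg_shares(y, cov, blocks)
        oracle = lmg_bruteforce(y, cov, blocks)
        for b in blocks:
            assert res.shares[b] == pytest.approx(oracle[b], abs=1e-10)

    def test_nonnegative_and_decompose(self, rng):
        n = 120
        blocks = make_blocks(rng, n, correlated=True)
        y = blocks["b1"][:, 0] + 0.5 * blocks["b2"][:, 0] + rng.normal(size=n)
        cov = rng.normal(size=n)
        res = lmg_shares(y, cov, blocks)
        for s in res.shares.values():
            assert s >= -1e-12
        assert sum(res.shares.values()) + res.covariate_r2 == pytest.approx(
            res.total_r2, abs=1e-10
        )

    def test_order_invariance_of_labels(self, rng):
        n = 60
        blocks = make_blocks(rng, n, correlated=True)
        y = blocks["b1"][:, 0] + rng.normal(size=n)
        res1 = lmg_shares(y, None, blocks)
        renamed = {"zz": blocks["b1"], "aa": blocks["b2"], "mm": blocks["b3"]}
        res2 = lmg_shares(y, None, renamed)
        assert res1.shares["b1"] == pytest.approx(res2.shares["zz"], abs=1e-12)
        assert res1.shares["b2"] == pytest.approx(res2.shares["aa"], abs=1e-12)

    def test_collinear_block_named(self, rng):
        n = 50
        x = rng.normal(size=(n, 1))
        blocks = {"b1": x, "b2": x.copy()}
        y = x[:, 0] + rng.normal(size=n)
        with pytest.raises(ImportanceError, match="b"):
            lmg_shares(y, None, blocks)


class TestNormalize:
    def test_single_block_100(self, rng):
        n = 50
        x = rng.normal(size=(n, 1))
        y = x[:, 0] + rng.normal(size=n)
        res = normalize_shares(lmg_shares(y, None, {"b": x}))
        assert res.normalized["b"] == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        from seedperf.importance import ImportanceResult

        res = ImportanceResult(
            species="X", metric="rgr_ht", total_r2=0.2, covariate_r2=0.08,
            shares={"a": 0.06, "b": 0.04, "c": 0.02},
        )
        normalize_shares(res)
        assert res.normalized["a"] == pytest.approx(50.0)
        assert res.normalized["b"] == pytest.approx(100.0 / 3.0)
        assert res.normalized["c"] == pytest.approx(50.0 / 3.0)

    def test_zero_variance_flagged(self):
        from seedperf.importance import ImportanceResult

        res = ImportanceResult(
            species="X", metric="rgr_ht", total_r2=0.1, covariate_r2=0.1,
            shares={"a": 0.0},
        )
        with pytest.raises(ImportanceError):
            normalize_shares(res)


class TestBuildDesign:
    def make_perf(self, rng, n=40):
        return pd.DataFrame(
            {
                "rgr_ht": rng.normal(0.2, 0.1, n),
                "initial_height_cm": rng.uniform(1, 8, n),
                "cat_tpar": rng.choice(["low", "medium", "high"], n),
                "cat_slope": rng.choice(["low", "medium", "high"], n),
                "cat_elevation": rng.choice(["low", "medium", "high"], n),
                "cat_aspect": rng.choice(["NE", "SE-SW", "W-NW"], n),
                "cat_substrate": rng.choice(
                    ["soil", "log", "rock", "root_mat", "live_tree_fern",
                     "dead_tree_fern"], n),
            }
        )

    def test_reference_coding_column_counts(self, rng):
        perf = self.make_perf(rng, 60)
        y, cov, blocks, dropped = build_design(perf, "rgr_ht")
        assert blocks["tpar"].shape[1] == 2
        assert blocks["aspect"].shape[1] == 2
        assert blocks["substrate"].shape[1] == 5
        assert dropped == ()

    def test_single_level_factor_dropped_with_warning(self, rng):
        perf = self.make_perf(rng, 40)
        perf["cat_tpar"] = "low"
        with pytest.warns(UserWarning, match="tpar"):
            y, cov, blocks, dropped = build_design(perf, "rgr_ht")
        assert "tpar" not in blocks
        assert dropped == ("tpar",)
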
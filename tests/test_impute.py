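"""Conditional-Gaussian Z-score imputation and window tiling."""

import numpy as np
import pandas as pd
import pytest

import cosmix as cx
from cosmix.exceptions import NumericalError
from cosmix.impute import (
    FLAG_IMPUTED,
    FLAG_LOW_INFO,
    FLAG_MONOMORPHIC,
    FLAG_OBSERVED,
    partition_windows,
)


def random_correlation(rng, m):
    A = rng.standard_normal((m, m + 5))
    V = A @ A.T / (m + 5)
    s = 1 / np.sqrt(np.diag(V))
    return V * np.outer(s, s)


class TestConditionalImpute:
    def test_perfect_proxy(self):
        zhat, info = cx.conditional_impute([2.5], [[1.0]], [[1.0]], lam=0.0)
        assert zhat[0] == pytest.approx(2.5)
        assert info[0] == pytest.approx(1.0)

    def test_no_ld_returns_prior_mean(self):
        zhat, info = cx.conditional_impute([2.5, 1.0], np.eye(2), [[0.0, 0.0]])
        assert zhat[0] == 0.0 and info[0] == 0.0

    def test_worked_two_observed_example(self):
        zhat, info = cx.conditional_impute(
            [2.0, 1.0], [[1.0, 0.5], [0.5, 1.0]], [[0.8, 0.4]], lam=0.0
        )
        assert zhat[0] == pytest.approx(1.6, abs=1e-12)
        assert info[0] == pytest.approx(0.64, abs=1e-12)
        assert zhat[0] / np.sqrt(info[0]) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.1])
    def test_matches_generic_solver(self, lam):
        rng = np.random.default_rng(17)
        for _ in range(25):
            m_o = rng.integers(1, 11)
            m_u = rng.integers(1, 6)
            R = random_correlation(rng, m_o + m_u)
            z_o = rng.standard_normal(m_o)
            Soo, Suo = R[:m_o, :m_o], R[m_o:, :m_o]
            zhat, info = cx.conditional_impute(z_o, Soo, Suo, lam=lam)
            A = np.linalg.solve(Soo + lam * np.eye(m_o), np.column_stack([z_o, Suo.T]))
            np.testing.assert_allclose(zhat, Suo @ A[:, 0], atol=1e-10)
            np.testing.assert_allclose(info, np.diag(Suo @ A[:, 1:]), atol=1e-10)

    def test_info_within_unit_interval(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            R = random_correlation(rng, 12)
            _, info = cx.conditional_impute(
                rng.standard_normal(8), R[:8, :8], R[8:, :8], lam=0.05
            )
            assert (info >= 0).all() and (info <= 1 + 1e-6).all()

    def test_info_monotone_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            R = random_correlation(rng, 10)
            z_o = rng.standard_normal(7)
            prev = None
            for lam in (0.0, 0.05, 0.2, 1.0):
                _, info = cx.conditional_impute(z_o, R[:7, :7], R[7:, :7], lam=lam)
                if prev is not None:
                    assert (info <= prev + 1e-12).all()
                prev = info

    def test_singular_system_advises_ridge(self):
        Soo = np.ones((3, 3))  # rank 1
        with pytest.raises(NumericalError, match="lambda"):
            cx.conditional_impute([1.0, 1.0, 1.0], Soo, [[1.0, 1.0, 1.0]], lam=0.0)

    def test_window_consistency_on_block_diagonal_ld(self):
        """Tiled solves equal the joint solve when LD is block-diagonal."""
        rng = np.random.default_rng(29)
        blocks = [random_correlation(rng, 6) for _ in range(3)]
        from scipy.linalg import block_diag

        R = block_diag(*blocks)
        obs = np.array([0, 1, 2, 6, 7, 8, 12, 13, 14])
        unm = np.array([3, 4, 5, 9, 10, 11, 15, 16, 17])
        z_o = rng.standard_normal(obs.size)
        joint_z, joint_i = cx.conditional_impute(
            z_o, R[np.ix_(obs, obs)], R[np.ix_(unm, obs)], lam=0.1
        )
        for b in range(3):
            sel_o = slice(3 * b, 3 * b + 3)
            o = obs[sel_o]
            u = unm[sel_o]
            zb, ib = cx.conditional_impute(
                z_o[sel_o], R[np.ix_(o, o)], R[np.ix_(u, o)], lam=0.1
            )
            np.testing.assert_allclose(zb, joint_z[sel_o], atol=1e-10)
            np.testing.assert_allclose(ib, joint_i[sel_o], atol=1e-10)


class TestPartitionWindows:
    def test_three_megabase_region(self):
        ws = partition_windows(("1", 1, 3_000_000))
        assert len(ws) == 3
        assert [(w.core_start, w.core_end) for w in ws] == [
            (1, 1_000_000), (1_000_001, 2_000_000), (2_000_001, 3_000_000),
        ]

    def test_partial_last_core(self):
        ws = partition_windows(("1", 1, 1_500_000))
        assert len(ws) == 2
        assert (ws[1].core_start, ws[1].core_end) == (1_000_001, 1_500_000)

    def test_flanks_clipped_at_region_bounds(self):
        ws = partition_windows(("1", 1, 2_000_000), flank_bp=250_000)
        assert ws[0].full_start == 1
        assert ws[0].full_end == 1_250_000
        assert ws[1].full_start == 750_001
        assert ws[1].full_end == 2_000_000

    def test_cores_tile_without_overlap(self):
        ws = partition_windows(("2", 500, 4_200_000), core_bp=700_000)
        for a, b in zip(ws, ws[1:]):
            assert b.core_start == a.core_end + 1
        assert ws[0].core_start == 500 and ws[-1].core_end == 4_200_000


class TestDistmix:
    @pytest.fixture(scope="class")
    def region(self, small_panel):
        bp = small_panel.variants["bp"]
        return ("1", int(bp.min()), int(bp.max()))

    def test_perfect_ld_copies_observed_z(self):
        variants = pd.DataFrame(
            {
                "rsid": ["rs1", "rs2"], "chr": ["1", "1"], "bp": [100, 200],
                "a1": ["A", "C"], "a2": ["G", "T"],
            }
        )
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]])
        panel = cx.ReferencePanel(variants, ["P"], {"P": g})
        zt = cx.zscore_table(panel, np.array([2.2]), idx=np.array([0]))
        za, _ = cx.align_to_panel(zt, panel)
        res = cx.dist(za, panel, "P", ("1", 1, 300), lam=0.0)
        row = res[res["rsid"] == "rs2"].iloc[0]
        assert row["flag"] == FLAG_IMPUTED
        assert row["info"] == pytest.approx(1.0, abs=1e-9)
        assert row["z"] == pytest.approx(2.2, abs=1e-9)

    def test_observed_variants_echoed(self, small_panel, pi_60_40, region):
        ld = cx.compute_ld(small_panel, pi_60_40)
        z = cx.simulate_gwas_z(ld.R, seed=31)[0]
        za, _ = cx.align_to_panel(cx.zscore_table(ld.variants, z), small_panel)
        half = za.iloc[::2]
        res = cx.distmix(half, small_panel, pi_60_40, region)
        obs = res[res["flag"] == FLAG_OBSERVED]
        merged = obs.merge(half, on="rsid", suffixes=("", "_in"))
        assert len(obs) == len(half)
        np.testing.assert_allclose(merged["z"], merged["z_in"])
        assert (obs["info"] == 1.0).all()

    def test_flags_partition_all_core_variants(self, small_panel, pi_60_40, region):
        ld = cx.compute_ld(small_panel, pi_60_40)
        z = cx.simulate_gwas_z(ld.R, seed=37)[0]
        za, _ = cx.align_to_panel(cx.zscore_table(ld.variants, z), small_panel)
        res = cx.distmix(za.iloc[::3], small_panel, pi_60_40, region)
        assert len(res) == small_panel.n_variants
        assert set(res["flag"]).issubset(
            {FLAG_OBSERVED, FLAG_IMPUTED, FLAG_LOW_INFO, FLAG_MONOMORPHIC}
        )
        imputed = res[res["flag"] == FLAG_IMPUTED]
        assert (imputed["info"] >= 0.3).all()
        assert imputed["p"].between(0, 1).all()

    def test_maf_filter_flags_monomorphic(self, small_panel, pi_60_40, region):
        ld = cx.compute_ld(small_panel, pi_60_40)
        z = cx.simulate_gwas_z(ld.R, seed=41)[0]
        za, _ = cx.align_to_panel(cx.zscore_table(ld.variants, z), small_panel)
        res = cx.distmix(za.iloc[::2], small_panel, pi_60_40, region, maf_min=0.2)
        assert (res["flag"] == FLAG_MONOMORPHIC).any()
        assert res.loc[res["flag"] == FLAG_MONOMORPHIC, "p"].isna().all()

    def test_empty_observed_set_skips_everything(self, small_panel, pi_60_40):
        za = pd.DataFrame(columns=["rsid", "chr", "bp", "a1", "a2", "z", "panel_idx"])
        za = za.astype({"bp": int, "z": float, "panel_idx": int})
        res = cx.distmix(za, small_panel, pi_60_40, ("1", 1, 200_000))
        assert set(res["flag"]).issubset({FLAG_LOW_INFO, FLAG_MONOMORPHIC})
        assert (res["info"].fillna(0) == 0).all()

    def test_dist_equals_distmix_at_vertex(self, small_panel, region):
        ld = cx.compute_ld(
            small_panel, cx.MixingProportions.vertex(small_panel, "POP2")
        )
        z = cx.simulate_gwas_z(ld.R, seed=43)[0]
        za, _ = cx.align_to_panel(cx.zscore_table(ld.variants, z), small_panel)
        a = cx.dist(za.iloc[::2], small_panel, "POP2", region)
        b = cx.distmix(
            za.iloc[::2], small_panel,
            cx.MixingProportions.vertex(small_panel, "POP2"), region,
        )
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_population_lists_available(self, small_panel, region):
        za = pd.DataFrame(
            {"rsid": ["rs1"], "chr": ["1"], "bp": [1], "a1": ["A"], "a2": ["G"],
             "z": [1.0], "panel_idx": [0]}
        )
        with pytest.raises(cx.CosmixError, match="POP1"):
            cx.dist(za, small_panel, "EUR", region)

    def test_holdout_recovery_on_masked_null_gwas(self):
        """Masked variants in strong LD are recovered with high fidelity.

        The attainable pooled correlation between predicted and held-out
        Z-scores is sqrt(mean info), so the >= 0.9 bar needs a dense-LD
        design with plenty of high-info targets.
        """
        cfg = cx.SyntheticConfig(
            n_pops=2, n_per_pop=300, m_variants=300, fst=[0.1, 0.2],
            rho=0.97, block_size=50, seed=61,
        )
        panel = cx.simulate_panel(cfg)
        pi = cx.MixingProportions(panel.populations, np.array([0.6, 0.4]))
        ld = cx.compute_ld(panel, pi)
        rng = np.random.default_rng(47)
        Z = cx.simulate_gwas_z(ld.R, seed=53, n_draws=60)
        mask = rng.random(len(ld.variants)) < 0.2
        region = ("1", 1, 300_000)
        zh_all, zt_all = [], []
        for z in Z:
            za, _ = cx.align_to_panel(
                cx.zscore_table(ld.variants[~mask], z[~mask]), panel
            )
            res = cx.distmix(za, panel, pi, region, lam=0.0)
            imp = res[res["flag"] == FLAG_IMPUTED].merge(
                cx.zscore_table(ld.variants[mask], z[mask]),
                on="rsid", suffixes=("", "_true"),
            )
            good = imp[imp["info"] >= 0.8]
            zh_all.extend(good["z"] * np.sqrt(good["info"]))  # back to zhat scale
            zt_all.extend(good["z_true"])
        r = np.corrcoef(zh_all, zt_all)[0, 1]
        assert r >= 0.9
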
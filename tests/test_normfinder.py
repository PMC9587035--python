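import numpy as np
import pandas as pd
import pytest

import oracles
from refstab.data_io import GroupDesign
from refstab.normfinder import (
    analyze,
    best_combination,
    intergroup_analysis,
    intragroup_variance,
    log_and_center,
    stability_values,
)

from conftest import make_cq


def _z_and_design(cq, n_groups=2, genes=None):
    t = make_cq(cq, genes=genes)
    z = log_and_center(t)
    samples = list(z.columns)
    chunks = np.array_split(np.arange(len(samples)), n_groups)
    design = GroupDesign(
        "g", {f"grp{i}": [samples[j] for j in c] for i, c in enumerate(chunks)}
    )
    return z, design


class TestLogAndCenter:
    def test_equal_genes_center_to_zero(self):
        z = log_and_center(make_cq([[20.0, 21], [20, 21], [20, 21]]))
        assert np.allclose(z.to_numpy(), 0)

    def test_sample_constant_removed(self, rng):
        cq = 20 + rng.normal(0, 0.5, (4, 6))
        t1 = make_cq(cq)
        t2 = make_cq(cq + rng.uniform(-2, 2, 6)[None, :])
        pd.testing.assert_frame_equal(log_and_center(t1), log_and_center(t2))

    def test_hand_example(self):
        # 3 genes x 2 samples; z = -Cq + column mean of Cq
        cq = np.array([[20.0, 21.0], [22.0, 22.0], [24.0, 26.0]])
        z = log_and_center(make_cq(cq))
        expected = -cq + cq.mean(axis=0)[None, :]
        np.testing.assert_allclose(z.to_numpy(), expected, atol=1e-12)

    def test_needs_three_genes(self):
        with pytest.raises(ValueError, match="3 genes"):
            log_and_center(make_cq([[20.0, 21], [22, 23]]))


class TestIntragroup:
    def test_noiseless_zero(self):
        z, d = _z_and_design(np.tile([[20.0], [22.0], [23.0], [25.0]], 8), 2)
        s2 = intragroup_variance(z, d)
        assert (s2.to_numpy() == 0).all()

    def test_equal_variance_recovery_unbiased(self):
        """i.i.d. equal-noise genes: de-mixed estimates recover the true
        variance with < 5% relative bias (n = 2000, k = 8, 100 seeds)."""
        k, n, sigma = 8, 2000, 0.3
        rel = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            cq = 20 + r.normal(0, sigma, (k, n))
            z, d = _z_and_design(cq, 1)
            s2 = intragroup_variance(z, d)
            rel.append(s2.iloc[:, 0].to_numpy() / sigma**2 - 1)
        bias = np.mean(rel, axis=0)
        assert np.abs(bias).max() < 0.05

    def test_high_variance_gene_found(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            sds = np.array([0.3, 0.3, 0.6, 0.3, 0.3])  # gene 3: 4x variance
            cq = 20 + r.normal(0, 1, (5, 50)) * sds[:, None]
            z, d = _z_and_design(cq, 1)
            s2 = intragroup_variance(z, d)
            hits += s2.iloc[:, 0].idxmax() == "G3"
        assert hits >= 95

    def test_truncation_non_negative(self, rng):
        # adversarial: one gene nearly constant drives raw estimate < 0
        cq = np.vstack(
            [np.full(20, 20.0), 22 + rng.normal(0, 2, 20), 24 + rng.normal(0, 2, 20)]
        )
        z, d = _z_and_design(cq, 2)
        assert (intragroup_variance(z, d).to_numpy() >= 0).all()

    def test_matches_bruteforce(self, rng):
        cq = 20 + rng.normal(0, 0.5, (5, 12))
        z, d = _z_and_design(cq, 2)
        s2 = intragroup_variance(z, d)
        zd = {g: dict(z.loc[g]) for g in z.index}
        ref, _, _, _ = oracles.normfinder_components(zd, d.groups)
        for g in z.index:
            for label in d.groups:
                assert s2.loc[g, label] == pytest.approx(ref[g][label], abs=1e-12)


class TestIntergroup:
    def test_centering_identity(self, rng):
        cq = 20 + rng.normal(0, 0.5, (6, 20))
        z, d = _z_and_design(cq, 2)
        s2 = intragroup_variance(z, d)
        _, _, dhat = intergroup_analysis(z, d, s2)
        np.testing.assert_allclose(dhat.sum(axis=0).to_numpy(), 0, atol=1e-10)

    def test_null_gamma_shrinks_to_zero(self):
        # both groups from one distribution: at large n the (truncated)
        # between-group variance and all shrunken differences are tiny
        g2s, dts = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            cq = 20 + r.normal(0, 0.3, (6, 400))
            z, d = _z_and_design(cq, 2)
            s2 = intragroup_variance(z, d)
            dt, g2, _ = intergroup_analysis(z, d, s2)
            g2s.append(g2)
            dts.append(dt.abs().max().max())
        assert np.mean(g2s) < 0.002  # true gamma2 = 0
        assert max(dts) < 0.05

    def test_offset_gene_detected(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            cq = 20 + r.normal(0, 0.3, (6, 60))
            cq[2, 30:] += 1.0  # one-cycle group offset on gene 3
            z, d = _z_and_design(cq, 2)
            s2 = intragroup_variance(z, d)
            dt, _, _ = intergroup_analysis(z, d, s2)
            hits += dt.abs().max(axis=1).idxmax() == "G3"
        assert hits >= 95

    def test_single_group_rejected(self, rng):
        cq = 20 + rng.normal(0, 0.3, (4, 10))
        z, d = _z_and_design(cq, 1)
        s2 = intragroup_variance(z, d)
        with pytest.raises(ValueError, match="single-group"):
            intergroup_analysis(z, d, s2)

    def test_matches_bruteforce(self, rng):
        cq = 20 + rng.normal(0, 0.4, (5, 24))
        cq[1, 12:] += 0.8
        z, d = _z_and_design(cq, 2)
        s2 = intragroup_variance(z, d)
        dt, g2, _ = intergroup_analysis(z, d, s2)
        zd = {g: dict(z.loc[g]) for g in z.index}
        _, ref_dt, ref_g2, _ = oracles.normfinder_components(zd, d.groups)
        assert g2 == pytest.approx(ref_g2, abs=1e-12)
        for g in z.index:
            for label in d.groups:
                assert dt.loc[g, label] == pytest.approx(ref_dt[g][label], abs=1e-12)


class TestStabilityValues:
    def test_zero_noise_zero_sv(self):
        z, d = _z_and_design(np.tile([[20.0], [22.0], [23.0]], 10), 2)
        s2 = intragroup_variance(z, d)
        dt, g2, _ = intergroup_analysis(z, d, s2)
        res = stability_values(s2, dt, d, g2)
        assert (res.sv == 0).all()

    def test_grouped_matches_bruteforce(self, rng):
        cq = 20 + rng.normal(0, 0.4, (6, 30))
        cq[0, 15:] += 0.5
        z, d = _z_and_design(cq, 2)
        s2 = intragroup_variance(z, d)
        dt, g2, _ = intergroup_analysis(z, d, s2)
        res = stability_values(s2, dt, d, g2)
        zd = {g: dict(z.loc[g]) for g in z.index}
        _, _, _, ref_sv = oracles.normfinder_components(zd, d.groups)
        for g in z.index:
            assert res.sv[g] == pytest.approx(ref_sv[g], abs=1e-12)

    def test_best_true_gene_top_ranked(self):
        """Gene with the smallest (noise, offset) pair should win the
        grouped ranking in >= 90% of seeds."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            sds = np.array([0.1, 0.45, 0.5, 0.55, 0.6, 0.65])
            # gene-centering removes the mean offset, so the stable gene
            # carries the average offset (relative d = 0), others spread
            offs = np.array([0.5, 0.0, 0.9, 1.0, 0.6, 0.0])
            cq = 20 + r.normal(0, 1, (6, 60)) * sds[:, None]
            cq[:, 30:] += offs[:, None]
            z, d = _z_and_design(cq, 2)
            s2 = intragroup_variance(z, d)
            dt, g2, _ = intergroup_analysis(z, d, s2)
            hits += stability_values(s2, dt, d, g2).sv.idxmin() == "G1"
        assert hits >= 90

    def test_grouped_reduces_to_single_when_no_group_signal(self):
        # gamma2 == 0 and dtilde == 0 => grouped SV equals the shrunken
        # SE term alone, which is 0; continuity with the single-group SV
        z, d = _z_and_design(np.tile([[20.0], [21.0], [23.0]], 12), 2)
        s2 = intragroup_variance(z, d)
        dt, g2, _ = intergroup_analysis(z, d, s2)
        grouped = stability_values(s2, dt, d, g2).sv
        single = stability_values(s2, None, d, mode="single").sv
        np.testing.assert_allclose(grouped.to_numpy(), single.to_numpy(), atol=1e-12)

    def test_parameter_recovery_large_groups(self):
        """Simulated from the assumed model (normal noise, additive
        group offsets): sigma2 and dhat recover truth within 2 MC SEs
        at n_g = 500."""
        sds = np.array([0.2, 0.3, 0.4, 0.5])
        offs = np.array([0.4, -0.1, -0.2, -0.1])  # sums to zero across genes
        n_g, reps = 500, 40
        s2_est, d_est = [], []
        for seed in range(reps):
            r = np.random.default_rng(seed)
            cq = 20 + r.normal(0, 1, (4, 2 * n_g)) * sds[:, None]
            cq[:, n_g:] -= offs[:, None]  # lower Cq = higher expression
            z, d = _z_and_design(cq, 2)
            s2 = intragroup_variance(z, d)
            dt, g2, dh = intergroup_analysis(z, d, s2)
            s2_est.append(s2.mean(axis=1).to_numpy())
            d_est.append(dh.iloc[:, 1].to_numpy())
        s2_mean = np.mean(s2_est, axis=0)
        s2_se = np.std(s2_est, axis=0, ddof=1) / np.sqrt(reps)
        d_mean = np.mean(d_est, axis=0)
        d_se = np.std(d_est, axis=0, ddof=1) / np.sqrt(reps)
        assert (np.abs(s2_mean - sds**2) <= 2 * s2_se + 1e-3).all()
        assert (np.abs(d_mean - offs / 2) <= 2 * d_se + 1e-3).all()


class TestBestCombination:
    def test_duplicated_gene_pair_equals_single_sv(self, rng):
        cq = 20 + rng.normal(0, 0.4, (5, 40))
        cq[0, 20:] += 0.5  # give A a group offset so the test bites
        cq = np.vstack([cq, cq[0]])  # duplicate of gene 1
        genes = ["A", "B", "C", "D", "E", "Adup"]
        z, d = _z_and_design(cq, 2, genes=genes)
        _, sv_pair = best_combination(z, d, candidates=["A", "Adup"])
        # single-gene SV of A computed on the de-duplicated gene set
        z_single = z.drop(index=["Adup"])
        z_single = z_single - z_single.mean(axis=0)
        s2s = intragroup_variance(z_single, d)
        dts, g2s, _ = intergroup_analysis(z_single, d, s2s)
        sv_single = stability_values(s2s, dts, d, g2s).sv["A"]
        assert sv_pair == pytest.approx(sv_single, abs=1e-12)

    def test_independent_pair_beats_sqrt2_heuristic(self):
        """Two equal-noise independent genes without group effects:
        averaging halves the noise variance, so the pair's value should
        approach the single SV / sqrt(2) at large n."""
        r = np.random.default_rng(42)
        k, n = 6, 4000
        cq = 20 + r.normal(0, 0.5, (k, n))
        z, d = _z_and_design(cq, 2)
        s2 = intragroup_variance(z, d)
        single_sv = np.sqrt(s2.mean(axis=1))
        z2 = z.drop(index=["G1", "G2"])
        z2.loc["G1+G2"] = (z.loc["G1"] + z.loc["G2"]) / 2
        z2 = z2 - z2.mean(axis=0)
        s2p = intragroup_variance(z2, d)
        pair_s2 = s2p.loc["G1+G2"].mean()
        expected = (single_sv["G1"] ** 2 + single_sv["G2"] ** 2) / 4
        assert pair_s2 == pytest.approx(expected, rel=0.15)

    def test_exhaustive_search_matches_enumeration(self, rng):
        cq = 20 + rng.normal(0, 0.4, (5, 30))
        cq[1, 15:] += 0.6
        z, d = _z_and_design(cq, 2)
        pair, sd = best_combination(z, d)
        # independent enumeration via the brute-force oracle
        from itertools import combinations

        best = (None, np.inf)
        for g1, g2 in combinations(sorted(z.index), 2):
            z2 = z.drop(index=[g1, g2])
            z2.loc["pseudo"] = (z.loc[g1] + z.loc[g2]) / 2
            z2 = z2 - z2.mean(axis=0)
            zd = {g: dict(z2.loc[g]) for g in z2.index}
            _, _, _, sv = oracles.normfinder_components(zd, d.groups)
            if sv["pseudo"] < best[1]:
                best = ((g1, g2), sv["pseudo"])
        assert pair == best[0]
        assert sd == pytest.approx(best[1], abs=1e-12)


class TestAnalyzeFacade:
    def test_single_group_is_sqrt_sigma(self, rng):
        t = make_cq(20 + rng.normal(0, 0.4, (5, 16)))
        res = analyze(t)
        assert res.mode == "single"
        np.testing.assert_allclose(
            res.sv.to_numpy(), np.sqrt(res.sigma2.iloc[:, 0].to_numpy()), atol=1e-12
        )

    def test_grouped_run_with_best_pair(self, rng):
        cq = 20 + rng.normal(0, 0.3, (5, 24))
        cq[0, :12] += 0.8
        t = make_cq(cq)
        d = GroupDesign("g", {"a": t.samples[:12], "b": t.samples[12:]})
        res = analyze(t, d, with_best_pair=True)
        assert res.mode == "grouped"
        assert res.best_pair is not None and res.best_pair_sd >= 0
        assert res.ranks[res.best_gene] == 1
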
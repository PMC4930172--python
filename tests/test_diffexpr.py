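"""Moderated-t differential expression, BH adjustment, SDE calling and ranking."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import naive_bh, naive_pooled_t

from conftest import make_matrix, small_config
from ffl_dynamics.diffexpr import (
    DEConfig,
    bh_adjust,
    call_sde,
    fit_scaled_chisq_prior,
    moderated_t_test,
    sde_summary,
    top_k,
)
from ffl_dynamics.synthetic import simulate_expression


def two_group_matrix(rng, n_genes=20, n1=5, n2=7, sd_range=(0.3, 1.2)):
    sd = rng.uniform(*sd_range, n_genes)
    base = rng.normal(8, 1.5, n_genes)
    vals = base[:, None] + rng.normal(0, 1, (n_genes, n1 + n2)) * sd[:, None]
    return make_matrix(vals, ["case"] * n1 + ["control"] * n2, [1] * n1 + [None] * n2), vals


class TestModeratedT:
    def test_ordinary_mode_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        m, vals = two_group_matrix(rng)
        table = moderated_t_test(m, 1, DEConfig(moderation="ordinary"))
        for i, g in enumerate(table.index):
            expected = naive_pooled_t(vals[i, :5], vals[i, 5:])
            assert abs(table.loc[g, "t"] - expected) < 1e-10

    def test_matches_limma(self, tmp_path):
        """Moderated t, p and prior df agree with the R limma reference."""
        rng = np.random.default_rng(42)
        n_genes, n1, n2 = 200, 6, 6
        sd = rng.uniform(0.2, 1.5, n_genes)
        base = rng.normal(8, 1.5, n_genes)
        vals = base[:, None] + rng.normal(0, 1, (n_genes, n1 + n2)) * sd[:, None]
        vals[:20, :n1] += 1.0
        m = make_matrix(vals, ["case"] * n1 + ["control"] * n2, [1] * n1 + [None] * n2)
        table = moderated_t_test(m, 1)

        fix = tmp_path / "fix.tsv"
        out = tmp_path / "limma_out.tsv"
        pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)]).to_csv(fix, sep="\t")
        script = tmp_path / "run.R"
        script.write_text(
            f"""
            library(limma)
            x <- as.matrix(read.delim("{fix}", row.names=1))
            design <- cbind(Intercept=1, Case=c(rep(1,{n1}), rep(0,{n2})))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"Case"], p=fit$p.value[,"Case"], d0=fit$df.prior)
            write.table(out, "{out}", sep="\\t", quote=FALSE)
            """
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t")
        np.testing.assert_allclose(table["t"].to_numpy(), ref["t"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(table["p"].to_numpy(), ref["p"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(table["d0"].iloc[0], ref["d0"].iloc[0], rtol=1e-8)

    def test_identical_groups_null_gene(self):
        vals = np.array([[5.0, 5.0, 5.0, 5.0], [5.0, 6.0, 5.0, 6.0]])
        m = make_matrix(vals, ["case", "case", "control", "control"], [1, 1, None, None])
        table = moderated_t_test(m, 1, DEConfig(moderation="ordinary"))
        assert table.iloc[0]["log2fc"] == 0
        assert table.iloc[0]["t"] == 0 and table.iloc[0]["p"] == 1.0

    def test_homogeneous_variances_give_infinite_prior(self):
        """When all gene variances look alike, shrinkage goes all the way to s0."""
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1.0, (300, 12)) + rng.normal(8, 1.5, (300, 1))
        m = make_matrix(vals, ["case"] * 6 + ["control"] * 6, [1] * 6 + [None] * 6)
        table = moderated_t_test(m, 1)
        d0 = table["d0"].iloc[0]
        if np.isinf(d0):
            assert table["s2_post"].nunique() == 1
        else:
            assert d0 > 50  # heavy shrinkage either way

    def test_prior_fit_recovers_known_d0(self):
        # variances drawn from s0^2 * d0 / chi2(d0): moment matching should
        # approximately recover the generating parameters
        rng = np.random.default_rng(1)
        d0_true, s0_true, df = 4.0, 0.5, 10
        s2 = s0_true * d0_true / rng.chisquare(d0_true, 20000) * rng.chisquare(df, 20000) / df
        d0, s0 = fit_scaled_chisq_prior(s2, df)
        assert abs(d0 - d0_true) / d0_true < 0.15
        assert abs(s0 - s0_true) / s0_true < 0.1

    def test_too_few_samples_raise(self):
        m = make_matrix(np.ones((3, 3)), ["case", "control", "control"], [1, None, None])
        with pytest.raises(ValueError, match=">=2"):
            moderated_t_test(m, 1)


class TestBH:
    def test_known_values(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_matches_statsmodels_and_naive(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random(rng.integers(1, 50))
            mine = bh_adjust(p)
            _, sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(mine, sm, atol=1e-12)
            np.testing.assert_allclose(mine, naive_bh(p), atol=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_properties(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)  # adjusted >= raw
        assert np.all((q >= 0) & (q <= 1))
        # monotone in raw-p rank order
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestSDECalling:
    def make_table(self, adj_p, lfc):
        return pd.DataFrame(
            {"adj_p": adj_p, "log2fc": lfc, "fold_change": np.exp2(np.abs(lfc))},
            index=[f"g{i}" for i in range(len(adj_p))],
        )

    def test_strict_thresholds(self):
        t = self.make_table(
            [0.0005, 0.0005, 0.001, 0.0005],
            [np.log2(1.3), np.log2(1.1), np.log2(1.3), -np.log2(1.3)],
        )
        assert call_sde(t) == {"g0", "g3"}  # g1 fails FC, g2 fails strict p, g3 down-regulated ok

    def test_fc_boundary_strict(self):
        t = self.make_table([0.0001], [np.log2(1.2)])
        assert call_sde(t) == set()


class TestSummaryAndRanking:
    def test_set_algebra(self):
        t1 = TestSDECalling().make_table([1e-5, 1e-5, 0.5], [1.0, 1.0, 1.0])
        t2 = TestSDECalling().make_table([1e-5, 0.5, 1e-5], [1.0, 1.0, 1.0])
        s = sde_summary({1: t1, 2: t2})
        assert s["per_stage"] == {1: 2, 2: 2}
        assert s["union"] == 3
        assert s["intersection"] == {"g0"}

    def test_identical_and_disjoint(self):
        t = TestSDECalling().make_table([1e-5, 1e-5], [1.0, 1.0])
        s = sde_summary({1: t, 2: t.copy()})
        assert s["union"] == len(s["intersection"]) == 2

    def test_top_k_sort_oracle(self):
        rng = np.random.default_rng(9)
        n = 50
        tables = {}
        for s in (1, 2):
            tables[s] = pd.DataFrame(
                {
                    "adj_p": rng.random(n) * 1e-3,
                    "log2fc": rng.normal(0, 2, n),
                },
                index=[f"g{i:02d}" for i in range(n)],
            )
            tables[s]["fold_change"] = np.exp2(np.abs(tables[s]["log2fc"]))
        got = top_k(tables, 10)
        # independent sort on (min adj p, -max |lfc|, id)
        keys = {}
        for g in tables[1].index:
            keys[g] = (
                min(tables[1].loc[g, "adj_p"], tables[2].loc[g, "adj_p"]),
                -max(abs(tables[1].loc[g, "log2fc"]), abs(tables[2].loc[g, "log2fc"])),
                g,
            )
        cands = set().union(*(call_sde(t) for t in tables.values()))
        expected = sorted(cands, key=lambda g: keys[g])[:10]
        assert got == expected

    def test_top_k_truncates_with_warning(self, caplog):
        t = TestSDECalling().make_table([1e-5, 1e-5], [1.0, 1.0])
        assert len(top_k({1: t}, 10)) == 2


class TestRecovery:
    def test_planted_gene_recovery(self):
        """Power at the study design: most planted DE genes are recalled."""
        cfg = small_config(n_genes=1000, n_controls=14, n_cases_per_stage=28,
                           frac_de_per_stage=0.1, de_log2fc=1.0, noise_sd=0.5, seed=21)
        expr, truth = simulate_expression(cfg)
        table = moderated_t_test(expr, 1)
        called = call_sde(table)
        de = truth.de_genes_per_stage[1]
        recall = len(called & de) / len(de)
        fdp = len(called - de) / max(len(called), 1)
        assert recall >= 0.9
        assert fdp <= 0.05

    def test_sde_probability_monotone_in_effect_size(self):
        """Larger planted fold changes never hurt recovery (Monte-Carlo grid)."""
        recalls = []
        for lfc in (0.4, 0.8, 1.4):
            hits = total = 0
            for seed in range(4):
                cfg = small_config(n_genes=300, frac_de_per_stage=0.1, de_log2fc=lfc,
                                   noise_sd=0.5, n_planted_ffls=2, seed=100 + seed)
                expr, truth = simulate_expression(cfg)
                called = call_sde(moderated_t_test(expr, 1))
                de = truth.de_genes_per_stage[1]
                hits += len(called & de)
                total += len(de)
            recalls.append(hits / total)
        assert recalls[0] <= recalls[1] + 0.02 <= recalls[2] + 0.04
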
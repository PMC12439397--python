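"""Moderated-t differential expression: eligibility, OLS, shrinkage, FDR.

The empirical-Bayes fixture values below were computed with the reference
Bioconductor implementation of the moderated t (limma 3.58.1) on the exact
matrix rebuilt here from a fixed generator seed.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctbulk.containers import PseudobulkTensor
from ctbulk.diffexp import (DesignSpec, bh_fdr, ebayes_moderate,
                            eligible_genes, fit_linear_models, run_de,
                            top_signature_genes, trigamma_inverse)


def tensor_from_frame(frame: pd.DataFrame, groups: pd.Series,
                      min_cells: int = 10) -> PseudobulkTensor:
    support = pd.DataFrame(np.where(frame.isna(), 0, min_cells),
                           index=frame.index, columns=frame.columns)
    return PseudobulkTensor({"ct": frame}, {"ct": support}, groups,
                            min_cells=min_cells)


@pytest.fixture()
def limma_fixture():
    """120 genes, 5v5, first 10 genes shifted by 1; matches the frozen
    reference values."""
    rng = np.random.default_rng(42)
    G, nA, nB = 120, 5, 5
    sigma2 = 0.25 * 4 / rng.chisquare(4, G)
    Y = rng.normal(0, np.sqrt(sigma2)[:, None], size=(G, nA + nB))
    Y[:10, nA:] += 1.0
    pats = [f"A{i}" for i in range(nA)] + [f"B{i}" for i in range(nB)]
    frame = pd.DataFrame(Y, index=[f"G{i}" for i in range(G)], columns=pats)
    groups = pd.Series(["A"] * nA + ["B"] * nB, index=pats)
    return frame, groups


class TestEligibility:
    def _tensor(self):
        pats = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(10)]
        groups = pd.Series(["A"] * 4 + ["B"] * 10, index=pats)
        frame = pd.DataFrame(1.0, index=["G0", "G1"], columns=pats)
        frame.loc["G0", "A3"] = np.nan  # only 3 A patients
        return tensor_from_frame(frame, groups)

    def test_four_patient_rule(self):
        pb = self._tensor()
        d4 = DesignSpec(groups=pb.groups, min_patients_per_group=4)
        assert eligible_genes(pb, "ct", d4) == ["G1"]

    def test_three_patient_variant(self):
        pb = self._tensor()
        d3 = DesignSpec(groups=pb.groups, min_patients_per_group=3)
        assert eligible_genes(pb, "ct", d3) == ["G0", "G1"]

    def test_fully_observed_all_eligible(self):
        pats = ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4"]
        frame = pd.DataFrame(np.ones((5, 8)),
                             index=[f"G{i}" for i in range(5)], columns=pats)
        pb = tensor_from_frame(frame,
                               pd.Series(["A"] * 4 + ["B"] * 4, index=pats))
        assert len(eligible_genes(pb, "ct",
                                  DesignSpec(groups=pb.groups))) == 5


class TestLinearModels:
    def test_two_group_closed_form(self, limma_fixture):
        frame, groups = limma_fixture
        pb = tensor_from_frame(frame, groups)
        fits = fit_linear_models(pb, "ct", DesignSpec(groups=groups))
        a_cols = groups.index[groups == "A"]
        b_cols = groups.index[groups == "B"]
        for g in frame.index[:20]:
            diff = frame.loc[g, b_cols].mean() - frame.loc[g, a_cols].mean()
            assert fits.loc[g, "coef"] == pytest.approx(diff, abs=1e-12)
            assert fits.loc[g, "log2fc"] == pytest.approx(
                diff / np.log(2), abs=1e-12)

    def test_orthogonal_covariate_leaves_coef(self, limma_fixture):
        frame, groups = limma_fixture
        # balanced binary covariate orthogonal to group
        cov = pd.DataFrame(
            {"treated": [0, 0, 1, 1, 0] [:5] + [0, 0, 1, 1, 0][:5]},
            index=groups.index, dtype=float)
        cov.iloc[:, 0] = [1, 1, 0, 0, 0, 1, 1, 0, 0, 0]
        pb = tensor_from_frame(frame, groups)
        plain = fit_linear_models(pb, "ct", DesignSpec(groups=groups))
        with_cov = fit_linear_models(
            pb, "ct", DesignSpec(groups=groups, covariates=cov))
        assert np.allclose(plain["coef"], with_cov["coef"], atol=1e-10)

    def test_missing_patients_row_deletion(self):
        pats = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=pats)
        frame = pd.DataFrame([[1, 2, 3, 4, np.nan, 5, 6, 7, 8, np.nan]],
                             index=["G0"], columns=pats, dtype=float)
        pb = tensor_from_frame(frame, groups)
        fits = fit_linear_models(pb, "ct", DesignSpec(groups=groups))
        assert fits.loc["G0", "n_A"] == 4 and fits.loc["G0", "n_B"] == 4
        assert fits.loc["G0", "coef"] == pytest.approx(6.5 - 2.5)


class TestEbayes:
    def test_d0_zero_equals_ordinary_t(self, limma_fixture):
        """With moderation disabled the statistic must equal the classical
        two-sample regression t to 1e-10."""
        frame, groups = limma_fixture
        pb = tensor_from_frame(frame, groups)
        res = run_de(pb, DesignSpec(groups=groups), d0_override=0.0)
        a_cols = groups.index[groups == "A"]
        b_cols = groups.index[groups == "B"]
        for g in frame.index:
            row = res.table[res.table.gene == g].iloc[0]
            t_ref, _ = stats.ttest_ind(frame.loc[g, b_cols],
                                       frame.loc[g, a_cols], equal_var=True)
            assert row["t"] == pytest.approx(float(t_ref), abs=1e-10)

    def test_d0_inf_complete_shrinkage(self, limma_fixture):
        frame, groups = limma_fixture
        pb = tensor_from_frame(frame, groups)
        fits = fit_linear_models(pb, "ct", DesignSpec(groups=groups))
        d0, s0, s2_post = ebayes_moderate(fits["s2"].to_numpy(),
                                          fits["df"].to_numpy(),
                                          d0_override=np.inf)
        assert np.allclose(s2_post, s0)

    def test_matches_limma_reference(self, limma_fixture):
        frame, groups = limma_fixture
        pb = tensor_from_frame(frame, groups)
        res = run_de(pb, DesignSpec(groups=groups))
        d0, s0 = res.priors["ct"]
        assert d0 == pytest.approx(4.4274551040, abs=1e-6)
        assert s0 == pytest.approx(0.2749349080, abs=1e-7)
        expected = {
            "G0": (2.4512688340, 0.02990360306),
            "G1": (2.0368212090, 0.0635513289),
            "G2": (5.3111935235, 0.0001643032174),
            "G50": (1.0398091434, 0.318236585),
            "G119": (-1.4120582541, 0.1824802324),
        }
        tab = res.table.set_index("gene")
        for g, (t_exp, p_exp) in expected.items():
            assert tab.loc[g, "t"] == pytest.approx(t_exp, abs=1e-6)
            assert tab.loc[g, "p"] == pytest.approx(p_exp, rel=1e-5)

    def test_hyperparameter_recovery(self):
        """(d0, s0^2) recovered from 5,000 scaled-F variances."""
        rng = np.random.default_rng(123)
        G, d0_true, s0_true, d_g = 5000, 4.0, 0.25, 10.0
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, G)
        s2 = sigma2 * rng.chisquare(d_g, G) / d_g
        d0, s0, _ = ebayes_moderate(s2, np.full(G, d_g))
        assert abs(d0 - d0_true) / d0_true <= 0.25
        assert abs(s0 - s0_true) / s0_true <= 0.10

    def test_identical_variances_infinite_d0(self):
        d0, s0, s2_post = ebayes_moderate(np.full(50, 0.3), np.full(50, 8.0))
        assert np.isinf(d0)
        assert np.allclose(s2_post, s0)

    def test_trigamma_inverse_roundtrip(self):
        from scipy import special
        for x in (0.1, 0.7, 2.0, 15.0, 300.0):
            y = float(special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestBH:
    def test_hand_computed(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])
        assert bh_fdr([0.02]) == pytest.approx([0.02])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(8)

        def brute(p):
            n = len(p)
            q = np.empty(n)
            for i, pi in enumerate(p):
                # q_i = min over thresholds t >= p_i of t*n/#{p <= t}
                cands = [pj * n / (p <= pj).sum() for pj in p if pj >= pi]
                q[i] = min(1.0, min(cands))
            return q

        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_properties_hold_for_arbitrary_p(self, p):
        q = bh_fdr(p)
        p = np.asarray(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p-rank


class TestRunDE:
    def test_eligibility_shrinks_tested_set(self, limma_fixture):
        frame, groups = limma_fixture
        drop = groups.index[groups == "B"][:3]
        frame2 = frame.copy()
        frame2.loc[frame2.index[:30], drop] = np.nan  # 30 genes lose 3 B pats
        pb = tensor_from_frame(frame2, groups)
        res = run_de(pb, DesignSpec(groups=groups, min_patients_per_group=4))
        tested = set(res.table.gene)
        assert all(f"G{i}" not in tested for i in range(30))
        assert len(tested) == 90

    def test_summary_counts_direction(self, limma_fixture):
        frame, groups = limma_fixture
        pb = tensor_from_frame(frame, groups)
        res = run_de(pb, DesignSpec(groups=groups))
        row = res.summary[(res.summary.fdr_cutoff == 0.05)].iloc[0]
        assert row.n_significant == row.n_up + row.n_down
        assert row.n_tested == 120


class TestSignature:
    def test_tie_break_deterministic(self):
        table = pd.DataFrame({
            "cell_type": "ct",
            "gene": ["Gb", "Ga", "Gc", "Gd"],
            "p": [0.01, 0.01, 0.01, 0.5],
            "t": [2.0, -3.0, 2.0, 1.0],
        })
        de = type("DE", (), {})()
        from ctbulk.containers import DEResult
        de = DEResult(table=table, priors={"ct": (1.0, 1.0)})
        # ties on p break by |t| desc then gene id
        assert top_signature_genes(de, "ct", 3) == ["Ga", "Gb", "Gc"]
        assert top_signature_genes(de, "ct", 1) == ["Ga"]

    def test_k_larger_than_tested(self):
        from ctbulk.containers import DEResult
        table = pd.DataFrame({"cell_type": "ct", "gene": ["G1", "G2"],
                              "p": [0.1, 0.2], "t": [1.0, 0.5]})
        de = DEResult(table=table, priors={"ct": (1.0, 1.0)})
        with pytest.warns(UserWarning):
            assert top_signature_genes(de, "ct", 5) == ["G1", "G2"]

    def test_unknown_cell_type_errors(self):
        from ctbulk.containers import DEResult
        de = DEResult(table=pd.DataFrame(columns=["cell_type", "gene"]),
                      priors={})
        with pytest.raises(KeyError):
            top_signature_genes(de, "nope", 5)
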
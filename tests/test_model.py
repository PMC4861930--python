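import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wsppq import (QuantTable, SimConfig, aggregate_peptides, aggregate_proteins,
                   compute_spectrum_ratios, estimate_sigma2, fit_spectrum_variance,
                   generate, run_wspp, standardize)
from wsppq.errors import ConfigError, EmptyInputError, EstimationError
from wsppq.model import apply_spectrum_variance

from conftest import CHANNELS, CHANNEL_MAP


def _spectra_frame(x_s, w_s, peptide_key=None, protein_id=None):
    n = len(x_s)
    return pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(n)],
        "peptide_key": peptide_key or ["PEP/2"] * n,
        "protein_id": protein_id or ["P1"] * n,
        "x_s": x_s, "w_s": w_s, "v_s": [1.0 / w for w in w_s],
        "I_A": 1.0, "I_B": 1.0,
    })


# ---------------------------------------------------------------------------
# spectrum ratios
# ---------------------------------------------------------------------------

class TestSpectrumRatios:
    def test_exact_log2_ratios(self, small_table, design):
        r = compute_spectrum_ratios(small_table, design, ("G2", "G1"))
        got = dict(zip(r.data["protein_id"], r.data["x_s"]))
        assert got == {"P0": 0.0, "P1": 1.0, "P2": -1.0}
        # cohort intensities are summed channel intensities
        assert np.allclose(r.data.sort_values("protein_id")["I_B"], 2000.0)

    def test_zero_intensity_side_dropped_and_counted(self, design):
        rows = []
        for i in range(5):
            row = {"spectrum_id": f"s{i}", "peptide_key": f"K{i}/2",
                   "protein_id": f"P{i}"}
            for ch in CHANNELS:
                row[ch] = 1000.0
            rows.append(row)
        rows[2]["113"] = rows[2]["114"] = 0.0  # kills the reference side
        table = QuantTable(pd.DataFrame(rows), CHANNELS)
        r = compute_spectrum_ratios(table, design, ("G2", "G1"))
        assert len(r.data) == 4 and r.n_dropped == 1
        assert "s2" not in set(r.data["spectrum_id"])

    def test_unmapped_cohort_is_config_error(self, small_table, design):
        with pytest.raises(ConfigError):
            compute_spectrum_ratios(small_table, design, ("G2", "NOPE"))

    def test_all_dropped_is_empty_input_error(self, design):
        rows = [{"spectrum_id": "s0", "peptide_key": "K/2", "protein_id": "P",
                 **{ch: 0.0 if CHANNEL_MAP[ch] == "G1" else 1.0 for ch in CHANNELS}}]
        table = QuantTable(pd.DataFrame(rows), CHANNELS)
        with pytest.raises(EmptyInputError):
            compute_spectrum_ratios(table, design, ("G2", "G1"))


# ---------------------------------------------------------------------------
# spectrum variance calibration
# ---------------------------------------------------------------------------

class TestSpectrumVariance:
    def test_parameter_recovery(self, null_dataset):
        ds = null_dataset
        r = compute_spectrum_ratios(ds.table, ds.design, ("G2", "G1"))
        assert len(r.data) >= 5000
        k = fit_spectrum_variance(r.data)
        assert abs(k / ds.truth.config.k_spec - 1.0) < 0.15

    def test_scale_equivariance(self, null_dataset):
        ds = null_dataset
        r = compute_spectrum_ratios(ds.table, ds.design, ("G2", "G1"))
        k1 = fit_spectrum_variance(r.data)
        doubled = r.data.copy()
        doubled[["I_A", "I_B"]] *= 2.0  # halves u = 1/I_A + 1/I_B
        k2 = fit_spectrum_variance(doubled)
        assert k2 == pytest.approx(2.0 * k1, rel=1e-9)
        w1 = apply_spectrum_variance(r.data, k1)["w_s"]
        w2 = apply_spectrum_variance(doubled, k2)["w_s"]
        assert np.allclose(w1, w2)

    def test_identical_duplicates_are_degenerate(self):
        df = pd.DataFrame({
            "spectrum_id": [f"s{i}" for i in range(100)],
            "peptide_key": [f"K{i // 2}/2" for i in range(100)],
            "protein_id": "P1", "x_s": 0.3, "I_A": 1000.0, "I_B": 1000.0,
        })
        with pytest.raises(EstimationError, match="degenerate"):
            fit_spectrum_variance(df)

    def test_too_few_replicates(self):
        df = pd.DataFrame({
            "spectrum_id": ["a", "b"], "peptide_key": ["K/2", "K/2"],
            "protein_id": "P1", "x_s": [0.0, 1.0],
            "I_A": 1000.0, "I_B": 1000.0,
        })
        with pytest.raises(EstimationError, match="fixed k"):
            fit_spectrum_variance(df)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregation:
    def test_singleton_peptide(self):
        peps = aggregate_peptides(_spectra_frame([0.7], [2.5]))
        assert peps.loc[0, "x_p"] == 0.7
        assert peps.loc[0, "W_p_within"] == 2.5
        assert peps.loc[0, "n_spectra"] == 1

    def test_hand_computed_weighted_mean(self):
        peps = aggregate_peptides(_spectra_frame([0.0, 1.0], [1.0, 3.0]))
        assert peps.loc[0, "x_p"] == pytest.approx(0.75, abs=1e-15)
        assert peps.loc[0, "W_p_within"] == pytest.approx(4.0)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equal_weights_reduce_to_mean_and_stay_in_hull(self, xs):
        peps = aggregate_peptides(_spectra_frame(xs, [2.0] * len(xs)))
        x_p = peps.loc[0, "x_p"]
        assert x_p == pytest.approx(np.mean(xs), abs=1e-12)
        assert min(xs) - 1e-12 <= x_p <= max(xs) + 1e-12

    def test_protein_limit_cases_and_hand_fixture(self):
        peps = pd.DataFrame({
            "protein_id": "Q", "peptide_key": ["a/2", "b/2", "c/2"],
            "x_p": [0.0, 0.5, 1.0], "W_p_within": [1.0, 2.0, 4.0],
            "n_spectra": 1,
        })
        # sigma2_P = 0: pure inverse-variance weights
        prot = aggregate_proteins(peps, 0.0)
        expect = (1 * 0.0 + 2 * 0.5 + 4 * 1.0) / 7.0
        assert prot.loc[0, "x_q"] == pytest.approx(expect, abs=1e-12)
        assert prot.loc[0, "W_q_within"] == pytest.approx(7.0)
        # sigma2_P -> inf: weights equalize, unweighted mean
        prot_inf = aggregate_proteins(peps, 1e9)
        assert prot_inf.loc[0, "x_q"] == pytest.approx(0.5, abs=1e-6)

    def test_adding_a_spectrum_never_decreases_weight(self):
        base = aggregate_peptides(_spectra_frame([0.1, 0.4], [1.0, 2.0]))
        more = aggregate_peptides(_spectra_frame([0.1, 0.4, -3.0], [1.0, 2.0, 0.5]))
        assert more.loc[0, "W_p_within"] >= base.loc[0, "W_p_within"]


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

class TestEstimateSigma2:
    def test_zero_residuals_clip_to_zero(self):
        x = np.zeros(40)
        assert estimate_sigma2(x, x, np.ones(40) * 3.0) == 0.0

    def test_matches_grid_search(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0.5, 20.0, size=60)
        true_s2 = 0.04
        child = rng.normal(0.0, np.sqrt(1.0 / w + true_s2))
        s2 = estimate_sigma2(child, np.zeros(60), w, n_eff=59)
        grid = np.arange(0.0, 0.2, 1e-6)
        vals = np.abs((child[None, :] ** 2 / (1.0 / w[None, :] + grid[:, None])
                       ).sum(axis=1) - 59)
        s2_grid = grid[np.argmin(vals)]
        assert abs(s2 - s2_grid) < 1e-5

    def test_too_few_pairs(self):
        with pytest.raises(EstimationError):
            estimate_sigma2([0.1] * 5, [0.0] * 5, [1.0] * 5)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def _protein_frame(x_q, W, ids=None):
    n = len(x_q)
    return pd.DataFrame({
        "protein_id": ids or [f"P{i}" for i in range(n)],
        "x_q": x_q, "W_q_within": W, "n_peptides": 1, "n_spectra": 1,
    })


class TestStandardize:
    def test_protein_at_grand_mean_has_zero_zq(self):
        res = standardize(_protein_frame([0.5, 0.5, 0.5], [1.0, 2.0, 3.0]), 0.0)
        assert np.allclose(res.proteins["Zq"], 0.0)

    def test_equal_weight_closed_form(self):
        # with equal weights W and sigma2_Q = 0, Zq = (x - mean(x)) * sqrt(W)
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        res = standardize(_protein_frame(x, np.full(200, 7.0)), 0.0)
        expect = (x - x.mean()) * math.sqrt(7.0)
        assert np.allclose(res.proteins["Zq"], expect, atol=1e-9)

    def test_conservation_invariant(self, null_result):
        df = null_result.included
        balance = float((df["Wq"] * df["Xprime_q"]).sum())
        assert abs(balance) <= 1e-8 * float(df["Wq"].sum())

    def test_excluded_get_zq_but_not_grand_mean(self):
        frame = _protein_frame([0.0, 0.0, 5.0], [1.0, 1.0, 1.0])
        res = standardize(frame, 0.0, exclusions={"P2"})
        assert res.grand_mean == pytest.approx(0.0)
        p2 = res.proteins.set_index("protein_id").loc["P2"]
        assert p2["excluded_flag"] and p2["Zq"] == pytest.approx(5.0)
        assert res.gof["n"] == 2

    def test_all_excluded_raises(self):
        with pytest.raises(EmptyInputError):
            standardize(_protein_frame([0.0, 1.0], [1.0, 1.0]), 0.0,
                        exclusions={"P0", "P1"})


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

class TestRunWspp:
    def test_tiny_fixture_matches_hand_computation(self, tiny):
        e = tiny.expected
        res = run_wspp(tiny.table, tiny.design, ("G2", "G1"),
                       k=e["k"], sigma2_P=e["sigma2_P"], sigma2_Q=e["sigma2_Q"])
        got = res.proteins.set_index("protein_id")
        for pid in ("P1", "P2", "P3"):
            assert got.loc[pid, "x_q"] == pytest.approx(e["x_q"][pid], abs=1e-12)
            assert got.loc[pid, "W_q_within"] == pytest.approx(
                e["W_q_within"][pid], abs=1e-12)
            assert got.loc[pid, "Zq"] == pytest.approx(e["Zq"][pid], abs=1e-12)
        assert res.grand_mean == pytest.approx(e["grand_mean"], abs=1e-12)

    def test_deterministic_and_permutation_invariant(self, null_dataset):
        ds = null_dataset
        res1 = run_wspp(ds.table, ds.design, ("G2", "G1"), ds.exclusions)
        res2 = run_wspp(ds.table, ds.design, ("G2", "G1"), ds.exclusions)
        pd.testing.assert_frame_equal(res1.proteins, res2.proteins)

        rng = np.random.default_rng(99)
        shuffled = QuantTable(
            ds.table.data.sample(frac=1.0, random_state=rng.integers(2**31))
                         .reset_index(drop=True),
            ds.table.channel_ids)
        res3 = run_wspp(shuffled, ds.design, ("G2", "G1"), ds.exclusions)
        z1 = res1.proteins.set_index("protein_id")["Zq"]
        z3 = res3.proteins.set_index("protein_id")["Zq"]
        assert float((z1 - z3).abs().max()) < 1e-9

    def test_null_calibration_single_seed(self, null_result):
        g = null_result.gof
        assert -0.05 < g["mean"] < 0.05
        assert 0.9 < g["sd"] < 1.1
        z = null_result.included["Zq"]
        assert 0.03 < float((z.abs() >= 2).mean()) < 0.06

    def test_three_comparison_design_yields_three_results(self):
        from wsppq import run_study
        ds = generate(SimConfig(n_proteins=300, n_null_categories=0,
                                n_planted_categories=0, seed=4))
        study = run_study(ds.table, ds.design, ds.exclusions)
        assert len(study.comparisons) == 3
        assert set(study.comparisons) == {"G2_vs_G1", "G3_vs_G1", "G4_vs_G3"}
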
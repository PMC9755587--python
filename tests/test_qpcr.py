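import numpy as np
import pandas as pd
import pytest

from coexq import (
    CqTable,
    CqValidationError,
    PlateSimConfig,
    aggregate_technical,
    delta_delta_ct,
    efficiency_from_slope,
    fit_standard_curve,
    qc_standard_curve,
    quantify,
    simulate_plate,
)
from coexq.qpcr import StandardCurveFit, fit_standard_curves

DOUBLING_SLOPE = -1.0 / np.log10(2.0)  # -3.3219...: perfect doubling


def make_cq_table(cq_map, refs=("RCE1", "TUA2", "YLS8"), n_tech=1):
    """Build a CqTable from {(sample, gene, bio_rep): cq}; refs fixed."""
    rows = []
    for (sample, gene, bio), cq in cq_map.items():
        for t in range(1, n_tech + 1):
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "role": "reference" if gene in refs else "target",
                    "bio_rep": bio,
                    "tech_rep": t,
                    "cq": cq,
                }
            )
    return CqTable(pd.DataFrame(rows))


class TestStandardCurve:
    def test_perfect_doubling_chemistry(self):
        x = [-1.0, -2.0, -3.0]
        y = [20.0 + DOUBLING_SLOPE * d for d in x]
        fit = fit_standard_curve(x, y)
        assert fit.slope == pytest.approx(DOUBLING_SLOPE, rel=1e-12)
        assert fit.efficiency_pct == pytest.approx(100.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_efficiency_at_slope_minus_3_6(self):
        # frozen from a high-precision evaluation of 10^(1/3.6) - 1
        assert efficiency_from_slope(-3.6) == pytest.approx(89.5735652, abs=1e-6)

    @pytest.mark.parametrize("k", [2.0, 1.9, 2.1])
    def test_efficiency_closed_form_round_trip(self, k):
        # slope = -1/log10(k)  =>  E = (k - 1) * 100 exactly
        assert efficiency_from_slope(-1.0 / np.log10(k)) == pytest.approx(
            (k - 1.0) * 100.0, abs=1e-9
        )

    def test_translation_invariance_of_slope(self):
        rng = np.random.default_rng(3)
        x = np.array([-1.0, -2.0, -3.0, -1.0, -2.0, -3.0])
        y = 21.0 - 3.4 * x + rng.normal(0, 0.15, size=6)
        f1 = fit_standard_curve(x, y)
        f2 = fit_standard_curve(x, y + 5.0)
        assert f2.slope == pytest.approx(f1.slope, rel=1e-12)
        assert f2.r_squared == pytest.approx(f1.r_squared, rel=1e-12)
        assert f2.efficiency_pct == pytest.approx(f1.efficiency_pct, rel=1e-12)
        assert f2.intercept == pytest.approx(f1.intercept + 5.0, rel=1e-9)

    def test_too_few_or_degenerate_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_standard_curve([-1, -2], [20, 23])
        with pytest.raises(ValueError, match="singular"):
            fit_standard_curve([-1, -1, -1], [20, 20.1, 19.9])

    def test_fit_per_gene_table(self):
        df = pd.DataFrame(
            {
                "gene": ["A"] * 3 + ["B"] * 3,
                "log10_dilution": [-1, -2, -3] * 2,
                "cq": [23.3, 26.6, 29.9, 20.0, 23.6, 27.2],
            }
        )
        fits = fit_standard_curves(df)
        assert [f.gene_id for f in fits] == ["A", "B"]
        assert fits[1].slope == pytest.approx(-3.6, rel=1e-9)


class TestCurveQC:
    def test_interior_point_passes(self):
        fit = StandardCurveFit("g", DOUBLING_SLOPE, 20.0, 0.999, 100.0)
        assert qc_standard_curve(fit).passed

    def test_low_efficiency_fails_with_reason(self):
        fit = StandardCurveFit("g", -3.6, 20.0, 0.999, efficiency_from_slope(-3.6))
        verdict = qc_standard_curve(fit)
        assert not verdict.passed
        assert any("efficiency" in r for r in verdict.reasons)
        assert not any("R^2" in r for r in verdict.reasons)

    def test_low_r_squared_fails_with_reason(self):
        fit = StandardCurveFit("g", DOUBLING_SLOPE, 20.0, 0.975, 100.0)
        verdict = qc_standard_curve(fit)
        assert not verdict.passed
        assert any("R^2" in r for r in verdict.reasons)


class TestCqTableValidation:
    def test_duplicate_record_rejected(self):
        rows = pd.DataFrame(
            {
                "sample": ["s1", "s1", "s1"],
                "gene": ["T", "T", "R"],
                "role": ["target", "target", "reference"],
                "bio_rep": [1, 1, 1],
                "tech_rep": [1, 1, 1],
                "cq": [20.0, 20.1, 18.0],
            }
        )
        with pytest.raises(CqValidationError, match="duplicate"):
            CqTable(rows)

    def test_empty_reference_set_rejected(self):
        rows = pd.DataFrame(
            {
                "sample": ["s1"],
                "gene": ["T"],
                "role": ["target"],
                "bio_rep": [1],
                "tech_rep": [1],
                "cq": [20.0],
            }
        )
        with pytest.raises(CqValidationError, match="reference"):
            CqTable(rows)

    def test_non_positive_cq_rejected(self):
        rows = pd.DataFrame(
            {
                "sample": ["s1", "s1"],
                "gene": ["T", "R"],
                "role": ["target", "reference"],
                "bio_rep": [1, 1],
                "tech_rep": [1, 1],
                "cq": [-2.0, 18.0],
            }
        )
        with pytest.raises(CqValidationError, match="non-positive"):
            CqTable(rows)

    def test_csv_round_trip(self, tmp_path):
        cfg = PlateSimConfig(seed=3)
        table, _ = simulate_plate(cfg)
        path = tmp_path / "plate.csv"
        table.to_csv(path)
        back = CqTable.read_csv(path)
        pd.testing.assert_frame_equal(back.data, table.data)


class TestAggregateTechnical:
    def test_mean_of_three(self):
        rows = pd.DataFrame(
            {
                "sample": ["s1"] * 3 + ["s1"],
                "gene": ["T"] * 3 + ["R"],
                "role": ["target"] * 3 + ["reference"],
                "bio_rep": [1, 1, 1, 1],
                "tech_rep": [1, 2, 3, 1],
                "cq": [20.0, 20.2, 20.4, 18.0],
            }
        )
        agg = aggregate_technical(CqTable(rows))
        t_row = agg.loc[agg["gene"] == "T"].iloc[0]
        assert t_row["cq"] == pytest.approx(20.2)
        assert t_row["n_tech"] == 3

    def test_single_replicate_unchanged(self):
        table = make_cq_table({("s1", "T", 1): 23.45, ("s1", "RCE1", 1): 19.0})
        agg = aggregate_technical(table)
        assert agg.loc[agg["gene"] == "T", "cq"].iloc[0] == 23.45

    def test_matches_loop_oracle_on_full_design(self):
        cfg = PlateSimConfig(
            target_folds={f"T{i}": {} for i in range(1, 5)}, seed=13
        )
        table, _ = simulate_plate(cfg)
        agg = aggregate_technical(table).set_index(["sample", "gene", "bio_rep"])
        # brute-force group-and-average oracle
        sums: dict = {}
        counts: dict = {}
        for rec in table.data.itertuples():
            key = (rec.sample, rec.gene, rec.bio_rep)
            sums[key] = sums.get(key, 0.0) + rec.cq
            counts[key] = counts.get(key, 0) + 1
        for key, total in sums.items():
            assert agg.at[key, "cq"] == pytest.approx(total / counts[key], rel=1e-12)


class TestDeltaDeltaCt:
    def test_powers_of_two_worked_example(self):
        # sample: Cq_target 24, refs at 20; calibrator: Cq_target 26, refs 20
        cq = {}
        for s, tgt in (("tissue", 24.0), ("cal", 26.0)):
            for b in (1, 2):
                cq[(s, "T", b)] = tgt
                for r in ("RCE1", "TUA2", "YLS8"):
                    cq[(s, r, b)] = 20.0
        rq = delta_delta_ct(make_cq_table(cq), "T", "cal")
        summary = rq.summary.set_index("sample")
        assert summary.at["tissue", "mean_fold"] == pytest.approx(4.0)
        assert summary.at["cal", "mean_fold"] == pytest.approx(1.0)
        ddct = rq.per_rep.set_index(["sample", "bio_rep"]).at[("tissue", 1), "delta_delta_ct"]
        assert ddct == pytest.approx(-2.0)

    def test_calibrator_identity(self):
        cq = {}
        for b in (1, 2, 3):
            cq[("cal", "T", b)] = 25.0
            for r in ("RCE1", "TUA2", "YLS8"):
                cq[("cal", r, b)] = 20.0
        cq.update({("other", "T", b): 24.0 for b in (1, 2, 3)})
        cq.update(
            {("other", r, b): 20.0 for b in (1, 2, 3) for r in ("RCE1", "TUA2", "YLS8")}
        )
        rq = delta_delta_ct(make_cq_table(cq), "T", "cal")
        summary = rq.summary.set_index("sample")
        assert summary.at["cal", "mean_fold"] == pytest.approx(1.0)
        assert summary.at["cal", "sem_fold"] == pytest.approx(0.0)

    def test_plate_wide_offset_cancels(self):
        cfg = PlateSimConfig(seed=21, cq_noise_sd=0.05)
        table, _ = simulate_plate(cfg)
        rq1 = delta_delta_ct(table, "AGP24", "anther_st12")
        # add a constant to every Cq of one biological replicate
        shifted = table.data.copy()
        mask = shifted["bio_rep"] == 2
        shifted.loc[mask, "cq"] += 3.7
        rq2 = delta_delta_ct(CqTable(shifted), "AGP24", "anther_st12")
        np.testing.assert_allclose(
            rq1.per_rep["fold"].to_numpy(), rq2.per_rep["fold"].to_numpy(), rtol=1e-9
        )

    def test_reference_gene_permutation_symmetry(self):
        cfg = PlateSimConfig(seed=5)
        table, _ = simulate_plate(cfg)
        relabel = {"RCE1": "TUA2", "TUA2": "YLS8", "YLS8": "RCE1"}
        permuted = table.data.copy()
        permuted["gene"] = permuted["gene"].map(lambda g: relabel.get(g, g))
        rq1 = delta_delta_ct(table, "AGP24", "anther_st12")
        rq2 = delta_delta_ct(CqTable(permuted), "AGP24", "anther_st12")
        np.testing.assert_allclose(
            rq1.summary["mean_fold"].to_numpy(),
            rq2.summary["mean_fold"].to_numpy(),
            rtol=1e-12,
        )

    def test_missing_reference_named(self):
        cq = {
            ("s1", "T", 1): 24.0,
            ("s1", "RCE1", 1): 20.0,
            ("s2", "T", 1): 25.0,
        }
        rows = make_cq_table(cq).data
        with pytest.raises(CqValidationError, match="sample=s2"):
            delta_delta_ct(CqTable(rows), "T", "s1")

    def test_noisy_plate_estimate_within_monte_carlo_band(self):
        # band [0.2, 0.31] frozen from a 1000-plate simulation oracle at
        # true fold 0.25, technical noise sd 0.1
        cfg = PlateSimConfig(
            target_folds={"T1": {"pistil_st11": 0.25}},
            cq_noise_sd=0.1,
            seed=7,
        )
        table, _ = simulate_plate(cfg)
        rq = delta_delta_ct(table, "T1", "anther_st12")
        est = rq.summary.set_index("sample").at["pistil_st11", "mean_fold"]
        assert 0.2 <= est <= 0.31


class TestQuantify:
    def test_summary_has_p_and_labels(self):
        cfg = PlateSimConfig(seed=2)
        table, _ = simulate_plate(cfg)
        rq = quantify(table, "AGP24", "anther_st12")
        summary = rq.summary.set_index("sample")
        assert np.isnan(summary.at["anther_st12", "p_adjusted"])
        others = summary.drop(index="anther_st12")
        assert others["p_adjusted"].between(0, 1).all()
        assert set(others["label"]) <= {"ns", "*", "**", "***", "****"}
        assert rq.anova["df_between"] == 4

    def test_test_on_fold_changes_p_but_not_folds(self):
        cfg = PlateSimConfig(seed=2)
        table, _ = simulate_plate(cfg)
        r_dct = quantify(table, "AGP24", "anther_st12", test_on="dct")
        r_fold = quantify(table, "AGP24", "anther_st12", test_on="fold")
        np.testing.assert_allclose(
            r_dct.summary["mean_fold"], r_fold.summary["mean_fold"], rtol=1e-12
        )
        assert not np.allclose(
            r_dct.summary["p_adjusted"].dropna(),
            r_fold.summary["p_adjusted"].dropna(),
        )
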
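import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytogate.quantify import (
    DEFAULT_FLAG_RULES,
    GrowthInputs,
    QuantifyError,
    WellSummary,
    _logistic4,
    fit_dose_response,
    flag_compound,
    growth_rate,
    normalize_to_dmso,
    population_heatmap_table,
    summaries_to_table,
    well_fractions,
)


def records(**label_lists):
    n = max(len(v) for v in label_lists.values())
    return pd.DataFrame({k: pd.Series(v, dtype=object) for k, v in label_lists.items()})


class TestWellFractions:
    def test_simple_nuclei_partition(self):
        labels = ["healthy"] * 80 + ["pyknosed"] * 15 + ["fragmented"] * 5
        s = well_fractions(records(label_nuclei=labels, label_hio=["normal"] * 100))
        fr = s.fractions["nuclei"]
        assert fr == {"healthy": 0.80, "pyknosed": 0.15, "fragmented": 0.05}
        assert abs(sum(fr.values()) - 1.0) < 1e-9

    def test_fucci_excludes_unlabeled(self):
        labels = ["red"] * 40 + ["green"] * 40 + ["yellow"] * 10 + ["unlabeled"] * 10
        s = well_fractions(records(label_fucci=labels, label_hio=["normal"] * 100))
        fr = s.fractions["fucci"]
        assert fr["red"] == pytest.approx(4 / 9)
        assert fr["green"] == pytest.approx(4 / 9)
        assert fr["yellow"] == pytest.approx(1 / 9)

    def test_counts_match_brute_force(self, rng):
        classes = ["healthy", "pyknosed", "fragmented"]
        labels = [classes[i] for i in rng.integers(0, 3, 157)]
        s = well_fractions(records(label_nuclei=labels, label_hio=["normal"] * 157))
        for c in classes:
            brute = sum(1 for l in labels if l == c)  # independent counting loop
            assert s.counts["nuclei"][c] == brute

    def test_zero_cells(self):
        s = well_fractions(pd.DataFrame())
        assert s.low_count_flag
        assert s.fractions == {}

    def test_low_count_flag(self):
        s = well_fractions(records(label_hio=["normal"] * 10), min_count=50)
        assert s.low_count_flag

    def test_mito_fraction_excludes_not_evaluated(self):
        df = records(
            label_hio=["normal"] * 4,
            label_nuclei=["healthy"] * 4,
            label_mito=["increased", "not_increased", "not_evaluated", "not_evaluated"],
        )
        s = well_fractions(df)
        assert s.frac_mito_increased == pytest.approx(0.5)


class TestNormalizeToDmso:
    def mk(self, well, role, healthy, tp=24.0):
        s = WellSummary(well=well, timepoint=tp, role=role)
        s.healthy_count = healthy
        return s

    def test_basic_ratios(self):
        sums = [self.mk("B02", "dmso_control", 120), self.mk("B04", "treatment", 120),
                self.mk("B05", "treatment", 60)]
        normalize_to_dmso(sums)
        assert sums[1].healthy_nuclei_norm == pytest.approx(1.0)
        assert sums[2].healthy_nuclei_norm == pytest.approx(0.5)

    def test_two_dmso_wells_mean_is_one(self):
        sums = [self.mk("B02", "dmso_control", 100), self.mk("B03", "dmso_control", 140)]
        normalize_to_dmso(sums)
        assert sums[0].healthy_nuclei_norm == pytest.approx(100 / 120)
        assert sums[1].healthy_nuclei_norm == pytest.approx(140 / 120)
        mean = np.mean([s.healthy_nuclei_norm for s in sums])
        assert mean == pytest.approx(1.0, abs=1e-12)

    def test_no_dmso_errors(self):
        with pytest.raises(QuantifyError, match="DMSO"):
            normalize_to_dmso([self.mk("B04", "treatment", 10)])


class TestGrowthRate:
    def test_identities(self):
        assert growth_rate(400, 100, 400) == pytest.approx(1.0, abs=1e-12)
        assert growth_rate(100, 100, 400) == pytest.approx(0.0, abs=1e-12)
        assert growth_rate(200, 100, 400) == pytest.approx(2**0.5 - 1, abs=1e-12)

    def test_undefined_for_shrinking_control(self):
        with pytest.raises(QuantifyError):
            growth_rate(50, 100, 90)
        with pytest.raises(QuantifyError):
            growth_rate(0, 100, 200)

    @given(
        x0=st.floats(1.0, 1e5),
        fold_c=st.floats(0.01, 10.0),
        fold_ctrl=st.floats(1.01, 10.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_independent_reimplementation(self, x0, fold_c, fold_ctrl):
        x_c, x_ctrl = x0 * fold_c, x0 * fold_ctrl
        # independent oracle: same quantity via natural logs
        oracle = math.exp(math.log(2) * (math.log(x_c / x0) / math.log(x_ctrl / x0))) - 1
        assert growth_rate(x_c, x0, x_ctrl) == pytest.approx(oracle, rel=1e-10)

    def test_growth_inputs_wrapper(self):
        assert GrowthInputs(200, 100, 400).gr() == pytest.approx(2**0.5 - 1)


class TestDoseResponse:
    conc7 = 10.0 ** np.arange(-1.5, 2.0, 0.5)  # 7-point half-log series

    def test_noiseless_recovery(self):
        resp = _logistic4(np.log10(self.conc7), 1.0, 0.0, 0.0, 1.0)
        fit = fit_dose_response(self.conc7, resp)
        assert fit.converged
        assert abs(fit.ic50 - 1.0) < 1e-4

    def test_noise_monte_carlo(self):
        resp = _logistic4(np.log10(self.conc7), 1.0, 0.0, 0.0, 1.0)
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(100):
            noisy = resp * rng.normal(1.0, 0.05, resp.shape)
            fit = fit_dose_response(self.conc7, noisy)
            errs.append(abs(np.log10(fit.ic50 / 1.0)))
        assert np.median(errs) <= np.log10(1.2)

    def test_flat_series_not_converged(self):
        fit = fit_dose_response(self.conc7, np.ones(7))
        assert not fit.converged
        assert fit.reason == "no effect within tested range"
        assert math.isnan(fit.ic50)

    def test_too_few_concentrations(self):
        with pytest.raises(QuantifyError, match="4 distinct"):
            fit_dose_response([1.0, 2.0, 4.0], [1.0, 0.5, 0.0])

    def test_unit_rescaling_equivariance(self):
        resp = _logistic4(np.log10(self.conc7), 1.0, 0.05, 0.0, 1.3)
        f_um = fit_dose_response(self.conc7, resp)
        f_nm = fit_dose_response(self.conc7 * 1e3, resp)
        assert f_nm.ic50 / f_um.ic50 == pytest.approx(1e3, rel=1e-9)


def random_summary_table(rng, n_lines=3):
    rows = []
    for line in [f"line_{i}" for i in range(n_lines)]:
        for conc in (1.0, 10.0):
            for tp in (12.0, 24.0):
                rows.append(
                    {
                        "compound": "X",
                        "cell_line": line,
                        "concentration": conc,
                        "timepoint": tp,
                        "hio_ratio": rng.random(),
                        "frac_healthy_nuclei": rng.random(),
                        "frac_pyknosed_nuclei": rng.random(),
                        "frac_fragmented_nuclei": rng.random(),
                        "frac_tubulin_effect": rng.random(),
                        "frac_mito_increased": rng.random(),
                        "frac_membrane_permeable": rng.random(),
                        "low_count_flag": False,
                    }
                )
    return pd.DataFrame(rows)


def brute_force_flags(table, rules):
    """Independent exhaustive evaluator over rows/lines/rules."""
    lines = sorted(table["cell_line"].unique())
    fired = {}
    for rule_id, (col, op, thr) in rules.items():
        per_line = {}
        for line in lines:
            hit = False
            for _, row in table[table["cell_line"] == line].iterrows():
                v = row[col]
                if pd.notna(v) and ((op == ">" and v > thr) or (op == "<" and v < thr)):
                    hit = True
            per_line[line] = hit
        fired[rule_id] = all(per_line.values())
    return sorted(r for r, f in fired.items() if f)


class TestFlagCompound:
    def test_healthy_below_half_flags(self, rng):
        table = random_summary_table(rng)
        table["frac_healthy_nuclei"] = 0.45
        cert = flag_compound("X", table)
        assert "healthy_nuclei_lt_50" in cert.flags
        assert cert.flagged_overall

    def test_tubulin_flag(self, rng):
        table = random_summary_table(rng)
        for col, _, _ in DEFAULT_FLAG_RULES.values():
            table[col] = 0.05
        table["frac_healthy_nuclei"] = 0.9
        table["frac_tubulin_effect"] = 0.92
        cert = flag_compound("X", table)
        assert cert.flags == ["tubulin_gt_50"]

    def test_dmso_like_no_flags(self, rng):
        table = random_summary_table(rng)
        for col, _, _ in DEFAULT_FLAG_RULES.values():
            table[col] = 0.05
        table["frac_healthy_nuclei"] = 0.9
        cert = flag_compound("X", table)
        assert cert.flags == []
        assert not cert.flagged_overall

    def test_rule_needs_all_cell_lines(self, rng):
        table = random_summary_table(rng)
        for col, _, _ in DEFAULT_FLAG_RULES.values():
            table[col] = 0.05
        table["frac_healthy_nuclei"] = 0.9
        table.loc[table["cell_line"] == "line_0", "frac_pyknosed_nuclei"] = 0.9
        cert = flag_compound("X", table)
        assert cert.flags == []

    def test_incomplete_panel_noted(self, rng):
        table = random_summary_table(rng, n_lines=2)
        cert = flag_compound("X", table, cell_lines=["line_0", "line_1", "line_2"])
        assert any("incomplete-panel" in n for n in cert.notes)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(200):
            table = random_summary_table(rng)
            cert = flag_compound("X", table)
            assert sorted(cert.flags) == brute_force_flags(table, DEFAULT_FLAG_RULES)


class TestHeatmapTable:
    def test_cardinality(self, rng):
        rows = []
        for compound in ("a", "b"):
            for tp in (12.0, 24.0):
                rows.append({"compound": compound, "timepoint": tp,
                             "m1": 1.0, "m2": 2.0, "m3": 3.0})
        table = population_heatmap_table(pd.DataFrame(rows), ["m1", "m2", "m3"])
        assert len(table) == 12

    def test_replicate_mean(self):
        df = pd.DataFrame(
            [
                {"compound": "a", "timepoint": 12.0, "m": 0.2},
                {"compound": "a", "timepoint": 12.0, "m": 0.4},
            ]
        )
        table = population_heatmap_table(df, ["m"])
        assert table["value"].iloc[0] == pytest.approx(0.3)

    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [{"compound": "a", "timepoint": 12.0, "m": 0.25},
             {"compound": "b", "timepoint": 24.0, "m": 0.75}]
        )
        table = population_heatmap_table(df, ["m"])
        path = tmp_path / "t.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(table, back)


class TestSummaryInvariants:
    def test_fraction_partitions_sum_to_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 200))
            labels = [["healthy", "pyknosed", "fragmented"][i] for i in rng.integers(0, 3, n)]
            s = well_fractions(records(label_nuclei=labels, label_hio=["normal"] * n))
            if "nuclei" in s.fractions:
                assert abs(sum(s.fractions["nuclei"].values()) - 1.0) < 1e-9

    def test_to_row_columns(self):
        labels = ["healthy"] * 10
        s = well_fractions(records(label_nuclei=labels, label_hio=["normal"] * 10),
                           well="B02", timepoint=12.0, compound="x")
        row = summaries_to_table([s]).iloc[0]
        assert row["frac_healthy_nuclei"] == 1.0
        assert row["well"] == "B02"
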
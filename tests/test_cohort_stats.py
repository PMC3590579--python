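"""Two-sample t-tests, Pearson correlation and cohort report tables."""

import math

import numpy as np
import pandas as pd
import pytest

from pulsemei import cohort_report, independent_t, pearson, summary_t


def _welch_by_hand(a, b):
    """Closed-form Welch t and Satterthwaite df, written independently."""
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    t = (ma - mb) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


class TestIndependentT:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t, df, p = independent_t(a, a)
        assert t == 0.0
        assert p == 1.0

    def test_matches_closed_form_welch(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, int(rng.integers(5, 40)))
            b = rng.normal(0.5, 2, int(rng.integers(5, 40)))
            t, df, p = independent_t(a, b, welch=True)
            t_ref, df_ref = _welch_by_hand(a, b)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert df == pytest.approx(df_ref, abs=1e-8)

    def test_pooled_matches_closed_form(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=20)
        t, df, p = independent_t(a, b, welch=False)
        sp2 = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_ref = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == len(a) + len(b) - 2

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            independent_t([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            independent_t([1.0], [2.0, 3.0])


class TestSummaryT:
    def test_equals_raw_sample_test(self, rng):
        for welch in (True, False):
            a = rng.normal(1, 1.5, 25)
            b = rng.normal(0.3, 0.8, 31)
            t_raw, df_raw, p_raw = independent_t(a, b, welch=welch)
            t_sum, df_sum, p_sum = summary_t(
                np.mean(a), np.std(a, ddof=1), len(a),
                np.mean(b), np.std(b, ddof=1), len(b), welch=welch,
            )
            assert t_sum == pytest.approx(t_raw, abs=1e-10)
            assert df_sum == pytest.approx(df_raw, abs=1e-8)
            assert p_sum == pytest.approx(p_raw, abs=1e-10)

    def test_equal_means_zero_t(self):
        t, _, p = summary_t(5.0, 1.0, 10, 5.0, 2.0, 15)
        assert t == 0.0
        assert p == 1.0

    def test_published_group_summaries_consistency(self):
        """Welch t reproduces the printed significance levels for the group
        summaries that are internally consistent (large-scale entropy index,
        groups 1 vs 2 and 3 vs 4)."""
        _, _, p12 = summary_t(4.22, 1.41, 30, 3.53, 0.99, 40)
        assert 0.02 <= p12 <= 0.03
        _, _, p34 = summary_t(3.02, 1.48, 40, 2.34, 0.96, 30)
        assert 0.015 <= p34 <= 0.035

    def test_degenerate_summaries_rejected(self):
        with pytest.raises(ValueError):
            summary_t(1.0, 0.0, 10, 2.0, 0.0, 10)
        with pytest.raises(ValueError):
            summary_t(1.0, 1.0, 1, 2.0, 1.0, 10)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(2024)
        n = 10_000
        x = rng.standard_normal(n)
        y = 0.5 * x + math.sqrt(1 - 0.25) * rng.standard_normal(n)
        r, p = pearson(x, y)
        assert abs(r - 0.5) < 0.03
        assert p < 1e-6

    def test_matches_closed_form(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _ = pearson(x, y)
        r_ref = float(np.sum((x - x.mean()) * (y - y.mean()))
                      / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCohortReport:
    def _results(self, rng, n_per_group=8):
        rows = []
        for g, (di_mu, ls_mu) in enumerate(
            [(200, 4.2), (165, 3.5), (160, 3.0), (133, 2.3)], start=1
        ):
            for k in range(n_per_group):
                rows.append(
                    {
                        "subject_id": f"g{g}s{k}",
                        "group": g,
                        "di_percent": di_mu + rng.normal(0, 5),
                        "mei_ss": 3.0 + rng.normal(0, 0.3),
                        "mei_ls": ls_mu + rng.normal(0, 0.3),
                        "age": 25 + 10 * g + rng.normal(0, 2),
                        "hba1c": 5 + g + rng.normal(0, 0.2),
                    }
                )
        return pd.DataFrame(rows)

    def test_table_shapes_and_ordering(self, rng):
        rep = cohort_report(self._results(rng))
        t1 = rep["table1"]
        assert set(t1["variable"]) >= {"di_percent", "mei_ss", "mei_ls"}
        row = t1.set_index("variable").loc["mei_ls"]
        assert row["g1_mean"] > row["g2_mean"] > row["g3_mean"] > row["g4_mean"]
        assert {"p_g1_vs_g2", "p_g2_vs_g3", "p_g3_vs_g4"} <= set(t1.columns)
        t2 = rep["table2"]
        assert {"di_percent_R", "mei_ls_R"} <= set(t2.columns)
        assert "age" in set(t2["parameter"])

    def test_significance_marks(self, rng):
        rep = cohort_report(self._results(rng, n_per_group=12))
        row = rep["table1"].set_index("variable").loc["di_percent"]
        assert row["p_g1_vs_g2_sig"] in ("*", "**")

    def test_no_correction_note(self, rng):
        rep = cohort_report(self._results(rng))
        assert any("no multiple-testing correction" in n.lower() for n in rep["notes"])

    def test_single_subject_group_degrades_gracefully(self, rng):
        df = self._results(rng)
        df = pd.concat([df[df.group != 4], df[df.group == 4].head(1)])
        rep = cohort_report(df)
        row = rep["table1"].set_index("variable").loc["mei_ls"]
        assert math.isnan(row["g4_sd"])
        assert math.isnan(row["p_g3_vs_g4"])

    def test_missing_group_warned(self, rng):
        df = self._results(rng)
        rep = cohort_report(df[df.group != 2])
        assert any("group 2" in n for n in rep["notes"])

    def test_csv_round_trip(self, rng, tmp_path):
        rep = cohort_report(self._results(rng))
        path = tmp_path / "table1.csv"
        rep["table1"].to_csv(path, index=False)
        back = pd.read_csv(path, float_precision="round_trip")
        # empty significance marks read back as NaN; compare the data columns
        num_cols = [c for c in rep["table1"].columns if not c.endswith("_sig")]
        pd.testing.assert_frame_equal(
            back[num_cols], rep["table1"][num_cols], check_exact=False, rtol=1e-12
        )
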
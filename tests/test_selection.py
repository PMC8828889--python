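"""Tests for correlation screening, CSI, ranking and segregant detection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from droughtsel import (
    NoSignificantIndexError,
    CSIWeights,
    composite_index,
    correlate_with_yield,
    index_table,
    paired_yields,
    population_means,
    rank_by_score,
    select_significant,
    simulate_trial,
    transgressive_segregants,
    truth_report,
    SimSpec,
)
from droughtsel.datasets import l53_index_values, pooled_weights
from droughtsel.selection import pearson_with_p

from conftest import make_pairs


def t_two_sided_p_by_quadrature(t, df):
    """Numeric integration of the Student-t density (independent oracle)."""

    def pdf(x):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + x**2 / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return 2 * tail


class TestPearson:
    def test_closed_form_example(self):
        """x=(1..5), y=(2,1,4,3,5): r=0.8, t=2.309 on 3 df, p≈0.104."""
        r, p = pearson_with_p(np.arange(1, 6), np.array([2, 1, 4, 3, 5]))
        assert r == pytest.approx(0.8)
        assert p == pytest.approx(t_two_sided_p_by_quadrature(2.309401, 3), abs=1e-6)
        assert p > 0.05  # not significant at alpha=0.05

    def test_self_correlation(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        r, p = pearson_with_p(y, y)
        assert (r, p) == (1.0, 0.0)

    @pytest.mark.parametrize("n", [5, 12, 30])
    def test_p_matches_quadrature_oracle_and_scipy(self, n, rng):
        for _ in range(10):
            x, y = rng.normal(size=(2, n))
            r, p = pearson_with_p(x, y)
            t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
            assert p == pytest.approx(t_two_sided_p_by_quadrature(t, n - 2), abs=1e-6)
            r_sp, p_sp = stats.pearsonr(x, y)
            assert (r, p) == (pytest.approx(r_sp), pytest.approx(p_sp, abs=1e-9))


class TestCorrelateWithYield:
    def _table(self, rng, n=30):
        pairs = make_pairs(rng.uniform(1, 8, n), rng.uniform(0.2, 4, n))
        return index_table(pairs)

    def test_index_identical_to_ys_has_unit_correlation(self, rng):
        table = self._table(rng)
        report = correlate_with_yield(table)
        # YI is YS rescaled by a constant, hence r_ys = 1 exactly
        assert report.loc["yi", "r_ys"] == pytest.approx(1.0)
        assert report.loc["yi", "p_ys"] == pytest.approx(0.0, abs=1e-12)

    def test_flags_match_p_values(self, rng):
        report = correlate_with_yield(self._table(rng), alpha=0.05)
        expected = (report["p_yp"] < 0.05) & (report["p_ys"] < 0.05)
        assert (report["significant_both"] == expected).all()
        assert report["r_yp"].between(-1, 1).all()
        assert report["n"].eq(30).all()

    def test_zero_variance_column_warns_and_is_nan(self, rng):
        table = self._table(rng)
        table["sti"] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            report = correlate_with_yield(table)
        assert np.isnan(report.loc["sti", "r_yp"])
        assert not report.loc["sti", "significant_both"]


class TestSelectSignificant:
    def _report(self, sig):
        rows = {
            name: {
                "r_yp": 0.9, "p_yp": 0.001 if name in sig else 0.5,
                "r_ys": 0.8, "p_ys": 0.001 if name in sig else 0.5,
                "n": 157, "significant_both": name in sig,
            }
            for name in ("ssi", "rsi", "tol", "mp", "ysi", "hm", "gmp", "sti", "yi")
        }
        report = pd.DataFrame.from_dict(rows, orient="index")
        report.attrs["alpha"] = 0.05
        return report

    def test_published_selection_pattern(self):
        w = select_significant(self._report({"mp", "gmp", "hm", "sti"}))
        assert w.index_names == ["mp", "hm", "gmp", "sti"]  # canonical order

    def test_empty_selection_raises(self):
        with pytest.raises(NoSignificantIndexError, match="CSI is undefined"):
            select_significant(self._report(set()))

    def test_all_nine_retained_with_signed_weights(self):
        report = self._report(set(report_all := {"ssi", "rsi", "tol", "mp", "ysi",
                                                 "hm", "gmp", "sti", "yi"}))
        report["significant_both"] = True
        report.loc["ssi", ["r_yp", "r_ys"]] = [-0.7, -0.9]
        # brute-force filter oracle: everything flagged stays, signs kept
        w = select_significant(report)
        assert set(w.index_names) == report_all
        assert w.weights.loc["ssi", "r_ys"] == -0.9

    def test_require_positive_drops_negative_indices(self):
        report = self._report({"mp", "gmp"})
        report.loc["mp", ["r_yp", "r_ys"]] = [-0.9, -0.8]
        w = select_significant(report, require_positive=True)
        assert w.index_names == ["gmp"]


class TestCompositeIndex:
    def test_published_worked_example(self):
        """L53's printed index values and pooled weights give CSI=10.083."""
        csi = composite_index(l53_index_values(), pooled_weights())
        assert csi.loc["L53"] == pytest.approx(10.083, abs=1e-3)

    def test_unit_weight_single_index_returns_the_index(self):
        w = CSIWeights(
            weights=pd.DataFrame({"r_yp": [1.0], "r_ys": [1.0]}, index=["mp"]),
            alpha=0.05,
        )
        table = pd.DataFrame({"mp": [2.5, 4.0]}, index=["A", "B"])
        assert composite_index(table, w).tolist() == [2.5, 4.0]

    def test_half_weights_on_mp_give_half_mp(self):
        w = CSIWeights(
            weights=pd.DataFrame({"r_yp": [0.5], "r_ys": [0.5]}, index=["mp"]),
            alpha=0.05,
        )
        table = pd.DataFrame({"mp": [3.0, 5.0]}, index=["A", "B"])
        assert composite_index(table, w).tolist() == [1.5, 2.5]

    def test_matches_brute_force_summation(self, rng):
        table = pd.DataFrame(
            rng.uniform(0, 5, (5, 2)), columns=["mp", "sti"],
            index=[f"G{i}" for i in range(5)],
        )
        r = rng.uniform(-1, 1, (2, 2))
        w = CSIWeights(
            weights=pd.DataFrame({"r_yp": r[:, 0], "r_ys": r[:, 1]},
                                 index=["mp", "sti"]),
            alpha=0.05,
        )
        csi = composite_index(table, w)
        for g in table.index:
            brute = 0.5 * sum(
                r[j, 0] * table.loc[g, name] + r[j, 1] * table.loc[g, name]
                for j, name in enumerate(["mp", "sti"])
            )
            assert csi[g] == pytest.approx(brute, rel=1e-12)

    def test_linearity_in_each_index_column(self, rng):
        table = pd.DataFrame(rng.uniform(0, 5, (6, 2)), columns=["mp", "gmp"])
        w = CSIWeights(
            weights=pd.DataFrame({"r_yp": [0.9, 0.4], "r_ys": [0.7, 0.6]},
                                 index=["mp", "gmp"]),
            alpha=0.05,
        )
        base = composite_index(table, w)
        scaled_table = table.assign(mp=3.0 * table["mp"])
        contribution = 0.5 * (0.9 + 0.7) * table["mp"]
        assert composite_index(scaled_table, w).to_numpy() == pytest.approx(
            (base + 2.0 * contribution).to_numpy()
        )

    def test_missing_index_value_gives_nan_with_warning(self):
        table = pd.DataFrame({"mp": [1.0, np.nan]}, index=["A", "B"])
        w = CSIWeights(
            weights=pd.DataFrame({"r_yp": [1.0], "r_ys": [1.0]}, index=["mp"]),
            alpha=0.05,
        )
        with pytest.warns(UserWarning, match="missing"):
            csi = composite_index(table, w)
        assert np.isnan(csi["B"]) and csi["A"] == 1.0

    def test_csi_ranking_tracks_gmp_on_synthetic_population(self, default_trial):
        """With the published weight pattern, CSI ranks like GMP (ρ > 0.9)."""
        pairs = paired_yields(default_trial, scope="pooled")
        table = index_table(pairs, population_means(pairs))
        csi = composite_index(table, pooled_weights())
        rho = stats.spearmanr(csi, table["gmp"]).statistic
        assert rho > 0.9


class TestRankByScore:
    def test_descending_and_topk(self):
        scores = pd.Series({"A": 2.0, "B": 3.0, "C": 1.0})
        assert rank_by_score(scores, top_k=2) == ["B", "A"]

    def test_tie_breaks_by_genotype_id(self):
        assert rank_by_score(pd.Series({"B": 1.0, "A": 1.0}), top_k=1) == ["A"]

    def test_topk_beyond_population_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="exceeds population"):
            out = rank_by_score(pd.Series({"A": 1.0, "B": 2.0}), top_k=5)
        assert out == ["B", "A"]

    def test_csi_topk_enriched_for_true_genetic_value(self, default_trial):
        """Top-k by CSI overlaps top-k by true genetic merit above chance."""
        pairs = paired_yields(default_trial, scope="pooled")
        table = index_table(pairs, population_means(pairs))
        csi = composite_index(table, pooled_weights())
        truth = truth_report(default_trial).set_index("genotype")
        merit = (truth["g_p"] + truth["g_s"]) / 2
        k = 20
        top_csi = set(rank_by_score(csi[truth.index[truth["entry_type"] == "line"]], k))
        top_true = set(rank_by_score(merit[truth["entry_type"] == "line"], k))
        # chance overlap would be k²/152 ≈ 2.6 lines
        assert len(top_csi & top_true) >= 10


class TestTransgressiveSegregants:
    def _trial(self, rows):
        return pd.DataFrame(rows, columns=["genotype", "entry_type", "year",
                                           "condition", "yield"])

    def test_line_above_parents_everywhere_is_overall_positive(self):
        rows = []
        for year in ("y1", "y2"):
            for cond in ("N", "D"):
                rows += [
                    ("P1", "parent", year, cond, 3.0),
                    ("P2", "parent", year, cond, 2.0),
                    ("L1", "line", year, cond, 4.0),
                    ("L2", "line", year, cond, 2.5),
                ]
        rep = transgressive_segregants(self._trial(rows), ("P1", "P2"))
        assert rep.positive == {f"{y}{c}": ["L1"] for y in ("y1", "y2") for c in "ND"}
        assert rep.overall_positive == {"D": ["L1"], "N": ["L1"]}
        assert all(not v for v in rep.negative.values())

    def test_equal_to_best_parent_is_not_transgressive(self):
        rows = [
            ("P1", "parent", "y1", "N", 3.0),
            ("P2", "parent", "y1", "N", 2.0),
            ("L1", "line", "y1", "N", 3.0),
        ]
        rep = transgressive_segregants(self._trial(rows), ("P1", "P2"),
                                       require_all_envs=False)
        assert rep.positive["y1N"] == []

    def test_positive_negative_disjoint_per_environment(self, default_trial):
        rep = transgressive_segregants(default_trial, ("P1", "P2"))
        for env in rep.positive:
            assert not set(rep.positive[env]) & set(rep.negative[env])

    def test_parent_missing_environment_skipped_with_warning(self):
        rows = [
            ("P1", "parent", "y1", "N", 3.0),
            ("P2", "parent", "y1", "N", 2.0),
            ("L1", "line", "y1", "N", 4.0),
            ("P1", "parent", "y2", "N", 3.0),
            ("L1", "line", "y2", "N", 4.0),
        ]
        with pytest.warns(UserWarning, match="parent missing"):
            rep = transgressive_segregants(self._trial(rows), ("P1", "P2"))
        assert set(rep.positive) == {"y1N"}

    def test_frequency_increases_with_parental_divergence(self):
        """More divergent parents (larger per-locus effects) produce more
        positive segregants — the generator is the oracle."""
        counts = []
        for a in (0.05, 0.4):
            spec = SimSpec(seed=3, locus_effect=a, sd_error=0.05, sd_gxe=0.05,
                           deltas=(0.3, 0.3, 0.3))
            trial = simulate_trial(spec)
            rep = transgressive_segregants(trial, ("P1", "P2"),
                                           require_all_envs=False)
            counts.append(sum(len(v) for v in rep.positive.values()))
        assert counts[1] > counts[0]
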
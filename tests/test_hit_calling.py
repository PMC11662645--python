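import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special

from hetscreen import hit_calling as hc
from hetscreen.errors import ConfigError


def t_two_sided_p_oracle(t: float, df: int) -> float:
    """Brute-force two-sided tail of Student's t via numerical integration."""
    def density(x):
        c = special.gamma((df + 1) / 2) / (np.sqrt(df * np.pi) * special.gamma(df / 2))
        return c * (1 + x**2 / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(density, abs(t), np.inf)
    return 2.0 * tail


class TestGeneStatistics:
    def test_derived_example(self):
        # {2,3,4}: t = 3/(1/sqrt(3)) = 5.196; df=2 closed form p = 1 - t/sqrt(t^2+2)
        rec = hc.gene_statistics([2.0, 3.0, 4.0])
        t = rec["t_stat"]
        assert t == pytest.approx(3 * np.sqrt(3), abs=1e-9)
        closed_form = 1 - t / np.sqrt(t**2 + 2)
        assert rec["p_value"] == pytest.approx(closed_form, abs=1e-12)
        assert rec["p_value"] == pytest.approx(0.0351, abs=5e-5)
        assert rec["p_value"] == pytest.approx(t_two_sided_p_oracle(t, 2), abs=1e-10)

    def test_all_zero(self):
        rec = hc.gene_statistics([0.0, 0.0, 0.0, 0.0])
        assert rec["p_value"] == 1.0 and not rec["degenerate"]

    def test_constant_nonzero_degenerate(self):
        rec = hc.gene_statistics([1.5, 1.5, 1.5])
        assert rec["p_value"] == 0.0 and rec["degenerate"]

    def test_single_value_untestable(self):
        rec = hc.gene_statistics([2.0])
        assert np.isnan(rec["p_value"]) and rec["degenerate"]

    @pytest.mark.parametrize("n", range(2, 9))
    def test_oracle_equivalence(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            x = rng.normal(0.3, 1.0, n)
            if x.std(ddof=1) == 0:
                continue
            rec = hc.gene_statistics(x)
            assert rec["p_value"] == pytest.approx(
                t_two_sided_p_oracle(rec["t_stat"], n - 1), abs=1e-10)

    def test_vectorized_table_matches_scalar(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in range(30):
            for s in ("CEN", "MAT"):
                n = rng.integers(1, 7)
                for b in range(n):
                    rows.append({"gene_name": f"g{g}", "screen": s, "bio_rep": b + 1,
                                 "value": rng.normal()})
        combined = pd.DataFrame(rows)
        table = hc.gene_statistics_table(combined)
        for (g, s), grp in combined.groupby(["gene_name", "screen"]):
            rec = hc.gene_statistics(grp["value"].to_numpy())
            row = table[(table["gene"] == g) & (table["screen"] == s)].iloc[0]
            for key in ("n_bio", "mean", "median", "t_stat", "p_value"):
                got, want = row[key], rec[key]
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want, abs=1e-12)


class TestCallHits:
    def stats_row(self, screen, median, p, n=5):
        return pd.DataFrame([{"gene": "g", "screen": screen, "n_bio": n, "mean": median,
                              "median": median, "t_stat": 3.0, "p_value": p,
                              "degenerate": False, "p_bh": p}])

    @pytest.mark.parametrize("screen,median,p,expected", [
        ("MAT", 2.6, 0.01, "silencing"),
        ("CEN", 2.6, 0.01, "none"),       # CEN threshold is stricter (>3)
        ("CEN", 3.2, 0.01, "silencing"),
        ("TEL", -2.2, 0.03, "anti_silencing"),
        ("CEN", -2.2, 0.03, "none"),      # CEN anti threshold is < -3
        ("MAT", 2.6, 0.2, "none"),        # not significant
        ("MAT", 2.4, 0.01, "none"),       # below effect threshold
    ])
    def test_threshold_rules(self, screen, median, p, expected):
        hits = hc.call_hits(self.stats_row(screen, median, p))
        assert hits["direction"].iloc[0] == expected

    def test_untestable_not_none(self):
        hits = hc.call_hits(self.stats_row("MAT", 5.0, np.nan, n=1))
        assert hits["direction"].iloc[0] == "untestable"

    def test_missing_screen_config_error(self):
        cfg = hc.ThresholdConfig(silencing_min={"MAT": 2.5}, antisilencing_max={"MAT": -2.0})
        with pytest.raises(ConfigError):
            hc.call_hits(self.stats_row("CEN", 3.5, 0.01), cfg)

    def test_invalid_threshold_signs(self):
        cfg = hc.ThresholdConfig(silencing_min={"MAT": -1.0}, antisilencing_max={"MAT": -2.0})
        with pytest.raises(ConfigError):
            cfg.validate(["MAT"])


class TestOverlapSummary:
    def hits_frame(self, gene_screens, direction="silencing"):
        rows = []
        for gene, screens in gene_screens.items():
            for s in ("CEN", "MAT", "SUBTEL", "TEL"):
                rows.append({"gene": gene, "screen": s,
                             "direction": direction if s in screens else "none"})
        return pd.DataFrame(rows)

    def test_toy_histogram(self):
        hits = self.hits_frame({"A": {"CEN", "MAT", "SUBTEL", "TEL"}, "B": {"MAT"}})
        out = hc.overlap_summary(hits, "silencing")
        assert out["histogram"] == {1: 1, 2: 0, 3: 0, 4: 1}
        assert out["single_domain"] == {"CEN": 0, "MAT": 1, "SUBTEL": 0, "TEL": 0}

    def test_no_hits(self):
        hits = self.hits_frame({"A": set()})
        out = hc.overlap_summary(hits, "silencing")
        assert out["histogram"] == {1: 0, 2: 0, 3: 0, 4: 0}
        assert out["n_genes"] == 0

    def test_histogram_sums_to_gene_count(self, rng):
        gene_screens = {}
        for g in range(50):
            k = rng.integers(0, 5)
            gene_screens[f"g{g}"] = set(rng.choice(["CEN", "MAT", "SUBTEL", "TEL"], k, replace=False))
        out = hc.overlap_summary(self.hits_frame(gene_screens), "silencing")
        assert sum(out["histogram"].values()) == out["n_genes"]
        assert out["n_genes"] == sum(1 for v in gene_screens.values() if v)


class TestRecallPrecision:
    def hits_for(self, hit_genes, tested, screen="CEN"):
        return pd.DataFrame([
            {"gene": g, "screen": screen,
             "direction": "silencing" if g in hit_genes else "none"}
            for g in tested
        ])

    def test_recall_counting(self):
        hits = self.hits_for({"a", "b", "c", "x"}, ["a", "b", "c", "d", "x", "y"])
        assert hc.compute_recall(hits, {"a", "b", "c", "d"}, "CEN") == 0.75

    def test_recall_extremes(self):
        hits = self.hits_for({"x"}, ["a", "b", "x"])
        assert hc.compute_recall(hits, {"a", "b"}, "CEN") == 0.0
        hits = self.hits_for({"a", "b"}, ["a", "b"])
        assert hc.compute_recall(hits, {"a", "b"}, "CEN") == 1.0

    def test_recall_restricted_to_tested(self):
        hits = self.hits_for({"a"}, ["a", "b"])
        # gold gene "z" was never tested: denominator is gold & tested
        assert hc.compute_recall(hits, {"a", "z"}, "CEN") == 1.0

    def test_recall_empty_intersection_errors(self):
        hits = self.hits_for({"a"}, ["a"])
        with pytest.raises(ValueError):
            hc.compute_recall(hits, {"z"}, "CEN")

    def test_group_normalize(self):
        out = hc.group_normalize_expression([2.0, 4.0])
        np.testing.assert_allclose(out, [2 / 3, 4 / 3], atol=1e-12)
        assert hc.group_normalize_expression([5.0])[0] == 1.0

    def test_group_normalize_mean_one(self, rng):
        out = hc.group_normalize_expression(rng.uniform(0.1, 10.0, 37))
        assert out.mean() == pytest.approx(1.0, abs=1e-12)

    def test_group_normalize_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hc.group_normalize_expression([1.0, 0.0])

    def test_precision_strict_threshold(self):
        val = pd.DataFrame({"gene": ["a", "b", "c"], "fold_change": [2.0, 1.2, 1.6]})
        assert hc.compute_precision({"a", "b", "c"}, val) == pytest.approx(2 / 3)
        val_all_at = pd.DataFrame({"gene": ["a", "b"], "fold_change": [1.5, 1.5]})
        assert hc.compute_precision({"a", "b"}, val_all_at) == 0.0
        val_all_over = pd.DataFrame({"gene": ["a", "b"], "fold_change": [1.6, 9.0]})
        assert hc.compute_precision({"a", "b"}, val_all_over) == 1.0

    def test_precision_empty_validation_errors(self):
        with pytest.raises(ValueError):
            hc.compute_precision({"a"}, pd.DataFrame({"gene": ["z"], "fold_change": [2.0]}))


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def point(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)) / math.comb(n, r1)

    p_obs = point(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(point(k) for k in range(lo, hi + 1) if point(k) <= p_obs * (1 + 1e-9))


class TestFisherEnrichment:
    def _sets(self, a, b, c, d):
        universe = {f"u{i}" for i in range(a + b + c + d)}
        items = sorted(universe)
        cluster = set(items[: a + b])
        pathway = set(items[:a]) | set(items[a + b: a + b + c])
        return cluster, pathway, universe

    def test_derived_table(self):
        cluster, pathway, universe = self._sets(4, 1, 1, 4)
        odds, p = hc.fisher_enrichment(cluster, pathway, universe)
        assert p == pytest.approx(fisher_two_sided_oracle(4, 1, 1, 4), abs=1e-12)
        assert p == pytest.approx(0.2063, abs=5e-5)

    def test_perfect_overlap_point_mass(self):
        # point mass of the observed table is 1/C(20,10); the two-sided p
        # also counts the equally extreme zero-overlap table, giving twice that
        cluster, pathway, universe = self._sets(10, 0, 0, 10)
        _, p = hc.fisher_enrichment(cluster, pathway, universe)
        assert p == pytest.approx(fisher_two_sided_oracle(10, 0, 0, 10), rel=1e-9)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_enumeration_all_small_margins(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 7, 4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            cluster, pathway, universe = self._sets(int(a), int(b), int(c), int(d))
            _, p = hc.fisher_enrichment(cluster, pathway, universe)
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-9)

    def test_null_uniformity(self, rng):
        """Independent random sets give roughly uniform p (coarse check)."""
        universe = {f"u{i}" for i in range(60)}
        items = sorted(universe)
        ps = []
        for _ in range(300):
            cluster = set(rng.choice(items, 15, replace=False))
            pathway = set(rng.choice(items, 15, replace=False))
            ps.append(hc.fisher_enrichment(cluster, pathway, universe)[1])
        # discrete and conservative, so just bound gross miscalibration
        assert 0.0 < np.mean(np.array(ps) < 0.5) < 0.75
        assert np.mean(ps) > 0.3

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            hc.fisher_enrichment(set(), set(), set())
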
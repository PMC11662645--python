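"""Hit calling from combined-score replicates, plus caller calibration.

A gene is a silencing hit in a screen when its one-sample t-test against 0
gives P < 0.05 and the median combined score of its biological replicates
exceeds the per-screen threshold (+2.5 for MAT/SUBTEL/TEL, +3 for CEN); the
anti-silencing call uses the reciprocal thresholds (-2 / -3).  Raw P values
are used for calling (no multiple-testing correction); a Benjamini-Hochberg
column is emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hetscreen import SCREENS
from hetscreen.errors import ConfigError


@dataclass(frozen=True)
class ThresholdConfig:
    """Calling thresholds; defaults follow the published screen analysis."""

    p_max: float = 0.05
    silencing_min: dict[str, float] = field(
        default_factory=lambda: {"CEN": 3.0, "MAT": 2.5, "SUBTEL": 2.5, "TEL": 2.5}
    )
    antisilencing_max: dict[str, float] = field(
        default_factory=lambda: {"CEN": -3.0, "MAT": -2.0, "SUBTEL": -2.0, "TEL": -2.0}
    )

    def validate(self, screens) -> None:
        for s in screens:
            if s not in self.silencing_min or s not in self.antisilencing_max:
                raise ConfigError(f"screen {s!r} missing from threshold maps")
            if not self.silencing_min[s] > 0 > self.antisilencing_max[s]:
                raise ConfigError(f"thresholds for {s!r} must straddle 0")


def gene_statistics(scores) -> dict:
    """One-sample t-test of combined scores against 0 for one gene x screen.

    Returns n, mean, median, t, two-sided p and a ``degenerate`` flag.
    n < 2 gives undefined statistics (NaN, flagged); SD = 0 with nonzero
    mean gives p = 0 (degenerate); SD = 0 with zero mean gives p = 1.
    """
    x = np.asarray(scores, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        return {"n_bio": n, "mean": float(x.mean()) if n else np.nan, "median": float(np.median(x)) if n else np.nan,
                "t_stat": np.nan, "p_value": np.nan, "degenerate": True}
    mean = float(x.mean())
    med = float(np.median(x))
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return {"n_bio": n, "mean": mean, "median": med, "t_stat": 0.0, "p_value": 1.0, "degenerate": False}
        return {"n_bio": n, "mean": mean, "median": med,
                "t_stat": np.inf if mean > 0 else -np.inf, "p_value": 0.0, "degenerate": True}
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return {"n_bio": n, "mean": mean, "median": med, "t_stat": float(t), "p_value": p, "degenerate": False}


def gene_statistics_table(combined: pd.DataFrame, gene_col: str = "gene_name") -> pd.DataFrame:
    """Per (gene, screen) statistics from a long combined-score table.

    Vectorized equivalent of applying :func:`gene_statistics` per group
    (the equivalence is regression-tested).
    """
    grp = combined.dropna(subset=["value"]).groupby([gene_col, "screen"], sort=False)["value"]
    out = grp.agg(n_bio="count", mean="mean", median="median", sd=lambda s: s.std(ddof=1)).reset_index()
    out = out.rename(columns={gene_col: "gene"})
    # re-attach groups that were entirely missing
    all_keys = combined[[gene_col, "screen"]].drop_duplicates().rename(columns={gene_col: "gene"})
    out = all_keys.merge(out, on=["gene", "screen"], how="left")
    out["n_bio"] = out["n_bio"].fillna(0).astype(int)

    n = out["n_bio"].to_numpy(dtype=float)
    mean = out["mean"].to_numpy()
    sd = out["sd"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 1, 1))
    degenerate = np.zeros(len(out), dtype=bool)

    small = n < 2
    t[small], p[small], degenerate[small] = np.nan, np.nan, True
    zero_sd = (~small) & (sd == 0)
    zs_null = zero_sd & (mean == 0)
    t[zs_null], p[zs_null] = 0.0, 1.0
    zs_deg = zero_sd & (mean != 0)
    t[zs_deg] = np.where(mean[zs_deg] > 0, np.inf, -np.inf)
    p[zs_deg], degenerate[zs_deg] = 0.0, True

    out["t_stat"], out["p_value"], out["degenerate"] = t, p, degenerate
    out = out[["gene", "screen", "n_bio", "mean", "median", "t_stat", "p_value", "degenerate"]]
    # informational BH-adjusted p, per screen, over testable genes
    out["p_bh"] = np.nan
    for screen, idx in out.groupby("screen").groups.items():
        mask = out.loc[idx, "p_value"].notna()
        if mask.any():
            sub = out.loc[idx][mask]
            out.loc[sub.index, "p_bh"] = multipletests(sub["p_value"], method="fdr_bh")[1]
    return out


def call_hits(stats_table: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Assign silencing / anti_silencing / none per (gene, screen).

    Genes with n_bio < 2 are marked ``untestable`` rather than called none.
    """
    cfg = cfg or ThresholdConfig()
    cfg.validate(stats_table["screen"].unique())
    out = stats_table.copy()
    sil_min = out["screen"].map(cfg.silencing_min)
    anti_max = out["screen"].map(cfg.antisilencing_max)
    sig = out["p_value"] < cfg.p_max
    out["direction"] = "none"
    out.loc[sig & (out["median"] > sil_min), "direction"] = "silencing"
    out.loc[sig & (out["median"] < anti_max), "direction"] = "anti_silencing"
    out.loc[out["n_bio"] < 2, "direction"] = "untestable"
    return out


def overlap_summary(hits: pd.DataFrame, direction: str) -> dict:
    """Histogram over the number of domains hit per gene, for one direction.

    Returns ``histogram`` over {1, 2, 3, 4} domain counts, the number of hit
    genes, and for single-domain genes the per-domain breakdown.
    """
    sel = hits[hits["direction"] == direction]
    counts = sel.groupby("gene")["screen"].nunique()
    histogram = {k: int((counts == k).sum()) for k in (1, 2, 3, 4)}
    singles = counts[counts == 1].index
    single_breakdown = (
        sel[sel["gene"].isin(singles)].groupby("screen")["gene"].nunique().to_dict()
    )
    single_breakdown = {s: int(single_breakdown.get(s, 0)) for s in SCREENS}
    return {"histogram": histogram, "n_genes": int(counts.size), "single_domain": single_breakdown}


def compute_recall(hits: pd.DataFrame, gold: set[str], screen: str,
                   direction: str = "silencing") -> float:
    """Fraction of tested gold-standard genes retrieved as hits in a screen."""
    screen_hits = hits[hits["screen"] == screen]
    tested = set(screen_hits.loc[screen_hits["direction"] != "untestable", "gene"])
    gold_tested = set(gold) & tested
    if not gold_tested:
        raise ValueError(f"no gold-standard gene was tested in screen {screen!r}")
    retrieved = set(screen_hits.loc[screen_hits["direction"] == direction, "gene"])
    return len(gold_tested & retrieved) / len(gold_tested)


def group_normalize_expression(levels) -> np.ndarray:
    """Divide act1-normalized transcript levels by their batch mean.

    Output mean is 1 by construction.
    """
    x = np.asarray(levels, dtype=float)
    if np.any(~(x > 0)):
        raise ValueError("expression levels must be positive")
    return x / x.mean()


def compute_precision(hit_genes: set[str], validation: pd.DataFrame,
                      fold_threshold: float = 1.5) -> float:
    """Fraction of validated hit genes with fold_change strictly > threshold.

    ``validation`` has columns (gene, fold_change) and covers a subset of
    ``hit_genes``.
    """
    tested = validation[validation["gene"].isin(hit_genes)]
    if tested.empty:
        raise ValueError("validation table covers no hit gene")
    return float((tested["fold_change"] > fold_threshold).mean())


def fisher_enrichment(cluster_genes: set[str], pathway_genes: set[str],
                      universe: set[str]) -> tuple[float, float]:
    """Two-sided Fisher's exact test for pathway enrichment in a cluster.

    Returns (sample odds ratio, p).  The odds ratio is the unconditional
    sample estimate ad/bc (inf when bc = 0).
    """
    if not universe:
        raise ValueError("empty universe")
    if not cluster_genes <= universe or not pathway_genes <= universe:
        raise ValueError("cluster and pathway genes must be subsets of the universe")
    a = len(cluster_genes & pathway_genes)
    b = len(cluster_genes - pathway_genes)
    c = len(pathway_genes - cluster_genes)
    d = len(universe) - a - b - c
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
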
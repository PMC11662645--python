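"""Replication mode: headline numbers from processed per-replicate scores.

Consumes an already-tidied long table of per-biological-replicate combined
FOA/URA scores (columns: gene, screen, bio_rep, value) — e.g. the study's
supplementary score tables after reshaping — and recomputes the headline
quantities: hit counts per direction, the MAT candidate count, the
domain-overlap histogram, gold-standard recall, and the within/between
complex coherence fractions.
"""

from __future__ import annotations

import pandas as pd

from hetscreen import complex_coherence, hit_calling


def replication_report(
    combined: pd.DataFrame,
    gold: set[str] | None = None,
    complexes: dict[str, set[str]] | None = None,
    cfg: hit_calling.ThresholdConfig | None = None,
    gene_col: str = "gene",
    r_threshold: float = 0.9,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Recompute the headline screen statistics from per-replicate scores."""
    cfg = cfg or hit_calling.ThresholdConfig()
    stats = hit_calling.gene_statistics_table(combined, gene_col=gene_col)
    hits = hit_calling.call_hits(stats, cfg)
    sil = hit_calling.overlap_summary(hits, "silencing")
    anti = hit_calling.overlap_summary(hits, "anti_silencing")
    report: dict = {
        "n_silencing_genes": sil["n_genes"],
        "n_antisilencing_genes": anti["n_genes"],
        "n_mat_silencing": int(
            hits[(hits["screen"] == "MAT") & (hits["direction"] == "silencing")]["gene"].nunique()
        ),
        "silencing_overlap_histogram": sil["histogram"],
        "silencing_single_domain": sil["single_domain"],
        "hits": hits,
    }
    if gold is not None:
        report["recall_pct"] = {
            s: 100.0 * hit_calling.compute_recall(hits, gold, s)
            for s in sorted(hits["screen"].unique())
        }
    if complexes is not None:
        profiles = complex_coherence.build_profiles(combined, gene_col=gene_col)
        summary, _ = complex_coherence.coherence_analysis(
            profiles, complexes, r_threshold=r_threshold, n_perm=n_perm, seed=seed)
        report["coherence"] = summary.to_dict()
    return report
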
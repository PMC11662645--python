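"""Within- vs between-complex similarity of phenotypic profiles.

Profiles are per-gene vectors of mean combined FOA/URA scores over
biological replicates, one entry per screen (4-dimensional by default; an
8-dimensional screen x readout mode is available).  Coherence is assessed
by the fraction of same-complex gene pairs whose pairwise Pearson r reaches
a threshold, and by a one-sided permutation test of the difference between
mean within-complex and mean between-complex correlation under random
reassignment of genes to complexes (complex sizes preserved).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from itertools import permutations

import numpy as np
import pandas as pd

from hetscreen import SCREENS
from hetscreen.errors import ConfigError, IntegrityError


@dataclass
class CoherenceSummary:
    within_pairs: int
    between_pairs: int
    frac_within_ge_r: float
    frac_between_ge_r: float
    r_threshold: float
    observed_stat: float
    perm_p: float
    n_perm: int
    exhaustive: bool
    mode: str = "screen-mean"

    def to_dict(self) -> dict:
        return asdict(self)


def build_profiles(combined: pd.DataFrame, gene_col: str = "gene_name",
                   mode: str = "screen-mean") -> pd.DataFrame:
    """Per-gene profile matrix from a long combined-score table.

    ``screen-mean`` (default) yields the 4-vector of per-screen means over
    biological replicates.  ``screen-readout`` expects a ``readout`` column
    and yields the 8-vector of per-(screen, readout) means.
    """
    if mode == "screen-mean":
        prof = (combined.groupby([gene_col, "screen"])["value"].mean()
                .unstack("screen").reindex(columns=list(SCREENS)))
    elif mode == "screen-readout":
        prof = (combined.groupby([gene_col, "screen", "readout"])["value"].mean()
                .unstack(["screen", "readout"]))
        prof.columns = [f"{s}_{r}" for s, r in prof.columns]
    else:
        raise ConfigError(f"unknown profile mode {mode!r}")
    return prof.dropna(how="any")


def pairwise_profile_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson r for every unordered gene pair; diagonal 1.

    Zero-variance profiles are excluded with a warning.  Profiles need
    >= 3 points.
    """
    if profiles.shape[0] < 2:
        raise ConfigError("need >= 2 gene profiles")
    if profiles.shape[1] < 3:
        raise ConfigError("profiles need >= 3 points for Pearson r")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        zero = list(profiles.index[sd == 0])
        warnings.warn(f"excluding zero-variance profile(s): {zero}")
        profiles = profiles.loc[sd > 0]
        X = profiles.to_numpy(dtype=float)
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=profiles.index, columns=profiles.index)


def _check_complexes(corr: pd.DataFrame, complexes: dict[str, set[str]]) -> list[str]:
    seen: dict[str, str] = {}
    for cid, members in complexes.items():
        for g in members:
            if g in seen:
                raise IntegrityError(f"gene {g!r} in both {seen[g]!r} and {cid!r}")
            seen[g] = cid
    missing = sorted(g for g in seen if g not in corr.index)
    if missing:
        raise IntegrityError(f"complex gene(s) absent from correlation matrix: {missing}")
    return sorted(seen)


def _pair_layout(corr: pd.DataFrame, complexes: dict[str, set[str]]):
    """Condensed pair r-values and block sizes over annotated genes."""
    genes = _check_complexes(corr, complexes)
    # order genes by complex so a label permutation is an index permutation
    ordered, sizes = [], []
    for cid in sorted(complexes):
        members = sorted(complexes[cid] & set(genes))
        ordered.extend(members)
        sizes.append(len(members))
    R = corr.loc[ordered, ordered].to_numpy(dtype=float)
    m = len(ordered)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    iu = np.triu_indices(m, k=1)
    within_mask = labels[iu[0]] == labels[iu[1]]
    return R, iu, within_mask, labels, ordered


def within_between_summary(corr: pd.DataFrame, complexes: dict[str, set[str]],
                           r_threshold: float = 0.9) -> dict:
    """Classify complex-gene pairs as within/between; threshold fractions."""
    R, iu, within_mask, _, _ = _pair_layout(corr, complexes)
    r = R[iu]
    n_within = int(within_mask.sum())
    n_between = int((~within_mask).sum())
    if n_within == 0:
        raise ConfigError("no within-complex pairs (all complexes have < 2 members)")
    return {
        "within_pairs": n_within,
        "between_pairs": n_between,
        "frac_within_ge_r": float(np.mean(r[within_mask] >= r_threshold)),
        "frac_between_ge_r": float(np.mean(r[~within_mask] >= r_threshold)),
        "r_threshold": r_threshold,
        "within_r": r[within_mask],
        "between_r": r[~within_mask],
    }


def permutation_test(
    corr: pd.DataFrame,
    complexes: dict[str, set[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "mean-diff",
    r_threshold: float = 0.9,
) -> tuple[float, float, dict]:
    """One-sided permutation test of within > between profile similarity.

    The gene -> complex assignment is permuted with complex sizes preserved.
    ``mean-diff`` (default) uses mean(within r) - mean(between r);
    ``frac-diff`` uses the difference of the >= r_threshold fractions.
    Monte-Carlo p uses the add-one estimator (never 0).  When the number of
    distinct ordered assignments is <= n_perm the null is enumerated
    exhaustively instead (flagged in the returned info dict).

    Both statistics are monotone in the sum of the pair quantity over
    within-complex pairs (the all-pair sum is permutation-invariant), so
    each permutation only evaluates the within-block pairs.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    R, iu, within_mask, labels, _ = _pair_layout(corr, complexes)
    m = len(labels)

    if statistic == "mean-diff":
        M = R
    elif statistic == "frac-diff":
        M = (R >= r_threshold).astype(float)
    else:
        raise ConfigError(f"unknown statistic {statistic!r}")

    n_w = int(within_mask.sum())
    n_b = int((~within_mask).sum())
    if n_w == 0 or n_b == 0:
        raise ConfigError("permutation test needs both within and between pairs")
    pair_vals = M[iu]
    total_sum = float(pair_vals.sum())
    within_a = iu[0][within_mask]
    within_b = iu[1][within_mask]

    def stat_from_within_sum(s_w):
        return s_w / n_w - (total_sum - s_w) / n_b

    observed_sw = float(pair_vals[within_mask].sum())
    observed = stat_from_within_sum(observed_sw)

    def within_sums(perms: np.ndarray) -> np.ndarray:
        """Within-pair sums for a (P x m) array of permuted gene indices."""
        s = np.zeros(perms.shape[0])
        for a, b in zip(within_a, within_b):
            s += M[perms[:, a], perms[:, b]]
        return s

    counts = np.bincount(labels)
    n_distinct = math.factorial(m) // math.prod(math.factorial(int(c)) for c in counts)
    if n_distinct <= n_perm:
        seen, rows = set(), []
        inv = np.empty(m, dtype=int)
        for perm in permutations(range(m)):
            # dedupe by the induced gene -> complex assignment: gene perm[a]
            # receives the label of position a
            inv[list(perm)] = np.arange(m)
            key = tuple(labels[inv])
            if key not in seen:
                seen.add(key)
                rows.append(perm)
        sums = within_sums(np.array(rows))
        p = float(np.mean(sums >= observed_sw - 1e-12))
        info = {"exhaustive": True, "n_perm": len(rows)}
    else:
        rng = np.random.default_rng(seed)
        ge = 0
        batch = 2048
        remaining = n_perm
        while remaining > 0:
            k = min(batch, remaining)
            perms = np.argsort(rng.random((k, m)), axis=1)
            ge += int(np.sum(within_sums(perms) >= observed_sw - 1e-12))
            remaining -= k
        p = (1 + ge) / (1 + n_perm)
        info = {"exhaustive": False, "n_perm": n_perm}
    return p, observed, info


def coherence_analysis(
    profiles: pd.DataFrame,
    complexes: dict[str, set[str]],
    r_threshold: float = 0.9,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "mean-diff",
    mode: str = "screen-mean",
) -> tuple[CoherenceSummary, dict]:
    """Full coherence analysis: correlations, fractions, permutation test.

    Returns the summary plus extras (correlation matrix, within/between r
    arrays for density curves, per-complex sub-matrices).
    """
    corr = pairwise_profile_correlation(profiles)
    summary = within_between_summary(corr, complexes, r_threshold=r_threshold)
    p, observed, info = permutation_test(
        corr, complexes, n_perm=n_perm, seed=seed, statistic=statistic, r_threshold=r_threshold
    )
    result = CoherenceSummary(
        within_pairs=summary["within_pairs"],
        between_pairs=summary["between_pairs"],
        frac_within_ge_r=summary["frac_within_ge_r"],
        frac_between_ge_r=summary["frac_between_ge_r"],
        r_threshold=r_threshold,
        observed_stat=observed,
        perm_p=p,
        n_perm=info["n_perm"],
        exhaustive=info["exhaustive"],
        mode=mode,
    )
    per_complex = {
        cid: corr.loc[sorted(members & set(corr.index)), sorted(members & set(corr.index))]
        for cid, members in complexes.items()
    }
    extras = {
        "corr": corr,
        "within_r": summary["within_r"],
        "between_r": summary["between_r"],
        "per_complex": per_complex,
    }
    return result, extras
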
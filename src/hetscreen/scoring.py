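"""Colony sizes -> combined selection scores.

Fixed stage order (regression-pinned by the test suite):

    ratio -> plate-median normalize -> log2 -> technical mean
          -> scale/center per (screen, readout) -> combine readouts

Ratios use colony size on selective medium over size on non-selective
medium.  A zero or missing size on either medium yields a missing ratio
(no pseudocount).  Scaling divides by the sample SD (ddof=1) and centers on
the median, pooled over all biological replicates of one (screen, readout)
dataset.  The combined score is scaled(URA) - scaled(FOA).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from hetscreen import READOUTS
from hetscreen.errors import DegenerateDataError
from hetscreen.screen_io import PlateSet

PLATE_GROUP = ["screen", "readout", "plate_id", "bio_rep", "tech_rep"]
BIO_KEY = ["screen", "readout", "strain_id", "gene_name", "bio_rep"]


def relative_growth(selective_size, nonselective_size):
    """Selective/non-selective size ratio; missing if either is missing or <= 0.

    Accepts scalars or array-likes.  Negative sizes raise.
    """
    sel = np.asarray(selective_size, dtype=float)
    ns = np.asarray(nonselective_size, dtype=float)
    if np.any(sel[~np.isnan(sel)] < 0) or np.any(ns[~np.isnan(ns)] < 0):
        raise ValueError("colony sizes must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((sel > 0) & (ns > 0), sel / ns, np.nan)
    if np.ndim(selective_size) == 0 and np.ndim(nonselective_size) == 0:
        return float(ratio)
    return ratio


def ratio_table(plateset: PlateSet) -> pd.DataFrame:
    """Join selective (URA/FOA) observations to their NS counterparts.

    Keyed on (screen, strain_id, bio_rep, tech_rep): each strain occupies one
    library position per technical replicate, and the NS plate shares the
    selective plates' layout.
    """
    obs = plateset.observations
    layout_key = ["screen", "strain_id", "bio_rep", "tech_rep"]
    ns = obs[obs["medium"] == "NS"][layout_key + ["size"]].rename(columns={"size": "ns_size"})
    sel = obs[obs["medium"].isin(READOUTS)].rename(columns={"medium": "readout", "size": "sel_size"})
    merged = sel.merge(ns, on=layout_key, how="left", validate="many_to_one")
    merged["ratio"] = relative_growth(merged["sel_size"].to_numpy(), merged["ns_size"].to_numpy())
    return merged[
        ["screen", "readout", "plate_id", "row", "col", "strain_id", "gene_name",
         "bio_rep", "tech_rep", "ratio"]
    ]


def plate_median_normalize(ratios: pd.DataFrame, group: list[str] | None = None) -> pd.DataFrame:
    """Divide each ratio by the median of its plate group.

    Plates whose non-missing median is 0 or whose ratios are all missing are
    dropped with a warning.  Missing ratios propagate.
    """
    group = PLATE_GROUP if group is None else group
    out = ratios.copy()
    med = out.groupby(group, sort=False)["ratio"].transform("median")
    bad = med.isna() | (med == 0)
    if bad.any():
        plates = out.loc[bad, group].drop_duplicates().to_dict("records")
        warnings.warn(f"dropping {len(plates)} plate group(s) with all-missing or zero median: {plates[:5]}")
        out = out[~bad].copy()
        med = med[~bad]
    out["ratio"] = out["ratio"] / med
    return out


def log2_transform(ratios: pd.DataFrame) -> pd.DataFrame:
    out = ratios.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_value"] = np.log2(out["ratio"].to_numpy(dtype=float))
    return out


def aggregate_technical(log2_table: pd.DataFrame, key: list[str] | None = None) -> pd.DataFrame:
    """Mean of technical replicates -> one biological-replicate value per key.

    Groups with no non-missing technical value yield a missing biological
    value (mean over an empty set); 2-4 technical replicates are supported
    but any positive count works.
    """
    key = BIO_KEY if key is None else key
    agg = (
        log2_table.groupby(key, sort=False, dropna=False)["log2_value"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "log2_value", "count": "n_tech"})
    )
    return agg


def scale_and_center(values, allow_constant: bool = False) -> np.ndarray:
    """(x - median(x)) / sample SD(x), over the non-missing values.

    SD uses the n-1 denominator.  SD = 0 raises :class:`DegenerateDataError`
    unless ``allow_constant`` is set, in which case a constant dataset maps
    to all zeros (the limit of centering a constant on itself); this path
    exists for noiseless synthetic nulls.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 3:
        raise DegenerateDataError(f"need >= 3 non-missing values, got {obs.size}")
    sd = float(np.std(obs, ddof=1))
    med = float(np.median(obs))
    if sd == 0.0:
        if allow_constant:
            return np.where(np.isnan(x), np.nan, 0.0)
        raise DegenerateDataError("dataset SD is 0; cannot scale")
    return (x - med) / sd


def scale_table(bio_table: pd.DataFrame, allow_constant: bool = False) -> pd.DataFrame:
    """Apply :func:`scale_and_center` per (screen, readout) dataset."""
    out = bio_table.copy()
    out["value"] = np.nan
    for _, idx in out.groupby(["screen", "readout"], sort=False).groups.items():
        out.loc[idx, "value"] = scale_and_center(
            out.loc[idx, "log2_value"].to_numpy(), allow_constant=allow_constant
        )
    return out.drop(columns=["log2_value"])


def combine_readouts(ura_scaled, foa_scaled):
    """Combined score = scaled(URA) - scaled(FOA); missing propagates."""
    ura = np.asarray(ura_scaled, dtype=float)
    foa = np.asarray(foa_scaled, dtype=float)
    combined = ura - foa
    if np.ndim(ura_scaled) == 0 and np.ndim(foa_scaled) == 0:
        return float(combined)
    return combined


def combine_table(scaled: pd.DataFrame) -> pd.DataFrame:
    key = ["screen", "strain_id", "gene_name", "bio_rep"]
    wide = scaled.pivot(index=key, columns="readout", values="value")
    for r in READOUTS:
        if r not in wide.columns:
            wide[r] = np.nan
    out = wide.reset_index()
    out["value"] = combine_readouts(out["URA"].to_numpy(), out["FOA"].to_numpy())
    return out[key + ["value"]]


def score_plateset(plateset: PlateSet, allow_constant: bool = False) -> dict[str, pd.DataFrame]:
    """Run the full scoring pipeline on a plateset.

    Returns the intermediate and final tables:

    - ``ratios``: per-technical-replicate normalized relative growth
    - ``log2_bio``: per-biological-replicate log2 relative growth (the
      clustering/heatmap quantity)
    - ``scaled``: per-(screen, readout) scaled scores
    - ``combined``: combined FOA/URA score per (screen, strain, bio_rep)
    """
    ratios = plate_median_normalize(ratio_table(plateset))
    log2_bio = aggregate_technical(log2_transform(ratios))
    scaled = scale_table(log2_bio, allow_constant=allow_constant)
    combined = combine_table(scaled)
    return {"ratios": ratios, "log2_bio": log2_bio, "scaled": scaled, "combined": combined}
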
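"""Single-cell reporter-state quantification from per-cell fluorescence.

Green/orange signals are normalized per cell to the euchromatic red channel,
color-negative cells are gated out using a red-only ("fully repressed")
control, signals are scaled to the "max" level of color-positive cells in a
no-heterochromatin control, and the scaled orange channel is partitioned
into OFF / intermediate / ON fractions.  Density curves and a rectangular
2D histogram ("hexbin") are produced for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from hetscreen.errors import ConfigError, DegenerateDataError

#: scaled values are clipped at this ceiling for summaries/plots
SCALE_CEILING = 2.0


@dataclass(frozen=True)
class GatingModel:
    min_cutoff_green: float
    min_cutoff_orange: float
    max_green: float
    max_orange: float
    cutoff_quantile: float
    max_estimator: str

    def __post_init__(self) -> None:
        if not (self.max_green > self.min_cutoff_green > 0
                and self.max_orange > self.min_cutoff_orange > 0):
            raise ConfigError("gating requires max_* > min_cutoff_* > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def normalize_to_red(cells: pd.DataFrame, red_floor: float = 0.0) -> pd.DataFrame:
    """Per-cell green/red and orange/red ratios.

    Cells with red <= red_floor are excluded and counted in the
    ``n_excluded_red`` attribute of the returned frame.
    """
    keep = cells["red"] > red_floor
    n_excl = int((~keep).sum())
    if not keep.any():
        raise DegenerateDataError("all cells excluded by the red floor")
    out = cells.loc[keep].copy()
    out["green_norm"] = out["green"] / out["red"]
    out["orange_norm"] = out["orange"] / out["red"]
    out.attrs["n_excluded_red"] = n_excl
    return out


def fit_gating(
    control_red_only: pd.DataFrame,
    control_no_het: pd.DataFrame,
    cutoff_quantile: float = 0.995,
    max_estimator: str = "mean",
    min_cells: int = 200,
) -> GatingModel:
    """Derive min cutoffs and max levels from the two control populations.

    Min cutoffs are the ``cutoff_quantile`` of the red-normalized signals in
    the red-only control; max levels are the ``max_estimator`` (mean or
    median) of the red-normalized signals among no-heterochromatin control
    cells above the cutoffs (color-positive cells).
    """
    if not 0 < cutoff_quantile <= 1:
        raise ConfigError("cutoff_quantile must be in (0, 1]")
    if max_estimator not in ("mean", "median"):
        raise ConfigError("max_estimator must be 'mean' or 'median'")
    for name, ctrl in (("red-only", control_red_only), ("no-het", control_no_het)):
        if len(ctrl) < min_cells:
            raise ConfigError(f"{name} control has {len(ctrl)} cells; need >= {min_cells}")

    neg = normalize_to_red(control_red_only)
    cut_g = float(np.quantile(neg["green_norm"], cutoff_quantile))
    cut_o = float(np.quantile(neg["orange_norm"], cutoff_quantile))

    pos = normalize_to_red(control_no_het)
    est = np.mean if max_estimator == "mean" else np.median
    pos_g = pos.loc[pos["green_norm"] > cut_g, "green_norm"]
    pos_o = pos.loc[pos["orange_norm"] > cut_o, "orange_norm"]
    if pos_g.empty or pos_o.empty:
        raise DegenerateDataError(
            "no color-positive cells in the no-heterochromatin control "
            "(possible reporter loss)"
        )
    return GatingModel(
        min_cutoff_green=cut_g,
        min_cutoff_orange=cut_o,
        max_green=float(est(pos_g)),
        max_orange=float(est(pos_o)),
        cutoff_quantile=cutoff_quantile,
        max_estimator=max_estimator,
    )


def scale_and_summarize(
    cells: pd.DataFrame,
    gate: GatingModel,
    off_bound: float = 0.1,
    on_bound: float = 0.8,
    hexbin_bins: int = 50,
    density_points: int = 256,
) -> dict:
    """Scale to the gate max and summarize OFF/intermediate/ON fractions.

    Cells below the orange min cutoff are color-negative and excluded (their
    count is reported).  Scaled values are red-normalized signals divided by
    the corresponding max, clipped at ``SCALE_CEILING``.  State boundaries
    act on scaled orange: OFF < off_bound <= intermediate < on_bound <= ON.
    """
    if not 0 < off_bound < on_bound:
        raise ConfigError("need 0 < off_bound < on_bound")
    norm = normalize_to_red(cells)
    gated = norm[norm["orange_norm"] >= gate.min_cutoff_orange].copy()
    n_negative = len(norm) - len(gated)
    if gated.empty:
        raise DegenerateDataError("no cells remain after color-negative gating")

    gated["green_scaled"] = np.clip(gated["green_norm"] / gate.max_green, 0, SCALE_CEILING)
    gated["orange_scaled"] = np.clip(gated["orange_norm"] / gate.max_orange, 0, SCALE_CEILING)

    o = gated["orange_scaled"].to_numpy()
    n = o.size
    frac_off = float(np.mean(o < off_bound))
    frac_on = float(np.mean(o >= on_bound))
    frac_int = 1.0 - frac_off - frac_on

    grid = np.linspace(0, SCALE_CEILING, density_points)
    if np.std(o) > 0:
        dens = stats.gaussian_kde(o)(grid)  # Silverman bandwidth default
    else:
        dens = np.zeros_like(grid)
    counts, xe, ye = np.histogram2d(
        gated["green_scaled"], gated["orange_scaled"],
        bins=hexbin_bins, range=[[0, SCALE_CEILING], [0, SCALE_CEILING]],
    )
    xi, yi = np.nonzero(counts)
    hexbin = pd.DataFrame({
        "x_bin": 0.5 * (xe[xi] + xe[xi + 1]),
        "y_bin": 0.5 * (ye[yi] + ye[yi + 1]),
        "count": counts[xi, yi].astype(int),
    })
    return {
        "n_cells": n,
        "n_color_negative": n_negative,
        "fraction_off": frac_off,
        "fraction_intermediate": frac_int,
        "fraction_on": frac_on,
        "off_bound": off_bound,
        "on_bound": on_bound,
        "density_curve": pd.DataFrame({"scaled_orange": grid, "density": dens}),
        "hexbin": hexbin,
        "cells": gated,
        "gate": gate.to_dict(),
    }
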
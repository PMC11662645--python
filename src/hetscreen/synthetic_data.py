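"""Synthetic screens, complex-profile sets and cell populations.

Every generator is deterministic given its seed and returns a ground-truth
object alongside the data.  Truth objects are for test assertions only and
are never consumed by analysis code.

Screen generative model (the scoring pipeline's inverse):

    NS size        ~ 2^Normal(baseline_log2_mean, baseline_log2_sd)
    URA size       = NS * plate_effect * 2^(+alpha * effect + eps)
    FOA size       = NS * plate_effect * 2^(-beta  * effect + eps)
    plate_effect   = 2^Normal(0, plate_effect_sd), shared per selective plate
    eps            ~ Normal(0, noise_sd), independent per colony

Plate effects hit selective plates only, so relative growth retains them;
this is the stress case that plate-median normalization must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hetscreen.errors import ConfigError
from hetscreen.screen_io import COLONY_COLUMNS, N_COLS, N_ROWS, PlateSet

PLATE_CAPACITY = N_ROWS * N_COLS  # 384

DEFAULT_N_BIO = {"CEN": 8, "MAT": 7, "SUBTEL": 3, "TEL": 6}


@dataclass
class SimConfig:
    """Configuration of the screen generator."""

    n_genes: int = 2000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"null": 0.90, "silencing": 0.05, "anti_silencing": 0.05}
    )
    effect_magnitudes: dict[str, float] = field(
        default_factory=lambda: {"null": 0.0, "silencing": 4.0, "anti_silencing": -4.0}
    )
    n_bio: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_BIO))
    n_tech: int = 2
    plate_effect_sd: float = 0.25
    noise_sd: float = 0.5
    alpha: float = 0.5
    beta: float = 0.5
    baseline_log2_mean: float = 8.6
    baseline_log2_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ConfigError("class proportions must be non-negative")
        if set(self.class_proportions) - set(self.effect_magnitudes):
            raise ConfigError("every class needs an effect magnitude")
        for sd in (self.plate_effect_sd, self.noise_sd, self.baseline_log2_sd):
            if sd < 0:
                raise ConfigError("SDs must be >= 0")
        if self.n_tech < 1 or any(n < 1 for n in self.n_bio.values()):
            raise ConfigError("replicate counts must be >= 1")


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = sorted(cfg.class_proportions)
    counts = {c: int(round(cfg.class_proportions[c] * cfg.n_genes)) for c in classes}
    # fix rounding drift on the largest class
    drift = cfg.n_genes - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    labels = np.concatenate([np.full(counts[c], c) for c in classes])
    rng.shuffle(labels)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    effects = np.array([cfg.effect_magnitudes[c] for c in labels])
    return pd.DataFrame({"gene_name": genes, "gene_class": labels, "effect": effects})


def generate_screen(cfg: SimConfig, screens: list[str] | None = None) -> tuple[PlateSet, pd.DataFrame]:
    """Generate a long-format plateset plus per-gene truth.

    ``screens`` defaults to the keys of ``cfg.n_bio``.  Effects are shared
    across screens (gene class is global).  Genes are laid out row-major on
    384-position plates; each (screen, bio, tech, medium) combination is a
    separate physical plate series.
    """
    cfg.validate()
    screens = list(cfg.n_bio) if screens is None else list(screens)
    rng = np.random.default_rng(cfg.seed)
    truth = _assign_classes(cfg, rng)

    n = cfg.n_genes
    plate_idx = np.arange(n) // PLATE_CAPACITY
    well = np.arange(n) % PLATE_CAPACITY
    rows = well // N_COLS + 1
    cols = well % N_COLS + 1
    effects = truth["effect"].to_numpy()

    frames = []
    for screen in screens:
        for b in range(1, cfg.n_bio[screen] + 1):
            for t in range(1, cfg.n_tech + 1):
                ns_log2 = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
                base = {
                    "screen": screen, "row": rows, "col": cols,
                    "strain_id": truth["gene_name"], "gene_name": truth["gene_name"],
                    "bio_rep": b, "tech_rep": t,
                }
                frames.append(pd.DataFrame({
                    **base, "medium": "NS",
                    "plate_id": [f"{screen}_b{b}t{t}_NS_p{p}" for p in plate_idx],
                    "size": 2.0 ** ns_log2,
                }))
                for medium, sign, coef in (("URA", +1.0, cfg.alpha), ("FOA", -1.0, cfg.beta)):
                    n_plates = plate_idx[-1] + 1
                    pe = rng.normal(0.0, cfg.plate_effect_sd, n_plates)[plate_idx]
                    eps = rng.normal(0.0, cfg.noise_sd, n)
                    sel_log2 = ns_log2 + pe + sign * coef * effects + eps
                    frames.append(pd.DataFrame({
                        **base, "medium": medium,
                        "plate_id": [f"{screen}_b{b}t{t}_{medium}_p{p}" for p in plate_idx],
                        "size": 2.0 ** sel_log2,
                    }))
    obs = pd.concat(frames, ignore_index=True)[COLONY_COLUMNS]
    strains = (truth[["gene_name"]]
               .assign(strain_id=truth["gene_name"], status="verified",
                       corrected_name="", exclusion_reason="")
               [["strain_id", "gene_name", "status", "corrected_name", "exclusion_reason"]])
    return PlateSet(observations=obs, strains=strains), truth


def generate_complex_profiles(
    n_complexes: int = 12,
    sizes: list[int] | None = None,
    within_rho: float = 0.9,
    n_background: int = 0,
    n_dims: int = 4,
    scale: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]], pd.DataFrame]:
    """Gene profiles where same-complex members share a latent vector.

    Each member profile is sqrt(rho) * latent + sqrt(1 - rho) * noise, so
    two members of a complex are coordinate-wise correlated at ``rho``.
    Background genes are independent noise.  Returns (profiles, complex
    map, truth).
    """
    if not -1.0 <= within_rho <= 1.0:
        raise ConfigError("|within_rho| must be <= 1")
    sizes = ([5] * n_complexes) if sizes is None else list(sizes)
    if len(sizes) != n_complexes:
        raise ConfigError("len(sizes) must equal n_complexes")
    if all(s < 2 for s in sizes):
        raise ConfigError("at least one complex needs >= 2 members")
    rng = np.random.default_rng(seed)

    rows, complex_map, truth_rows = [], {}, []
    names = []
    for ci in range(n_complexes):
        cid = f"cplx{ci + 1:02d}"
        latent = rng.standard_normal(n_dims)
        members = set()
        for mi in range(sizes[ci]):
            gene = f"{cid}_m{mi + 1}"
            noise = rng.standard_normal(n_dims)
            profile = np.sqrt(max(within_rho, 0.0)) * latent + np.sqrt(1 - max(within_rho, 0.0)) * noise
            rows.append(scale * profile)
            names.append(gene)
            members.add(gene)
            truth_rows.append({"gene": gene, "complex_id": cid})
        complex_map[cid] = members
    for bi in range(n_background):
        gene = f"bg_{bi + 1:03d}"
        rows.append(scale * rng.standard_normal(n_dims))
        names.append(gene)
        truth_rows.append({"gene": gene, "complex_id": ""})

    cols = ["CEN", "MAT", "SUBTEL", "TEL"] if n_dims == 4 else [f"d{i}" for i in range(n_dims)]
    profiles = pd.DataFrame(np.asarray(rows), index=names, columns=cols)
    return profiles, complex_map, pd.DataFrame(truth_rows)


def generate_cell_population(
    n_cells: int,
    off_mean: float,
    on_mean: float,
    on_fraction: float,
    cv: float = 0.3,
    red_log_mean: float = np.log(500.0),
    red_log_sd: float = 0.3,
    green_off_mean: float | None = None,
    green_on_mean: float | None = None,
    sample_id: str = "sim",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-component (OFF/ON) reporter population with per-cell red scaling.

    red ~ lognormal; orange = red * component_level * multiplicative noise
    with unit mean and coefficient of variation ``cv``; green analogous
    (defaults to the orange levels).  Truth stores each cell's component.
    """
    if not 0.0 <= on_fraction <= 1.0:
        raise ConfigError("on_fraction must be in [0, 1]")
    if off_mean <= 0 or on_mean <= 0:
        raise ConfigError("component means must be > 0")
    green_off_mean = off_mean if green_off_mean is None else green_off_mean
    green_on_mean = on_mean if green_on_mean is None else green_on_mean
    rng = np.random.default_rng(seed)

    comp = rng.random(n_cells) < on_fraction
    red = np.exp(rng.normal(red_log_mean, red_log_sd, n_cells))
    sigma = np.sqrt(np.log1p(cv**2))

    def noisy(n):  # lognormal with mean exactly 1
        return np.exp(rng.normal(-sigma**2 / 2, sigma, n))

    orange_level = np.where(comp, on_mean, off_mean)
    green_level = np.where(comp, green_on_mean, green_off_mean)
    cells = pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "sample_id": sample_id,
        "green": red * green_level * noisy(n_cells),
        "orange": red * orange_level * noisy(n_cells),
        "red": red,
    })
    truth = pd.DataFrame({"cell_id": np.arange(n_cells),
                          "component": np.where(comp, "on", "off")})
    return cells, truth
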
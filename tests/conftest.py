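import numpy as np
import pandas as pd
import pytest

from hetscreen.screen_io import COLONY_COLUMNS, PlateSet


def make_observations(rows: list[dict]) -> pd.DataFrame:
    """Build an observation frame from sparse row dicts with defaults."""
    defaults = {
        "screen": "MAT", "medium": "NS", "plate_id": "p0", "row": 1, "col": 1,
        "strain_id": "s1", "gene_name": "gene1", "bio_rep": 1, "tech_rep": 1,
        "size": 100.0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])[COLONY_COLUMNS]


def make_plateset(rows: list[dict]) -> PlateSet:
    obs = make_observations(rows)
    strains = (
        obs[["strain_id", "gene_name"]].drop_duplicates("strain_id")
        .assign(status="verified", corrected_name="", exclusion_reason="")
        .reset_index(drop=True)
    )
    return PlateSet(observations=obs, strains=strains)


@pytest.fixture
def tiny_plateset() -> PlateSet:
    """3 strains x {NS, URA, FOA}, one plate, one replicate."""
    rows = []
    for i, (strain, ns, ura, foa) in enumerate(
        [("s1", 400.0, 200.0, 400.0), ("s2", 300.0, 300.0, 150.0), ("s3", 200.0, 100.0, 50.0)]
    ):
        for medium, size in (("NS", ns), ("URA", ura), ("FOA", foa)):
            rows.append({"strain_id": strain, "gene_name": f"gene{i + 1}",
                         "medium": medium, "col": i + 1, "size": size})
    return make_plateset(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
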
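"""Shared fixtures: small synthetic designs and a hand-crafted photo set."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wcscomm.synthetic import (
    SimulationConfig,
    generate_counts,
    generate_monthly_covariates,
    generate_site_covariates,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_sites=6, n_months=5, n_species=6, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    sites = generate_site_covariates(small_config)
    monthly = generate_monthly_covariates(small_config)
    counts, truth = generate_counts(small_config, sites, monthly)
    return {"config": small_config, "sites": sites, "monthly": monthly,
            "counts": counts, "truth": truth}


def random_rate_matrix(rng: np.random.Generator, n_obs: int, n_species: int) -> pd.DataFrame:
    """Sparse non-negative rate matrix resembling monthly detection rates."""
    dense = rng.lognormal(mean=-1.5, sigma=1.0, size=(n_obs, n_species))
    mask = rng.uniform(size=(n_obs, n_species)) < 0.65
    return pd.DataFrame(dense * mask, columns=[f"sp{j}" for j in range(n_species)])


def photo(site, camera, minute, species, n=1, codes=None, period="", day=1, month="2024-05"):
    ts = pd.Timestamp(f"{month}-{day:02d}") + pd.Timedelta(minutes=minute)
    return {
        "site_id": site,
        "camera_id": camera,
        "timestamp": ts,
        "species": species,
        "n_individuals": n,
        "interaction_codes": codes,
        "period_label": period,
    }


@pytest.fixture(scope="session")
def event_fixture():
    """50 photos covering gap boundaries, crossings, splits and exclusions.

    Expected independent events and category counts are listed alongside
    each block; derived by hand from the grouping and classification
    rules (chain gaps <= 30 min, A capped at 2, E once per event,
    construction-period events lack codes).
    """
    rows = []
    # block 1 (fox, S1): chain 0/30/60 min -> ONE event, codes A on first photo
    rows += [photo("S1", "S1-C1", 0, "fox", codes="A"),
             photo("S1", "S1-C1", 30, "fox"),
             photo("S1", "S1-C2", 60, "fox")]          # camera pooled       (3)
    # block 2 (fox, S1): 31-min gap -> TWO events, each C=1
    rows += [photo("S1", "S1-C1", 180, "fox", codes="C"),
             photo("S1", "S1-C1", 211, "fox", codes="C")]                  # (5)
    # block 3 (fox, S1): back-and-forth: three A annotations in one event -> A=2
    rows += [photo("S1", "S1-C1", 300, "fox", codes="A"),
             photo("S1", "S1-C1", 310, "fox", codes="A"),
             photo("S1", "S1-C1", 320, "fox", codes="A")]                  # (8)
    # block 4 (fox, S1): two individuals, one crosses one approaches -> A=1, C=1
    rows += [photo("S1", "S1-C1", 420, "fox", n=2, codes="A;C")]           # (9)
    # block 5 (fox, S1): day bed annotated on three photos -> E=1
    rows += [photo("S1", "S1-C1", 540, "fox", codes="E"),
             photo("S1", "S1-C1", 560, "fox", codes="E"),
             photo("S1", "S1-C1", 580, "fox", codes="E")]                  # (12)
    # block 6 (fox, S1): detection only -> D=1 (total only)
    rows += [photo("S1", "S1-C1", 660, "fox", codes="D")]                  # (13)
    # block 7 (coyote, S1): same minute as fox photo -> separate event, B=1
    rows += [photo("S1", "S1-C1", 0, "coyote", codes="B")]                 # (14)
    # block 8 (fox, S2): own site, B=1
    rows += [photo("S2", "S2-C1", 0, "fox", codes="B")]                    # (15)
    # block 9 (fox, S1): un-coded event in the analysis period -> total only
    rows += [photo("S1", "S1-C1", 800, "fox"),
             photo("S1", "S1-C1", 815, "fox")]                             # (17)
    # block 10 (june, S1, fox): construction period, 3 events x 2 photos, no codes
    for e in range(3):
        base = e * 120
        rows += [photo("S1", "S1-C1", base, "fox", period="construction", month="2024-06"),
                 photo("S1", "S1-C1", base + 20, "fox", period="construction", month="2024-06")]
    #                                                                        (23)
    # block 11 (coyote, S2): exact 30-min boundary -> ONE event, two B codes
    rows += [photo("S2", "S2-C1", 100, "coyote", codes="B"),
             photo("S2", "S2-C1", 130, "coyote", codes="B")]               # (25)
    # block 12 (nilgai, S2): multi-individual split across categories
    rows += [photo("S2", "S2-C1", 300, "nilgai", n=3, codes="A;B;D")]      # (26)
    # filler: 24 single-photo fox events at S2, > 31 min apart, code D
    for e in range(24):
        rows.append(photo("S2", "S2-C2", 600 + 40 * e, "fox", codes="D"))  # (50)
    photos = pd.DataFrame(rows)
    assert len(photos) == 50

    expected = {
        # may 2024 (analysis period)
        "events_total": {
            ("S1", "fox"): 1 + 2 + 1 + 1 + 1 + 1 + 1,  # blocks 1-6, 9
            ("S1", "coyote"): 1,
            ("S2", "fox"): 1 + 24,
            ("S2", "coyote"): 1,
            ("S2", "nilgai"): 1,
        },
        # construction month contributes total-only events
        "events_construction": {("S1", "fox"): 3},
        "A": {("S1", "fox"): 1 + 2 + 1, ("S2", "nilgai"): 1},
        "failed": {  # B + C + E
            ("S1", "fox"): 2 + 1 + 1,   # block-2 Cs, block-4 C, block-5 E
            ("S1", "coyote"): 1,
            ("S2", "fox"): 1,
            ("S2", "coyote"): 2,
            ("S2", "nilgai"): 1,
        },
    }
    return photos, expected
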
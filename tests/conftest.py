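"""Shared fixtures: a hand-built ten-birth dataset and a small colony."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nestchoice import SimConfig, generate_colony
from nestchoice.config import DAY
from nestchoice.dataset import ColonyDataset, genotype_columns
from nestchoice.simulate import simulate_dyad_panel


def stay(tag: int, box: int, t0: int, dur: int) -> dict:
    return {"tag": tag, "box": box, "entry_s": t0, "exit_s": t0 + dur}


def day_stay(tag: int, box: int, day: float, dur: int) -> dict:
    return stay(tag, box, int(day * DAY), dur)


def build_tenbirth_dataset() -> ColonyDataset:
    """Hand-built dataset: 10 births covering every bookkeeping branch.

    Planned outcomes (window 16 d, tracking 30 d, 300 s rule):

    =====  ===  ===  =======  ======================================
    birth  day  box  home     expectation
    =====  ===  ===  =======  ======================================
    101    40   1    {1}      excluded: no_options (first birth)
    110    46   3    {1,3}    option 101 (age 6); P=1/2; y=0
    102    45   2    {1,2}    option 101 (age 5); P=1/2; y=0
    103    50   1    {1,3}    options 101 (age 10), 110 (age 4); P=1;
                              y=1 chose 101 (resident in box 1)
    104    56   4    {4}      excluded: no_options
    105    57   5    {5}      cryptic pair with 106 (one is focal,
    106    57   5    {5}      the other excluded: cryptic_partner);
                              focal: option = partner (age 0), P=0, y=1
    107    58   9    --       excluded: no_home_area (never tagged)
    108    60   1    {1,2}    options 102 (age 15), 103 (age 10);
                              P=1; y=1 chose 103 (resident in box 1)
    109    62   3    {2,3}    option 110 (age 16, boundary); P=1/2;
                              y=1 chose 110
    =====  ===  ===  =======  ======================================

    Female 102 also has a 299 s stay in box 6 (below the 300 s rule, so
    box 6 is not regular) and 103 a stay exactly 300 s long in box 3
    (regular: threshold inclusive).
    """
    homes = {101: [1], 102: [1, 2], 103: [1], 104: [4], 105: [5],
             106: [5], 108: [1, 2], 109: [2, 3], 110: [1, 3]}
    births = [
        (101, 40, 1), (110, 46, 3), (102, 45, 2), (103, 50, 1),
        (104, 56, 4), (105, 57, 5), (106, 57, 5), (107, 58, 9),
        (108, 60, 1), (109, 62, 3),
    ]
    bday = {m: d for m, d, _ in births}
    events = []
    for f, boxes in homes.items():
        for b in boxes:
            events.append(day_stay(f, b, bday[f] - 10 + b * 0.05, 3600))
    events.append(day_stay(102, 6, bday[102] - 5, 299))   # sub-threshold
    events.append(day_stay(103, 3, bday[103] - 5, 300))   # exactly 300 s
    events = pd.DataFrame(events)

    rows = [{"mother": m, "birth_day": d, "date": f"day{d}", "box": b,
             "litter_size": 4, "observed_size": 4, "discovery_age": 0}
            for m, d, b in births]
    births_df = pd.DataFrame(rows)

    mothers = sorted({m for m, _, _ in births})
    pedigree = pd.DataFrame({
        "id": mothers, "dam": pd.array([pd.NA] * len(mothers), dtype="Int64"),
        "sire": pd.array([pd.NA] * len(mothers), dtype="Int64"),
        "birth_day": -100, "date": "day-100", "sex": "F",
        "death_day": pd.NA})

    rng = np.random.default_rng(99)
    geno = pd.DataFrame(rng.integers(1, 5, size=(len(mothers), 6)),
                        columns=genotype_columns(3))
    geno.insert(0, "id", mothers)

    layout = pd.DataFrame({"box": list(range(1, 11)),
                           "x": [100.0 * b for b in range(1, 11)],
                           "y": 0.0, "section": 1})
    return ColonyDataset(events=events, births=births_df, genotypes=geno,
                         pedigree=pedigree, layout=layout)


# the ten-birth fixture's home areas, mirrored for the oracle in tests
TENBIRTH_HOMES = {101: {1}, 102: {1, 2}, 103: {1, 3}, 104: {4},
                  105: {5}, 106: {5}, 108: {1, 2}, 109: {2, 3},
                  110: {1, 3}}


@pytest.fixture(scope="session")
def tenbirth() -> ColonyDataset:
    return build_tenbirth_dataset()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=4, n_founders=12, study_days=540)


@pytest.fixture(scope="session")
def small_colony(small_config) -> ColonyDataset:
    return generate_colony(small_config)


@pytest.fixture(scope="session")
def panel60():
    return simulate_dyad_panel(60, seed=3)
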
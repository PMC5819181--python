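"""Seeded generator of a synthetic barn colony.

The generator emulates the data structure of a two-year RFID study of
free-living house mice in a sectioned barn: an age-structured pedigree with
overlapping generations, Mendelian microsatellite genotypes from Dirichlet
founder frequencies, kin-clustered female settlement (daughters settle near
their mothers), per-female nest-box movement producing a realistic antenna
event log, and litters whose nest-box placement follows a configurable
decision rule (random box / occupancy power law / covariate preference).

Every downstream inference has recorded ground truth: the pedigree, the
founder allele frequencies, home centres, and the per-birth decision record
(occupancy proportion P, options, outcome, chosen partner).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import DAY, SimConfig
from .dataset import ColonyDataset, genotype_columns
from . import tracking
from .relatedness import PedigreeKinship

GESTATION_DAYS = 20          # house-mouse gestation is 19-21 days
REST_START_HOURS = (9.0, 11.0)
SHORT_VISIT_S = (120, 900)
EXPLORE_VISIT_S = (30, 60)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class _Indiv:
    id: int
    dam: int | None
    sire: int | None
    birth_day: int
    sex: str
    death_day: int
    generation: int
    breeds: bool


@dataclass
class Litter:
    dam: int
    sire: int
    birth_day: int
    pup_ids: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.pup_ids)


def _trunc_poisson(rng: np.random.Generator, mean: float) -> int:
    """Poisson truncated at 1 (a litter has at least one pup)."""
    for _ in range(1000):
        k = rng.poisson(mean)
        if k >= 1:
            return int(k)
    return 1


def simulate_pedigree(config: SimConfig,
                      rng: np.random.Generator | None = None,
                      min_dyads_per_class: int = 50,
                      check_dyads: bool = True
                      ) -> tuple[pd.DataFrame, list[Litter]]:
    """Age-structured pedigree with overlapping generations.

    Founders are adults shortly before the study window opens; females
    breed from ``first_litter_age_days`` at intervals drawn uniformly from
    ``interbirth_days``, reusing the previous sire with probability
    ``mate_fidelity`` (producing full sibs across litters) and otherwise
    mating with a random adult male alive at conception (producing paternal
    half sibs).  Generations up to ``n_generations - 1`` breed; the last
    generation exists as pups only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.n_founders < 4:
        raise ValueError("need at least 4 founders")

    indivs: list[_Indiv] = []
    next_id = 1

    def add(dam, sire, birth_day, sex, generation) -> _Indiv:
        nonlocal next_id
        if generation == 0 or rng.random() < config.pup_survival:
            death = birth_day + config.adult_age_days + \
                rng.exponential(config.mean_adult_lifespan_days)
        else:
            death = birth_day + rng.uniform(5, 30)
        breeds = (sex == "F" and generation < config.n_generations
                  and death > birth_day + config.first_litter_age_days)
        ind = _Indiv(id=next_id, dam=dam, sire=sire, birth_day=int(birth_day),
                     sex=sex, death_day=int(math.ceil(death)),
                     generation=generation, breeds=breeds)
        indivs.append(ind)
        next_id += 1
        return ind

    for k in range(config.n_founders):
        sex = "F" if k % 2 == 0 else "M"
        bday = int(rng.integers(-180, -90))
        add(None, None, bday, sex, 0)

    litters: list[Litter] = []
    queue = [i for i in indivs if i.breeds]
    qi = 0
    while qi < len(queue):
        fem = queue[qi]
        qi += 1
        t = fem.birth_day + config.first_litter_age_days + rng.uniform(0, 30)
        prev_sire: _Indiv | None = None
        while t < min(fem.death_day, config.study_days):
            day = int(round(t))
            conception = day - GESTATION_DAYS
            sire = None
            if prev_sire is not None and rng.random() < config.mate_fidelity \
                    and _is_adult_male(prev_sire, conception, config):
                sire = prev_sire
            else:
                pool = [m for m in indivs
                        if _is_adult_male(m, conception, config)]
                if pool:
                    sire = pool[rng.integers(len(pool))]
            if sire is not None:
                prev_sire = sire
                litter = Litter(dam=fem.id, sire=sire.id, birth_day=day)
                for _ in range(_trunc_poisson(rng, config.litter_mean)):
                    sex = "F" if rng.random() < 0.5 else "M"
                    pup = add(fem.id, sire.id, day, sex, fem.generation + 1)
                    litter.pup_ids.append(pup.id)
                    if pup.breeds:
                        queue.append(pup)
                litters.append(litter)
            t += rng.uniform(*config.interbirth_days)

    pedigree = pd.DataFrame({
        "id": [i.id for i in indivs],
        "dam": pd.array([i.dam for i in indivs], dtype="Int64"),
        "sire": pd.array([i.sire for i in indivs], dtype="Int64"),
        "birth_day": [i.birth_day for i in indivs],
        "date": [_iso_date(i.birth_day, config) for i in indivs],
        "sex": [i.sex for i in indivs],
        "death_day": [i.death_day for i in indivs],
        "generation": [i.generation for i in indivs],
    })
    litters.sort(key=lambda lt: (lt.birth_day, lt.dam))
    if check_dyads:
        _check_dyad_classes(pedigree, min_dyads_per_class)
    return pedigree, litters


def _is_adult_male(ind: _Indiv, day: int, config: SimConfig) -> bool:
    return (ind.sex == "M"
            and ind.birth_day + config.adult_age_days <= day < ind.death_day)


def _iso_date(day: int, config: SimConfig) -> str:
    return str((pd.Timestamp(config.epoch_date)
                + pd.Timedelta(days=int(day))).date())


def _check_dyad_classes(pedigree: pd.DataFrame, minimum: int) -> None:
    from .relatedness import enumerate_dyads_by_class
    pools = enumerate_dyads_by_class(pedigree)
    for cls, pairs in pools.items():
        if len(pairs) < minimum:
            raise ValueError(
                f"config infeasible: pedigree yields only {len(pairs)} "
                f"{cls} dyads (need {minimum}); increase founders, "
                f"generations or litter sizes")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(pedigree: pd.DataFrame, config: SimConfig,
                       rng: np.random.Generator | None = None,
                       founder_freqs: np.ndarray | None = None
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Mendelian genotype transmission down the pedigree.

    Founder allele frequencies are drawn per locus from a symmetric
    Dirichlet; founders sample two alleles from them, non-founders receive
    one allele Mendelian-sampled from each parent.  An individual with one
    unknown parent receives the missing allele from the founder
    frequencies.  Allele codes are 1-based (0 = missing call).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L, A = config.n_loci, config.alleles_per_locus
    if founder_freqs is None:
        founder_freqs = rng.dirichlet([config.dirichlet_conc] * A, size=L)
    order = pedigree.sort_values("birth_day", kind="stable")
    geno: dict[int, np.ndarray] = {}

    def founder_draw(n: int) -> np.ndarray:
        out = np.empty((L, n), dtype=np.int16)
        for loc in range(L):
            out[loc] = rng.choice(A, size=n, p=founder_freqs[loc]) + 1
        return out

    for _, row in order.iterrows():
        i = int(row["id"])
        dam = None if pd.isna(row["dam"]) else int(row["dam"])
        sire = None if pd.isna(row["sire"]) else int(row["sire"])
        g = np.empty((L, 2), dtype=np.int16)
        for slot, parent in enumerate((dam, sire)):
            if parent is None:
                g[:, slot] = founder_draw(1)[:, 0]
            else:
                pick = rng.integers(0, 2, size=L)
                g[:, slot] = geno[parent][np.arange(L), pick]
        geno[i] = g

    ids = pedigree["id"].to_numpy()
    arr = np.stack([geno[int(i)] for i in ids])          # (n, L, 2)
    if config.ungenotyped_rate > 0:
        drop = rng.random(len(ids)) < config.ungenotyped_rate
        arr[drop] = 0
    if config.genotype_missing_rate > 0:
        mask = rng.random((len(ids), L)) < config.genotype_missing_rate
        arr[mask] = 0
    table = pd.DataFrame(arr.reshape(len(ids), -1),
                         columns=genotype_columns(L))
    table.insert(0, "id", ids)
    return table, founder_freqs


# ---------------------------------------------------------------------------
# settlement, movement, event log
# ---------------------------------------------------------------------------

def make_layout(config: SimConfig) -> pd.DataFrame:
    """Nest boxes on a grid: sections tile the barn, boxes tile sections."""
    W, H = config.barn_size_cm
    ns = config.n_sections
    scols = int(math.ceil(math.sqrt(ns)))
    srows = int(math.ceil(ns / scols))
    sw, sh = W / scols, H / srows
    bcols = 5 if config.boxes_per_section % 5 == 0 else \
        int(math.ceil(math.sqrt(config.boxes_per_section)))
    brows = int(math.ceil(config.boxes_per_section / bcols))
    rows = []
    box_id = 1
    for s in range(ns):
        sx, sy = (s % scols) * sw, (s // scols) * sh
        placed = 0
        for r in range(brows):
            for c in range(bcols):
                if placed >= config.boxes_per_section:
                    break
                rows.append({
                    "box": box_id,
                    "x": round(sx + (c + 0.5) * sw / bcols, 1),
                    "y": round(sy + (r + 0.5) * sh / brows, 1),
                    "section": s + 1,
                })
                box_id += 1
                placed += 1
    return pd.DataFrame(rows)


def simulate_settlement_and_movement(
        pedigree: pd.DataFrame, config: SimConfig,
        rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Kin-clustered settlement and the antenna event log.

    Daughters' home centres are displaced from their mother's by an
    exponential distance (mean ``dispersal_mean_cm``) in a uniform
    direction, clipped to the barn; founder females settle uniformly.
    Each adult female's day has one long rest stay (in a weighted home
    box) plus short visits, and occasional sub-300-s exploration visits to
    distant boxes, so that the count of regularly-used boxes averages
    ``home_boxes_mean``.  Per-individual stays never overlap in time.

    Returns (layout, home_centres, events).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layout = make_layout(config)
    box_xy = layout[["x", "y"]].to_numpy()
    box_ids = layout["box"].to_numpy()
    W, H = config.barn_size_cm

    order = pedigree.sort_values("birth_day", kind="stable")
    centres: dict[int, tuple[float, float]] = {}
    for _, row in order.iterrows():
        i = int(row["id"])
        dam = None if pd.isna(row["dam"]) else int(row["dam"])
        if dam is None or dam not in centres:
            centres[i] = (rng.uniform(0, W), rng.uniform(0, H))
        else:
            d = rng.exponential(config.dispersal_mean_cm)
            theta = rng.uniform(0, 2 * math.pi)
            mx, my = centres[dam]
            centres[i] = (float(np.clip(mx + d * math.cos(theta), 0, W)),
                          float(np.clip(my + d * math.sin(theta), 0, H)))

    home_centres = pd.DataFrame({
        "id": list(centres),
        "x": [round(c[0], 1) for c in centres.values()],
        "y": [round(c[1], 1) for c in centres.values()],
    })

    females = order[order["sex"] == "F"]
    tag_rows: list[tuple[int, int, int, int]] = []
    home_boxes: dict[int, np.ndarray] = {}
    home_weights: dict[int, np.ndarray] = {}
    for _, row in females.iterrows():
        i = int(row["id"])
        start = max(int(row["birth_day"]) + config.adult_age_days, 0)
        stop = min(int(row["death_day"]), config.study_days)
        if stop <= start:
            continue
        cx, cy = centres[i]
        dist = np.hypot(box_xy[:, 0] - cx, box_xy[:, 1] - cy)
        k = int(np.clip(round(rng.normal(config.home_boxes_mean,
                                         config.home_boxes_sd)),
                        2, len(box_ids)))
        nearest = np.argsort(dist)[:k]
        weights = 0.6 ** np.arange(k)
        weights /= weights.sum()
        home_boxes[i] = box_ids[nearest]
        home_weights[i] = weights
        far = box_ids[np.argsort(dist)[k:]]
        _female_days(rng, config, i, start, stop, box_ids[nearest], weights,
                     far, tag_rows)

    events = pd.DataFrame(tag_rows,
                          columns=["tag", "box", "entry_s", "exit_s"])
    events = events.sort_values(["entry_s", "tag"]).reset_index(drop=True)
    return layout, home_centres, events


def _female_days(rng, config, tag, start_day, stop_day, boxes, weights,
                 far_boxes, out_rows) -> None:
    n_days = stop_day - start_day
    rest_start_h = rng.uniform(*REST_START_HOURS, size=n_days)
    rest_dur_h = rng.uniform(*config.rest_hours, size=n_days)
    rest_box = rng.choice(boxes, size=n_days, p=weights)
    n_short = rng.poisson(config.short_visits_per_day, size=n_days)
    explore = rng.random(n_days) < config.exploration_prob
    for d in range(n_days):
        t0 = (start_day + d) * DAY
        rest_s = t0 + int(rest_start_h[d] * 3600)
        rest_e = rest_s + int(rest_dur_h[d] * 3600)
        out_rows.append((tag, int(rest_box[d]), rest_s, rest_e))
        # short visits: some before the rest stay, the remainder after
        n = int(n_short[d])
        n_before = n // 2
        cursor = t0 + int(rng.uniform(3600, 3 * 3600))
        for _ in range(n_before):
            cursor += int(rng.exponential(3600))
            dur = int(rng.uniform(*SHORT_VISIT_S))
            if cursor + dur >= rest_s - 60:
                break
            out_rows.append((tag, int(rng.choice(boxes, p=weights)),
                             cursor, cursor + dur))
            cursor += dur
        cursor = rest_e + 600
        for _ in range(n - n_before):
            cursor += int(rng.exponential(3600))
            dur = int(rng.uniform(*SHORT_VISIT_S))
            if cursor + dur >= t0 + DAY - 60:
                break
            out_rows.append((tag, int(rng.choice(boxes, p=weights)),
                             cursor, cursor + dur))
            cursor += dur
        if explore[d] and len(far_boxes) and cursor + 120 < t0 + DAY - 60:
            cursor += 60
            dur = int(rng.uniform(*EXPLORE_VISIT_S))
            out_rows.append((tag, int(rng.choice(far_boxes)),
                             cursor, cursor + dur))


def nest_check_schedule(config: SimConfig) -> pd.DataFrame:
    """First nest check of each month, at 13:00 (mice usually resting)."""
    epoch = pd.Timestamp(config.epoch_date)
    months = pd.date_range(epoch, epoch + pd.Timedelta(days=config.study_days),
                           freq="MS")
    rows = []
    for k, m in enumerate(months):
        day = (m - epoch).days
        if 0 <= day < config.study_days:
            rows.append({"check_id": k + 1, "time_s": day * DAY + 13 * 3600,
                         "date": str(m.date())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# births and nursing decisions
# ---------------------------------------------------------------------------

def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_births_and_decisions(
        pedigree: pd.DataFrame, litters: list[Litter], layout: pd.DataFrame,
        events: pd.DataFrame, config: SimConfig,
        rng: np.random.Generator | None = None,
        kinship: PedigreeKinship | None = None
) -> tuple[pd.DataFrame, list[dict[str, Any]]]:
    """Place each litter in a nest box under the configured decision rule.

    Litters are processed chronologically.  For each focal birth the
    mother's regular boxes are computed from the event log exactly as the
    analysis does (>= 300 s within the 30 days before birth), the occupied
    boxes are those holding a <= 16-day-old litter, and P = occupied /
    regular.  Modes:

    * ``random_box`` — the focal picks uniformly among her regular boxes;
      the outcome is communal iff the picked box is occupied.
    * ``power`` — communal with probability P ** power_a; the box is then
      uniform among occupied (resp. unoccupied) regular boxes.
    * ``preference`` — communal with probability
      sigmoid(intercept + w * n_options); the partner follows a
      conditional-logit rule over (option-pup age, association hours,
      pedigree relatedness).

    Ground truth (mode, parameters, P, options, outcome, chosen partner,
    forcing flags) is recorded per birth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if kinship is None:
        kinship = PedigreeKinship(pedigree)
    idx = tracking.EventIndex(events)
    weights = config.preference_weights
    w16 = config.option_window_days

    # litters born before the study window are unobserved (no event data)
    observed = [lt for lt in litters if lt.birth_day >= 0]
    # randomise processing order within a day so cryptic (same-day) nests
    # do not depend on litter construction order
    day_jitter = rng.random(len(observed))
    order = np.lexsort((day_jitter, [lt.birth_day for lt in observed]))
    observed = [observed[i] for i in order]

    placed: list[dict[str, Any]] = []    # birth rows, chronological
    truth: list[dict[str, Any]] = []

    for lt in observed:
        day = lt.birth_day
        birth_ts = day * DAY
        ha = tracking.home_area(idx, lt.dam, birth_ts,
                                window_days=config.tracking_window_days)
        regular = sorted(ha.regular_boxes)
        flags: list[str] = []
        if not regular:
            # early birth with no tracking data: fall back to all boxes
            regular = sorted(layout["box"].tolist())
            flags.append("no_tracking_data")

        # litters already present: born 1..16 days before the focal birth.
        # Same-day litters are invisible at decision time; cryptic communal
        # nests arise when two same-day females happen to pick one box.
        qualifying = [b for b in placed
                      if day - w16 <= b["birth_day"] < day
                      and b["mother"] != lt.dam]
        occupied = sorted({b["box"] for b in qualifying if b["box"] in
                           set(regular)})
        P = len(occupied) / len(regular)
        options = [b for b in qualifying if b["box"] in set(occupied)]

        mode = config.decision_mode
        communal = False
        box = None
        chosen = None
        if mode == "random_box":
            box = int(rng.choice(regular))
            communal = box in set(occupied)
        elif mode == "power":
            communal = rng.random() < P ** config.power_a
            pool = occupied if communal else \
                [b for b in regular if b not in set(occupied)]
            box = int(rng.choice(pool))
        else:  # preference
            n_opt = len(options)
            if n_opt == 0:
                communal = False
                flags.append("forced_solitary")
                box = int(rng.choice(regular))
            else:
                p_comm = _sigmoid(weights.get("decision_intercept", 0.0)
                                  + weights.get("decision_n_options", 0.0)
                                  * n_opt)
                communal = rng.random() < p_comm
                unocc = [b for b in regular if b not in set(occupied)]
                if not communal and not unocc:
                    communal = True
                    flags.append("forced_communal")
                if communal:
                    util = np.array([
                        weights.get("pup_age", 0.0) * (day - o["birth_day"])
                        + weights.get("association", 0.0)
                        * tracking.meetings(idx, lt.dam, o["mother"],
                                            ha.window).seconds / 3600.0
                        + weights.get("relatedness", 0.0)
                        * kinship.expected_r(lt.dam, o["mother"])
                        for o in options])
                    pr = np.exp(util - util.max())
                    pr /= pr.sum()
                    pick = options[rng.choice(len(options), p=pr)]
                    box = int(pick["box"])
                    chosen = int(pick["mother"])
                else:
                    box = int(rng.choice(unocc))
        if communal and chosen is None and occupied:
            if box in {b["box"] for b in options}:
                in_box = [b for b in options if b["box"] == box]
                chosen = int(max(in_box, key=lambda b: b["birth_day"])
                             ["mother"])

        size = lt.size
        deaths = rng.binomial(size, config.pre_discovery_death_rate) \
            if config.pre_discovery_death_rate > 0 else 0
        lo, hi = config.discovery_age_days
        row = {
            "mother": lt.dam, "birth_day": day,
            "date": _iso_date(day, config), "box": box,
            "litter_size": size, "observed_size": max(size - deaths, 0),
            "discovery_age": int(rng.integers(lo, hi + 1)),
        }
        placed.append(row)
        truth.append({
            "mother": lt.dam, "birth_day": day, "box": box,
            "P": P, "n_regular": len(regular), "n_options": len(options),
            "communal": bool(communal), "chosen": chosen, "flags": flags,
        })

    births = pd.DataFrame(placed).sort_values(
        ["birth_day", "mother"]).reset_index(drop=True)
    return births, truth


# ---------------------------------------------------------------------------
# end-to-end generation
# ---------------------------------------------------------------------------

def generate_colony(config: SimConfig) -> ColonyDataset:
    """Run all generator stages under one master seed (split per stage)."""
    ss = np.random.SeedSequence(config.seed)
    s_ped, s_gen, s_mov, s_dec = ss.spawn(4)
    pedigree, litters = simulate_pedigree(
        config, np.random.default_rng(s_ped))
    genotypes, founder_freqs = simulate_genotypes(
        pedigree, config, np.random.default_rng(s_gen))
    layout, centres, events = simulate_settlement_and_movement(
        pedigree, config, np.random.default_rng(s_mov))
    births, decisions = simulate_births_and_decisions(
        pedigree, litters, layout, events, config,
        np.random.default_rng(s_dec))
    checks = nest_check_schedule(config)
    truth = {
        "config": config.to_dict(),
        "founder_freqs": founder_freqs.tolist(),
        "home_centres": {str(r["id"]): [r["x"], r["y"]]
                         for _, r in centres.iterrows()},
        "decisions": decisions,
    }
    ped_out = pedigree.drop(columns=["generation"])
    return ColonyDataset(events=events, births=births, genotypes=genotypes,
                         pedigree=ped_out, layout=layout, checks=checks,
                         truth=truth)


# ---------------------------------------------------------------------------
# dyad validation panel
# ---------------------------------------------------------------------------

def simulate_dyad_panel(n_per_class: int = 500, n_loci: int = 25,
                        alleles_per_locus: int = 8,
                        dirichlet_conc: float = 1.0, seed: int = 0
                        ) -> tuple[pd.DataFrame, pd.DataFrame,
                                   dict[str, list[tuple[int, int]]]]:
    """Independent families yielding one dyad of each pedigree class.

    Unlike a closed colony -- where even "unrelated" dyads share distant
    founder ancestry and so carry background relatedness -- every family
    here draws fresh founders, so the pedigree-class expectations (0.5,
    0.5, 0.25, 0) are exact.  Per family: a full-sib pair, a half-sib
    pair (one shared parent), a parent-offspring pair, and two extra
    founders as the unrelated pair; the four dyads are disjoint.

    Returns (pedigree, genotypes, dyads-by-class).
    """
    rows = []
    dyads: dict[str, list[tuple[int, int]]] = {
        "full_sib": [], "parent_offspring": [], "half_sib": [],
        "unrelated": []}
    nid = 0

    def add(dam=None, sire=None, birth_day=0):
        nonlocal nid
        nid += 1
        rows.append({"id": nid, "dam": dam, "sire": sire,
                     "birth_day": birth_day, "date": "2000-01-01",
                     "sex": "F", "death_day": pd.NA})
        return nid

    for _ in range(n_per_class):
        f = [add() for _ in range(9)]                    # founders
        c1 = add(dam=f[0], sire=f[1], birth_day=1)
        c2 = add(dam=f[0], sire=f[1], birth_day=1)
        h1 = add(dam=f[2], sire=f[3], birth_day=1)
        h2 = add(dam=f[2], sire=f[4], birth_day=1)
        po = add(dam=f[5], sire=f[6], birth_day=1)
        dyads["full_sib"].append((c1, c2))
        dyads["half_sib"].append((h1, h2))
        dyads["parent_offspring"].append((f[5], po))
        dyads["unrelated"].append((f[7], f[8]))

    pedigree = pd.DataFrame(rows)
    pedigree["dam"] = pedigree["dam"].astype("Int64")
    pedigree["sire"] = pedigree["sire"].astype("Int64")
    cfg = SimConfig(seed=seed, n_loci=n_loci,
                    alleles_per_locus=alleles_per_locus,
                    dirichlet_conc=dirichlet_conc,
                    genotype_missing_rate=0.0, ungenotyped_rate=0.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genotypes, _ = simulate_genotypes(pedigree, cfg, rng=rng)
    return pedigree, genotypes, dyads
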
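"""Choice-set construction: focal births, option females, occupancy P.

For every focal birth this module assembles the decision the pregnant
female faced: the set of *option females* (mothers of litters born within
the 16 days before her birth in the nest boxes she regularly used), the
occupancy proportion P (occupied regular boxes / regular boxes), the
outcome (communal if she gave birth into a box already holding a
qualifying litter, solitary otherwise), and the per-option covariates the
partner-choice analysis needs.

Cryptic communal nests — two females giving birth the same day in the same
box — are resolved by a seeded random designation of the focal female; a
focal who joins an existing cryptic nest gets a single pseudo-option whose
covariates are the arithmetic mean over the two residents.

Births with zero options are excluded from the decision analysis and
counted separately; the exclusion bookkeeping is exact
(events + excluded = births).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .config import DAY
from .dataset import ColonyDataset, genotype_lookup
from . import tracking
from .relatedness import (AlleleFrequencies, ESTIMATORS,
                          cohort_year_frequencies)

OPTION_WINDOW_DAYS = 16

#: continuous option covariates that participate in centring/scaling
SCALED_OPTION_COLUMNS = ["pup_age", "litter_size_diff", "shared_boxes",
                         "age_diff", "option_age", "r_hat", "association_s"]


@dataclass
class OptionRecord:
    option_id: int                      # -1 for an averaged cryptic pseudo-option
    pup_age: int                        # option litter age at focal birth, days
    litter_size_diff: float             # absolute, observed sizes
    shared_boxes: int                   # focal's regular boxes also regular for option
    age_diff: float                     # absolute female age difference, days
    option_age: float                   # option female age at focal birth, days
    r_hat: float | None                 # pairwise relatedness, None if missing
    association_s: int                  # association time in focal's window
    option_litter_solitary: bool
    chosen: bool = False
    juvenile_familiar: bool = False     # descriptive flag only
    members: tuple[int, ...] = ()       # residents behind a pseudo-option


@dataclass
class ChoiceEvent:
    event_id: int
    focal: int
    birth_day: int
    home_area: tracking.HomeArea
    options: list[OptionRecord]
    P: float
    y: int                              # 1 communal, 0 solitary
    chosen_id: int | None
    cryptic: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def n_options(self) -> int:
        return len(self.options)


@dataclass
class ChoiceTable:
    events: list[ChoiceEvent]
    excluded: pd.DataFrame              # birth rows that yield no event, with reason
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def event_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append({
                "event_id": e.event_id, "focal": e.focal,
                "birth_day": e.birth_day, "n_regular_boxes":
                    e.home_area.n_regular, "n_options": e.n_options,
                "P": e.P, "y": e.y,
                "chosen": e.chosen_id if e.chosen_id is not None else pd.NA,
                "cryptic": e.cryptic, "flags": ";".join(e.flags),
            })
        return pd.DataFrame(rows)

    def option_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            for o in e.options:
                rows.append({
                    "event_id": e.event_id, "focal": e.focal,
                    "option_id": o.option_id, "pup_age": o.pup_age,
                    "litter_size_diff": o.litter_size_diff,
                    "shared_boxes": o.shared_boxes, "age_diff": o.age_diff,
                    "option_age": o.option_age, "r_hat": o.r_hat,
                    "association_s": o.association_s,
                    "option_litter_solitary": o.option_litter_solitary,
                    "chosen": o.chosen,
                    "juvenile_familiar": o.juvenile_familiar,
                })
        frame = pd.DataFrame(rows)
        if self.scaling and len(frame):
            frame = apply_scaling(frame, self.scaling)
        return frame


# ---------------------------------------------------------------------------
# litter classification
# ---------------------------------------------------------------------------

def classify_litters(births: pd.DataFrame,
                     window_days: int = OPTION_WINDOW_DAYS) -> pd.DataFrame:
    """Group litters into nests: litters sharing a box within 16 days.

    Returns the birth table with ``nest_id``, ``nest_size`` (litters in the
    nest), ``nest_type`` (solitary / communal), ``cryptic`` (same-day
    same-box pair) and ``joiner`` (the litter was born into a box already
    holding a younger-than-17-days litter).
    """
    out = births.sort_values(["box", "birth_day"]).reset_index()
    nest_id = np.zeros(len(out), dtype=int)
    current = 0
    for i in range(len(out)):
        if i == 0 or out.loc[i, "box"] != out.loc[i - 1, "box"] \
                or out.loc[i, "birth_day"] - out.loc[i - 1, "birth_day"] \
                > window_days:
            current += 1
        nest_id[i] = current
    out["nest_id"] = nest_id
    sizes = out.groupby("nest_id")["mother"].transform("size")
    out["nest_size"] = sizes
    out["nest_type"] = np.where(sizes > 1, "communal", "solitary")
    first_day = out.groupby("nest_id")["birth_day"].transform("min")
    same_first = out.groupby("nest_id")["birth_day"].transform(
        lambda s: (s == s.min()).sum())
    out["cryptic"] = (sizes > 1) & (same_first > 1) \
        & (out["birth_day"] == first_day)
    out["joiner"] = (sizes > 1) & (out["birth_day"] > first_day)
    return out.set_index("index").sort_index().rename_axis(None)


def resolve_cryptic(group: list[int], seed: int) -> int:
    """Seeded random designation of the focal female in a cryptic nest."""
    if len(group) < 2:
        raise ValueError("cryptic group needs at least two females")
    ss = np.random.SeedSequence([int(seed)] + sorted(int(g) for g in group))
    rng = np.random.default_rng(ss)
    return int(sorted(group)[rng.integers(len(group))])


# ---------------------------------------------------------------------------
# option sets and occupancy
# ---------------------------------------------------------------------------

def qualifying_litters(births: pd.DataFrame, focal: int, birth_day: int,
                       window_days: int = OPTION_WINDOW_DAYS) -> pd.DataFrame:
    """Other mothers' litters born 1..16 days before the focal birth."""
    sel = (births["mother"] != focal) \
        & (births["birth_day"] >= birth_day - window_days) \
        & (births["birth_day"] < birth_day)
    return births[sel]


def option_females(births: pd.DataFrame, focal: int, birth_day: int,
                   home_area: tracking.HomeArea,
                   window_days: int = OPTION_WINDOW_DAYS) -> pd.DataFrame:
    """Qualifying litters located in the focal's regular boxes.

    Litters older than 16 days at the focal birth are past-weaning and
    excluded, as are litters in boxes the focal did not regularly use.
    """
    qual = qualifying_litters(births, focal, birth_day, window_days)
    return qual[qual["box"].isin(home_area.regular_boxes)]


def occupancy_proportion(home_area: tracking.HomeArea,
                         births: pd.DataFrame, focal: int,
                         birth_day: int,
                         window_days: int = OPTION_WINDOW_DAYS) -> float:
    """P = occupied regular boxes / regular boxes (boxes, not litters)."""
    if home_area.n_regular == 0:
        raise ValueError(f"female {focal} has an empty home area")
    opts = option_females(births, focal, birth_day, home_area, window_days)
    return len(set(opts["box"])) / home_area.n_regular


# ---------------------------------------------------------------------------
# full table
# ---------------------------------------------------------------------------

class _Covariates:
    """Shared context for building option covariates."""

    def __init__(self, dataset: ColonyDataset, estimator: str,
                 window_days: int, tracking_window_days: int,
                 days_per_year: int = 365):
        self.births = dataset.births.reset_index(drop=True)
        self.pedigree = dataset.pedigree.set_index("id")
        self.idx = tracking.EventIndex(dataset.events)
        self.estimator = ESTIMATORS[estimator]
        self.estimator_name = estimator
        self.geno = genotype_lookup(dataset.genotypes)
        self.genotypes = dataset.genotypes
        self.window_days = window_days
        self.tracking_window_days = tracking_window_days
        self.days_per_year = days_per_year
        self._freqs: dict[int, AlleleFrequencies] = {}
        self._home: dict[tuple[int, int], tracking.HomeArea] = {}
        self._dataset = dataset

    def home_area(self, female: int, birth_day: int) -> tracking.HomeArea:
        key = (int(female), int(birth_day))
        if key not in self._home:
            self._home[key] = tracking.home_area(
                self.idx, female, birth_day * DAY,
                window_days=self.tracking_window_days)
        return self._home[key]

    def year_freqs(self, year: int) -> AlleleFrequencies:
        if year not in self._freqs:
            try:
                self._freqs[year] = cohort_year_frequencies(
                    self.genotypes, self._dataset.pedigree, year,
                    days_per_year=self.days_per_year)
            except ValueError:
                # degenerate cohort (no females born that year): fall back
                # to the whole genotyped sample
                from .relatedness import allele_frequencies
                self._freqs[year] = allele_frequencies(self.genotypes)
        return self._freqs[year]

    def relatedness(self, a: int, b: int, year: int) -> float | None:
        if a not in self.geno or b not in self.geno:
            return None
        est = self.estimator(self.geno[a], self.geno[b],
                             self.year_freqs(year), dyad=(a, b))
        return est.r_hat

    def age_days(self, female: int, at_day: int) -> float | None:
        if female not in self.pedigree.index:
            return None
        return float(at_day - self.pedigree.loc[female, "birth_day"])

    def natal_litter(self, female: int) -> tuple[int, int] | None:
        """(birth box, birth day) of the female's own natal litter."""
        if female not in self.pedigree.index:
            return None
        dam = self.pedigree.loc[female, "dam"]
        bday = int(self.pedigree.loc[female, "birth_day"])
        if pd.isna(dam):
            return None
        rows = self.births[(self.births["mother"] == int(dam))
                           & (self.births["birth_day"] == bday)]
        if len(rows) == 0:
            return None
        return int(rows.iloc[0]["box"]), bday

    def juvenile_familiar(self, a: int, b: int) -> bool:
        """Same birth litter, or same communal nest with <=16 d age gap."""
        if a not in self.pedigree.index or b not in self.pedigree.index:
            return False
        ra, rb = self.pedigree.loc[a], self.pedigree.loc[b]
        if not pd.isna(ra["dam"]) and not pd.isna(rb["dam"]) \
                and int(ra["dam"]) == int(rb["dam"]) \
                and ra["birth_day"] == rb["birth_day"]:
            return True
        na, nb = self.natal_litter(a), self.natal_litter(b)
        if na is None or nb is None:
            return False
        return na[0] == nb[0] and abs(na[1] - nb[1]) <= OPTION_WINDOW_DAYS

    def option_litter_solitary(self, option: pd.Series,
                               focal_day: int) -> bool:
        """Was the option litter still the only litter in its nest, as seen
        the day before the focal birth?"""
        o_day, o_box = int(option["birth_day"]), int(option["box"])
        others = self.births[
            (self.births["box"] == o_box)
            & (self.births["birth_day"] < focal_day)
            & (abs(self.births["birth_day"] - o_day) <= self.window_days)
            & ~((self.births["mother"] == option["mother"])
                & (self.births["birth_day"] == o_day))]
        return len(others) == 0

    def build_option(self, focal: int, focal_day: int, focal_size: float,
                     ha: tracking.HomeArea, option: pd.Series,
                     year: int) -> OptionRecord:
        mother = int(option["mother"])
        opt_ha = self.home_area(mother, int(option["birth_day"]))
        assoc = tracking.meetings(self.idx, focal, mother, ha.window)
        age_f = self.age_days(focal, focal_day)
        age_o = self.age_days(mother, focal_day)
        return OptionRecord(
            option_id=mother,
            pup_age=int(focal_day - option["birth_day"]),
            litter_size_diff=abs(float(focal_size)
                                 - float(option["observed_size"])),
            shared_boxes=len(ha.regular_boxes & opt_ha.regular_boxes),
            age_diff=abs(age_f - age_o)
            if age_f is not None and age_o is not None else np.nan,
            option_age=age_o if age_o is not None else np.nan,
            r_hat=self.relatedness(focal, mother, year),
            association_s=assoc.seconds,
            option_litter_solitary=self.option_litter_solitary(
                option, focal_day),
            juvenile_familiar=self.juvenile_familiar(focal, mother),
        )


def _average_options(options: list[OptionRecord]) -> OptionRecord:
    """Arithmetic-mean pseudo-option over the residents of a cryptic nest."""
    rs = [o.r_hat for o in options]
    return OptionRecord(
        option_id=-1,
        pup_age=int(round(np.mean([o.pup_age for o in options]))),
        litter_size_diff=float(np.mean([o.litter_size_diff for o in options])),
        shared_boxes=int(round(np.mean([o.shared_boxes for o in options]))),
        age_diff=float(np.mean([o.age_diff for o in options])),
        option_age=float(np.mean([o.option_age for o in options])),
        r_hat=None if any(r is None for r in rs) else float(np.mean(rs)),
        association_s=int(round(np.mean([o.association_s for o in options]))),
        option_litter_solitary=all(o.option_litter_solitary
                                   for o in options),
        members=tuple(o.option_id for o in options),
    )


def build_choice_table(dataset: ColonyDataset, estimator: str = "wang",
                       seed: int = 0, scale: bool = False,
                       window_days: int = OPTION_WINDOW_DAYS,
                       tracking_window_days: int = 30,
                       days_per_year: int = 365) -> ChoiceTable:
    """One ChoiceEvent per focal birth that had at least one option.

    Exclusion reasons recorded per non-event birth: ``no_options``,
    ``no_home_area`` (no tracking data in the window) and
    ``cryptic_partner`` (the seeded designation picked the other female of
    a same-day pair as focal).  Events whose option covariates are
    incomplete (an option female without genotypes) are kept but flagged
    ``incomplete_relatedness``.
    """
    ctx = _Covariates(dataset, estimator, window_days, tracking_window_days,
                      days_per_year)
    births = ctx.births
    events: list[ChoiceEvent] = []
    excluded_rows: list[dict[str, Any]] = []
    event_id = 0
    for i, b in births.iterrows():
        focal = int(b["mother"])
        day = int(b["birth_day"])
        box = int(b["box"])
        year = day // days_per_year

        # cryptic designation: same-day same-box litters form one decision
        same_nest = births[(births["box"] == box)
                           & (births["birth_day"] == day)
                           & (births["mother"] != focal)]
        cryptic_group = [focal] + [int(m) for m in same_nest["mother"]]
        if len(cryptic_group) > 1 \
                and resolve_cryptic(cryptic_group, seed) != focal:
            excluded_rows.append({"mother": focal, "birth_day": day,
                                  "reason": "cryptic_partner"})
            continue

        ha = ctx.home_area(focal, day)
        if ha.n_regular == 0:
            excluded_rows.append({"mother": focal, "birth_day": day,
                                  "reason": "no_home_area"})
            continue

        opts_df = option_females(births, focal, day, ha, window_days)
        options = [ctx.build_option(focal, day, b["observed_size"], ha,
                                    row, year)
                   for _, row in opts_df.iterrows()]
        # cryptic partners enter as age-0 options
        for _, row in same_nest.iterrows():
            o = ctx.build_option(focal, day, b["observed_size"], ha, row,
                                 year)
            options.append(replace(o, pup_age=0))
        if not options:
            excluded_rows.append({"mother": focal, "birth_day": day,
                                  "reason": "no_options"})
            continue

        P = occupancy_proportion(ha, births, focal, day, window_days)
        flags: list[str] = []
        cryptic = len(cryptic_group) > 1
        residents = opts_df[opts_df["box"] == box]
        chosen_id: int | None = None
        if cryptic:
            y = 1
            partners = [o for o in options if o.pup_age == 0]
            if len(partners) == 1:
                chosen_id = partners[0].option_id
                partners[0].chosen = True
            else:  # >2 same-day litters: all-pairs averaging, flagged
                flags.append("multi_cryptic_average")
                options = [o for o in options if o.pup_age != 0]
                pseudo = _average_options(partners)
                pseudo.chosen = True
                options.append(pseudo)
        elif len(residents) >= 1:
            y = 1
            res_mothers = [int(m) for m in residents["mother"]]
            res_days = residents["birth_day"].tolist()
            if len(residents) >= 2 and len(set(res_days)) == 1:
                # joined an existing cryptic nest: averaged pseudo-option
                flags.append("cryptic_join")
                keep, members = [], []
                for o in options:
                    (members if o.option_id in res_mothers else keep).append(o)
                pseudo = _average_options(members)
                pseudo.chosen = True
                options = keep + [pseudo]
            else:
                # the nest is defined by its youngest resident litter
                youngest = residents.loc[residents["birth_day"].idxmax()]
                chosen_id = int(youngest["mother"])
                for o in options:
                    o.chosen = o.option_id == chosen_id
        else:
            y = 0

        if any(o.r_hat is None for o in options):
            flags.append("incomplete_relatedness")

        events.append(ChoiceEvent(
            event_id=event_id, focal=focal, birth_day=day, home_area=ha,
            options=options, P=P, y=y, chosen_id=chosen_id,
            cryptic=cryptic, flags=flags))
        event_id += 1

    excluded = pd.DataFrame(excluded_rows,
                            columns=["mother", "birth_day", "reason"])
    table = ChoiceTable(events=events, excluded=excluded)
    if scale:
        scale_options(table)
    return table


def scale_options(table: ChoiceTable) -> None:
    """Centre and scale the continuous option covariates in place.

    Means and standard deviations are stored in ``table.scaling`` so the
    transformation is invertible (see :func:`unscale_options`).
    """
    frame = table.option_frame()
    for col in SCALED_OPTION_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        mu = float(vals.mean())
        sd = float(vals.std(ddof=0))
        table.scaling[col] = (mu, sd if sd > 0 else 1.0)


def apply_scaling(frame: pd.DataFrame,
                  scaling: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = frame.copy()
    for col, (mu, sd) in scaling.items():
        if col in out:
            out[col] = (pd.to_numeric(out[col], errors="coerce") - mu) / sd
    return out


def unscale(frame: pd.DataFrame,
            scaling: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = frame.copy()
    for col, (mu, sd) in scaling.items():
        if col in out:
            out[col] = pd.to_numeric(out[col], errors="coerce") * sd + mu
    return out


# ---------------------------------------------------------------------------
# event-level covariates for the decision model
# ---------------------------------------------------------------------------

def decision_covariates(table: ChoiceTable, dataset: ColonyDataset,
                        monitoring_interval_days: int = 49,
                        days_per_year: int = 365) -> pd.DataFrame:
    """Per-event predictors of the communal-vs-solitary decision.

    Number of options, number of regular boxes, focal age, breeding
    experience (an earlier litter on record), adult population density at
    the closest population-monitoring event, and season (summer = March to
    August).
    """
    ped = dataset.pedigree.set_index("id")
    births = dataset.births
    adult_from = ped["birth_day"] + 60
    death = ped["death_day"] if "death_day" in ped else None
    monitor_days = np.arange(0, births["birth_day"].max() + 1,
                             monitoring_interval_days)

    def density(day: int) -> int:
        t = monitor_days[np.argmin(np.abs(monitor_days - day))]
        alive = adult_from <= t
        if death is not None:
            alive &= death > t
        return int(alive.sum())

    epoch = pd.Timestamp(dataset.truth.get("config", {}).get(
        "epoch_date", "2008-01-01"))
    rows = []
    for e in table.events:
        age = float(e.birth_day - ped.loc[e.focal, "birth_day"]) \
            if e.focal in ped.index else np.nan
        earlier = births[(births["mother"] == e.focal)
                         & (births["birth_day"] < e.birth_day)]
        month = (epoch + pd.Timedelta(days=e.birth_day)).month
        rows.append({
            "event_id": e.event_id, "y": e.y,
            "n_options": e.n_options,
            "n_regular_boxes": e.home_area.n_regular,
            "focal_age": age,
            "experience": int(len(earlier) > 0),
            "density": density(e.birth_day),
            "summer": int(3 <= month <= 8),
        })
    return pd.DataFrame(rows)
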
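"""Simulation and pipeline configuration.

Time base: integer seconds from the dataset epoch (day 0 of the study);
1 day = 86,400 s.  Dates in CSV output are ISO-8601, derived from the
configurable ``epoch_date``.  All geometry is in centimetres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

DAY = 86_400  # seconds

#: decision rules the generator can play out for a pregnant focal female
DECISION_MODES = ("random_box", "power", "preference")


@dataclass
class SimConfig:
    """Parameters of the synthetic barn colony.

    The defaults emulate the structure of a two-year study of a free-living
    house-mouse population in a 72 m^2 barn: four sections of ten nest boxes,
    females using on average ~5 nest boxes regularly, and pregnant females
    having on average ~3.5 potential nursing partners ("options") at a birth.
    """

    seed: int = 0

    # --- pedigree / demography ---
    n_founders: int = 16             # half female, half male
    n_generations: int = 3
    study_days: int = 730            # two year-cohorts
    adult_age_days: int = 60
    first_litter_age_days: int = 90
    mean_adult_lifespan_days: float = 200.0
    interbirth_days: tuple[float, float] = (40.0, 80.0)
    litter_mean: float = 5.0         # Poisson, truncated at 1
    pup_survival: float = 0.4        # probability a pup is recruited as adult
    mate_fidelity: float = 0.6       # P(reuse previous sire) -> full sibs

    # --- genetics ---
    n_loci: int = 25
    alleles_per_locus: int = 6
    dirichlet_conc: float = 1.0      # founder allele-frequency concentration
    genotype_missing_rate: float = 0.05  # per-locus missing-call probability
    ungenotyped_rate: float = 0.0        # P(an individual has no genotype)

    # --- space ---
    barn_size_cm: tuple[float, float] = (850.0, 850.0)
    n_sections: int = 4
    boxes_per_section: int = 10
    dispersal_mean_cm: float = 100.0  # mother-daughter home-centre distance

    # --- movement ---
    home_boxes_mean: float = 5.0
    home_boxes_sd: float = 1.2
    rest_hours: tuple[float, float] = (4.0, 7.0)
    short_visits_per_day: float = 3.0
    exploration_prob: float = 0.2     # P(one brief far-box visit on a day)

    # --- reproduction bookkeeping ---
    discovery_age_days: tuple[int, int] = (1, 12)   # uniform inclusive
    pre_discovery_death_rate: float = 0.0

    # --- nursing decision rule ---
    decision_mode: str = "random_box"
    power_a: float = 1.0
    preference_weights: dict[str, float] = field(
        default_factory=lambda: {
            "decision_intercept": 0.0,
            "decision_n_options": 0.5,
            "pup_age": -0.25,          # per day of option-pup age
            "association": 0.5,        # per hour of association time
            "relatedness": 1.0,        # per unit of pedigree r
        }
    )

    # --- analysis windows (study constants) ---
    option_window_days: int = 16
    tracking_window_days: int = 30

    # --- calendar ---
    epoch_date: str = "2008-01-01"

    def __post_init__(self) -> None:
        if self.decision_mode not in DECISION_MODES:
            raise ValueError(
                f"decision_mode must be one of {DECISION_MODES}, "
                f"got {self.decision_mode!r}"
            )
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.power_a <= 0:
            raise ValueError("power_a must be > 0")
        if self.n_founders < 4:
            raise ValueError("need at least 4 founders (both sexes)")
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        for name in ("pup_survival", "genotype_missing_rate",
                     "ungenotyped_rate", "exploration_prob",
                     "pre_discovery_death_rate", "mate_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("interbirth_days", "rest_hours", "discovery_age_days"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be an increasing "
                                 f"non-negative range, got ({lo}, {hi})")
        if self.study_days < 1:
            raise ValueError("study_days must be >= 1")
        if self.dispersal_mean_cm <= 0:
            raise ValueError("dispersal_mean_cm must be > 0")

    @property
    def n_boxes(self) -> int:
        return self.n_sections * self.boxes_per_section

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["barn_size_cm"] = list(self.barn_size_cm)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("barn_size_cm", "interbirth_days", "rest_hours",
                    "discovery_age_days"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
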
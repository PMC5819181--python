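"""End-to-end analysis pipeline: simulate, track, build choices, analyse.

``run_pipeline`` chains every stage on one synthetic colony and writes all
intermediate tables, the fitted models and a run manifest (configuration,
seeds, file checksums, library versions) under a single output directory,
so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import os
import platform
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import DAY, SimConfig
from .dataset import ColonyDataset, _json_default, genotype_lookup
from . import tracking
from .choices import build_choice_table, decision_covariates
from .relatedness import estimator_calibration
from .spatial import build_located_dataset, correlogram, plot_correlogram
from .stats import (fit_decision_model, fit_partner_model, fit_power_null,
                    mann_whitney)
from .simulate import generate_colony


@dataclass
class RunManifest:
    config: dict[str, Any]
    package_version: str = __version__
    python: str = field(default_factory=platform.python_version)
    library_versions: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)      # name -> path
    checksums: dict[str, str] = field(default_factory=dict)    # path -> sha256
    summary: dict[str, Any] = field(default_factory=dict)

    def add(self, name: str, path: str) -> None:
        self.outputs[name] = path
        with open(path, "rb") as fh:
            self.checksums[os.path.relpath(path)] = \
                hashlib.sha256(fh.read()).hexdigest()

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=_json_default)


def _library_versions() -> dict[str, str]:
    import matplotlib
    import scipy
    import statsmodels
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "matplotlib": matplotlib.__version__}


def _fit_to_dict(fit) -> dict[str, Any]:
    return {"kind": fit.kind, "names": list(fit.names),
            "coef": [float(c) for c in fit.coef],
            "se": [float(s) for s in fit.se],
            "loglik": float(fit.loglik), "n_events": int(fit.n_events),
            "converged": bool(fit.converged), "flags": list(fit.flags)}


def association_summary(dataset: ColonyDataset, table,
                        window_days: int = 30) -> pd.DataFrame:
    """Per choice event: number of distinct females met in the window."""
    idx = tracking.EventIndex(dataset.events)
    rows = []
    for e in table.events:
        t1 = e.birth_day * DAY
        window = (t1 - window_days * DAY, t1)
        met = 0
        for other in idx.tags:
            if other == e.focal:
                continue
            if tracking.meetings(idx, e.focal, other, window).n_meetings > 0:
                met += 1
        rows.append({"event_id": e.event_id, "focal": e.focal,
                     "birth_day": e.birth_day, "females_met": met})
    return pd.DataFrame(rows)


def run_pipeline(config: SimConfig | None = None, outdir: str = "run",
                 estimator: str = "wang", n_perm: int = 999,
                 n_boot: int = 1000, calibration_n: int = 50,
                 make_plot: bool = True, verbose: bool = True) -> RunManifest:
    """Run every stage on one synthetic colony; returns the run manifest.

    Output layout::

        outdir/
          data/         simulated colony tables (events, births, ...)
          tracking/     home areas and association summary
          choices/      choice events, options, exclusions, covariates
          relatedness/  estimator calibration report
          spatial/      correlogram table (and plot)
          stats/        fitted models
          summary.json  headline numbers
          manifest.json configuration, checksums, versions
    """
    if config is None:
        config = SimConfig()
    manifest = RunManifest(config=config.to_dict(),
                           library_versions=_library_versions())
    say = print if verbose else (lambda *a, **k: None)
    for sub in ("data", "tracking", "choices", "relatedness", "spatial",
                "stats"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)

    # 1. simulate ----------------------------------------------------------
    say(f"[1/6] simulating colony (seed={config.seed}) ...")
    dataset = generate_colony(config)
    for name, path in dataset.write(os.path.join(outdir, "data")).items():
        manifest.add(f"data/{name}", path)

    # 2. tracking ----------------------------------------------------------
    say("[2/6] home areas ...")
    homes = tracking.home_area_table(dataset.events, dataset.births,
                                     window_days=config.tracking_window_days)
    p = os.path.join(outdir, "tracking", "home_areas.csv")
    homes.to_csv(p, index=False)
    manifest.add("tracking/home_areas", p)

    # 3. choice sets -------------------------------------------------------
    say("[3/6] choice sets ...")
    table = build_choice_table(dataset, estimator=estimator,
                               seed=config.seed,
                               window_days=config.option_window_days,
                               tracking_window_days=config.tracking_window_days)
    events = table.event_frame()
    options = table.option_frame()
    deccov = decision_covariates(table, dataset)
    for name, df in [("events", events), ("options", options),
                     ("excluded", table.excluded),
                     ("decision_covariates", deccov)]:
        p = os.path.join(outdir, "choices", f"{name}.csv")
        df.to_csv(p, index=False)
        manifest.add(f"choices/{name}", p)
    assoc = association_summary(dataset, table,
                                window_days=config.tracking_window_days)
    p = os.path.join(outdir, "tracking", "females_met.csv")
    assoc.to_csv(p, index=False)
    manifest.add("tracking/females_met", p)

    # 4. relatedness calibration ------------------------------------------
    say("[4/6] relatedness calibration ...")
    calib = estimator_calibration(dataset.pedigree, dataset.genotypes,
                                  n_per_class=calibration_n,
                                  seed=config.seed)
    p = os.path.join(outdir, "relatedness", "calibration.csv")
    calib.to_csv(p, index=False)
    manifest.add("relatedness/calibration", p)

    # 5. spatial genetic structure ----------------------------------------
    say("[5/6] spatial autocorrelation ...")
    geno = genotype_lookup(dataset.genotypes)
    located = build_located_dataset(dataset.events, dataset.layout,
                                    dataset.checks,
                                    females=sorted(geno))
    corr = correlogram(located, geno, n_perm=n_perm, n_boot=n_boot,
                       seed=config.seed)
    p = os.path.join(outdir, "spatial", "correlogram.csv")
    corr.to_csv(p, index=False)
    manifest.add("spatial/correlogram", p)
    if make_plot:
        p = os.path.join(outdir, "spatial", "correlogram.png")
        plot_correlogram(corr, p)
        manifest.add("spatial/correlogram_plot", p)

    # 6. statistical models ------------------------------------------------
    say("[6/6] model fits ...")
    power = fit_power_null((events["P"].to_numpy(),
                            events["y"].to_numpy()))
    decision = fit_decision_model(deccov)
    partner = None
    partner_error = None
    try:
        partner = fit_partner_model(options)
    except (ValueError, KeyError) as exc:     # e.g. too few communal events
        partner_error = str(exc)

    complete = options.dropna(subset=["r_hat"])
    chosen_r = complete.loc[complete["chosen"].astype(bool), "r_hat"]
    other_r = complete.loc[~complete["chosen"].astype(bool), "r_hat"]
    if len(chosen_r) >= 2 and len(other_r) >= 2:
        W, mw_p = mann_whitney(chosen_r.to_numpy(), other_r.to_numpy())
        r_compare = {"mean_chosen": float(chosen_r.mean()),
                     "mean_unchosen": float(other_r.mean()),
                     "W": float(W), "p": float(mw_p)}
    else:
        r_compare = None

    fits = {"power_null": {"a": power.a, "se": power.se, "t": power.t,
                           "p": power.p, "n": power.n},
            "decision": _fit_to_dict(decision),
            "partner": _fit_to_dict(partner) if partner is not None
                       else {"error": partner_error},
            "chosen_vs_unchosen_relatedness": r_compare}
    p = os.path.join(outdir, "stats", "fits.json")
    with open(p, "w") as fh:
        json.dump(fits, fh, indent=1, default=_json_default)
    manifest.add("stats/fits", p)

    ring1 = corr.iloc[1] if len(corr) > 1 else None
    manifest.summary = {
        "n_births_observed": int(len(dataset.births)),
        "n_choice_events": int(len(events)),
        "n_excluded": int(len(table.excluded)),
        "communal_fraction": float(events["y"].mean()) if len(events) else None,
        "mean_options": float(events["n_options"].mean()) if len(events) else None,
        "mean_regular_boxes": float(events["n_regular_boxes"].mean())
            if len(events) else None,
        "mean_females_met": float(assoc["females_met"].mean())
            if len(assoc) else None,
        "power_a": power.a, "power_t": power.t, "power_p": power.p,
        "calibration": {row["estimator"]: float(row["pearson_r"])
                        for _, row in calib.iterrows()},
        "spatial_first_ring_r": float(ring1["r"]) if ring1 is not None else None,
        "spatial_first_ring_p": float(ring1["p"]) if ring1 is not None else None,
    }
    mp = os.path.join(outdir, "manifest.json")
    manifest.write(mp)
    sp = os.path.join(outdir, "summary.json")
    with open(sp, "w") as fh:
        json.dump(manifest.summary, fh, indent=1, default=_json_default)
    say(f"done; manifest at {mp}")
    return manifest
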
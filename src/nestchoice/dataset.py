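"""The linked tables of a barn-colony dataset and their on-disk formats.

A :class:`ColonyDataset` bundles the five tables the analysis consumes —
antenna event log, birth table, multilocus genotypes, pedigree, nest-box
layout — plus the nest-check schedule and, for synthetic colonies, the
ground-truth decision record.

On disk everything is plain text: one CSV per table, genotypes additionally
in GenePop format, ground truth as JSON.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

MISSING_ALLELE = 0  # GenePop convention: allele code 0 = missing call

EVENT_COLUMNS = ["tag", "box", "entry_s", "exit_s"]
BIRTH_COLUMNS = [
    "mother", "birth_day", "date", "box",
    "litter_size", "observed_size", "discovery_age",
]
PEDIGREE_COLUMNS = ["id", "dam", "sire", "birth_day", "date", "sex", "death_day"]
LAYOUT_COLUMNS = ["box", "x", "y", "section"]
CHECK_COLUMNS = ["check_id", "time_s", "date"]


def locus_names(n_loci: int) -> list[str]:
    return [f"L{i + 1:02d}" for i in range(n_loci)]


def genotype_columns(n_loci: int) -> list[str]:
    cols = []
    for name in locus_names(n_loci):
        cols += [f"{name}_1", f"{name}_2"]
    return cols


def genotypes_to_array(genotypes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return (ids, array of shape (n, n_loci, 2)) from a wide genotype table."""
    ids = genotypes["id"].to_numpy()
    allele_cols = [c for c in genotypes.columns if c != "id"]
    arr = genotypes[allele_cols].to_numpy(dtype=int)
    return ids, arr.reshape(len(genotypes), -1, 2)


def genotype_lookup(genotypes: pd.DataFrame) -> dict[int, np.ndarray]:
    """id -> (n_loci, 2) allele array, 0 = missing."""
    ids, arr = genotypes_to_array(genotypes)
    return {int(i): arr[k] for k, i in enumerate(ids)}


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def write_genepop(genotypes: pd.DataFrame, path: str,
                  title: str = "nestchoice synthetic colony") -> None:
    """Write a wide genotype table as a 2-digit GenePop file (one pop)."""
    n_loci = (len(genotypes.columns) - 1) // 2
    names = locus_names(n_loci)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in names:
            fh.write(name + "\n")
        fh.write("Pop\n")
        for _, row in genotypes.iterrows():
            codes = []
            for name in names:
                a, b = int(row[f"{name}_1"]), int(row[f"{name}_2"])
                codes.append(f"{a:02d}{b:02d}")
            fh.write(f"{int(row['id'])}, " + " ".join(codes) + "\n")


def read_genepop(path: str) -> pd.DataFrame:
    """Read a 2- or 3-digit GenePop file into the wide genotype table.

    Multiple populations are concatenated; individual labels must be
    integer ids (the convention used by :func:`write_genepop`).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty GenePop file")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names may be one per line or comma-separated
        loci += [t.strip() for t in body[i].split(",") if t.strip()]
        i += 1
    if i == len(body):
        raise ValueError("no 'Pop' line in GenePop file")
    rows: list[list[int]] = []
    ids: list[int] = []
    digits: int | None = None
    for ln in body[i:]:
        s = ln.strip()
        if not s or s.lower() == "pop":
            continue
        if "," not in s:
            raise ValueError(f"malformed GenePop individual line: {s!r}")
        label, geno = s.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"individual {label!r}: {len(codes)} genotypes for "
                f"{len(loci)} loci")
        if digits is None:
            digits = len(codes[0]) // 2
        alleles: list[int] = []
        for code in codes:
            alleles += [int(code[:digits]), int(code[digits:])]
        ids.append(int(label.strip()))
        rows.append(alleles)
    out = pd.DataFrame(rows, columns=genotype_columns(len(loci)))
    out.insert(0, "id", ids)
    return out


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class ColonyDataset:
    """The five linked tables plus nest-check schedule and ground truth."""

    events: pd.DataFrame
    births: pd.DataFrame
    genotypes: pd.DataFrame
    pedigree: pd.DataFrame
    layout: pd.DataFrame
    checks: pd.DataFrame | None = None
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df, cols, name in [
            (self.events, EVENT_COLUMNS, "events"),
            (self.births, BIRTH_COLUMNS, "births"),
            (self.pedigree, PEDIGREE_COLUMNS, "pedigree"),
            (self.layout, LAYOUT_COLUMNS, "layout"),
        ]:
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"{name} table missing columns {sorted(missing)}")

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, df in [("events", self.events), ("births", self.births),
                         ("pedigree", self.pedigree), ("layout", self.layout),
                         ("genotypes", self.genotypes)]:
            p = os.path.join(outdir, f"{name}.csv")
            df.to_csv(p, index=False)
            paths[name] = p
        if self.checks is not None:
            p = os.path.join(outdir, "checks.csv")
            self.checks.to_csv(p, index=False)
            paths["checks"] = p
        gp = os.path.join(outdir, "genotypes.gen")
        write_genepop(self.genotypes, gp)
        paths["genepop"] = gp
        tp = os.path.join(outdir, "truth.json")
        with open(tp, "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_json_default)
        paths["truth"] = tp
        return paths

    @classmethod
    def read(cls, indir: str) -> "ColonyDataset":
        def rd(name: str) -> pd.DataFrame:
            return pd.read_csv(os.path.join(indir, f"{name}.csv"))

        pedigree = rd("pedigree")
        for col in ("dam", "sire"):
            pedigree[col] = pedigree[col].astype("Int64")
        checks_path = os.path.join(indir, "checks.csv")
        checks = pd.read_csv(checks_path) if os.path.exists(checks_path) else None
        truth_path = os.path.join(indir, "truth.json")
        truth: dict[str, Any] = {}
        if os.path.exists(truth_path):
            with open(truth_path) as fh:
                truth = json.load(fh)
        return cls(events=rd("events"), births=rd("births"),
                   genotypes=rd("genotypes"), pedigree=pedigree,
                   layout=rd("layout"), checks=checks, truth=truth)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
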
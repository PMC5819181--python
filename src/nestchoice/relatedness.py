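"""Pairwise relatedness from microsatellite genotypes and from the pedigree.

Two genotype-based estimators are bundled:

* :func:`queller_goodnight_r` — the classic allele-sharing regression
  estimator, computed as a per-direction ratio of sums across loci and
  symmetrised by averaging the two directions.
* :func:`wang_r` — a moment estimator in the Wang (2002) family.  Each
  locus's dyadic genotype pattern is classified into the four sharing
  categories (identical; homozygote + heterozygote sharing one allele; two
  heterozygotes sharing one allele; no allele shared).  The expected
  category probabilities are exact linear functions of the two-gene IBD
  coefficient phi (one pair of genes identical by descent) and the
  four-gene coefficient Delta (both pairs IBD), with coefficients built
  from power sums of the reference allele frequencies.  phi and Delta are
  estimated jointly by weighted least squares on the category equations,
  combining loci with weights 1/(2*a2 - a4) (low-diversity loci are
  down-weighted), and r-hat = phi/2 + Delta.

Pedigree expected r is the coefficient of relationship, computed from the
recursive kinship coefficient with founders treated as unrelated and
non-inbred (r = 2 * kinship).

The estimator interface is pluggable: any callable
``(g1, g2, freqs) -> RelatednessEstimate`` can enter the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .dataset import MISSING_ALLELE, genotype_lookup, locus_names

DYAD_CLASSES = ("full_sib", "parent_offspring", "half_sib", "unrelated")
EXPECTED_R = {"full_sib": 0.5, "parent_offspring": 0.5,
              "half_sib": 0.25, "unrelated": 0.0}


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies of a reference cohort."""

    freqs: list[dict[int, float]]       # one dict per locus
    sample_size: list[int]              # genotyped individuals per locus
    cohort: str = ""

    @property
    def n_loci(self) -> int:
        return len(self.freqs)

    def vector(self, locus: int) -> np.ndarray:
        return np.array(list(self.freqs[locus].values()))


def allele_frequencies(genotypes: pd.DataFrame,
                       ids: list[int] | None = None,
                       cohort: str = "") -> AlleleFrequencies:
    """Frequencies by allele counting over the cohort individuals.

    Missing calls (allele 0) are excluded from the counts.  Monomorphic
    loci are retained with frequency 1; estimators skip them as
    uninformative.
    """
    sub = genotypes if ids is None else genotypes[genotypes["id"].isin(ids)]
    if len(sub) == 0:
        raise ValueError("empty cohort")
    allele_cols = [c for c in sub.columns if c != "id"]
    arr = sub[allele_cols].to_numpy(dtype=int).reshape(len(sub), -1, 2)
    freqs: list[dict[int, float]] = []
    n_l: list[int] = []
    for loc in range(arr.shape[1]):
        alleles = arr[:, loc, :]
        present = alleles[(alleles != MISSING_ALLELE).all(axis=1)]
        n_l.append(len(present))
        if len(present) == 0:
            freqs.append({})
            continue
        vals, counts = np.unique(present.ravel(), return_counts=True)
        total = counts.sum()
        freqs.append({int(a): c / total for a, c in zip(vals, counts)})
    return AlleleFrequencies(freqs=freqs, sample_size=n_l, cohort=cohort)


def cohort_year_frequencies(genotypes: pd.DataFrame, pedigree: pd.DataFrame,
                            year: int, females_only: bool = True,
                            days_per_year: int = 365) -> AlleleFrequencies:
    """Reference frequencies from all (female) individuals born in a year.

    The cohort year of a focal birth is ``birth_day // days_per_year``.
    """
    ped = pedigree
    if females_only:
        ped = ped[ped["sex"] == "F"]
    ids = ped.loc[ped["birth_day"] // days_per_year == year, "id"].tolist()
    if not ids:
        raise ValueError(f"no cohort individuals for year {year}")
    return allele_frequencies(genotypes, ids=ids, cohort=str(year))


# ---------------------------------------------------------------------------
# pedigree expected r
# ---------------------------------------------------------------------------

@dataclass
class PedigreeDyad:
    dyad: frozenset[int]
    expected_r: float
    dyad_class: str


class PedigreeKinship:
    """Recursive kinship coefficients over a pedigree table."""

    def __init__(self, pedigree: pd.DataFrame):
        self.parents: dict[int, tuple[int | None, int | None]] = {}
        self.birth: dict[int, int] = {}
        self.death: dict[int, int | None] = {}
        has_death = "death_day" in pedigree.columns
        for _, row in pedigree.iterrows():
            i = int(row["id"])
            dam = None if pd.isna(row["dam"]) else int(row["dam"])
            sire = None if pd.isna(row["sire"]) else int(row["sire"])
            self.parents[i] = (dam, sire)
            self.birth[i] = int(row["birth_day"])
            self.death[i] = (int(row["death_day"])
                             if has_death and not pd.isna(row["death_day"])
                             else None)
        self._memo: dict[tuple[int, int], float] = {}

    def kinship(self, a: int, b: int) -> float:
        a, b = int(a), int(b)
        for x in (a, b):
            if x not in self.parents:
                raise KeyError(f"individual {x} not in pedigree")
        return self._phi(a, b)

    def _phi(self, a: int, b: int) -> float:
        if a > b:
            a, b = b, a
        key = (a, b)
        if key in self._memo:
            return self._memo[key]
        if a == b:
            dam, sire = self.parents[a]
            f = self._phi(dam, sire) if dam is not None and sire is not None \
                else 0.0
            val = 0.5 * (1.0 + f)
        else:
            # recurse through the parents of the younger individual
            younger, other = (a, b) if self.birth[a] >= self.birth[b] else (b, a)
            dam, sire = self.parents[younger]
            val = 0.0
            if dam is not None:
                val += 0.5 * self._phi(dam, other)
            if sire is not None:
                val += 0.5 * self._phi(sire, other)
        self._memo[key] = val
        return val

    def expected_r(self, a: int, b: int) -> float:
        """Coefficient of relationship: twice the kinship coefficient."""
        return 2.0 * self.kinship(a, b)

    # -- dyad classification -------------------------------------------------

    def _ancestors2(self, i: int) -> set[int]:
        """Self, parents and grandparents (known ones)."""
        out = {i}
        dam, sire = self.parents[i]
        for p in (dam, sire):
            if p is not None:
                out.add(p)
                for gp in self.parents[p]:
                    if gp is not None:
                        out.add(gp)
        return out

    def contemporaneous(self, a: int, b: int,
                        max_birth_gap_days: int = 365) -> bool:
        """Overlapping lifespans when death dates are known, else birth
        dates within a year of each other."""
        da, db = self.death.get(a), self.death.get(b)
        if da is not None and db is not None:
            return self.birth[a] < db and self.birth[b] < da
        return abs(self.birth[a] - self.birth[b]) <= max_birth_gap_days

    def classify(self, a: int, b: int) -> str:
        a, b = int(a), int(b)
        pa, pb = self.parents[a], self.parents[b]
        if a in pb or b in pa:
            return "parent_offspring"
        shared = {p for p in pa if p is not None} & \
                 {p for p in pb if p is not None}
        if len(shared) == 2:
            return "full_sib"
        if len(shared) == 1:
            return "half_sib"
        if not (self._ancestors2(a) & self._ancestors2(b)) \
                and self.contemporaneous(a, b):
            return "unrelated"
        return "other"

    def dyad(self, a: int, b: int) -> PedigreeDyad:
        return PedigreeDyad(dyad=frozenset((int(a), int(b))),
                            expected_r=self.expected_r(a, b),
                            dyad_class=self.classify(a, b))


def pedigree_expected_r(pedigree, a: int, b: int) -> PedigreeDyad:
    """Expected r and dyad class for one pair (convenience wrapper)."""
    kin = pedigree if isinstance(pedigree, PedigreeKinship) \
        else PedigreeKinship(pedigree)
    return kin.dyad(a, b)


def enumerate_dyads_by_class(pedigree, classes=DYAD_CLASSES,
                             ids: list[int] | None = None
                             ) -> dict[str, list[tuple[int, int]]]:
    """Exhaustive scan of all pairs, binned by pedigree class.

    The full-pedigree scan (``ids=None``) is cached on the
    :class:`PedigreeKinship` instance, since the calibration procedure
    resamples from the same pools many times.
    """
    kin = pedigree if isinstance(pedigree, PedigreeKinship) \
        else PedigreeKinship(pedigree)
    full_scan = ids is None
    cached = getattr(kin, "_dyad_pool_cache", None)
    if full_scan and cached is not None:
        return {c: list(cached.get(c, [])) for c in classes}
    pool = sorted(kin.parents) if ids is None else sorted(ids)
    parents = {i: frozenset(p for p in kin.parents[i] if p is not None)
               for i in pool}
    anc2 = {i: kin._ancestors2(i) for i in pool}
    out: dict[str, list[tuple[int, int]]] = {c: [] for c in DYAD_CLASSES}
    for i, a in enumerate(pool):
        pa, aa = parents[a], anc2[a]
        for b in pool[i + 1:]:
            pb = parents[b]
            if a in pb or b in pa:
                c = "parent_offspring"
            else:
                shared = len(pa & pb)
                if shared == 2:
                    c = "full_sib"
                elif shared == 1:
                    c = "half_sib"
                elif aa.isdisjoint(anc2[b]) and kin.contemporaneous(a, b):
                    c = "unrelated"
                else:
                    continue
            out[c].append((a, b))
    if full_scan:
        kin._dyad_pool_cache = out
    return {c: list(out[c]) for c in classes}


# ---------------------------------------------------------------------------
# genotype-based estimators
# ---------------------------------------------------------------------------

@dataclass
class RelatednessEstimate:
    dyad: frozenset[int]
    estimator: str
    r_hat: float | None          # None when no locus was usable
    loci_used: int

    @property
    def defined(self) -> bool:
        return self.r_hat is not None


def _usable(g1: np.ndarray, g2: np.ndarray, loc: int) -> bool:
    return (MISSING_ALLELE not in g1[loc]) and (MISSING_ALLELE not in g2[loc])


def queller_goodnight_r(g1: np.ndarray, g2: np.ndarray,
                        freqs: AlleleFrequencies,
                        dyad: tuple[int, int] = (-1, -1)
                        ) -> RelatednessEstimate:
    """Queller & Goodnight allele-sharing estimator, symmetrised.

    For focal x = (a, b) and partner y = (c, d) at one locus the direction
    x<-y contributes numerator 0.5*(I_ac + I_ad + I_bc + I_bd) - p_a - p_b
    and denominator 1 + I_ab - p_a - p_b; each direction is a ratio of
    sums over loci, and the two directions are averaged.  Loci with an
    undefined denominator in a direction are skipped for that direction.
    """
    num = [0.0, 0.0]
    den = [0.0, 0.0]
    loci_used = 0
    for loc in range(freqs.n_loci):
        if not _usable(g1, g2, loc):
            continue
        p = freqs.freqs[loc]
        pair_used = False
        for k, (x, y) in enumerate(((g1[loc], g2[loc]), (g2[loc], g1[loc]))):
            a, b = int(x[0]), int(x[1])
            c, d = int(y[0]), int(y[1])
            pa, pb = p.get(a, 0.0), p.get(b, 0.0)
            d_loc = 1.0 + (a == b) - pa - pb
            if d_loc <= 1e-12:      # focal homozygous for a fixed allele
                continue
            share = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
            num[k] += share - pa - pb
            den[k] += d_loc
            pair_used = True
        if pair_used:
            loci_used += 1
    parts = [num[k] / den[k] for k in range(2) if den[k] > 0]
    r = float(np.mean(parts)) if parts else None
    return RelatednessEstimate(dyad=frozenset(dyad), estimator="qg",
                               r_hat=r, loci_used=loci_used)


def _sharing_category(x: np.ndarray, y: np.ndarray) -> int:
    """Wang's four dyadic genotype-sharing categories (1..4)."""
    a, b = int(x[0]), int(x[1])
    c, d = int(y[0]), int(y[1])
    if {a, b} == {c, d}:
        return 1
    shared = len({a, b} & {c, d})
    if shared == 0:
        return 4
    hom1, hom2 = a == b, c == d
    if hom1 or hom2:
        return 2                      # homozygote + heterozygote, one shared
    return 3                          # two heterozygotes sharing one allele


def wang_r(g1: np.ndarray, g2: np.ndarray, freqs: AlleleFrequencies,
           dyad: tuple[int, int] = (-1, -1)) -> RelatednessEstimate:
    """Wang-family moment estimator of pairwise relatedness.

    Expected category probabilities given the IBD mode (derived under
    Hardy-Weinberg reference frequencies; a_m = sum_i p_i^m):

    ==========  ==========  ======================  =========================
    category    both pairs  one pair IBD (phi)      no IBD (1 - phi - Delta)
                IBD (Delta)
    ==========  ==========  ======================  =========================
    identical   1           a2                      2*a2^2 - a4
    hom + het   0           2*(a2 - a3)             4*(a3 - a4)
    het + het   0           1 - 3*a2 + 2*a3         4*(a2 - a2^2 - 2*a3 + 2*a4)
    ==========  ==========  ======================  =========================

    Category indicators and coefficients are averaged over usable loci with
    weights 1/(2*a2 - a4); (phi, Delta) solve the resulting 3x2 linear
    system by least squares, and r-hat = phi/2 + Delta.  Monomorphic and
    missing-data loci are skipped; with fewer than one usable locus the
    estimate is undefined.
    """
    obs = np.zeros(3)
    U = np.zeros(3)   # weighted one-pair-IBD coefficients
    V = np.zeros(3)   # weighted no-IBD coefficients
    wsum = 0.0
    loci_used = 0
    for loc in range(freqs.n_loci):
        if not _usable(g1, g2, loc):
            continue
        p = freqs.vector(loc)
        a2 = float(np.sum(p ** 2))
        if a2 >= 1.0 - 1e-12:        # monomorphic: uninformative
            continue
        a3 = float(np.sum(p ** 3))
        a4 = float(np.sum(p ** 4))
        u = np.array([a2, 2.0 * (a2 - a3), 1.0 - 3.0 * a2 + 2.0 * a3])
        v = np.array([2.0 * a2 ** 2 - a4, 4.0 * (a3 - a4),
                      4.0 * (a2 - a2 ** 2 - 2.0 * a3 + 2.0 * a4)])
        cat = _sharing_category(g1[loc], g2[loc])
        ind = np.zeros(3)
        if cat <= 3:
            ind[cat - 1] = 1.0
        w = 1.0 / (2.0 * a2 - a4)
        obs += w * ind
        U += w * u
        V += w * v
        wsum += w
        loci_used += 1
    if loci_used == 0:
        return RelatednessEstimate(dyad=frozenset(dyad), estimator="wang",
                                   r_hat=None, loci_used=0)
    obs /= wsum
    U /= wsum
    V /= wsum
    t = np.array([1.0, 0.0, 0.0])    # both-pairs-IBD column
    design = np.column_stack([U - V, t - V])
    sol, *_ = np.linalg.lstsq(design, obs - V, rcond=None)
    phi, delta = float(sol[0]), float(sol[1])
    return RelatednessEstimate(dyad=frozenset(dyad), estimator="wang",
                               r_hat=phi / 2.0 + delta, loci_used=loci_used)


ESTIMATORS: dict[str, Callable] = {
    "wang": wang_r,
    "qg": queller_goodnight_r,
}


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def sample_dyads_by_class(pedigree, n_per_class: int, seed: int,
                          ids: list[int] | None = None
                          ) -> dict[str, list[tuple[int, int]]]:
    """Seeded sample without replacement of dyads from each pedigree class."""
    rng = np.random.default_rng(seed)
    pools = enumerate_dyads_by_class(pedigree, ids=ids)
    out: dict[str, list[tuple[int, int]]] = {}
    for cls in DYAD_CLASSES:
        pool = pools[cls]
        if len(pool) < n_per_class:
            raise ValueError(
                f"pedigree supplies only {len(pool)} {cls} dyads, "
                f"need {n_per_class}")
        pick = rng.choice(len(pool), size=n_per_class, replace=False)
        out[cls] = [pool[i] for i in sorted(pick)]
    return out


def estimator_calibration(pedigree: pd.DataFrame, genotypes: pd.DataFrame,
                          estimators: dict[str, Callable] | None = None,
                          n_per_class: int = 50, seed: int = 0,
                          freqs: AlleleFrequencies | None = None
                          ) -> pd.DataFrame:
    """Estimator-selection procedure: correlate estimates with expected r.

    Samples ``n_per_class`` dyads from each of the four pedigree classes,
    runs every estimator on every dyad against the reference allele
    frequencies, and reports the Pearson correlation between expected and
    estimated r per estimator, ranked best-first.  A constant estimator has
    zero variance and its correlation is reported as NaN.
    """
    if estimators is None:
        estimators = ESTIMATORS
    kin = PedigreeKinship(pedigree)
    if freqs is None:
        freqs = allele_frequencies(genotypes)
    geno = genotype_lookup(genotypes)
    dyads = sample_dyads_by_class(kin, n_per_class, seed)
    rows = []
    for name, fn in estimators.items():
        expected, estimated = [], []
        per_class: dict[str, list[float]] = {c: [] for c in DYAD_CLASSES}
        for cls, pairs in dyads.items():
            for a, b in pairs:
                if a not in geno or b not in geno:
                    continue
                est = fn(geno[a], geno[b], freqs, dyad=(a, b))
                if not est.defined:
                    continue
                expected.append(kin.expected_r(a, b))
                estimated.append(est.r_hat)
                per_class[cls].append(est.r_hat)
        expected_arr = np.asarray(expected)
        estimated_arr = np.asarray(estimated)
        if len(expected) >= 2 and np.std(estimated_arr) > 1e-12 \
                and np.std(expected_arr) > 1e-12:
            corr = float(np.corrcoef(expected_arr, estimated_arr)[0, 1])
        else:
            corr = float("nan")
        row = {"estimator": name, "pearson_r": corr, "n_dyads": len(expected)}
        for cls in DYAD_CLASSES:
            vals = per_class[cls]
            row[f"mean_{cls}"] = float(np.mean(vals)) if vals else float("nan")
            row[f"sd_{cls}"] = float(np.std(vals, ddof=1)) \
                if len(vals) > 1 else float("nan")
        rows.append(row)
    report = pd.DataFrame(rows)
    report["rank"] = report["pearson_r"].rank(ascending=False, na_option="bottom")
    return report.sort_values("rank").reset_index(drop=True)


def relatedness_table(genotypes: pd.DataFrame, pairs: list[tuple[int, int]],
                      freqs: AlleleFrequencies,
                      estimator: str = "wang") -> pd.DataFrame:
    """Estimate r for a list of dyads; one row per pair."""
    fn = ESTIMATORS[estimator]
    geno = genotype_lookup(genotypes)
    rows = []
    for a, b in pairs:
        if a in geno and b in geno:
            est = fn(geno[a], geno[b], freqs, dyad=(a, b))
            r, used = est.r_hat, est.loci_used
        else:
            r, used = None, 0
        rows.append({"id_a": a, "id_b": b, "estimator": estimator,
                     "r_hat": r, "loci_used": used})
    return pd.DataFrame(rows)
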
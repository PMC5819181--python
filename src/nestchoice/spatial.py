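"""Spatial genetic autocorrelation of females over nest-box locations.

Each female is located at the nest box where she was detected during a
nest check (the first check of each month to reduce temporal
autocorrelation).  Squared multilocus genotype distances follow the
codominant metric used for microsatellites: per locus, identical
genotypes score 0; AA-AB and AB-AC score 1; AB-CD scores 2; AA-BC scores
3; AA-BB scores 4; loci with a missing call in either genotype are
skipped; scores are summed over loci.

Per nest check the squared-distance matrix is double-centred (Gower) into
a covariance-like matrix C; the autocorrelation coefficient of a
geographic distance class pools, across checks, the sum of off-diagonal
C entries of in-class dyads over the corresponding diagonal terms:

    r(class) = sum c_ij / sum 0.5 * (c_ii + c_jj)

Dyads are formed only within a check (a female is never paired with
herself at another time).  Significance comes from permuting genotypes
among the located records within each check; confidence intervals from
bootstrapping in-class dyads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tracking


# ---------------------------------------------------------------------------
# genotype distance
# ---------------------------------------------------------------------------

def genotype_sq_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared multilocus genotype distance (codominant pattern metric)."""
    total = 0.0
    for loc in range(g1.shape[0]):
        a, b = int(g1[loc, 0]), int(g1[loc, 1])
        c, d = int(g2[loc, 0]), int(g2[loc, 1])
        if 0 in (a, b, c, d):
            continue
        total += _locus_sq_distance(a, b, c, d)
    return total


def _locus_sq_distance(a: int, b: int, c: int, d: int) -> int:
    s1, s2 = {a, b}, {c, d}
    if s1 == s2:
        return 0
    shared = len(s1 & s2)
    hom1, hom2 = a == b, c == d
    if hom1 and hom2:
        return 4                      # AA vs BB
    if hom1 or hom2:
        return 1 if shared else 3     # AA vs AB / AA vs BC
    return 1 if shared else 2         # AB vs AC / AB vs CD


def squared_distance_matrix(genos: np.ndarray) -> np.ndarray:
    """Pairwise squared genotype distances for an (n, L, 2) array.

    Vectorised equivalent of :func:`genotype_sq_distance` over all pairs.
    """
    g = np.sort(genos, axis=2)
    a, b = g[:, :, 0], g[:, :, 1]                    # (n, L)
    a1, b1 = a[:, None, :], b[:, None, :]
    a2, b2 = a[None, :, :], b[None, :, :]
    valid = (a1 > 0) & (a2 > 0)                      # 0 = missing call
    identical = (a1 == a2) & (b1 == b2)
    hom1, hom2 = a1 == b1, a2 == b2
    shared = (a1 == a2) | (a1 == b2) | (b1 == a2) | (b1 == b2)
    score = np.where(
        identical, 0,
        np.where(hom1 & hom2, 4,
                 np.where(hom1 | hom2,
                          np.where(shared, 1, 3),
                          np.where(shared, 1, 2))))
    D = (score * valid).sum(axis=2).astype(float)
    np.fill_diagonal(D, 0.0)
    return D


def double_centre(D2: np.ndarray) -> np.ndarray:
    """Gower double-centring: C = -0.5 * J D2 J (row/col sums ~ 0)."""
    row = D2.mean(axis=1, keepdims=True)
    col = D2.mean(axis=0, keepdims=True)
    grand = D2.mean()
    return -0.5 * (D2 - row - col + grand)


# ---------------------------------------------------------------------------
# located genotypes
# ---------------------------------------------------------------------------

def build_located_dataset(events, layout: pd.DataFrame,
                          check_times: pd.DataFrame | list[int],
                          females: list[int] | None = None) -> pd.DataFrame:
    """One (female, check, box, x, y) record per detection at a check.

    The occupant of a box at a check instant is the female whose stay
    covers that timestamp; females not inside any box at a check are
    omitted for that check.  A female cannot be in two boxes at one
    instant (event-log invariant).
    """
    idx = tracking._as_index(events)
    if isinstance(check_times, pd.DataFrame):
        checks = list(zip(check_times["check_id"].astype(int),
                          check_times["time_s"].astype(int)))
    else:
        checks = [(k + 1, int(t)) for k, t in enumerate(check_times)]
    pos = layout.set_index("box")[["x", "y"]]
    tags = idx.tags if females is None else [f for f in females
                                             if f in idx.tags]
    rows = []
    for tag in tags:
        box, ent, ext = idx.stays(tag)
        for check_id, t in checks:
            inside = (ent <= t) & (t < ext)
            hits = np.flatnonzero(inside)
            if len(hits) == 0:
                continue
            assert len(hits) == 1, "individual inside two boxes at once"
            bx = int(box[hits[0]])
            rows.append({"female": int(tag), "check_id": check_id,
                         "box": bx, "x": float(pos.loc[bx, "x"]),
                         "y": float(pos.loc[bx, "y"])})
    return pd.DataFrame(rows,
                        columns=["female", "check_id", "box", "x", "y"])


# ---------------------------------------------------------------------------
# correlogram
# ---------------------------------------------------------------------------

@dataclass
class CorrelogramPoint:
    distance_class: tuple[float, float]   # (lo, hi]; (0, 0) is the same-box class
    r: float
    n_dyads: int
    null_lo: float
    null_hi: float
    boot_lo: float
    boot_hi: float
    p: float


def correlogram(located: pd.DataFrame, genotypes_by_id: dict[int, np.ndarray],
                class_width_cm: float = 100.0,
                max_distance_cm: float | None = None,
                n_perm: int = 999, n_boot: int = 1000,
                seed: int = 0) -> pd.DataFrame:
    """Spatial autocorrelation r per distance class with permutation null
    band and bootstrap CI.

    Distance classes are the same-box class {0} followed by half-open
    rings ((k-1)*w, k*w].  The permutation p value is the fraction of
    genotype-shuffled replicates whose r is at least the observed one
    (positive structure); the null band holds the central 95% of the
    permuted values.  Bootstrap CIs resample in-class dyads.
    """
    rng = np.random.default_rng(seed)
    checks = []
    for _, grp in located.groupby("check_id"):
        if len(grp) < 2:
            continue
        genos = np.stack([genotypes_by_id[int(f)] for f in grp["female"]])
        C = double_centre(squared_distance_matrix(genos))
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        geo = np.hypot(xy[:, 0, None] - xy[None, :, 0],
                       xy[:, 1, None] - xy[None, :, 1])
        checks.append((C, geo))
    if not checks:
        raise ValueError("no nest check has two or more located genotypes")

    all_geo = np.concatenate([geo[np.triu_indices(len(geo), k=1)]
                              for _, geo in checks])
    if max_distance_cm is None:
        max_distance_cm = float(all_geo.max()) if len(all_geo) else 0.0
    n_rings = int(np.ceil(max_distance_cm / class_width_cm)) \
        if max_distance_cm > 0 else 0
    classes = [(0.0, 0.0)] + [(k * class_width_cm, (k + 1) * class_width_cm)
                              for k in range(n_rings)]

    def class_of(dist: np.ndarray) -> np.ndarray:
        out = np.full(dist.shape, -1, dtype=int)
        out[dist == 0] = 0
        pos = dist > 0
        ring = np.ceil((dist[pos] - 1e-9) / class_width_cm).astype(int)
        ring[ring < 1] = 1
        ring[ring > n_rings] = -1      # beyond the last class: excluded
        out[pos] = ring
        return out

    # Per check: dyad index arrays, class labels, and the finite-sample
    # centring term.  Under within-check permutation the expected numerator
    # contribution of a dyad is -tr(C)/(N(N-1)) (the Moran -1/(N-1)
    # analogue, because C is double-centred on the sample itself), so that
    # amount is added back to every dyad's numerator; the permutation null
    # is then centred on zero, as in the reference correlogram.
    per_check = []
    for C, geo in checks:
        n = len(geo)
        iu, ju = np.triu_indices(n, k=1)
        cls = class_of(geo[iu, ju])
        keep = cls >= 0
        bias = float(np.trace(C)) / (n * (n - 1))
        per_check.append((C, iu[keep], ju[keep], cls[keep], bias))

    n_classes = len(classes)

    def class_sums(perms: list[np.ndarray] | None):
        num = np.zeros(n_classes)
        den = np.zeros(n_classes)
        for k, (C, iu, ju, cls, bias) in enumerate(per_check):
            if perms is None:
                i, j = iu, ju
            else:
                i, j = perms[k][iu], perms[k][ju]
            np.add.at(num, cls, C[i, j] + bias)
            np.add.at(den, cls, 0.5 * (C[i, i] + C[j, j]))
        return num, den

    num, den = class_sums(None)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_obs = np.where(den != 0, num / den, np.nan)
    counts = np.zeros(n_classes, dtype=int)
    for _, _, _, cls, _ in per_check:
        np.add.at(counts, cls, 1)

    # permutation null: shuffle genotypes among records within each check
    perm_r = np.full((n_perm, n_classes), np.nan)
    for p_i in range(n_perm):
        perms = [rng.permutation(len(C)) for C, *_ in per_check]
        pn, pdn = class_sums(perms)
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_r[p_i] = np.where(pdn != 0, pn / pdn, np.nan)

    # bootstrap: resample in-class dyads (pooled across checks)
    contrib_num: list[list[float]] = [[] for _ in range(n_classes)]
    contrib_den: list[list[float]] = [[] for _ in range(n_classes)]
    for C, iu, ju, cls, bias in per_check:
        cn = C[iu, ju] + bias
        cd = 0.5 * (C[iu, iu] + C[ju, ju])
        for c, vn, vd in zip(cls, cn, cd):
            contrib_num[c].append(vn)
            contrib_den[c].append(vd)

    rows = []
    for c, (lo, hi) in enumerate(classes):
        n_d = int(counts[c])
        if n_d == 0:
            rows.append({"class_lo": lo, "class_hi": hi, "r": np.nan,
                         "n_dyads": 0, "null_mean": np.nan,
                         "null_lo": np.nan, "null_hi": np.nan,
                         "boot_lo": np.nan, "boot_hi": np.nan, "p": np.nan})
            continue
        pr = perm_r[:, c]
        pr = pr[~np.isnan(pr)]
        null_mean = float(np.mean(pr)) if len(pr) else np.nan
        null_lo, null_hi = (np.percentile(pr, [2.5, 97.5])
                            if len(pr) else (np.nan, np.nan))
        p_val = (1 + np.sum(pr >= r_obs[c] - 1e-12)) / (len(pr) + 1) \
            if len(pr) else np.nan
        cn = np.asarray(contrib_num[c])
        cd = np.asarray(contrib_den[c])
        if n_boot > 0 and n_d > 1:
            picks = rng.integers(0, n_d, size=(n_boot, n_d))
            bn = cn[picks].sum(axis=1)
            bd = cd[picks].sum(axis=1)
            ok = bd != 0
            boot = bn[ok] / bd[ok]
            boot_lo, boot_hi = (np.percentile(boot, [2.5, 97.5])
                                if len(boot) else (np.nan, np.nan))
        else:
            boot_lo = boot_hi = np.nan
        rows.append({"class_lo": lo, "class_hi": hi, "r": float(r_obs[c]),
                     "n_dyads": n_d, "null_mean": null_mean,
                     "null_lo": null_lo, "null_hi": null_hi,
                     "boot_lo": boot_lo, "boot_hi": boot_hi, "p": p_val})
    return pd.DataFrame(rows)


def plot_correlogram(corr: pd.DataFrame, path: str | None = None):
    """Correlogram figure: r per class with bootstrap CI and null band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    valid = corr[corr["n_dyads"] > 0]
    x = [(lo + hi) / 2.0 if hi > lo else 0.0
         for lo, hi in zip(valid["class_lo"], valid["class_hi"])]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(x, valid["null_lo"], valid["null_hi"],
                    color="steelblue", alpha=0.25,
                    label="95% permutation band")
    ax.errorbar(x, valid["r"],
                yerr=[valid["r"] - valid["boot_lo"],
                      valid["boot_hi"] - valid["r"]],
                fmt="o-", color="black", capsize=3,
                label="r (95% bootstrap CI)")
    ax.axhline(0.0, color="steelblue", lw=1)
    ax.set_xlabel("distance class (cm)")
    ax.set_ylabel("autocorrelation r")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
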
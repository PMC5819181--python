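"""Pedigree kinship vs gene-dropping, and the genotype estimators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nestchoice.dataset import genotype_columns, genotype_lookup
from nestchoice.relatedness import (
    EXPECTED_R, AlleleFrequencies, PedigreeKinship, allele_frequencies,
    cohort_year_frequencies, enumerate_dyads_by_class, estimator_calibration,
    queller_goodnight_r, sample_dyads_by_class, wang_r)


def hand_pedigree() -> pd.DataFrame:
    """Founders 1-4; 5,6 = 1x2; 7 = 1x3; 8 = 5x6 (inbred); 9 = 5x7; 10 = 8x9."""
    rows = [(1, None, None, 0), (2, None, None, 0), (3, None, None, 0),
            (4, None, None, 0), (5, 1, 2, 100), (6, 1, 2, 100),
            (7, 1, 3, 100), (8, 5, 6, 200), (9, 5, 7, 200), (10, 8, 9, 300)]
    df = pd.DataFrame(rows, columns=["id", "dam", "sire", "birth_day"])
    df["dam"] = df["dam"].astype("Int64")
    df["sire"] = df["sire"].astype("Int64")
    df["date"] = "d"
    df["sex"] = "F"
    df["death_day"] = pd.NA
    return df


def gene_drop_kinship(pedigree: pd.DataFrame, a: int, b: int,
                      n_drops: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo kinship: unique founder alleles dropped down the
    pedigree; phi = P(one random allele from each is identical by descent).
    Vectorised across replicates (independent oracle)."""
    rng = np.random.default_rng(seed)
    order = pedigree.sort_values("birth_day")
    alleles: dict[int, np.ndarray] = {}
    label = 0
    for _, row in order.iterrows():
        i = int(row["id"])
        g = np.empty((n_drops, 2), dtype=np.int64)
        for slot, parent in enumerate((row["dam"], row["sire"])):
            if pd.isna(parent):
                g[:, slot] = label
                label += 1
            else:
                pg = alleles[int(parent)]
                pick = rng.integers(0, 2, size=n_drops)
                g[:, slot] = pg[np.arange(n_drops), pick]
        alleles[i] = g
    ga = alleles[a][np.arange(n_drops), rng.integers(0, 2, n_drops)]
    gb = alleles[b][np.arange(n_drops), rng.integers(0, 2, n_drops)]
    return float(np.mean(ga == gb))


class TestPedigreeKinship:
    def test_textbook_values(self):
        kin = PedigreeKinship(hand_pedigree())
        assert kin.expected_r(5, 6) == pytest.approx(0.5)       # full sibs
        assert kin.expected_r(1, 5) == pytest.approx(0.5)       # parent
        assert kin.expected_r(5, 7) == pytest.approx(0.25)      # half sibs
        assert kin.expected_r(1, 4) == 0.0                      # founders
        # offspring of full-sib mating: phi(8,8) = (1 + 0.25)/2
        assert kin.kinship(8, 8) == pytest.approx(0.625)

    @pytest.mark.parametrize("a,b", [(5, 6), (5, 7), (1, 5), (8, 9),
                                     (8, 10), (5, 10), (1, 4)])
    def test_matches_gene_dropping(self, a, b):
        kin = PedigreeKinship(hand_pedigree())
        mc = gene_drop_kinship(hand_pedigree(), a, b,
                               n_drops=200_000, seed=a * 31 + b)
        se = max(np.sqrt(mc * (1 - mc) / 200_000), 1e-4)
        assert kin.kinship(a, b) == pytest.approx(mc, abs=4 * se)

    def test_classification(self):
        kin = PedigreeKinship(hand_pedigree())
        assert kin.classify(5, 6) == "full_sib"
        assert kin.classify(1, 5) == "parent_offspring"
        assert kin.classify(5, 7) == "half_sib"
        assert kin.classify(1, 4) == "unrelated"
        assert kin.classify(8, 9) == "half_sib"  # share parent 5
        assert kin.classify(7, 8) == "other"     # share grandparent 1 only
        # the class definition only checks ancestry two generations deep,
        # so a great-grandparent pair counts as "unrelated" by definition
        # (the background-relatedness caveat of pedigree classes)
        assert kin.classify(1, 10) == "unrelated"
        assert kin.expected_r(1, 10) > 0         # though truly related

    def test_contemporaneous_gate(self):
        ped = hand_pedigree()
        ped.loc[ped["id"] == 4, "birth_day"] = 2000   # far in the future
        kin = PedigreeKinship(ped)
        assert kin.classify(1, 4) == "other"     # unrelated but not coeval

    def test_enumerate_matches_classify(self):
        kin = PedigreeKinship(hand_pedigree())
        pools = enumerate_dyads_by_class(kin)
        for cls, pairs in pools.items():
            for a, b in pairs:
                assert kin.classify(a, b) == cls
        n_binned = sum(len(v) for v in pools.values())
        ids = sorted(kin.parents)
        n_other = sum(kin.classify(a, b) == "other"
                      for i, a in enumerate(ids) for b in ids[i + 1:])
        assert n_binned + n_other == len(ids) * (len(ids) - 1) // 2


def test_allele_frequencies_counting():
    g = pd.DataFrame([[1, 1, 2, 3, 3], [2, 1, 2, 3, 3], [3, 1, 3, 0, 0]],
                     columns=["id"] + genotype_columns(2))
    f = allele_frequencies(g)
    assert f.freqs[0] == {1: 3 / 6, 2: 2 / 6, 3: 1 / 6}
    assert f.freqs[1] == {3: 1.0}                  # missing pair excluded
    assert f.sample_size == [3, 2]
    with pytest.raises(ValueError, match="empty cohort"):
        allele_frequencies(g, ids=[99])


def test_queller_goodnight_hand_computed():
    freqs = AlleleFrequencies(
        freqs=[{1: 0.5, 2: 0.3, 3: 0.2}, {1: 0.4, 2: 0.6},
               {1: 0.2, 2: 0.3, 3: 0.5}],
        sample_size=[10, 10, 10], cohort="hand")
    g1 = np.array([[1, 2], [1, 1], [2, 3]])
    g2 = np.array([[1, 1], [1, 2], [3, 3]])
    est = queller_goodnight_r(g1, g2, freqs, dyad=(1, 2))
    # direction 1->2: (0.2+0.2+0.2)/(0.2+1.2+0.2) = 0.375; direction
    # 2->1: locus 2 skipped (denominator 0), remaining sum to 0; mean .1875
    assert est.r_hat == pytest.approx(0.1875, abs=1e-12)
    assert est.loci_used == 3


def test_estimators_skip_missing_and_monomorphic():
    freqs = AlleleFrequencies(freqs=[{1: 0.5, 2: 0.5}, {1: 1.0}],
                              sample_size=[4, 4], cohort="x")
    g_full = np.array([[1, 2], [1, 1]])
    g_missing = np.array([[0, 0], [1, 1]])
    for fn in (wang_r, queller_goodnight_r):
        est = fn(g_full, g_missing, freqs)
        assert not est.defined and est.r_hat is None
    est = wang_r(g_full, np.array([[1, 1], [1, 1]]), freqs)
    assert est.loci_used == 1        # monomorphic locus 2 uninformative


def test_wang_identical_twins_estimate_near_one():
    rng = np.random.default_rng(0)
    freqs = AlleleFrequencies(
        freqs=[{a: 0.125 for a in range(1, 9)} for _ in range(25)],
        sample_size=[50] * 25, cohort="x")
    g = rng.integers(1, 9, size=(25, 2))
    est = wang_r(g, g.copy(), freqs)
    assert est.r_hat == pytest.approx(1.0, abs=0.15)


def test_wang_unbiased_on_dyad_panel(panel60):
    ped, geno_df, dyads = panel60
    freqs = allele_frequencies(geno_df)
    geno = genotype_lookup(geno_df)
    for cls, pairs in dyads.items():
        vals = np.array([wang_r(geno[a], geno[b], freqs).r_hat
                         for a, b in pairs])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(EXPECTED_R[cls],
                                              abs=max(4 * se, 0.02))


def test_panel_pedigree_classes_match_construction(panel60):
    ped, _, dyads = panel60
    kin = PedigreeKinship(ped)
    for cls, pairs in dyads.items():
        for a, b in pairs[:10]:
            assert kin.classify(a, b) == cls
            assert kin.expected_r(a, b) == EXPECTED_R[cls]


def test_sample_dyads_seeded_and_errors(panel60):
    ped, _, _ = panel60
    kin = PedigreeKinship(ped)
    s1 = sample_dyads_by_class(kin, 20, seed=9)
    s2 = sample_dyads_by_class(kin, 20, seed=9)
    assert s1 == s2
    with pytest.raises(ValueError, match="full_sib"):
        sample_dyads_by_class(kin, 10_000, seed=0)


def test_estimator_calibration_report(panel60):
    ped, geno_df, _ = panel60

    def constant(g1, g2, freqs, dyad=(-1, -1)):
        from nestchoice.relatedness import RelatednessEstimate
        return RelatednessEstimate(dyad=frozenset(dyad), estimator="const",
                                   r_hat=0.1, loci_used=1)

    from nestchoice.relatedness import ESTIMATORS
    report = estimator_calibration(
        ped, geno_df, estimators={**ESTIMATORS, "const": constant},
        n_per_class=40, seed=2)
    by = report.set_index("estimator")
    assert by.loc["wang", "pearson_r"] > 0.7
    assert by.loc["qg", "pearson_r"] > 0.7
    assert np.isnan(by.loc["const", "pearson_r"])
    assert by.loc["const", "rank"] == report["rank"].max()
    assert by.loc["wang", "mean_full_sib"] == pytest.approx(0.5, abs=0.1)


def test_cohort_year_frequencies(small_colony):
    f = cohort_year_frequencies(small_colony.genotypes,
                                small_colony.pedigree, year=1)
    assert f.cohort == "1"
    assert all(abs(sum(d.values()) - 1) < 1e-9 for d in f.freqs if d)
    with pytest.raises(ValueError, match="year 99"):
        cohort_year_frequencies(small_colony.genotypes,
                                small_colony.pedigree, year=99)
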
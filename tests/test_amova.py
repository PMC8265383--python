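"""Distances, AMOVA sums of squares, Phi-statistics and permutation tests."""

import numpy as np
import pytest

from bandpop.amova import (Amova, amova_one_level, amova_hierarchical,
                           pairwise_phipt)
from bandpop.distance import DistanceMatrix, pairwise_distance
from bandpop.matrix import PopulationLayout

from conftest import make_matrix, random_matrix


def _dist(matrix):
    return pairwise_distance(matrix)


# ---- distances ------------------------------------------------------------

def test_mismatch_count_hand_examples():
    m = make_matrix([[1, 0, 1, 0], [1, 1, 0, 0], [1, 0, 1, 0]],
                    ["p"] * 3)
    d = _dist(m)
    assert d.values[0, 1] == 2          # 1010 vs 1100
    assert d.values[0, 2] == 0          # identical rows
    assert d.metric == "mismatch-count"


def test_p_distance_scaling(rng):
    m = random_matrix(rng, 6, 20)
    d = pairwise_distance(m, metric="p-distance")
    dm = pairwise_distance(m, metric="mismatch-count")
    assert np.allclose(d.values, dm.values / 20)
    with pytest.raises(ValueError, match="unknown metric"):
        pairwise_distance(m, metric="euclid")


def test_mismatch_matches_xor_oracle(rng):
    m = random_matrix(rng, 10, 20)
    d = _dist(m).values
    for i in range(10):
        for j in range(10):
            expected = int(np.logical_xor(m.values[i], m.values[j]).sum())
            assert d[i, j] == expected


# ---- one-level AMOVA ------------------------------------------------------

def test_two_population_toy_full_hand_computation(toy_two_pop):
    res = amova_one_level(_dist(toy_two_pop), toy_two_pop.layout(),
                          n_permutations=0)
    t = res.table
    assert t.loc["Total", "SS"] == pytest.approx(2.0)
    assert t.loc["Among populations", "SS"] == pytest.approx(2.0)
    assert t.loc["Within populations", "SS"] == pytest.approx(0.0)
    assert t.loc["Among populations", "sigma2"] == pytest.approx(1.0)
    assert res.phi["PhiPT"] == pytest.approx(1.0)
    assert t["df"].iloc[:-1].sum() == toy_two_pop.n_individuals - 1


def test_all_identical_individuals_give_undefined_phi():
    m = make_matrix([[1, 0]] * 6, ["a"] * 3 + ["b"] * 3)
    res = amova_one_level(_dist(m), m.layout(), n_permutations=19, seed=0)
    assert res.table.loc["Total", "SS"] == 0.0
    assert np.isnan(res.phi["PhiPT"])       # undefined, never 0
    assert np.isnan(res.p_values["PhiPT"])


def test_all_singleton_layout_rejected():
    m = make_matrix([[1, 0], [0, 1], [1, 1]], ["a", "b", "c"])
    with pytest.raises(ValueError, match="singleton"):
        amova_one_level(_dist(m), m.layout())


def test_additivity_on_random_inputs(rng):
    for _ in range(10):
        m = random_matrix(rng, 12, 25, n_pops=3)
        res = amova_one_level(_dist(m), m.layout(), n_permutations=0)
        t = res.table
        assert t.loc["Among populations", "SS"] + \
            t.loc["Within populations", "SS"] == \
            pytest.approx(t.loc["Total", "SS"], abs=1e-9)


def test_amova_equals_per_locus_anova_oracle(rng):
    """Squared-distance algebra == summed per-locus one-way ANOVA."""
    m = random_matrix(rng, 12, 30, n_pops=3)   # equal sizes of 4
    res = amova_one_level(_dist(m), m.layout(), n_permutations=0)
    x = m.values.astype(float)
    groups = [m.population_indices(p) for p in m.populations]
    n, k = 12, 3
    ss_within = ss_total = 0.0
    for j in range(x.shape[1]):
        col = x[:, j]
        ss_total += ((col - col.mean()) ** 2).sum()
        ss_within += sum(((col[g] - col[g].mean()) ** 2).sum()
                         for g in groups)
    ss_among = ss_total - ss_within
    t = res.table
    assert t.loc["Total", "SS"] == pytest.approx(ss_total, abs=1e-9)
    assert t.loc["Within populations", "SS"] == pytest.approx(ss_within,
                                                              abs=1e-9)
    ms_a, ms_w = ss_among / (k - 1), ss_within / (n - k)
    n0 = (n - sum(len(g) ** 2 for g in groups) / n) / (k - 1)
    sigma_a = (ms_a - ms_w) / n0
    expect_phi = max(sigma_a, 0) / (max(sigma_a, 0) + ms_w)
    assert res.phi["PhiPT"] == pytest.approx(expect_phi, abs=1e-12)


def test_phipt_invariant_to_locus_and_within_pop_order(rng):
    m = random_matrix(rng, 12, 25, n_pops=3)
    base = amova_one_level(_dist(m), m.layout(), n_permutations=0)
    # permute loci
    perm = rng.permutation(25)
    m2 = make_matrix(m.values[:, perm],
                     [m.pop_of[a] for a in m.accession_ids])
    r2 = amova_one_level(_dist(m2), m2.layout(), n_permutations=0)
    assert r2.phi["PhiPT"] == pytest.approx(base.phi["PhiPT"], abs=1e-12)
    # permute individuals within populations
    order = []
    for p in m.populations:
        idx = m.population_indices(p)
        order.extend(rng.permutation(idx).tolist())
    m3 = make_matrix(m.values[order],
                     [m.pop_of[m.accession_ids[i]] for i in order])
    r3 = amova_one_level(_dist(m3), m3.layout(), n_permutations=0)
    assert r3.phi["PhiPT"] == pytest.approx(base.phi["PhiPT"], abs=1e-12)


def test_permutation_p_deterministic_given_seed(rng):
    m = random_matrix(rng, 10, 15, n_pops=2)
    d, layout = _dist(m), m.layout()
    p1 = amova_one_level(d, layout, n_permutations=99, seed=42).p_values
    p2 = amova_one_level(d, layout, n_permutations=99, seed=42).p_values
    assert p1 == p2
    assert 0 < p1["PhiPT"] <= 1


def test_size_one_population_is_allowed():
    m = make_matrix([[1, 1], [1, 0], [0, 0]], ["a", "a", "b"])
    res = amova_one_level(_dist(m), m.layout(), n_permutations=0)
    assert res.table.loc["Within populations", "df"] == 1


# ---- hierarchical AMOVA ---------------------------------------------------

def _toy_hier():
    # 2 taxa x 2 pops x 2 individuals, 4 loci
    values = [[1, 1, 0, 0], [1, 1, 0, 1],
              [1, 0, 0, 0], [1, 0, 1, 0],
              [0, 1, 1, 1], [0, 1, 1, 0],
              [0, 0, 1, 1], [0, 1, 0, 1]]
    pops = ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"]
    taxa = {"p1": "t1", "p2": "t1", "p3": "t2", "p4": "t2"}
    return make_matrix(values, pops, taxon_of=taxa)


def test_hierarchical_strata_match_definitional_sums():
    m = _toy_hier()
    res = amova_hierarchical(_dist(m), m.layout(), n_permutations=0)
    # independent brute-force via the definitional sums on squared distances
    dsq = _dist(m).values  # mismatch counts are the squared distances
    n = 8

    def ss_blocks(blocks):
        out = 0.0
        for b in blocks:
            sub = dsq[np.ix_(b, b)]
            out += sub.sum() / (2 * len(b))
        return out

    pops = [[0, 1], [2, 3], [4, 5], [6, 7]]
    taxa = [[0, 1, 2, 3], [4, 5, 6, 7]]
    ss_total = ss_blocks([list(range(n))])
    ss_wp = ss_blocks(pops)
    ss_wg = ss_blocks(taxa)
    t = res.table
    assert t.loc["Within populations", "SS"] == pytest.approx(ss_wp)
    assert t.loc["Among populations within taxa", "SS"] == \
        pytest.approx(ss_wg - ss_wp)
    assert t.loc["Among taxa", "SS"] == pytest.approx(ss_total - ss_wg)
    assert t.loc["Total", "SS"] == pytest.approx(ss_total)
    assert list(t["df"].iloc[:-1]) == [1, 2, 4]


def test_taxa_identical_to_populations_collapse_to_one_level():
    m = _toy_hier()
    taxa = {p: p for p in m.populations}
    layout = m.layout()
    hl = PopulationLayout(layout.populations, layout.sizes, taxa)
    hier = amova_hierarchical(_dist(m), hl, n_permutations=0)
    one = amova_one_level(_dist(m), layout, n_permutations=0)
    assert hier.table.loc["Among populations within taxa", "df"] == 0
    assert hier.phi["PhiPT"] == pytest.approx(one.phi["PhiPT"], abs=1e-12)
    assert hier.phi["PhiRT"] == pytest.approx(one.phi["PhiPT"], abs=1e-12)
    assert np.isnan(hier.phi["PhiPR"])


def test_single_taxon_reduces_to_one_level_phipr():
    m = _toy_hier()
    layout = m.layout()
    hl = PopulationLayout(layout.populations, layout.sizes,
                          {p: "only" for p in layout.populations})
    hier = amova_hierarchical(_dist(m), hl, n_permutations=0)
    one = amova_one_level(_dist(m), layout, n_permutations=0)
    assert np.isnan(hier.phi["PhiRT"])
    assert hier.phi["PhiPR"] == pytest.approx(one.phi["PhiPT"], abs=1e-12)


def test_hierarchical_permutations_deterministic():
    m = _toy_hier()
    r1 = amova_hierarchical(_dist(m), m.layout(), n_permutations=49, seed=7)
    r2 = amova_hierarchical(_dist(m), m.layout(), n_permutations=49, seed=7)
    assert r1.p_values == r2.p_values


# ---- pairwise PhiPT -------------------------------------------------------

def test_pairwise_phipt_toy_and_self_copy(toy_two_pop):
    res = pairwise_phipt(_dist(toy_two_pop), toy_two_pop.layout(),
                         n_permutations=0)
    assert res.phipt.loc["popA", "popB"] == pytest.approx(1.0)
    assert res.phipt.loc["popA", "popA"] == 0.0
    # population against a copy of itself: sigma_among floored to 0
    m = make_matrix([[1, 0], [0, 1], [1, 0], [0, 1]],
                    ["a", "a", "b", "b"])
    r2 = pairwise_phipt(_dist(m), m.layout(), n_permutations=0)
    assert r2.phipt.loc["a", "b"] == 0.0


def test_pairwise_phipt_symmetric_and_seeded(rng):
    m = random_matrix(rng, 12, 15, n_pops=3)
    r1 = pairwise_phipt(_dist(m), m.layout(), n_permutations=49, seed=3)
    r2 = pairwise_phipt(_dist(m), m.layout(), n_permutations=49, seed=3)
    assert np.allclose(r1.phipt.values, r1.phipt.values.T)
    assert np.allclose(np.diag(r1.phipt.values), 0)
    assert r1.p_values.equals(r2.p_values)


# ---- model surface --------------------------------------------------------

def test_amova_model_from_band_matrix(toy_two_pop):
    res = Amova.from_band_matrix(toy_two_pop).fit(n_permutations=19, seed=0)
    assert res.phi["PhiPT"] == pytest.approx(1.0)
    assert "PhiPT" in res.summary()


def test_amova_model_rejects_p_distance(toy_two_pop):
    d = pairwise_distance(toy_two_pop, metric="p-distance")
    with pytest.raises(ValueError, match="mismatch-count"):
        Amova(d, toy_two_pop.layout())
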
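"""MLG clustering, distance spectrum, recombinant triads, frequency change."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import rand_score

from selfpop.mlg import (
    MLGClusterer,
    cluster_mlgs,
    detect_recombinants,
    distance_spectrum,
    frequency_change,
    genotype_distance,
)
from selfpop.synth import make_fixture

from conftest import homozygous_gm, make_gm


def hom(row):
    return np.repeat(np.asarray(row)[:, None], 2, axis=1)


class TestGenotypeDistance:
    def test_identical(self):
        a = hom(np.arange(1, 17))
        assert genotype_distance(a, a) == (0, 16, 0.0)

    def test_one_mismatch_is_error_tolerance(self):
        a = hom(np.arange(1, 17))
        b = a.copy()
        b[5] = (9, 9)
        n_mis, n_cmp, frac = genotype_distance(a, b)
        assert (n_mis, n_cmp) == (1, 16) and frac == pytest.approx(1 / 16)

    def test_missing_loci_excluded(self):
        a = hom(np.arange(1, 17))
        b = a.copy()
        b[:4] = 0
        b[5] = (9, 9)
        n_mis, n_cmp, frac = genotype_distance(a, b)
        assert (n_mis, n_cmp) == (1, 12) and frac == pytest.approx(1 / 12)

    def test_no_comparable_loci_and_mismatched_shapes(self):
        a = hom([1, 2])
        b = np.zeros((2, 2), dtype=int)
        assert np.isnan(genotype_distance(a, b)[2])
        with pytest.raises(ValueError):
            genotype_distance(a, hom([1, 2, 3]))

    def test_heterozygous_pair_counts_one_mismatch(self):
        a = np.array([[1, 2]])
        b = np.array([[1, 1]])
        assert genotype_distance(a, b)[0] == 1


class TestClustering:
    def test_all_identical_one_mlg(self):
        gm = homozygous_gm(np.tile(np.arange(1, 9), (6, 1)))
        cat = cluster_mlgs(gm, seed=0)
        assert cat.n_mlgs == 1 and len(cat.mlgs[0].members) == 6

    def test_threshold_logic(self):
        base = np.arange(1, 17)
        a, a2, b = base.copy(), base.copy(), base.copy()
        a2[0] = 9          # 1/16 from a
        b[:8] = 20         # 8/16 from both
        gm = homozygous_gm([a, a2, b])
        cat = cluster_mlgs(gm, error_rate=1 / 16, seed=0)
        assert cat.n_mlgs == 2
        assert sorted(len(r.members) for r in cat.mlgs) == [1, 2]

    def test_zero_error_equals_exact_match_oracle(self, rng):
        alleles = rng.integers(1, 4, size=(30, 6))
        gm = homozygous_gm(alleles)
        labels = MLGClusterer(error_rate=0.0, random_state=1).fit_predict(gm)
        oracle = {}
        truth = [oracle.setdefault(tuple(row), len(oracle)) for row in alleles]
        assert rand_score(truth, labels) == 1.0

    def test_unambiguous_assignment_is_seed_independent(self, rng):
        alleles = rng.integers(1, 3, size=(25, 8))
        gm = homozygous_gm(alleles)
        l1 = MLGClusterer(error_rate=0.0, random_state=1).fit_predict(gm)
        l2 = MLGClusterer(error_rate=0.0, random_state=999).fit_predict(gm)
        assert rand_score(l1, l2) == 1.0

    def test_ambiguous_assigned_to_compatible_group(self):
        a = np.arange(1, 17)
        b = a + 20
        rows = [a] * 4 + [b] * 2
        calls = np.repeat(np.asarray(rows)[:, :, None], 2, axis=2)
        amb = np.repeat(a[:, None], 2, axis=1)
        amb[8:] = 0  # missing half the loci, still only compatible with group A
        calls = np.concatenate([calls, amb[None]], axis=0)
        gm = make_gm(calls)
        for seed in (0, 1, 2):
            cat = cluster_mlgs(gm, seed=seed)
            assert cat.labels["I06"] == cat.labels["I00"]

    def test_residual_heterozygosity_flags(self):
        calls = np.array([[[1, 1], [2, 3], [4, 4], [5, 6]]] * 3)
        gm = make_gm(calls)
        cat = cluster_mlgs(gm, seed=0)
        rec = cat.mlgs[0]
        assert rec.residual_heterozygosity == pytest.approx(0.5)
        assert not rec.fully_homozygous

    def test_counts_partition_invariant(self, two_year_gm):
        cat = cluster_mlgs(two_year_gm, error_rate=0.0, seed=3)
        years = two_year_gm.year_array
        for y in cat.years:
            assert sum(r.counts_by_year.get(y, 0) for r in cat.mlgs) == (years == y).sum()
        assert sum(len(r.members) for r in cat.mlgs) == two_year_gm.n_individuals


class TestSpectrumAndFixture:
    def test_two_mlgs_distance_five(self):
        a = np.arange(1, 9)
        b = a.copy()
        b[:5] = 30
        cat = cluster_mlgs(homozygous_gm([a, b]), error_rate=0.0, seed=0)
        assert distance_spectrum(cat) == {5: 1}

    def test_error_spike_removed_by_tolerance(self):
        fx = make_fixture("tiny_clones", seed=0)
        gm = fx["genotypes"]
        cat0 = cluster_mlgs(gm, error_rate=0.0, seed=0)
        assert 1 in distance_spectrum(cat0)  # read error shows as a distance-1 pair
        cat = cluster_mlgs(gm, error_rate=1 / 16, seed=0)
        assert cat.n_mlgs == 3
        assert 1 not in distance_spectrum(cat)
        labels = [cat.labels[i] for i in gm.individuals]
        assert rand_score(fx["true_labels"], labels) == 1.0


class TestRecombinants:
    def test_exact_additivity_triad(self):
        A, B, C = [1, 1, 1, 1], [2, 2, 2, 2], [1, 1, 2, 2]
        cat = cluster_mlgs(homozygous_gm([A, B, C]), error_rate=0.0, seed=0)
        triads = detect_recombinants(cat)
        children = {t["child"] for t in triads}
        assert cat.labels["I02"] in children

    def test_non_additive_not_reported(self):
        A, B, C = [1, 1, 1, 1], [2, 2, 2, 2], [1, 3, 2, 2]
        cat = cluster_mlgs(homozygous_gm([A, B, C]), error_rate=0.0, seed=0)
        c_id = cat.labels["I02"]
        assert not any(t["child"] == c_id for t in detect_recombinants(cat))

    def test_equidistant_catalog_has_no_triads(self):
        # 4 mutually equidistant genotypes (distance 3 between every pair)
        rows = [[1, 1, 1], [2, 2, 2], [3, 3, 3], [4, 4, 4]]
        cat = cluster_mlgs(homozygous_gm(rows), error_rate=0.0, seed=0)
        from selfpop.mlg import genotype_distance as gd

        d = {(i, j): gd(cat.mlgs[i].consensus, cat.mlgs[j].consensus)[0]
             for i in range(4) for j in range(4) if i != j}
        assert len(set(d.values())) == 1  # construction check: all pairs equidistant
        assert detect_recombinants(cat) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(1, 4, size=(12, 6))
        gm = homozygous_gm(alleles)
        cat = cluster_mlgs(gm, error_rate=0.0, seed=0)
        got = {(t["child"], frozenset((t["parent_a"], t["parent_b"])))
               for t in detect_recombinants(cat)}
        expect = set()
        cons = {r.mlg_id: r.consensus for r in cat.mlgs}
        for a, b, c in itertools.permutations(cons, 3):
            if a > b:
                continue
            dac = genotype_distance(cons[a], cons[c])[0]
            dcb = genotype_distance(cons[c], cons[b])[0]
            dab = genotype_distance(cons[a], cons[b])[0]
            if dac > 0 and dcb > 0 and dac + dcb == dab:
                expect.add((c, frozenset((a, b))))
        assert got == expect


class TestFrequencyChange:
    def _catalog(self, rows, years):
        return cluster_mlgs(homozygous_gm(rows, years=years), error_rate=0.0, seed=0)

    def test_signed_delta(self):
        # year1 {A, B}, year2 {A, A}
        rows = [[1, 1], [2, 2], [1, 1], [1, 1]]
        cat = self._catalog(rows, ["1987", "1987", "2009", "2009"])
        ft = frequency_change(cat, "1987", "2009")
        by = ft.table.set_index("mlg")["delta"]
        a = cat.labels["I00"]
        b = cat.labels["I01"]
        assert by[a] == pytest.approx(0.5) and by[b] == pytest.approx(-0.5)
        assert ft.table["freq1"].sum() == pytest.approx(1.0)
        assert ft.table["freq2"].sum() == pytest.approx(1.0)

    def test_restrict_to_year1(self):
        rows = [[1, 1], [1, 1], [2, 2]]
        cat = self._catalog(rows, ["1987", "2009", "2009"])
        ft = frequency_change(cat, "1987", "2009", restrict_to_year1=True)
        assert len(ft.table) == 1 and ft.table["present_in_year1"].all()

    def test_heterozygous_excluded_and_renormalized(self):
        calls = np.array(
            [[[1, 1], [2, 2]], [[1, 1], [2, 2]], [[1, 2], [2, 2]], [[3, 3], [4, 4]]]
        )
        gm = make_gm(calls, years=["1987", "2009", "1987", "2009"])
        cat = cluster_mlgs(gm, error_rate=0.0, seed=0)
        ft = frequency_change(cat, "1987", "2009", homozygous_only=True)
        assert ft.n_year1 == 1  # het individual dropped from 1987
        assert ft.table["freq1"].sum() == pytest.approx(1.0)

    def test_empty_year_errors(self):
        rows = [[1, 1], [2, 2]]
        cat = self._catalog(rows, ["1987", "1987"])
        with pytest.raises(ValueError):
            frequency_change(cat, "1987", "2009")
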
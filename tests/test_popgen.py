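"""Unit and property tests for the population-genetic statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from genescape.popgen import (
    DatasetError,
    Haplotype,
    PopulationSample,
    SpeciesDataset,
    UndefinedStatisticError,
    diversity_table,
    filter_min_sample,
    fst_matrix,
    haplotype_diversity,
    index_correlation,
    nucleotide_diversity,
    pairwise_phist,
    read_species_dataset,
)
from genescape.simulate import StudyConfig, simulate_study

from conftest import make_haplotypes, random_population


# ---------------------------------------------------------------------------
# oracles


def expand_individuals(pop: PopulationSample) -> list[str]:
    out = []
    for h in sorted(pop.counts):
        out.extend([h] * pop.counts[h])
    return out


def site_diffs(a: str, b: str) -> tuple[int, int]:
    pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    return sum(1 for x, y in pairs if x != y), len(pairs)


def pi_pair_oracle(pop: PopulationSample, haplotypes: list[Haplotype]) -> float:
    """Average per-site difference over every pair of sampled individuals."""
    seq = {h.id: h.sequence for h in haplotypes}
    inds = expand_individuals(pop)
    vals = []
    for a, b in itertools.combinations(inds, 2):
        d, c = site_diffs(seq[a], seq[b])
        vals.append(d / c)
    return float(np.mean(vals))


def phist_ss_oracle(
    popA: PopulationSample, popB: PopulationSample, haplotypes: list[Haplotype]
) -> float:
    """Two-population AMOVA from explicit per-individual sums of squares."""
    seq = {h.id: h.sequence for h in haplotypes}
    groups = [expand_individuals(popA), expand_individuals(popB)]
    everyone = groups[0] + groups[1]
    n_tot = len(everyone)

    def d2(a: str, b: str) -> float:
        return float(site_diffs(seq[a], seq[b])[0])

    def ssd(individuals: list[str]) -> float:
        total = 0.0
        for a in individuals:
            for b in individuals:
                total += d2(a, b)
        return total / (2 * len(individuals))

    ssd_total = ssd(everyone)
    ssd_within = sum(ssd(g) for g in groups)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n_tot - 2)
    n_c = n_tot - (len(groups[0]) ** 2 + len(groups[1]) ** 2) / n_tot
    sigma_a = (ssd_among - sigma_w) / n_c
    if sigma_a + sigma_w == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


# ---------------------------------------------------------------------------
# loading and filtering


class TestReadSpeciesDataset:
    def test_single_haplotype_population_expands_to_identical_rows(self, tmp_path):
        (tmp_path / "sp.fasta").write_text(">h1\nACGTACGT\n")
        pd.DataFrame(
            [("sp", "p1", 100.0, 25.0, "h1", 5)],
            columns=["species", "pop_id", "lon", "lat", "haplotype", "count"],
        ).to_csv(tmp_path / "pops.csv", index=False)
        ds = read_species_dataset(tmp_path / "sp.fasta", tmp_path / "pops.csv", "sp")
        assert ds.populations[0].n == 5
        rows = ds.expanded_matrix(ds.populations[0])
        assert rows == ["ACGTACGT"] * 5

    def test_population_totals_match_independent_csv_sums(self, tmp_path):
        cfg = StudyConfig(n_species=2, pops_per_species=(4, 8), resolution=1.0, seed=1)
        bundle = simulate_study(cfg, tmp_path / "study")
        table = pd.read_csv(bundle.population_table)
        for sp in bundle.species:
            ds = read_species_dataset(bundle.fasta_paths[sp], bundle.population_table, sp)
            expected = table[table["species"] == sp]["count"].sum()
            assert sum(p.n for p in ds.populations) == expected

    def test_unknown_haplotype_id_is_named_in_error(self, tmp_path):
        (tmp_path / "sp.fasta").write_text(">h1\nACGT\n")
        pd.DataFrame(
            [("sp", "p1", 0.0, 0.0, "h9", 5)],
            columns=["species", "pop_id", "lon", "lat", "haplotype", "count"],
        ).to_csv(tmp_path / "pops.csv", index=False)
        with pytest.raises(DatasetError, match="h9"):
            read_species_dataset(tmp_path / "sp.fasta", tmp_path / "pops.csv", "sp")

    def test_unequal_sequence_lengths_rejected(self, tmp_path):
        (tmp_path / "sp.fasta").write_text(">h1\nACGT\n>h2\nACGTAA\n")
        pd.DataFrame(
            [("sp", "p1", 0.0, 0.0, "h1", 5)],
            columns=["species", "pop_id", "lon", "lat", "haplotype", "count"],
        ).to_csv(tmp_path / "pops.csv", index=False)
        with pytest.raises(DatasetError, match="aligned"):
            read_species_dataset(tmp_path / "sp.fasta", tmp_path / "pops.csv", "sp")

    def test_negative_count_rejected(self, tmp_path):
        (tmp_path / "sp.fasta").write_text(">h1\nACGT\n")
        pd.DataFrame(
            [("sp", "p1", 0.0, 0.0, "h1", -2)],
            columns=["species", "pop_id", "lon", "lat", "haplotype", "count"],
        ).to_csv(tmp_path / "pops.csv", index=False)
        with pytest.raises(DatasetError, match="negative"):
            read_species_dataset(tmp_path / "sp.fasta", tmp_path / "pops.csv", "sp")


class TestFilterMinSample:
    def _dataset(self, ns):
        haps = [Haplotype("h1", "ACGT")]
        pops = [PopulationSample(f"p{i}", 0.0, 0.0, {"h1": n}) for i, n in enumerate(ns)]
        return SpeciesDataset("sp", haps, pops)

    def test_boundary_is_inclusive(self):
        out = filter_min_sample(self._dataset([4, 5, 6]), min_n=5)
        assert [p.n for p in out.populations] == [5, 6]

    def test_min_n_one_is_identity(self):
        ds = self._dataset([1, 3, 7])
        out = filter_min_sample(ds, min_n=1)
        assert [p.pop_id for p in out.populations] == [p.pop_id for p in ds.populations]

    def test_all_removed_sets_flag_with_warning(self):
        with pytest.warns(UserWarning, match="every population removed"):
            out = filter_min_sample(self._dataset([1, 2]), min_n=5)
        assert out.empty_after_filter and not out.populations

    def test_retained_count_matches_brute_force_table_scan(self, tmp_path):
        cfg = StudyConfig(
            n_species=2, pops_per_species=(6, 10), resolution=1.0,
            contaminate_fraction=0.4, seed=7,
        )
        bundle = simulate_study(cfg, tmp_path / "study")
        table = pd.read_csv(bundle.population_table)
        for sp in bundle.species:
            ds = read_species_dataset(bundle.fasta_paths[sp], bundle.population_table, sp)
            kept = filter_min_sample(ds, 5)
            per_pop = table[table["species"] == sp].groupby("pop_id")["count"].sum()
            assert len(kept.populations) == int((per_pop >= 5).sum())


# ---------------------------------------------------------------------------
# H_D


class TestHaplotypeDiversity:
    def test_monomorphic_population_has_zero_diversity(self):
        assert haplotype_diversity(PopulationSample("p", 0, 0, {"h1": 10})) == 0.0

    def test_all_distinct_haplotypes_give_unit_diversity(self):
        pop = PopulationSample("p", 0, 0, {f"h{i}": 1 for i in range(5)})
        assert haplotype_diversity(pop) == pytest.approx(1.0, abs=1e-15)

    def test_hand_computed_example(self):
        pop = PopulationSample("p", 0, 0, {"h1": 3, "h2": 2, "h3": 1})
        assert haplotype_diversity(pop) == pytest.approx(11 / 15, abs=1e-15)

    def test_undefined_below_two_individuals(self):
        with pytest.raises(UndefinedStatisticError):
            haplotype_diversity(PopulationSample("p", 0, 0, {"h1": 1}))

    def test_bounds_and_extremes_on_random_populations(self):
        rng = np.random.default_rng(11)
        hap_ids = [f"h{i}" for i in range(6)]
        for i in range(1000):
            pop = random_population(rng, hap_ids, pop_id=f"p{i}")
            h = haplotype_diversity(pop)
            assert 0.0 <= h <= 1.0
            if all(c == 1 for c in pop.counts.values()):
                assert h == pytest.approx(1.0, abs=1e-14)
            if len(pop.counts) == 1:
                assert h == 0.0
            if h == 0.0:
                assert len(pop.counts) == 1

    def test_label_invariance(self):
        pop = PopulationSample("p", 0, 0, {"h1": 3, "h2": 2, "h3": 1})
        relabeled = PopulationSample("p", 0, 0, {"x": 1, "y": 3, "z": 2})
        assert haplotype_diversity(pop) == pytest.approx(haplotype_diversity(relabeled), abs=1e-14)


# ---------------------------------------------------------------------------
# pi


class TestNucleotideDiversity:
    def test_monomorphic_population_is_zero(self, small_pool):
        pop = PopulationSample("p", 0, 0, {"h1": 6})
        assert nucleotide_diversity(pop, small_pool) == 0.0

    def test_hand_computed_two_haplotype_example(self):
        haps = [Haplotype("h1", "A" * 10), Haplotype("h2", "A" * 9 + "C")]
        pop = PopulationSample("p", 0, 0, {"h1": 2, "h2": 2})
        assert nucleotide_diversity(pop, haps) == pytest.approx(4 / 3 * 2 * 0.25 * 0.1, abs=1e-15)

    def test_matches_pair_enumeration_oracle_on_random_populations(self):
        rng = np.random.default_rng(3)
        pool = make_haplotypes(k=6, length=40, seed=5)
        # include gap/ambiguity characters to exercise pairwise deletion
        gapped = pool[:4] + [
            Haplotype("h5", pool[4].sequence[:-4] + "N-N-"),
            Haplotype("h6", "--" + pool[5].sequence[2:]),
        ]
        ids = [h.id for h in gapped]
        for i in range(200):
            pop = random_population(rng, ids, pop_id=f"p{i}")
            expected = pi_pair_oracle(pop, gapped)
            assert nucleotide_diversity(pop, gapped) == pytest.approx(expected, abs=1e-12)

    def test_zero_comparable_sites_pair_warns(self):
        haps = [Haplotype("h1", "AC--"), Haplotype("h2", "--AC")]
        pop = PopulationSample("p", 0, 0, {"h1": 2, "h2": 2})
        with pytest.warns(UserWarning, match="no comparable sites"):
            nucleotide_diversity(pop, haps)


# ---------------------------------------------------------------------------
# Phi_ST


class TestPairwisePhist:
    def test_identical_compositions_give_nonpositive_estimate(self, small_pool):
        # no among-population variance: the unbiased AMOVA estimator is <= 0
        # (negative, not zero, because the observed among-group sum of squares
        # sits below its null expectation)
        a = PopulationSample("a", 0, 0, {"h1": 3, "h2": 3})
        b = PopulationSample("b", 1, 1, {"h1": 3, "h2": 3})
        assert pairwise_phist(a, b, small_pool) <= 1e-12

    def test_fixed_difference_gives_one(self, small_pool):
        a = PopulationSample("a", 0, 0, {"h1": 5})
        b = PopulationSample("b", 1, 1, {"h2": 5})
        assert pairwise_phist(a, b, small_pool) == pytest.approx(1.0, abs=1e-12)

    def test_shared_monomorphism_is_degenerate_zero(self, small_pool):
        a = PopulationSample("a", 0, 0, {"h1": 4})
        b = PopulationSample("b", 1, 1, {"h1": 6})
        assert pairwise_phist(a, b, small_pool) == 0.0

    @pytest.mark.parametrize("distance", ["nucleotide", "frequency"])
    def test_symmetry_and_upper_bound_random_instances(self, distance):
        rng = np.random.default_rng(17)
        pool = make_haplotypes(k=5, length=25, seed=2)
        ids = [h.id for h in pool]
        for i in range(50):
            a = random_population(rng, ids, pop_id="a")
            b = random_population(rng, ids, pop_id="b")
            ab = pairwise_phist(a, b, pool, distance=distance)
            ba = pairwise_phist(b, a, pool, distance=distance)
            assert ab == pytest.approx(ba, abs=1e-12)
            assert ab <= 1.0 + 1e-12
            # self-comparison carries no among-population variance
            assert pairwise_phist(a, a, pool, distance=distance) <= 1e-12

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(23)
        pool = make_haplotypes(k=5, length=25, seed=4)
        ids = [h.id for h in pool]
        for i in range(100):
            a = random_population(rng, ids, pop_id="a")
            b = random_population(rng, ids, pop_id="b")
            assert pairwise_phist(a, b, pool) == pytest.approx(
                phist_ss_oracle(a, b, pool), abs=1e-10
            )

    def test_monotone_under_composition_mixing(self, small_pool):
        # mix two populations from identical toward fixed-different compositions
        n = 10
        prev = -np.inf
        for t in np.linspace(0, 1, 6):
            ka = int(round(n * (1 + t) / 2))
            a = PopulationSample("a", 0, 0, {k: v for k, v in {"h1": ka, "h2": n - ka}.items() if v})
            b = PopulationSample("b", 1, 1, {k: v for k, v in {"h2": ka, "h1": n - ka}.items() if v})
            phi = pairwise_phist(a, b, small_pool)
            assert phi >= prev - 1e-12
            prev = phi


class TestFstMatrix:
    def test_identical_populations_give_nonpositive_matrix(self, small_pool):
        pops = [
            PopulationSample("p1", 0, 0, {"h1": 3, "h2": 2}),
            PopulationSample("p2", 1, 1, {"h1": 3, "h2": 2}),
        ]
        m = fst_matrix(SpeciesDataset("sp", small_pool, pops))
        assert np.all(np.diag(m.values) == 0.0)
        assert np.all(m.values <= 1e-12)

    def test_two_identical_plus_one_fixed_different(self, small_pool):
        pops = [
            PopulationSample("p1", 0, 0, {"h1": 5}),
            PopulationSample("p2", 1, 1, {"h1": 5}),
            PopulationSample("p3", 2, 2, {"h3": 5}),
        ]
        m = fst_matrix(SpeciesDataset("sp", small_pool, pops))
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert m.values[0, 2] == pytest.approx(1.0, abs=1e-12)
        assert m.values[1, 2] == pytest.approx(1.0, abs=1e-12)

    def test_matrix_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(3)
        pool = make_haplotypes(k=5, length=30, seed=3)
        ids = [h.id for h in pool]
        pops = [random_population(rng, ids, pop_id=f"p{i}") for i in range(6)]
        ds = SpeciesDataset("sp", pool, pops)
        m = fst_matrix(ds)
        for i in range(6):
            for j in range(6):
                expected = 0.0 if i == j else pairwise_phist(pops[i], pops[j], pool)
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_requires_two_populations(self, small_pool):
        ds = SpeciesDataset("sp", small_pool, [PopulationSample("p1", 0, 0, {"h1": 5})])
        with pytest.raises(DatasetError):
            fst_matrix(ds)


# ---------------------------------------------------------------------------


class TestIndexCorrelation:
    def test_perfectly_correlated_and_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert index_correlation(x, x)[0] == pytest.approx(1.0)
        assert index_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r, _ = index_correlation(x, y)
        expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            index_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_diversity_table_columns_and_row_order(two_pop_dataset):
    table = diversity_table(two_pop_dataset)
    assert list(table.columns) == ["species", "pop_id", "lon", "lat", "N", "H_D", "pi"]
    assert list(table["pop_id"]) == ["p1", "p2"]
    assert ((table["H_D"] >= 0) & (table["H_D"] <= 1)).all()
    assert (table["pi"] >= 0).all()


def test_statistics_invariant_to_population_row_order(small_pool):
    pops = [
        PopulationSample("p1", 0, 0, {"h1": 4, "h3": 3}),
        PopulationSample("p2", 1, 1, {"h2": 5, "h4": 2}),
    ]
    fwd = fst_matrix(SpeciesDataset("sp", small_pool, pops))
    rev = fst_matrix(SpeciesDataset("sp", small_pool, pops[::-1]))
    assert fwd.values[0, 1] == pytest.approx(rev.values[0, 1], abs=1e-14)


# ---------------------------------------------------------------------------
# hypothesis property tests

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=8))
def test_haplotype_diversity_bounds_property(counts):
    pop = PopulationSample("p", 0, 0, {f"h{i}": c for i, c in enumerate(counts)})
    if pop.n < 2:
        return
    h = haplotype_diversity(pop)
    assert 0.0 <= h <= 1.0
    assert (h == 0.0) == (len(pop.counts) == 1)
    if all(c == 1 for c in counts):
        assert h == pytest.approx(1.0, abs=1e-14)


@settings(derandomize=True, max_examples=100)
@given(
    st.floats(min_value=0.0, max_value=1.0),
    st.integers(min_value=10, max_value=10_000),
    st.integers(min_value=0, max_value=8),
)
def test_adjusted_r2_never_exceeds_raw_r2(r2, n, p):
    from genescape.attribution import adjusted_r2

    adj = adjusted_r2(r2, n, p)
    assert adj <= r2 + 1e-12
    assert adj <= 1.0
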
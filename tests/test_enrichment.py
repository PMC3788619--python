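"""Poisson exact tests, FDR, impact bins, permutation, domain/pathway/PPI."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosphorewire import errors
from phosphorewire.annotation import (MissenseVariant, annotate_psnvs,
                                      build_site_windows, count_by_context,
                                      merge_regions)
from phosphorewire.config import RunConfig
from phosphorewire.enrichment import (ImpactBinCounts, bh_fdr,
                                      context_enrichment, domain_enrichment,
                                      impact_bin_test, pathway_enrichment,
                                      permutation_mean_diff, poisson_exact_p,
                                      poisson_expected_range,
                                      ppi_group_enrichment)

from conftest import make_protein


def poisson_upper_tail_oracle(k, lam):
    """Independent log-space series for P(X >= k)."""
    total, j = 0.0, k
    while True:
        term = math.exp(j * math.log(lam) - lam - math.lgamma(j + 1))
        total += term
        if j > lam and term < 1e-18 * max(total, 1e-300):
            break
        j += 1
    return total


class TestPoissonExact:
    def test_observed_zero_enriched_is_one(self):
        assert poisson_exact_p(0, 3.7, "enriched") == 1.0

    @pytest.mark.parametrize("k,lam", [(5, 1.0), (3, 0.2), (10, 4.5),
                                       (120, 100.0), (1, 9.0)])
    def test_matches_series_oracle(self, k, lam):
        assert poisson_exact_p(k, lam, "enriched") == pytest.approx(
            poisson_upper_tail_oracle(k, lam), rel=1e-10)

    def test_printed_example(self):
        # P(X >= 5 | lambda = 1) = 1 - sum_{k<5} e^-1 / k!
        assert poisson_exact_p(5, 1.0, "enriched") == pytest.approx(
            0.00365984682734371, rel=1e-9)

    def test_tail_identity(self):
        for k, lam in [(1, 0.5), (5, 5.0), (50, 47.2), (200, 180.0)]:
            up = poisson_exact_p(k, lam, "enriched")
            down = poisson_exact_p(k - 1, lam, "depleted")
            assert up + down == pytest.approx(1.0, abs=1e-12)

    def test_median_count_near_half(self):
        lam = 400.0
        assert poisson_exact_p(400, lam, "enriched") == pytest.approx(
            0.5, abs=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(errors.FormatError):
            poisson_exact_p(3, 0.0)
        with pytest.raises(errors.FormatError):
            poisson_exact_p(3, 1.0, "sideways")


class TestExpectedRange:
    def test_zero_rate(self):
        assert poisson_expected_range(0.0, 1000, seed=1) == (0.0, 0.0)

    def test_median_close_to_mean(self):
        med, mad = poisson_expected_range(100.0, 10000, seed=4)
        assert abs(med - 100) <= 2
        assert 4 <= mad <= 10  # MAD of Poisson(100) ≈ 0.6745·10

    def test_seeded_determinism(self):
        assert poisson_expected_range(17.3, 2000, seed=9) == \
            poisson_expected_range(17.3, 2000, seed=9)

    def test_too_few_draws_rejected(self):
        with pytest.raises(errors.FormatError):
            poisson_expected_range(5.0, 10, seed=0)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_fdr_at_least_p_and_monotone(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04, 0.0004])
        fdr = bh_fdr(p)
        assert np.all(fdr >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-15)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_permutation(self, ps):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ps))
        direct = bh_fdr(ps)
        permuted = bh_fdr([ps[i] for i in perm])
        assert np.allclose([direct[i] for i in perm], permuted)

    def test_out_of_range_rejected(self):
        with pytest.raises(errors.FormatError):
            bh_fdr([0.5, 1.2])


class TestImpactBins:
    def test_matching_frequencies_give_p_one(self):
        bins = [ImpactBinCounts("low", 50, 500),
                ImpactBinCounts("moderate", 30, 300),
                ImpactBinCounts("high", 20, 200)]
        ps = impact_bin_test(bins)
        assert all(p == pytest.approx(1.0) for p in ps.values())

    def test_matches_tail_sum_oracle(self):
        # 60 of 100 pSNVs in the high bin against background frequency 0.5:
        # symmetric two-sided tail P(X>=60) + P(X<=40)
        bins = [ImpactBinCounts("high", 60, 500),
                ImpactBinCounts("low", 40, 500)]
        ps = impact_bin_test(bins)
        tail = sum(math.comb(100, i) * 0.5 ** 100
                   for i in range(101) if i >= 60 or i <= 40)
        assert ps["high"] == pytest.approx(tail, rel=1e-9)

    def test_empty_psnv_set_skipped_with_warning(self):
        bins = [ImpactBinCounts("low", 0, 10)]
        with pytest.warns(UserWarning):
            assert impact_bin_test(bins) == {}


class TestPermutation:
    def test_identical_groups_near_one(self):
        a = [1.0, 2.0, 3.0, 4.0] * 5
        p = permutation_mean_diff(a, list(a), n_perm=500, seed=0)
        assert p > 0.9

    def test_separated_groups_hit_floor(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)  # ~10 pooled SDs apart
        p = permutation_mean_diff(a, b, n_perm=2000, seed=1)
        assert p == pytest.approx(1 / 2001)

    def test_seeded_determinism(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        assert permutation_mean_diff(a, b, 300, seed=7) == \
            permutation_mean_diff(a, b, 300, seed=7)


def toy_context(n_other=0):
    """A tiny proteome for context tests."""
    seq = list("A" * 60)
    seq[29] = "S"
    prot = make_protein(pid="P1", sequence="".join(seq))
    sites = build_site_windows(prot, [(30, "S", set())])
    proteins = {"P1": prot}
    regions = merge_regions(sites, 7, proteins)
    variants = [MissenseVariant("P1", 3 + i, "A", "V", f"S{i}", "CT1")
                for i in range(n_other)]
    annotations = annotate_psnvs(variants, sites, proteins)
    return count_by_context(annotations, variants, proteins, regions)


class TestContext:
    def test_no_mutations_all_p_one(self):
        results = context_enrichment(toy_context(0))
        enriched = [r for r in results if r.direction == "enriched"]
        assert enriched and all(r.p_value == 1.0 for r in enriched)

    def test_direct_depletion_direction(self):
        results = {r.unit_id: r for r in context_enrichment(toy_context(5))}
        assert results["direct"].direction == "depleted"
        assert results["direct"].observed == 0


class TestDomains:
    def make_inputs(self, domain_rows, variants, n_proteins=6):
        proteins = {}
        sites = []
        for i in range(n_proteins):
            seq = list("A" * 80)
            seq[39] = "S"
            pid = f"P{i}"
            prot = make_protein(pid=pid, sequence="".join(seq))
            proteins[pid] = prot
            sites += build_site_windows(prot, [(40, "S", set())])
        regions = merge_regions(sites, 7, proteins)
        annotations = annotate_psnvs(variants, sites, proteins)
        return (pd.DataFrame(domain_rows), annotations, regions)

    def test_domain_in_two_proteins_filtered(self):
        rows = [{"protein_id": f"P{i}", "domain_name": "RARE", "start": 30,
                 "end": 50, "source": "Pfam"} for i in range(2)]
        rows += [{"protein_id": f"P{i}", "domain_name": "COMMON", "start": 30,
                  "end": 50, "source": "Pfam"} for i in range(4)]
        variants = [MissenseVariant(f"P{i}", 38, "A", "V", f"S{i}", "CT1")
                    for i in range(4)]
        domains, annotations, regions = self.make_inputs(rows, variants)
        results = domain_enrichment(domains, annotations, regions)
        assert [r.unit_id for r in results] == ["COMMON"]

    def test_sparsely_mutated_domain_filtered(self):
        rows = [{"protein_id": f"P{i}", "domain_name": "D", "start": 30,
                 "end": 50, "source": "Pfam"} for i in range(4)]
        variants = [MissenseVariant("P0", 38, "A", "V", "S0", "CT1"),
                    MissenseVariant("P1", 38, "A", "V", "S1", "CT1")]
        domains, annotations, regions = self.make_inputs(rows, variants)
        assert domain_enrichment(domains, annotations, regions) == []

    def test_domain_without_phospho_overlap_skipped(self):
        rows = [{"protein_id": f"P{i}", "domain_name": "FAR", "start": 1,
                 "end": 20, "source": "Pfam"} for i in range(4)]
        variants = [MissenseVariant(f"P{i}", 38, "A", "V", f"S{i}", "CT1")
                    for i in range(3)]
        domains, annotations, regions = self.make_inputs(rows, variants)
        assert domain_enrichment(domains, annotations, regions) == []


class TestPathways:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "sample_id",
                                           "cancer_type", "is_psnv"])

    def test_small_set_excluded(self):
        sets = {"tiny": {"source": "GO", "genes": frozenset({"G1", "G2"})}}
        variants = self.frame([("G1", "S1", "CT1", True),
                               ("G2", "S2", "CT1", True),
                               ("G3", "S3", "CT1", False)])
        table, selected = pathway_enrichment(
            sets, variants, ["G1", "G2", "G3"], ["G1", "G2", "G3"])
        assert table.empty
        assert selected == []

    def test_single_gene_or_sample_sets_discarded(self):
        genes = [f"G{i}" for i in range(10)]
        sets = {"one_gene": {"source": "GO",
                             "genes": frozenset({"G1", "G2", "G3"})},
                "one_sample": {"source": "GO",
                               "genes": frozenset({"G4", "G5", "G6"})}}
        variants = self.frame(
            [("G1", f"S{i}", "CT1", True) for i in range(5)]  # one gene only
            + [("G4", "SX", "CT1", True), ("G5", "SX", "CT1", True)]  # 1 sample
            + [("G7", "S7", "CT1", True), ("G8", "S8", "CT1", True)])
        table, _ = pathway_enrichment(sets, variants, genes, genes)
        assert table.empty


class TestPpiGroups:
    def test_singleton_group(self):
        edges = [frozenset({"A", "B"}), frozenset({"B", "C"})]
        results = ppi_group_enrichment(edges, {"solo": {"A"}})
        within = [r for r in results if r.unit_id == "within:solo"]
        assert within[0].observed == 0
        assert within[0].p_value == 1.0

    def test_planted_clique_highly_significant(self, rng):
        nodes = [f"N{i}" for i in range(60)]
        edges = set()
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if rng.random() < 0.03:
                    edges.add(frozenset({a, b}))
        clique = nodes[:10]
        for i, a in enumerate(clique):
            for b in clique[i + 1:]:
                edges.add(frozenset({a, b}))
        results = ppi_group_enrichment(sorted(edges, key=sorted),
                                       {"clique": clique})
        within = [r for r in results if r.unit_id == "within:clique"][0]
        assert within.observed == 45
        assert within.p_value < 1e-6

    def test_disconnected_groups_between_p_one(self):
        edges = [frozenset({"A", "B"}), frozenset({"C", "D"})]
        results = ppi_group_enrichment(edges, {"g1": {"A", "B"},
                                               "g2": {"C", "D"}})
        between = [r for r in results if r.unit_id.startswith("between")][0]
        assert between.observed == 0
        assert between.p_value == 1.0

    def test_missing_protein_rejected(self):
        edges = [frozenset({"A", "B"})]
        with pytest.raises(errors.FormatError, match="ZZ"):
            ppi_group_enrichment(edges, {"bad": {"A", "ZZ"}})
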
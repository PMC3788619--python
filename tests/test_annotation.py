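"""Phosphosite windows, region merging, pSNV classification and tallies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosphorewire import errors
from phosphorewire.annotation import (MissenseVariant, annotate_psnvs,
                                      build_site_windows, classify_distance,
                                      count_by_context, merge_regions)

from conftest import make_protein


class TestSiteWindows:
    def test_interior_site_has_no_padding(self):
        prot = make_protein(sequence="ABCDEFGSIJKLMNOPQRST".replace("B", "G")
                            .replace("O", "L").replace("J", "V"))
        # position 8 of a 20-mer: window = residues 1..15
        sites = build_site_windows(prot, [(8, prot.sequence[7], set())])
        assert sites[0].window == prot.sequence[:15]

    @pytest.mark.parametrize("position,expect_lead,expect_trail", [
        (3, 5, 0),   # 7 - (3 - 1) leading pads, by direct index arithmetic
        (1, 7, 0),
        (30, 0, 7),  # last residue: 7 trailing pads
    ])
    def test_terminal_padding(self, position, expect_lead, expect_trail):
        seq = list("MKTAYIAKQRQISFVKSHFSRQLEERLGLI")
        seq[position - 1] = "S"
        prot = make_protein(sequence="".join(seq))
        site = build_site_windows(prot, [(position, "S", set())])[0]
        assert len(site.window) == 15
        assert site.window[7] == "S"
        lead = len(site.window) - len(site.window.lstrip("_"))
        trail = len(site.window) - len(site.window.rstrip("_"))
        assert (lead, trail) == (expect_lead, expect_trail)

    def test_non_sty_center_rejected(self):
        prot = make_protein(sequence="MKTAYIAKQRQISFV")
        with pytest.raises(errors.FormatError):
            build_site_windows(prot, [(8, "K", set())])
        with pytest.raises(errors.FormatError, match="does not match"):
            build_site_windows(prot, [(8, "S", set())])  # sequence has K


class TestMergeRegions:
    def make_sites(self, positions, length=100):
        seq = list("A" * length)
        for p in positions:
            seq[p - 1] = "S"
        prot = make_protein(pid="P1", sequence="".join(seq))
        return prot, build_site_windows(prot, [(p, "S", set())
                                               for p in positions])

    def test_overlapping_windows_merge(self):
        prot, sites = self.make_sites([10, 20])
        regions = merge_regions(sites, 7, {"P1": prot})
        assert [(r.start, r.end) for r in regions] == [(3, 27)]
        assert len(regions[0].member_sites) == 2

    def test_single_site_region(self):
        prot, sites = self.make_sites([50])
        regions = merge_regions(sites, 7, {"P1": prot})
        assert [(r.start, r.end) for r in regions] == [(43, 57)]

    def test_distant_sites_stay_separate(self):
        prot, sites = self.make_sites([10, 40])
        regions = merge_regions(sites, 7, {"P1": prot})
        assert [(r.start, r.end) for r in regions] == [(3, 17), (33, 47)]

    @given(positions=st.lists(st.integers(8, 93), min_size=1, max_size=8,
                              unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_merge_is_idempotent_and_covers_all_windows(self, positions):
        prot, sites = self.make_sites(sorted(positions))
        regions = merge_regions(sites, 7, {"P1": prot})
        # disjoint and sorted
        for a, b in zip(regions, regions[1:]):
            assert a.end + 1 < b.start
        covered = set()
        for r in regions:
            covered.update(range(r.start, r.end + 1))
        expected = set()
        for p in positions:
            expected.update(range(max(1, p - 7), min(100, p + 7) + 1))
        assert covered == expected
        again = merge_regions([s for r in regions for s in r.member_sites],
                              7, {"P1": prot})
        assert [(r.start, r.end) for r in again] == \
            [(r.start, r.end) for r in regions]


class TestClassification:
    def test_direct_proximal_distal_rules(self):
        assert classify_distance(0, "S", "A") == "direct"
        assert classify_distance(0, "S", "T") == "proximal"
        assert classify_distance(0, "T", "S") == "proximal"
        assert classify_distance(0, "Y", "F") == "direct"
        for d in (1, 2, -1, -2):
            assert classify_distance(d, "A", "V") == "proximal"
        for d in (3, 7, -3, -7):
            assert classify_distance(d, "A", "V") == "distal"
        assert classify_distance(8, "A", "V") is None

    def test_classification_total_over_window(self):
        """Every |offset| in 0..7 × substitution maps to exactly one class."""
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for d in range(-7, 8):
            for ref in aas:
                for alt in aas:
                    if ref == alt:
                        continue
                    cls = classify_distance(d, ref, alt)
                    if d == 0:
                        expected = ("proximal" if {ref, alt} == {"S", "T"}
                                    else "direct")
                    elif abs(d) <= 2:
                        expected = "proximal"
                    else:
                        expected = "distal"
                    assert cls == expected


class TestAnnotate:
    def setup_method(self):
        seq = list("A" * 40)
        seq[19] = "S"
        self.prot = make_protein(pid="P1", sequence="".join(seq))
        self.sites = build_site_windows(self.prot, [(20, "S", {"KIN1"})])
        self.proteins = {"P1": self.prot}

    def var(self, pos, ref, alt):
        return MissenseVariant("P1", pos, ref, alt, "S1", "CT1")

    def test_central_substitution_is_direct(self):
        result = annotate_psnvs([self.var(20, "S", "A")], self.sites,
                                self.proteins)
        assert [a.psnv_class for a in result] == ["direct"]
        assert result.annotations[0].distance == 0

    def test_central_s_to_t_is_proximal_not_direct(self):
        result = annotate_psnvs([self.var(20, "S", "T")], self.sites,
                                self.proteins)
        assert [a.psnv_class for a in result] == ["proximal"]

    def test_window_boundary(self):
        inside = annotate_psnvs([self.var(25, "A", "V")], self.sites,
                                self.proteins)
        outside = annotate_psnvs([self.var(28, "A", "V")], self.sites,
                                 self.proteins)
        assert [a.psnv_class for a in inside] == ["distal"]
        assert len(outside) == 0

    def test_reference_mismatch_excluded_and_reported(self):
        result = annotate_psnvs([self.var(20, "T", "A")], self.sites,
                                self.proteins)
        assert len(result) == 0
        assert len(result.ref_mismatches) == 1


class TestContextCounts:
    def test_hand_tally_on_toy_proteome(self):
        # P1: 30 aa, site at 15, fully structured
        s1 = list("A" * 30); s1[14] = "S"
        p1 = make_protein(pid="P1", sequence="".join(s1))
        # P2: 30 aa, site at 10, fully disordered
        s2 = list("A" * 30); s2[9] = "T"
        p2 = make_protein(pid="P2", sequence="".join(s2),
                          disorder=np.ones(30, dtype=bool))
        # P3: 20 aa, no sites, structured
        p3 = make_protein(pid="P3", sequence="A" * 20)
        proteins = {"P1": p1, "P2": p2, "P3": p3}
        sites = build_site_windows(p1, [(15, "S", set())]) + \
            build_site_windows(p2, [(10, "T", set())])
        regions = merge_regions(sites, 7, proteins)
        variants = [
            MissenseVariant("P1", 15, "S", "A", "S1", "CT1"),  # direct, struct
            MissenseVariant("P1", 12, "A", "V", "S1", "CT1"),  # pSNV, struct
            MissenseVariant("P1", 29, "A", "V", "S2", "CT1"),  # other, struct
            MissenseVariant("P2", 11, "A", "V", "S2", "CT1"),  # pSNV, disord
            MissenseVariant("P2", 25, "A", "V", "S3", "CT1"),  # other, disord
            MissenseVariant("P3", 5, "A", "V", "S3", "CT1"),   # other, struct
        ]
        annotations = annotate_psnvs(variants, sites, proteins)
        counts = count_by_context(annotations, variants, proteins, regions)
        # exposures: P1 region [8,22] = 15 structured; P2 region [3,17] = 15
        assert counts.exposure[("phospho", "structured")] == 15
        assert counts.exposure[("phospho", "disordered")] == 15
        assert counts.exposure[("other", "structured")] == 15 + 20
        assert counts.exposure[("other", "disordered")] == 15
        assert counts.total_residues == 80
        assert counts.mutations[("phospho", "structured")] == 2
        assert counts.mutations[("phospho", "disordered")] == 1
        assert counts.mutations[("other", "structured")] == 2
        assert counts.mutations[("other", "disordered")] == 1
        assert counts.n_direct == 1
        assert counts.n_central == 2

    def test_empty_variants_zero_counts(self):
        s1 = list("A" * 30); s1[14] = "S"
        p1 = make_protein(pid="P1", sequence="".join(s1))
        sites = build_site_windows(p1, [(15, "S", set())])
        regions = merge_regions(sites, 7, {"P1": p1})
        annotations = annotate_psnvs([], sites, {"P1": p1})
        counts = count_by_context(annotations, [], {"P1": p1}, regions)
        assert counts.total_variants == 0
        assert counts.total_residues == 30

    def test_fully_structured_protein_has_empty_disordered_cells(self):
        s1 = list("A" * 30); s1[14] = "S"
        p1 = make_protein(pid="P1", sequence="".join(s1))
        sites = build_site_windows(p1, [(15, "S", set())])
        regions = merge_regions(sites, 7, {"P1": p1})
        variants = [MissenseVariant("P1", 13, "A", "V", "S1", "CT1"),
                    MissenseVariant("P1", 29, "A", "V", "S1", "CT1")]
        annotations = annotate_psnvs(variants, sites, {"P1": p1})
        counts = count_by_context(annotations, variants, {"P1": p1}, regions)
        assert counts.mutations[("phospho", "disordered")] == 0
        assert counts.mutations[("other", "disordered")] == 0
        assert counts.exposure[("phospho", "disordered")] == 0

    def test_overlapping_windows_count_variant_once(self):
        seq = list("A" * 40); seq[19] = "S"; seq[24] = "T"
        p1 = make_protein(pid="P1", sequence="".join(seq))
        sites = build_site_windows(p1, [(20, "S", set()), (25, "T", set())])
        regions = merge_regions(sites, 7, {"P1": p1})
        v = MissenseVariant("P1", 22, "A", "V", "S1", "CT1")
        annotations = annotate_psnvs([v], sites, {"P1": p1})
        assert len(annotations) == 2  # one per overlapping window
        counts = count_by_context(annotations, [v], {"P1": p1}, regions)
        assert counts.mutations[("phospho", "structured")] == 1
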
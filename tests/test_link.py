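"""Link discovery: normalization policies, exact-key and positional rules,
region-to-gene mapping, and the brute-force oracle equivalences."""

import random

import pytest
from hypothesis import given, strategies as st
from rdflib import Literal, URIRef

from omicsfed.link import (
    LinkRule,
    discover_exact_links,
    discover_positional_links,
    link_stats,
    links_to_quads,
    map_region_to_genes,
    normalize_key,
)
from omicsfed.quads import Quad
from omicsfed.records import Locus

GA = URIRef("http://ex/gA")
GB = URIRef("http://ex/gB")
PA = URIRef("http://ex/keyA")
PB = URIRef("http://ex/keyB")
CSE_A = (URIRef("http://ex/a#chrom"), URIRef("http://ex/a#start"), URIRef("http://ex/a#end"))
CSE_B = (URIRef("http://ex/b#chrom"), URIRef("http://ex/b#start"), URIRef("http://ex/b#end"))


def key_quads(graph, pred, keys, base):
    return [
        Quad(URIRef(f"{base}/row/{i}"), pred, URIRef(f"{base}/key/{k}"), graph)
        for i, k in enumerate(keys)
    ]


def seg_quads(graph, preds, segments, base):
    chrom_p, start_p, end_p = preds
    quads = []
    for i, (c, s, e) in enumerate(segments):
        subj = URIRef(f"{base}/row/{i}")
        quads += [
            Quad(subj, chrom_p, Literal(c), graph),
            Quad(subj, start_p, Literal(s), graph),
            Quad(subj, end_p, Literal(e), graph),
        ]
    return quads


class TestNormalizeKey:
    def test_tcga_barcode_truncates_to_patient(self):
        assert normalize_key("TCGA-13-0920-01A", "tcga_patient_barcode") == "TCGA-13-0920"

    def test_case_fold(self):
        assert normalize_key("Myh7", "case_fold") == "MYH7"

    def test_verbatim_is_identity(self):
        assert normalize_key("AnYtHiNg-01A", "verbatim") == "AnYtHiNg-01A"

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            normalize_key("x", "soundex")

    @given(st.text(max_size=30), st.sampled_from(
        ["verbatim", "case_fold", "tcga_patient_barcode"]))
    def test_idempotent(self, raw, policy):
        once = normalize_key(raw, policy)
        assert normalize_key(once, policy) == once


class TestExactKeyLinks:
    def _rule(self, normalizer="verbatim"):
        return LinkRule("exact_key", left=(GA, PA), right=(GB, PB),
                        normalizer=normalizer, name="t")

    def test_disjoint_key_sets_no_links(self):
        a = key_quads(GA, PA, ["K1", "K2"], "http://ex/a")
        b = key_quads(GB, PB, ["K3"], "http://ex/b")
        assert discover_exact_links(a, b, self._rule()) == set()

    def test_planted_overlap_recovered_exactly(self):
        shared = [f"S{i}" for i in range(17)]
        a_keys = shared + [f"A{i}" for i in range(33)]  # 50 resources
        b_keys = shared + [f"B{i}" for i in range(43)]  # 60 resources
        a = key_quads(GA, PA, a_keys, "http://ex/a")
        b = key_quads(GB, PB, b_keys, "http://ex/b")
        links = discover_exact_links(a, b, self._rule())
        assert len(links) == 17
        # equals the exhaustive pairwise comparison
        brute = {
            (qa.object, qb.object)
            for qa in a for qb in b
            if str(qa.object).rsplit("/", 1)[-1] == str(qb.object).rsplit("/", 1)[-1]
        }
        assert {(l.subject, l.object) for l in links} == brute

    def test_sample_identity_linking_via_barcode_policy(self):
        a = key_quads(GA, PA, ["TCGA-13-0920", "TCGA-24-1850", "TCGA-09-0366"],
                      "http://ex/a")
        b = key_quads(GB, PB, ["TCGA-13-0920-01A", "TCGA-24-1850-01B",
                               "TCGA-25-1313-01A"], "http://ex/b")
        links = discover_exact_links(a, b, self._rule("tcga_patient_barcode"))
        assert len(links) == 2

    def test_missing_key_predicate_warns_and_yields_nothing(self):
        a = key_quads(GA, URIRef("http://ex/other"), ["K"], "http://ex/a")
        b = key_quads(GB, PB, ["K"], "http://ex/b")
        with pytest.warns(UserWarning, match="absent"):
            assert discover_exact_links(a, b, self._rule()) == set()

    def test_symmetry_under_rule_swap(self):
        a = key_quads(GA, PA, ["K1", "K2", "X"], "http://ex/a")
        b = key_quads(GB, PB, ["K2", "K1", "Y"], "http://ex/b")
        fwd = discover_exact_links(a, b, self._rule())
        swapped = LinkRule("exact_key", left=(GB, PB), right=(GA, PA), name="t")
        rev = discover_exact_links(b, a, swapped)
        assert {(l.subject, l.object) for l in fwd} == {
            (l.object, l.subject) for l in rev
        }


class TestPositionalLinks:
    def _rule(self, mode="exact", tol=0):
        return LinkRule("positional", left=(GA,), right=(GB,),
                        mode=mode, tolerance_bp=tol, name="pos")

    def test_identical_segment_lists_fully_linked(self):
        segs = [("14", 100, 200), ("2", 500, 900), ("X", 10, 20)]
        a = seg_quads(GA, CSE_A, segs, "http://ex/a")
        b = seg_quads(GB, CSE_B, segs, "http://ex/b")
        links = discover_positional_links(a, b, self._rule(), CSE_A, CSE_B)
        assert len(links) == 3

    def test_recurrent_cnv_locus_links_across_sources(self):
        # the chr14 MYH6/MYH7 loss segment present in both stores
        a = seg_quads(GA, CSE_A, [("14", 23857092, 23886486), ("6", 149661, 384546)],
                      "http://ex/a")
        b = seg_quads(GB, CSE_B, [("14", 23857092, 23886486), ("9", 1, 10)],
                      "http://ex/b")
        links = discover_positional_links(a, b, self._rule(), CSE_A, CSE_B)
        assert len(links) == 1
        (lk,) = links
        assert str(lk.subject).endswith("/row/0") and str(lk.object).endswith("/row/0")

    @pytest.mark.parametrize("mode,tol", [("overlap", 0), ("overlap", 500), ("exact", 0)])
    def test_equals_quadratic_oracle_on_random_segments(self, mode, tol):
        rng = random.Random(99)
        def rand_segs(n):
            out = []
            for _ in range(n):
                s = rng.randrange(1, 5000)
                out.append((str(rng.randrange(1, 4)), s, s + rng.randrange(1, 800)))
            return out
        sa, sb = rand_segs(200), rand_segs(200)
        a = seg_quads(GA, CSE_A, sa, "http://ex/a")
        b = seg_quads(GB, CSE_B, sb, "http://ex/b")
        links = discover_positional_links(a, b, self._rule(mode, tol), CSE_A, CSE_B)
        got = {(str(l.subject).rsplit("/", 1)[-1], str(l.object).rsplit("/", 1)[-1])
               for l in links}
        brute = set()
        for i, (ca, s1, e1) in enumerate(sa):
            for j, (cb, s2, e2) in enumerate(sb):
                if ca != cb:
                    continue
                if mode == "exact":
                    hit = (s1, e1) == (s2, e2)
                else:
                    hit = s1 - tol <= e2 + tol and s2 - tol <= e1 + tol
                if hit:
                    brute.add((str(i), str(j)))
        assert got == brute

    def test_exact_mode_forbids_tolerance(self):
        with pytest.raises(ValueError):
            LinkRule("positional", left=(GA,), right=(GB,), mode="exact",
                     tolerance_bp=5)


class TestRegionToGenes:
    ANNOT = [
        ("INSIDE", Locus("14", 120, 150)),
        ("SPANNING", Locus("14", 90, 110)),
        ("ELSEWHERE", Locus("14", 500, 600)),
        ("OTHERCHROM", Locus("2", 120, 150)),
    ]

    def test_overlap_semantics(self):
        got = map_region_to_genes(Locus("14", 100, 200), self.ANNOT)
        assert got == {"INSIDE", "SPANNING"}

    def test_equals_bruteforce_on_random_annotation(self):
        rng = random.Random(5)
        annot = []
        for i in range(500):
            s = rng.randrange(1, 10_000)
            annot.append((f"g{i}", Locus(str(rng.randrange(1, 5)), s, s + rng.randrange(1, 300))))
        query = Locus("2", 3_000, 6_000)
        got = map_region_to_genes(query, annot)
        brute = {
            name for name, loc in annot
            if loc.chrom == "2" and loc.start <= 6_000 and 3_000 <= loc.end
        }
        assert got == brute


class TestLinkStats:
    def _link(self, i, j, rule):
        from omicsfed.link import Link
        return Link(URIRef(f"http://ex/a/{i}"), URIRef(f"http://ex/b/{j}"), rule)

    def test_empty(self):
        assert link_stats({}) == {}

    def test_disjoint_rules_sum_per_pair(self):
        rule = LinkRule("exact_key", left=(GA, PA), right=(GB, PB))
        sets = {
            (("cosmic", "tcga"), "r1"): {self._link(i, i, rule) for i in range(3)},
            (("cosmic", "tcga"), "r2"): {self._link(i + 10, i, rule) for i in range(4)},
        }
        assert link_stats(sets) == {("cosmic", "tcga"): 7}

    def test_duplicate_link_from_two_rules_counted_once(self):
        rule = LinkRule("exact_key", left=(GA, PA), right=(GB, PB))
        dup = self._link(0, 0, rule)
        sets = {
            (("cosmic", "tcga"), "r1"): {dup},
            (("cosmic", "tcga"), "r2"): {dup, self._link(1, 1, rule)},
        }
        assert link_stats(sets) == {("cosmic", "tcga"): 2}

    def test_materialized_links_deduplicated_and_sorted(self):
        rule = LinkRule("exact_key", left=(GA, PA), right=(GB, PB))
        quads = links_to_quads([self._link(1, 1, rule), self._link(0, 0, rule),
                                self._link(1, 1, rule)])
        assert len(quads) == 2
        assert quads == sorted(quads)
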
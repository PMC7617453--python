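"""Peptide assignment, parsimony grouping, iBAQ, enrichment calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import xenotrace as xt
from xenotrace.deconv import _greedy_parsimony


def _evidence(pairs):
    return pd.DataFrame(
        {"peptide": [p for p, _ in pairs], "intensity": [i for _, i in pairs],
         "sample": "S1"}
    )


class TestAssign:
    def test_labels_follow_library_classes(self, toy_proteomes, toy_library):
        human, mouse = toy_proteomes
        ev = _evidence([("WWYYK", 10.0), ("DDCCK", 20.0), ("SSSSK", 5.0)])
        a = xt.assign_peptides(ev, toy_library)
        got = dict(zip(a.table["peptide"], a.table["label"]))
        assert got["WWYYK"] == "unique_to_human"  # Hs-only peptide
        assert got["DDCCK"] == "unique_to_mouse"  # Ms-only peptide
        assert got["SSSSK"] == "shared"
        assert a.unmatched_fraction == 0.0

    def test_shared_peptide_lists_parents_from_both_species(self, toy_library):
        a = xt.assign_peptides(_evidence([("SSSSK", 5.0)]), toy_library)
        tags = {t for t, _ in a.table["parents"].iloc[0]}
        assert tags == {"human", "mouse"}

    def test_all_unmatched_is_warning_not_error(self, toy_library):
        with pytest.warns(UserWarning, match="no observed peptide matched"):
            a = xt.assign_peptides(_evidence([("WWWWWWWK", 1.0)]), toy_library)
        assert a.unmatched_fraction == 1.0

    def test_empty_evidence_rejected(self, toy_library):
        with pytest.raises(ValueError):
            xt.assign_peptides(_evidence([]), toy_library)


class TestClassify:
    def test_two_host_unique_peptides_give_host_exclusive(self, toy_library):
        ev = _evidence([("DDCCK", 1.0), ("EEEEER", 1.0)])  # both Ms-only
        calls = xt.classify_proteins(
            xt.assign_peptides(ev, toy_library), min_peptides=2, host_tag="mouse"
        )
        assert [c.species_class for c in calls] == ["host_exclusive"]
        assert calls[0].protein_id == "Ms"

    def test_host_unique_plus_shared_is_conserved(self, toy_library):
        # M1's unique peptide plus a peptide shared with H1
        ev = _evidence([("AEPTADEK", 1.0), ("MAGIK", 1.0), ("GGR", 1.0)])
        calls = xt.classify_proteins(
            xt.assign_peptides(ev, toy_library), min_peptides=2, host_tag="mouse"
        )
        cls = {c.protein_id: c.species_class for c in calls}
        assert cls["M1"] == "conserved"

    def test_relaxed_mode_tolerates_shared_peptides(self, toy_library):
        ev = _evidence([("AEPTADEK", 1.0), ("MAGIK", 1.0), ("GGR", 1.0)])
        calls = xt.classify_proteins(
            xt.assign_peptides(ev, toy_library), min_peptides=2, host_tag="mouse",
            mode="relaxed",
        )
        cls = {c.protein_id: c.species_class for c in calls}
        assert cls["M1"] == "host_exclusive"

    def test_min_peptides_filter_and_validation(self, toy_library):
        ev = _evidence([("DDCCK", 1.0)])
        a = xt.assign_peptides(ev, toy_library)
        assert xt.classify_proteins(a, min_peptides=2) == []
        assert len(xt.classify_proteins(a, min_peptides=1)) == 1
        with pytest.raises(ValueError):
            xt.classify_proteins(a, min_peptides=0)

    def test_nested_peptide_sets_collapse_to_one_group(self):
        # q's observed peptides are a subset of p's -> one group led by p
        a = xt.Proteome("a", [("p", "AAAWDKCCCWDKDDDWDK"), ("q", "AAAWDKCCCWDK")])
        b = xt.Proteome("b", [("z", "WWWWWK")])
        lib = xt.build_libraries(a, b, length_window=(1, 50), mass_window=(0, 1e6))
        ev = _evidence([("AAAWDK", 1.0), ("CCCWDK", 1.0), ("DDDWDK", 1.0)])
        calls = xt.classify_proteins(xt.assign_peptides(ev, lib), min_peptides=2)
        assert len(calls) == 1
        assert calls[0].protein_id == "p"
        assert "a:q" in calls[0].group_members


def _brute_force_min_cover(protein_peptides):
    """Smallest number of proteins covering all observed peptides."""
    universe = set().union(*protein_peptides.values())
    prots = list(protein_peptides)
    for r in range(1, len(prots) + 1):
        for combo in itertools.combinations(prots, r):
            if set().union(*(protein_peptides[p] for p in combo)) == universe:
                return r
    raise AssertionError("unreachable")


class TestParsimonyOracle:
    def test_greedy_equals_exhaustive_min_cover_on_small_instances(self):
        """Protein-inference-like instances: mostly disjoint peptide sets plus
        nested/duplicated proteins, <= 8 proteins each."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            n_prot = rng.integers(2, 9)
            peptides = [f"pep{i}" for i in range(rng.integers(3, 10))]
            protein_peptides = {}
            for j in range(n_prot):
                size = rng.integers(1, len(peptides) + 1)
                chosen = rng.choice(peptides, size=size, replace=False)
                protein_peptides[("a", f"P{j}")] = set(map(str, chosen))
            # add a subset protein (a common inference situation)
            base = protein_peptides[("a", "P0")]
            if len(base) > 1:
                protein_peptides[("a", "Psub")] = set(list(base)[:-1])
            groups = _greedy_parsimony(protein_peptides)
            covered = set().union(*(protein_peptides[lead] for lead, _ in groups))
            assert covered == set().union(*protein_peptides.values())
            assert len(groups) == _brute_force_min_cover(protein_peptides)


class TestQuantify:
    def _calls(self, lib, ev, **kw):
        a = xt.assign_peptides(ev, lib)
        calls = xt.classify_proteins(a, min_peptides=kw.pop("min_peptides", 1), **kw)
        xt.quantify_ibaq(calls, a)
        return calls

    def test_ibaq_is_intensity_sum_over_expected(self):
        a = xt.Proteome("a", [("p", "AAAWDKCCCWDKDDDWDKEEEWDK")])  # 4 observable
        b = xt.Proteome("b", [("z", "WWWWWK")])
        lib = xt.build_libraries(a, b, length_window=(1, 50), mass_window=(0, 1e6))
        ev = _evidence([("AAAWDK", 100.0), ("CCCWDK", 100.0), ("DDDWDK", 100.0), ("EEEWDK", 100.0)])
        calls = self._calls(lib, ev)
        p = next(c for c in calls if c.protein_id == "p")
        assert p.n_expected_peptides == 4
        assert p.ibaq == pytest.approx(100.0)
        assert p.obs_exp_ratio == pytest.approx(1.0)

    def test_single_quantified_protein_gets_full_ppm(self):
        a = xt.Proteome("a", [("p", "AAAWDKCCCWDK")])
        b = xt.Proteome("b", [("z", "WWWWWK")])
        lib = xt.build_libraries(a, b, length_window=(1, 50), mass_window=(0, 1e6))
        ev = _evidence([("AAAWDK", 10.0), ("CCCWDK", 30.0)])
        calls = self._calls(lib, ev)
        p = next(c for c in calls if c.protein_id == "p")
        assert p.ibaq_ppm == pytest.approx(1e6)
        assert p.ibaq_score == pytest.approx(6.0)

    def test_ppm_proportionality_1_1_2(self):
        a = xt.Proteome("a", [("p1", "AAAWDK"), ("p2", "CCCWDK"), ("p3", "DDDWDK")])
        b = xt.Proteome("b", [("z", "WWWWWK")])
        lib = xt.build_libraries(a, b, length_window=(1, 50), mass_window=(0, 1e6))
        ev = _evidence([("AAAWDK", 1.0), ("CCCWDK", 1.0), ("DDDWDK", 2.0)])
        calls = self._calls(lib, ev)
        ppm = {c.protein_id: c.ibaq_ppm for c in calls}
        assert ppm["p1"] == pytest.approx(250_000.0)
        assert ppm["p2"] == pytest.approx(250_000.0)
        assert ppm["p3"] == pytest.approx(500_000.0)

    def test_conservation_and_scale_invariance(self, toy_library):
        ev = _evidence(
            [("MAGIK", 40.0), ("GGR", 10.0), ("AEPTIDEK", 25.0), ("SSSSK", 7.0),
             ("FFFFR", 3.0), ("WWYYK", 90.0), ("NNNNNR", 12.0), ("DDCCK", 6.0),
             ("EEEEER", 4.0)]
        )

        def run(scale):
            e = ev.copy()
            e["intensity"] *= scale
            a = xt.assign_peptides(e, toy_library)
            calls = xt.classify_proteins(a, min_peptides=1, host_tag="mouse")
            xt.quantify_ibaq(calls, a)
            xt.call_enriched(calls)
            return calls

        base = run(1.0)
        total = sum(c.ibaq_ppm for c in base if c.quantifiable)
        assert total == pytest.approx(1e6, rel=1e-9)
        for c in (0.001, 3.7, 1e6):
            scaled = run(c)
            for x, y in zip(base, scaled):
                assert x.protein_id == y.protein_id
                assert x.ibaq_ppm == pytest.approx(y.ibaq_ppm, rel=1e-9)
                assert x.obs_exp_ratio == y.obs_exp_ratio
                assert x.enriched == y.enriched


class TestEnrichment:
    def _toy_calls(self, scores, ratios, cls="conserved"):
        calls = []
        for i, (s, r) in enumerate(zip(scores, ratios)):
            c = xt.ProteinCall(
                protein_id=f"p{i}", species_tag="a", species_class=cls,
                group_members=(), n_observed_peptides=1, n_expected_peptides=1,
                obs_exp_ratio=r, ibaq_score=s, ibaq_ppm=10 ** s, ibaq=1.0,
            )
            calls.append(c)
        return calls

    def test_single_member_class_is_undefined(self):
        calls = self._toy_calls([5.0], [0.5])
        thr = xt.call_enriched(calls)
        assert calls[0].enriched is None
        assert thr["conserved"]["defined"] is False

    def test_dominating_protein_is_the_only_enriched(self):
        calls = self._toy_calls([2.0, 3.0, 6.0], [0.2, 0.3, 0.9])
        xt.call_enriched(calls)
        assert [c.enriched for c in calls] == [False, False, True]

    def test_strictly_above_both_means_required(self):
        # p1 above mean score but below mean ratio -> not enriched
        calls = self._toy_calls([6.0, 2.0, 2.0], [0.1, 0.5, 0.5])
        xt.call_enriched(calls)
        assert calls[0].enriched is False

    def test_sum_rule_alternative(self):
        calls = self._toy_calls([6.0, 2.0, 2.0], [0.1, 0.5, 0.5])
        xt.call_enriched(calls, rule="sum")
        assert calls[0].enriched is True  # 6.1 > mean sum (3.7)


class TestCompositionAndMarkers:
    def test_all_one_category(self):
        calls = TestEnrichment()._toy_calls([2.0, 6.0, 7.0], [0.1, 0.8, 0.9])
        xt.call_enriched(calls)
        comp = xt.category_composition(calls, {"p1": "translation", "p2": "translation"})
        assert comp["translation"] == pytest.approx(100.0)

    def test_five_of_twelve(self):
        calls = TestEnrichment()._toy_calls(
            list(np.linspace(2, 8, 13)), list(np.linspace(0.1, 0.9, 13))
        )
        xt.call_enriched(calls)
        enriched = [c for c in calls if c.enriched]
        assert len(enriched) == 6  # 13 members, strictly-above-mean on both
        cat = {c.protein_id: ("translation" if i < 5 else "other")
               for i, c in enumerate(enriched)}
        comp = xt.category_composition(calls, cat)
        assert comp["translation"] == pytest.approx(5 / 6 * 100)

    def test_empty_enriched_set(self):
        calls = TestEnrichment()._toy_calls([2.0, 2.0], [0.5, 0.5])
        xt.call_enriched(calls)
        assert xt.category_composition(calls, {}).empty

    def test_marker_overlap(self):
        detected = [f"P{i}" for i in range(100)]
        markers = [f"p{i}" for i in range(90, 100)] + ["QQQ1", "QQQ2"]
        n, missing = xt.marker_overlap(detected, markers)
        assert n == 10 and missing == ["QQQ1", "QQQ2"]
        n2, missing2 = xt.marker_overlap(detected, ["ZZZ"])
        assert n2 == 0 and missing2 == ["ZZZ"]
        assert xt.marker_overlap(detected, detected[:5]) == (5, [])
        with pytest.raises(ValueError):
            xt.marker_overlap(detected, [])
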
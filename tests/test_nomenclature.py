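import itertools

import pytest

from phylonom import family_catalog as fc
from phylonom import nomenclature as nm
from phylonom import phylogeny as ph


def make_catalog(rows, reference="At", outgroup=None):
    """rows: list of (id, species) or (id, species, extra-kwargs)."""
    species = sorted({r[1] for r in rows})
    registry = [fc.SpeciesRecord(code=s, name=s,
                                 is_reference_anchor=(s == reference),
                                 is_outgroup=(s == outgroup))
                for s in species]
    records = []
    for row in rows:
        rid, sp = row[0], row[1]
        kwargs = row[2] if len(row) > 2 else {}
        records.append(fc.ProteinRecord(id=rid, species_code=sp,
                                        length_aa=0, **kwargs))
    return fc.Catalog(registry=registry, records=records)


def with_supports(newick, default=100.0):
    t = ph.read_newick(newick)
    for node in t.internal_edges():
        if node.support is None:
            node.support = default
    return t


class TestRootWithOutgroup:
    def test_monophyletic_outgroup_separated(self):
        t = with_supports("((O1:1,(O2:1,O3:1)95:1)99:1,(A:1,B:1)90:1,C:1);")
        rooted = nm.root_with_outgroup(t, {"O1", "O2", "O3"})
        assert rooted.rooted
        sides = [frozenset(s) for s in
                 (set(ph.PhyloTree(c, rooted=True).leaf_names())
                  if c.children else {c.name}
                  for c in rooted.root.children)]
        assert frozenset({"O1", "O2", "O3"}) in sides

    def test_empty_outgroup_rejected(self):
        t = with_supports("((A:1,B:1)90:1,C:1,D:1);")
        with pytest.raises(ValueError):
            nm.root_with_outgroup(t, set())

    def test_missing_outgroup_id_rejected(self):
        t = with_supports("((A:1,B:1)90:1,C:1,D:1);")
        with pytest.raises(ValueError):
            nm.root_with_outgroup(t, {"Z"})

    def test_non_monophyletic_uses_max_separation_edge(self):
        # outgroup {O1, O2} cannot be separated; best edge isolates O1+O2+A
        # side scoring: exhaustive scan oracle
        t = with_supports("((O1:1,A:1)80:1,(O2:1,B:1)85:1,C:1);")
        rooted = nm.root_with_outgroup(t, {"O1", "O2"})
        sets = rooted.clade_leafsets()
        leaves = set(rooted.leaf_names())
        # oracle: best achievable score over all edges/orientations
        unrooted = t.copy()
        usets = unrooted.clade_leafsets()
        best = None
        for node in unrooted.edges():
            side = set(usets[node])
            for cand in (side, leaves - side):
                score = len(cand & {"O1", "O2"}) - len(cand - {"O1", "O2"})
                best = score if best is None else max(best, score)
        root_sides = [sets[c] for c in rooted.root.children]
        achieved = max(
            len(set(s) & {"O1", "O2"}) - len(set(s) - {"O1", "O2"})
            for s in root_sides)
        assert achieved == best


class TestSupportedClades:
    def test_all_strong_returns_every_internal_clade(self):
        t = with_supports("(((A:1,B:1)100:1,C:1)100:1,(D:1,E:1)100:1);")
        clades = nm.supported_clades(t, 70)
        assert frozenset("AB") in clades and frozenset("ABC") in clades
        assert frozenset("DE") in clades

    def test_threshold_is_strict(self):
        t = with_supports("(((A:1,B:1)100:1,C:1)100:1,(D:1,E:1)100:1;"
                          .replace(";", ");"))
        assert nm.supported_clades(t, 100) == []

    def test_sorted_by_size_descending(self):
        t = with_supports("(((A:1,B:1)90:1,C:1)95:1,(D:1,E:1)85:1);")
        clades = nm.supported_clades(t, 70)
        assert [len(c) for c in clades] == sorted(
            [len(c) for c in clades], reverse=True)

    def test_mixed_supports_match_manual_enumeration(self):
        t = with_supports("(((A:1,B:1)60:1,C:1)95:1,((D:1,E:1)75:1,F:1)40:1);")
        clades = nm.supported_clades(t, 70)
        assert set(clades) == {frozenset("ABC"), frozenset("DE")}

    def test_missing_support_rejected(self):
        t = ph.read_newick("((A:1,B:1):1,C:1,D:1);")
        with pytest.raises(ValueError):
            nm.supported_clades(t, 70)


class TestExcludeDistantRelatives:
    def test_all_clustered_nothing_excluded(self):
        t = with_supports("((A1:1,(B1:1,C1:1)90:1)100:1,Out:3);")
        cat = make_catalog([("A1", "At"), ("B1", "Pt"), ("C1", "Os")])
        retained, excluded = nm.exclude_distant_relatives(t, cat)
        assert sorted(retained) == ["A1", "B1", "C1"] and excluded == {}

    def test_catalog_flag_excludes(self):
        t = with_supports("((A1:1,(B1:1,C1:1)90:1)100:1,Out:3);")
        cat = make_catalog([("A1", "At"), ("B1", "Pt"),
                            ("C1", "Os", {"not_family_flag": True})])
        retained, excluded = nm.exclude_distant_relatives(t, cat)
        assert excluded == {"C1": nm.NOT_FAMILY_FLAG}
        assert "C1" not in retained

    def test_unclustered_leaf_reported_for_like_naming(self):
        t = with_supports("((A1:1,B1:1)90:1,(C1:1,D1:9)20:1,Out:3);", None)
        for node in t.internal_edges():
            if node.support is None:
                node.support = 20.0
        cat = make_catalog([("A1", "At"), ("B1", "Pt"), ("C1", "Os"),
                            ("D1", "Os")])
        retained, excluded = nm.exclude_distant_relatives(t, cat)
        assert excluded.get("C1") == nm.NO_SUPPORTED_CLUSTER
        assert excluded.get("D1") == nm.NO_SUPPORTED_CLUSTER
        assert sorted(retained) == ["A1", "B1"]

    def test_threshold_100_excludes_everything(self):
        t = with_supports("((A1:1,B1:1)100:1,C1:1,Out:3);")
        cat = make_catalog([("A1", "At"), ("B1", "Pt"), ("C1", "Os")])
        cfg = nm.NomenclatureConfig(assignment_threshold=100,
                                    support_strong=100, support_weak=100)
        retained, excluded = nm.exclude_distant_relatives(t, cat, cfg)
        assert retained == [] and len(excluded) == 3


@pytest.fixture
def anchored_tree_and_catalog():
    """Rooted, supported tree with two anchored groups, one stray leaf and
    one ambiguous leaf."""
    newick = ("((((At1:0.1,Pt1:0.1)95:0.1,Cr1:0.15)95:0.2,"
              "((At2:0.1,Pt2:0.1)95:0.1,Amb:0.4)60:0.2)98:0.3,"
              "(Stray:0.5,Out:0.5)90:0.3);")
    t = ph.read_newick(newick)
    cat = make_catalog([
        ("At1", "At", {"established_name": "Deg1"}),
        ("At2", "At", {"established_name": "Deg2"}),
        ("Pt1", "Pt"), ("Pt2", "Pt"), ("Cr1", "Cr"),
        ("Amb", "Cr"), ("Stray", "Pt"),
    ], outgroup=None)
    return t, cat


class TestAssignOrthologGroups:
    def test_leaf_in_single_anchor_clade_joins_that_group(
            self, anchored_tree_and_catalog):
        t, cat = anchored_tree_and_catalog
        groups = {(g.anchor_name, g.status): g
                  for g in nm.assign_ortholog_groups(t, cat)}
        assert "Cr1" in groups[("Deg1", nm.ANCHORED)].members["Cr"]
        assert "Pt1" in groups[("Deg1", nm.ANCHORED)].members["Pt"]
        assert "Pt2" in groups[("Deg2", nm.ANCHORED)].members["Pt"]

    def test_leaf_outside_anchored_clades_gets_like_group(
            self, anchored_tree_and_catalog):
        t, cat = anchored_tree_and_catalog
        groups = nm.assign_ortholog_groups(t, cat)
        like = [g for g in groups if g.status == nm.LIKE]
        assert len(like) == 1
        assert like[0].members == {"Pt": ["Stray"]}
        assert like[0].anchor_name == "Deg-like 1"

    def test_ambiguous_leaf_marked_group_like(self, anchored_tree_and_catalog):
        t, cat = anchored_tree_and_catalog
        # Amb's minimal supported clade (98%) holds both anchors
        groups = nm.assign_ortholog_groups(t, cat)
        gl = [g for g in groups if g.status == nm.GROUP_LIKE]
        assert len(gl) == 1
        assert gl[0].members == {"Cr": ["Amb"]}
        assert gl[0].anchor_name == "Deg2"   # nearest anchor

    def test_every_leaf_assigned_exactly_once(self, anchored_tree_and_catalog):
        t, cat = anchored_tree_and_catalog
        groups = nm.assign_ortholog_groups(t, cat)
        assigned = [rid for g in groups for rid in g.all_members()]
        catalog_leaves = [r.id for r in cat.records]
        assert sorted(assigned) == sorted(catalog_leaves)

    def test_raising_threshold_never_promotes_to_anchored(
            self, anchored_tree_and_catalog):
        t, cat = anchored_tree_and_catalog

        def anchored_leaves(threshold):
            cfg = nm.NomenclatureConfig(assignment_threshold=threshold)
            return {rid for g in nm.assign_ortholog_groups(t, cat, cfg)
                    if g.status == nm.ANCHORED for rid in g.all_members()}

        for lo, hi in itertools.combinations([0, 50, 70, 90, 96, 99], 2):
            assert anchored_leaves(hi) <= anchored_leaves(lo)

    def test_no_anchor_rejected(self):
        t = with_supports("((B1:1,C1:1)90:1,B2:1,Out:3);")
        cat = make_catalog([("B1", "Pt"), ("B2", "Pt"), ("C1", "Os")],
                           reference="At")
        cat.registry.append(fc.SpeciesRecord("At", "ref",
                                             is_reference_anchor=True))
        cat.registry = [s for s in cat.registry
                        if not (s.code == "At" and not s.is_reference_anchor)]
        with pytest.raises(ValueError, match="anchor"):
            nm.assign_ortholog_groups(t, cat)


class TestProposeNames:
    def test_paralogs_suffixed_by_patristic_distance(
            self, anchored_tree_and_catalog):
        t, cat = anchored_tree_and_catalog
        cat.records.append(fc.ProteinRecord(id="Cr2", species_code="Cr",
                                            length_aa=0))
        # graft Cr2 inside the Deg1 clade, farther from the anchor than Cr1
        target = next(n for n in t.postorder() if n.name == "Cr1")
        parent = target.parent
        new = ph.Node(None, 0.05)
        new.support = 95.0
        pos = parent.children.index(target)
        parent.children[pos] = new
        new.parent = parent
        target.length = 0.4
        new.add(target)
        new.add(ph.Node("Cr2", 0.01))
        t2 = ph.PhyloTree(t.root, rooted=True)
        groups = nm.assign_ortholog_groups(t2, cat)
        names = nm.propose_names(groups, cat)
        assert names["Cr2"] == "CrDeg1.1"     # closer to the anchor
        assert names["Cr1"] == "CrDeg1.2"

    def test_single_member_unsuffixed(self, anchored_tree_and_catalog):
        t, cat = anchored_tree_and_catalog
        names = nm.propose_names(nm.assign_ortholog_groups(t, cat), cat)
        assert names["Pt1"] == "PtDeg1"
        assert names["At1"] == "AtDeg1"       # reference keeps its name

    def test_like_and_group_like_names(self, anchored_tree_and_catalog):
        t, cat = anchored_tree_and_catalog
        names = nm.propose_names(nm.assign_ortholog_groups(t, cat), cat)
        assert names["Stray"] == "PtDeg-like 1"
        assert names["Amb"] == "CrDeg2-group-like"

    def test_names_unique(self, anchored_tree_and_catalog):
        t, cat = anchored_tree_and_catalog
        names = nm.propose_names(nm.assign_ortholog_groups(t, cat), cat)
        assert len(set(names.values())) == len(names)


class TestArchitectureConcordance:
    def test_uniform_group_concordant(self):
        cat = fc.load_bundled_catalog("At")
        groups = nm.groups_from_catalog(cat)
        report = {c.group: c for c in nm.architecture_concordance(groups, cat)}
        assert report["Deg1"].concordant
        assert report["Deg1"].majority_architecture == "PD-PDZ"

    def test_fusion_member_flagged_discordant(self):
        inv = fc.load_bundled_inventory()
        groups = nm.groups_from_catalog(inv)
        report = {c.group: c for c in nm.architecture_concordance(groups, inv)}
        assert "Cre19.g752200" in report["Deg9"].discordant
        assert report["Deg9"].majority_architecture == "PD-PDZ-PDZ"

    def test_member_without_architecture_unassessed(self):
        cat = make_catalog([("A1", "At", {"declared_group": "Deg1"}),
                            ("A2", "At", {"declared_group": "Deg1"})])
        groups = nm.groups_from_catalog(cat)
        report = nm.architecture_concordance(groups, cat)
        assert report[0].unassessed == ["A1", "A2"]

    def test_empty_group_list(self):
        cat = fc.load_bundled_catalog("At")
        assert nm.architecture_concordance([], cat) == []
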
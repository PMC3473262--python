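"""Reference-anchored ortholog groups and standardized names.

Given a bootstrapped tree over validated family members, this module roots
the tree on the outgroup, extracts bootstrap-supported clades, groups every
leaf with the reference-species (anchor) proteins it clusters with, and
derives standardized names: same group, same name across species, with
``.1/.2/...`` suffixes for same-species paralogs, a ``-like`` series for
members outside every anchored clade, and a ``group-like`` designation when
the tree cannot decide between neighboring anchored groups.

Group delineation codifies the expert tree reading as: the group of a leaf
is the anchor content of the *minimal* supported clade (support strictly
above the assignment threshold) that contains the leaf and at least one
anchor.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .family_catalog import Catalog
from .phylogeny import PhyloTree

logger = logging.getLogger(__name__)

NOT_FAMILY_FLAG = "NOT_FAMILY_FLAG"
NO_SUPPORTED_CLUSTER = "NO_SUPPORTED_CLUSTER"

ANCHORED = "anchored"
LIKE = "like"
GROUP_LIKE = "group_like"

#: published clade labels by anchor name (reporting annotation only)
DEFAULT_CLADE_LABELS = {
    "Deg1": "I A", "Deg5": "I A", "Deg8": "I A",
    "Deg14": "I B",
    "Deg2": "II", "Deg3": "II", "Deg4": "II", "Deg9": "II",
    "Deg10": "II", "Deg11": "II", "Deg12": "II", "Deg13": "II",
    "Deg7": "III",
    "Deg15": "IV",
}


@dataclass
class NomenclatureConfig:
    support_strong: float = 90.0
    support_weak: float = 70.0
    assignment_threshold: float = 70.0
    reference_species: str | None = None    # default: the registry anchor
    like_prefix: str = "Deg-like"
    grouplike_suffix: str = "group-like"

    def __post_init__(self) -> None:
        if not (0 <= self.support_weak <= self.support_strong <= 100):
            raise ValueError("require 0 <= weak <= strong <= 100")


@dataclass
class OrthologGroup:
    """One ortholog group: an anchor name plus per-species member lists."""

    anchor_name: str
    members: dict[str, list[str]] = field(default_factory=dict)
    support: float | None = None
    status: str = ANCHORED
    clade_label: str = ""

    def __post_init__(self) -> None:
        if self.status not in (ANCHORED, LIKE, GROUP_LIKE):
            raise ValueError(f"unknown group status {self.status!r}")

    def all_members(self) -> list[str]:
        return [rid for ids in self.members.values() for rid in ids]

    def size(self) -> int:
        return len(self.all_members())


# ---------------------------------------------------------------------------
# Rooting and supported clades
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup_ids: set[str]) -> PhyloTree:
    """Root on the outgroup's stem edge (lengths split evenly).

    If the outgroup is not monophyletic in the unrooted tree, the edge whose
    one side is richest in outgroup leaves and poorest in ingroup leaves is
    used instead, with a logged warning.
    """
    leaves = set(tree.leaf_names())
    og = set(outgroup_ids)
    if not og:
        raise ValueError("empty outgroup set")
    if not og <= leaves:
        raise ValueError(f"outgroup ids absent from tree: {sorted(og - leaves)}")
    unrooted = tree.unroot() if tree.rooted else tree.copy()
    sets = unrooted.clade_leafsets()

    def finish(rooted: PhyloTree) -> PhyloTree:
        # the root split is in every replicate by definition; give a root
        # child without support its sibling's value (or 100 if the split
        # was trivial in the unrooted tree, e.g. a single-leaf outgroup)
        kids = rooted.root.children
        sup = next((k.support for k in kids if k.support is not None), 100.0)
        for k in kids:
            if not k.is_leaf and k.support is None:
                k.support = sup
        return rooted

    # exact stem edge
    for node in unrooted.edges():
        side = set(sets[node])
        if side == og or (leaves - side) == og:
            return finish(unrooted.reroot_on_edge(node, 0.5))
    logger.warning("outgroup is not monophyletic; rooting on the edge that "
                   "best separates it")
    best = None
    for node in unrooted.edges():
        side = set(sets[node])
        for cand in (side, leaves - side):
            score = len(cand & og) - len(cand - og)
            key = (-score, len(cand), tuple(sorted(cand)))
            if best is None or key < best[0]:
                best = (key, node)
    return finish(unrooted.reroot_on_edge(best[1], 0.5))


def supported_clades(tree: PhyloTree, threshold: float
                     ) -> list[frozenset[str]]:
    """Leaf sets of all clades whose subtending edge has support strictly
    above the threshold, sorted by size descending."""
    sets = tree.clade_leafsets()
    out: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for node in tree.internal_edges():
        if node.support is None:
            raise ValueError("internal edge without bootstrap support")
        if node.support > threshold and sets[node] not in seen:
            seen.add(sets[node])
            out.append(sets[node])
    out.sort(key=lambda s: (-len(s), tuple(sorted(s))))
    return out


# ---------------------------------------------------------------------------
# Distant relatives
# ---------------------------------------------------------------------------

def exclude_distant_relatives(tree: PhyloTree, catalog: Catalog,
                              cfg: NomenclatureConfig | None = None
                              ) -> tuple[list[str], dict[str, str]]:
    """Leaves kept for the final analysis, and exclusions with reasons.

    A leaf is excluded if the catalog flags it as outside the family, or if
    no supported clade (at the assignment threshold) clusters it with any
    other family member — such entries are reported for "-like" naming.
    """
    cfg = cfg or NomenclatureConfig()
    flagged = {r.id for r in catalog.records if r.not_family_flag}
    catalog_ids = {r.id for r in catalog.records}
    try:
        clades = supported_clades(tree, cfg.assignment_threshold)
    except ValueError:
        clades = []
    retained: list[str] = []
    excluded: dict[str, str] = {}
    for name in tree.leaf_names():
        if name not in catalog_ids:
            continue        # outgroup or foreign leaf: not subject to the rule
        if name in flagged:
            excluded[name] = NOT_FAMILY_FLAG
            continue
        clustered = any(
            name in clade and (clade & catalog_ids) - flagged - {name}
            for clade in clades
        )
        if clustered:
            retained.append(name)
        else:
            excluded[name] = NO_SUPPORTED_CLUSTER
    return retained, excluded


# ---------------------------------------------------------------------------
# Group assignment
# ---------------------------------------------------------------------------

def _anchor_name(record) -> str:
    return record.established_name or record.declared_group or record.id


def assign_ortholog_groups(tree: PhyloTree, catalog: Catalog,
                           cfg: NomenclatureConfig | None = None,
                           clade_labels: dict[str, str] | None = None
                           ) -> list[OrthologGroup]:
    """Group every catalog leaf with reference-species anchors.

    Anchors are the reference-species leaves, each carrying its established
    name. A non-reference leaf joins the group named by the anchors of the
    minimal supported clade containing it; if that clade mixes several
    anchor names the leaf gets ``group_like`` status under the nearest
    anchor's name; leaves outside every anchored supported clade form new
    like-numbered groups (clustered when a supported clade holds only such
    leaves), numbered in leaf order.
    """
    cfg = cfg or NomenclatureConfig()
    labels = clade_labels if clade_labels is not None else DEFAULT_CLADE_LABELS
    ref = cfg.reference_species or catalog.reference_species
    if ref is None:
        raise ValueError("no reference species configured or in the registry")
    records = {r.id: r for r in catalog.records}
    species_of = {rid: r.species_code for rid, r in records.items()}
    og_codes = {s.code for s in catalog.registry if s.is_outgroup}
    leaf_order = [n for n in tree.leaf_names()
                  if n in records and species_of[n] not in og_codes]
    anchors = {rid: _anchor_name(records[rid])
               for rid in leaf_order if species_of[rid] == ref}
    if not anchors:
        raise ValueError(f"no anchors: reference species {ref!r} absent from tree")

    clades = supported_clades(tree, cfg.assignment_threshold)
    clades_small_first = sorted(clades, key=lambda s: (len(s), tuple(sorted(s))))
    support_of = {}
    sets = tree.clade_leafsets()
    for node in tree.internal_edges():
        s = sets[node]
        if s not in support_of or (node.support or 0) > support_of[s]:
            support_of[s] = node.support

    def nearest_anchor(leaf: str, candidates: set[str]) -> str:
        dist = {a: tree.patristic_distance(leaf, a) for a in candidates}
        return min(candidates, key=lambda a: (dist[a], anchors[a], a))

    assignment: dict[str, tuple[str, str, float | None]] = {}
    unanchored: list[str] = []
    for leaf in leaf_order:
        if leaf in anchors:
            assignment[leaf] = (anchors[leaf], ANCHORED, None)
            continue
        minimal = None
        for clade in clades_small_first:
            if leaf in clade and any(a in clade for a in anchors):
                minimal = clade
                break
        if minimal is None:
            unanchored.append(leaf)
            continue
        in_clade = {a for a in anchors if a in minimal}
        names = {anchors[a] for a in in_clade}
        if len(names) == 1:
            assignment[leaf] = (names.pop(), ANCHORED, support_of.get(minimal))
        else:
            base = anchors[nearest_anchor(leaf, in_clade)]
            assignment[leaf] = (base, GROUP_LIKE, support_of.get(minimal))
            logger.info("%s: minimal supported clade mixes anchors %s; "
                        "designated %s-%s", leaf, sorted(names), base,
                        cfg.grouplike_suffix)

    # like groups: maximal supported clades made only of unanchored leaves
    like_sets: list[list[str]] = []
    covered: set[str] = set()
    pool = set(unanchored)
    for clade in clades:     # size descending: maximal first
        if clade <= pool and not clade & covered:
            like_sets.append([l for l in leaf_order if l in clade])
            covered |= clade
    for leaf in unanchored:
        if leaf not in covered:
            like_sets.append([leaf])
    like_sets.sort(key=lambda ls: leaf_order.index(ls[0]))

    # assemble groups
    groups: dict[tuple[str, str], OrthologGroup] = {}

    def group_for(name: str, status: str) -> OrthologGroup:
        key = (name, status)
        if key not in groups:
            groups[key] = OrthologGroup(
                anchor_name=name, status=status,
                clade_label=labels.get(name, "") if status == ANCHORED else "")
        return groups[key]

    for leaf in leaf_order:
        if leaf not in assignment:
            continue
        name, status, supp = assignment[leaf]
        grp = group_for(name, status)
        grp.members.setdefault(species_of[leaf], []).append(leaf)
        if supp is not None:
            grp.support = supp if grp.support is None else min(grp.support, supp)
    for k, members in enumerate(like_sets, start=1):
        grp = OrthologGroup(anchor_name=f"{cfg.like_prefix} {k}", status=LIKE)
        clade = frozenset(members)
        grp.support = support_of.get(clade) if len(members) > 1 else None
        for leaf in members:
            grp.members.setdefault(species_of[leaf], []).append(leaf)
        groups[(grp.anchor_name, LIKE)] = grp

    # order same-species paralogs by patristic distance to the nearest
    # same-group anchor (lexicographic id on ties)
    out = list(groups.values())
    for grp in out:
        if grp.status != ANCHORED:
            continue
        grp_anchors = [rid for rid in grp.members.get(ref, [])]
        for code, ids in grp.members.items():
            if code == ref or len(ids) < 2 or not grp_anchors:
                continue
            def sort_key(rid: str):
                d = min(tree.patristic_distance(rid, a) for a in grp_anchors)
                return (d, rid)
            ids.sort(key=sort_key)

    def order_key(grp: OrthologGroup):
        status_rank = {ANCHORED: 0, GROUP_LIKE: 1, LIKE: 2}[grp.status]
        m = re.search(r"(\d+)", grp.anchor_name)
        return (status_rank, int(m.group(1)) if m else 0, grp.anchor_name)

    out.sort(key=order_key)
    return out


def groups_from_catalog(catalog: Catalog) -> list[OrthologGroup]:
    """Ortholog groups read off a catalog's declared group columns
    (catalog-only mode; no tree required)."""
    groups: dict[tuple[str, str], OrthologGroup] = {}
    for rec in catalog.records:
        if not rec.declared_group:
            continue
        status = rec.declared_group_status or ANCHORED
        key = (rec.declared_group, status)
        if key not in groups:
            groups[key] = OrthologGroup(
                anchor_name=rec.declared_group, status=status,
                clade_label=DEFAULT_CLADE_LABELS.get(rec.declared_group, ""))
        groups[key].members.setdefault(rec.species_code, []).append(rec.id)
    out = list(groups.values())
    out.sort(key=lambda g: ({ANCHORED: 0, GROUP_LIKE: 1, LIKE: 2}[g.status],
                            _numeric_key(g.anchor_name)))
    return out


def _numeric_key(name: str):
    m = re.search(r"(\d+)", name)
    return (int(m.group(1)) if m else 0, name)


# ---------------------------------------------------------------------------
# Name proposal
# ---------------------------------------------------------------------------

def propose_names(groups: list[OrthologGroup], catalog: Catalog,
                  cfg: NomenclatureConfig | None = None) -> dict[str, str]:
    """Standardized name per record id.

    Species prefix + group name, with ``.1/.2/...`` suffixes when a species
    holds several members of one group (ordered by patristic distance to
    the nearest anchor, as stored in the group); reference-species members
    keep their established names.
    """
    cfg = cfg or NomenclatureConfig()
    ref = cfg.reference_species or catalog.reference_species
    records = {r.id: r for r in catalog.records}
    names: dict[str, str] = {}
    for grp in groups:
        for code, ids in grp.members.items():
            if code == ref and grp.status == ANCHORED:
                # keep established names; suffix only if duplicates share one
                by_name: dict[str, list[str]] = {}
                for rid in ids:
                    by_name.setdefault(_anchor_name(records[rid]), []).append(rid)
                for base, rids in by_name.items():
                    if len(rids) == 1:
                        names[rids[0]] = f"{code}{base}"
                    else:
                        for k, rid in enumerate(rids, start=1):
                            names[rid] = f"{code}{base}.{k}"
                continue
            if grp.status == GROUP_LIKE:
                base = f"{grp.anchor_name}-{cfg.grouplike_suffix}"
            else:
                base = grp.anchor_name
            if len(ids) == 1:
                names[ids[0]] = f"{code}{base}"
            else:
                for k, rid in enumerate(ids, start=1):
                    names[rid] = f"{code}{base}.{k}"
    collisions = {n for n in names.values() if list(names.values()).count(n) > 1}
    if collisions:
        raise ValueError(f"name collisions after construction: {sorted(collisions)}")
    return names


# ---------------------------------------------------------------------------
# Domain-arrangement concordance
# ---------------------------------------------------------------------------

@dataclass
class GroupConcordance:
    group: str
    majority_architecture: str
    discordant: dict[str, str] = field(default_factory=dict)
    unassessed: list[str] = field(default_factory=list)

    @property
    def concordant(self) -> bool:
        return not self.discordant


def architecture_concordance(groups: list[OrthologGroup], catalog: Catalog
                             ) -> list[GroupConcordance]:
    """Per group: the majority domain arrangement and discordant members.

    A reporting operation; a member without an architecture is listed as
    unassessed, never an error.
    """
    records = {r.id: r for r in catalog.records}
    out: list[GroupConcordance] = []
    for grp in groups:
        archs: dict[str, str] = {}
        unassessed: list[str] = []
        for rid in grp.all_members():
            rec = records.get(rid)
            if rec is None or rec.declared_architecture is None:
                unassessed.append(rid)
            else:
                archs[rid] = str(rec.declared_architecture)
        if not archs:
            out.append(GroupConcordance(grp.anchor_name, "", {}, unassessed))
            continue
        counts: dict[str, int] = {}
        for a in archs.values():
            counts[a] = counts.get(a, 0) + 1
        majority = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        discordant = {rid: a for rid, a in archs.items() if a != majority}
        out.append(GroupConcordance(grp.anchor_name, majority, discordant,
                                    unassessed))
    return out
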
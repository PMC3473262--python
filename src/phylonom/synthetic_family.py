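"""Synthetic gene families with known ground truth.

Generates what the study mined from genome databases: a multi-species
protein family shaped by lineage-specific duplications and losses, with
divergent paralogs, proteolytically inactivated members (one catalytic-triad
residue substituted), and variable domain architectures. Every pipeline
stage is testable against the generator's truth tables without downloads.

Model: a species tree (coalescent-style random ultrametric topology) with a
stem branch above the root; one ancestral gene enters the stem and evolves
under a linear birth-death process (duplication rate λ, loss rate μ per
unit branch length). Gene lineages surviving at the first speciation found
the *true ortholog groups* (named Deg1, Deg2, ...); duplications after the
first speciation create within-group, lineage-specific paralogs. Sequences
evolve site-independently under the substitution model with no indels; the
three catalytic-triad residues are held invariant in active genes. A single
outgroup gene diverging above the stem provides the rooting point, mirroring
the use of distant homologs to orient the tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._aa import AMINO_ACIDS
from .family_catalog import (Catalog, ProteinRecord, SpeciesRecord,
                             save_catalog, save_registry, write_fasta)
from .phylogeny import Node, PhyloTree, RateModel, write_newick

logger = logging.getLogger(__name__)

OUTGROUP_CODE = "Out"

# rng stream tags (kept below 2**31 together with the user seed)
_STREAM_SPECIES = 1
_STREAM_GENES = 2
_STREAM_SEQS = 3
_STREAM_ARCH = 4
_STREAM_INACT = 5

#: substitutions applied when knocking out a triad residue (Asp->Asn is the
#: classic inactivating change; His and Ser get similarly conservative ones)
_TRIAD_KNOCKOUT = {"H": "L", "D": "N", "S": "A"}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic family."""

    n_species: int = 5
    species_tree_height: float = 0.7     # expected substitutions/site, root to tip
    stem_length: float = 0.7             # pre-speciation branch (group founders)
    duplication_rate: float = 0.3        # events per unit branch length
    loss_rate: float = 0.1
    sequence_length: int = 300
    model: RateModel | None = None       # default: WAG
    inactivation_fraction: float = 0.15
    architecture_palette: list[tuple[str, float]] = field(default_factory=lambda: [
        ("PD-PDZ", 0.4), ("PD-PDZ-PDZ", 0.3), ("PD", 0.2), ("NT-PD", 0.1)])
    architecture_switch_prob: float = 0.02   # per duplication
    include_outgroup: bool = True
    outgroup_branch: float | None = None     # default: height + stem
    # the reference species stands for a fully curated genome whose members
    # are the naming anchors; its genes are exempt from inactivation
    protect_reference: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0 <= self.inactivation_fraction <= 1):
            raise ValueError("inactivation_fraction must be in [0, 1]")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")

    def rate_model(self) -> RateModel:
        return self.model if self.model is not None else RateModel.wag()


@dataclass
class GeneFamilyTruth:
    """Ground truth of one simulated family."""

    config: SimulationConfig
    species_tree: PhyloTree
    gene_tree: PhyloTree | None               # None if the family went extinct
    true_group: dict[str, str] = field(default_factory=dict)
    architecture: dict[str, str] = field(default_factory=dict)
    active: dict[str, bool] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    triad_positions: tuple[int, int, int] | None = None
    n_duplications: int = 0
    n_losses: int = 0
    outgroup_id: str | None = None

    @property
    def empty(self) -> bool:
        return self.gene_tree is None

    def genes(self) -> list[str]:
        return [] if self.empty else list(self.gene_tree.leaf_names())

    def ingroup_genes(self) -> list[str]:
        return [g for g in self.genes() if g != self.outgroup_id]

    @staticmethod
    def species_of(gene_id: str) -> str:
        return gene_id.rsplit("_", 1)[0]

    def registry(self) -> list[SpeciesRecord]:
        out = [SpeciesRecord(code=f"S{k}", name=f"Simulated species {k}",
                             is_reference_anchor=(k == 1))
               for k in range(1, self.config.n_species + 1)]
        if self.outgroup_id is not None:
            out.append(SpeciesRecord(code=OUTGROUP_CODE,
                                     name="Simulated outgroup",
                                     is_outgroup=True))
        return out

    def to_catalog(self) -> Catalog:
        """Catalog view of the family: declared architectures and activity
        as a genome-annotation stage would provide them; reference-species
        members carry their true group as established name."""
        from .domain_annotation import MISSING_TRIAD_RESIDUE, parse_architecture

        records = []
        for gid in self.genes():
            sp = self.species_of(gid)
            established = (self.true_group[gid]
                           if sp == "S1" and gid != self.outgroup_id else "")
            records.append(ProteinRecord(
                id=gid, species_code=sp,
                length_aa=len(self.sequences[gid]),
                sequence=self.sequences[gid],
                declared_architecture=parse_architecture(self.architecture[gid]),
                declared_activity=self.active[gid],
                activity_reason="" if self.active[gid] else MISSING_TRIAD_RESIDUE,
                established_name=established,
            ))
        return Catalog(registry=self.registry(), records=records,
                       provenance=f"synthetic family, seed {self.config.seed}")


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(cfg: SimulationConfig) -> PhyloTree:
    """Random ultrametric topology: lineages are joined pairwise at sorted
    uniform times scaled so the root sits at the configured height."""
    rng = np.random.default_rng((cfg.seed & 0x7FFFFFFF, _STREAM_SPECIES))
    n = cfg.n_species
    if n == 1:
        return PhyloTree(Node("S1"), rooted=True)
    raw = np.sort(rng.uniform(size=n - 1))
    times = raw / raw[-1] * cfg.species_tree_height if raw[-1] > 0 else raw
    lineages: list[tuple[Node, float]] = [(Node(f"S{k}"), 0.0)
                                          for k in range(1, n + 1)]
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, da), (b, db) = lineages[i], lineages[j]
        parent = Node()
        a.length = t - da
        b.length = t - db
        parent.add(a)
        parent.add(b)
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append((parent, t))
    root = lineages[0][0]
    return PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# Gene tree (birth-death along the species tree)
# ---------------------------------------------------------------------------

class _BirthDeath:
    def __init__(self, lam: float, mu: float, rng: np.random.Generator):
        self.lam, self.mu, self.rng = lam, mu, rng
        self.dups = 0
        self.losses = 0
        self.serial: dict[str, int] = {}

    def _wait(self) -> float:
        rate = self.lam + self.mu
        if rate == 0:
            return math.inf
        return float(self.rng.exponential(1.0 / rate))

    def _new_leaf(self, species: str, length: float) -> Node:
        k = self.serial.get(species, 0) + 1
        self.serial[species] = k
        return Node(f"{species}_{k}", length)

    def sim_branch(self, sp_node: Node, remaining: float) -> Node | None:
        """One gene lineage with ``remaining`` length left on the species
        branch into ``sp_node``; returns the surviving gene subtree (its
        root length measured from the lineage entry point) or None."""
        wait = self._wait()
        if wait < remaining:
            if self.rng.random() < self.mu / (self.lam + self.mu):
                self.losses += 1
                return None
            self.dups += 1
            a = self.sim_branch(sp_node, remaining - wait)
            b = self.sim_branch(sp_node, remaining - wait)
            alive = [x for x in (a, b) if x is not None]
            if not alive:
                return None
            if len(alive) == 1:
                alive[0].length += wait
                return alive[0]
            node = Node("D", wait)
            for x in alive:
                node.add(x)
            return node
        # reached the bottom of the branch
        if sp_node.is_leaf:
            return self._new_leaf(sp_node.name, remaining)
        kids = [self.sim_branch(c, c.length) for c in sp_node.children]
        alive = [k for k in kids if k is not None]
        if not alive:
            return None
        if len(alive) == 1:
            alive[0].length += remaining
            return alive[0]
        node = Node("S", remaining)
        for k in alive:
            node.add(k)
        return node


def simulate_gene_tree(species_tree: PhyloTree, duplication_rate: float,
                       loss_rate: float, seed: int, stem_length: float = 0.0
                       ) -> tuple[Node | None, dict[str, str], int, int]:
    """Birth-death gene tree along the species tree.

    One root gene enters the stem above the species root; lineages surviving
    at the first speciation found the true groups (Deg1, Deg2, ... in
    simulation order). Returns (gene subtree root or None, gene -> group,
    duplication count, loss count). Total extinction yields (None, {}, ...)
    with a warning.
    """
    rng = np.random.default_rng((seed & 0x7FFFFFFF, _STREAM_GENES))
    bd = _BirthDeath(duplication_rate, loss_rate, rng)
    sp_root = species_tree.root

    founders: list[Node] = []

    def sim_stem(remaining: float) -> Node | None:
        wait = bd._wait()
        if wait < remaining:
            if rng.random() < bd.mu / (bd.lam + bd.mu):
                bd.losses += 1
                return None
            bd.dups += 1
            a = sim_stem(remaining - wait)
            b = sim_stem(remaining - wait)
            alive = [x for x in (a, b) if x is not None]
            if not alive:
                return None
            if len(alive) == 1:
                alive[0].length += wait
                return alive[0]
            node = Node("D", wait)
            for x in alive:
                node.add(x)
            return node
        # survived to the first speciation: found a group
        if sp_root.is_leaf:
            leaf = bd._new_leaf(sp_root.name, remaining)
            founders.append(leaf)
            return leaf
        kids = [bd.sim_branch(c, c.length) for c in sp_root.children]
        alive = [k for k in kids if k is not None]
        if not alive:
            return None
        if len(alive) == 1:
            alive[0].length += remaining
            founders.append(alive[0])
            return alive[0]
        node = Node("S", remaining)
        for k in alive:
            node.add(k)
        founders.append(node)
        return node

    root = sim_stem(stem_length)
    if root is None:
        logger.warning("gene family went extinct during simulation")
        return None, {}, bd.dups, bd.losses

    groups: dict[str, str] = {}
    for k, founder in enumerate(founders, start=1):
        name = f"Deg{k}"
        stack = [founder]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                groups[node.name] = name
            stack.extend(node.children)
    return root, groups, bd.dups, bd.losses


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def evolve_sequences(gene_tree: PhyloTree, model: RateModel, length: int,
                     seed: int) -> dict[str, str]:
    """Root sequence from equilibrium; residues evolve independently per
    site along branches via the model's transition probabilities (no indels)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng((seed & 0x7FFFFFFF, _STREAM_SEQS))
    pi = model.frequencies
    states: dict[int, np.ndarray] = {
        id(gene_tree.root): rng.choice(20, size=length, p=pi)}
    out: dict[str, str] = {}
    if gene_tree.root.is_leaf:
        st = states[id(gene_tree.root)]
        return {gene_tree.root.name: "".join(AMINO_ACIDS[k] for k in st)}
    for node in gene_tree.preorder():
        if node is gene_tree.root:
            continue
        p = model.transition_matrix(node.length or 0.0)
        cum = p.cumsum(axis=1)
        parent_states = states[id(node.parent)]
        u = rng.random(length)
        st = (u[:, None] > cum[parent_states]).sum(axis=1).clip(0, 19)
        states[id(node)] = st
        if node.is_leaf:
            out[node.name] = "".join(AMINO_ACIDS[k] for k in st)
    return out


def _plant_triad(sequences: dict[str, str], length: int
                 ) -> tuple[dict[str, str], tuple[int, int, int]]:
    """Fix the catalytic His/Asp/Ser at deterministic positions in every
    gene (the triad is invariant in active family members)."""
    h, d, s = (max(0, int(length * 0.15)), min(length - 1, int(length * 0.5)),
               min(length - 1, int(length * 0.85)))
    if len({h, d, s}) < 3:
        raise ValueError("sequence too short to hold a catalytic triad")
    out = {}
    for gid, seq in sequences.items():
        chars = list(seq)
        chars[h], chars[d], chars[s] = "H", "D", "S"
        out[gid] = "".join(chars)
    return out, (h, d, s)


def inject_inactivation(truth: GeneFamilyTruth, fraction: float, seed: int,
                        protect_species: set[str] | None = None
                        ) -> GeneFamilyTruth:
    """Substitute one triad residue in a seeded random subset of ingroup
    genes (proportion = fraction) and mark them inactive; genes of
    ``protect_species`` are exempt from selection."""
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    if truth.empty or truth.triad_positions is None:
        return truth
    rng = np.random.default_rng((seed & 0x7FFFFFFF, _STREAM_INACT))
    protect = protect_species or set()
    genes = [g for g in truth.ingroup_genes()
             if truth.species_of(g) not in protect]
    k = int(round(fraction * len(genes)))
    chosen = sorted(rng.choice(len(genes), size=k, replace=False).tolist())
    for idx in chosen:
        gid = genes[idx]
        which = int(rng.integers(0, 3))
        pos = truth.triad_positions[which]
        chars = list(truth.sequences[gid])
        chars[pos] = _TRIAD_KNOCKOUT["HDS"[which]]
        truth.sequences[gid] = "".join(chars)
        truth.active[gid] = False
    return truth


def _assign_architectures(truth: GeneFamilyTruth, cfg: SimulationConfig
                          ) -> None:
    """Architecture labels: sampled per founder lineage, inherited, with a
    low-probability switch at each duplication node."""
    rng = np.random.default_rng((cfg.seed & 0x7FFFFFFF, _STREAM_ARCH))
    archs = [a for a, _ in cfg.architecture_palette]
    weights = np.array([w for _, w in cfg.architecture_palette], dtype=float)
    weights = weights / weights.sum()

    def sample() -> str:
        return archs[int(rng.choice(len(archs), p=weights))]

    if truth.outgroup_id is not None:
        truth.architecture[truth.outgroup_id] = sample()
    tree = truth.gene_tree
    state: dict[int, str] = {}
    for node in tree.preorder():
        if node is tree.root:
            state[id(node)] = sample()
        else:
            arch = state[id(node.parent)]
            if node.parent.name == "D" and rng.random() < cfg.architecture_switch_prob:
                arch = sample()
            state[id(node)] = arch
        if node.is_leaf and node.name != truth.outgroup_id:
            truth.architecture[node.name] = state[id(node)]


# ---------------------------------------------------------------------------
# Orchestration and output
# ---------------------------------------------------------------------------

def simulate(cfg: SimulationConfig) -> GeneFamilyTruth:
    """Full synthetic family: species tree, gene tree, sequences, triad
    planting, architectures, inactivation, optional outgroup gene."""
    species_tree = simulate_species_tree(cfg)
    subtree, groups, dups, losses = simulate_gene_tree(
        species_tree, cfg.duplication_rate, cfg.loss_rate, cfg.seed,
        stem_length=cfg.stem_length)
    if subtree is None:
        return GeneFamilyTruth(config=cfg, species_tree=species_tree,
                               gene_tree=None, n_duplications=dups,
                               n_losses=losses)
    outgroup_id: str | None = None
    if cfg.include_outgroup:
        out_len = (cfg.outgroup_branch if cfg.outgroup_branch is not None
                   else cfg.species_tree_height + cfg.stem_length)
        root = Node("R")
        outgroup_id = f"{OUTGROUP_CODE}_1"
        root.add(Node(outgroup_id, out_len))
        subtree.length = 0.0 if subtree.length is None else subtree.length
        root.add(subtree)
        gene_tree = PhyloTree(root, rooted=True)
        groups = dict(groups)
        groups[outgroup_id] = "outgroup"
    else:
        subtree.length = None
        gene_tree = PhyloTree(subtree, rooted=True)

    truth = GeneFamilyTruth(config=cfg, species_tree=species_tree,
                            gene_tree=gene_tree, true_group=groups,
                            n_duplications=dups, n_losses=losses,
                            outgroup_id=outgroup_id)
    model = cfg.rate_model()
    seqs = evolve_sequences(gene_tree, model, cfg.sequence_length, cfg.seed)
    truth.sequences, truth.triad_positions = _plant_triad(
        seqs, cfg.sequence_length)
    truth.active = {g: True for g in truth.genes()}
    _assign_architectures(truth, cfg)
    inject_inactivation(truth, cfg.inactivation_fraction, cfg.seed,
                        protect_species={"S1"} if cfg.protect_reference else None)
    return truth


def emit_dataset(truth: GeneFamilyTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, catalog + registry TSV, truth TSV and Newick trees.

    The files load back through the catalog module; every FASTA id appears
    exactly once in the truth table.
    """
    if truth.empty:
        raise ValueError("cannot emit an extinct (empty) family")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "family.fasta",
        "catalog": out_dir / "catalog.tsv",
        "registry": out_dir / "registry.tsv",
        "truth": out_dir / "truth.tsv",
        "species_tree": out_dir / "species_tree.nwk",
        "gene_tree": out_dir / "gene_tree.nwk",
    }
    catalog = truth.to_catalog()
    write_fasta(truth.sequences, paths["fasta"])
    save_catalog(catalog, paths["catalog"])
    save_registry(catalog.registry, paths["registry"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("id\tspecies\ttrue_group\tactive\tarchitecture\n")
        for gid in truth.genes():
            fh.write("\t".join([
                gid, truth.species_of(gid), truth.true_group[gid],
                "yes" if truth.active[gid] else "no",
                truth.architecture.get(gid, ""),
            ]) + "\n")
    paths["species_tree"].write_text(write_newick(truth.species_tree) + "\n")
    paths["gene_tree"].write_text(write_newick(truth.gene_tree) + "\n")
    return paths
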
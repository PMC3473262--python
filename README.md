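# phylonom

Phylogeny-based standardization of gene-family nomenclature across plant
genomes, built around the Deg/HtrA family of ATP-independent serine
endopeptidases.

During genome annotation, members of multi-copy protease families are
usually numbered in order of discovery, so orthologous enzymes end up with
different names in different species — and unrelated enzymes share a name.
`phylonom` implements the analysis that fixes this: it validates candidate
family members (complete trypsin-type protease domain, intact His-Asp-Ser
catalytic triad), aligns the protease domains, infers a bootstrapped
maximum-likelihood phylogeny, delimits reference-anchored ortholog groups,
proposes standardized names, checks that domain arrangements agree within
each group, and extracts the conserved "core set" of family members present
in every species.

It is aimed at comparative genomicists curating gene-family inventories:
the pipeline is a reproducible, scriptable replacement for the manual
tree-reading such nomenclature proposals normally rely on.

## The method

1. **Eligibility.** A candidate enters the phylogeny only if it has a
   complete protease domain (PD) and the full catalytic triad; members with
   a degenerated domain (PD_ia), a truncated domain, or a catalog flag are
   inventoried but excluded from the tree. Domain architectures are ordered
   token lists (`PD-PDZ-PDZ`, `NT-PD`, ...), either declared in the catalog
   or detected by a bundled PSSM scanner.
2. **Alignment.** Protease domains are aligned by a progressive
   affine-gap aligner under two parameterizations (BLOSUM62/open 11 and
   BLOSUM45/open 13); only columns on which both runs assert the same
   residue homology are kept (strict consensus), and gapped columns are
   stripped. Single-residue runs of ≥10 aa are masked to `X` first.
3. **Phylogeny.** Maximum likelihood under the WAG model: Felsenstein
   pruning, per-branch Brent optimization, NNI topology search from a
   neighbor-joining start, and nonparametric bootstrap (default 100
   replicates) for clade supports. NJ and Fitch parsimony serve as
   topology cross-checks (Robinson–Foulds distances are logged).
4. **Nomenclature.** The tree is rooted on the outgroup; the ortholog group
   of each leaf is the anchor content of the minimal supported clade
   (support > 70) containing it and a reference-species protein. Same
   group ⇒ same name; same-species paralogs get `.1/.2/...` suffixes
   ordered by patristic distance to the anchor; members outside every
   anchored clade become a numbered `Deg-like` series; leaves whose minimal
   supported clade mixes anchors are designated `<name>-group-like`.
5. **Core set.** The species × group conservation matrix yields the groups
   present in every species at their minimum copy number, plus a
   per-species duplication report.

Fixtures bundled with the package encode the published Deg/HtrA inventories
of *Arabidopsis thaliana* (At), *Populus trichocarpa* (Pt), *Oryza sativa*
(Os), *Physcomitrella patens* (Pp) and *Chlamydomonas reinhardtii* (Cr). A
built-in simulator generates families with known ground truth (species
tree, duplications/losses, inactivated paralogs, architecture labels) so
every stage is testable without downloads.

## Worked example

Simulate a five-species family and run the full pipeline:

```bash
phylonom simulate --seed 2 --out-dir demo/data
phylonom run-all --config demo/config.yaml
```

with `demo/config.yaml`:

```yaml
catalog: demo/data/catalog.tsv
registry: demo/data/registry.tsv
fasta: demo/data/family.fasta
out_dir: demo/out
bootstrap_replicates: 100
seed: 2
```

The same analysis from Python, on the bundled published inventory
(catalog-only mode — groups come from the declared table annotations):

```python
>>> from phylonom import (load_bundled_inventory, groups_from_catalog,
...                       build_conservation_matrix, compute_core_set,
...                       duplication_report)
>>> inv = load_bundled_inventory()
>>> groups = groups_from_catalog(inv)
>>> matrix = build_conservation_matrix(groups, inv.registry)
>>> core = compute_core_set(matrix)
>>> core.groups
['Deg1', 'Deg2', 'Deg5', 'Deg7', 'Deg8', 'Deg9', 'Deg10', 'Deg15']
>>> duplication_report(matrix)["Pt"]
{'Deg2': 2, 'Deg7': 3, 'Deg9': 2, 'Deg15': 2, 'Deg17': 3}
```

Eight groups are conserved across all five genomes — the minimal Deg/HtrA
complement a plant cell appears to need — and the poplar column shows the
lineage-specific duplications (three *Deg7* copies, etc.) that inflate its
family size.

Validating the *A. thaliana* inventory:

```python
>>> from phylonom import load_bundled_catalog, validate_catalog
>>> results = validate_catalog(load_bundled_catalog("At"))
>>> sum(r.eligible for r in results.values())
14
>>> {k: v.reasons for k, v in results.items() if not v.eligible}
{'At1g51150': ['TRUNCATED_PD'], 'At5g54745': ['MISSING_TRIAD_RESIDUE']}
```

Fourteen of the sixteen members are potentially active proteases; the two
exclusions are the truncated-domain member and the one lacking the
catalytic Asp.

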
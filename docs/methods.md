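# Methods

This note documents the models, rules and numerical choices behind
`phylonom`, and what the synthetic-data experiments do and do not show.

## Eligibility model

A family member may enter the phylogenetic analysis only with a complete
trypsin-type protease domain and an intact His-Asp-Ser catalytic triad.
Reason codes: `TRUNCATED_PD` (best protease-domain hit covers < 60% of the
profile; the threshold is a package choice, exposed as
`truncation_threshold`, since "incomplete" is otherwise unquantified),
`MISSING_TRIAD_RESIDUE`, `NO_PD_DETECTED`, and `NOT_FAMILY_FLAG` (a catalog
annotation marking database hits judged outside the family). Declared
catalog annotations always take precedence over de-novo detection, so a
curated inventory is reproduced exactly.

Domain detection is a position-specific score matrix (PSSM) scan with two
bundled profiles (protease domain with triad anchor offsets, PDZ). Profiles
are log₂-odds tables (pseudocount 0.5, uniform background) built from small
seed sets; the acceptance threshold is 0.55 × the consensus self-score,
prorated by coverage for terminal (truncated) hits, and is calibrated so
that scanning shuffled sequences produces hits in ≤ 1% of trials (tested).
Triad checking accepts the expected residue within ±3 positions of its
anchored profile position (`triad_window`, configurable); a protease-domain
hit with an incomplete triad is labeled `PD_ia`. The scanner is a
deliberately simple annotator: it stands behind the same interface as
externally supplied (declared) annotations, which any richer
domain-annotation source can populate.

## Alignment stage

The original analysis aligned protease domains with three external
aligners and merged them into a manually curated consensus. Here the same
progressive aligner (profile–profile Gotoh, affine gaps costing
`open + k·extend` for a run of length k, guide tree = NJ on
1 − identity distances) is run under two parameterizations — BLOSUM62 with
open 11 / extend 1, and BLOSUM45 with open 13 / extend 1 — and
`consensus_merge` keeps exactly the columns whose induced
residue–residue homology is identical in every run (k-of-n agreement is
available but strict agreement is the default, as the conservative
automation of a manual step). Columns containing any gap are then dropped
(`max_gap_frac = 0`, matching outright removal of gapped positions), and
single-residue runs ≥ 10 aa are masked to `X` beforehand because such
repeats demonstrably degrade alignments. On divergent data the strict
consensus can retain a minority of columns; that is intentional — it trades
sites for homology confidence, exactly like the manual curation it
replaces.

Deterministic tie-breaks: alignment traceback prefers substitution over a
gap in the second sequence over a gap in the first.

## Phylogeny

* **Model.** WAG exchangeabilities with the published equilibrium
  frequencies, rate matrix normalized to one expected substitution per
  unit branch length; single rate class. The original tool's exact
  defaults are not recoverable, so the model is surfaced as a parameter
  rather than hidden; WAG is the era-appropriate default. Transition
  matrices come from the eigendecomposition of the π-symmetrized
  generator, with scaling-and-squaring as a conditioning fallback.
* **Likelihood.** Felsenstein pruning over site patterns; gaps and X are
  marginalized (all-ones tip partials). Likelihood is invariant under
  re-rooting (tested to 1e-9).
* **Branch lengths.** Per-branch bounded Brent in [1e-8, 50], sweeps until
  the log-likelihood improves by < 1e-6 or 20 sweeps. Down-partials are
  cached and refreshed incrementally along the ancestor path of an updated
  branch; the outside message is computed only along the root-to-edge
  path.
* **Topology search.** NNI from an NJ start: each round evaluates both
  rearrangements of every internal edge with the five adjacent branch
  lengths re-optimized, accepts the best strict improvement, and fully
  re-optimizes; terminates when no rearrangement improves.
* **Bootstrap.** Nonparametric (columns resampled with replacement), 100
  replicates by default, one full ML inference per replicate; the support
  of an internal edge of the point tree is the percentage of replicate
  trees containing the same bipartition. Replicate RNG streams are derived
  from `(seed, replicate_index)`, so partial re-runs reproduce. The root
  split created by outgroup rooting is present in every replicate by
  construction and carries support 100.
* **Cross-checks.** NJ (with the lexicographic tie-break on equal Q and
  zero-clamped negative branch lengths) and Fitch parsimony (gaps/X
  union-neutral) confirm the overall topology; the pipeline logs
  Robinson–Foulds distances between the ML and NJ trees.

## Nomenclature rules

The expert reading of the tree is codified as: root on the outgroup (stem
edge split evenly; if the outgroup is not monophyletic, the edge best
separating it is used with a warning); a *supported clade* is one whose
subtending edge has bootstrap support strictly above the threshold
(defaults: 90 strong, 70 weak, 70 for assignment, matching the published
support marks); the group of a non-reference leaf is the anchor content of
the minimal supported clade containing it and at least one
reference-species protein.

* One anchor name ⇒ the leaf joins that anchored group.
* Several anchor names ⇒ the tree cannot decide; the leaf is designated
  `<nearest-anchor-name>-group-like` (nearest by patristic distance) — a
  flag, not a decision, mirroring how unresolvable placements are reported
  rather than forced.
* No anchored supported clade ⇒ the leaf joins a `Deg-like N` group;
  unanchored leaves forming a supported clade of their own share one like
  group (numbered in leaf order).

Paralog suffixes `.1/.2/...` within a species–group cell are ordered by
ascending patristic distance to the nearest anchor with lexicographic
tie-break (the ordering is otherwise unspecified; this rule is
deterministic). Reference-species members keep their established names; if
several reference paralogs of one group share an established name they are
suffixed the same way — an extension needed for generality, since a curated
reference genome normally has distinct names. Members flagged as outside
the family, and members in no supported cluster with another family
member, are excluded before the final tree and reported for like-naming.

Architecture concordance is a report, never a filter: per group it lists
the majority domain arrangement and any discordant members (e.g. a
glycan-hydrolase fusion), with members lacking an architecture marked
unassessed.

## Core set

The conservation matrix counts members per (group, species), excluding
outgroup species; like and group-like rows are included so the rendered
table reproduces the full published layout. The core set is the list of
groups with ≥ 1 member in every species, each reported at its minimum copy
number; the duplication report lists per species the groups with ≥ 2
copies. Core-set size is non-increasing in the number of species (tested).

## Synthetic families

The generator emulates what the study mined from databases. A random
ultrametric species tree (pairwise joins at sorted uniform times scaled to
the configured height) carries a linear birth–death gene process
(duplication rate λ, loss rate μ per unit branch length) that starts from
one gene at the top of a stem branch above the root. Lineages surviving at
the first speciation found the true ortholog groups; later duplications
create lineage-specific paralogs, matching the observation that most
family expansion is species-specific. Sequences evolve site-independently
under the same substitution model with **no indels** — alignment
correctness is thereby decoupled from inference tests — and the three
catalytic-triad residues are overwritten as invariant H/D/S (at 15%/50%/85%
of the sequence) in active genes. Inactivation substitutes one triad
residue (Asp→Asn, His→Leu, Ser→Ala) in a seeded random subset of genes.
Architecture labels are sampled per founder lineage and inherited, with a
0.02 per-duplication switch probability to exercise the concordance
checker. A single outgroup gene diverging above the stem provides the
rooting point, standing in for the distant homologs used to orient the real
tree.

Defaults (the study conditions for all experiments): 5 species, root-to-tip
height 0.7 substitutions/site, stem length 0.7, λ = 0.3, μ = 0.1, 300
columns, inactivation fraction 0.15, bootstrap 100. Height and stem are
package choices representing a deep (algae-to-dicot scale) divergence with
occasional pre-speciation duplications; the inactivation fraction mirrors
the 2–3 inactive members per 15–17 seen in real inventories. The reference
species is exempt from inactivation by default (`protect_reference`): it
stands for a fully curated genome whose members are the naming anchors —
the analysis is undefined without reference members, just as the real study
presupposes its reference inventory.

**What the experiments show.** On 20 seeded default-condition families the
pooled fraction of non-reference genes assigned to their true group is
0.97 (68/70; regression bound frozen at ≥ 0.9). Datasets in which the
reference species lost all members (2 of 20 seeds) are skipped as
unanchorable. A gene is scored correct if it lands in the anchored group of
its true founder lineage, or — when that lineage has no reference member —
if it is given like/group-like status. The known failure mode is real and
instructive: a group that lost its reference anchor funnels its members
into the smallest supported clade that does contain an anchor, which is how
the rule behaves with sparse anchors; with a rich reference inventory
(14 named anchors in the real data) the minimal clades are small and the
effect vanishes. What these tests do **not** show: robustness to indels and
alignment error (no indels are simulated), rate heterogeneity across sites
(single rate class), or annotation noise in declared architectures.

## Numerical and degenerate-input choices

Poisson-corrected distances are clamped at 10 with a saturation flag; NJ
clamps negative intermediate branch lengths to zero; optimization bounds
are [1e-8, 50]; thresholds use strict `>` comparisons, so threshold 100
yields no supported clades (documented degenerate behavior). A
single-column alignment bootstrap is degenerate but defined (every
replicate resamples that column). Sequences are validated against the
20-letter alphabet plus X; `*` is stripped with a warning. Coordinates are
0-based half-open internally and 1-based inclusive in reports. The
two-taxon boundary cases of branch-length optimization (all sites
identical → lower bound; all sites different → upper bound) hold under the
equal-rates model; under empirical matrices an all-mismatch pair can have a
finite interior optimum, which is expected behavior, not an optimizer
failure.

Problem sizes used by the packaged experiments (tests and
`scripts/acceptance.py`): 20 seeds × (~4–10 genes, 300 columns, 100
bootstrap replicates) for the recovery experiment; 400 columns × 100
replicates for the bootstrap-certainty check; 20 replicates for the
byte-determinism check. These sizes are the package's chosen study scale;
all are parameters.

## Known limitations

* No rate heterogeneity by default. Discrete-gamma averaging (4
  equal-probability categories) is available as a flag on the likelihood
  evaluator for model exploration, but tree inference runs single-rate,
  since nothing in the source analysis specifies heterogeneity.
* The PSSM scanner is not a remote-homology detector; genuinely novel
  domains surface only as OTHER tokens via declared annotations.
* Strict consensus alignment discards signal on highly divergent data;
  k-of-n agreement is available when that trade-off is wrong for a
  dataset.
* The like-group numbering depends on leaf order, which is deterministic
  for a given tree but not biologically meaningful.
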
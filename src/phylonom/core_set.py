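"""Species x group conservation matrix, core set, and duplication report.

The conservation matrix counts, per species and ortholog group, how many
family members the species contributes to the group. The *core set* is the
list of groups present in every (non-outgroup) species — the hypothetical
minimum complement of the family — reported with each group's lowest copy
number across species. The duplication report lists, per species, the
groups it carries in two or more copies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .family_catalog import SpeciesRecord
from .nomenclature import OrthologGroup


@dataclass
class ConservationMatrix:
    """Counts per (group, species); outgroup species never appear."""

    species: list[str]
    groups: list[str]
    counts: pd.DataFrame                       # index: groups, columns: species
    isoform_labels: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def count(self, group: str, species: str) -> int:
        return int(self.counts.loc[group, species])

    def to_tsv(self, path: str | Path) -> None:
        """Render with '+' (single copy), '-' (absent), or isoform lists."""
        rendered = pd.DataFrame(index=self.groups, columns=self.species,
                                dtype=object)
        for g in self.groups:
            for s in self.species:
                c = self.count(g, s)
                if c == 0:
                    rendered.loc[g, s] = "-"
                elif c == 1:
                    rendered.loc[g, s] = "+"
                else:
                    labels = self.isoform_labels.get((g, s), [])
                    rendered.loc[g, s] = ", ".join(labels) if labels else str(c)
        rendered.index.name = "group"
        rendered.to_csv(path, sep="\t")


@dataclass
class CoreSetResult:
    groups: list[str]
    min_copies: dict[str, int]

    def __post_init__(self) -> None:
        bad = [g for g in self.groups if self.min_copies.get(g, 0) < 1]
        if bad:
            raise ValueError(f"core groups with zero minimum copies: {bad}")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"group": self.groups,
                           "min_copies": [self.min_copies[g] for g in self.groups]})
        df.to_csv(path, sep="\t", index=False)


def build_conservation_matrix(groups: list[OrthologGroup],
                              registry: list[SpeciesRecord],
                              names: dict[str, str] | None = None
                              ) -> ConservationMatrix:
    """Count group members per species; like/group-like groups included.

    ``names`` (record id -> proposed name) supplies isoform labels for
    multi-copy cells, e.g. "9.1, 9.2".
    """
    species = [s.code for s in registry if not s.is_outgroup]
    if not groups:
        return ConservationMatrix(species, [],
                                  pd.DataFrame(index=[], columns=species))
    row_names: list[str] = []
    for grp in groups:
        label = grp.anchor_name
        if grp.status == "group_like":
            label = f"{grp.anchor_name}-group-like"
        row_names.append(label)
    counts = pd.DataFrame(0, index=row_names, columns=species, dtype=int)
    labels: dict[tuple[str, str], list[str]] = {}
    for grp, row in zip(groups, row_names):
        for code, ids in grp.members.items():
            if code not in species:
                continue
            counts.loc[row, code] = len(ids)
            if len(ids) > 1 and names:
                iso = []
                for rid in ids:
                    name = names.get(rid, rid)
                    if name.startswith(code):
                        name = name[len(code):]
                    # published style: "9.1, 9.2", not "Deg9.1, Deg9.2"
                    short = re.sub(r"^[^0-9]*", "", name)
                    iso.append(short or name)
                labels[(row, code)] = iso
    return ConservationMatrix(species, row_names, counts, labels)


def compute_core_set(matrix: ConservationMatrix) -> CoreSetResult:
    """Groups with at least one member in every species, at the lowest copy
    number observed across species; order follows the matrix rows."""
    if not matrix.species:
        raise ValueError("conservation matrix has no species")
    core: list[str] = []
    minima: dict[str, int] = {}
    for g in matrix.groups:
        row = matrix.counts.loc[g]
        if (row >= 1).all():
            core.append(g)
            minima[g] = int(row.min())
    return CoreSetResult(core, minima)


def duplication_report(matrix: ConservationMatrix) -> dict[str, dict[str, int]]:
    """Per species, the groups present in two or more copies."""
    out: dict[str, dict[str, int]] = {}
    for s in matrix.species:
        multi = {g: int(matrix.counts.loc[g, s]) for g in matrix.groups
                 if matrix.counts.loc[g, s] >= 2}
        out[s] = multi
    return out
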
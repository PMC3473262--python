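"""Species registries, protein catalogs, and FASTA I/O.

A *catalog* is the tabular inventory of candidate family members for one or
more species: gene-model identifier, species, protein length, declared
domain architecture, activity state, prior names, and (where a published
inventory provides them) ortholog-group assignments. Bundled fixtures under
``phylonom/data`` encode the published Deg/HtrA inventories for
*A. thaliana* (At), *P. trichocarpa* (Pt), *O. sativa* (Os),
*P. patens* (Pp) and *C. reinhardtii* (Cr), plus the cyanobacterial
outgroup species entry.

Coordinates are 0-based half-open internally; human-readable reports use
1-based inclusive positions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from ._aa import AMINO_ACIDS

logger = logging.getLogger(__name__)

_ALLOWED = set(AMINO_ACIDS) | {"X"}

CATALOG_COLUMNS = [
    "id", "species", "length_aa", "architecture", "established_name",
    "prior_names", "group", "group_status", "proposed_name",
    "active", "activity_reason", "not_family",
]
REGISTRY_COLUMNS = ["code", "name", "is_outgroup", "is_reference_anchor"]


@dataclass
class SpeciesRecord:
    code: str
    name: str
    is_outgroup: bool = False
    is_reference_anchor: bool = False


@dataclass
class ProteinRecord:
    """One candidate family member."""

    id: str
    species_code: str
    length_aa: int
    sequence: str = ""
    prior_names: list[str] = field(default_factory=list)
    declared_architecture: "object | None" = None  # domain_annotation.Architecture
    declared_activity: bool | None = None
    activity_reason: str = ""
    not_family_flag: bool = False
    established_name: str = ""
    declared_group: str = ""
    declared_group_status: str = ""
    proposed_name: str = ""

    def __post_init__(self) -> None:
        if self.length_aa < 0:
            raise ValueError(f"{self.id}: negative length")
        if self.sequence and len(self.sequence) != self.length_aa:
            raise ValueError(
                f"{self.id}: length_aa {self.length_aa} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass
class Catalog:
    registry: list[SpeciesRecord]
    records: list[ProteinRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.registry:
            raise ValueError("registry must contain at least one species")
        codes = [s.code for s in self.registry]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate species codes in registry")
        anchors = [s.code for s in self.registry if s.is_reference_anchor]
        if len(anchors) > 1:
            raise ValueError(f"multiple reference-anchor species: {anchors}")
        if not self.records:
            raise ValueError("catalog must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if rec.species_code not in codes:
                raise ValueError(
                    f"record {rec.id!r}: unknown species code {rec.species_code!r}"
                )

    @property
    def reference_species(self) -> str | None:
        for s in self.registry:
            if s.is_reference_anchor:
                return s.code
        return None

    def by_species(self, code: str) -> list[ProteinRecord]:
        return [r for r in self.records if r.species_code == code]

    def get(self, record_id: str) -> ProteinRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("1", "true", "yes", "y")


def load_registry(path: str | Path) -> list[SpeciesRecord]:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t", restval="")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty registry file")
        missing = set(REGISTRY_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: registry missing columns {sorted(missing)}")
        out = [
            SpeciesRecord(
                code=row["code"].strip(),
                name=row["name"].strip(),
                is_outgroup=_parse_bool(row["is_outgroup"]),
                is_reference_anchor=_parse_bool(row["is_reference_anchor"]),
            )
            for row in reader
        ]
    if not out:
        raise ValueError(f"{path}: registry has no species rows")
    return out


def load_catalog(path: str | Path, registry_path: str | Path) -> Catalog:
    """Read a tab-separated catalog plus its species registry.

    Declared architecture strings are parsed into token lists; rows flagged
    as not belonging to the family are retained but marked.
    """
    from .domain_annotation import parse_architecture

    registry = load_registry(registry_path)
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t", restval="")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty catalog file")
        missing = set(CATALOG_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: catalog missing columns {sorted(missing)}")
        for row in reader:
            arch_text = row["architecture"].strip()
            active_text = row["active"].strip().lower()
            records.append(ProteinRecord(
                id=row["id"].strip(),
                species_code=row["species"].strip(),
                length_aa=int(row["length_aa"]),
                prior_names=[p for p in row["prior_names"].split(";") if p],
                declared_architecture=(
                    parse_architecture(arch_text) if arch_text else None
                ),
                declared_activity=(
                    None if active_text == "" else active_text in ("yes", "true", "1")
                ),
                activity_reason=row["activity_reason"].strip(),
                not_family_flag=_parse_bool(row["not_family"]),
                established_name=row["established_name"].strip(),
                declared_group=row["group"].strip(),
                declared_group_status=row["group_status"].strip(),
                proposed_name=row["proposed_name"].strip(),
            ))
    if not records:
        raise ValueError(f"{path}: catalog has no records")
    return Catalog(registry=registry, records=records, provenance=str(path))


def save_catalog(catalog: Catalog, path: str | Path,
                 registry_path: str | Path | None = None) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CATALOG_COLUMNS)
        for r in catalog.records:
            writer.writerow([
                r.id, r.species_code, r.length_aa,
                str(r.declared_architecture) if r.declared_architecture else "",
                r.established_name, ";".join(r.prior_names),
                r.declared_group, r.declared_group_status, r.proposed_name,
                "" if r.declared_activity is None
                else ("yes" if r.declared_activity else "no"),
                r.activity_reason,
                "yes" if r.not_family_flag else "",
            ])
    if registry_path is not None:
        save_registry(catalog.registry, registry_path)


def save_registry(registry: Iterable[SpeciesRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REGISTRY_COLUMNS)
        for s in registry:
            writer.writerow([
                s.code, s.name,
                "yes" if s.is_outgroup else "",
                "yes" if s.is_reference_anchor else "",
            ])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path, allow_gaps: bool = False) -> dict[str, str]:
    """Strict FASTA reader: id = first whitespace token of the header.

    Sequences are upper-cased; ``*`` is stripped with a warning; characters
    outside the amino-acid alphabet plus X (and ``-`` when ``allow_gaps``)
    raise with the offending line number, as do duplicate header tokens and
    structurally malformed input.
    """
    path = Path(path)
    out: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    allowed = _ALLOWED | ({"-"} if allow_gaps else set())
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    out[current] = "".join(chunks)
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                token = header.split()[0]
                if token in out:
                    raise ValueError(f"{path}:{lineno}: duplicate FASTA id {token!r}")
                current, chunks = token, []
            else:
                if current is None:
                    raise ValueError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                seq = line.upper()
                if "*" in seq:
                    logger.warning("%s:%d: stripping '*' from sequence %s",
                                   path, lineno, current)
                    seq = seq.replace("*", "")
                bad = set(seq) - allowed
                if bad:
                    raise ValueError(
                        f"{path}:{lineno}: invalid characters {sorted(bad)!r} "
                        f"in sequence {current!r}"
                    )
                chunks.append(seq)
        if current is not None:
            out[current] = "".join(chunks)
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=rid, description="")
               for rid, seq in sequences.items()]
    with open(path, "w", encoding="utf-8") as fh:
        seqio_write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Consistency checks
# ---------------------------------------------------------------------------

@dataclass
class Discrepancy:
    kind: str          # "missing_in_fasta" | "missing_in_catalog" | "length_mismatch"
    record_id: str
    detail: str


def cross_validate(catalog: Catalog, sequences: Mapping[str, str]
                   ) -> list[Discrepancy]:
    """Report ids present in only one source and length mismatches.

    An empty list means the two sources are consistent.
    """
    out: list[Discrepancy] = []
    catalog_ids = {r.id for r in catalog.records}
    for rec in catalog.records:
        if rec.id not in sequences:
            out.append(Discrepancy("missing_in_fasta", rec.id,
                                   "catalog record has no sequence"))
            continue
        seq_len = len(sequences[rec.id])
        if rec.length_aa and seq_len != rec.length_aa:
            out.append(Discrepancy(
                "length_mismatch", rec.id,
                f"catalog length_aa {rec.length_aa} vs sequence length {seq_len}"))
    for rid in sequences:
        if rid not in catalog_ids:
            out.append(Discrepancy("missing_in_catalog", rid,
                                   "sequence id absent from catalog"))
    return out


# ---------------------------------------------------------------------------
# Bundled fixtures (published inventory tables)
# ---------------------------------------------------------------------------

_SPECIES_FILES = {
    "At": "catalog_at.tsv",
    "Pt": "catalog_pt.tsv",
    "Os": "catalog_os.tsv",
    "Pp": "catalog_pp.tsv",
    "Cr": "catalog_cr.tsv",
}


def _data_path(name: str):
    return resources.files("phylonom").joinpath("data").joinpath(name)


def load_bundled_registry() -> list[SpeciesRecord]:
    with resources.as_file(_data_path("registry.tsv")) as p:
        return load_registry(p)


def load_bundled_catalog(species_code: str) -> Catalog:
    """Catalog fixture for one species (At, Pt, Os, Pp or Cr)."""
    try:
        fname = _SPECIES_FILES[species_code]
    except KeyError:
        raise KeyError(f"no bundled catalog for species {species_code!r}")
    with resources.as_file(_data_path(fname)) as p, \
         resources.as_file(_data_path("registry.tsv")) as rp:
        return load_catalog(p, rp)


def load_bundled_inventory() -> Catalog:
    """All five species catalogs merged over the shared registry."""
    registry = load_bundled_registry()
    records: list[ProteinRecord] = []
    for code in _SPECIES_FILES:
        records.extend(load_bundled_catalog(code).records)
    return Catalog(registry=registry, records=records,
                   provenance="bundled inventory fixtures")
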
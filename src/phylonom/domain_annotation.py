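"""Domain architectures, catalytic-triad state, and eligibility filters.

The family's members are annotated with an N-to-C ordered list of domain
tokens (``PD`` protease domain, ``PD_ia`` degenerated/inactive protease
domain, ``PDZ``, ``NT`` N-terminal extension, or a free ``OTHER`` label such
as a glycan-hydrolase fusion) and with the state of the His-Asp-Ser
catalytic triad. Only members with a complete protease domain and an intact
triad are eligible for the phylogenetic analysis; the others are retained in
the inventory but excluded from the tree.

Domain detection is a position-specific score-matrix (PSSM) scan over
bundled seed profiles. External annotations (the catalog's declared
architecture and activity columns) take precedence over detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._aa import AA_INDEX, AMINO_ACIDS, MISSING_CODE, encode
from .family_catalog import ProteinRecord

# machine-readable ineligibility codes
TRUNCATED_PD = "TRUNCATED_PD"
MISSING_TRIAD_RESIDUE = "MISSING_TRIAD_RESIDUE"
NO_PD_DETECTED = "NO_PD_DETECTED"
NOT_FAMILY_FLAG = "NOT_FAMILY_FLAG"


# ---------------------------------------------------------------------------
# Domain kinds and architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainKind:
    """A domain token; the token set is closed except OTHER."""

    token: str
    label: str = ""

    def __str__(self) -> str:
        return self.label if self.token == "OTHER" else self.token


PD = DomainKind("PD")
PD_IA = DomainKind("PD_ia")
PDZ = DomainKind("PDZ")
NT = DomainKind("NT")

_KNOWN = {"PD": PD, "PD_IA": PD_IA, "PDZ": PDZ, "NT": NT}


def other(label: str) -> DomainKind:
    return DomainKind("OTHER", label)


@dataclass(frozen=True)
class Architecture:
    """Ordered domain tokens, N- to C-terminal; string form uses '-'."""

    tokens: tuple[DomainKind, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("architecture must contain at least one domain")

    def __str__(self) -> str:
        return "-".join(str(t) for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def parse_architecture(text: str) -> Architecture:
    """Parse a domain-arrangement string like ``PD-PDZ-PDZ-PD_ia-PDZ-PDZ``.

    Spacing and trailing-underscore variants of ``PD_ia`` are normalized;
    unknown tokens become OTHER with their label preserved.
    """
    if not text or not text.strip():
        raise ValueError("empty architecture string")
    tokens: list[DomainKind] = []
    for raw in text.split("-"):
        tok = raw.strip().strip("_")
        if not tok:
            continue
        kind = _KNOWN.get(tok.upper().replace(" ", ""))
        tokens.append(kind if kind is not None else other(tok))
    if not tokens:
        raise ValueError(f"no domain tokens in {text!r}")
    return Architecture(tuple(tokens))


def count_domains(architecture: Architecture, kind: DomainKind) -> int:
    return sum(1 for t in architecture.tokens if t == kind)


# ---------------------------------------------------------------------------
# Triad status
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriadStatus:
    has_his: bool
    has_asp: bool
    has_ser: bool
    positions: tuple[int, int, int] | None = None

    @property
    def complete(self) -> bool:
        return self.has_his and self.has_asp and self.has_ser


# ---------------------------------------------------------------------------
# Profiles and PSSM scanning
# ---------------------------------------------------------------------------

@dataclass
class DomainProfile:
    """PSSM over the amino-acid alphabet with an acceptance threshold.

    ``score_threshold`` is the full-coverage acceptance score, prorated by
    coverage for partial (terminal) hits; it is set as a fraction of the
    consensus self-score, calibrated so that scanning shuffled sequences
    yields a false-positive rate of at most 1%.
    ``triad_anchor_offsets`` (PD profiles only) are the profile positions of
    the catalytic His, Asp and Ser.
    """

    kind: DomainKind
    pssm: np.ndarray                      # (length, 21): 20 residues + X=0
    score_threshold: float
    triad_anchor_offsets: tuple[int, int, int] | None = None
    name: str = ""

    @property
    def length(self) -> int:
        return self.pssm.shape[0]


@dataclass(frozen=True)
class DomainHit:
    kind: DomainKind
    start: int                # half-open span on the sequence
    end: int
    score: float
    profile_start: int        # first profile position covered by the span
    profile: DomainProfile | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def build_profile(kind: DomainKind, seed_sequences: list[str],
                  threshold_factor: float = 0.55,
                  triad_anchor_offsets: tuple[int, int, int] | None = None,
                  name: str = "") -> DomainProfile:
    """PSSM (log2 odds vs uniform background, pseudocount 0.5) from equal
    length ungapped seed sequences; threshold = factor x consensus score."""
    lengths = {len(s) for s in seed_sequences}
    if len(lengths) != 1:
        raise ValueError("seed sequences must share one length")
    w = lengths.pop()
    n = len(seed_sequences)
    counts = np.zeros((w, 20))
    for seq in seed_sequences:
        codes = encode(seq)
        for k, c in enumerate(codes):
            if c < MISSING_CODE:
                counts[k, c] += 1
    freqs = (counts + 0.5) / (n + 10.0)
    pssm = np.zeros((w, 21))
    pssm[:, :20] = np.log2(freqs / 0.05)
    self_score = float(pssm[np.arange(w), counts.argmax(axis=1)].sum())
    return DomainProfile(kind=kind, pssm=pssm,
                         score_threshold=threshold_factor * self_score,
                         triad_anchor_offsets=triad_anchor_offsets,
                         name=name or str(kind))


# Seed alignments for the two scanned domain types. The protease-domain seed
# carries the catalytic triad (His, Asp in the HD motif, Ser in the GDSGG
# motif) at fixed offsets; seeds are the consensus plus fixed substitution
# variants at non-anchor positions.
_PD_CONSENSUS = (
    "LGSGVVVSKDGHIVTNNHVI"
    "AGADKITVTLHDGREFDAKV"
    "VGSDPRSDIALIQLGDSGGP"
)
PD_TRIAD_OFFSETS = (17, 31, 56)
_PD_VARIANTS = [
    {0: "I", 13: "I", 24: "R", 38: "R", 50: "V"},
    {4: "I", 21: "S", 33: "K", 45: "K", 53: "I"},
    {7: "A", 15: "S", 27: "I", 41: "A", 58: "A"},
    {2: "T", 19: "L", 36: "E", 44: "A", 52: "R"},
]

_PDZ_CONSENSUS = "RVVEVAPGSPAERAGLKAGDVILAVNGKPVKSAEELRNLI"
_PDZ_VARIANTS = [
    {1: "I", 11: "D", 23: "S", 33: "D"},
    {3: "Q", 14: "S", 27: "E", 37: "K"},
    {6: "A", 18: "S", 29: "I", 38: "V"},
]


def _apply_variants(consensus: str, variants: list[dict[int, str]]) -> list[str]:
    seeds = [consensus]
    for sub in variants:
        chars = list(consensus)
        for pos, res in sub.items():
            chars[pos] = res
        seeds.append("".join(chars))
    return seeds


def pd_consensus() -> str:
    """The protease-domain seed consensus (triad intact)."""
    return _PD_CONSENSUS


def pdz_consensus() -> str:
    return _PDZ_CONSENSUS


def default_profiles() -> list[DomainProfile]:
    """The bundled PD and PDZ scan profiles."""
    return [
        build_profile(PD, _apply_variants(_PD_CONSENSUS, _PD_VARIANTS),
                      triad_anchor_offsets=PD_TRIAD_OFFSETS, name="PD"),
        build_profile(PDZ, _apply_variants(_PDZ_CONSENSUS, _PDZ_VARIANTS),
                      name="PDZ"),
    ]


def detect_domains(sequence: str, profiles: list[DomainProfile],
                   min_coverage: float = 0.5) -> list[DomainHit]:
    """Scan a sequence with every profile; greedy non-overlapping hits.

    Hits may hang over either sequence end (a truncated domain); the
    acceptance score is prorated by the covered fraction of the profile,
    and hits must cover at least ``min_coverage`` of it. Hits are selected
    greedily by descending score and reported sorted by start.
    """
    if not profiles:
        raise ValueError("empty profile list")
    codes = encode(sequence)
    n = len(codes)
    candidates: list[DomainHit] = []
    for prof in profiles:
        w = prof.length
        min_cov = max(1, int(np.ceil(min_coverage * w)))
        scores_by_pos = prof.pssm[:, codes]          # (w, n)
        for off in range(-(w - min_cov), n - min_cov + 1):
            k0 = max(0, -off)
            k1 = min(w, n - off)
            if k1 - k0 < min_cov:
                continue
            ks = np.arange(k0, k1)
            score = float(scores_by_pos[ks, off + ks].sum())
            coverage = (k1 - k0) / w
            if score >= prof.score_threshold * coverage:
                candidates.append(DomainHit(
                    kind=prof.kind, start=off + k0, end=off + k1,
                    score=score, profile_start=k0, profile=prof))
    candidates.sort(key=lambda h: (-h.score, h.start))
    chosen: list[DomainHit] = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda h: h.start)
    return chosen


def check_triad(sequence: str, pd_span: tuple[int, int] | DomainHit,
                profile: DomainProfile, window: int = 3) -> TriadStatus:
    """Catalytic-triad state of a protease-domain hit.

    Each of His/Asp/Ser must occur within ±``window`` residues of its
    anchored profile position, projected onto the sequence.
    """
    if profile.triad_anchor_offsets is None:
        raise ValueError("profile has no triad anchors (not a PD profile)")
    if isinstance(pd_span, DomainHit):
        start, end = pd_span.span
        profile_start = pd_span.profile_start
    else:
        start, end = pd_span
        profile_start = 0
    if start < 0 or end > len(sequence) or start >= end:
        raise ValueError(f"span ({start}, {end}) outside sequence of length "
                         f"{len(sequence)}")
    flags: list[bool] = []
    positions: list[int] = []
    for anchor, expected in zip(profile.triad_anchor_offsets, "HDS"):
        pos = start + (anchor - profile_start)
        lo = max(start, pos - window)
        hi = min(end, pos + window + 1)
        found = sequence.find(expected, lo, hi) if lo < hi else -1
        flags.append(found >= 0)
        positions.append(found)
    status = TriadStatus(*flags)
    if status.complete:
        status = TriadStatus(*flags, positions=tuple(positions))
    return status


def annotate_architecture(sequence: str,
                          profiles: list[DomainProfile] | None = None,
                          min_coverage: float = 0.5) -> Architecture:
    """Architecture from detected hits; PD hits with an incomplete triad or
    truncated coverage are labeled PD_ia."""
    profiles = profiles if profiles is not None else default_profiles()
    hits = detect_domains(sequence, profiles, min_coverage=min_coverage)
    if not hits:
        raise ValueError("no domains detected")
    tokens: list[DomainKind] = []
    for hit in hits:
        if hit.kind == PD:
            triad = check_triad(sequence, hit, hit.profile)
            coverage = (hit.end - hit.start) / hit.profile.length
            tokens.append(PD if triad.complete and coverage >= 0.6 else PD_IA)
        else:
            tokens.append(hit.kind)
    return Architecture(tuple(tokens))


# ---------------------------------------------------------------------------
# Eligibility for phylogenetic analysis
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    eligible: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.eligible != (not self.reasons):
            raise ValueError("eligible flag inconsistent with reasons")


def validate_entry(record: ProteinRecord,
                   hits: list[DomainHit] | None = None,
                   truncation_threshold: float = 0.6,
                   triad_window: int = 3) -> ValidationResult:
    """Eligibility of one record for the protease-domain phylogeny.

    Members lacking the catalytic triad or with an incomplete protease
    domain are ineligible, as are records the catalog flags as outside the
    family. Declared catalog annotations take precedence over detected hits.
    """
    reasons: list[str] = []
    if record.not_family_flag:
        reasons.append(NOT_FAMILY_FLAG)

    declared = (record.declared_activity is not None
                or record.declared_architecture is not None)
    if declared:
        if record.declared_activity is False:
            code = record.activity_reason or MISSING_TRIAD_RESIDUE
            if code not in (TRUNCATED_PD, MISSING_TRIAD_RESIDUE):
                code = MISSING_TRIAD_RESIDUE
            reasons.append(code)
        arch = record.declared_architecture
        if arch is not None:
            n_pd = count_domains(arch, PD)
            n_pd_ia = count_domains(arch, PD_IA)
            if n_pd == 0 and n_pd_ia == 0:
                reasons.append(NO_PD_DETECTED)
            elif n_pd == 0 and record.declared_activity is None:
                # only degenerated protease domains declared
                reasons.append(MISSING_TRIAD_RESIDUE)
    else:
        if hits is None:
            if not record.sequence:
                raise ValueError(
                    f"{record.id}: neither detected hits nor declared "
                    "annotations available")
            hits = detect_domains(record.sequence, default_profiles())
        pd_hits = [h for h in hits if h.kind in (PD, PD_IA)]
        if not pd_hits:
            reasons.append(NO_PD_DETECTED)
        else:
            best = max(pd_hits, key=lambda h: h.score)
            coverage = (best.end - best.start) / best.profile.length
            if coverage < truncation_threshold:
                reasons.append(TRUNCATED_PD)
            triad = check_triad(record.sequence, best, best.profile,
                                window=triad_window)
            if not triad.complete:
                reasons.append(MISSING_TRIAD_RESIDUE)

    # deduplicate, preserving order
    seen: set[str] = set()
    reasons = [r for r in reasons if not (r in seen or seen.add(r))]
    return ValidationResult(eligible=not reasons, reasons=reasons)


def validate_catalog(catalog, **kwargs) -> dict[str, ValidationResult]:
    """validate_entry over every catalog record, keyed by record id."""
    return {rec.id: validate_entry(rec, **kwargs) for rec in catalog.records}
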
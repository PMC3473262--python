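"""Multiple alignment of protease-domain sequences.

The alignment stage mirrors the consensus design of the original analysis:
the same progressive aligner is run under at least two parameterizations
(different substitution matrices / gap penalties), the runs are merged by
strict column agreement (``consensus_merge``), and gapped columns are then
stripped. Long single-residue repeats, which degrade alignment quality, are
masked to X beforehand.

Gap cost convention: a gap run of length k costs ``open + k * extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._aa import AA_INDEX, AMINO_ACIDS, MISSING_CODE, encode
from .family_catalog import load_fasta
from .phylogeny import DistanceMatrix, Node, PhyloTree, neighbor_joining

_GAP = "-"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMatrix:
    """Symmetric 20x20 integer residue-pair scores; X scores 0 everywhere."""

    scores: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("scores must be a symmetric 20x20 table")
        if (np.diag(s) <= 0).any():
            raise ValueError("diagonal scores must be positive")
        # pad to 21x21 so the X code (20) scores 0 against everything
        padded = np.zeros((21, 21))
        padded[:20, :20] = s
        self.scores = padded

    @classmethod
    def load(cls, name: str) -> "SubstitutionMatrix":
        """A named matrix from Biopython's collection (e.g. BLOSUM62)."""
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load(name)
        idx = [mat.alphabet.index(a) for a in AMINO_ACIDS]
        arr = np.asarray(mat)[np.ix_(idx, idx)]
        return cls(arr, name=name)


def blosum62() -> SubstitutionMatrix:
    return SubstitutionMatrix.load("BLOSUM62")


def blosum45() -> SubstitutionMatrix:
    return SubstitutionMatrix.load("BLOSUM45")


@dataclass
class GapPenalties:
    open: float = 11.0
    extend: float = 1.0

    def __post_init__(self) -> None:
        if self.open < 0 or self.extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.open < self.extend:
            raise ValueError("gap open penalty must be >= extend penalty")


# ---------------------------------------------------------------------------
# Alignment containers
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)].replace(_GAP, "")

    def sequences(self) -> dict[str, str]:
        return {rid: self.degapped(rid) for rid in self.ids}

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    # -- I/O ----------------------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n")
                for k in range(0, len(row), 60):
                    fh.write(row[k:k + 60] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MultipleAlignment":
        mapping = load_fasta(path, allow_gaps=True)
        return cls(list(mapping), list(mapping.values()))

    def to_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP (name, two spaces, full sequence)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)} {self.n_columns}\n")
            for rid, row in zip(self.ids, self.rows):
                fh.write(f"{rid}  {row}\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "MultipleAlignment":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed PHYLIP header")
            n, ncol = int(header[0]), int(header[1])
            ids, rows = [], []
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                ids.append(name)
                rows.append(seq.replace(" ", "").strip())
        if len(ids) != n or any(len(r) != ncol for r in rows):
            raise ValueError(f"{path}: PHYLIP body does not match header")
        return cls(ids, rows)


@dataclass
class PairwiseAlignment:
    a: str
    b: str
    score: float


# ---------------------------------------------------------------------------
# Low-complexity masking
# ---------------------------------------------------------------------------

def mask_low_complexity(sequence: str, min_run: int = 10) -> str:
    """Replace maximal single-residue runs of length >= min_run with X.

    Long (10-20 aa) single-residue repeats degrade alignment quality; X is
    marginalized by all downstream computations.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    out: list[str] = []
    i, n = 0, len(sequence)
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        run = j - i
        out.append("X" * run if run >= min_run and sequence[i] != _GAP else
                   sequence[i:j])
        i = j
    return "".join(out)


# ---------------------------------------------------------------------------
# Core affine-gap DP (Gotoh), shared by the pairwise and profile aligners
# ---------------------------------------------------------------------------

_NEG = -1e30


def _gotoh(scores: np.ndarray, g: GapPenalties
           ) -> tuple[list[tuple[int | None, int | None]], float]:
    """Global alignment over a precomputed (la x lb) column-score matrix.

    Returns the aligned index path [(i or None, j or None), ...] and the
    optimal score. Deterministic tie-break: match > gap-in-b > gap-in-a,
    applied both to state selection and within-state transitions.
    """
    la, lb = scores.shape
    first = g.open + g.extend
    e = g.extend
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)   # gap in b (consumes a)
    Y = np.full((la + 1, lb + 1), _NEG)   # gap in a (consumes b)
    M[0, 0] = 0.0
    X[1:, 0] = -(g.open + np.arange(1, la + 1) * e)
    Y[0, 1:] = -(g.open + np.arange(1, lb + 1) * e)
    # row-wise DP: M and X depend on the previous row only; the within-row
    # Y recurrence Y[j] = max(B[j-1], Y[j-1]-e) with B = max(M, X) - open-e
    # is a decaying running maximum, done with maximum.accumulate
    decay = e * np.arange(lb)
    for i in range(1, la + 1):
        M[i, 1:] = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]),
                              Y[i - 1, :-1]) + scores[i - 1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] - first,
                              np.maximum(X[i - 1, 1:] - e,
                                         Y[i - 1, 1:] - first))
        B = np.maximum(M[i, :-1], X[i, :-1]) - first
        Y[i, 1:] = np.maximum.accumulate(B + decay) - decay
    # traceback, preferring M > X > Y throughout
    i, j = la, lb
    state = max(("M", "X", "Y"),
                key=lambda s: ({"M": M, "X": X, "Y": Y}[s][i, j],
                               {"M": 2, "X": 1, "Y": 0}[s]))
    best = {"M": M, "X": X, "Y": Y}[state][i, j]
    path: list[tuple[int | None, int | None]] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            prev = M[i - 1, j - 1] + scores[i - 1, j - 1]
            for cand, val in (("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]),
                              ("Y", Y[i - 1, j - 1])):
                if abs(val + scores[i - 1, j - 1] - M[i, j]) < tol:
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            path.append((i - 1, None))
            cur = X[i, j]
            if i == 1 and j == 0:
                state = "M"
            elif abs(M[i - 1, j] - first - cur) < tol:
                state = "M"
            elif abs(X[i - 1, j] - g.extend - cur) < tol:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            path.append((None, j - 1))
            cur = Y[i, j]
            if j == 1 and i == 0:
                state = "M"
            elif abs(M[i, j - 1] - first - cur) < tol:
                state = "M"
            elif abs(Y[i, j - 1] - g.extend - cur) < tol:
                state = "Y"
            else:
                state = "X"
            j -= 1
    path.reverse()
    return path, float(best)


def global_affine_align(a: str, b: str, m: SubstitutionMatrix | None = None,
                        g: GapPenalties | None = None) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps.

    Score = sum of residue-pair scores minus sum of gap-run costs, where a
    run of length k costs open + k*extend. X scores 0 against everything.
    """
    m = m if m is not None else blosum62()
    g = g if g is not None else GapPenalties()
    if not a and not b:
        return PairwiseAlignment("", "", 0.0)
    if not a or not b:
        n = len(a or b)
        cost = -(g.open + n * g.extend)
        return PairwiseAlignment(a or _GAP * n, b or _GAP * n, cost)
    ca, cb = encode(a), encode(b)
    scores = m.scores[np.ix_(ca, cb)]
    path, score = _gotoh(scores, g)
    row_a = "".join(a[i] if i is not None else _GAP for i, _ in path)
    row_b = "".join(b[j] if j is not None else _GAP for _, j in path)
    return PairwiseAlignment(row_a, row_b, score)


# ---------------------------------------------------------------------------
# Guide tree and progressive alignment
# ---------------------------------------------------------------------------

def _identity_distance(a: str, b: str, m: SubstitutionMatrix,
                       g: GapPenalties) -> float:
    aln = global_affine_align(a, b, m, g)
    matches = comparable = 0
    for x, y in zip(aln.a, aln.b):
        if x != _GAP and y != _GAP:
            comparable += 1
            if x == y:
                matches += 1
    if comparable == 0:
        return 1.0
    return 1.0 - matches / comparable


def build_guide_tree(sequences: Mapping[str, str],
                     m: SubstitutionMatrix | None = None,
                     g: GapPenalties | None = None) -> PhyloTree:
    """NJ guide tree on d = 1 - identity over aligned non-gap pairs."""
    m = m if m is not None else blosum62()
    g = g if g is not None else GapPenalties()
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences for a guide tree")
    if len(ids) == 2:
        root = Node()
        root.add(Node(ids[0], 0.5))
        root.add(Node(ids[1], 0.5))
        return PhyloTree(root, rooted=True)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _identity_distance(
                sequences[ids[i]], sequences[ids[j]], m, g)
    return neighbor_joining(DistanceMatrix(ids, d))


def _profile_counts(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column canonical-residue counts (L x 20) and non-gap totals."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, 20))
    for row in rows:
        codes = np.frombuffer(row.encode(), dtype=np.uint8)
        for j in range(ncol):
            ch = chr(codes[j])
            if ch in AA_INDEX:
                counts[j, AA_INDEX[ch]] += 1
    totals = counts.sum(axis=1)
    return counts, totals


def _merge_profiles(ids_a: list[str], rows_a: list[str],
                    ids_b: list[str], rows_b: list[str],
                    m: SubstitutionMatrix, g: GapPenalties
                    ) -> tuple[list[str], list[str]]:
    ca, na = _profile_counts(rows_a)
    cb, nb = _profile_counts(rows_b)
    core = m.scores[:20, :20]
    pair = ca @ core @ cb.T
    denom = np.outer(na, nb)
    scores = np.divide(pair, denom, out=np.zeros_like(pair),
                       where=denom > 0)
    path, _ = _gotoh(scores, g)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for i, j in path:
        for k, row in enumerate(rows_a):
            out_a[k] += row[i] if i is not None else _GAP
        for k, row in enumerate(rows_b):
            out_b[k] += row[j] if j is not None else _GAP
    return ids_a + ids_b, out_a + out_b


def progressive_align(sequences: Mapping[str, str],
                      guide: PhyloTree | None = None,
                      m: SubstitutionMatrix | None = None,
                      g: GapPenalties | None = None) -> MultipleAlignment:
    """Profile-profile progressive alignment in guide-tree post-order.

    Column pairs are scored by the mean substitution score over non-gap
    residue pairs. De-gapping any output row reproduces its input sequence.
    """
    m = m if m is not None else blosum62()
    g = g if g is not None else GapPenalties()
    ids = list(sequences)
    if len(ids) == 1:
        return MultipleAlignment(ids, [sequences[ids[0]]])
    if guide is None:
        guide = build_guide_tree(sequences, m, g)
    if set(guide.leaf_names()) != set(ids):
        raise ValueError("guide-tree leaves do not match sequence ids")
    profiles: dict[int, tuple[list[str], list[str]]] = {}
    for node in guide.postorder():
        if node.is_leaf:
            profiles[id(node)] = ([node.name], [sequences[node.name]])
        else:
            acc_ids, acc_rows = profiles[id(node.children[0])]
            for child in node.children[1:]:
                cid, crows = profiles[id(child)]
                acc_ids, acc_rows = _merge_profiles(
                    acc_ids, acc_rows, cid, crows, m, g)
            profiles[id(node)] = (acc_ids, acc_rows)
    out_ids, out_rows = profiles[id(guide.root)]
    order = {rid: k for k, rid in enumerate(out_ids)}
    rows = [out_rows[order[rid]] for rid in ids]
    return MultipleAlignment(ids, rows)


# ---------------------------------------------------------------------------
# Consensus of multiple alignment runs
# ---------------------------------------------------------------------------

def _column_keys(aln: MultipleAlignment, id_order: list[str]
                 ) -> list[tuple[int | None, ...]]:
    """Each column as the tuple of per-row residue indices (None for gap);
    two columns are the same homology statement iff their keys are equal."""
    pos = {rid: 0 for rid in id_order}
    rows = {rid: aln.rows[aln.ids.index(rid)] for rid in id_order}
    keys: list[tuple[int | None, ...]] = []
    for j in range(aln.n_columns):
        key: list[int | None] = []
        for rid in id_order:
            ch = rows[rid][j]
            if ch == _GAP:
                key.append(None)
            else:
                key.append(pos[rid])
                pos[rid] += 1
        keys.append(tuple(key))
    return keys


def consensus_merge(alignments: Sequence[MultipleAlignment],
                    min_agreement: int | None = None) -> MultipleAlignment:
    """Columns on which every input run states the same homology.

    Automated surrogate for manual discrepancy resolution: a column is kept
    iff the identical residue-correspondence column occurs in every input
    alignment (``min_agreement`` relaxes this to k-of-n). Retained columns
    keep the order of the first alignment.
    """
    if not alignments:
        raise ValueError("no alignments to merge")
    id_order = sorted(alignments[0].ids)
    needed = min_agreement if min_agreement is not None else len(alignments)
    if not (1 <= needed <= len(alignments)):
        raise ValueError("min_agreement out of range")
    for aln in alignments[1:]:
        if sorted(aln.ids) != id_order:
            raise ValueError("alignments have different row sets")
        for rid in id_order:
            if aln.degapped(rid) != alignments[0].degapped(rid):
                raise ValueError(
                    f"row {rid!r} differs between alignments after de-gapping")
    counts: dict[tuple, int] = {}
    for aln in alignments:
        for key in set(_column_keys(aln, id_order)):
            counts[key] = counts.get(key, 0) + 1
    first_keys = _column_keys(alignments[0], id_order)
    kept = [j for j, key in enumerate(first_keys) if counts.get(key, 0) >= needed]
    if not kept:
        raise ValueError(
            "no columns agree across all alignment runs; relax min_agreement "
            "or revisit alignment parameters")
    rows = {rid: alignments[0].rows[alignments[0].ids.index(rid)]
            for rid in alignments[0].ids}
    return MultipleAlignment(
        list(alignments[0].ids),
        ["".join(rows[rid][j] for j in kept) for rid in alignments[0].ids])


def strip_gap_columns(aln: MultipleAlignment, max_gap_frac: float = 0.0
                      ) -> tuple[MultipleAlignment, list[int]]:
    """Drop columns whose gap fraction exceeds the threshold (default: any
    gap). Returns the stripped alignment and the kept-column index map."""
    n_rows = len(aln.rows)
    kept: list[int] = []
    for j in range(aln.n_columns):
        gaps = sum(1 for row in aln.rows if row[j] == _GAP)
        if gaps / n_rows <= max_gap_frac:
            kept.append(j)
    rows = ["".join(row[j] for j in kept) for row in aln.rows]
    return MultipleAlignment(list(aln.ids), rows), kept


def consensus_pipeline(sequences: Mapping[str, str],
                       parameterizations: Sequence[tuple[SubstitutionMatrix,
                                                         GapPenalties]] | None = None,
                       mask_min_run: int = 10,
                       max_gap_frac: float = 0.0,
                       min_agreement: int | None = None
                       ) -> MultipleAlignment:
    """Mask -> align under >= 2 parameterizations -> consensus -> strip."""
    masked = {rid: mask_low_complexity(seq, mask_min_run)
              for rid, seq in sequences.items()}
    if parameterizations is None:
        parameterizations = [
            (blosum62(), GapPenalties(11.0, 1.0)),
            (blosum45(), GapPenalties(13.0, 1.0)),
        ]
    runs = [progressive_align(masked, None, m, g)
            for m, g in parameterizations]
    merged = consensus_merge(runs, min_agreement=min_agreement)
    stripped, _ = strip_gap_columns(merged, max_gap_frac)
    if stripped.n_columns == 0:
        raise ValueError("no columns left after gap stripping")
    return stripped
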
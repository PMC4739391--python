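"""Pairwise and progressive multiple alignment, plus alignment-column statistics.

Pairwise global (Needleman–Wunsch/Gotoh) and local (Smith–Waterman) alignment
are computed with Bio.Align.PairwiseAligner; the progressive multiple
alignment is built in-repo: a neighbor-joining guide tree on pairwise
(1 - identity) distances, then profile–profile merges in guide-tree
postorder using an affine-gap dynamic program over column count profiles,
vectorised along anti-diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align as _BioAlign

from .phylo import neighbor_joining

__all__ = [
    "PairwiseAlignment",
    "MultipleAlignment",
    "global_align",
    "local_align",
    "progressive_msa",
    "count_variable_sites",
    "count_indel_sites",
    "count_gap_columns",
    "read_aligned_fasta",
    "write_aligned_fasta",
]

GAP = "-"

# symbol classes: A,C,G,T -> 0..3, any ambiguity code -> 4, gap -> 5
_CLASS = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CLASS[ord(_b)] = _i
    _CLASS[ord(_b.lower())] = _i
_CLASS[ord("-")] = 5


def _classes(s: str) -> np.ndarray:
    return _CLASS[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


@dataclass
class PairwiseAlignment:
    """Gapped alignment of two sequences.

    ``identity`` is the fraction of aligned (non-gap-pair) columns whose
    symbols are equal; ``coverage_a`` the fraction of a's residues that are
    paired with a residue of b.
    """

    gapped_a: str
    gapped_b: str
    score: float
    identity: float = field(init=False)
    coverage_a: float = field(init=False)

    def __post_init__(self):
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped rows must have equal length")
        a = np.frombuffer(self.gapped_a.encode(), dtype=np.uint8)
        b = np.frombuffer(self.gapped_b.encode(), dtype=np.uint8)
        gap = ord(GAP)
        paired = (a != gap) & (b != gap)
        self.identity = float((a[paired] == b[paired]).mean()) if paired.any() else 0.0
        na = int((a != gap).sum())
        self.coverage_a = float(paired.sum() / na) if na else 0.0

    @property
    def is_empty(self) -> bool:
        return not self.gapped_a


def _aligner(match, mismatch, gap_open, gap_extend, mode):
    al = _BioAlign.PairwiseAligner()
    al.mode = mode
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def global_align(a: str, b: str, match: float = 1, mismatch: float = -1,
                 gap_open: float = -5, gap_extend: float = -1) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two nucleotide sequences.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Among
    co-optimal alignments the engine's first traceback is returned, which is
    deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    a, b = a.upper(), b.upper()
    res = _aligner(match, mismatch, gap_open, gap_extend, "global").align(a, b)
    best = res[0]
    return PairwiseAlignment(str(best[0]), str(best[1]), float(best.score))


def local_align(a: str, b: str, match: float = 1, mismatch: float = -1,
                gap_open: float = -5, gap_extend: float = -1):
    """Optimal local (Smith–Waterman) alignment.

    Returns ``(alignment, a_span, b_span)`` where the spans are 0-based
    half-open coordinate ranges of the aligned block on the ungapped inputs.
    When no positive-scoring block exists the alignment is empty with score 0
    and spans ``(0, 0)``.
    """
    if not a or not b:
        return PairwiseAlignment("", "", 0.0), (0, 0), (0, 0)
    a, b = a.upper(), b.upper()
    res = _aligner(match, mismatch, gap_open, gap_extend, "local").align(a, b)
    if len(res) == 0:
        return PairwiseAlignment("", "", 0.0), (0, 0), (0, 0)
    best = res[0]
    blocks = best.aligned
    a_span = (int(blocks[0][0][0]), int(blocks[0][-1][1]))
    b_span = (int(blocks[1][0][0]), int(blocks[1][-1][1]))
    return (PairwiseAlignment(str(best[0]), str(best[1]), float(best.score)),
            a_span, b_span)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over an ordered set of accessions."""

    rows: list[str]
    row_ids: list[str]

    def __post_init__(self):
        if len(self.rows) != len(self.row_ids):
            raise ValueError("rows and row_ids must correspond 1:1")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValueError("all MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """(n_rows, n_columns) array of symbol classes."""
        return np.vstack([_classes(r) for r in self.rows])

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


# ---------------------------------------------------------------------------
# profile-profile affine DP (anti-diagonal vectorised Gotoh)

_NEG = -1e30


def _profile_counts(rows: list[str]) -> np.ndarray:
    """(L, 6) column counts over symbol classes."""
    mat = np.vstack([_classes(r) for r in rows])
    L = mat.shape[1]
    counts = np.zeros((L, 6))
    for k in range(6):
        counts[:, k] = (mat == k).sum(axis=0)
    return counts


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    match=1.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-1.0):
    """Merge two gapped profiles into one; returns the merged row list
    (rows of a first).  Column score is the expected residue-pair score,
    gaps/ambiguity scoring 0."""
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    na, nb = len(rows_a), len(rows_b)
    m, n = ca.shape[0], cb.shape[0]
    res_a = ca[:, :4].sum(axis=1)
    res_b = cb[:, :4].sum(axis=1)
    matchsum = ca[:, :4] @ cb[:, :4].T
    S = (match * matchsum + mismatch * (np.outer(res_a, res_b) - matchsum)) / (na * nb)

    go, ge = gap_open, gap_extend
    M = np.full((m + 1, n + 1), _NEG)
    E = np.full((m + 1, n + 1), _NEG)  # gap in A (consumes B column)
    F = np.full((m + 1, n + 1), _NEG)  # gap in B (consumes A column)
    TM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    TE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    TF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    j = np.arange(1, n + 1)
    E[0, 1:] = go + (j - 1) * ge
    TE[0, 2:] = 1
    i = np.arange(1, m + 1)
    F[1:, 0] = go + (i - 1) * ge
    TF[2:, 0] = 2

    for k in range(2, m + n + 1):
        lo = max(1, k - n)
        hi = min(m, k - 1)
        if lo > hi:
            continue
        ii = np.arange(lo, hi + 1)
        jj = k - ii
        # match state
        prev = np.stack([M[ii - 1, jj - 1], E[ii - 1, jj - 1], F[ii - 1, jj - 1]])
        tm = prev.argmax(axis=0)
        M[ii, jj] = S[ii - 1, jj - 1] + prev[tm, np.arange(len(ii))]
        TM[ii, jj] = tm
        # gap in A
        cand = np.stack([M[ii, jj - 1] + go, E[ii, jj - 1] + ge, F[ii, jj - 1] + go])
        te = cand.argmax(axis=0)
        E[ii, jj] = cand[te, np.arange(len(ii))]
        TE[ii, jj] = te
        # gap in B
        cand = np.stack([M[ii - 1, jj] + go, E[ii - 1, jj] + go, F[ii - 1, jj] + ge])
        tf = cand.argmax(axis=0)
        F[ii, jj] = cand[tf, np.arange(len(ii))]
        TF[ii, jj] = tf

    finals = (M[m, n], E[m, n], F[m, n])
    state = int(np.argmax(finals))
    ops = []
    ci, cj = m, n
    while ci > 0 or cj > 0:
        if state == 0:
            ops.append("D")
            state = int(TM[ci, cj])
            ci -= 1
            cj -= 1
        elif state == 1:
            ops.append("A")  # gap column in A rows
            state = int(TE[ci, cj])
            cj -= 1
        else:
            ops.append("B")
            state = int(TF[ci, cj])
            ci -= 1
    ops.reverse()

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    pa = pb = 0
    for op in ops:
        if op in ("D", "B"):
            for r, row in zip(out_a, rows_a):
                r.append(row[pa])
            pa += 1
        else:
            for r in out_a:
                r.append(GAP)
        if op in ("D", "A"):
            for r, row in zip(out_b, rows_b):
                r.append(row[pb])
            pb += 1
        else:
            for r in out_b:
                r.append(GAP)
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def progressive_msa(dataset, match: float = 1, mismatch: float = -1,
                    gap_open: float = -5, gap_extend: float = -1) -> MultipleAlignment:
    """Progressive multiple alignment of a locus dataset.

    Guide tree: neighbor joining on (1 - identity) of all pairwise global
    alignments.  Profiles are merged in guide-tree postorder; output row
    order equals input record order and all-gap columns are dropped.
    """
    records = list(dataset)
    n = len(records)
    if n < 2:
        raise ValueError("progressive_msa needs at least 2 records")
    seqs = [r.sequence for r in records]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa = global_align(seqs[i], seqs[j], match, mismatch, gap_open, gap_extend)
            d[i, j] = d[j, i] = 1.0 - pa.identity
    guide = neighbor_joining(d, [str(i) for i in range(n)])

    def merge(node):
        # returns (indices, gapped rows)
        if node.is_leaf:
            i = int(node.name)
            return [i], [seqs[i]]
        idx, rows = merge(node.children[0])
        for child in node.children[1:]:
            idx2, rows2 = merge(child)
            rows = _align_profiles(rows, rows2, match, mismatch, gap_open, gap_extend)
            idx = idx + idx2
        return idx, rows

    idx, rows = merge(guide)
    order = np.argsort(idx)
    rows = [rows[k] for k in order]
    # drop all-gap columns (possible after profile merges)
    mat = np.vstack([_classes(r) for r in rows])
    keep = (mat != 5).any(axis=0)
    if not keep.all():
        rows = ["".join(r[c] for c in np.nonzero(keep)[0]) for r in rows]
    return MultipleAlignment(rows=rows, row_ids=[r.accession_id for r in records])


# ---------------------------------------------------------------------------
# column statistics

def count_variable_sites(msa: MultipleAlignment) -> int:
    """Columns containing >= 2 distinct unambiguous bases (gaps and ambiguity
    codes are not states)."""
    mat = msa.matrix()
    var = 0
    for k in range(mat.shape[1]):
        col = mat[:, k]
        states = np.unique(col[col < 4])
        if states.size >= 2:
            var += 1
    return var


def count_indel_sites(msa: MultipleAlignment) -> int:
    """Number of distinct indel events: maximal gap runs, counted once per
    distinct (start, end) column interval regardless of how many rows share
    the run."""
    events = set()
    for row in msa.rows:
        start = None
        for k, ch in enumerate(row):
            if ch == GAP:
                if start is None:
                    start = k
            elif start is not None:
                events.add((start, k - 1))
                start = None
        if start is not None:
            events.add((start, len(row) - 1))
    return len(events)


def count_gap_columns(msa: MultipleAlignment) -> int:
    """Alternative indel measure: number of columns containing any gap."""
    mat = msa.matrix()
    return int((mat == 5).any(axis=0).sum())


# ---------------------------------------------------------------------------
# aligned-FASTA I/O

def write_aligned_fasta(msa: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.row_ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


def read_aligned_fasta(path) -> MultipleAlignment:
    ids, rows = [], []
    with open(path) as fh:
        cur = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                ids.append(line[1:].split()[0])
                cur = []
                rows.append(cur)
            else:
                cur.append(line.upper())
    return MultipleAlignment(rows=["".join(r) for r in rows], row_ids=ids)
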
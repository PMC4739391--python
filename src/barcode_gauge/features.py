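"""Species-diagnostic sequence features: homopolymer runs, perfect tandem
repeats, inverted segments, and fully diagnostic alignment columns.

All reported coordinates are 1-based inclusive on the ungapped sequence
(the "171-177 bp" convention); the BED writer converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import MultipleAlignment, local_align

__all__ = [
    "FeatureHit",
    "find_homopolymers",
    "find_tandem_repeats",
    "detect_inversion",
    "diagnostic_positions",
    "reverse_complement",
    "ungapped_to_gapped",
    "gapped_to_ungapped",
    "write_features_tsv",
    "write_features_bed",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class FeatureHit:
    kind: str  # "homopolymer" | "tandem_repeat" | "inversion"
    sequence_id: str
    start: int  # 1-based inclusive, ungapped coordinates
    end: int
    length: int
    motif: str | None = None  # repeat unit or run base
    copies: int | None = None
    identity: float | None = None  # inversions only
    reference_id: str | None = None  # inversions: sequence aligned against

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("require 1 <= start <= end")
        if self.end - self.start + 1 != self.length:
            raise ValueError("length must equal end - start + 1")


def find_homopolymers(seq: str, min_len: int = 6,
                      sequence_id: str = "") -> list[FeatureHit]:
    """Maximal single-base runs of length >= ``min_len``."""
    seq = seq.upper()
    hits = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] in "ACGT":
            hits.append(FeatureHit(
                kind="homopolymer", sequence_id=sequence_id,
                start=i + 1, end=j, length=j - i,
                motif=seq[i], copies=j - i))
        i = j
    return hits


def _min_period(s: str) -> int:
    """Smallest period of s (via the KMP failure function)."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[-1] if n else 0


def find_tandem_repeats(seq: str, unit_min: int = 3, unit_max: int = 10,
                        min_copies: int = 2, min_total: int = 12,
                        sequence_id: str = "") -> list[FeatureHit]:
    """Maximal perfect tandem arrays of a primitive unit in
    [``unit_min``, ``unit_max``] with at least ``min_copies`` full copies and
    total array length >= ``min_total``.

    Homopolymer arrays are excluded (that kind is reserved for
    :func:`find_homopolymers`); arrays whose primitive period is below
    ``unit_min`` are likewise not reported.  The unit is reported as it
    appears at the array start.
    """
    seq = seq.upper()
    n = len(seq)
    hits: dict[tuple[int, int], FeatureHit] = {}
    for u in range(unit_min, unit_max + 1):
        i = 0
        limit = n - u
        while i < limit:
            if seq[i] != seq[i + u]:
                i += 1
                continue
            run = i
            while run < limit and seq[run] == seq[run + u]:
                run += 1
            # seq[i : run + u] is periodic with period u and maximal
            region_start, region_end = i, run + u  # 0-based half-open
            region = seq[region_start:region_end]
            i = run + 1
            if _min_period(region) != u:
                continue  # reported at its primitive period (or excluded)
            if len(set(region)) == 1:
                continue  # homopolymer
            copies = len(region) // u
            if copies < min_copies or len(region) < min_total:
                continue
            key = (region_start, region_end)
            if key not in hits:
                hits[key] = FeatureHit(
                    kind="tandem_repeat", sequence_id=sequence_id,
                    start=region_start + 1, end=region_end,
                    length=len(region), motif=region[:u], copies=copies)
    return sorted(hits.values(), key=lambda h: (h.start, h.end))


def detect_inversion(query: str, reference: str, min_len: int = 50,
                     min_identity: float = 0.98, sequence_id: str = "",
                     reference_id: str = "", max_hits: int = 5,
                     **align_params) -> list[FeatureHit]:
    """Segments of ``query`` that align to ``reference`` better in
    reverse-complement orientation than forward.

    The reverse complement of the query is locally aligned against the
    reference; a block qualifies if it spans >= ``min_len`` query residues
    with identity >= ``min_identity`` and its score strictly exceeds the
    forward-strand local alignment of the same query segment.  Found segments
    are masked and the scan repeated, so multiple inversions can be reported.
    Coordinates are 1-based inclusive on the ungapped query.
    """
    query = query.upper()
    reference = reference.upper()
    work = query
    hits = []
    for _ in range(max_hits):
        rc = reverse_complement(work)
        aln, rc_span, _ = local_align(rc, reference, **align_params)
        if aln.is_empty:
            break
        core = _high_identity_core(aln.gapped_a, aln.gapped_b, min_identity)
        if core is None:
            break
        c0, c1, identity, core_score = core
        # rc residues covered by the trimmed columns, then back to query coords
        rc_start = rc_span[0] + sum(ch != "-" for ch in aln.gapped_a[:c0])
        rc_len = sum(ch != "-" for ch in aln.gapped_a[c0:c1])
        q_start = len(query) - (rc_start + rc_len)  # 0-based
        q_end = len(query) - rc_start  # half-open
        if rc_len < min_len or identity < min_identity:
            break
        fwd, _, _ = local_align(query[q_start:q_end], reference, **align_params)
        if fwd.score >= core_score:
            break
        hits.append(FeatureHit(
            kind="inversion", sequence_id=sequence_id,
            start=q_start + 1, end=q_end, length=q_end - q_start,
            identity=identity, reference_id=reference_id or None))
        work = work[:q_start] + "N" * (q_end - q_start) + work[q_end:]
    return sorted(hits, key=lambda h: (h.start, h.end))


def _high_identity_core(gapped_a: str, gapped_b: str, min_identity: float):
    """Trim a local alignment to the contiguous column range that maximises
    (matches - w * non-matches) with w chosen so a segment scores positive
    only above ``min_identity``; returns (col_start, col_end, identity,
    +1/-1 score of the range) or None."""
    w = (min_identity / (1.0 - min_identity)) if min_identity < 1 else 1e6
    best_sum = 0.0
    best = None
    run_sum = 0.0
    run_start = 0
    for k, (x, y) in enumerate(zip(gapped_a, gapped_b)):
        match = x == y and x != "-" and x in "ACGT"
        run_sum += 1.0 if match else -w
        if run_sum <= 0:
            run_sum = 0.0
            run_start = k + 1
            continue
        if run_sum > best_sum:
            best_sum = run_sum
            best = (run_start, k + 1)
    if best is None:
        return None
    c0, c1 = best
    cols = list(zip(gapped_a[c0:c1], gapped_b[c0:c1]))
    matches = sum(1 for x, y in cols if x == y and x != "-")
    aligned = sum(1 for x, y in cols if x != "-" and y != "-")
    identity = matches / aligned if aligned else 0.0
    score = sum(1.0 if (x == y and x != "-") else -1.0 for x, y in cols)
    return c0, c1, identity, score


def diagnostic_positions(msa: MultipleAlignment, species: list[str],
                         target: str) -> list[int]:
    """1-based MSA columns where the states (base or gap) carried by the
    target species are disjoint from those of every other accession."""
    if len(species) != len(msa.rows):
        raise ValueError("species labels must match MSA rows")
    t_rows = [r for r, s in zip(msa.rows, species) if s == target]
    o_rows = [r for r, s in zip(msa.rows, species) if s != target]
    if not t_rows:
        raise ValueError(f"no rows of target species {target!r}")
    cols = []
    for k in range(msa.n_columns):
        t_states = {r[k] for r in t_rows}
        o_states = {r[k] for r in o_rows}
        if not (t_states & o_states):
            cols.append(k + 1)
    return cols


# ---------------------------------------------------------------------------
# coordinate mapping between gapped (MSA) and ungapped sequence positions

def ungapped_to_gapped(row: str, pos: int) -> int:
    """Map a 1-based ungapped position to its 1-based MSA column."""
    seen = 0
    for k, ch in enumerate(row):
        if ch != "-":
            seen += 1
            if seen == pos:
                return k + 1
    raise IndexError(f"position {pos} beyond ungapped length {seen}")


def gapped_to_ungapped(row: str, col: int) -> int:
    """Map a 1-based MSA column holding a residue to its 1-based ungapped
    position."""
    if row[col - 1] == "-":
        raise ValueError(f"column {col} is a gap in this row")
    return col - row[:col].count("-")


def write_features_tsv(hits: list[FeatureHit], path) -> None:
    pd.DataFrame([vars(h) for h in hits]).to_csv(path, sep="\t", index=False)


def write_features_bed(hits: list[FeatureHit], path) -> None:
    """BED6: 0-based half-open conversion happens here."""
    with open(path, "w") as fh:
        for h in hits:
            name = f"{h.kind}:{h.motif or ''}"
            fh.write(f"{h.sequence_id}\t{h.start - 1}\t{h.end}\t{name}\t0\t+\n")
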
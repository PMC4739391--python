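"""Kimura 2-parameter distances with pairwise deletion.

The K2P model separates transition differences (A<->G, C<->T; proportion P)
from transversion differences (proportion Q) and estimates the expected
number of substitutions per site as

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Columns where either sequence carries a gap or an ambiguity code are skipped
pair by pair (pairwise deletion); saturated pairs (1 - 2P - Q <= 0 or
1 - 2Q <= 0) are flagged undefined and excluded from downstream means, never
silently set to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import MultipleAlignment

__all__ = [
    "PairwiseComparison",
    "DistanceMatrix",
    "compare_pair",
    "k2p_distance",
    "distance_matrix",
    "overall_mean_distance",
]

_PURINE = {"A", "G"}
_PYRIMIDINE = {"C", "T"}

# byte-class table: A=0 C=1 G=2 T=3, everything else (incl. gap) = 4
_K2P_CLASS = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _K2P_CLASS[ord(_b)] = _i
    _K2P_CLASS[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PairwiseComparison:
    """Transition/transversion difference proportions over L compared sites."""

    P: float
    Q: float
    L: int

    @property
    def defined(self) -> bool:
        return self.L > 0


def _encode(row: str) -> np.ndarray:
    return _K2P_CLASS[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


def compare_pair(row_a: str, row_b: str) -> PairwiseComparison:
    """Count transition and transversion differences between two gapped rows.

    Pairwise deletion: a column is compared only if both rows carry an
    unambiguous base there.  L = 0 yields an undefined comparison.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal (aligned) length")
    a = _encode(row_a)
    b = _encode(row_b)
    valid = (a < 4) & (b < 4)
    L = int(valid.sum())
    if L == 0:
        return PairwiseComparison(P=float("nan"), Q=float("nan"), L=0)
    av, bv = a[valid], b[valid]
    diff = av != bv
    # A(0)<->G(2) and C(1)<->T(3) are transitions: class parity is equal
    transitions = diff & ((av % 2) == (bv % 2))
    ts = int(transitions.sum())
    tv = int(diff.sum()) - ts
    return PairwiseComparison(P=ts / L, Q=tv / L, L=L)


def k2p_distance(c: PairwiseComparison) -> float:
    """K2P distance for one comparison; NaN when undefined or saturated."""
    if not c.defined:
        return float("nan")
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with species labels.

    Undefined entries (saturation, or no shared unambiguous sites) are NaN.
    """

    ids: list[str]
    species: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if len(self.species) != n:
            raise ValueError("species labels do not match ids")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmin(np.diag(self.d)) != 0 or np.nanmax(np.diag(self.d)) != 0:
                raise ValueError("diagonal must be zero")

    def __len__(self):
        return len(self.ids)

    def index(self, accession_id: str) -> int:
        return self.ids.index(accession_id)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.d)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="accession_id")

    @classmethod
    def read_tsv(cls, path, species: list[str] | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(i) for i in df.index]
        return cls(ids=ids, species=list(species or ids), d=df.to_numpy())


def distance_matrix(msa: MultipleAlignment, species: list[str]) -> DistanceMatrix:
    """K2P distance matrix over all row pairs of an alignment."""
    n = len(msa.rows)
    if len(species) != n:
        raise ValueError("species labels must match MSA rows")
    enc = [_encode(r) for r in msa.rows]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            valid = (a < 4) & (b < 4)
            L = int(valid.sum())
            if L == 0:
                d[i, j] = d[j, i] = float("nan")
                continue
            av, bv = a[valid], b[valid]
            diff = av != bv
            ts = int((diff & ((av % 2) == (bv % 2))).sum())
            tv = int(diff.sum()) - ts
            d[i, j] = d[j, i] = k2p_distance(
                PairwiseComparison(P=ts / L, Q=tv / L, L=L))
    return DistanceMatrix(ids=list(msa.row_ids), species=list(species), d=d)


def overall_mean_distance(dm: DistanceMatrix) -> float:
    """Mean of all defined off-diagonal distances, each unordered pair once."""
    iu = np.triu_indices(len(dm), k=1)
    vals = dm.d[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())
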
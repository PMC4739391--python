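"""Inter/intraspecific divergence parameters, barcoding-gap profiles, and
Wilcoxon signed-rank comparison of loci.

Six summary parameters are computed from a pairwise distance matrix:

* all intraspecific distance — mean +- SD over all conspecific pairs;
* theta — per species, the mean conspecific distance, averaged over species;
* coalescent depth — per species, the maximum conspecific distance, averaged
  over species;
* all interspecific distance — mean +- SD over all heterospecific pairs;
* theta prime — per species, the mean distance from its members to all
  congeners, averaged over species;
* minimum interspecific distance — per species, the smallest distance from
  any member to any heterospecific member, averaged over species.

Species represented by a single accession contribute only to the
interspecific parameters.  SDs use the n-1 denominator (0 for a single
value).  Undefined (saturated) distances are excluded throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .distances import DistanceMatrix

__all__ = [
    "MeanSD",
    "DivergenceSummary",
    "GapProfile",
    "WilcoxonResult",
    "divergence_parameters",
    "barcoding_gap",
    "wilcoxon_signed_rank",
    "compare_loci",
    "intraspecific_distances",
    "interspecific_distances",
]


@dataclass(frozen=True)
class MeanSD:
    mean: float
    sd: float
    n: int

    def __str__(self):
        return f"{self.mean:.4f} ± {self.sd:.4f}"


def _mean_sd(values) -> MeanSD:
    v = np.asarray(list(values), dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return MeanSD(float("nan"), float("nan"), 0)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return MeanSD(float(v.mean()), sd, int(v.size))


@dataclass
class DivergenceSummary:
    locus: str
    theta: MeanSD
    coalescent_depth: MeanSD
    all_intra: MeanSD
    theta_prime: MeanSD
    min_inter: MeanSD
    all_inter: MeanSD

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("theta", "coalescent_depth", "all_intra",
                     "theta_prime", "min_inter", "all_inter"):
            ms: MeanSD = getattr(self, name)
            rows.append((self.locus, name, ms.mean, ms.sd, ms.n))
        return pd.DataFrame(rows, columns=["locus", "parameter", "mean", "sd", "n"])


def _pair_distances(dm: DistanceMatrix, same_species: bool):
    """Iterate (i, j, distance) over defined unordered pairs of the given kind."""
    sp = dm.species
    n = len(dm)
    for i in range(n):
        for j in range(i + 1, n):
            if (sp[i] == sp[j]) != same_species:
                continue
            v = dm.d[i, j]
            if not math.isnan(v):
                yield i, j, v


def intraspecific_distances(dm: DistanceMatrix) -> np.ndarray:
    return np.array([v for _, _, v in _pair_distances(dm, True)])


def interspecific_distances(dm: DistanceMatrix) -> np.ndarray:
    return np.array([v for _, _, v in _pair_distances(dm, False)])


def divergence_parameters(dm: DistanceMatrix, locus: str = "") -> DivergenceSummary:
    """The six divergence parameters for one locus distance matrix."""
    species = sorted(set(dm.species))
    if len(species) < 2:
        raise ValueError("divergence parameters need >= 2 species")
    sp = np.asarray(dm.species)
    idx_of = {s: np.nonzero(sp == s)[0] for s in species}

    intra_all, theta_per, depth_per = [], [], []
    inter_all = interspecific_distances(dm)
    theta_prime_per, min_inter_per = [], []
    for s in species:
        idx = idx_of[s]
        others = np.nonzero(sp != s)[0]
        if len(idx) >= 2:
            vals = []
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    v = dm.d[idx[a], idx[b]]
                    if not math.isnan(v):
                        vals.append(v)
            if vals:
                intra_all.extend(vals)
                theta_per.append(float(np.mean(vals)))
                depth_per.append(float(np.max(vals)))
        if len(others):
            block = dm.d[np.ix_(idx, others)].ravel()
            block = block[~np.isnan(block)]
            if block.size:
                theta_prime_per.append(float(block.mean()))
                min_inter_per.append(float(block.min()))

    return DivergenceSummary(
        locus=locus,
        theta=_mean_sd(theta_per),
        coalescent_depth=_mean_sd(depth_per),
        all_intra=_mean_sd(intra_all),
        theta_prime=_mean_sd(theta_prime_per),
        min_inter=_mean_sd(min_inter_per),
        all_inter=_mean_sd(inter_all),
    )


@dataclass
class GapProfile:
    """Histograms of conspecific vs heterospecific distances.

    ``overlap`` is the fraction of intraspecific distances at or above the
    5th percentile of the interspecific distribution — 0 for a clean
    barcoding gap, ~0.95 when the distributions coincide.
    """

    bin_edges: np.ndarray
    intra_histogram: np.ndarray
    inter_histogram: np.ndarray
    bin_width: float
    overlap: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1],
            "intra_count": self.intra_histogram,
            "inter_count": self.inter_histogram,
        })


def barcoding_gap(dm: DistanceMatrix, bin_width: float = 0.005) -> GapProfile:
    intra = intraspecific_distances(dm)
    inter = interspecific_distances(dm)
    hi = max(intra.max(initial=0.0), inter.max(initial=0.0), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    ih, _ = np.histogram(intra, bins=edges)
    eh, _ = np.histogram(inter, bins=edges)
    if intra.size == 0 or inter.size == 0:
        overlap = float("nan")
    else:
        cutoff = float(np.percentile(inter, 5.0))
        overlap = float((intra >= cutoff).mean())
    return GapProfile(bin_edges=edges, intra_histogram=ih, inter_histogram=eh,
                      bin_width=bin_width, overlap=overlap)


@dataclass
class WilcoxonResult:
    w_plus: float
    w_minus: float
    n: int
    p_value: float
    direction: str  # "greater" | "less" | "equal" (x relative to y)


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic under random signs.

    Computed by dynamic programming over the distribution of W+ (identical to
    enumerating all 2^n sign patterns; midranks are handled by doubling the
    ranks to integers).
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    mu = total / 2.0
    dev = abs(2.0 * w_plus - mu)
    support = np.arange(total + 1)
    p = counts[np.abs(support - mu) >= dev - 1e-9].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped, ties midranked; the two-sided p-value is
    exact (sign enumeration) for n <= ``exact_max_n``, otherwise a normal
    approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length 1-d samples")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 0, 1.0, "equal")
    ranks = _stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= exact_max_n:
        p = _exact_two_sided_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
            p = float(min(1.0, 2.0 * _stats.norm.sf(max(z, 0.0))))
    med = float(np.median(d))
    if med > 0 or (med == 0 and w_plus > w_minus):
        direction = "greater"
    elif med < 0 or (med == 0 and w_plus < w_minus):
        direction = "less"
    else:
        direction = "equal"
    return WilcoxonResult(w_plus, w_minus, n, p, direction)


def _pair_map(dm: DistanceMatrix, mode: str) -> dict[frozenset, float]:
    same = mode == "intra"
    return {frozenset((dm.ids[i], dm.ids[j])): v
            for i, j, v in _pair_distances(dm, same)}


def compare_loci(distance_sets: dict[str, DistanceMatrix], mode: str = "inter",
                 min_common: int = 4) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank comparison of loci.

    For each locus pair, distances belonging to the same unordered accession
    pair present (and defined) in both loci are paired and tested.  Pairs with
    fewer than ``min_common`` shared accession pairs are flagged underpowered
    and not tested.
    """
    if mode not in ("inter", "intra"):
        raise ValueError("mode must be 'inter' or 'intra'")
    if len(distance_sets) < 2:
        raise ValueError("need at least two loci to compare")
    maps = {locus: _pair_map(dm, mode) for locus, dm in distance_sets.items()}
    loci = list(distance_sets)
    rows = []
    for a_idx in range(len(loci)):
        for b_idx in range(a_idx + 1, len(loci)):
            la, lb = loci[a_idx], loci[b_idx]
            common = sorted(set(maps[la]) & set(maps[lb]),
                            key=lambda k: sorted(k))
            if len(common) < min_common:
                rows.append((la, lb, float("nan"), float("nan"), len(common),
                             float("nan"), "underpowered"))
                continue
            x = [maps[la][k] for k in common]
            y = [maps[lb][k] for k in common]
            res = wilcoxon_signed_rank(x, y)
            if res.direction == "greater":
                verdict = f"{la} > {lb}"
            elif res.direction == "less":
                verdict = f"{la} < {lb}"
            else:
                verdict = f"{la} = {lb}"
            rows.append((la, lb, res.w_plus, res.w_minus, res.n,
                         res.p_value, verdict))
    return pd.DataFrame(
        rows, columns=["locus_a", "locus_b", "w_plus", "w_minus", "n",
                       "p_value", "result"])
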
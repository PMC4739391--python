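"""Leave-one-out species identification efficiency.

Two assignment methods are evaluated per locus:

* nearest distance — the query is assigned the species of its
  minimum-K2P-distance reference after removing itself from the reference set;
* top hit ("BLAST1"-style) — the query is assigned the species of the
  highest-scoring local alignment hit, computed with the in-repo
  Smith–Waterman engine rather than an external BLAST executable.

Tie policy: a tie on the optimum counts as a success only if ALL tied
references agree with the query at the level being scored, which makes the
outcome independent of record order.  Queries whose species has no other
representative cannot be identified correctly at species level and are
excluded from the species-level denominator (they still count at genus
level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import local_align
from .dataset_io import LocusDataset
from .distances import DistanceMatrix

__all__ = [
    "IdentificationResult",
    "nearest_distance_id",
    "top_hit_id",
    "efficiency",
    "all_results",
]

_REL_TOL = 1e-9  # relative tolerance for calling two scores/distances tied


@dataclass
class IdentificationResult:
    query_id: str
    method: str  # "nearest_distance" | "top_hit"
    best_hit_id: str | None
    assigned_species: str | None
    correct_species: bool
    correct_genus: bool
    tie: bool


def _genus(species: str) -> str:
    return species.split()[0]


def _resolve(query_species, hit_ids, hit_species, method, query_id):
    """Apply the all-tied-must-agree policy to the set of optimal hits."""
    tie = len(hit_ids) > 1
    species_set = set(hit_species)
    genus_set = {_genus(s) for s in hit_species}
    assigned = hit_species[0] if len(species_set) == 1 else "ambiguous"
    correct_species = species_set == {query_species}
    correct_genus = genus_set == {_genus(query_species)}
    return IdentificationResult(
        query_id=query_id, method=method, best_hit_id=hit_ids[0],
        assigned_species=assigned, correct_species=correct_species,
        correct_genus=correct_genus, tie=tie)


def nearest_distance_id(dm: DistanceMatrix, query_id: str) -> IdentificationResult:
    """Leave-one-out nearest-distance assignment of one query."""
    qi = dm.index(query_id)
    if len(dm) < 2:
        raise ValueError("need at least one reference record")
    dists = dm.d[qi].copy()
    dists[qi] = np.nan
    if np.isnan(dists).all():
        return IdentificationResult(query_id, "nearest_distance", None, None,
                                    False, False, False)
    dmin = np.nanmin(dists)
    with np.errstate(invalid="ignore"):
        hits = np.nonzero(dists <= dmin + _REL_TOL * max(dmin, 1.0))[0]
    return _resolve(dm.species[qi], [dm.ids[h] for h in hits],
                    [dm.species[h] for h in hits], "nearest_distance", query_id)


def top_hit_id(dataset: LocusDataset, query_id: str, **align_params) -> IdentificationResult:
    """Leave-one-out top-local-alignment-hit assignment of one query."""
    query = dataset.get(query_id)
    refs = [r for r in dataset if r.accession_id != query_id]
    if not refs:
        raise ValueError("need at least one reference record")
    scores = np.array([
        local_align(query.ungapped, r.ungapped, **align_params)[0].score
        for r in refs])
    smax = scores.max()
    if smax <= 0:
        return IdentificationResult(query_id, "top_hit", None, None,
                                    False, False, False)
    hits = np.nonzero(scores >= smax - _REL_TOL * smax)[0]
    return _resolve(query.species, [refs[h].accession_id for h in hits],
                    [refs[h].species for h in hits], "top_hit", query_id)


def all_results(dataset: LocusDataset, method: str,
                dm: DistanceMatrix | None = None,
                **align_params) -> list[IdentificationResult]:
    """Leave-one-out identification of every record in the dataset."""
    if method == "nearest_distance":
        if dm is None:
            raise ValueError("nearest_distance requires a distance matrix")
        return [nearest_distance_id(dm, rid) for rid in dataset.ids]
    if method == "top_hit":
        return [top_hit_id(dataset, rid, **align_params) for rid in dataset.ids]
    raise ValueError(f"unknown method {method!r}")


def efficiency(dataset: LocusDataset, method: str, level: str = "species",
               dm: DistanceMatrix | None = None,
               results: list[IdentificationResult] | None = None,
               **align_params) -> float:
    """Leave-one-out identification efficiency in percent.

    ``level`` is "species" or "genus".  At species level, queries whose
    species has a single representative are excluded from the denominator.
    """
    if level not in ("species", "genus"):
        raise ValueError("level must be 'species' or 'genus'")
    if results is None:
        results = all_results(dataset, method, dm=dm, **align_params)
    counts = pd.Series(dataset.species).value_counts()
    species_of = {r.accession_id: r.species for r in dataset}
    num = den = 0
    for res in results:
        sp = species_of[res.query_id]
        if level == "species":
            if counts[sp] < 2:
                continue
            den += 1
            num += res.correct_species
        else:
            den += 1
            num += res.correct_genus
    if den == 0:
        return float("nan")
    return 100.0 * num / den


def results_frame(results: list[IdentificationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
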
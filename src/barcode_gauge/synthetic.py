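"""Synthetic congeneric barcode datasets with known truth.

The generator emulates the regime of a congeneric barcoding study: a genus of
S species with n_i accessions each, conspecific pairs at a target K2P
distance, heterospecific pairs at a (larger) target, locus-specific GC
content and length, occasional indels, and optional planted diagnostic
features (homopolymer run, tandem repeat, inverted segment).

Sequences evolve along an ultrametric species tree under the Kimura
2-parameter substitution process: each branch of length t (expected
substitutions/site) applies the exact K2P transition-probability matrix
site by site, so multiple hits are handled exactly and the expected
estimated K2P distance between two tips equals their path length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset_io import LocusDataset, SequenceRecord
from .features import FeatureHit, reverse_complement
from .phylo import Phylogeny, TreeNode

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "PRESETS",
    "preset",
    "simulate_species_tree",
    "evolve_sequences",
    "simulate_dataset",
    "truth_report",
    "write_fasta",
    "write_metadata",
]

_GENUS = "Simulia"


@dataclass
class SimulationConfig:
    n_species: int = 10
    accessions_per_species: int | list[int] = 5
    root_length: int = 500
    kappa: float = 2.0  # transition/transversion rate ratio
    target_intra: float = 0.006  # expected conspecific K2P distance
    target_inter: float = 0.035  # expected heterospecific K2P distance
    gc_target: float = 0.5
    indel_rate: float = 0.05  # events per site per unit branch length
    indel_mean_len: float = 3.0  # geometric mean length
    locus: str = "other"
    # planted features: dicts like
    #   {"kind": "homopolymer", "species": 0, "base": "A", "length": 7}
    #   {"kind": "tandem_repeat", "species": 0, "unit": "ATTAAA", "copies": 2}
    #   {"kind": "inversion", "species": 0, "length": 74}
    planted_features: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not (self.target_inter > self.target_intra >= 0):
            raise ValueError("require target_inter > target_intra >= 0")
        if not (0 < self.gc_target < 1):
            raise ValueError("require 0 < gc_target < 1")
        if self.kappa <= 0:
            raise ValueError("require kappa > 0")

    @property
    def accession_counts(self) -> list[int]:
        if isinstance(self.accessions_per_species, int):
            return [self.accessions_per_species] * self.n_species
        counts = list(self.accessions_per_species)
        if len(counts) != self.n_species:
            raise ValueError("per-species accession list length mismatch")
        return counts


# regimes of the two best-performing loci in the study this package models:
# a GC-rich, short, moderately divergent nuclear spacer and an AT-rich
# chloroplast spacer with a much deeper divergence structure.
PRESETS = {
    "ITS2": dict(root_length=220, gc_target=0.66,
                 target_intra=0.006, target_inter=0.035, locus="ITS2"),
    "psbA-trnH": dict(root_length=287, gc_target=0.25,
                      target_intra=0.048, target_inter=0.107, locus="psbA-trnH"),
}


def preset(name: str, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class SimulatedDataset:
    dataset: LocusDataset
    truth_tree: Phylogeny
    truth_features: list[FeatureHit]
    config: SimulationConfig


def _species_name(i: int) -> str:
    return f"{_GENUS} taxon{i + 1:02d}"


def simulate_species_tree(config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> Phylogeny:
    """Ultrametric species tree with accession tips.

    Random coalescent-style topology over species, rescaled so the mean
    heterospecific tip-tip path equals ``target_inter``; accessions hang off
    their species node at depth ``target_intra / 2`` (star-like within
    species), so conspecific pairs sit at exactly ``target_intra``.
    """
    rng = rng or np.random.default_rng(config.seed)
    S = config.n_species
    if S < 1:
        raise ValueError("need at least one species")
    # star-like radiation: every species hangs off the root on its own stem,
    # with mild lognormal stem jitter, normalised so the mean species-pair
    # path is exactly target_inter - target_intra (accession tips below add
    # target_intra to every heterospecific path)
    nodes = [TreeNode(name=_species_name(i)) for i in range(S)]
    if S > 1:
        base = (config.target_inter - config.target_intra) / 2.0
        jitter = rng.lognormal(0.0, 0.1, size=S)
        jitter /= jitter.mean()
        for node, j in zip(nodes, jitter):
            node.length = node.raw_length = base * j
    root = nodes[0] if S == 1 else TreeNode(children=nodes)

    # attach accession tips
    species_map = {}
    tip_depth = config.target_intra / 2.0
    counts = config.accession_counts

    def attach(species_node, i):
        tips = []
        for a in range(counts[i]):
            tip = TreeNode(name=f"T{i + 1:02d}A{a + 1:02d}", length=tip_depth)
            species_map[tip.name] = species_node.name
            tips.append(tip)
        species_node.name = None
        species_node.children = tips

    for leaf in list(root.leaves()):
        attach(leaf, int(leaf.name.split("taxon")[1]) - 1)
    return Phylogeny(root=root, species_map=species_map)


# ---------------------------------------------------------------------------
# K2P sequence evolution

_TRANSITION_OF = np.array([2, 3, 0, 1])  # A<->G, C<->T in ACGT coding


def _k2p_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """Exact K2P P(t) with rates normalised to one expected substitution per
    site per unit t."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    for b in range(4):
        P[b, b] = p_same
        P[b, _TRANSITION_OF[b]] = p_ts
    return P


def _evolve_branch(seq: np.ndarray, t: float, config: SimulationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    if t < 0:
        raise ValueError("negative branch length")
    out = seq.copy()
    if t > 0:
        P = _k2p_transition_matrix(t, config.kappa)
        cum = P.cumsum(axis=1)
        u = rng.random(out.size)
        out = (u[:, None] > cum[out]).sum(axis=1).astype(np.int8)
    # indels: Poisson number of events, geometric lengths, uniform placement
    if config.indel_rate > 0 and t > 0:
        n_events = rng.poisson(config.indel_rate * out.size * t)
        for _ in range(n_events):
            length = int(rng.geometric(1.0 / config.indel_mean_len))
            pos = int(rng.integers(0, max(1, out.size)))
            if rng.random() < 0.5 and out.size > length + 20:
                out = np.delete(out, slice(pos, pos + length))
            else:
                ins = rng.integers(0, 4, size=length).astype(np.int8)
                out = np.insert(out, pos, ins)
    return out


_BASES = np.array(list("ACGT"))


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def evolve_sequences(tree: Phylogeny, config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> LocusDataset:
    """Evolve sequences down the tree and plant the configured features."""
    rng = rng or np.random.default_rng(config.seed)
    gc = config.gc_target
    root_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    root_seq = rng.choice(4, size=config.root_length, p=root_probs).astype(np.int8)

    seqs: dict[str, str] = {}

    def descend(node, seq):
        for child in node.children:
            child_seq = _evolve_branch(seq, child.length, config, rng)
            if child.is_leaf:
                seqs[child.name] = _decode(child_seq)
            else:
                descend(child, child_seq)

    descend(tree.root, root_seq)

    truth_features = _plant_features(seqs, tree, config, rng)

    records = [
        SequenceRecord(accession_id=name, species=tree.species_map[name],
                       locus=config.locus, sequence=seqs[name])
        for name in sorted(seqs)
    ]
    ds = LocusDataset(locus=config.locus, records=records,
                      provenance=f"simulated(seed={config.seed})")
    return ds, truth_features


def _plant_features(seqs: dict[str, str], tree: Phylogeny,
                    config: SimulationConfig,
                    rng: np.random.Generator) -> list[FeatureHit]:
    """Inject planted features into every accession of their carrier species,
    at sharp boundaries so detectors can recover exact coordinates."""
    truth: list[FeatureHit] = []
    if not config.planted_features:
        return truth
    species_names = sorted(set(tree.species_map.values()))
    by_species: dict[str, list[str]] = {s: [] for s in species_names}
    for acc in sorted(seqs):
        by_species[tree.species_map[acc]].append(acc)

    for spec in config.planted_features:
        kind = spec["kind"]
        carrier_sp = species_names[spec["species"]]
        carriers = by_species[carrier_sp]
        non_carriers = [a for s in species_names if s != carrier_sp
                        for a in by_species[s]]
        # one anchor per feature: accessions of the carrier species receive
        # the feature at (close to) the same position, like a real
        # species-diagnostic insertion
        anchor = int(rng.integers(1, max(2, min(len(seqs[a]) for a in carriers)
                                         - int(spec.get("length", 20)) - 40)))
        for acc in carriers:
            seq = seqs[acc]
            if kind == "homopolymer":
                base = spec.get("base", "A")
                length = int(spec.get("length", 7))
                ins = base * length
                pos = _insertion_site(seq, rng, lambda p, s=seq:
                                      s[p - 1] != base and s[p] != base,
                                      anchor=anchor)
                seqs[acc] = seq[:pos] + ins + seq[pos:]
                truth.append(FeatureHit(
                    kind="homopolymer", sequence_id=acc, start=pos + 1,
                    end=pos + length, length=length, motif=base, copies=length))
            elif kind == "tandem_repeat":
                unit = spec.get("unit", "ATTAAA").upper()
                copies = int(spec.get("copies", 2))
                ins = unit * copies
                pos = _insertion_site(seq, rng, lambda p, s=seq:
                                      s[p - 1] != unit[-1] and s[p] != unit[0],
                                      anchor=anchor)
                seqs[acc] = seq[:pos] + ins + seq[pos:]
                truth.append(FeatureHit(
                    kind="tandem_repeat", sequence_id=acc, start=pos + 1,
                    end=pos + len(ins), length=len(ins), motif=unit,
                    copies=copies))
            elif kind == "inversion":
                if not non_carriers:
                    raise ValueError("inversion needs a non-carrier reference")
                ref_id = non_carriers[0]
                ref = seqs[ref_id]
                length = int(spec.get("length", 74))
                if length >= min(len(seq), len(ref)) - 4:
                    raise ValueError("feature longer than sequence")

                def sharp(p, s=seq, r=ref, L=length):
                    if p + L >= min(len(s), len(r)) or p < 1:
                        return False
                    # gap-free extension beyond either block edge must never
                    # reach a positive score, or the local aligner would grow
                    # the block past the planted coordinates
                    left_ref = r[p - 1::-1]
                    left_qry = "".join(_COMP.get(c, "N") for c in s[p + L:])
                    right_ref = r[p + L:]
                    right_qry = "".join(_COMP.get(c, "N")
                                        for c in s[p - 1::-1])
                    return (_edge_safe(left_ref, left_qry)
                            and _edge_safe(right_ref, right_qry))

                pos = _insertion_site(seq, rng, sharp,
                                      hi=min(len(seq), len(ref)) - length - 2,
                                      anchor=anchor)
                block = reverse_complement(ref[pos:pos + length])
                seqs[acc] = seq[:pos] + block + seq[pos + length:]
                truth.append(FeatureHit(
                    kind="inversion", sequence_id=acc, start=pos + 1,
                    end=pos + length, length=length, identity=1.0,
                    reference_id=ref_id))
            else:
                raise ValueError(f"unknown planted feature kind {kind!r}")
    return truth


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _edge_safe(x: str, y: str, window: int = 40) -> bool:
    """True when a gap-free match/mismatch (+1/-1) extension along the paired
    strings x and y never attains a positive running score."""
    score = 0
    for cx, cy in zip(x[:window], y[:window]):
        score += 1 if cx == cy and cx in "ACGT" else -1
        if score > 0:
            return False
    return True


def _insertion_site(seq: str, rng: np.random.Generator, ok,
                    hi: int | None = None, anchor: int | None = None) -> int:
    """Pick an insertion position satisfying the sharpness predicate ``ok``,
    scanning outward from ``anchor`` first, then sampling at random."""
    hi = hi if hi is not None else len(seq) - 2
    if hi <= 2:
        raise ValueError("feature longer than sequence")
    if anchor is not None:
        for delta in range(0, hi):
            for pos in (anchor + delta, anchor - delta):
                if 1 <= pos < hi and ok(pos):
                    return pos
    for _ in range(200):
        pos = int(rng.integers(1, hi))
        if ok(pos):
            return pos
    raise RuntimeError("could not find a sharp insertion site")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full simulation: species tree, K2P evolution, planted features."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_species_tree(config, rng)
    dataset, truth_features = evolve_sequences(tree, config, rng)
    return SimulatedDataset(dataset=dataset, truth_tree=tree,
                            truth_features=truth_features, config=config)


def truth_report(sim: SimulatedDataset) -> dict:
    """Analytic expectations implied by the simulation targets."""
    cfg = sim.config
    ratio = (cfg.target_inter / cfg.target_intra
             if cfg.target_intra > 0 else float("inf"))
    expected_eff = 100.0 if ratio >= 5 else None
    return {
        "expected_all_intra": cfg.target_intra,
        "expected_all_inter": cfg.target_inter,
        "gap_ratio": ratio,
        "expected_species_efficiency":
            expected_eff if expected_eff is not None else "not predicted",
        "n_accessions": len(sim.dataset),
        "n_species": len(set(sim.dataset.species)),
        "n_planted_features": len(sim.truth_features),
    }


def write_fasta(dataset: LocusDataset, path) -> None:
    with open(path, "w") as fh:
        for rec in dataset:
            fh.write(f">{rec.accession_id}\n{rec.sequence}\n")


def write_metadata(dataset: LocusDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("accession_id\tspecies\tlocus\tvoucher\torigin\n")
        for rec in dataset:
            fh.write(f"{rec.accession_id}\t{rec.species}\t{rec.locus}\t"
                     f"{rec.voucher or ''}\t{rec.origin or ''}\n")


def write_truth_json(sim: SimulatedDataset, path) -> None:
    payload = {
        "config": asdict(sim.config),
        "report": truth_report(sim),
        "features": [vars(h) for h in sim.truth_features],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
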
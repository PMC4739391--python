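"""End-to-end locus evaluation: QC -> alignment -> distances -> divergence ->
identification -> features -> NJ monophyly, for one or more loci, with a
report bundle mirroring the summary tables of a barcoding-locus study."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import align as _align
from . import dataset_io as _io
from . import distances as _dist
from . import divergence as _div
from . import features as _feat
from . import identify as _ident
from . import phylo as _phylo

log = logging.getLogger("barcode_gauge")

__all__ = ["LocusInput", "RunConfig", "run_evaluation"]


@dataclass
class LocusInput:
    locus: str
    fasta: str
    metadata: str


@dataclass
class RunConfig:
    inputs: list[LocusInput]
    out_dir: str
    min_len: int = 100
    max_ambiguous: int = 1
    similarity_min: float = 0.90
    coverage_min: float = 0.90
    bin_width: float = 0.005
    min_homopolymer: int = 6
    tandem_min_total: int = 12
    inversion_min_len: int = 50
    inversion_min_identity: float = 0.98
    detect_inversions: bool = True
    seed: int = 0
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        inputs = [LocusInput(**i) for i in raw.pop("inputs")]
        return cls(inputs=inputs, **raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_evaluation(config: RunConfig) -> dict:
    """Run the full evaluation; returns {locus: result dict} and writes the
    report bundle (TSV tables, newick trees, histograms, features, provenance
    sidecar) under ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict[str, str] = {"seed": str(config.seed)}
    results: dict[str, dict] = {}
    matrices: dict[str, _dist.DistanceMatrix] = {}
    summaries, divergences, efficiencies = [], [], []

    for inp in config.inputs:
        locus = inp.locus
        ldir = out / locus.replace("/", "_")
        ldir.mkdir(exist_ok=True)
        res: dict = {}

        meta = _stage("read_metadata")(_io.read_metadata)(inp.metadata)
        dataset = _stage("read_fasta")(_io.read_fasta)(inp.fasta, locus, meta)
        log.info("%s: %d records in", locus, len(dataset))

        dataset, qc = _stage("qc_filter")(_io.qc_filter)(
            dataset, min_len=config.min_len, max_ambiguous=config.max_ambiguous,
            similarity_min=config.similarity_min, coverage_min=config.coverage_min)
        qc.to_frame().to_csv(ldir / "qc_report.tsv", sep="\t", index=False)
        provenance[str(ldir / "qc_report.tsv")] = "qc_filter"
        log.info("%s: %d kept / %d rejected", locus, len(qc.kept), len(qc.rejected))
        res["qc"] = qc
        if len(dataset) < 2:
            res["note"] = "fewer than 2 records after QC; downstream skipped"
            results[locus] = res
            continue

        msa = _stage("progressive_msa")(_align.progressive_msa)(dataset)
        _align.write_aligned_fasta(msa, ldir / "alignment.fasta")
        provenance[str(ldir / "alignment.fasta")] = "progressive_msa"

        summary = _stage("summarize_locus")(_io.summarize_locus)(dataset, msa)
        summaries.append(summary.to_frame())
        res["summary"] = summary

        dm = _stage("distance_matrix")(_dist.distance_matrix)(msa, dataset.species)
        dm.write_tsv(ldir / "k2p_distances.tsv")
        provenance[str(ldir / "k2p_distances.tsv")] = "distance_matrix"
        matrices[locus] = dm
        res["distance_matrix"] = dm
        res["overall_mean_distance"] = _dist.overall_mean_distance(dm)

        n_species = len(set(dataset.species))
        if n_species >= 2:
            div = _stage("divergence_parameters")(_div.divergence_parameters)(
                dm, locus=locus)
            divergences.append(div.to_frame())
            res["divergence"] = div
            gap = _stage("barcoding_gap")(_div.barcoding_gap)(
                dm, bin_width=config.bin_width)
            gap.to_frame().to_csv(ldir / "gap_histogram.tsv", sep="\t", index=False)
            provenance[str(ldir / "gap_histogram.tsv")] = "barcoding_gap"
            res["gap"] = gap
        else:
            log.warning("%s: single species; interspecific sections absent", locus)
            res["divergence"] = None

        eff_rows = []
        nd_results = _ident.all_results(dataset, "nearest_distance", dm=dm)
        th_results = _ident.all_results(dataset, "top_hit")
        _ident.results_frame(nd_results + th_results).to_csv(
            ldir / "identification.tsv", sep="\t", index=False)
        provenance[str(ldir / "identification.tsv")] = "nearest_distance_id/top_hit_id"
        for method, rset in (("nearest_distance", nd_results), ("top_hit", th_results)):
            for level in ("species", "genus"):
                eff = _ident.efficiency(dataset, method, level, results=rset)
                eff_rows.append((locus, method, level, eff))
        eff_df = pd.DataFrame(eff_rows,
                              columns=["locus", "method", "level", "efficiency_pct"])
        efficiencies.append(eff_df)
        res["efficiency"] = eff_df

        hits = []
        for rec in dataset:
            hits += _feat.find_homopolymers(
                rec.ungapped, min_len=config.min_homopolymer,
                sequence_id=rec.accession_id)
            hits += _feat.find_tandem_repeats(
                rec.ungapped, min_total=config.tandem_min_total,
                sequence_id=rec.accession_id)
        if config.detect_inversions:
            for rec in dataset:
                ref = next((r for r in dataset if r.species != rec.species), None)
                if ref is not None:
                    hits += _feat.detect_inversion(
                        rec.ungapped, ref.ungapped,
                        min_len=config.inversion_min_len,
                        min_identity=config.inversion_min_identity,
                        sequence_id=rec.accession_id,
                        reference_id=ref.accession_id)
        _feat.write_features_tsv(hits, ldir / "features.tsv")
        _feat.write_features_bed(hits, ldir / "features.bed")
        provenance[str(ldir / "features.tsv")] = (
            "find_homopolymers/find_tandem_repeats/detect_inversion")
        res["features"] = hits

        if len(dataset) >= 3:
            tree = _stage("nj_tree")(_phylo.nj_tree)(dm)
            (ldir / "nj_tree.nwk").write_text(_phylo.write_newick(tree))
            provenance[str(ldir / "nj_tree.nwk")] = "nj_tree"
            report, misplaced = _phylo.monophyly_report(tree)
            pd.DataFrame(
                [(sp, v["n"], v["misplaced"], v["monophyletic"])
                 for sp, v in report.items()],
                columns=["species", "n", "misplaced", "monophyletic"],
            ).to_csv(ldir / "monophyly.tsv", sep="\t", index=False)
            provenance[str(ldir / "monophyly.tsv")] = "monophyly_report"
            res["tree"] = tree
            res["misplaced"] = misplaced
        results[locus] = res

    if summaries:
        pd.concat(summaries).to_csv(out / "locus_summaries.tsv", sep="\t", index=False)
        provenance[str(out / "locus_summaries.tsv")] = "summarize_locus"
    if divergences:
        pd.concat(divergences).to_csv(out / "divergence_parameters.tsv",
                                      sep="\t", index=False)
        provenance[str(out / "divergence_parameters.tsv")] = "divergence_parameters"
    if efficiencies:
        pd.concat(efficiencies).to_csv(out / "identification_efficiency.tsv",
                                       sep="\t", index=False)
        provenance[str(out / "identification_efficiency.tsv")] = "efficiency"
    if len(matrices) >= 2:
        for mode in ("inter", "intra"):
            table = _div.compare_loci(matrices, mode=mode)
            table.to_csv(out / f"wilcoxon_{mode}.tsv", sep="\t", index=False)
            provenance[str(out / f"wilcoxon_{mode}.tsv")] = "compare_loci"
            results[f"wilcoxon_{mode}"] = table
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return results
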
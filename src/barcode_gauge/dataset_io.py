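"""Reading, validation and QC filtering of per-locus barcode sequence sets.

A locus dataset couples a FASTA file with a metadata table (TSV with columns
``accession_id, species, locus, voucher, origin``).  The package ships the
study's accession table as such a TSV
(``barcode_gauge/data/uncaria_accessions.tsv``): 257 GenBank accessions of
*Uncaria* across the five candidate loci ITS2, rbcL, psbA-trnH, ITS and matK.
No sequence data are packaged; a helper emits per-locus accession lists so
the sequences can be fetched separately.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import align as _align

__all__ = [
    "LOCI",
    "SequenceRecord",
    "LocusDataset",
    "QCReport",
    "LocusSummary",
    "read_metadata",
    "load_study_metadata",
    "read_fasta",
    "qc_filter",
    "summarize_locus",
]

LOCI = ("ITS2", "rbcL", "psbA-trnH", "ITS", "matK", "other")

IUPAC = frozenset("ACGTNRYSWKMBDHV-")
UNAMBIGUOUS = frozenset("ACGT-")

# species-name tokens marking undetermined taxa (case-insensitive)
_INDET_TOKENS = {"sp.", "spp.", "aff.", "cf."}

METADATA_COLUMNS = ["accession_id", "species", "locus", "voucher", "origin"]


@dataclass
class SequenceRecord:
    """One accession: identifier, taxonomy and raw nucleotide string."""

    accession_id: str
    species: str
    locus: str
    sequence: str
    voucher: str | None = None
    origin: str | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.accession_id}: empty sequence")
        bad = set(self.sequence) - IUPAC
        if bad:
            raise ValueError(
                f"{self.accession_id}: non-IUPAC symbols {sorted(bad)!r}")
        if self.locus not in LOCI:
            self.locus = "other" if not self.locus else self.locus
            if self.locus not in LOCI:
                raise ValueError(f"unknown locus {self.locus!r}")
        if not self.species.strip():
            raise ValueError(f"{self.accession_id}: empty species name")

    @property
    def genus(self) -> str:
        return self.species.split()[0]

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for c in self.sequence if c not in UNAMBIGUOUS)


@dataclass
class LocusDataset:
    """Ordered collection of records sharing one locus."""

    locus: str
    records: list[SequenceRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [r.accession_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate accession ids: {dup}")
        off = [r.accession_id for r in self.records if r.locus != self.locus]
        if off:
            raise ValueError(f"records not of locus {self.locus}: {off}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.accession_id for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def get(self, accession_id: str) -> SequenceRecord:
        for r in self.records:
            if r.accession_id == accession_id:
                return r
        raise KeyError(accession_id)

    def subset(self, keep_ids) -> "LocusDataset":
        keep = set(keep_ids)
        return LocusDataset(
            locus=self.locus,
            records=[r for r in self.records if r.accession_id in keep],
            provenance=self.provenance,
        )


@dataclass
class QCReport:
    kept: list[str]
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, "kept", "") for i in self.kept]
        rows += [(i, "rejected", reason) for i, reason in self.rejected]
        return pd.DataFrame(rows, columns=["accession_id", "status", "reason"])


@dataclass
class LocusSummary:
    locus: str
    n_species: int
    n_accessions: int
    length_min: int
    length_max: int
    length_mean: float
    gc_mean: float
    n_variable_sites: int
    n_indel_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata TSV; validates the fixed column set."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing columns {missing}")
    return df


def load_study_metadata() -> pd.DataFrame:
    """The packaged accession table of the *Uncaria* barcoding study."""
    ref = importlib.resources.files("barcode_gauge") / "data" / "uncaria_accessions.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_metadata(p)


def read_fasta(path, locus: str, metadata: pd.DataFrame) -> LocusDataset:
    """Build a LocusDataset from a FASTA file joined against metadata.

    Every FASTA id must resolve (with the requested locus) in the metadata
    table; input order is preserved.
    """
    meta = metadata[metadata["locus"] == locus] if "locus" in metadata else metadata
    by_id = {row.accession_id: row for row in meta.itertuples()}
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid not in by_id:
            raise KeyError(
                f"FASTA id {rid!r} has no metadata row for locus {locus!r}")
        row = by_id[rid]
        records.append(SequenceRecord(
            accession_id=rid,
            species=row.species,
            locus=locus,
            sequence=str(entry.seq),
            voucher=getattr(row, "voucher", "") or None,
            origin=getattr(row, "origin", "") or None,
        ))
    if not records:
        raise ValueError(f"no FASTA records read from {path}")
    return LocusDataset(locus=locus, records=records, provenance=str(path))


def _is_indeterminate(species: str) -> bool:
    return any(tok.lower() in _INDET_TOKENS for tok in species.split())


def qc_filter(dataset: LocusDataset, min_len: int = 100, max_ambiguous: int = 1,
              similarity_min: float = 0.90, coverage_min: float = 0.90,
              ) -> tuple[LocusDataset, QCReport]:
    """Quality-control filter for a locus dataset.

    Rejects records that are shorter than ``min_len`` ungapped bases
    (reason ``short``), carry more than ``max_ambiguous`` ambiguous symbols
    (``ambiguous``), belong to an undetermined taxon — species name with a
    ``sp./spp./aff./cf.`` token — (``indeterminate_taxon``), or fail the
    congener screen (``congener_screen``): their best global-alignment
    identity AND query coverage against any surviving conspecific record must
    both reach the thresholds.  Sole representatives of a species pass the
    screen vacuously.  The screen is iterated to a fixed point so the filter
    is idempotent.
    """
    if not dataset.records:
        raise ValueError("qc_filter: empty dataset")
    rejected: list[tuple[str, str]] = []
    survivors = []
    for rec in dataset.records:
        if len(rec.ungapped) < min_len:
            rejected.append((rec.accession_id, "short"))
        elif rec.n_ambiguous > max_ambiguous:
            rejected.append((rec.accession_id, "ambiguous"))
        elif _is_indeterminate(rec.species):
            rejected.append((rec.accession_id, "indeterminate_taxon"))
        else:
            survivors.append(rec)

    def screen_fails(rec, peers):
        if not peers:
            return False  # vacuous pass for singletons
        for other in peers:
            pa = _align.global_align(rec.ungapped, other.ungapped)
            if pa.identity >= similarity_min and pa.coverage_a >= coverage_min:
                return False
        return True

    # fixed-point iteration: removing a record can orphan its conspecifics
    changed = True
    while changed:
        changed = False
        failing = []
        for rec in survivors:
            peers = [o for o in survivors
                     if o is not rec and o.species == rec.species]
            if screen_fails(rec, peers):
                failing.append(rec)
        if failing:
            changed = True
            for rec in failing:
                survivors.remove(rec)
                rejected.append((rec.accession_id, "congener_screen"))

    kept_ids = [r.accession_id for r in survivors]
    return dataset.subset(kept_ids), QCReport(kept=kept_ids, rejected=rejected)


def _gc_fraction(seq: str) -> float:
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom


def summarize_locus(dataset: LocusDataset, msa: _align.MultipleAlignment) -> LocusSummary:
    """Per-locus summary: length range/mean and GC on ungapped sequences
    (ambiguous bases excluded from the GC numerator and denominator),
    variable-site and indel-event counts on the alignment."""
    if not dataset.records:
        raise ValueError("summarize_locus: empty dataset")
    if msa.row_ids != dataset.ids:
        raise ValueError("MSA rows do not correspond 1:1 to dataset records")
    lengths = np.array([len(r.ungapped) for r in dataset.records])
    gcs = np.array([_gc_fraction(r.ungapped) for r in dataset.records])
    return LocusSummary(
        locus=dataset.locus,
        n_species=len(set(dataset.species)),
        n_accessions=len(dataset.records),
        length_min=int(lengths.min()),
        length_max=int(lengths.max()),
        length_mean=float(lengths.mean()),
        gc_mean=float(np.nanmean(gcs) * 100.0),
        n_variable_sites=_align.count_variable_sites(msa),
        n_indel_sites=_align.count_indel_sites(msa),
    )
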
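"""Core domain types and readers/writers for sequences, taxonomy and tables.

Sequence records move between stages as small frozen dataclasses; file
formats are deliberately boring: FASTA for sequences, TSV sidecars for
per-record metadata (keyed by FASTA id), Newick for trees.  All
alignment and amino-acid coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import IUPAC_NUC

FAMILIES = ("Crocodilidae", "Alligatoridae")
EXON_TARGETS = ("IIa_ex2", "IIa_ex3", "IIb_ex3")
VARIANT_NAME_RE = re.compile(r"^[A-Z][a-z]{3}-D[AB]\d{2}$")

#: genus -> family, mirroring the study taxonomy
GENUS_FAMILY = {
    "Crocodylus": "Crocodilidae",
    "Mecistops": "Crocodilidae",
    "Osteolaemus": "Crocodilidae",
    "Alligator": "Alligatoridae",
    "Caiman": "Alligatoridae",
    "Paleosuchus": "Alligatoridae",
    "Melanosuchus": "Alligatoridae",
}


@dataclass(frozen=True)
class SpeciesMeta:
    common_name: str
    scientific_name: str
    genus: str
    gene_prefix: str
    family: str = ""

    def __post_init__(self):
        if not re.fullmatch(r"[A-Z][a-z]{3}", self.gene_prefix):
            raise ValueError(f"gene_prefix must be a 4-letter code: {self.gene_prefix!r}")
        fam = self.family or GENUS_FAMILY.get(self.genus, "")
        if fam not in FAMILIES:
            raise ValueError(f"unknown family for genus {self.genus!r}")
        object.__setattr__(self, "family", fam)


@dataclass(frozen=True)
class CloneRead:
    read_id: str
    species: SpeciesMeta
    individual_id: str
    pcr_id: str
    direction: str  # forward | reverse
    seq: str
    exon_target: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError("empty sequence")
        bad = set(self.seq.upper()) - set(IUPAC_NUC) - {"-"}
        if bad:
            raise ValueError(f"non-IUPAC characters in {self.read_id}: {sorted(bad)}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.exon_target not in EXON_TARGETS:
            raise ValueError(f"bad exon_target {self.exon_target!r}")


@dataclass(frozen=True)
class ConsensusSequence:
    read_id: str
    species: SpeciesMeta
    individual_id: str
    pcr_id: str
    seq: str
    exon_target: str
    n_reads: int = 2


@dataclass(frozen=True)
class ValidatedVariant:
    name: str
    seq: str
    n_clones: int
    n_individuals: int
    species: SpeciesMeta | None = None
    functionality: str = "functional"
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if not VARIANT_NAME_RE.match(self.name):
            raise ValueError(f"variant name {self.name!r} violates naming scheme")
        if self.functionality == "functional" and self.reasons:
            raise ValueError("functional variant cannot carry reasons")


@dataclass
class Alignment:
    """Ordered gapped records of equal length; columns are 1-based."""

    records: list[tuple[str, str]]
    kind: str = "nucleotide"  # nucleotide | amino_acid | codon

    def __post_init__(self):
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.kind == "codon" and self.records and len(self.records[0][1]) % 3:
            raise ValueError("codon alignment length not divisible by 3")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.records]

    @property
    def n_sites(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, name: str) -> str:
        for n, s in self.records:
            if n == name:
                return s
        raise KeyError(name)

    def column(self, pos: int) -> str:
        """1-based column as a string over records."""
        return "".join(s[pos - 1] for _, s in self.records)

    def subset_codons(self, codon_sites: list[int]) -> "Alignment":
        """Restrict a codon alignment to the given 1-based codon columns."""
        if self.kind != "codon":
            raise ValueError("codon subset requires a codon alignment")
        keep = []
        for name, seq in self.records:
            keep.append((name, "".join(seq[3 * (c - 1) : 3 * c] for c in codon_sites)))
        return Alignment(keep, kind="codon")


METADATA_COLUMNS = ["read_id", "species_prefix", "individual_id", "pcr_id",
                    "direction", "exon_target"]
TAXONOMY_COLUMNS = ["gene_prefix", "common_name", "scientific_name", "genus", "family"]


def read_taxonomy(path: str | Path) -> dict[str, SpeciesMeta]:
    """Taxonomy TSV (one row per species, keyed by gene_prefix)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TAXONOMY_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        meta = SpeciesMeta(
            common_name=row.common_name, scientific_name=row.scientific_name,
            genus=row.genus, gene_prefix=row.gene_prefix,
            family=getattr(row, "family", "") or "",
        )
        if meta.gene_prefix in out:
            raise ValueError(f"duplicate gene_prefix {meta.gene_prefix}")
        out[meta.gene_prefix] = meta
    return out


def write_taxonomy(taxonomy: dict[str, SpeciesMeta], path: str | Path) -> None:
    rows = [
        {"gene_prefix": m.gene_prefix, "common_name": m.common_name,
         "scientific_name": m.scientific_name, "genus": m.genus, "family": m.family}
        for m in taxonomy.values()
    ]
    pd.DataFrame(rows, columns=TAXONOMY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta_with_metadata(
    fasta_path: str | Path,
    metadata_table: str | Path | pd.DataFrame,
    taxonomy: dict[str, SpeciesMeta],
) -> list[CloneRead]:
    """Join a clone FASTA with its metadata sidecar into CloneReads.

    Every FASTA record id must have a metadata row; order of the FASTA
    file is preserved.
    """
    if isinstance(metadata_table, pd.DataFrame):
        meta = metadata_table
    else:
        meta = pd.read_csv(metadata_table, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata table missing columns: {sorted(missing_cols)}")
    by_id = {row.read_id: row for row in meta.itertuples(index=False)}
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = by_id.get(rec.id)
        if row is None:
            raise KeyError(f"no metadata row for FASTA record {rec.id!r}")
        if row.species_prefix not in taxonomy:
            raise KeyError(f"unknown species prefix {row.species_prefix!r} for {rec.id}")
        reads.append(
            CloneRead(
                read_id=rec.id,
                species=taxonomy[row.species_prefix],
                individual_id=row.individual_id,
                pcr_id=row.pcr_id,
                direction=row.direction,
                seq=str(rec.seq).upper(),
                exon_target=row.exon_target,
            )
        )
    return reads


def write_clone_reads(reads: list[CloneRead], fasta_path: str | Path,
                      meta_path: str | Path) -> None:
    records = [SeqRecord(Seq(r.seq), id=r.read_id, description="") for r in reads]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {"read_id": r.read_id, "species_prefix": r.species.gene_prefix,
         "individual_id": r.individual_id, "pcr_id": r.pcr_id,
         "direction": r.direction, "exon_target": r.exon_target}
        for r in reads
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(meta_path, sep="\t", index=False)


def read_alignment_fasta(path: str | Path, kind: str = "nucleotide") -> Alignment:
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return Alignment(records, kind=kind)


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in aln.records]
    SeqIO.write(records, str(path), "fasta")


def write_variants_fasta(variants: list[ValidatedVariant], path: str | Path) -> None:
    records = [SeqRecord(Seq(v.seq), id=v.name, description="") for v in variants]
    SeqIO.write(records, str(path), "fasta")


def write_results(tables: dict[str, pd.DataFrame],
                  trees: dict[str, str],
                  variants: dict[str, list[ValidatedVariant]],
                  out_dir: str | Path) -> pd.DataFrame:
    """Write TSV tables, Newick trees and variant FASTAs; return a manifest.

    The manifest lists every file with its row (or record) count.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        entries.append({"file": path.name, "kind": "table", "rows": len(df)})
    for name, newick in trees.items():
        path = out / f"{name}.nwk"
        path.write_text(newick.rstrip() + "\n")
        entries.append({"file": path.name, "kind": "tree", "rows": 1})
    for name, vs in variants.items():
        path = out / f"{name}.fasta"
        write_variants_fasta(vs, path)
        entries.append({"file": path.name, "kind": "fasta", "rows": len(vs)})
    manifest = pd.DataFrame(entries, columns=["file", "kind", "rows"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


__all__ = [
    "SpeciesMeta", "CloneRead", "ConsensusSequence", "ValidatedVariant",
    "Alignment", "read_taxonomy", "write_taxonomy", "read_fasta_with_metadata",
    "write_clone_reads", "read_alignment_fasta", "write_alignment_fasta",
    "write_variants_fasta", "write_results", "GENUS_FAMILY", "EXON_TARGETS",
    "VARIANT_NAME_RE", "METADATA_COLUMNS",
]
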
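"""Readers, writers and core containers for every external format the
pipeline touches.

Formats handled: FASTA / FASTQ (phred+33) via Biopython, Newick via
dendropy, BLAST/DIAMOND-style 12-column tabular hit files, TSV gene-content
and phenotype tables, a protein reference registry (FASTA + TSV sidecar)
and a YAML config file.

Genome and gene ids are opaque, case-sensitive strings.  The variant→gene
mapping comes only from the registry table, never from parsing protein ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from flagmet.errors import ParseError, ValidationError

logger = logging.getLogger("flagmet")

ROLE_FLAGELLAR = "flagellar"
ROLE_MARKER = "marker"
ROLE_OTHER = "other"
ROLES = (ROLE_FLAGELLAR, ROLE_MARKER, ROLE_OTHER)

MOTILE = "motile"
NONMOTILE = "nonmotile"
PHENOTYPES = (MOTILE, NONMOTILE)


# ---------------------------------------------------------------------------
# Protein registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinEntry:
    """One protein variant of a gene family in the reference registry."""

    protein_id: str
    gene_id: str
    role: str
    aa_length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"protein {self.protein_id!r}: role {self.role!r} not in {ROLES}"
            )
        if self.aa_length <= 0:
            raise ValidationError(
                f"protein {self.protein_id!r}: aa_length must be > 0"
            )
        if self.sequence is not None and len(self.sequence) != self.aa_length:
            raise ValidationError(
                f"protein {self.protein_id!r}: aa_length {self.aa_length} "
                f"!= sequence length {len(self.sequence)}"
            )


class ProteinRegistry:
    """Reference set of protein variants grouped into gene families.

    Each gene family has one role — ``flagellar`` (the motility panel),
    ``marker`` (single-copy taxonomic markers used for normalization) or
    ``other`` — and one or more protein variants.
    """

    def __init__(self, entries: Iterable[ProteinEntry]):
        self.entries: list[ProteinEntry] = list(entries)
        self._by_protein: dict[str, ProteinEntry] = {}
        self.gene_index: dict[str, list[str]] = {}
        self._gene_role: dict[str, str] = {}
        for e in self.entries:
            if e.protein_id in self._by_protein:
                raise ValidationError(f"duplicate protein id {e.protein_id!r}")
            self._by_protein[e.protein_id] = e
            prior = self._gene_role.get(e.gene_id)
            if prior is not None and prior != e.role:
                raise ValidationError(
                    f"gene {e.gene_id!r} assigned two roles: {prior!r}, {e.role!r}"
                )
            self._gene_role[e.gene_id] = e.role
            self.gene_index.setdefault(e.gene_id, []).append(e.protein_id)

    def __len__(self) -> int:
        return len(self.entries)

    def protein(self, protein_id: str) -> ProteinEntry:
        try:
            return self._by_protein[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def role_of_gene(self, gene_id: str) -> str:
        return self._gene_role[gene_id]

    def gene_of_protein(self, protein_id: str) -> str:
        return self.protein(protein_id).gene_id

    def genes_with_role(self, role: str) -> list[str]:
        """Gene ids with the given role, in first-appearance order."""
        seen: list[str] = []
        for e in self.entries:
            if e.role == role and e.gene_id not in seen:
                seen.append(e.gene_id)
        return seen

    def gene_length_kb(self, gene_id: str) -> float:
        """Nucleotide gene length in kb: 3 × median variant aa length / 1000."""
        lengths = [self._by_protein[p].aa_length for p in self.gene_index[gene_id]]
        return 3.0 * median(lengths) / 1000.0


def read_registry(table_path, fasta_path=None) -> ProteinRegistry:
    """Load a protein registry from a TSV table and optional protein FASTA.

    The table needs columns ``protein_id``, ``gene_id``, ``role`` and
    (when no FASTA is given) ``aa_length``.  When a FASTA is supplied the
    amino-acid sequences are attached and lengths taken from them.
    """
    table = pd.read_csv(table_path, sep="\t", dtype=str)
    required = {"protein_id", "gene_id", "role"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{table_path}: registry table missing columns {sorted(missing)}")
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        seqs = {rid: s for rid, s in read_fasta(fasta_path)}
    entries = []
    for _, row in table.iterrows():
        pid = row["protein_id"]
        seq = seqs.get(pid)
        if seq is not None:
            aa_len = len(seq)
        elif "aa_length" in table.columns and not pd.isna(row["aa_length"]):
            aa_len = int(row["aa_length"])
        else:
            raise ParseError(
                f"{table_path}: protein {pid!r} has no aa_length and no FASTA sequence"
            )
        entries.append(ProteinEntry(pid, row["gene_id"], row["role"], aa_len, seq))
    return ProteinRegistry(entries)


def write_registry(registry: ProteinRegistry, table_path, fasta_path=None) -> None:
    rows = [
        {"protein_id": e.protein_id, "gene_id": e.gene_id, "role": e.role,
         "aa_length": e.aa_length}
        for e in registry.entries
    ]
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    if fasta_path is not None:
        records = [(e.protein_id, e.sequence) for e in registry.entries
                   if e.sequence is not None]
        write_fasta(records, fasta_path)


# ---------------------------------------------------------------------------
# Translated-search hits (12-column tabular)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    """One translated-search hit of a read against a registry protein."""

    read_id: str
    protein_id: str
    pct_identity: float  # percent, 0–100
    aln_length: int
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(
                f"hit {self.read_id!r}: pct_identity {self.pct_identity} outside [0, 100]"
            )
        if self.e_value < 0:
            raise ValidationError(f"hit {self.read_id!r}: negative e-value")


def read_hits_tabular(path) -> list[HitRecord]:
    """Parse standard 12-column translated-search tabular output.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Extra columns are ignored with a logged
    warning; fewer than 12 is a parse error naming the line.
    """
    hits: list[HitRecord] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            if len(parts) > 12 and not warned_extra:
                logger.warning(
                    "%s: line %d has %d columns; extra columns ignored",
                    path, lineno, len(parts),
                )
                warned_extra = True
            try:
                rec = HitRecord(
                    read_id=parts[0],
                    protein_id=parts[1],
                    pct_identity=float(parts[2]),
                    aln_length=int(parts[3]),
                    bit_score=float(parts[11]),
                    e_value=float(parts[10]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if not pd.notna(rec.bit_score) or rec.bit_score in (float("inf"), float("-inf")):
                raise ParseError(f"{path}: line {lineno}: non-finite bit score")
            hits.append(rec)
    return hits


def write_hits_tabular(hits: Sequence[HitRecord], path) -> None:
    """Write hits in the 12-column dialect (unmodelled columns zero-filled)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.protein_id}\t{h.pct_identity:g}\t{h.aln_length}"
                f"\t0\t0\t0\t0\t0\t0\t{h.e_value:g}\t{h.bit_score:g}\n"
            )


# ---------------------------------------------------------------------------
# Gene-content matrix and phenotype table
# ---------------------------------------------------------------------------

@dataclass
class GeneContentMatrix:
    """Genomes × gene families matrix of copy counts or presence/absence."""

    data: pd.DataFrame  # index: genome ids, columns: gene ids, int values
    is_binary: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate genome ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if (self.data.values < 0).any():
            raise ValidationError("gene-content matrix contains negative counts")
        if self.is_binary and not self.data.isin([0, 1]).all().all():
            raise ValidationError("matrix flagged binary but has values outside {0, 1}")

    @property
    def genome_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.data.columns.tolist()


def read_gene_content(path) -> GeneContentMatrix:
    """Read a TSV gene-content matrix (rows genomes, header row gene ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    genes = header[1:]
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ParseError(f"{path}: repeated gene columns {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ParseError(f"{path}: column {col!r} contains non-integer values")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate genome ids {dups}")
    is_binary = bool(df.isin([0, 1]).all().all())
    return GeneContentMatrix(df, is_binary=is_binary)


def write_gene_content(matrix: GeneContentMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t")


def read_phenotypes(path) -> pd.Series:
    """Read a two-column TSV (genome_id, label) into a genome→label Series.

    Labels must be ``motile`` or ``nonmotile``; ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: phenotype table needs two columns")
    ids, labels = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate genome ids {dups}")
    bad = sorted(set(labels) - set(PHENOTYPES))
    if bad:
        raise ParseError(f"{path}: unknown phenotype labels {bad}")
    series = pd.Series(labels.values, index=ids.values, name="phenotype")
    return series


def write_phenotypes(phenotypes: pd.Series, path) -> None:
    pd.DataFrame({"genome_id": phenotypes.index, "phenotype": phenotypes.values}) \
        .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / FASTQ / Newick / config
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) tuples, order preserved."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read FASTQ (phred+33) into (id, sequence, quality-string) tuples.

    Mismatched sequence/quality lengths raise a parse error.
    """
    out: list[tuple[str, str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq), qual))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ValidationError(
                    f"record {rid!r}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_newick(path) -> dendropy.Tree:
    """Read a Newick tree, preserving branch lengths and tip labels."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"{path}: malformed Newick: {exc}") from exc
    return tree


def load_config(path) -> dict:
    """Load the structured YAML config (thresholds, seeds, calibration)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping at top level")
    return cfg
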
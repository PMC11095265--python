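"""Ground-truth synthetic communities for calibrating the motility index.

This module builds synthetic bacterial genomes with a known trait state
(every genome carries each of the 120 single-copy marker families exactly
once; the 21 flagellar families are present iff the genome is motile),
simulates 150-bp shotgun reads from genome mixtures spanning a gradient of
flagellated-taxon proportions at 0.5× fold-coverage, and annotates reads
with a naive six-frame seed-and-extend translated search so the whole
pipeline runs without an external aligner.

The naive annotator's scores are surrogates (2 × matched aa for the bit
score, 10^(−matched aa / 2) for the e-value) and are NOT BLOSUM-based;
real-data runs must use genuine translated-search tabular output read
through :mod:`flagmet.io`.

A genome-tier generator (:func:`rule_labeled_gene_matrix`) producing
presence/absence matrices whose labels follow a known decision rule is
also provided for exercising the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from flagmet.errors import ValidationError
from flagmet.io import (
    GeneContentMatrix,
    HitRecord,
    MOTILE,
    NONMOTILE,
    ProteinEntry,
    ProteinRegistry,
    ROLE_FLAGELLAR,
    ROLE_MARKER,
)

logger = logging.getLogger("flagmet")

N_MARKER_GENES = 120
N_FLAGELLAR_GENES = 21

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# standard codon table, DNA alphabet
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.items():
    _CODONS_FOR_AA.setdefault(aa, []).append(codon)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def translate(seq: str) -> str:
    """Translate a DNA string (frame 0); stops are '*', ambiguity is 'X'."""
    return "".join(
        _CODON_TABLE.get(seq[i:i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def six_frame(seq: str) -> list[str]:
    rc = reverse_complement(seq)
    return [translate(seq[o:]) for o in range(3)] + [translate(rc[o:]) for o in range(3)]


# ---------------------------------------------------------------------------
# Synthetic genomes and registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    protein_id: str


@dataclass
class SyntheticGenome:
    """A synthetic genome with known gene layout and motility state."""

    genome_id: str
    sequence: str
    features: list[GeneFeature]
    motile: bool

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        prev_end = 0
        for f in sorted(self.features, key=lambda f: f.start):
            if f.start < prev_end:
                raise ValidationError(
                    f"{self.genome_id}: overlapping features at {f.start}"
                )
            prev_end = f.end
        if prev_end > self.length_bp:
            raise ValidationError(f"{self.genome_id}: feature span exceeds genome")


@dataclass
class GenomeConfig:
    """Knobs for one synthetic genome.

    ``flagellar_dropout`` removes flagellar genes from motile genomes;
    ``flagellar_contamination`` adds individual flagellar genes to
    nonmotile genomes (mimicking gene conservation in nonmotile taxa).
    Both default to zero, in which case flagellar genes occur iff motile.
    """

    genome_id: str
    motile: bool
    intergenic_length_range: tuple[int, int] = (50, 200)
    flagellar_dropout: float = 0.0
    flagellar_contamination: float = 0.0


def _random_protein(rng: np.random.Generator, aa_len: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=aa_len))


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [rng.choice(_CODONS_FOR_AA[aa]) for aa in protein]
    codons.append(rng.choice(_CODONS_FOR_AA["*"]))
    return "".join(codons)


def build_reference(
    n_marker: int = N_MARKER_GENES,
    n_flagellar: int = N_FLAGELLAR_GENES,
    seed: int = 0,
    variants_per_gene: int = 1,
    gene_length_range_nt: tuple[int, int] = (300, 1800),
) -> ProteinRegistry:
    """Create the synthetic protein registry shared by a genome pool.

    Gene nucleotide lengths (including the stop codon) are drawn uniformly
    from ``gene_length_range_nt``; the marker and flagellar families share
    the distribution so their RPK medians are comparable.
    """
    rng = np.random.default_rng(seed)
    entries = []
    specs = [(f"marker_{i + 1:03d}", ROLE_MARKER) for i in range(n_marker)]
    specs += [(f"flag_{i + 1:03d}", ROLE_FLAGELLAR) for i in range(n_flagellar)]
    for gene_id, role in specs:
        nt_len = int(rng.integers(gene_length_range_nt[0], gene_length_range_nt[1] + 1))
        aa_len = max(nt_len // 3 - 1, 30)  # minus stop codon
        for v in range(variants_per_gene):
            seq = _random_protein(rng, aa_len)
            entries.append(ProteinEntry(
                protein_id=f"{gene_id}_v{v + 1}", gene_id=gene_id,
                role=role, aa_length=aa_len, sequence=seq,
            ))
    return ProteinRegistry(entries)


def generate_genome(
    config: GenomeConfig, registry: ProteinRegistry, seed: int = 0
) -> SyntheticGenome:
    """Lay out one genome: every marker family once, flagellar iff motile.

    Gene order is shuffled; each gene picks one registry variant, is
    reverse-translated with random synonymous codons, placed on a random
    strand and separated by random intergenic spacers.  Byte-identical
    output under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(registry.genes_with_role(ROLE_MARKER))
    flag_genes = registry.genes_with_role(ROLE_FLAGELLAR)
    if config.motile:
        for g in flag_genes:
            if rng.random() >= config.flagellar_dropout:
                gene_ids.append(g)
    else:
        for g in flag_genes:
            if rng.random() < config.flagellar_contamination:
                gene_ids.append(g)
    order = rng.permutation(len(gene_ids))
    gene_ids = [gene_ids[i] for i in order]

    lo, hi = config.intergenic_length_range
    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for gene_id in gene_ids:
        spacer_len = int(rng.integers(lo, hi + 1))
        spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
        chunks.append(spacer)
        pos += spacer_len
        variants = registry.gene_index[gene_id]
        protein_id = variants[int(rng.integers(len(variants)))]
        protein = registry.protein(protein_id)
        if protein.sequence is None:
            raise ValidationError(f"registry protein {protein_id} lacks a sequence")
        nt = _reverse_translate(rng, protein.sequence)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            placed = reverse_complement(nt)
        else:
            placed = nt
        features.append(GeneFeature(gene_id, pos, pos + len(nt), strand, protein_id))
        chunks.append(placed)
        pos += len(nt)
    tail = "".join(rng.choice(list("ACGT"), size=int(rng.integers(lo, hi + 1))))
    chunks.append(tail)
    genome = SyntheticGenome(
        genome_id=config.genome_id, sequence="".join(chunks),
        features=features, motile=config.motile,
    )
    genome.validate()
    return genome


def generate_pool(
    n_motile: int, n_nonmotile: int, registry: ProteinRegistry, seed: int = 0,
    **config_kwargs,
) -> list[SyntheticGenome]:
    """Generate a pool of motile and nonmotile genomes from one registry."""
    rng = np.random.default_rng(seed)
    pool = []
    for i in range(n_motile):
        cfg = GenomeConfig(genome_id=f"motile_{i + 1:02d}", motile=True, **config_kwargs)
        pool.append(generate_genome(cfg, registry, seed=int(rng.integers(2**31))))
    for i in range(n_nonmotile):
        cfg = GenomeConfig(genome_id=f"nonmotile_{i + 1:02d}", motile=False, **config_kwargs)
        pool.append(generate_genome(cfg, registry, seed=int(rng.integers(2**31))))
    return pool


# ---------------------------------------------------------------------------
# Mixtures, read simulation, gradient
# ---------------------------------------------------------------------------

@dataclass
class MockMixtureSpec:
    """One mock community: members, abundances and simulation settings."""

    mixture_id: str
    members: list[tuple[str, float]]  # (genome_id, relative abundance)
    proportion_flagellated: float
    coverage_fold: float = 0.5
    read_length_bp: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def validate(self, genomes: dict[str, SyntheticGenome]) -> None:
        total = sum(a for _, a in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"{self.mixture_id}: abundances sum to {total}, not 1")
        motile_mass = sum(
            a for g, a in self.members if genomes[g].motile
        )
        if abs(motile_mass - self.proportion_flagellated) > 1e-9:
            raise ValidationError(
                f"{self.mixture_id}: stated proportion {self.proportion_flagellated} "
                f"inconsistent with abundance-weighted motile mass {motile_mass}"
            )


def simulate_reads(
    mixture: MockMixtureSpec, genomes: dict[str, SyntheticGenome]
) -> list[tuple[str, str, str]]:
    """Simulate uniform shotgun reads from a mixture; FASTQ-style records.

    The read count for member genome *i* is
    ``floor(abundance_i × L_total × coverage_fold / read_length)`` where
    ``L_total`` is the summed length of all member genomes, so an
    equal-abundance mixture sequences every member at ``coverage_fold``×
    fold-coverage.  Start positions are uniform, reads are
    reverse-complemented with probability 0.5, substitution errors are
    applied at ``error_rate`` and qualities are constant phred+33 'I'.
    """
    if mixture.coverage_fold <= 0:
        raise ValidationError("coverage_fold must be > 0")
    rng = np.random.default_rng(mixture.seed)
    rl = mixture.read_length_bp
    l_total = sum(genomes[g].length_bp for g, _ in mixture.members)
    reads: list[tuple[str, str, str]] = []
    qual = "I" * rl
    bases = np.array(list("ACGT"))
    for genome_id, abundance in mixture.members:
        genome = genomes[genome_id]
        if rl > genome.length_bp:
            raise ValidationError(
                f"read length {rl} exceeds genome {genome_id} ({genome.length_bp} bp)"
            )
        n_reads = int(abundance * l_total * mixture.coverage_fold / rl)
        starts = rng.integers(0, genome.length_bp - rl + 1, size=n_reads)
        flips = rng.random(n_reads) < 0.5
        for i, (start, flip) in enumerate(zip(starts, flips)):
            seq = genome.sequence[start:start + rl]
            if flip:
                seq = reverse_complement(seq)
            if mixture.error_rate > 0:
                arr = np.array(list(seq))
                err = rng.random(rl) < mixture.error_rate
                if err.any():
                    arr[err] = bases[rng.integers(0, 4, size=int(err.sum()))]
                    seq = "".join(arr)
            reads.append((f"{mixture.mixture_id}|{genome_id}|{i}", seq, qual))
    return reads


@dataclass
class GradientDesign:
    """A series of mixtures spanning proportions 0→1 of flagellated taxa."""

    mixtures: list[MockMixtureSpec]

    @property
    def n_points(self) -> int:
        return len(self.mixtures)

    @property
    def proportions(self) -> list[float]:
        return [m.proportion_flagellated for m in self.mixtures]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mixture_id": [m.mixture_id for m in self.mixtures],
            "proportion_flagellated": self.proportions,
        })


def build_gradient(
    pool: list[SyntheticGenome], n_points: int = 14, seed: int = 0,
    coverage_fold: float = 0.5, read_length_bp: int = 150,
    error_rate: float = 0.0,
) -> GradientDesign:
    """Mixtures at evenly spaced flagellated proportions from 0 to 1.

    At proportion *p* the motile pool members share abundance *p* equally
    and the nonmotile members share 1−*p*; zero-abundance members are
    dropped, so the endpoints contain a single class.
    """
    motile = [g for g in pool if g.motile]
    nonmotile = [g for g in pool if not g.motile]
    if not motile or not nonmotile:
        raise ValidationError("genome pool must contain both motile and nonmotile genomes")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    proportions = np.linspace(0.0, 1.0, n_points)
    mixtures = []
    for j, p in enumerate(proportions):
        members: list[tuple[str, float]] = []
        if p > 0:
            for g in motile:
                members.append((g.genome_id, p / len(motile)))
        if p < 1:
            for g in nonmotile:
                members.append((g.genome_id, (1 - p) / len(nonmotile)))
        spec = MockMixtureSpec(
            mixture_id=f"mix_{j:02d}",
            members=members,
            proportion_flagellated=float(p),
            coverage_fold=coverage_fold,
            read_length_bp=read_length_bp,
            error_rate=error_rate,
            seed=int(rng.integers(2**31)),
        )
        spec.validate({g.genome_id: g for g in pool})
        mixtures.append(spec)
    return GradientDesign(mixtures)


# ---------------------------------------------------------------------------
# Naive translated-search annotator
# ---------------------------------------------------------------------------

def annotate_reads_naive(
    reads: list[tuple[str, str, str]] | list[tuple[str, str]],
    registry: ProteinRegistry,
    k: int = 7,
) -> list[HitRecord]:
    """Six-frame seed-and-extend translated search against the registry.

    Each read is translated in six frames; exact ``k``-aa seeds anchor
    ungapped alignments over the full read/protein overlap on that
    diagonal.  Percent identity is matches / aligned aa × 100; the
    surrogate bit score is 2 × matched aa and the surrogate e-value
    10^(−matched aa / 2).  At most one hit is emitted per read — the
    highest bit score, ties broken by lower e-value, then lexicographic
    protein id.
    """
    if len(registry) == 0:
        raise ValidationError("empty protein registry")
    proteins = [e for e in registry.entries if e.sequence is not None]
    if not proteins:
        raise ValidationError("registry has no protein sequences to search against")
    proteins.sort(key=lambda e: e.protein_id)
    index: dict[str, list[tuple[int, int]]] = {}
    for pidx, entry in enumerate(proteins):
        s = entry.sequence
        for pos in range(len(s) - k + 1):
            index.setdefault(s[pos:pos + k], []).append((pidx, pos))

    hits: list[HitRecord] = []
    for rec in reads:
        read_id, seq = rec[0], rec[1]
        frames = six_frame(seq.upper())
        candidates: set[tuple[int, int, int]] = set()
        for fi, t in enumerate(frames):
            for i in range(len(t) - k + 1):
                seeds = index.get(t[i:i + k])
                if seeds:
                    for pidx, pos in seeds:
                        candidates.add((fi, pidx, pos - i))
        best = None  # (-matches, protein_id, aligned)
        for fi, pidx, off in candidates:
            t = frames[fi]
            s = proteins[pidx].sequence
            a = max(0, -off)
            b = min(len(t), len(s) - off)
            if b <= a:
                continue
            matches = sum(1 for x in range(a, b) if t[x] == s[off + x])
            key = (-matches, proteins[pidx].protein_id, b - a)
            if best is None or key < best:
                best = key
        if best is not None:
            matches = -best[0]
            aligned = best[2]
            hits.append(HitRecord(
                read_id=read_id,
                protein_id=best[1],
                pct_identity=100.0 * matches / aligned,
                aln_length=aligned,
                bit_score=2.0 * matches,
                e_value=10.0 ** (-matches / 2.0),
            ))
    return hits


# ---------------------------------------------------------------------------
# Genome-tier synthetic data: rule-labeled gene matrices
# ---------------------------------------------------------------------------

def rule_labeled_gene_matrix(
    n_genomes: int = 600,
    n_genes: int = 21,
    rule_threshold: int = 15,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[GeneContentMatrix, pd.Series]:
    """Binary matrix whose labels follow a known deterministic rule.

    Each genome draws a per-genome gene-carriage probability from a
    two-component mixture — half the genomes gene-rich (Beta(24, 2), i.e.
    carrying nearly the complete panel, as flagellated taxa do), half
    gene-poor (Beta(2, 8), with a small tail of nonmotile-style genomes
    that conserve most flagellar genes) — then carries a
    Binomial(n_genes, θ) subset.  The label is motile iff at least
    ``rule_threshold`` of the ``n_genes`` panel genes are present, giving
    roughly balanced classes with a small, hard boundary population.
    """
    rng = np.random.default_rng(seed)
    gene_ids = gene_ids or [f"flag_{i + 1:03d}" for i in range(n_genes)]
    rich = rng.random(n_genomes) < 0.5
    theta = np.where(
        rich, rng.beta(24, 2, size=n_genomes), rng.beta(2, 8, size=n_genomes)
    )
    X = (rng.random((n_genomes, n_genes)) < theta[:, None]).astype(int)
    labels = np.where(X.sum(axis=1) >= rule_threshold, MOTILE, NONMOTILE)
    genome_ids = [f"genome_{i + 1:04d}" for i in range(n_genomes)]
    matrix = GeneContentMatrix(
        pd.DataFrame(X, index=genome_ids, columns=gene_ids), is_binary=True
    )
    return matrix, pd.Series(labels, index=genome_ids, name="phenotype")
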
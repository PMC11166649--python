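"""Reference sequences, gene annotations and spliced CDS extraction.

Gene models are held as ordered CDS intervals on a reference chromosome.
Internally all intervals are 0-based half-open (BED convention); VCF
positions are 1-based and converted where variants are parsed.

Annotations are accepted either as BED12 (one line per gene, blocks =
CDS pieces) or as a minimal GFF3 subset restricted to ``gene`` /
``mRNA`` / ``CDS`` features with ``ID`` and ``Parent`` attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "CanonicalRef",
    "GeneModel",
    "ReferenceBundle",
    "load_reference",
    "spliced_cds",
    "translate",
    "DEFAULT_RESISTANCE_GENES",
]

#: genes treated as resistance loci unless the caller overrides the set
DEFAULT_RESISTANCE_GENES = ("vgsc", "ace1", "rdl", "gste2")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class GeneModelError(ValueError):
    """Raised for malformed or inconsistent gene annotations."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GeneModelError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise GeneModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CanonicalRef:
    """Cross-species reference protein used for residue renumbering."""

    species: str
    protein_id: str
    sequence: str


@dataclass
class GeneModel:
    gene_id: str
    name: str
    intervals: tuple[GenomicInterval, ...]
    strand: str
    is_resistance_gene: bool = False
    canonical_ref: CanonicalRef | None = None

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals, key=lambda iv: iv.start))
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise GeneModelError(f"{self.gene_id}: overlapping CDS intervals")
            if a.chrom != b.chrom:
                raise GeneModelError(f"{self.gene_id}: intervals on multiple chromosomes")
        if any(iv.strand != self.strand for iv in ivs):
            raise GeneModelError(f"{self.gene_id}: mixed strands in one gene")
        self.intervals = ivs
        if self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (start of first interval, end of last)."""
        return self.intervals[0].start, self.intervals[-1].end

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a 0-based genomic position to a 0-based CDS offset.

        Returns ``None`` when the position falls outside every CDS
        interval (intron or flank).  On the minus strand the CDS runs
        antiparallel to the genome, so offsets count from the interval
        block with the highest coordinates.
        """
        offset = 0
        for iv in self.intervals:
            if iv.start <= pos0 < iv.end:
                fwd = offset + (pos0 - iv.start)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            offset += len(iv)
        return None

    def cds_to_genomic(self, cds_idx: int) -> int:
        """Inverse of :meth:`genomic_to_cds` (0-based both ways)."""
        if not (0 <= cds_idx < self.cds_length):
            raise GeneModelError(f"CDS offset {cds_idx} out of range")
        fwd = cds_idx if self.strand == "+" else self.cds_length - 1 - cds_idx
        offset = 0
        for iv in self.intervals:
            if fwd < offset + len(iv):
                return iv.start + (fwd - offset)
            offset += len(iv)
        raise AssertionError("unreachable")


@dataclass
class ReferenceBundle:
    """Chromosome sequences, gene models and canonical proteins."""

    sequences: dict[str, str]
    genes: dict[str, GeneModel]
    canonical_proteins: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for gid, model in self.genes.items():
            if model.chrom not in self.sequences:
                raise GeneModelError(
                    f"gene {gid}: chromosome {model.chrom!r} missing from FASTA"
                )
            chrom_len = len(self.sequences[model.chrom])
            for iv in model.intervals:
                if iv.end > chrom_len:
                    raise GeneModelError(
                        f"gene {gid}: interval {iv.start}-{iv.end} exceeds "
                        f"{model.chrom} length {chrom_len}"
                    )

    def resistance_genes(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.is_resistance_gene]

    def background_genes(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if not g.is_resistance_gene]

    def protein(self, gene_id: str) -> str:
        """Native protein sequence of a gene (stop stripped)."""
        return translate(spliced_cds(self.genes[gene_id], self))


def _parse_bed12(path: Path) -> dict[str, GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise GeneModelError(f"BED12 requires 12 columns, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise GeneModelError(f"{name}: blockCount mismatch")
            ivs = [
                GenomicInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            genes[name] = GeneModel(name, name, tuple(ivs), strand)
    return genes


def _gff3_attributes(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _parse_gff3(path: Path) -> dict[str, GeneModel]:
    # minimal subset: gene/mRNA give IDs, CDS rows carry Parent links
    mrna_to_gene: dict[str, str] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            a = _gff3_attributes(attrs)
            if ftype == "mRNA":
                mrna_to_gene[a["ID"]] = a.get("Parent", a["ID"])
            elif ftype == "CDS":
                parent = a["Parent"]
                gene = mrna_to_gene.get(parent, parent)
                cds.setdefault(gene, []).append(
                    GenomicInterval(chrom, int(start) - 1, int(end), strand)
                )
    return {
        gid: GeneModel(gid, gid, tuple(ivs), ivs[0].strand)
        for gid, ivs in cds.items()
    }


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_reference(
    fasta_path: str | Path,
    annotation_path: str | Path,
    canonical_fasta_path: str | Path | None = None,
    resistance_genes: Iterable[str] = DEFAULT_RESISTANCE_GENES,
    canonical_map: Mapping[str, tuple[str, str]] | None = None,
) -> ReferenceBundle:
    """Load FASTA + annotation (+ canonical proteins) into a validated bundle.

    Parameters
    ----------
    canonical_map
        gene_id -> (species label, canonical FASTA record id).  Links each
        resistance gene to the cross-species protein whose numbering the
        field uses for that gene (e.g. vgsc -> *M. domestica* VGSC).
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    seqs = _read_fasta(fasta_path)
    if str(annotation_path).endswith((".gff", ".gff3")):
        genes = _parse_gff3(annotation_path)
    else:
        genes = _parse_bed12(annotation_path)

    resistance = set(resistance_genes)
    canon_seqs: dict[str, str] = {}
    if canonical_fasta_path is not None:
        canon_records = _read_fasta(Path(canonical_fasta_path))
    else:
        canon_records = {}
    for gid, model in genes.items():
        model.is_resistance_gene = gid in resistance
        if canonical_map and gid in canonical_map:
            species, rec_id = canonical_map[gid]
            if rec_id in canon_records:
                model.canonical_ref = CanonicalRef(species, rec_id, canon_records[rec_id])
                canon_seqs[species] = canon_records[rec_id]

    bundle = ReferenceBundle(seqs, genes, canon_seqs)
    bundle.validate()
    return bundle


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_cds(model: GeneModel, bundle: ReferenceBundle) -> str:
    """Concatenated exonic sequence in transcription order.

    Minus-strand genes are reverse-complemented so the returned sequence
    always starts at the start codon.
    """
    chrom_seq = bundle.sequences[model.chrom]
    parts = [chrom_seq[iv.start : iv.end] for iv in model.intervals]
    seq = "".join(parts).upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise GeneModelError(
            f"{model.gene_id}: ambiguous bases {sorted(bad)} in CDS"
        )
    if model.strand == "-":
        seq = reverse_complement(seq)
    assert len(seq) == model.cds_length
    return seq


def translate(cds: str, allow_internal_stop: bool = False) -> str:
    """Standard-genetic-code translation with one trailing stop stripped.

    ``N``-containing codons translate to ``X``.  An internal stop raises
    unless ``allow_internal_stop`` is set, in which case it is kept as
    ``'*'``.
    """
    if len(cds) % 3 != 0:
        raise GeneModelError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot and not allow_internal_stop:
        raise GeneModelError(f"internal stop at codon {prot.index('*') + 1}")
    return prot


def codons_for(aa: str) -> list[str]:
    """All standard-code codons encoding an amino acid (or '*' for stop)."""
    if aa == "*":
        return list(_STANDARD_TABLE.stop_codons)
    return [c for c, a in _STANDARD_TABLE.forward_table.items() if a == aa]


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Serialise gene models as BED12 (inverse of the BED12 loader)."""
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.span
            sizes = ",".join(str(len(iv)) for iv in g.intervals)
            starts = ",".join(str(iv.start - start) for iv in g.intervals)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(start),
                        str(end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(g.intervals)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
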
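"""Codon-level consequence calling for variants in resistance genes.

Each biallelic VCF record is classified independently against the gene
model it overlaps: SNPs are substituted into the spliced CDS and the
affected codon retranslated; indels whose length is a multiple of three
become in-frame insertions/deletions, anything else a frameshift.
Adjacent SNPs are *not* merged into haplotype-aware codons — the variant
catalogue is per-record, which mirrors how per-SNP surveys are usually
reported and is a documented limitation.

Also provides the codon-arithmetic utilities behind mutational
accessibility arguments (e.g. ace-1 G119S needs two nucleotide changes
in *Ae. aegypti* whereas single-hit substitutions dominate observed
resistance alleles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np

from .gene_models import (
    GeneModel,
    ReferenceBundle,
    codons_for,
    reverse_complement,
    spliced_cds,
    translate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "AminoAcidEffect",
    "read_vcf",
    "decompose_variants",
    "filter_min_depth",
    "classify_effect",
    "classify_all",
    "min_codon_substitutions",
    "aa_transition_bound",
]

EFFECT_CLASSES = (
    "synonymous",
    "missense",
    "stop_gained",
    "stop_lost",
    "inframe_insertion",
    "inframe_deletion",
    "frameshift",
    "unknown",
)

MISSING = -1


@dataclass
class VariantRecord:
    """One VCF site with per-sample genotypes.

    ``genotypes`` is an (n_samples, 2) int array of allele indices with
    ``-1`` for missing; ``phased`` a boolean vector; ``depths`` an int
    vector (``-1`` when the DP field was absent).
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray
    phased: np.ndarray
    depths: np.ndarray | None = None
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError(f"{self.chrom}:{self.pos} alt equals ref")
        n_alleles = 1 + len(self.alts)
        if self.genotypes.size and self.genotypes.max() >= n_alleles:
            raise ValueError(f"{self.chrom}:{self.pos} allele index out of range")

    @property
    def alt(self) -> str:
        if len(self.alts) != 1:
            raise ValueError("record is not biallelic")
        return self.alts[0]

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carrier_mask(self) -> np.ndarray:
        """Samples carrying >=1 copy of the (single) alt allele."""
        return (self.genotypes == 1).any(axis=1)


@dataclass(frozen=True)
class AminoAcidEffect:
    gene_id: str
    codon_number_native: int
    ref_aa: str
    alt_aa: str
    effect_class: str
    native_label: str
    canonical_position: int | None = None
    canonical_species: str | None = None
    variant_key: tuple[str, int, str, str] | None = None

    @property
    def canonical_label(self) -> str | None:
        if self.canonical_position is None:
            return None
        return f"{self.ref_aa}{self.canonical_position}{self.alt_aa}"

    @property
    def label(self) -> str:
        """Canonical label when mappable, else the native one."""
        return self.canonical_label or self.native_label


# ---------------------------------------------------------------------------
# VCF I/O

def read_vcf(path: str | Path) -> tuple[list[VariantRecord], tuple[str, ...]]:
    """Parse a (possibly gzipped) VCF 4.2 into VariantRecords.

    Uses pysam; GT and DP FORMAT fields are honoured, everything else is
    ignored.  Returns (records, sample names).
    """
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = tuple(vf.header.samples)
        for rec in vf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            if not alts:
                continue
            n = len(samples)
            gts = np.full((n, 2), MISSING, dtype=np.int16)
            phased = np.zeros(n, dtype=bool)
            depths = np.full(n, MISSING, dtype=np.int32)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                alleles = call.get("GT", (None, None))
                for j, a in enumerate(alleles[:2]):
                    if a is not None:
                        gts[i, j] = a
                phased[i] = bool(call.phased)
                dp = call.get("DP")
                if dp is not None:
                    depths[i] = dp
            records.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, alts, gts, phased, depths, samples)
            )
    return records, samples


# ---------------------------------------------------------------------------
# Normalisation

def _left_align(chrom_seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared bases and shift an indel to its leftmost representation.

    ``pos`` is 1-based.  ``chrom_seq`` supplies context bases for the
    left extension step.  Implements the standard normalisation
    algorithm (repeated right-trim / left-extend, then left-trim).
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if ref and alt:
                continue
        if len(ref) == 0 or len(alt) == 0:
            if pos == 1:
                raise ValueError("cannot left-extend past chromosome start")
            base = chrom_seq[pos - 2].upper()
            ref, alt, pos = base + ref, base + alt, pos - 1
            continue
        if not (ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1)):
            break
    # left-trim shared prefix, keeping at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def decompose_variants(
    records: list[VariantRecord], bundle: ReferenceBundle | None = None
) -> list[VariantRecord]:
    """Split multiallelic records into biallelic ones and left-align indels.

    Genotypes are recoded per retained alt: the retained alt allele
    becomes 1, reference and *other* alt alleles become 0, missing stays
    missing.  Symbolic alleles (``<DEL>`` etc.) are dropped with a
    logged count.
    """
    out: list[VariantRecord] = []
    n_symbolic = 0
    for rec in records:
        for ai, alt in enumerate(rec.alts, start=1):
            if alt.startswith("<") or "]" in alt or "[" in alt:
                n_symbolic += 1
                continue
            gts = rec.genotypes.copy()
            keep = gts == ai
            missing = gts == MISSING
            gts = np.where(keep, 1, 0).astype(np.int16)
            gts[missing] = MISSING
            pos, ref, a = rec.pos, rec.ref, alt
            if bundle is not None and rec.chrom in bundle.sequences and len(ref) != len(a):
                pos, ref, a = _left_align(bundle.sequences[rec.chrom], pos, ref, a)
            elif len(ref) != len(a) or len(ref) > 1:
                # trim without context (no left extension possible)
                while len(ref) > 1 and len(a) > 1 and ref[-1] == a[-1]:
                    ref, a = ref[:-1], a[:-1]
                while len(ref) > 1 and len(a) > 1 and ref[0] == a[0]:
                    ref, a, pos = ref[1:], a[1:], pos + 1
            out.append(
                replace(rec, pos=pos, ref=ref, alts=(a,), genotypes=gts)
            )
    if n_symbolic:
        logger.warning("skipped %d symbolic alt alleles", n_symbolic)
    return out


def filter_min_depth(
    records: list[VariantRecord], min_depth: int = 5
) -> list[VariantRecord]:
    """Set genotypes with read depth below ``min_depth`` to missing.

    The filter is applied per genotype; a site where every genotype
    becomes missing is dropped.  Genotypes without depth information
    pass through unchanged (with a warning).
    """
    out = []
    n_dropped = 0
    n_nodepth = 0
    for rec in records:
        if rec.depths is None:
            n_nodepth += 1
            out.append(rec)
            continue
        if (rec.depths < MISSING).any():
            raise ValueError(f"{rec.chrom}:{rec.pos} negative depth")
        low = (rec.depths >= 0) & (rec.depths < min_depth)
        n_nodepth += int((rec.depths == MISSING).sum() > 0)
        gts = rec.genotypes.copy()
        gts[low, :] = MISSING
        if (gts == MISSING).all():
            n_dropped += 1
            continue
        out.append(replace(rec, genotypes=gts))
    if n_dropped:
        logger.info("depth filter removed %d sites entirely", n_dropped)
    if n_nodepth:
        logger.warning("%d records lacked per-sample depth; passed through", n_nodepth)
    return out


# ---------------------------------------------------------------------------
# Effect calling

def classify_effect(
    model: GeneModel, bundle: ReferenceBundle, v: VariantRecord
) -> AminoAcidEffect | None:
    """Amino-acid consequence of one biallelic variant, or None if
    the variant does not touch the gene's CDS."""
    cds = spliced_cds(model, bundle)
    pos0 = v.pos - 1

    if v.is_snp:
        cds_idx = model.genomic_to_cds(pos0)
        if cds_idx is None:
            return None
        ref_base, alt_base = v.ref, v.alt
        if model.strand == "-":
            ref_base = reverse_complement(ref_base)
            alt_base = reverse_complement(alt_base)
        if cds[cds_idx] != ref_base.upper():
            logger.warning(
                "%s:%d ref allele %s disagrees with reference CDS base %s",
                v.chrom, v.pos, v.ref, cds[cds_idx],
            )
        codon_i = cds_idx // 3
        within = cds_idx % 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        if "N" in codon:
            return AminoAcidEffect(
                model.gene_id, codon_i + 1, "X", "X", "unknown",
                f"X{codon_i + 1}X", variant_key=v.key,
            )
        new_codon = codon[:within] + alt_base.upper() + codon[within + 1 :]
        ref_aa = _codon_aa(codon)
        alt_aa = _codon_aa(new_codon)
        if ref_aa == alt_aa:
            klass = "synonymous"
        elif alt_aa == "*":
            klass = "stop_gained"
        elif ref_aa == "*":
            klass = "stop_lost"
        else:
            klass = "missense"
        return AminoAcidEffect(
            model.gene_id, codon_i + 1, ref_aa, alt_aa, klass,
            f"{ref_aa}{codon_i + 1}{alt_aa}", variant_key=v.key,
        )

    # indel / MNV path
    ref, alt = v.ref.upper(), v.alt.upper()
    start0, end0 = pos0, pos0 + len(ref) - 1
    idx_start = model.genomic_to_cds(start0)
    idx_end = model.genomic_to_cds(end0)
    span_start, span_end = model.span
    if end0 < span_start or start0 >= span_end:
        return None
    if idx_start is None and idx_end is None and len(ref) == 1:
        # pure insertion at an intronic anchor base
        return None
    if idx_start is None or idx_end is None:
        logger.info("%s:%d variant spans an exon boundary", v.chrom, v.pos)
        return AminoAcidEffect(
            model.gene_id, 0, "?", "?", "unknown", "spans_exon_boundary",
            variant_key=v.key,
        )
    # crossing an intron internally also counts as boundary-spanning
    if abs(idx_end - idx_start) != len(ref) - 1:
        return AminoAcidEffect(
            model.gene_id, 0, "?", "?", "unknown", "spans_exon_boundary",
            variant_key=v.key,
        )

    dlen = len(alt) - len(ref)
    if dlen == 0:
        # multi-nucleotide substitution: retranslate the touched window
        return _classify_mnv(model, cds, v, idx_start, idx_end)
    if dlen % 3 != 0:
        codon_n = min(idx_start, idx_end) // 3 + 1
        return AminoAcidEffect(
            model.gene_id, codon_n, "?", "?", "frameshift",
            f"fs{codon_n}", variant_key=v.key,
        )
    if dlen > 0:
        ins = alt[len(ref):] if alt.startswith(ref) else alt[1:]
        if model.strand == "-":
            ins = reverse_complement(ins)
        anchor = idx_start if model.strand == "+" else idx_end
        # insertion lands after the anchor base on the CDS strand
        codon_n = (anchor + 1) // 3 + 1
        # translate inserted residues in the frame they create
        insert_cds_pos = anchor + 1
        phase = insert_cds_pos % 3
        window = cds[insert_cds_pos - phase : insert_cds_pos] + ins + \
            cds[insert_cds_pos : insert_cds_pos + (3 - (phase + len(ins)) % 3) % 3]
        aa_ins = "".join(_codon_aa(window[i : i + 3]) for i in range(0, len(window) - len(window) % 3, 3))
        return AminoAcidEffect(
            model.gene_id, codon_n, "-", aa_ins, "inframe_insertion",
            f"{codon_n}ins{aa_ins}", variant_key=v.key,
        )
    # in-frame deletion
    ndel = -dlen
    del_start = (idx_start + 1) if model.strand == "+" else (idx_end - ndel)
    codon_n = del_start // 3 + 1
    deleted = cds[del_start : del_start + ndel]
    aa_del = "".join(
        _codon_aa(deleted[i : i + 3]) if del_start % 3 == 0 and len(deleted[i:i+3]) == 3 else "?"
        for i in range(0, ndel, 3)
    )
    return AminoAcidEffect(
        model.gene_id, codon_n, aa_del, "-", "inframe_deletion",
        f"{codon_n}del{aa_del}", variant_key=v.key,
    )


def _classify_mnv(model, cds, v, idx_start, idx_end):
    lo, hi = min(idx_start, idx_end), max(idx_start, idx_end)
    alt = v.alt.upper()
    if model.strand == "-":
        alt = reverse_complement(alt)
    new_cds = cds[:lo] + alt + cds[hi + 1 :]
    c0, c1 = lo // 3, hi // 3
    ref_aa = "".join(_codon_aa(cds[i * 3 : i * 3 + 3]) for i in range(c0, c1 + 1))
    alt_aa = "".join(_codon_aa(new_cds[i * 3 : i * 3 + 3]) for i in range(c0, c1 + 1))
    if ref_aa == alt_aa:
        klass = "synonymous"
    elif "*" in alt_aa:
        klass = "stop_gained"
    else:
        klass = "missense"
    return AminoAcidEffect(
        model.gene_id, c0 + 1, ref_aa, alt_aa, klass,
        f"{ref_aa}{c0 + 1}{alt_aa}", variant_key=v.key,
    )


def _codon_aa(codon: str) -> str:
    if "N" in codon:
        return "X"
    if _is_stop(codon):
        return "*"
    return str(translate(codon, allow_internal_stop=True))


def _is_stop(codon: str) -> bool:
    return codon in ("TAA", "TAG", "TGA")


def classify_all(
    bundle: ReferenceBundle,
    records: list[VariantRecord],
    gene_ids: list[str] | None = None,
) -> dict[tuple[str, int, str, str], AminoAcidEffect]:
    """Classify every record against the gene (if any) whose CDS it hits."""
    genes = [bundle.genes[g] for g in gene_ids] if gene_ids else list(bundle.genes.values())
    effects: dict[tuple[str, int, str, str], AminoAcidEffect] = {}
    for rec in records:
        for model in genes:
            if model.chrom != rec.chrom:
                continue
            span = model.span
            if not (span[0] - 1 <= rec.pos - 1 < span[1] + 1):
                continue
            eff = classify_effect(model, bundle, rec)
            if eff is not None:
                effects[rec.key] = eff
                break
    return effects


# ---------------------------------------------------------------------------
# Codon accessibility arithmetic

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY*")


def min_codon_substitutions(codon: str, target_aa: str) -> int:
    """Minimum number of nucleotide changes turning ``codon`` into any
    codon of ``target_aa`` (exhaustive over the standard code)."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise ValueError(f"invalid codon {codon!r}")
    if target_aa not in _AA_LETTERS:
        raise ValueError(f"invalid amino acid {target_aa!r}")
    return min(
        sum(a != b for a, b in zip(codon, t)) for t in codons_for(target_aa)
    )


def aa_transition_bound(aa_from: str, aa_to: str, mode: str = "min") -> int:
    """Best- or worst-case codon distance for an amino-acid transition.

    mode='min': fewest nucleotide changes over all source codons (is the
    change ever a single hit?).  mode='max': the requirement for the
    least favourable source codon (does *every* codon need k hits?).
    """
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    if aa_from not in _AA_LETTERS or aa_to not in _AA_LETTERS:
        raise ValueError("invalid amino acid")
    dists = [min_codon_substitutions(c, aa_to) for c in codons_for(aa_from)]
    return min(dists) if mode == "min" else max(dists)
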
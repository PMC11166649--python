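"""Synthetic multi-country cohort with machine-readable ground truth.

Generates a toy genome (three ~10-50 kb chromosomes) carrying the four
resistance genes — multi-exon, mixed strands — plus five background
genes, then diploid phased genotypes drawn from per-population
haplotype pools, per-base read depth with planted per-gene copy-number
folds, a sample manifest and a bioassay table.  The planted resistance
codons reuse the field's canonical mutation labels (V410L, F1534C,
V1016I/G, S989P, A301S, L111S, C115F, G12S, ...) on toy coordinates so
panel resolution and cross-species renumbering are exercised with
familiar names.

Every requested quantity is recorded in a :class:`TruthSet` written
alongside the fixtures, so each pipeline stage can be scored against
known truth.  All randomness flows from one master seed; each component
(genome, genotypes, depth, bioassays) derives its own stream from a
hash of (seed, component), so regenerating one fixture never perturbs
the others.

The canonical reference proteins bundled here are synthetic stand-ins
constructed from the toy native proteins (identity, an N-terminal
truncation, or an internal window), not the real cross-species
sequences; they exist to exercise the renumbering machinery.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .gene_models import (
    CanonicalRef,
    GeneModel,
    GenomicInterval,
    ReferenceBundle,
    codons_for,
    reverse_complement,
    spliced_cds,
    translate,
    write_bed12,
)

__all__ = [
    "SimulationConfig",
    "PopulationSpec",
    "LinkedPair",
    "CnvGroup",
    "TruthSet",
    "default_config",
    "cnv_demo_config",
    "build_reference",
    "simulate_cohort",
    "simulate_depth",
    "simulate_bioassays",
    "CANONICAL_MAP",
    "PLANTED_VARIANTS",
]


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Independent stream per fixture component, derived from the master seed."""
    digest = hashlib.sha256(f"{seed}:{component}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


# ---------------------------------------------------------------------------
# Planted resistance codons
#
# (gene, native codon number, ref codon, alt codon, label). Labels are the
# conventional canonical-species ones; native numbering differs from the
# label only for rdl, whose toy protein carries a 10-residue N-terminal
# extension relative to its canonical stand-in (so native 311 == A301S).

PLANTED_VARIANTS: list[tuple[str, int, str, str, str]] = [
    ("vgsc", 410, "GTA", "TTA", "V410L"),
    ("vgsc", 723, "AGT", "ACT", "S723T"),
    ("vgsc", 923, "GGT", "GTT", "G923V"),
    ("vgsc", 989, "TCA", "CCA", "S989P"),
    ("vgsc", 1011, "ATA", "ATG", "I1011M"),
    ("vgsc", 1016, "GTA", "ATA", "V1016I"),
    ("vgsc", 1016, "GTA", "GGA", "V1016G"),
    ("vgsc", 1520, "ACA", "ATA", "T1520I"),
    ("vgsc", 1534, "TTC", "TGC", "F1534C"),
    ("ace1", 12, "GGT", "AGT", "G12S"),
    ("ace1", 699, "TGT", "TCT", "C699S"),
    ("rdl", 311, "GCT", "TCT", "A301S"),
    ("gste2", 9, "CTA", "ATA", "L9I"),
    ("gste2", 111, "TTA", "TCA", "L111S"),
    ("gste2", 115, "TGT", "TTT", "C115F"),
    ("gste2", 150, "ATT", "GTT", "I150V"),
    ("gste2", 169, "ATT", "AGT", "I169S"),
    ("gste2", 198, "GCA", "GAA", "A198E"),
]

#: gene -> (species label, canonical FASTA record id)
CANONICAL_MAP: dict[str, tuple[str, str]] = {
    "vgsc": ("Musca domestica (synthetic stand-in)", "VGSC_REF_SYN"),
    "ace1": ("Torpedo californica (synthetic stand-in)", "ACE1_REF_SYN"),
    "rdl": ("Drosophila melanogaster (synthetic stand-in)", "RDL_REF_SYN"),
    "gste2": ("Anopheles gambiae (synthetic stand-in)", "GSTE2_REF_SYN"),
}

# gene -> (n codons incl. stop, exon piece lengths in nt, strand, chrom)
_GENE_PLAN: dict[str, tuple[int, tuple[int, ...], str, str]] = {
    "vgsc": (1561, (1800, 1800, 1083), "+", "chr1"),
    "ace1": (703, (1200, 909), "+", "chr2"),
    "rdl": (361, (600, 483), "-", "chr3"),
    "gste2": (222, (350, 316), "+", "chr2"),
    "bg1": (301, (903,), "+", "chr1"),
    "bg2": (301, (500, 403), "-", "chr1"),
    "bg3": (301, (903,), "+", "chr2"),
    "bg4": (301, (903,), "+", "chr3"),
    "bg5": (301, (450, 453), "+", "chr3"),
}
_INTRON_LEN = 300
_INTERGENIC = 500


@dataclass
class PopulationSpec:
    label: str
    n_samples: int
    #: haplotype (allele) frequency per planted variant label; absent = 0
    variant_freqs: dict[str, float] = field(default_factory=dict)
    #: private background SNPs: (count, haplotype frequency)
    n_private: int = 25
    private_freq: float = 0.7


@dataclass
class LinkedPair:
    """Two-locus coupling: p(AB) = coupling * min(fA, fB) in the pool."""

    var_a: str
    var_b: str
    coupling: float = 1.0


@dataclass
class CnvGroup:
    gene: str
    fold: float
    samples: list[str]


@dataclass
class SimulationConfig:
    seed: int = 1
    populations: list[PopulationSpec] = field(default_factory=list)
    linked_pairs: list[LinkedPair] = field(default_factory=list)
    cnv_groups: list[CnvGroup] = field(default_factory=list)
    depth_lambda: float = 30.0
    n_shared_background: int = 10
    shared_background_freq: float = 0.5
    #: (n_susceptible, n_possible, n_resistant) per (country, class) cell
    bioassay_mix: tuple[int, int, int] = (60, 25, 15)
    bioassay_cells: list[tuple[str, str, str]] = field(default_factory=list)
    phased: bool = True
    colony_samples: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for pop in self.populations:
            for label, f in pop.variant_freqs.items():
                if not (0 <= f <= 1):
                    raise ValueError(f"{pop.label}:{label} frequency {f} outside [0,1]")
        for grp in self.cnv_groups:
            if grp.fold <= 0:
                raise ValueError("CNV fold must be positive")
        if self.depth_lambda <= 0:
            raise ValueError("depth lambda must be positive")


@dataclass
class TruthSet:
    populations: dict[str, str]
    variant_freqs: dict[str, dict[str, float]]
    realized_carriers: dict[str, dict[str, int]]
    ld_pairs: list[dict]
    cnv_folds: dict[str, dict[str, float]]
    bioassay_counts: dict[str, dict[str, int]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def default_config(seed: int = 1) -> SimulationConfig:
    """Three populations of 50 samples with region-typical marker profiles.

    Frequency profiles follow the qualitative geography of kdr surveys:
    an Asian-type population (F1534C + V1016G/S989P/T1520I, no GSTe2
    variation), an American-type one (F1534C + V410L/S723T/V1016I) and a
    West-African-type one (lower kdr frequencies, GSTe2 variation).
    V410L–S723T are fully coupled; L9I–I169S and I150V–A198E strongly so.
    """
    thailand = PopulationSpec(
        "Thailand", 50,
        {
            "F1534C": 0.85, "V1016G": 0.45, "S989P": 0.35, "T1520I": 0.40,
            "A301S": 0.35,
        },
    )
    usa = PopulationSpec(
        "USA", 50,
        {
            "F1534C": 0.80, "V410L": 0.55, "S723T": 0.55, "V1016I": 0.50,
            "I1011M": 0.10, "G923V": 0.08, "A301S": 0.40, "G12S": 0.10,
            "C699S": 0.05, "C115F": 0.45, "L111S": 0.25, "I150V": 0.60,
            "A198E": 0.60,
        },
    )
    ghana = PopulationSpec(
        "Ghana", 50,
        {
            "F1534C": 0.30, "V410L": 0.10, "S723T": 0.10, "A301S": 0.05,
            "C699S": 0.08, "L9I": 0.25, "I169S": 0.25, "C115F": 0.35,
            "L111S": 0.30, "I150V": 0.70, "A198E": 0.70,
        },
    )
    cfg = SimulationConfig(
        seed=seed,
        populations=[thailand, usa, ghana],
        linked_pairs=[
            LinkedPair("V410L", "S723T", 1.0),
            LinkedPair("L9I", "I169S", 0.9),
            LinkedPair("I150V", "A198E", 0.95),
        ],
        bioassay_cells=[
            ("Thailand", "pyrethroid", "WHO_tube"),
            ("Thailand", "organochlorine", "WHO_tube"),
            ("USA", "pyrethroid", "CDC_bottle"),
            ("Ghana", "pyrethroid", "WHO_tube"),
            ("Ghana", "organophosphate", "WHO_bottle"),
        ],
    )
    # colony flag on two samples (exercises colony exclusion in LD scans)
    cfg.colony_samples = ["USA_045", "USA_046"]
    samples = {p.label: sample_names(p) for p in cfg.populations}
    cfg.cnv_groups = [
        CnvGroup("vgsc", 1.4, samples["USA"][:10] + samples["Ghana"][:5]),
        CnvGroup("gste2", 4.2, samples["Thailand"][:12] + samples["USA"][10:16]),
        CnvGroup("gste2", 9.3, samples["USA"][16:24]),
    ]
    return cfg


def cnv_demo_config(
    seed: int = 1, n_per_group: int = 20, lam: float = 30.0, gene: str = "vgsc"
) -> SimulationConfig:
    """Four equal sample groups at folds 1.0 / 1.4 / 4.2 / 9.3 on one gene.

    The fold ladder mirrors the duplication groups a global coverage
    survey resolves: single copy, heterozygous duplication and two
    amplification tiers.  The default gene (vgsc) has >1 kb of exon, so
    per-sample folds are recoverable well within 10%.
    """
    pops = [PopulationSpec(f"grp{i}", n_per_group, {}, n_private=0) for i in range(4)]
    cfg = SimulationConfig(seed=seed, populations=pops, depth_lambda=lam)
    names = {p.label: sample_names(p) for p in pops}
    cfg.cnv_groups = [
        CnvGroup(gene, fold, names[f"grp{i}"])
        for i, fold in enumerate([1.0, 1.4, 4.2, 9.3])
        if fold != 1.0
    ]
    return cfg


def sample_names(pop: PopulationSpec) -> list[str]:
    return [f"{pop.label}_{i:03d}" for i in range(pop.n_samples)]


# ---------------------------------------------------------------------------
# Genome construction

_SENSE_CODONS = sorted(set(
    c for aa in "ACDEFGHIKLMNPQRSTVWY" for c in codons_for(aa)
))


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    """Random CDS as a codon list: ATG, sense codons, one stop."""
    body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)]
    return ["ATG", *body, "TAA"]


def build_reference(seed: int) -> ReferenceBundle:
    """Toy genome + gene models with the planted reference codons in place."""
    rng = component_rng(seed, "genome")
    cds_by_gene: dict[str, str] = {}
    for gene, (n_codons, pieces, _strand, _chrom) in _GENE_PLAN.items():
        codons = _random_cds(rng, n_codons)
        for g, native_pos, ref_codon, _alt, _label in PLANTED_VARIANTS:
            if g == gene:
                codons[native_pos - 1] = ref_codon
        cds = "".join(codons)
        assert len(cds) == sum(pieces), f"{gene}: exon plan does not match CDS length"
        cds_by_gene[gene] = cds

    # lay genes onto chromosomes
    chrom_parts: dict[str, list[str]] = {}
    genes: dict[str, GeneModel] = {}
    cursor: dict[str, int] = {}
    bases = np.array(list("ACGT"))
    for gene, (_n, pieces, strand, chrom) in _GENE_PLAN.items():
        chrom_parts.setdefault(chrom, [])
        cursor.setdefault(chrom, 0)
        # intergenic spacer
        spacer = "".join(rng.choice(bases, _INTERGENIC))
        chrom_parts[chrom].append(spacer)
        cursor[chrom] += _INTERGENIC

        cds = cds_by_gene[gene]
        # split the CDS into transcription-order pieces
        tx_pieces = []
        off = 0
        for ln in pieces:
            tx_pieces.append(cds[off : off + ln])
            off += ln
        # genome order: forward strand keeps order; reverse strand places the
        # first transcribed piece at the highest coordinates, reverse-complemented
        if strand == "+":
            genome_pieces = tx_pieces
        else:
            genome_pieces = [reverse_complement(p) for p in reversed(tx_pieces)]
        intervals = []
        for i, piece in enumerate(genome_pieces):
            if i > 0:
                intron = "".join(rng.choice(bases, _INTRON_LEN))
                chrom_parts[chrom].append(intron)
                cursor[chrom] += _INTRON_LEN
            start = cursor[chrom]
            chrom_parts[chrom].append(piece)
            cursor[chrom] += len(piece)
            intervals.append(GenomicInterval(chrom, start, start + len(piece), strand))
        genes[gene] = GeneModel(
            gene, gene, tuple(intervals), strand,
            is_resistance_gene=gene in CANONICAL_MAP,
        )
    sequences = {
        chrom: "".join(parts) + "".join(rng.choice(bases, _INTERGENIC))
        for chrom, parts in chrom_parts.items()
    }
    bundle = ReferenceBundle(sequences, genes)
    bundle.validate()

    # canonical stand-ins: identity for vgsc/gste2, N-terminal truncation for
    # rdl (native = canonical + 10 extra leading residues), internal window
    # for ace1 (positions 101-650, so termini stay native-only, as for the
    # real acetylcholinesterase reference)
    proteins = {g: bundle.protein(g) for g in CANONICAL_MAP}
    canon_seq = {
        "vgsc": proteins["vgsc"],
        "gste2": proteins["gste2"],
        "rdl": proteins["rdl"][10:],
        "ace1": proteins["ace1"][100:650],
    }
    for gene, (species, rec_id) in CANONICAL_MAP.items():
        genes[gene].canonical_ref = CanonicalRef(species, rec_id, canon_seq[gene])
        bundle.canonical_proteins[species] = canon_seq[gene]
    return bundle


# ---------------------------------------------------------------------------
# Genotypes

@dataclass
class _Site:
    label: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


def _planted_sites(bundle: ReferenceBundle) -> dict[str, _Site]:
    """Genomic (pos, ref, alt) for each planted mutation label."""
    sites: dict[str, _Site] = {}
    for gene, native_pos, ref_codon, alt_codon, label in PLANTED_VARIANTS:
        model = bundle.genes[gene]
        diffs = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
        assert len(diffs) == 1, f"{label}: planted codons must differ at one base"
        within = diffs[0]
        cds_idx = (native_pos - 1) * 3 + within
        gpos0 = model.cds_to_genomic(cds_idx)
        ref_b, alt_b = ref_codon[within], alt_codon[within]
        if model.strand == "-":
            ref_b, alt_b = reverse_complement(ref_b), reverse_complement(alt_b)
        chrom_base = bundle.sequences[model.chrom][gpos0]
        if chrom_base != ref_b:
            raise ValueError(f"{label}: planted ref {ref_b} != reference base {chrom_base}")
        sites[label] = _Site(label, gene, model.chrom, gpos0 + 1, ref_b, alt_b)
    return sites


def _background_sites(
    bundle: ReferenceBundle, rng: np.random.Generator, n: int, prefix: str,
    used: set[tuple[str, int]],
) -> list[_Site]:
    """Random exonic SNPs in background genes, avoiding used positions."""
    out: list[_Site] = []
    bg = [g for g in bundle.genes.values() if not g.is_resistance_gene]
    while len(out) < n:
        model = bg[rng.integers(0, len(bg))]
        # avoid start/stop codons
        cds_idx = int(rng.integers(3, model.cds_length - 3))
        gpos0 = model.cds_to_genomic(cds_idx)
        if (model.chrom, gpos0 + 1) in used:
            continue
        ref_b = bundle.sequences[model.chrom][gpos0]
        alt_b = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_b]
        used.add((model.chrom, gpos0 + 1))
        out.append(
            _Site(f"{prefix}_{len(out)}", model.gene_id, model.chrom, gpos0 + 1, ref_b, alt_b)
        )
    return out


def _draw_haplotypes(
    rng: np.random.Generator,
    pop: PopulationSpec,
    site_order: list[str],
    linked: list[LinkedPair],
) -> tuple[np.ndarray, list[dict]]:
    """(2n, n_sites) haplotype matrix for one population + LD truth rows."""
    n_hap = 2 * pop.n_samples
    H = np.zeros((n_hap, len(site_order)), dtype=np.int8)
    idx = {lab: j for j, lab in enumerate(site_order)}
    in_pair = set()
    ld_rows = []
    for pair in linked:
        fa = pop.variant_freqs.get(pair.var_a, 0.0)
        fb = pop.variant_freqs.get(pair.var_b, 0.0)
        if fa == 0 or fb == 0:
            continue
        in_pair.update((pair.var_a, pair.var_b))
        p_ab_joint = pair.coupling * min(fa, fb)
        probs = np.array([
            p_ab_joint, fa - p_ab_joint, fb - p_ab_joint,
            1 - fa - fb + p_ab_joint,
        ])
        if (probs < -1e-9).any():
            raise ValueError(f"inconsistent coupling for {pair.var_a}/{pair.var_b}")
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        draw = rng.choice(4, size=n_hap, p=probs)
        H[:, idx[pair.var_a]] = (draw == 0) | (draw == 1)
        H[:, idx[pair.var_b]] = (draw == 0) | (draw == 2)
        # expected r2 from the pool
        D = p_ab_joint - fa * fb
        den = fa * (1 - fa) * fb * (1 - fb)
        ld_rows.append(
            {
                "population": pop.label, "var_a": pair.var_a, "var_b": pair.var_b,
                "true_r2": float(D * D / den) if den > 0 else None,
            }
        )
    for lab, f in pop.variant_freqs.items():
        if lab in in_pair or f == 0:
            continue
        H[:, idx[lab]] = rng.random(n_hap) < f
    return H, ld_rows


def simulate_cohort(config: SimulationConfig, outdir: str | Path) -> TruthSet:
    """Write FASTA, BED12, phased VCF, manifest and truth JSON to ``outdir``.

    Returns the TruthSet (also serialised as ``truth.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = build_reference(config.seed)
    rng = component_rng(config.seed, "genotypes")

    planted = _planted_sites(bundle)
    used = {(s.chrom, s.pos) for s in planted.values()}
    shared_bg = _background_sites(bundle, rng, config.n_shared_background, "shared", used)
    private_bg = {
        pop.label: _background_sites(bundle, rng, pop.n_private, f"priv_{pop.label}", used)
        for pop in config.populations
    }

    all_sites: list[_Site] = list(planted.values()) + shared_bg + [
        s for sites in private_bg.values() for s in sites
    ]
    site_order = [s.label for s in all_sites]
    col = {lab: j for j, lab in enumerate(site_order)}

    sample_ids: list[str] = []
    pop_of: dict[str, str] = {}
    haplos = []
    ld_truth: list[dict] = []
    for pop in config.populations:
        names = sample_names(pop)
        sample_ids.extend(names)
        for s in names:
            pop_of[s] = pop.label
        # planted + shared + this population's private variants
        freqs = dict(pop.variant_freqs)
        for s in shared_bg:
            freqs[s.label] = config.shared_background_freq
        for s in private_bg[pop.label]:
            freqs[s.label] = pop.private_freq
        spec = PopulationSpec(pop.label, pop.n_samples, freqs)
        H_pop, ld_rows = _draw_haplotypes(rng, spec, site_order, config.linked_pairs)
        haplos.append(H_pop)
        # realized r2 for linked pairs in this population
        for row in ld_rows:
            a, b = H_pop[:, col[row["var_a"]]], H_pop[:, col[row["var_b"]]]
            pa, pb, pab = a.mean(), b.mean(), (a & b).mean()
            den = pa * (1 - pa) * pb * (1 - pb)
            row["realized_r2"] = float((pab - pa * pb) ** 2 / den) if den > 0 else None
        ld_truth.extend(ld_rows)
    H = np.vstack(haplos)  # (2N, sites), sample i -> rows 2i, 2i+1

    # truth bookkeeping
    pop_labels = np.array([pop_of[s] for s in sample_ids])
    carriers = (H[0::2] | H[1::2]).astype(bool)
    realized_carriers = {
        lab: {
            pop: int(carriers[pop_labels == pop, col[lab]].sum())
            for pop in sorted(set(pop_labels))
        }
        for lab in site_order
    }
    variant_freqs = {
        pop.label: {k: v for k, v in pop.variant_freqs.items()} for pop in config.populations
    }
    cnv_folds: dict[str, dict[str, float]] = {s: {} for s in sample_ids}
    for grp in config.cnv_groups:
        for s in grp.samples:
            if s not in cnv_folds:
                raise ValueError(f"CNV plan references unknown sample {s}")
            cnv_folds[s][grp.gene] = grp.fold

    _write_fasta(bundle.sequences, outdir / "reference.fa")
    write_bed12(list(bundle.genes.values()), outdir / "genes.bed")
    _write_canonical_fasta(bundle, outdir / "canonical_proteins.fa")
    _write_vcf(outdir / "cohort.vcf", all_sites, H, sample_ids, config, rng)
    _write_manifest(outdir / "manifest.tsv", sample_ids, pop_of, config.colony_samples)

    truth = TruthSet(
        populations=pop_of,
        variant_freqs=variant_freqs,
        realized_carriers=realized_carriers,
        ld_pairs=ld_truth,
        cnv_folds=cnv_folds,
        bioassay_counts={},
    )
    truth.to_json(outdir / "truth.json")
    return truth


def _write_fasta(seqs: dict[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_canonical_fasta(bundle: ReferenceBundle, path: Path) -> None:
    with open(path, "w") as fh:
        for gene, (species, rec_id) in CANONICAL_MAP.items():
            cref = bundle.genes[gene].canonical_ref
            fh.write(f">{rec_id} {species}\n")
            seq = cref.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _write_vcf(
    path: Path,
    sites: list[_Site],
    H: np.ndarray,
    sample_ids: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    sep = "|" if config.phased else "/"
    # stable per-sample sequencing depth around lambda, floored at the
    # 5x acceptance threshold so planted genotypes survive the filter
    dp = np.maximum(5, rng.poisson(config.depth_lambda, size=len(sample_ids)))
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in sorted({s.chrom for s in sites}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for i in order:
            s = sites[i]
            gts = []
            for j in range(len(sample_ids)):
                a, b = H[2 * j, i], H[2 * j + 1, i]
                gts.append(f"{a}{sep}{b}:{dp[j]}")
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.label}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(gts) + "\n"
            )


def _write_manifest(
    path: Path, sample_ids: list[str], pop_of: dict[str, str], colonies: list[str]
) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tcolony\tspecies\n")
        for s in sample_ids:
            colony = "1" if s in colonies else "0"
            fh.write(f"{s}\t{pop_of[s]}\t{colony}\tAedes aegypti\n")


# ---------------------------------------------------------------------------
# Depth simulation

def simulate_depth(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    outdir: str | Path,
    truth: TruthSet | None = None,
) -> Path:
    """samtools-depth-dialect TSV over all gene spans.

    Exonic depth ~ Poisson(lambda * fold); intronic depth uses a
    negative binomial with the same mean but inflated variance,
    mimicking repeat-driven mapping noise that motivates exon masking.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = component_rng(config.seed, "depth")
    sample_ids = [s for pop in config.populations for s in sample_names(pop)]
    fold = np.ones((len(sample_ids), len(bundle.genes)))
    gene_ids = list(bundle.genes)
    gi = {g: k for k, g in enumerate(gene_ids)}
    si = {s: k for k, s in enumerate(sample_ids)}
    for grp in config.cnv_groups:
        for s in grp.samples:
            fold[si[s], gi[grp.gene]] = grp.fold
    if truth is not None:
        truth.cnv_folds = {
            s: {
                g: float(fold[si[s], gi[g]])
                for g in gene_ids if fold[si[s], gi[g]] != 1.0
            }
            for s in sample_ids
        }

    lam = config.depth_lambda
    path = outdir / "depth.tsv"
    with open(path, "w") as fh:
        for gene in gene_ids:
            model = bundle.genes[gene]
            span_s, span_e = model.span
            positions = np.arange(span_s + 1, span_e + 1)
            exonic = np.zeros(len(positions), bool)
            for iv in model.intervals:
                exonic[(positions > iv.start) & (positions <= iv.end)] = True
            lam_vec = lam * fold[:, gi[gene]]  # per sample
            n_pos = len(positions)
            depth = np.empty((n_pos, len(sample_ids)), dtype=np.int64)
            ex_counts = rng.poisson(lam_vec, size=(int(exonic.sum()), len(sample_ids)))
            depth[exonic] = ex_counts
            n_intron = int((~exonic).sum())
            if n_intron:
                # negative binomial: mean lam, variance ~ 5x Poisson
                r = lam / 4.0
                p = r / (r + lam)
                depth[~exonic] = rng.negative_binomial(r, p, size=(n_intron, len(sample_ids)))
            for row, pos in enumerate(positions):
                fh.write(
                    f"{model.chrom}\t{pos}\t" + "\t".join(map(str, depth[row])) + "\n"
                )
    return path


# ---------------------------------------------------------------------------
# Bioassays

def simulate_bioassays(config: SimulationConfig, outdir: str | Path) -> Path:
    """Bioassay CSV with planted category mix plus filter decoys.

    Mortalities are drawn inside the WHO/CDC category bands for each
    cell's assay type; three decoy records (year 2000, PCR-only, wrong
    species) exercise the record filters.
    """
    import csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = component_rng(config.seed, "bioassays")
    n_s, n_p, n_r = config.bioassay_mix
    path = outdir / "bioassays.csv"
    bands = {
        "WHO_tube": (98.0, 90.0),
        "WHO_bottle": (98.0, 90.0),
        "CDC_bottle": (97.0, 90.0),
    }
    rows = []
    counts: dict[str, dict[str, int]] = {}
    for country, iclass, assay in config.bioassay_cells:
        s_min, p_min = bands[assay]
        cell = f"{country}|{iclass}"
        counts[cell] = {"susceptible": n_s, "possible": n_p, "resistant": n_r}
        draws = (
            [("susceptible", s_min, 100.0)] * n_s
            + [("possible", p_min, s_min - 0.1)] * n_p
            + [("resistant", 20.0, p_min - 0.1)] * n_r
        )
        for _cat, lo, hi in draws:
            m = float(rng.uniform(lo, hi))
            year = int(rng.integers(2005, 2023))
            rows.append(
                [country, f"{iclass}_compound", iclass, assay, f"{m:.1f}", year,
                 "Aedes aegypti", "bioassay"]
            )
    if config.bioassay_cells:
        country, iclass, assay = config.bioassay_cells[0]
        rows.append([country, f"{iclass}_compound", iclass, assay, "95.0", 2000,
                     "Aedes aegypti", "bioassay"])  # decoy: cutoff year
        rows.append([country, f"{iclass}_compound", iclass, assay, "80.0", 2010,
                     "Aedes aegypti", "RT-PCR genotyping"])  # decoy: PCR-only
        rows.append([country, f"{iclass}_compound", iclass, assay, "70.0", 2012,
                     "Aedes albopictus", "bioassay"])  # decoy: wrong species
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["country", "insecticide", "insecticide_class", "assay",
                    "mortality", "year", "species", "method_note"])
        w.writerows(rows)
    truth_path = Path(outdir) / "bioassay_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(counts, fh, indent=1)
    return path
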
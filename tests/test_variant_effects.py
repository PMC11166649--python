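"""Variant decomposition, depth filtering, effect calling and codon arithmetic."""

import numpy as np
import pytest

from resistscan.gene_models import (
    GeneModel,
    GenomicInterval,
    ReferenceBundle,
    reverse_complement,
    spliced_cds,
    translate,
)
from resistscan.variant_effects import (
    MISSING,
    VariantRecord,
    aa_transition_bound,
    classify_effect,
    decompose_variants,
    filter_min_depth,
    min_codon_substitutions,
)


def _rec(chrom, pos, ref, alts, gts, depths=None, samples=None):
    gts = np.asarray(gts, dtype=np.int16)
    n = gts.shape[0]
    return VariantRecord(
        chrom, pos, ref, tuple(alts), gts,
        np.ones(n, bool),
        None if depths is None else np.asarray(depths, dtype=np.int32),
        tuple(samples or [f"s{i}" for i in range(n)]),
    )


# ---------------------------------------------------------------------------
# decomposition / normalisation

def test_multiallelic_split_recodes_genotypes():
    rec = _rec("c", 5, "A", ["G", "T"], [[0, 1], [1, 2], [2, 2], [MISSING, MISSING]])
    out = decompose_variants([rec])
    assert len(out) == 2
    g_rec, t_rec = out
    assert g_rec.alt == "G" and t_rec.alt == "T"
    assert g_rec.genotypes.tolist() == [[0, 1], [1, 0], [0, 0], [MISSING, MISSING]]
    assert t_rec.genotypes.tolist() == [[0, 0], [0, 1], [1, 1], [MISSING, MISSING]]


def test_biallelic_snp_passes_through():
    rec = _rec("c", 5, "A", ["G"], [[0, 1]])
    (out,) = decompose_variants([rec])
    assert out.key == rec.key
    assert (out.genotypes == rec.genotypes).all()


def test_indel_left_alignment_is_idempotent():
    # sequence ...GCATT TTA...: deleting one T of the homopolymer run must
    # shift to the leftmost representation, and renormalising is a no-op
    chrom = "GCATTTTA"
    bundle = ReferenceBundle({"c": chrom}, {})
    rec = _rec("c", 5, "TT", ["T"], [[0, 1]])  # right-padded deletion
    (out,) = decompose_variants([rec], bundle)
    assert (out.pos, out.ref, out.alt) == (3, "AT", "A")
    (again,) = decompose_variants([out], bundle)
    assert (again.pos, again.ref, again.alt) == (out.pos, out.ref, out.alt)


def test_symbolic_alleles_skipped():
    rec = _rec("c", 5, "A", ["<DEL>"], [[0, 1]])
    assert decompose_variants([rec]) == []


# ---------------------------------------------------------------------------
# depth filter

def test_depth_filter_boundary_at_five():
    rec = _rec("c", 5, "A", ["G"], [[0, 1], [0, 1], [1, 1]], depths=[4, 5, 6])
    (out,) = filter_min_depth([rec], min_depth=5)
    assert out.genotypes[0].tolist() == [MISSING, MISSING]
    assert out.genotypes[1].tolist() == [0, 1]
    assert out.genotypes[2].tolist() == [1, 1]


def test_depth_filter_keeps_and_drops_whole_sites():
    ok = _rec("c", 5, "A", ["G"], [[0, 1], [1, 1]], depths=[9, 30])
    (out,) = filter_min_depth([ok])
    assert (out.genotypes == ok.genotypes).all()
    gone = _rec("c", 6, "A", ["G"], [[0, 1], [1, 1]], depths=[1, 2])
    assert filter_min_depth([gone]) == []


def test_depth_filter_rejects_negative_depth():
    rec = _rec("c", 5, "A", ["G"], [[0, 1]], depths=[-3])
    with pytest.raises(ValueError, match="negative"):
        filter_min_depth([rec])


# ---------------------------------------------------------------------------
# effect calling

def _toy_gene(seq_parts, strand="+", chrom="c", pad=4):
    """Build a bundle holding one gene whose genome-order CDS pieces are
    seq_parts, separated by short fake introns."""
    intervals = []
    seq = "A" * pad
    for part in seq_parts:
        start = len(seq)
        seq += part
        intervals.append(GenomicInterval(chrom, start, start + len(part), strand))
        seq += "GT" + "A" * 6 + "AG"  # fake intron
    model = GeneModel("toy", "toy", tuple(intervals), strand)
    return model, ReferenceBundle({chrom: seq}, {"toy": model})


def test_phe_to_cys_missense():
    # codon TTC, second base T->G gives TGC: Phe->Cys, the archetypal
    # sodium-channel F1534C class of change
    model, bundle = _toy_gene(["ATG" + "TTC" + "TAA"])
    rec = _rec("c", 4 + 3 + 2, "T", ["G"], [[0, 1]])
    eff = classify_effect(model, bundle, rec)
    assert (eff.effect_class, eff.native_label) == ("missense", "F2C")


def test_synonymous_third_base():
    model, bundle = _toy_gene(["ATG" + "AAA" + "TAA"])
    rec = _rec("c", 4 + 6, "A", ["G"], [[0, 1]])
    eff = classify_effect(model, bundle, rec)
    assert eff.effect_class == "synonymous"
    assert eff.native_label == "K2K"


def test_stop_gained():
    model, bundle = _toy_gene(["ATG" + "TAC" + "TAA"])  # TAC->TAA
    rec = _rec("c", 4 + 5 + 1, "C", ["A"], [[0, 1]])
    eff = classify_effect(model, bundle, rec)
    assert eff.effect_class == "stop_gained"


def test_inframe_insertion_of_glycine():
    # 3-bp GGA insertion between codons: one extra Gly, in-frame
    model, bundle = _toy_gene(["ATG" + "GGT" + "TTC" + "TAA"])
    rec = _rec("c", 4 + 6, "T", ["TGGA"], [[0, 1]])
    eff = classify_effect(model, bundle, rec)
    assert eff.effect_class == "inframe_insertion"
    assert eff.alt_aa == "G"
    assert eff.codon_number_native == 3


def test_frameshift_and_boundary_span():
    model, bundle = _toy_gene(["ATGGGT", "TTCTAA"])
    fs = _rec("c", 4 + 3, "G", ["GA"], [[0, 1]])
    assert classify_effect(model, bundle, fs).effect_class == "frameshift"
    # deletion crossing the intron boundary
    spanning = _rec("c", 4 + 6, "TGTAAAA", ["T"], [[0, 1]])
    assert classify_effect(model, bundle, spanning).effect_class == "unknown"


def test_intronic_variant_returns_none():
    model, bundle = _toy_gene(["ATGGGT", "TTCTAA"])
    rec = _rec("c", 4 + 8, "A", ["C"], [[0, 1]])
    assert classify_effect(model, bundle, rec) is None


def test_reference_n_gives_unknown():
    model, bundle = _toy_gene(["ATG" + "ANA" + "TAA"])
    rec = _rec("c", 4 + 4, "A", ["G"], [[0, 1]])
    # N sits in the codon: no guessing
    eff = classify_effect(model, bundle, rec)
    assert eff.effect_class == "unknown"


def _retranslation_oracle(model, bundle, rec):
    """Independent oracle: rebuild the whole CDS with the alt base and
    compare full translations."""
    cds = spliced_cds(model, bundle)
    idx = model.genomic_to_cds(rec.pos - 1)
    if idx is None:
        return None
    alt = rec.alt if model.strand == "+" else reverse_complement(rec.alt)
    new_cds = cds[:idx] + alt + cds[idx + 1 :]
    p_ref = translate(cds, allow_internal_stop=True)
    p_alt = translate(new_cds, allow_internal_stop=True)
    diffs = [i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
    if len(p_alt) > len(p_ref):  # the trailing stop was destroyed
        return "stop_lost"
    if not diffs:
        return "synonymous"
    (i,) = diffs
    if p_alt[i] == "*":
        return "stop_gained"
    if p_ref[i] == "*":
        return "stop_lost"
    return "missense"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_random_snps_match_retranslation_oracle(strand):
    """100 random SNPs classified identically by the production caller and
    a brute-force full-CDS retranslation, on both strands."""
    rng = np.random.default_rng(42)
    from resistscan.synthetic_data import _random_cds

    cds = "".join(_random_cds(rng, 120))
    genomic = cds if strand == "+" else reverse_complement(cds)
    model, bundle = _toy_gene([genomic[:180], genomic[180:]], strand=strand)
    span = model.span
    n_checked = 0
    while n_checked < 100:
        gpos0 = int(rng.integers(span[0], span[1]))
        if model.genomic_to_cds(gpos0) is None:
            continue
        ref = bundle.sequences["c"][gpos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        rec = _rec("c", gpos0 + 1, ref, [alt], [[0, 1]])
        eff = classify_effect(model, bundle, rec)
        assert eff.effect_class == _retranslation_oracle(model, bundle, rec), rec.key
        n_checked += 1


def test_strand_invariance_of_effects():
    """Complementing the gene and its variants yields identical effects."""
    rng = np.random.default_rng(3)
    from resistscan.synthetic_data import _random_cds

    cds = "".join(_random_cds(rng, 60))
    fwd_model, fwd_bundle = _toy_gene([cds], strand="+")
    rev_model, rev_bundle = _toy_gene([reverse_complement(cds)], strand="-")
    for _ in range(50):
        cds_idx = int(rng.integers(0, len(cds)))
        ref = cds[cds_idx]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        f_pos = fwd_model.cds_to_genomic(cds_idx) + 1
        r_pos = rev_model.cds_to_genomic(cds_idx) + 1
        ef = classify_effect(fwd_model, fwd_bundle, _rec("c", f_pos, ref, [alt], [[0, 1]]))
        er = classify_effect(
            rev_model, rev_bundle,
            _rec("c", r_pos, reverse_complement(ref), [reverse_complement(alt)], [[0, 1]]),
        )
        assert (ef.effect_class, ef.native_label) == (er.effect_class, er.native_label)


# ---------------------------------------------------------------------------
# codon accessibility

def _brute_min_subs(codon, aa):
    """Enumeration oracle over all 64 codons."""
    from itertools import product
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    best = 3
    for c in ("".join(p) for p in product("ACGT", repeat=3)):
        target = table.forward_table.get(c, "*")
        if target == aa:
            best = min(best, sum(x != y for x, y in zip(codon, c)))
    return best


@pytest.mark.parametrize(
    "codon,aa,expected",
    [
        ("GGA", "S", 2),  # Gly->Ser from GGA: two hits
        ("TTA", "L", 0),  # already Leu
        ("ATG", "S", 2),  # Met->Ser needs two changes
        ("TTG", "F", 1),
    ],
)
def test_min_codon_substitutions(codon, aa, expected):
    assert min_codon_substitutions(codon, aa) == expected
    assert min_codon_substitutions(codon, aa) == _brute_min_subs(codon, aa)


def test_min_codon_substitutions_validates_input():
    with pytest.raises(ValueError):
        min_codon_substitutions("GGX", "S")
    with pytest.raises(ValueError):
        min_codon_substitutions("GGA", "B")


def test_min_subs_zero_iff_codon_encodes_target():
    from itertools import product
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    for c in ("".join(p) for p in product("ACGT", repeat=3)):
        aa = table.forward_table.get(c, "*")
        d = min_codon_substitutions(c, "S")
        assert 0 <= d <= 3
        assert (d == 0) == (aa == "S")


@pytest.mark.parametrize(
    "aa_from,aa_to,mode,expected",
    [
        ("L", "S", "min", 1),  # Leu->Ser achievable in one hit from some codons
        ("G", "S", "max", 2),  # every Gly codon needs <=2; worst case is 2
        ("F", "F", "max", 0),
        ("L", "F", "max", 2),  # the worst Leu codon needs two hits to Phe
    ],
)
def test_aa_transition_bound(aa_from, aa_to, mode, expected):
    assert aa_transition_bound(aa_from, aa_to, mode) == expected


def test_effect_classes_partition_classified_variants(cohort, bundle):
    """Per-gene synonymous+missense+other tallies sum to total classified."""
    from collections import Counter

    records, effects, _, _ = cohort
    per_gene = Counter()
    per_class = Counter()
    for eff in effects.values():
        per_gene[eff.gene_id] += 1
        per_class[(eff.gene_id, eff.effect_class)] += 1
    for gene, total in per_gene.items():
        assert sum(n for (g, _), n in per_class.items() if g == gene) == total
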
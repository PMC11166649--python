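"""Cross-species residue renumbering by global protein alignment.

Resistance mutations are conventionally reported on a reference
species' protein — *M. domestica* for the sodium channel, *T.
californica* for acetylcholinesterase, *D. melanogaster* for the GABA
receptor and *An. gambiae* for GSTe2 — so that, e.g., "A301S" means the
same residue in any insect.  This module aligns the native mosquito
protein to the canonical reference globally (BLOSUM62, affine gaps) and
transfers residue numbers across aligned columns.  Residues that align
to a gap, or fall outside the canonical protein's termini, get no
canonical coordinate and keep their native label only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import Align
from Bio.Align import substitution_matrices

from .gene_models import ReferenceBundle
from .variant_effects import AminoAcidEffect

__all__ = ["PositionMap", "align_global", "map_position", "annotate_canonical"]


@dataclass
class PositionMap:
    """Monotone mapping query residue number -> reference residue number.

    ``pairs`` holds (query_pos, ref_pos) for every query residue, both
    1-based; ``ref_pos`` is None for unaligned query residues.
    """

    query_id: str
    ref_id: str
    species: str
    pairs: list[tuple[int, int | None]]

    def __post_init__(self) -> None:
        mapped = [(q, r) for q, r in self.pairs if r is not None]
        for (q1, r1), (q2, r2) in zip(mapped, mapped[1:]):
            if not (q1 < q2 and r1 < r2):
                raise ValueError("position map is not monotone")
        self._forward = {q: r for q, r in self.pairs}
        self._inverse = {r: q for q, r in mapped}

    def inverse(self, ref_pos: int) -> int | None:
        return self._inverse.get(ref_pos)


def _make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def align_global(
    query: str,
    reference: str,
    open_gap: float = 10.0,
    extend_gap: float = 0.5,
) -> Align.Alignment:
    """Global affine-gap protein alignment (BLOSUM62 by default).

    Deterministic: of co-optimal alignments the first in Biopython's
    fixed traceback order is returned.
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    for name, seq in (("query", query), ("reference", reference)):
        bad = set(seq.upper()) - set("ACDEFGHIKLMNPQRSTVWYX*")
        if bad:
            raise ValueError(f"{name} contains invalid residues {sorted(bad)}")
    aligner = _make_aligner(open_gap, extend_gap)
    return next(iter(aligner.align(query.upper(), reference.upper())))


def position_map(
    query: str,
    reference: str,
    query_id: str = "query",
    ref_id: str = "ref",
    species: str = "",
) -> PositionMap:
    """Build the residue-number map from a global alignment."""
    aln = align_global(query, reference)
    pairs: list[tuple[int, int | None]] = [(q + 1, None) for q in range(len(query))]
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        for off in range(qe - qs):
            pairs[qs + off] = (qs + off + 1, rs + off + 1)
    return PositionMap(query_id, ref_id, species, pairs)


def map_position(pmap: PositionMap, query_pos: int) -> int | None:
    """Canonical residue number for a native position, or None."""
    if not (1 <= query_pos <= len(pmap.pairs)):
        raise ValueError(f"query position {query_pos} out of range 1..{len(pmap.pairs)}")
    return pmap._forward[query_pos]


def annotate_canonical(
    effects: list[AminoAcidEffect], bundle: ReferenceBundle
) -> list[AminoAcidEffect]:
    """Fill canonical_position/species on missense-type effects.

    Genes without a configured canonical reference keep native-only
    labels.  Alignment per gene is computed once and cached locally.
    """
    maps: dict[str, PositionMap | None] = {}
    out = []
    for eff in effects:
        model = bundle.genes.get(eff.gene_id)
        if model is None or model.canonical_ref is None or eff.codon_number_native < 1:
            out.append(eff)
            continue
        if eff.gene_id not in maps:
            native_prot = bundle.protein(eff.gene_id)
            cref = model.canonical_ref
            maps[eff.gene_id] = position_map(
                native_prot, cref.sequence, eff.gene_id, cref.protein_id, cref.species
            )
        pmap = maps[eff.gene_id]
        if eff.codon_number_native > len(pmap.pairs):
            out.append(eff)  # e.g. stop codon position
            continue
        ref_pos = map_position(pmap, eff.codon_number_native)
        if ref_pos is None:
            out.append(eff)
        else:
            out.append(
                replace(
                    eff,
                    canonical_position=ref_pos,
                    canonical_species=model.canonical_ref.species,
                )
            )
    return out


def export_map_tsv(pmap: PositionMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("query_pos\tref_pos\n")
        for q, r in pmap.pairs:
            fh.write(f"{q}\t{'' if r is None else r}\n")
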
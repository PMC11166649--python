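"""Coverage-based gene-duplication detection.

Per-base read depth (samtools-depth dialect) is exon-masked, each
sample's depths are divided by that sample's median over the exons of a
set of putatively single-copy genes (the candidate CNV genes — vgsc and
GSTe2 by default — are excluded from the median so a duplication cannot
deflate its own normaliser), and per-(sample, gene) fold is the median
scaled exonic coverage.  Folds are binned into explicit copy-number
groups; a UMAP embedding of the scaled matrix is available for visual
QC but calls never depend on it.

Median convention: midpoint average for even counts (numpy), used
identically in scaling and in downstream checks so the "included-gene
scaled median == 1" invariant holds exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_models import ReferenceBundle

logger = logging.getLogger(__name__)

__all__ = [
    "DepthMatrix",
    "ScaledDepthMatrix",
    "CnvCall",
    "DEFAULT_FOLD_BINS",
    "load_depth",
    "median_scale",
    "gene_fold_calls",
    "coverage_embedding",
]

DEFAULT_CNV_GENES = frozenset({"vgsc", "gste2"})

#: (upper bound, label); folds bracket the empirically observed groups
#: ~1.0 (single copy), ~1.4 (het duplication), ~4.2 and ~9.3 (amplifications)
DEFAULT_FOLD_BINS = ((1.3, "normal"), (3.0, "duplication"), (6.0, "multi_copy"), (np.inf, "high_amplification"))
DEFAULT_DUP_THRESHOLD = 1.3


@dataclass
class DepthMatrix:
    chrom: np.ndarray  # per-position chromosome id
    pos: np.ndarray  # 1-based positions
    depth: np.ndarray  # positions x samples
    samples: tuple[str, ...]
    gene_mask: np.ndarray  # per-position gene id ('' outside exons)

    def exonic(self) -> np.ndarray:
        return self.gene_mask != ""


@dataclass
class ScaledDepthMatrix(DepthMatrix):
    sample_medians: np.ndarray = field(default_factory=lambda: np.array([]))
    included_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class CnvCall:
    sample: str
    gene: str
    fold: float
    group: str
    is_duplication: bool
    low_confidence: bool = False


def _exon_mask(bundle: ReferenceBundle, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    mask = np.full(len(pos), "", dtype=object)
    for gid, model in bundle.genes.items():
        on_chrom = chrom == model.chrom
        for iv in model.intervals:
            sel = on_chrom & (pos > iv.start) & (pos <= iv.end)
            mask[sel] = gid
    return mask.astype(str)


def load_depth(
    depth_table_path: str, bundle: ReferenceBundle, samples: tuple[str, ...]
) -> DepthMatrix:
    """Read a samtools-depth TSV (chrom, pos, depth per sample).

    Positions are restricted to annotated gene spans and the exon mask
    attached; intronic rows are kept in the matrix but masked out of all
    downstream statistics.  Duplicate (chrom, pos) rows are an error.
    """
    df = pd.read_csv(depth_table_path, sep="\t", header=None)
    if df.shape[1] != 2 + len(samples):
        raise ValueError(
            f"depth table has {df.shape[1] - 2} depth columns, manifest has {len(samples)} samples"
        )
    df.columns = ["chrom", "pos", *samples]
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) rows in depth table")
    if not df.groupby("chrom", sort=False)["pos"].apply(lambda s: s.is_monotonic_increasing).all():
        logger.warning("depth table positions unsorted; sorting")
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    chrom = df["chrom"].to_numpy(dtype=str)
    pos = df["pos"].to_numpy(dtype=np.int64)
    depth = df[list(samples)].to_numpy(dtype=np.float64)
    if (depth < 0).any():
        raise ValueError("negative depth values")
    # restrict to annotated gene spans
    span_keep = np.zeros(len(pos), bool)
    for model in bundle.genes.values():
        s, e = model.span
        span_keep |= (chrom == model.chrom) & (pos > s) & (pos <= e)
    chrom, pos, depth = chrom[span_keep], pos[span_keep], depth[span_keep]
    mask = _exon_mask(bundle, chrom, pos)
    return DepthMatrix(chrom, pos, depth, tuple(samples), mask)


def median_scale(
    depth: DepthMatrix,
    exclude_genes: frozenset[str] | set[str] = DEFAULT_CNV_GENES,
) -> ScaledDepthMatrix:
    """Divide each sample's depths by its median over included-gene exons.

    ``exclude_genes`` (candidate CNV genes) do not contribute to the
    median but are still scaled.  A sample whose median is zero cannot
    be normalised and is dropped with a QC error record.
    """
    exonic = depth.exonic()
    included = exonic & ~np.isin(depth.gene_mask, list(exclude_genes))
    if not included.any():
        raise ValueError("no exonic positions outside the excluded genes")
    medians = np.median(depth.depth[included], axis=0)
    keep = medians > 0
    if not keep.all():
        bad = [s for s, k in zip(depth.samples, keep) if not k]
        logger.error("dropping samples with zero median coverage: %s", bad)
    scaled = depth.depth[:, keep] / medians[keep]
    return ScaledDepthMatrix(
        depth.chrom,
        depth.pos,
        scaled,
        tuple(s for s, k in zip(depth.samples, keep) if k),
        depth.gene_mask,
        sample_medians=medians[keep],
        included_genes=tuple(
            sorted(set(depth.gene_mask[included]) - {""})
        ),
    )


def gene_fold_calls(
    scaled: ScaledDepthMatrix,
    dup_threshold: float = DEFAULT_DUP_THRESHOLD,
    bins: tuple[tuple[float, str], ...] = DEFAULT_FOLD_BINS,
    min_positions: int = 50,
) -> list[CnvCall]:
    """Per-(sample, gene) copy-number calls from median scaled coverage.

    fold = median scaled exonic coverage for the gene;
    is_duplication = fold >= dup_threshold; the group label comes from
    fixed 1-D fold bins.  Genes with fewer than ``min_positions``
    covered exonic positions yield low-confidence calls.
    """
    calls: list[CnvCall] = []
    genes = sorted(set(scaled.gene_mask) - {""})
    for gene in genes:
        sel = scaled.gene_mask == gene
        low_conf = int(sel.sum()) < min_positions
        folds = np.median(scaled.depth[sel], axis=0)
        for sample, fold in zip(scaled.samples, folds):
            group = next(label for bound, label in bins if fold < bound)
            calls.append(
                CnvCall(sample, gene, float(fold), group, bool(fold >= dup_threshold), low_conf)
            )
    return calls


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def coverage_embedding(scaled: ScaledDepthMatrix, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP (Euclidean) of samples on scaled exonic coverage; QC only."""
    import umap

    exonic = scaled.exonic()
    mat = scaled.depth[exonic].T  # samples x positions
    if mat.shape[0] < 10:
        raise ValueError("need >= 10 samples for a coverage embedding")
    if np.allclose(mat, mat[0]):
        raise ValueError("constant coverage matrix; embedding undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=min(n_neighbors, mat.shape[0] - 1),
            random_state=seed,
            n_jobs=1,
        )
        return reducer.fit_transform(mat)
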
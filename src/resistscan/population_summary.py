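"""Per-population allele-frequency tables, resistance-panel
co-occurrence and population-structure clustering.

The structure analysis follows the survey convention for binary variant
presence data: Russell–Rao dissimilarity between samples, a 2-D UMAP
embedding of that matrix, then density clustering (HDBSCAN) on the
embedding.  Resistance-gene and background-gene variant sets are run as
separate analyses — discordance between the two is itself informative,
since strong selection at resistance loci distorts local genealogies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_effects import MISSING, AminoAcidEffect, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationAssignment",
    "ResistancePanel",
    "DEFAULT_PANEL",
    "allele_frequency_table",
    "panel_cooccurrence",
    "russell_rao_matrix",
    "cluster_samples",
]


@dataclass
class PopulationAssignment:
    """Sample -> population label, with colony / outgroup flags."""

    population: dict[str, str]
    colony: set[str] = field(default_factory=set)
    outgroup: set[str] = field(default_factory=set)

    @classmethod
    def from_manifest(cls, path: str) -> "PopulationAssignment":
        """Read a manifest TSV with columns sample, population, colony, species."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        pops = dict(zip(df["sample"], df["population"].fillna("unknown")))
        colony = set(df.loc[df.get("colony", "0").astype(str).isin(["1", "True", "true"]), "sample"])
        outgroup = set()
        if "species" in df:
            outgroup = set(df.loc[~df["species"].str.contains("aegypti", case=False), "sample"])
        return cls(pops, colony, outgroup)

    def label(self, sample: str) -> str:
        return self.population.get(sample, "unknown")


@dataclass
class ResistancePanel:
    """Named marker set: (gene, canonical position, accepted alt residues)."""

    entries: list[tuple[str, int, str, tuple[str, ...]]]
    # (gene_id, canonical_position, ref_aa, accepted alt residues)

    def match(self, eff: AminoAcidEffect) -> bool:
        if eff.effect_class != "missense" or eff.canonical_position is None:
            return False
        for gene, pos, ref_aa, alts in self.entries:
            if eff.gene_id == gene and eff.canonical_position == pos and eff.alt_aa in alts:
                return True
        return False

    def entry_key(self, eff: AminoAcidEffect) -> tuple[str, int] | None:
        for gene, pos, _ref, alts in self.entries:
            if eff.gene_id == gene and eff.canonical_position == pos and eff.alt_aa in alts:
                return (gene, pos)
        return None


#: the nine markers conventionally screened for pyrethroid / dieldrin
#: resistance: rdl A301S plus eight sodium-channel kdr sites
DEFAULT_PANEL = ResistancePanel(
    [
        ("rdl", 301, "A", ("S", "G")),
        ("vgsc", 1534, "F", ("L", "C")),
        ("vgsc", 1520, "T", ("I",)),
        ("vgsc", 1016, "V", ("I", "G")),
        ("vgsc", 1011, "I", ("V", "M")),
        ("vgsc", 989, "S", ("P",)),
        ("vgsc", 923, "G", ("V",)),
        ("vgsc", 410, "V", ("L",)),
    ]
)


def allele_frequency_table(
    effects: dict[tuple, AminoAcidEffect],
    records: list[VariantRecord],
    populations: PopulationAssignment,
    min_carriers: int = 10,
    mode: str = "carrier",
) -> pd.DataFrame:
    """Per-population frequency table of missense variants.

    Rows are missense variants carried by at least ``min_carriers``
    samples cohort-wide (the threshold is cohort-wide, not per
    population).  ``mode='carrier'`` reports the fraction of genotyped
    samples with >=1 alt allele; ``mode='dosage'`` the alt-allele
    frequency over 2N called alleles.  Missing genotypes are excluded
    from numerator and denominator alike.
    """
    if mode not in ("carrier", "dosage"):
        raise ValueError("mode must be 'carrier' or 'dosage'")
    rows = []
    for rec in records:
        eff = effects.get(rec.key)
        if eff is None or eff.effect_class != "missense":
            continue
        carriers = rec.carrier_mask()
        if carriers.sum() < min_carriers:
            continue
        samples = rec.samples
        called = (rec.genotypes != MISSING).all(axis=1)
        pop_labels = np.array([populations.label(s) for s in samples])
        for pop in sorted(set(pop_labels)):
            sel = (pop_labels == pop) & called
            n = int(sel.sum())
            if n == 0:
                logger.warning("population %s has no genotyped samples at %s", pop, eff.label)
                continue
            n_carrier = int((carriers & sel).sum())
            if mode == "carrier":
                freq = n_carrier / n
            else:
                freq = float((rec.genotypes[sel] == 1).sum()) / (2 * n)
            rows.append(
                {
                    "gene": eff.gene_id,
                    "native_label": eff.native_label,
                    "canonical_label": eff.canonical_label or "",
                    "population": pop,
                    "carrier_count": n_carrier,
                    "sample_count": n,
                    "frequency": freq,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "native_label", "canonical_label", "population",
            "carrier_count", "sample_count", "frequency",
        ],
    )
    return df.sort_values(["gene", "native_label", "population"]).reset_index(drop=True)


def panel_cooccurrence(
    effects: dict[tuple, AminoAcidEffect],
    records: list[VariantRecord],
    populations: PopulationAssignment,
    panel: ResistancePanel = DEFAULT_PANEL,
    min_pop: int = 10,
) -> pd.DataFrame:
    """Per-population distribution of per-sample panel-mutation counts.

    A sample's count is the number of *distinct* panel sites at which it
    carries an accepted resistance residue (het or hom).  Populations
    with <= ``min_pop`` samples are excluded.  Returns long-format rows
    (population, k, n_samples, proportion_ge_k) for k = 1..panel size.
    """
    panel_records = []
    for rec in records:
        eff = effects.get(rec.key)
        if eff is None:
            continue
        key = panel.entry_key(eff) if panel.match(eff) else None
        if key is not None:
            panel_records.append((key, rec))
    if panel_records:
        samples = panel_records[0][1].samples
    else:
        samples = records[0].samples if records else ()
    n_samples = len(samples)
    # distinct sites per sample
    site_hits: dict[tuple, np.ndarray] = {}
    for key, rec in panel_records:
        hit = rec.carrier_mask()
        site_hits[key] = site_hits.get(key, np.zeros(n_samples, bool)) | hit
    counts = np.zeros(n_samples, int)
    for hit in site_hits.values():
        counts += hit.astype(int)

    pop_labels = np.array([populations.label(s) for s in samples])
    n_entries = len({(g, p) for g, p, _r, _a in panel.entries})
    rows = []
    for pop in sorted(set(pop_labels)):
        sel = pop_labels == pop
        n = int(sel.sum())
        if n <= min_pop:
            continue
        for k in range(1, n_entries + 1):
            rows.append(
                {
                    "population": pop,
                    "k": k,
                    "n_samples": n,
                    "proportion_ge_k": float((counts[sel] >= k).mean()),
                }
            )
    return pd.DataFrame(rows, columns=["population", "k", "n_samples", "proportion_ge_k"])


def presence_matrix(
    records: list[VariantRecord], samples: tuple[str, ...] | None = None
) -> tuple[np.ndarray, list[tuple]]:
    """Binary sample x variant carrier matrix; missing imputed as 0."""
    if not records:
        raise ValueError("no variant records")
    samples = samples or records[0].samples
    mat = np.zeros((len(samples), len(records)), dtype=np.int8)
    n_missing = 0
    for j, rec in enumerate(records):
        mat[:, j] = rec.carrier_mask().astype(np.int8)
        n_missing += int((rec.genotypes == MISSING).any(axis=1).sum())
    if n_missing:
        logger.info("imputed %d sample-genotypes with missing calls as absent", n_missing)
    return mat, [r.key for r in records]


def russell_rao_matrix(presence: np.ndarray) -> np.ndarray:
    """Pairwise Russell–Rao dissimilarity d(x,y) = (n - a)/n.

    ``a`` counts variants present in *both* samples.  Note the metric's
    quirk: two all-zero vectors are at distance 1, and d(x,x)=0 only for
    an all-ones vector — joint absence carries no similarity.
    """
    x = np.asarray(presence)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("presence matrix must be 2-D with >=1 variant")
    xb = (x > 0).astype(np.float64)
    a = xb @ xb.T
    return (x.shape[1] - a) / x.shape[1]


#: default embedding/density-clustering hyperparameters; every CLI run
#: records the values used in its output metadata
CLUSTER_DEFAULTS = {"n_neighbors": 15, "min_dist": 0.1, "min_cluster_size": 10}


def cluster_samples(
    presence: np.ndarray,
    seed: int = 0,
    n_neighbors: int = CLUSTER_DEFAULTS["n_neighbors"],
    min_cluster_size: int = CLUSTER_DEFAULTS["min_cluster_size"],
    min_dist: float = CLUSTER_DEFAULTS["min_dist"],
) -> tuple[np.ndarray, np.ndarray]:
    """UMAP embedding (Russell–Rao, precomputed) + HDBSCAN labels.

    Returns (labels, embedding); label -1 marks noise points.
    Deterministic for a fixed seed (single-threaded UMAP).
    """
    import umap
    from sklearn.cluster import HDBSCAN

    n = presence.shape[0]
    if n < 10:
        raise ValueError("need >= 10 samples for structure clustering")
    if n <= n_neighbors:
        raise ValueError(
            f"{n} samples <= n_neighbors={n_neighbors}; lower n_neighbors"
        )
    dist = russell_rao_matrix(presence)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            metric="precomputed",
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
            n_jobs=1,
        )
        emb = reducer.fit_transform(dist)
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(emb)
    return labels, emb
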
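"""Two-locus linkage disequilibrium between missense variants.

r² is computed per population, either by direct gamete counting on
phased genotypes or — for unphased input — from maximum-likelihood
haplotype frequencies estimated with the classic two-locus EM algorithm
(the only latent phase is in double heterozygotes).  Pairs exceeding a
reporting threshold (default r² > 0.5) are flagged; no multiple-testing
adjustment is applied to the flagging rule, though a Bonferroni-style
count is emitted for information.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_effects import MISSING, AminoAcidEffect, VariantRecord
from .population_summary import PopulationAssignment

logger = logging.getLogger(__name__)

__all__ = ["HaplotypeFreqs", "r2_from_haplotypes", "em_two_locus", "ld_scan"]

_EPS = 1e-12


@dataclass
class HaplotypeFreqs:
    """Two-locus haplotype frequencies (alleles coded A/a, B/b as 1/0)."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    n_haplotypes: int
    converged: bool = True
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        total = self.p_AB + self.p_Ab + self.p_aB + self.p_ab
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"haplotype frequencies sum to {total}")

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB

    @property
    def D(self) -> float:
        return self.p_AB - self.p_A * self.p_B

    @property
    def r2(self) -> float | None:
        """D²/(pA(1-pA) pB(1-pB)); None when either locus is monomorphic."""
        den = self.p_A * (1 - self.p_A) * self.p_B * (1 - self.p_B)
        if den < _EPS:
            return None
        return min(1.0, self.D ** 2 / den)


def r2_from_haplotypes(hap_a: np.ndarray, hap_b: np.ndarray) -> HaplotypeFreqs:
    """Count gametes directly from phased haplotypes (1 = alt allele)."""
    a = np.asarray(hap_a, dtype=int)
    b = np.asarray(hap_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("haplotype vectors must be 1-D and equal length")
    if a.size < 2:
        raise ValueError("need >= 2 haplotypes")
    n = a.size
    n_AB = int(((a == 1) & (b == 1)).sum())
    n_Ab = int(((a == 1) & (b == 0)).sum())
    n_aB = int(((a == 0) & (b == 1)).sum())
    n_ab = int(((a == 0) & (b == 0)).sum())
    return HaplotypeFreqs(n_AB / n, n_Ab / n, n_aB / n, n_ab / n, n)


def em_two_locus(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeFreqs:
    """EM haplotype-frequency estimation from unphased diploid genotypes.

    ``geno_a``/``geno_b`` hold alt-allele dosages (0/1/2) per
    individual; pairs with a missing value at either locus are dropped.
    Initialised at linkage equilibrium; the only E-step latency is the
    coupling/repulsion split of double heterozygotes.  The observed-data
    log-likelihood is non-decreasing across iterations (asserted).
    """
    ga = np.asarray(geno_a, dtype=int)
    gb = np.asarray(geno_b, dtype=int)
    keep = (ga >= 0) & (gb >= 0)
    ga, gb = ga[keep], gb[keep]
    if ga.size < 1:
        raise ValueError("no complete two-locus genotypes")
    if ga.size == 1:
        logger.warning("two-locus EM on a single individual; estimates are degenerate")
    n = ga.size
    # known gamete counts from everything except double heterozygotes
    dh = (ga == 1) & (gb == 1)
    n_dh = int(dh.sum())
    cA = np.zeros(4)  # AB, Ab, aB, ab
    for a_, b_ in zip(ga[~dh], gb[~dh]):
        # phase is known unless het at both loci; at most one locus is het here
        if a_ == 1:  # b homozygous: both gametes carry the same b allele
            pairs = [(1, b_ // 2), (0, b_ // 2)]
        elif b_ == 1:
            pairs = [(a_ // 2, 1), (a_ // 2, 0)]
        else:
            pairs = [(a_ // 2, b_ // 2)] * 2
        for ha_, hb_ in pairs:
            cA[_hap_index(ha_, hb_)] += 1

    pA = ga.mean() / 2
    pB = gb.mean() / 2
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    p = np.clip(p, _EPS, None)
    p /= p.sum()

    def loglik(p4: np.ndarray) -> float:
        ll = float(cA @ np.log(np.clip(p4, _EPS, None)))
        if n_dh:
            coupling = p4[0] * p4[3]
            repulsion = p4[1] * p4[2]
            ll += n_dh * np.log(max(2 * (coupling + repulsion), _EPS))
        return ll

    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        coupling = p[0] * p[3]
        repulsion = p[1] * p[2]
        denom = coupling + repulsion
        w = 0.5 if denom < _EPS else coupling / denom
        counts = cA.copy()
        counts[0] += n_dh * w
        counts[3] += n_dh * w
        counts[1] += n_dh * (1 - w)
        counts[2] += n_dh * (1 - w)
        p_new = counts / (2 * n)
        ll = loglik(p_new)
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            prev_ll = ll
            converged = True
            break
        p, prev_ll = p_new, ll
    if not converged:
        logger.warning("two-locus EM did not converge in %d iterations", max_iter)
    return HaplotypeFreqs(
        p[0], p[1], p[2], p[3], 2 * n, converged=converged, log_likelihood=prev_ll
    )


def _hap_index(a: int, b: int) -> int:
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(a, b)]


def ld_scan(
    records: list[VariantRecord],
    effects: dict[tuple, AminoAcidEffect],
    populations: PopulationAssignment,
    report_threshold: float = 0.5,
    min_diploids: int = 5,
    exclude_colonies: bool = True,
    use_phase: bool = True,
) -> pd.DataFrame:
    """All pairwise r² between missense variants, per population.

    Uses direct gamete counting when both loci are fully phased in the
    population (and ``use_phase``), otherwise the two-locus EM.  Pairs
    with r² above ``report_threshold`` carry ``flagged=True``; the full
    matrix is retained either way.  Populations with fewer than
    ``min_diploids`` complete individuals at a pair are skipped.
    """
    missense = [
        r for r in records
        if effects.get(r.key) is not None and effects[r.key].effect_class == "missense"
    ]
    if not missense:
        return pd.DataFrame(
            columns=["population", "gene_a", "label_a", "gene_b", "label_b",
                     "r2", "n_haplotypes", "method", "flagged"]
        )
    samples = missense[0].samples
    pop_labels = np.array([populations.label(s) for s in samples])
    include = np.ones(len(samples), bool)
    if exclude_colonies:
        include = np.array([s not in populations.colony for s in samples])

    rows = []
    n_tests = 0
    for ra, rb in itertools.combinations(missense, 2):
        ea, eb = effects[ra.key], effects[rb.key]
        for pop in sorted(set(pop_labels)):
            sel = (pop_labels == pop) & include
            ga = np.where((ra.genotypes[sel] == MISSING).any(axis=1), -1,
                          (ra.genotypes[sel] == 1).sum(axis=1))
            gb = np.where((rb.genotypes[sel] == MISSING).any(axis=1), -1,
                          (rb.genotypes[sel] == 1).sum(axis=1))
            complete = (ga >= 0) & (gb >= 0)
            if complete.sum() < min_diploids:
                continue
            ga_c, gb_c = ga[complete], gb[complete]
            if len(set(ga_c)) < 2 or len(set(gb_c)) < 2:
                continue  # monomorphic in this population -> r2 undefined
            phased_ok = (
                use_phase
                and ra.phased[sel][complete].all()
                and rb.phased[sel][complete].all()
            )
            if phased_ok:
                idx = np.flatnonzero(sel)[complete]
                ha = ra.genotypes[idx].reshape(-1)
                hb = rb.genotypes[idx].reshape(-1)
                hf = r2_from_haplotypes((ha == 1).astype(int), (hb == 1).astype(int))
                method = "count"
            else:
                hf = em_two_locus(ga_c, gb_c)
                method = "EM"
            r2 = hf.r2
            if r2 is None:
                continue
            n_tests += 1
            rows.append(
                {
                    "population": pop,
                    "gene_a": ea.gene_id, "label_a": ea.label,
                    "gene_b": eb.gene_id, "label_b": eb.label,
                    "r2": r2, "n_haplotypes": hf.n_haplotypes,
                    "method": method, "flagged": r2 > report_threshold,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["population", "gene_a", "label_a", "gene_b", "label_b",
                 "r2", "n_haplotypes", "method", "flagged"],
    )
    df.attrs["n_tests"] = n_tests  # for an informational Bonferroni column
    if n_tests:
        df["bonferroni_note"] = f"1/{n_tests}"
    return df
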
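"""Allele-frequency tables, panel co-occurrence and structure clustering."""

import numpy as np
import pytest

from resistscan.population_summary import (
    DEFAULT_PANEL,
    PopulationAssignment,
    allele_frequency_table,
    cluster_samples,
    panel_cooccurrence,
    presence_matrix,
    russell_rao_matrix,
)
from resistscan.variant_effects import MISSING, AminoAcidEffect, VariantRecord


def _rec(pos, gts, samples, chrom="c", ref="A", alt="G"):
    gts = np.asarray(gts, dtype=np.int16)
    return VariantRecord(
        chrom, pos, ref, (alt,), gts, np.ones(len(gts), bool), None, tuple(samples)
    )


def _eff(rec, gene="vgsc", codon=410, ref_aa="V", alt_aa="L", canonical=None):
    return AminoAcidEffect(
        gene, codon, ref_aa, alt_aa, "missense",
        f"{ref_aa}{codon}{alt_aa}", canonical_position=canonical,
        canonical_species="x" if canonical else None, variant_key=rec.key,
    )


def _pops(samples, labels):
    return PopulationAssignment(dict(zip(samples, labels)))


def test_carrier_threshold_is_cohort_wide():
    samples = [f"s{i}" for i in range(20)]
    pops = _pops(samples, ["A"] * 10 + ["B"] * 10)
    # 9 carriers -> excluded; 10 carriers -> included
    gts9 = [[0, 1]] * 9 + [[0, 0]] * 11
    gts10 = [[0, 1]] * 10 + [[0, 0]] * 10
    for gts, expect_rows in [(gts9, 0), (gts10, 2)]:
        rec = _rec(5, gts, samples)
        effects = {rec.key: _eff(rec)}
        df = allele_frequency_table(effects, [rec], pops, min_carriers=10)
        assert len(df) == expect_rows


def test_all_hom_ref_gives_empty_table():
    samples = [f"s{i}" for i in range(12)]
    rec = _rec(5, [[0, 0]] * 12, samples)
    df = allele_frequency_table({rec.key: _eff(rec)}, [rec], _pops(samples, ["A"] * 12))
    assert df.empty


def test_frequency_modes_and_missing_exclusion():
    samples = [f"s{i}" for i in range(12)]
    gts = [[1, 1]] * 4 + [[0, 1]] * 6 + [[MISSING, MISSING]] * 2
    rec = _rec(5, gts, samples)
    effects = {rec.key: _eff(rec)}
    pops = _pops(samples, ["A"] * 12)
    carrier = allele_frequency_table(effects, [rec], pops, mode="carrier")
    dosage = allele_frequency_table(effects, [rec], pops, mode="dosage")
    assert carrier.loc[0, "sample_count"] == 10  # missing excluded
    assert carrier.loc[0, "frequency"] == pytest.approx(1.0)
    assert dosage.loc[0, "frequency"] == pytest.approx(14 / 20)


def test_frequency_invariant_to_sample_and_variant_order(cohort):
    records, effects, pops, _ = cohort
    sub = [r for r in records if effects.get(r.key)][:8]
    df_fwd = allele_frequency_table(effects, sub, pops, min_carriers=1)
    df_rev = allele_frequency_table(effects, sub[::-1], pops, min_carriers=1)
    assert df_fwd.equals(df_rev)


def test_planted_frequencies_recovered(cohort, truth):
    """The pipeline's carrier counts equal the generator's realized truth
    exactly, and realized values track the nominal planted frequencies
    within binomial sampling error (3 SEs for nearly all of the ~30
    population x variant checks, never beyond 5)."""
    records, effects, pops, _ = cohort
    df = allele_frequency_table(effects, records, pops, min_carriers=1)
    checked, outside_3se = 0, 0
    for pop, freqs in truth.variant_freqs.items():
        for label, f in freqs.items():
            rows = df[(df.population == pop) & (df.canonical_label == label)]
            if rows.empty or f == 0:
                continue
            row = rows.iloc[0]
            assert row["carrier_count"] == truth.realized_carriers[label][pop], label
            p_exp = 1 - (1 - f) ** 2
            se = np.sqrt(p_exp * (1 - p_exp) / row["sample_count"])
            z = abs(row["frequency"] - p_exp) / se
            assert z <= 5, (label, pop, z)
            outside_3se += z > 3
            checked += 1
    assert checked >= 10
    assert outside_3se <= max(1, 0.1 * checked)


# ---------------------------------------------------------------------------
# panel co-occurrence

def test_panel_counts_distinct_sites():
    samples = [f"s{i}" for i in range(12)]
    pops = _pops(samples, ["A"] * 12)
    # sample 0 carries F1534C (het) + V410L (hom) -> panel count 2
    r1 = _rec(5, [[0, 1]] + [[0, 0]] * 11, samples)
    r2 = _rec(9, [[1, 1]] + [[0, 0]] * 11, samples)
    effects = {
        r1.key: _eff(r1, codon=1534, ref_aa="F", alt_aa="C", canonical=1534),
        r2.key: _eff(r2, codon=410, ref_aa="V", alt_aa="L", canonical=410),
    }
    df = panel_cooccurrence(effects, [r1, r2], pops, min_pop=10)
    assert df[(df.population == "A") & (df.k == 2)].proportion_ge_k.iloc[0] == pytest.approx(1 / 12)


def test_population_of_exactly_min_pop_excluded():
    samples = [f"s{i}" for i in range(22)]
    # population B has exactly 10 samples -> excluded ("more than 10")
    pops = _pops(samples, ["A"] * 12 + ["B"] * 10)
    rec = _rec(5, [[0, 1]] * 22, samples)
    effects = {rec.key: _eff(rec, codon=410, canonical=410)}
    df = panel_cooccurrence(effects, [rec], pops, min_pop=10)
    assert set(df.population) == {"A"}


def test_constructed_triple_carriers(cohort_dir):
    """A population where every sample carries three panel mutations has
    proportion >=3 equal to 1.0."""
    samples = [f"s{i}" for i in range(15)]
    pops = _pops(samples, ["X"] * 15)
    recs, effects = [], {}
    for pos, codon in [(5, 410), (9, 1016), (13, 1534)]:
        r = _rec(pos, [[0, 1]] * 15, samples)
        refaa, altaa = {410: ("V", "L"), 1016: ("V", "I"), 1534: ("F", "C")}[codon]
        recs.append(r)
        effects[r.key] = _eff(r, codon=codon, ref_aa=refaa, alt_aa=altaa, canonical=codon)
    df = panel_cooccurrence(effects, recs, pops, min_pop=10)
    assert df[(df.k == 3)].proportion_ge_k.iloc[0] == 1.0
    assert df[(df.k == 4)].proportion_ge_k.iloc[0] == 0.0


def test_panel_counting_idempotent(cohort):
    records, effects, pops, _ = cohort
    a = panel_cooccurrence(effects, records, pops)
    b = panel_cooccurrence(effects, records, pops)
    assert a.equals(b)


# ---------------------------------------------------------------------------
# Russell-Rao distance

def test_russell_rao_hand_example():
    x = np.array([[1, 1, 0, 0], [1, 0, 1, 0]])
    d = russell_rao_matrix(x)
    assert d[0, 1] == pytest.approx(0.75)  # a=1, n=4
    assert d[1, 0] == pytest.approx(0.75)


def test_russell_rao_quirks():
    ones = np.ones((2, 5))
    assert russell_rao_matrix(ones)[0, 1] == 0.0
    assert russell_rao_matrix(ones)[0, 0] == 0.0
    zeros = np.zeros((2, 5))
    # joint absence carries no similarity: all-zero pairs are maximally distant
    assert russell_rao_matrix(zeros)[0, 1] == 1.0
    assert russell_rao_matrix(zeros)[0, 0] == 1.0


def test_russell_rao_bounds_and_diag():
    rng = np.random.default_rng(2)
    x = (rng.random((10, 30)) < 0.4).astype(int)
    d = russell_rao_matrix(x)
    assert ((d >= 0) & (d <= 1)).all()
    for i in range(10):
        assert (d[i, i] == 0) == bool(x[i].all())


def test_russell_rao_rejects_empty():
    with pytest.raises(ValueError):
        russell_rao_matrix(np.zeros((3, 0)))


# ---------------------------------------------------------------------------
# clustering

def test_three_disjoint_populations_recovered():
    rng = np.random.default_rng(0)
    blocks, labels_true = [], []
    for p in range(3):
        m = np.zeros((40, 90), np.int8)
        m[:, p * 30 : (p + 1) * 30] = rng.random((40, 30)) < 0.8
        blocks.append(m)
        labels_true += [p] * 40
    labels, emb = cluster_samples(np.vstack(blocks), seed=1)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(labels_true, labels) >= 0.9
    assert emb.shape == (120, 2)


def test_homogeneous_population_not_split():
    """On exchangeable data (one population, iid variants) the pipeline
    should essentially never report more than one non-noise cluster."""
    rng = np.random.default_rng(0)
    fails = 0
    for seed in range(20):
        mat = (rng.random((40, 60)) < 0.3).astype(np.int8)
        labels, _ = cluster_samples(mat, seed=seed)
        fails += len(set(labels) - {-1}) > 1
    assert fails <= 1  # >= 95% of 20 seeds


def test_duplicated_samples_co_cluster():
    rng = np.random.default_rng(4)
    base = (rng.random((30, 40)) < 0.5).astype(np.int8)
    doubled = np.vstack([base, base])
    labels, _ = cluster_samples(doubled, seed=0, n_neighbors=10)
    for i in range(30):
        assert labels[i] == labels[30 + i]


def test_too_few_samples_raises_with_guidance():
    with pytest.raises(ValueError, match="n_neighbors"):
        cluster_samples(np.eye(12, dtype=np.int8), seed=0, n_neighbors=15)
    with pytest.raises(ValueError, match=">= 10"):
        cluster_samples(np.eye(5, dtype=np.int8), seed=0)


def test_presence_matrix_imputes_missing_as_absent():
    samples = ("a", "b")
    gts = np.array([[0, 1], [MISSING, MISSING]], dtype=np.int16)
    rec = VariantRecord("c", 5, "A", ("G",), gts, np.ones(2, bool), None, samples)
    mat, keys = presence_matrix([rec])
    assert mat.tolist() == [[1], [0]]
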
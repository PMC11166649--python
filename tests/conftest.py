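"""Shared fixtures: the default synthetic cohort, generated once per session."""

from __future__ import annotations

from pathlib import Path

import pytest

from resistscan.gene_models import load_reference
from resistscan.population_summary import PopulationAssignment
from resistscan.residue_mapping import annotate_canonical
from resistscan.synthetic_data import (
    CANONICAL_MAP,
    TruthSet,
    build_reference,
    default_config,
    simulate_bioassays,
    simulate_cohort,
    simulate_depth,
)
from resistscan.variant_effects import classify_all, decompose_variants, filter_min_depth, read_vcf

SEED = 1


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("cohort")
    cfg = default_config(SEED)
    truth = simulate_cohort(cfg, out)
    bundle = build_reference(SEED)
    simulate_depth(cfg, bundle, out, truth)
    truth.to_json(out / "truth.json")
    simulate_bioassays(cfg, out)
    return out


@pytest.fixture(scope="session")
def truth(cohort_dir) -> TruthSet:
    return TruthSet.from_json(cohort_dir / "truth.json")


@pytest.fixture(scope="session")
def bundle(cohort_dir):
    return load_reference(
        cohort_dir / "reference.fa",
        cohort_dir / "genes.bed",
        cohort_dir / "canonical_proteins.fa",
        canonical_map=CANONICAL_MAP,
    )


@pytest.fixture(scope="session")
def cohort(cohort_dir, bundle):
    """(records, effects, populations, samples) for the default cohort."""
    records, samples = read_vcf(cohort_dir / "cohort.vcf")
    records = decompose_variants(records, bundle)
    records = filter_min_depth(records, 5)
    effects = classify_all(bundle, records)
    effects = {
        e.variant_key: e for e in annotate_canonical(list(effects.values()), bundle)
    }
    populations = PopulationAssignment.from_manifest(cohort_dir / "manifest.tsv")
    return records, effects, populations, samples
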
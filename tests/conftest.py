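"""Shared fixtures: miniature cohorts and hand-built variants."""

from __future__ import annotations

import numpy as np
import pytest

from pedseg.datamodel import (
    AnnotatedVariant,
    Cohort,
    Consequence,
    PredictorCall,
    Role,
    Sample,
)
from pedseg.simulate import PlantedVariant, SimulationConfig, simulate

D = PredictorCall.DELETERIOUS
T = PredictorCall.TOLERATED
M = PredictorCall.MISSING


def make_variant(
    genotypes,
    gene="GENE1",
    consequence=Consequence.MISSENSE,
    maf_sas=0.0001,
    maf_global=0.0001,
    predictor_calls=(D, D, D, D, D),
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="G",
):
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        maf_sas=maf_sas,
        maf_global=maf_global,
        predictor_calls=tuple(predictor_calls),
        genotypes=np.asarray(genotypes, dtype=np.int8),
    )


@pytest.fixture
def trio_cohort():
    """One family (2 cases + 1 family control), plus 2 unrelated controls."""
    return Cohort(
        samples=[
            Sample("A1", "FAM1", affected=True, role=Role.CASE),
            Sample("A2", "FAM1", affected=True, role=Role.CASE),
            Sample("A3", "FAM1", affected=False, role=Role.FAMILY_CONTROL),
            Sample("U1", "", role=Role.UNRELATED_CONTROL),
            Sample("U2", "", role=Role.UNRELATED_CONTROL),
        ]
    )


@pytest.fixture
def multiplex_cohort():
    """Two 4-case families, one 2-case family, 3 unrelated controls."""
    samples = []
    for fam, n_cases in (("FAM1", 4), ("FAM2", 4), ("FAM3", 2)):
        for i in range(n_cases):
            samples.append(
                Sample(f"{fam}C{i}", fam, affected=True, role=Role.CASE)
            )
        samples.append(
            Sample(f"{fam}N0", fam, affected=False, role=Role.FAMILY_CONTROL)
        )
    for i in range(3):
        samples.append(Sample(f"U{i}", "", role=Role.UNRELATED_CONTROL))
    return Cohort(samples=samples)


MINI_CONFIG = SimulationConfig(
    n_families=10,
    n_multisample_families=4,
    n_unrelated_controls=15,
    n_genes=60,
    n_cns_genes=12,
    variants_per_gene=4,
    n_common_variants=200,
    seed=11,
)


@pytest.fixture(scope="session")
def mini_sim():
    """Small synthetic cohort reused across tests (seeded, deterministic)."""
    return simulate(MINI_CONFIG)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale synthetic cohort (75 families, ~2e4 variants)."""
    return simulate(SimulationConfig(seed=42))
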
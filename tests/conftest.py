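"""Shared fixtures: toy pedigrees, small synthetic cohorts, helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mitotreescan.kinship import (
    Pedigree,
    PedigreeMember,
    familial_adjustment_scores,
    kinship_matrix,
)
from mitotreescan.synthdata import SimulationConfig, SyntheticCohort, simulate_cohort
from mitotreescan.treescan import PhenotypeTable


@pytest.fixture(scope="session")
def three_gen_pedigree() -> Pedigree:
    """Three generations: grandparents, two full-sib parents' families, cousins.

    GF1 x GM1 -> P1, P2 (full sibs); P1 x S1 -> C1, C2 (full sibs);
    P2 x S2 -> C3 (C1/C3 are first cousins); GF1 x GM2 -> P3 (P1/P3 half sibs).
    """
    rows = [
        ("GF1", None, None, "M"), ("GM1", None, None, "F"),
        ("GM2", None, None, "F"),
        ("S1", None, None, "F"), ("S2", None, None, "F"),
        ("P1", "GF1", "GM1", "M"), ("P2", "GF1", "GM1", "F"),
        ("P3", "GF1", "GM2", "M"),
        ("C1", "P1", "S1", "F"), ("C2", "P1", "S1", "M"),
        ("C3", "S2", "P2", "F"),
    ]
    return Pedigree([PedigreeMember(i, f, m, s, 50.0) for i, f, m, s in rows])


@pytest.fixture(scope="session")
def small_cohort() -> SyntheticCohort:
    """A 400-individual synthetic cohort with an injected clade effect."""
    return simulate_cohort(SimulationConfig(seed=42, n_individuals=400,
                                            n_matrilineages=60))


def cohort_inputs(cohort: SyntheticCohort):
    """Phenotype table plus the cohort kinship matrix for the scan."""
    ids = sorted(cohort.truth.matrilineage_of)
    kin = kinship_matrix(cohort.pedigree).subset(ids)
    return PhenotypeTable(cohort.phenotypes.copy()), kin


def cohort_phenotypes(cohort: SyntheticCohort) -> PhenotypeTable:
    """Phenotype table with the observed-data FAS as a fixed covariate."""
    ids = sorted(cohort.truth.matrilineage_of)
    kin = kinship_matrix(cohort.pedigree).subset(ids)
    fas = familial_adjustment_scores(
        cohort.phenotypes["copy_number"].to_dict(), kin)
    table = cohort.phenotypes.copy()
    table["fas"] = fas
    return PhenotypeTable(table)


@pytest.fixture(scope="session")
def small_cohort_pheno(small_cohort) -> PhenotypeTable:
    return cohort_phenotypes(small_cohort)


def gene_dropping_kinship(ped: Pedigree, n_drops: int,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Monte-Carlo kinship oracle: drop unique founder alleles through the
    pedigree and estimate f(i, j) as the probability that randomly drawn
    alleles are identical by descent (averaged over the 4 allele pairings).
    """
    topo = ped._topological_order()
    by_id = {m.id: m for m in ped.members}
    a1: dict[str, np.ndarray] = {}
    a2: dict[str, np.ndarray] = {}
    next_allele = 0
    for ind in topo:
        m = by_id[ind]
        alleles = []
        for parent in (m.father, m.mother):
            if parent is None:
                # a unique, unrelated phantom founder contributes a fresh allele
                alleles.append(np.full(n_drops, next_allele))
                next_allele += 1
            else:
                pick = rng.random(n_drops) < 0.5
                alleles.append(np.where(pick, a1[parent], a2[parent]))
        a1[ind], a2[ind] = alleles
    ids = ped.ids
    est = np.zeros((len(ids), len(ids)))
    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            if j < i:
                continue
            f = 0.25 * ((a1[x] == a1[y]).mean() + (a1[x] == a2[y]).mean()
                        + (a2[x] == a1[y]).mean() + (a2[x] == a2[y]).mean())
            est[i, j] = est[j, i] = f
    return pd.DataFrame(est, index=ids, columns=ids)
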
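"""Synthetic cohorts with the structure the association analysis assumes.

The generator emulates a population-based elderly cohort in which full
mitochondrial genomes are sequenced for one representative per maternal
lineage (matrilineage) and imputed to the remaining matrilineal
relatives, while a continuous phenotype (relative mtDNA copy number)
carries age, sex, clade and kinship-structured familial effects.

The pieces, in the order they are generated:

1. a random matrilineal genealogy over the matrilineages (a random
   growing tree, so ancestral haplotypes remain sampled), with
   Poisson-distributed mutations on each branch placed at unique
   reference positions (infinite-sites: no recurrence, no back
   mutation), so pairwise Hamming distance between haplotypes equals
   path length in mutation counts on the tree;
2. aligned sequences for one representative per matrilineage plus a
   matrilineage map listing all other members;
3. a multi-generation pedigree whose maternal lines agree with the
   matrilineage assignment (members of a matrilineage coalesce through
   unobserved ancestral females; fathers are unrelated founders);
4. phenotypes y_i = mu + b_age*age_i + b_sex*sex_i + g_clade*1[clade]
   + g_i + e_i with g ~ N(0, 2*sigma2_g*K) for kinship matrix K and
   e ~ N(0, sigma2_e), a configured fraction set missing at random.

Default parameters are calibrated to the scale of a real cohort of this
design: 1007 individuals over 274 matrilineages, ~250 unique haplotypes
with ~900 segregating variants on a 16,569-bp reference, background
phenotype mean ~2.7 (SD ~0.9) with a target clade of 10-17 members
shifted upward by ~1.1 units (to ~3.8).

Everything is deterministic given (config, seed): the truth record and
every emitted file are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapacityError, ParameterError
from .kinship import Pedigree, PedigreeMember, kinship_matrix, write_pedigree
from .mtvar import (
    DELETION,
    INSERTION,
    SNV,
    AlignmentMatrix,
    HaplotypeTable,
    Variant,
    _build_coordinate_map,
    collapse_haplotypes,
    normalize_variant,
    write_alignment,
)

REFERENCE_ID = "REF"


@dataclass
class SimulationConfig:
    """Knobs for the synthetic cohort; defaults give the study-scale cohort."""

    seed: int = 0
    n_individuals: int = 1007
    n_matrilineages: int = 274
    reference_length: int = 16569
    # mutation process
    branch_mutation_mean: float = 3.15   # Poisson mean per genealogy branch
    root_mutation_mean: float = 8.0      # offset of the cohort ancestor vs reference
    indel_fraction: float = 0.05         # fraction of mutations that are indels
    max_indel_length: int = 9
    # pedigree
    sibship_sizes: tuple[int, ...] = (2, 3)  # maternal coalescence arities
    p_male: float = 0.44
    age_range: tuple[float, float] = (65.0, 95.0)
    # phenotype model (relative copy-number units)
    mu: float = 3.53
    beta_age: float = -0.01              # per year
    beta_sex: float = -0.10              # male minus female
    gamma_clade: float = 1.1             # target clade shift
    sigma2_g: float = 0.045              # kinship-structured variance component
    sigma2_e: float = 0.72               # residual variance
    clade_size_range: tuple[int, int] = (10, 17)  # in individuals
    missing_fraction: float = 0.19
    copy_number_floor: float = 0.2       # resample residuals below this floor

    def validate(self) -> None:
        if self.n_matrilineages < 2 or self.n_individuals < self.n_matrilineages:
            raise ParameterError(
                "need n_individuals >= n_matrilineages >= 2, got "
                f"{self.n_individuals} / {self.n_matrilineages}")
        if min(self.sigma2_g, self.sigma2_e) < 0:
            raise ParameterError("variance components must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ParameterError("missing_fraction must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Everything needed to check every downstream stage against the generator."""

    config: SimulationConfig
    reference: str
    # genealogy: node 0 is the root; leaves are matrilineages
    parent: list[int]                      # parent[node], -1 for root
    leaf_nodes: list[int]                  # genealogy node per matrilineage
    node_mutations: dict[int, tuple[Variant, ...]]  # per-node branch mutations
    haplotype_of_matrilineage: list[frozenset[Variant]]
    matrilineage_of: dict[str, int]        # individual -> matrilineage index
    representative_of: dict[str, str]      # individual -> sequenced representative
    target_node: int | None = None
    target_individuals: tuple[str, ...] = ()
    target_variants: tuple[Variant, ...] = ()
    ages: dict[str, float] = field(default_factory=dict)
    sexes: dict[str, int] = field(default_factory=dict)   # 0=female, 1=male
    g: dict[str, float] = field(default_factory=dict)
    phenotype: dict[str, float] = field(default_factory=dict)  # NaN = missing

    def tree_distance(self, m_a: int, m_b: int) -> int:
        """Mutation-count path length between two matrilineages' leaves."""
        path_a = self._path_to_root(self.leaf_nodes[m_a])
        path_b = self._path_to_root(self.leaf_nodes[m_b])
        common = set(path_a) & set(path_b)
        dist = 0
        for node in path_a + path_b:
            if node not in common:
                dist += len(self.node_mutations.get(node, ()))
        return dist

    def _path_to_root(self, node: int) -> list[int]:
        out = []
        while node != -1:
            out.append(node)
            node = self.parent[node]
        return out

    def haplotype_table(self) -> HaplotypeTable:
        """The true haplotype table (what the alignment pipeline must recover)."""
        variant_sets = {
            rep: self.haplotype_of_matrilineage[self.matrilineage_of[rep]]
            for rep in sorted(set(self.representative_of.values()))
        }
        return collapse_haplotypes(variant_sets, self.representative_of)


# ---------------------------------------------------------------------------
# Genealogy and mutations
# ---------------------------------------------------------------------------

def _random_reference(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _draw_mutation(reference: str, used: set[int], rng: np.random.Generator,
                   cfg: SimulationConfig) -> Variant:
    """One mutation at a fresh position (with a guard band around indels)."""
    L = len(reference)
    for _ in range(10_000):
        if rng.random() < cfg.indel_fraction:
            if rng.random() < 0.5:  # deletion
                length = int(rng.integers(1, cfg.max_indel_length + 1))
                start = int(rng.integers(2, L - length))
                span = range(start - 1, start + length + 1)
                if any(p in used for p in span):
                    continue
                v = normalize_variant(
                    Variant(DELETION, start, start + length - 1,
                            reference[start - 1 : start + length - 1], ""),
                    reference)
                if any(p in used for p in range(v.start - 1, v.end + 2)):
                    continue
                used.update(range(v.start - 1, v.end + 2))
                return v
            length = int(rng.integers(1, cfg.max_indel_length + 1))
            pos = int(rng.integers(2, L))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
            v = normalize_variant(Variant(INSERTION, pos, pos, "", seq), reference)
            if v.start < 2 or any(p in used for p in (v.start - 1, v.start, v.start + 1)):
                continue
            used.update((v.start - 1, v.start, v.start + 1))
            return v
        pos = int(rng.integers(1, L + 1))
        if pos in used:
            continue
        ref_base = reference[pos - 1]
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref_base:
            alt = "ACGT"[int(rng.integers(0, 4))]
        used.add(pos)
        return Variant(SNV, pos, pos, ref_base, alt)
    raise CapacityError(
        f"could not place a new mutation; {len(used)} of {L} positions used")


def simulate_genealogy(config: SimulationConfig,
                       rng: np.random.Generator) -> SimulationTruth:
    """Random matrilineal genealogy with infinite-sites mutations.

    The genealogy is a random growing tree over the matrilineages: each new
    matrilineage descends from a uniformly chosen existing one, acquiring a
    Poisson number of fresh mutations at unique reference positions.
    Ancestral haplotypes therefore remain sampled in the cohort — as in a
    densely sampled population, where common haplotypes are the ancestors
    of rare ones — and pairwise Hamming distance equals the mutation-count
    path length on the tree.  Branches with zero mutations merge parent and
    child into one haplotype, so the number of unique haplotypes is
    slightly below the number of matrilineages.
    """
    config.validate()
    M = config.n_matrilineages
    reference = _random_reference(config.reference_length, rng)

    # random recursive tree: node m attaches below a uniform earlier node
    parent = [-1] + [int(rng.integers(m)) for m in range(1, M)]

    used: set[int] = set()
    node_mutations: dict[int, tuple[Variant, ...]] = {}
    for node in range(M):
        mean = config.root_mutation_mean if node == 0 else config.branch_mutation_mean
        k = int(rng.poisson(mean))
        muts = tuple(_draw_mutation(reference, used, rng, config) for _ in range(k))
        if muts:
            node_mutations[node] = muts

    # haplotype per matrilineage: union of mutations on the root path
    haplotypes: list[frozenset[Variant]] = []
    for node in range(M):
        acc: set[Variant] = set(node_mutations.get(node, ()))
        if node > 0:
            acc.update(haplotypes[parent[node]])
        haplotypes.append(frozenset(acc))
    leaf_nodes = list(range(M))

    # matrilineage sizes: geometric (long tail), adjusted to sum exactly
    mean_size = config.n_individuals / M
    p = min(1.0, 1.0 / mean_size)
    sizes = rng.geometric(p, size=M).astype(int)
    while sizes.sum() > config.n_individuals:
        k = int(rng.integers(M))
        if sizes[k] > 1:
            sizes[k] -= 1
    while sizes.sum() < config.n_individuals:
        sizes[int(rng.integers(M))] += 1

    width = len(str(config.n_individuals))
    matrilineage_of: dict[str, int] = {}
    representative_of: dict[str, str] = {}
    ind = 0
    for m in range(M):
        rep = None
        for _ in range(int(sizes[m])):
            ind += 1
            name = f"I{ind:0{width}d}"
            matrilineage_of[name] = m
            if rep is None:
                rep = name
            representative_of[name] = rep

    return SimulationTruth(
        config=config,
        reference=reference,
        parent=parent,
        leaf_nodes=leaf_nodes,
        node_mutations=node_mutations,
        haplotype_of_matrilineage=haplotypes,
        matrilineage_of=matrilineage_of,
        representative_of=representative_of,
    )


# ---------------------------------------------------------------------------
# Sequence emission
# ---------------------------------------------------------------------------

def build_alignment(truth: SimulationTruth) -> AlignmentMatrix:
    """Aligned rows (reference + one representative per matrilineage)."""
    reference = truth.reference
    L = len(reference)
    reps = sorted(set(truth.representative_of.values()))
    hap_of_rep = {
        r: truth.haplotype_of_matrilineage[truth.matrilineage_of[r]] for r in reps
    }

    insertions = sorted(
        {v for hap in hap_of_rep.values() for v in hap if v.kind == INSERTION},
        key=lambda v: v.start,
    )
    ins_cols = {v.start: len(v.alt_allele) for v in insertions}

    ref_cells = [reference[p - 1] for p in range(1, L + 1)]
    ref_gap_cells = {p: "-" * w for p, w in ins_cols.items()}

    def render(hap: frozenset[Variant]) -> str:
        cells = list(ref_cells)
        gaps = dict(ref_gap_cells)
        for v in hap:
            if v.kind == SNV:
                cells[v.start - 1] = v.alt_allele
            elif v.kind == DELETION:
                for p in range(v.start, v.end + 1):
                    cells[p - 1] = "-"
            else:
                gaps[v.start] = v.alt_allele
        out = []
        for p in range(1, L + 1):
            out.append(cells[p - 1])
            if p in ins_cols:
                out.append(gaps[p])
        return "".join(out)

    ref_row_parts = []
    for p in range(1, L + 1):
        ref_row_parts.append(reference[p - 1])
        if p in ins_cols:
            ref_row_parts.append("-" * ins_cols[p])
    ref_row = "".join(ref_row_parts)

    ids = [REFERENCE_ID] + reps
    rows = [ref_row] + [render(hap_of_rep[r]) for r in reps]
    col_pos, col_ins = _build_coordinate_map(ref_row)
    return AlignmentMatrix(ids, rows, REFERENCE_ID, col_pos, col_ins)


def emit_sequences(truth: SimulationTruth, fasta_path: str | Path,
                   matrilineage_path: str | Path) -> None:
    """Write the aligned multi-FASTA and the matrilineage map TSV."""
    write_alignment(build_alignment(truth), fasta_path)
    pd.DataFrame(
        {
            "individual": sorted(truth.representative_of),
            "representative": [truth.representative_of[i]
                               for i in sorted(truth.representative_of)],
        }
    ).to_csv(matrilineage_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(truth: SimulationTruth,
                      rng: np.random.Generator) -> Pedigree:
    """Pedigree whose maternal lines realise the matrilineage assignment.

    Members of each matrilineage coalesce backwards through unobserved
    ancestral females (random sibship sizes); every sibship shares one
    unobserved founder father, so cross-matrilineage kinship is zero.
    Emitted rows are ordered ancestors-first (parents precede children).
    """
    cfg = truth.config
    lo, hi = cfg.age_range
    cohort = sorted(truth.matrilineage_of)
    ages = {i: float(np.round(rng.uniform(lo, hi), 1)) for i in cohort}
    sexes = {i: int(rng.random() < cfg.p_male) for i in cohort}
    truth.ages.update(ages)
    truth.sexes.update(sexes)

    members: list[PedigreeMember] = []
    anc_i = 0
    fa_i = 0
    by_lineage: dict[int, list[str]] = {}
    for ind, m in truth.matrilineage_of.items():
        by_lineage.setdefault(m, []).append(ind)

    for m in sorted(by_lineage):
        gen_members = sorted(by_lineage[m])
        if len(gen_members) == 1:
            ind = gen_members[0]
            members.append(PedigreeMember(
                ind, None, None, MALE_F(sexes[ind]), ages[ind]))
            continue
        # coalesce lineages backwards; record mother links level by level
        lineages: list[str] = list(gen_members)
        mother_of: dict[str, str] = {}
        levels: list[list[str]] = []  # ancestral females per generation back
        generation = 1
        while len(lineages) > 1:
            order = list(rng.permutation(len(lineages)))
            merged: list[str] = []
            level: list[str] = []
            pos = 0
            while pos < len(order):
                k = int(rng.choice(cfg.sibship_sizes))
                group = [lineages[j] for j in order[pos : pos + k]]
                pos += k
                if len(group) == 1:
                    merged.append(group[0])
                    continue
                anc_i += 1
                mother = f"A{anc_i:05d}"
                level.append(mother)
                for child in group:
                    mother_of[child] = mother
                merged.append(mother)
            lineages = merged
            if level:
                levels.append(level)
            generation += 1

        # fathers: one unobserved founder per sibship (full siblings)
        father_of_mother: dict[str, str] = {}

        def father_for(child: str) -> str:
            nonlocal fa_i
            mother = mother_of[child]
            if mother not in father_of_mother:
                fa_i += 1
                father_of_mother[mother] = f"P{fa_i:05d}"
            return father_of_mother[mother]

        base_age = max(ages[i] for i in gen_members)
        lineage_rows: list[PedigreeMember] = []
        # ancestors first, deepest generation first
        for depth in range(len(levels), 0, -1):
            for female in levels[depth - 1]:
                fa = father_for(female) if female in mother_of else None
                mo = mother_of.get(female)
                lineage_rows.append(PedigreeMember(
                    female, fa, mo, "F", base_age + 25.0 * depth))
        for ind in gen_members:
            lineage_rows.append(PedigreeMember(
                ind, father_for(ind), mother_of[ind],
                MALE_F(sexes[ind]), ages[ind]))
        father_members = [
            PedigreeMember(f, None, None, "M", None)
            for f in sorted(set(father_of_mother.values()))
        ]
        members.extend(father_members + lineage_rows)  # founders precede children

    # global ordering: founders and ancestors already precede children within
    # each lineage block; re-sort topologically for a clean emitted order
    ped = Pedigree(members)
    topo = ped._topological_order()
    by_id = {mm.id: mm for mm in members}
    return Pedigree([by_id[i] for i in topo])


def MALE_F(sex01: int) -> str:
    return "M" if sex01 else "F"


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _clade_individuals(truth: SimulationTruth, node: int) -> list[str]:
    """Cohort members whose matrilineage lies in the subtree under a node."""
    children: dict[int, list[int]] = {}
    for c, p in enumerate(truth.parent):
        if p >= 0:
            children.setdefault(p, []).append(c)
    stack, subtree = [node], set()
    while stack:
        n = stack.pop()
        subtree.add(n)
        stack.extend(children.get(n, []))
    lineage_idx = {truth.leaf_nodes[m]: m for m in range(len(truth.leaf_nodes))}
    target_lineages = {lineage_idx[n] for n in subtree if n in lineage_idx}
    return sorted(i for i, m in truth.matrilineage_of.items()
                  if m in target_lineages)


def select_target_clade(truth: SimulationTruth) -> tuple[int | None, list[str]]:
    """Pick the genealogy node whose clade size (individuals) best matches
    the configured range; the node's branch must carry >= 1 mutation so the
    clade is cleanly defined in the haplotype network."""
    lo, hi = truth.config.clade_size_range
    target_mid = (lo + hi) / 2
    best: tuple[float, int] | None = None
    for node in range(1, len(truth.parent)):
        if not truth.node_mutations.get(node):
            continue
        size = len(_clade_individuals(truth, node))
        if size < lo or size > hi:
            continue
        score = abs(size - target_mid)
        if best is None or (score, node) < best:
            best = (score, node)
    if best is None:
        return None, []
    node = best[1]
    return node, _clade_individuals(truth, node)


def simulate_phenotypes(truth: SimulationTruth, ped: Pedigree,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw phenotypes under the additive model with kinship-structured noise."""
    cfg = truth.config
    cohort = sorted(truth.matrilineage_of)
    n = len(cohort)

    kin = kinship_matrix(ped).subset(cohort)
    K2 = 2.0 * cfg.sigma2_g * kin.values
    if cfg.sigma2_g > 0:
        try:
            L = np.linalg.cholesky(K2 + 1e-10 * np.eye(n))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ParameterError("kinship covariance not positive definite") from exc
        g = L @ rng.standard_normal(n)
    else:
        g = np.zeros(n)

    node, clade_members = select_target_clade(truth)
    truth.target_node = node
    truth.target_individuals = tuple(clade_members)
    if node is not None:
        truth.target_variants = truth.node_mutations.get(node, ())
    clade = np.array([i in set(clade_members) for i in cohort], dtype=float)

    ages = np.array([truth.ages[i] for i in cohort])
    sexes = np.array([truth.sexes[i] for i in cohort], dtype=float)
    eps = np.sqrt(cfg.sigma2_e) * rng.standard_normal(n)
    y = (cfg.mu + cfg.beta_age * ages + cfg.beta_sex * sexes
         + cfg.gamma_clade * clade + g + eps)
    # copy number is a positive ratio: resample residuals that push it below
    # the floor (a cheap truncation that keeps the mean essentially intact)
    for _ in range(100):
        low = y < cfg.copy_number_floor
        if not low.any():
            break
        eps_new = np.sqrt(cfg.sigma2_e) * rng.standard_normal(int(low.sum()))
        y[low] = (cfg.mu + cfg.beta_age * ages[low] + cfg.beta_sex * sexes[low]
                  + cfg.gamma_clade * clade[low] + g[low] + eps_new)
    y = np.maximum(y, cfg.copy_number_floor)

    missing = np.zeros(n, dtype=bool)
    n_missing = int(round(cfg.missing_fraction * n))
    if n_missing:
        missing[rng.choice(n, size=n_missing, replace=False)] = True

    truth.g.update(dict(zip(cohort, g)))
    y_out = y.copy()
    y_out[missing] = np.nan
    truth.phenotype.update(dict(zip(cohort, y_out)))

    return pd.DataFrame(
        {
            "individual": cohort,
            "copy_number": y_out,
            "age": ages,
            "sex": sexes.astype(int),
        }
    ).set_index("individual")


# ---------------------------------------------------------------------------
# Cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    truth: SimulationTruth
    pedigree: Pedigree
    phenotypes: pd.DataFrame   # index individual; copy_number, age, sex

    def haplotype_table(self) -> HaplotypeTable:
        return self.truth.haplotype_table()

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the pipeline's four input files plus the truth record."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "alignment.fasta",
            "matrilineage": outdir / "matrilineage.tsv",
            "pedigree": outdir / "pedigree.tsv",
            "phenotype": outdir / "phenotype.tsv",
            "truth": outdir / "truth.json",
        }
        emit_sequences(self.truth, paths["fasta"], paths["matrilineage"])
        write_pedigree(self.pedigree, paths["pedigree"])
        self.phenotypes[["copy_number"]].rename_axis("individual").reset_index() \
            .to_csv(paths["phenotype"], sep="\t", index=False, float_format="%.6f")
        with open(paths["truth"], "w") as fh:
            json.dump(self._truth_json(), fh, indent=1, sort_keys=True)
        return paths

    def _truth_json(self) -> dict:
        t = self.truth
        return {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(t.config).items()},
            "n_haplotypes": t.haplotype_table().n_haplotypes,
            "target_node": t.target_node,
            "target_individuals": list(t.target_individuals),
            "target_variants": [v.label for v in t.target_variants],
            "clade_effect": t.config.gamma_clade,
            "beta_age": t.config.beta_age,
            "beta_sex": t.config.beta_sex,
            "haplotype_of_individual": {
                i: sorted(v.label for v in
                          t.haplotype_of_matrilineage[t.matrilineage_of[i]])
                for i in sorted(t.matrilineage_of)
            },
        }


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """End-to-end generation: genealogy, pedigree, phenotypes, truth record."""
    config = config or SimulationConfig()
    if seed is not None:
        config.seed = seed
    ss = np.random.SeedSequence(config.seed)
    rng_gene, rng_ped, rng_phen = (np.random.default_rng(s) for s in ss.spawn(3))
    truth = simulate_genealogy(config, rng_gene)
    ped = simulate_pedigree(truth, rng_ped)
    pheno = simulate_phenotypes(truth, ped, rng_phen)
    return SyntheticCohort(truth, ped, pheno)
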
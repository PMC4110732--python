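"""Association engine: partial-F statistic, Freedman-Lane permutations,
step-down correction, conditioning, and the conditional second round."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import cohort_phenotypes
from mitotreescan.errors import (
    ConsistencyError,
    DegenerateInputError,
    ParameterError,
)
from mitotreescan.hapnet import build_network, enumerate_branches, enumerate_loop_resolutions
from mitotreescan.mtvar import SNV, Haplotype, HaplotypeTable, Variant
from mitotreescan.synthdata import SimulationConfig, simulate_cohort
from mitotreescan.treescan import (
    PhenotypeTable,
    allele_vectors,
    branch_statistic,
    filter_testable,
    permutation_scan,
    scan,
    stepdown_correction,
)


def var(pos: int) -> Variant:
    return Variant(SNV, pos, pos, "A", "G")


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------

def test_constant_phenotype_gives_zero_statistic():
    y = np.full(20, 3.0)
    allele = np.r_[np.zeros(10), np.ones(10)]
    assert branch_statistic(y, None, allele) == pytest.approx(0.0)


def test_no_covariate_partial_f_equals_squared_t():
    rng = np.random.default_rng(1)
    y = rng.normal(size=24)
    allele = np.r_[np.zeros(11), np.ones(13)]
    t, _ = stats.ttest_ind(y[allele == 1], y[allele == 0], equal_var=True)
    assert branch_statistic(y, None, allele) == pytest.approx(t**2)


def test_partial_f_matches_normal_equations_oracle():
    """Independent oracle: residual sums of squares from explicit least-squares
    fits of the reduced and full models."""
    rng = np.random.default_rng(2)
    n = 30
    cov = rng.normal(size=(n, 3))
    allele = (rng.random(n) < 0.4).astype(float)
    y = rng.normal(size=n) + 0.5 * allele + cov @ [0.3, -0.2, 0.1]

    X_r = np.column_stack([np.ones(n), cov])
    X_f = np.column_stack([X_r, allele])
    sse = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
    df = n - X_f.shape[1]
    f_oracle = (sse(X_r) - sse(X_f)) / (sse(X_f) / df)
    assert branch_statistic(y, cov, allele) == pytest.approx(f_oracle)


def test_statistic_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        branch_statistic(np.ones(10), None, np.zeros(10))
    with pytest.raises(ConsistencyError):
        # duplicated covariate column -> rank deficient
        cov = np.ones((12, 2))
        branch_statistic(np.arange(12.0), cov, np.r_[np.zeros(6), np.ones(6)])


# ---------------------------------------------------------------------------
# testability filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n1,n0,kept", [(5, 5, True), (4, 1000, False),
                                        (0, 10, False), (6, 7, True)])
def test_min_class_filter(n1, n0, kept):
    alleles = np.r_[np.ones(n1), np.zeros(n0)][:, None]
    mask = filter_testable([None], alleles, min_class=5)
    assert bool(mask[0]) is kept


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

def test_constant_phenotype_gives_p_one():
    y = np.full(20, 2.5)
    alleles = np.r_[np.zeros(10), np.ones(10)][:, None]
    ps = permutation_scan(y, None, alleles, n_perm=99,
                          rng=np.random.default_rng(0))
    assert ps.nominal_p[0] == 1.0


def test_monte_carlo_p_matches_exhaustive_enumeration():
    """n = 10, one branch with a 5/5 split: the Monte-Carlo nominal p must sit
    within 3 binomial standard errors of the exact permutation p obtained by
    enumerating all C(10, 5) = 252 distinct group assignments."""
    rng = np.random.default_rng(3)
    y = rng.normal(size=10)
    y[5:] += 1.0
    allele = np.r_[np.zeros(5), np.ones(5)]

    def group_f(idx_set):
        a = np.zeros(10)
        a[list(idx_set)] = 1.0
        return branch_statistic(y, None, a)

    f_obs = group_f(range(5, 10))
    stats_all = [group_f(c) for c in itertools.combinations(range(10), 5)]
    p_exact = np.mean([s >= f_obs - 1e-12 for s in stats_all])

    n_perm = 4000
    ps = permutation_scan(y, None, allele[:, None], n_perm=n_perm,
                          rng=np.random.default_rng(4))
    se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
    assert abs(ps.nominal_p[0] - p_exact) <= 3 * se + 1 / (n_perm + 1)


def test_permutation_p_range_and_determinism():
    rng_y = np.random.default_rng(8)
    y = rng_y.normal(size=40)
    cov = rng_y.normal(size=(40, 2))
    alleles = (rng_y.random((40, 6)) < 0.5).astype(float)
    kw = dict(n_perm=200)
    ps1 = permutation_scan(y, cov, alleles, rng=np.random.default_rng(9), **kw)
    ps2 = permutation_scan(y, cov, alleles, rng=np.random.default_rng(9), **kw)
    assert np.array_equal(ps1.null_matrix, ps2.null_matrix)
    assert np.array_equal(ps1.nominal_p, ps2.nominal_p)
    assert (ps1.nominal_p >= 1 / 201).all() and (ps1.nominal_p <= 1).all()
    with pytest.raises(ParameterError):
        permutation_scan(y, cov, alleles, n_perm=0, rng=np.random.default_rng(0))


# ---------------------------------------------------------------------------
# step-down correction
# ---------------------------------------------------------------------------

def stepdown_oracle(t_obs, null):
    """Loop-based reimplementation of the step-down maxT procedure."""
    B, P = null.shape
    order = np.argsort(-t_obs, kind="stable")
    out = np.empty(B)
    prev = 0.0
    for r, b in enumerate(order):
        tail = null[order[r:], :].max(axis=0)
        p = (1 + np.sum(tail >= t_obs[b])) / (P + 1)
        prev = max(prev, p)
        out[b] = prev
    return out


def test_single_branch_corrected_equals_nominal():
    rng = np.random.default_rng(10)
    t = np.array([4.2])
    null = rng.chisquare(1, size=(1, 500))
    nominal = (1 + (null[0] >= t[0]).sum()) / 501
    assert stepdown_correction(t, null)[0] == pytest.approx(nominal)


def test_duplicated_branches_pay_no_multiplicity_penalty():
    rng = np.random.default_rng(11)
    row = rng.chisquare(1, size=300)
    null = np.vstack([row, row])
    t = np.array([3.3, 3.3])
    corrected = stepdown_correction(t, null)
    nominal = (1 + (row >= 3.3).sum()) / 301
    assert np.allclose(corrected, nominal)


def test_stepdown_matches_loop_oracle_and_bounds():
    rng = np.random.default_rng(12)
    B, P = 15, 400
    null = rng.chisquare(1, size=(B, P))
    t_obs = rng.chisquare(1, size=B) * 2
    corrected = stepdown_correction(t_obs, null)
    assert np.allclose(corrected, stepdown_oracle(t_obs, null))
    nominal = (1 + (null >= t_obs[:, None]).sum(axis=1)) / (P + 1)
    assert (corrected >= nominal - 1e-12).all()
    # union (Bonferroni-style) upper bound computed directly from the null
    union = (1 + (null >= t_obs[:, None]).sum(axis=1).sum()
             ) * np.ones(B)  # loosest possible count
    for b in range(B):
        count_union = (null.max(axis=0) >= t_obs[b]).sum()
        assert corrected[b] <= (1 + count_union) / (P + 1) + 1e-12
    order = np.argsort(-t_obs)
    assert (np.diff(corrected[order]) >= -1e-12).all()
    with pytest.raises(ConsistencyError):
        stepdown_correction(t_obs, null[:-1])


# ---------------------------------------------------------------------------
# full scan behavior
# ---------------------------------------------------------------------------

def test_scan_is_deterministic_given_seed(small_cohort, small_cohort_pheno):
    table = small_cohort.haplotype_table()
    r1 = scan(table, small_cohort_pheno, n_perm=100, seed=5)
    r2 = scan(table, small_cohort_pheno, n_perm=100, seed=5)
    pd.testing.assert_frame_equal(r1.table, r2.table)
    pd.testing.assert_frame_equal(r1.summary, r2.summary)


def test_scan_detects_shifted_clade_and_conditioning_removes_it():
    """A 12-member haplotype shifted by ~1.3 residual SDs is flagged, and the
    conditioning re-scan annihilates its own signal (the indicator becomes
    collinear with the covariates, so its conditional F is exactly 0)."""
    table = path_table([30, 20, 20, 12])
    rng = np.random.default_rng(21)
    pheno = path_phenotypes(
        table, {"H001": 2.7, "H002": 2.7, "H003": 2.7, "H004": 3.9}, rng)
    res = scan(table, pheno, n_perm=400, seed=5, do_round2=False)
    row = res.summary[res.summary.signature == "H004"]
    assert len(row) == 1 and bool(row.significant.iloc[0])
    assert row.mean_a.iloc[0] - row.mean_b.iloc[0] > 0.5
    cond = res.table.query("round == '1-cond'")
    own = cond[(cond.signature == "H004") & (cond.conditioned_on == "H004")]
    assert len(own) == 1
    assert own.F.iloc[0] == pytest.approx(0.0)
    assert own.nominal_p.iloc[0] == 1.0


def test_scan_reports_true_clade_contrast_on_synthetic_cohort(
        small_cohort, small_cohort_pheno):
    """The generator's target clade appears as a testable branch whose group
    means reflect the injected (positive) shift."""
    cohort = small_cohort
    table = cohort.haplotype_table()
    res = scan(table, small_cohort_pheno, n_perm=100, seed=5,
               do_round2=False, do_conditioning=False)
    mem = table.membership()
    sig = ";".join(sorted(frozenset(mem[i] for i in cohort.truth.target_individuals)))
    row = res.summary[res.summary.signature == sig]
    assert len(row) == 1 and bool(row.testable.iloc[0])
    assert row.mean_a.iloc[0] > row.mean_b.iloc[0]


def test_missing_phenotypes_counted_in_membership_not_in_tests(
        small_cohort, small_cohort_pheno):
    res = scan(small_cohort.haplotype_table(), small_cohort_pheno,
               n_perm=50, seed=1, do_round2=False, do_conditioning=False)
    r1 = res.table.query("round == '1'")
    assert (r1.n_a + r1.missing_a == r1.n_a_members).all()
    assert (r1.n_b + r1.missing_b == r1.n_b_members).all()
    n_missing = int(small_cohort.phenotypes.copy_number.isna().sum())
    assert (r1.n_a_members + r1.n_b_members == res.n_individuals).all()
    assert res.n_complete == res.n_individuals - n_missing


# ---------------------------------------------------------------------------
# round 2
# ---------------------------------------------------------------------------

def path_table(sizes: list[int]) -> HaplotypeTable:
    """Haplotypes on a path H1 - H2 - ... with given member counts."""
    haps = []
    acc: set[Variant] = set()
    for k, size in enumerate(sizes, start=1):
        haps.append(Haplotype(
            f"H{k:03d}", frozenset(acc),
            tuple(f"I{k}_{j}" for j in range(size)), ()))
        acc.add(var(k))
    return HaplotypeTable(haps)


def path_phenotypes(table: HaplotypeTable, means: dict[str, float],
                    rng: np.random.Generator) -> PhenotypeTable:
    rows = []
    for h in table.haplotypes:
        for ind in h.members:
            rows.append({
                "individual": ind,
                "copy_number": means[h.haplotype_id] + 0.5 * rng.standard_normal(),
                "age": float(rng.uniform(65, 95)),
                "sex": int(rng.random() < 0.5),
                "fas": float(rng.normal(0, 0.01)),
            })
    return PhenotypeTable(pd.DataFrame(rows).set_index("individual"))


def test_round2_finds_nested_heterogeneity():
    """A clade of three haplotypes is shifted upward; within it, one sub-clade
    is shifted further.  Round 2, conditioned on the significant parent
    branch, should rank the sub-clade's defining branch first in most
    replicates."""
    table = path_table([30, 10, 10, 10])  # H001 background; H002-4 the clade
    hits = 0
    n_rep = 60
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        pheno = path_phenotypes(
            table, {"H001": 2.7, "H002": 3.6, "H003": 3.6, "H004": 5.2}, rng)
        res = scan(table, pheno, n_perm=150, seed=rep, do_conditioning=False)
        r2 = res.table.query("round == '2' and testable")
        if not len(r2):
            continue
        best = r2.loc[r2.F.idxmax()]
        if best.signature == "H004":
            hits += 1
    assert hits >= 0.8 * n_rep


def test_round2_null_p_values_are_roughly_uniform():
    """When the sub-classes share the same phenotype distribution, the round-2
    nominal p of a fixed sub-branch is approximately uniform across
    replicates."""
    table = path_table([30, 10, 10, 10])
    pvals = []
    for rep in range(150):
        rng = np.random.default_rng(5000 + rep)
        pheno = path_phenotypes(
            table, {"H001": 2.7, "H002": 3.8, "H003": 3.8, "H004": 3.8}, rng)
        res = scan(table, pheno, n_perm=99, seed=rep, do_conditioning=False,
                   alpha=0.2)
        r2 = res.table.query("round == '2' and testable and signature == 'H004'")
        if len(r2):
            pvals.append(float(r2.nominal_p.iloc[0]))
    assert len(pvals) >= 50
    pvals = np.asarray(pvals)
    se = np.sqrt(1 / 12 / len(pvals))
    assert abs(pvals.mean() - 0.5) < 4 * se + 0.02
    assert (pvals < 0.05).mean() < 0.12


def test_round2_small_subclass_reported_untestable():
    table = path_table([30, 12, 3, 30])
    rng = np.random.default_rng(77)
    pheno = path_phenotypes(
        table, {"H001": 2.7, "H002": 4.0, "H003": 4.0, "H004": 2.7}, rng)
    res = scan(table, pheno, n_perm=200, seed=3, do_conditioning=False)
    r2 = res.table.query("round == '2'")
    if len(r2):
        small = r2[r2.signature == "H003"]
        assert (~small.testable.astype(bool)).all()
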
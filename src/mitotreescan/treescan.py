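"""Branch-wise association scanning of a haplotype network.

Every branch of the haplotype network bipartitions the haplotypes into
two allelic classes; the null hypothesis is that the phenotype does not
differ in distribution between the classes.  For a continuous phenotype
adjusted for covariates (age, sex, familial adjustment score) the test
statistic is the partial F for adding the branch's 0/1 allele indicator
to the covariate-only linear model (1 numerator degree of freedom).

Inference is by permutation under the Freedman-Lane scheme: the model
with the fixed covariates is fitted once, its residuals are permuted and
the fitted values added back, and all branch statistics are recomputed
on each permuted response.  The familial adjustment score is not a fixed
covariate — it is a function of the phenotype (relatives' copy numbers in
the numerator, the focal individual's own in the denominator) — so when a
kinship matrix is supplied the score is recomputed for every permuted
response before the statistic is evaluated.  Holding it fixed instead
makes clade-mates' residuals positively correlated with each other
through the score and grossly inflates the family-wise error rate.
Because every branch is evaluated on the same permutations, the joint
null distribution preserves the correlation between branches, which the
step-down maxT correction (a permutation analogue of the sequential
step-down Bonferroni) exploits for family-wise error control.  Only
branches whose two classes each contain at least ``min_class`` (default
5) individuals with complete data are tested.  Significance means
corrected p < alpha (default 0.05).

If a branch is significant, a second, conditional round looks for
phenotypic heterogeneity inside its allelic classes: each branch nested
strictly within one class subdivides that class into two sub-alleles (a
three-allele system), and permutations shuffle residuals only within
the subdivided class while the other class is held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DegenerateInputError, ParameterError
from .hapnet import (
    Branch,
    HaplotypeNetwork,
    SpanningTree,
    build_network,
    enumerate_branches,
    enumerate_loop_resolutions,
)
from .kinship import KinshipMatrix
from .mtvar import HaplotypeTable

ALPHA_DEFAULT = 0.05
MIN_CLASS_DEFAULT = 5


@dataclass
class PhenotypeTable:
    """Per-individual phenotype and covariates, indexed by individual id.

    Columns: copy_number, age, sex, and optionally fas.  When a kinship
    matrix is passed to :func:`scan`, the familial adjustment score is
    derived from the phenotype internally (and recomputed per permutation)
    and any fas column here is ignored for testing.  Individuals with a
    missing value in any used column are excluded from testing (listwise)
    but still counted in network membership bookkeeping.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("copy_number", "age", "sex")
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ConsistencyError(f"phenotype table lacks columns {missing}")
        floats = [c for c in ("copy_number", "age", "sex", "fas")
                  if c in self.data.columns]
        self.data = self.data.astype({c: float for c in floats})

    def used_columns(self, with_fas: bool) -> list[str]:
        cols = ["copy_number", "age", "sex"]
        if with_fas:
            if "fas" not in self.data.columns:
                raise ConsistencyError("phenotype table lacks a fas column")
            cols.append("fas")
        return cols

    def complete_ids(self, with_fas: bool = True) -> pd.Index:
        cols = self.used_columns(with_fas and "fas" in self.data.columns)
        return self.data.index[self.data[cols].notna().all(axis=1)]

    def response(self, ids, log_transform: bool = False) -> pd.Series:
        y = self.data.loc[ids, "copy_number"]
        return np.log(y) if log_transform else y


# ---------------------------------------------------------------------------
# Linear-model machinery
# ---------------------------------------------------------------------------

def _design(covariates: np.ndarray) -> np.ndarray:
    n = covariates.shape[0]
    return np.column_stack([np.ones(n), covariates])


def _qr_basis(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis of the column space of X; raises on rank deficiency."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    rank = int((diag > 1e-10 * max(1.0, diag.max())).sum())
    if rank < X.shape[1]:
        raise ConsistencyError(
            f"covariate matrix is rank deficient (rank {rank} < {X.shape[1]})")
    return Q, rank


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


def branch_statistic(y: np.ndarray, covariates: np.ndarray | None,
                     allele: np.ndarray) -> float:
    """Partial F for adding the allele indicator to the covariate model."""
    y = np.asarray(y, dtype=float)
    allele = np.asarray(allele, dtype=float)
    n = y.shape[0]
    if len(np.unique(allele)) < 2:
        raise DegenerateInputError("allele vector has a single class")
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    X = _design(cov)
    Q, rank = _qr_basis(X)
    e = _residualize(y[:, None], Q)
    a = _residualize(allele[:, None], Q)
    df = n - rank - 1
    if df < 1:
        raise DegenerateInputError(f"no residual degrees of freedom (n={n})")
    return float(_partial_f(a, e, df)[0, 0])


def _partial_f(A: np.ndarray, E: np.ndarray, df: int) -> np.ndarray:
    """F matrix (branches x responses) from residualized alleles/responses.

    ``A`` is n x B (alleles residualized on covariates), ``E`` is n x P
    (responses residualized on covariates).  Alleles that lie in the
    covariate span (zero residual norm) get F = 0.
    """
    sxx = np.einsum("ij,ij->j", A, A)
    degenerate = sxx <= 1e-12
    sxx_safe = np.where(degenerate, 1.0, sxx)
    C = A.T @ E                                  # B x P
    ss_model = (C * C) / sxx_safe[:, None]
    ss_total = np.einsum("ij,ij->j", E, E)       # P
    ss_resid = np.maximum(ss_total[None, :] - ss_model, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss_model / np.maximum(ss_resid / df, 1e-300)
    F[degenerate, :] = 0.0
    F[:, ss_total <= 1e-20] = 0.0  # constant response: nothing to explain
    return F


# ---------------------------------------------------------------------------
# Permutations
# ---------------------------------------------------------------------------

def _permutation_indices(n: int, n_perm: int, rng: np.random.Generator,
                         blocks: np.ndarray | None = None) -> np.ndarray:
    """n x n_perm matrix of permuted row indices (within blocks if given)."""
    idx = np.empty((n, n_perm), dtype=np.intp)
    base = np.arange(n)
    if blocks is None:
        for p in range(n_perm):
            idx[:, p] = rng.permutation(n)
        return idx
    blocks = np.asarray(blocks)
    groups = [np.flatnonzero(blocks == b) for b in np.unique(blocks)]
    for p in range(n_perm):
        col = base.copy()
        for g in groups:
            col[g] = g[rng.permutation(len(g))]
        idx[:, p] = col
    return idx


@dataclass
class PermutationScan:
    """Observed statistics, the full null matrix, and nominal p-values."""

    t_obs: np.ndarray          # (B,)
    null_matrix: np.ndarray    # (B, n_perm)
    nominal_p: np.ndarray      # (B,)
    n_perm: int


def permutation_scan(
    y: np.ndarray,
    covariates: np.ndarray | None,
    alleles: np.ndarray,
    n_perm: int,
    rng: np.random.Generator | None = None,
    blocks: np.ndarray | None = None,
    perm_chunk: int = 2000,
    perm_indices: np.ndarray | None = None,
) -> PermutationScan:
    """Freedman-Lane permutation scan over all branches at once.

    ``alleles`` is n x B.  The same permutations are applied to every
    branch, so the returned null matrix retains inter-branch correlation
    for the step-down correction.  ``blocks`` restricts permutation to
    within-block shuffles (used by the conditional second round).  A
    pre-built ``perm_indices`` (n x n_perm) schedule may be supplied to
    share permutations across several scans.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    if perm_indices is None and rng is None:
        raise ParameterError("either rng or perm_indices is required")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    alleles = np.asarray(alleles, dtype=float)
    if alleles.ndim == 1:
        alleles = alleles[:, None]
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    X = _design(cov)
    Q, rank = _qr_basis(X)
    df = n - rank - 1
    if df < 1:
        raise DegenerateInputError(f"no residual degrees of freedom (n={n})")
    e = _residualize(y[:, None], Q)[:, 0]
    A = _residualize(alleles, Q)
    t_obs = _partial_f(A, e[:, None], df)[:, 0]

    B = alleles.shape[1]
    null = np.empty((B, n_perm))
    done = 0
    while done < n_perm:
        k = min(perm_chunk, n_perm - done)
        if perm_indices is not None:
            idx = perm_indices[:, done : done + k]
        else:
            idx = _permutation_indices(n, k, rng, blocks)
        E = _residualize(e[idx], Q)
        null[:, done : done + k] = _partial_f(A, E, df)
        done += k
    nominal = (1 + (null >= t_obs[:, None]).sum(axis=1)) / (n_perm + 1)
    return PermutationScan(t_obs, null, nominal, n_perm)


def _fas_stats(Y: np.ndarray, Q: np.ndarray, A: np.ndarray, aa: np.ndarray,
               K0: np.ndarray, df: int, denom_floor: float) -> np.ndarray:
    """Partial F of each allele given fixed covariates plus the familial
    adjustment score *derived from each response column*.

    ``Y`` is n x k raw (unresidualized) responses; the score for column v is
    FAS_i(v) = sum_j K0[i, j] v_j / (n * v_i), with the denominator floored
    for numerical safety.  Everything is evaluated in the space orthogonal
    to the fixed covariates (basis ``Q``); ``A``/``aa`` are the residualized
    alleles and their squared norms.
    """
    n = Y.shape[0]
    denom = np.clip(Y, denom_floor, None)
    Fas = (K0 @ Y) / (n * denom)
    Yt = _residualize(Y, Q)
    Ft = _residualize(Fas, Q)
    ff = np.einsum("ij,ij->j", Ft, Ft)
    ff = np.maximum(ff, 1e-12)
    fy = np.einsum("ij,ij->j", Ft, Yt)
    yy = np.einsum("ij,ij->j", Yt, Yt)
    AF = A.T @ Ft                                # B x k
    AY = A.T @ Yt
    c = AF / ff
    sxy = AY - c * fy
    sxx = aa[:, None] - AF * AF / ff
    degenerate = sxx <= 1e-12
    sxx = np.where(degenerate, 1.0, sxx)
    ss_model = sxy * sxy / sxx
    ss_resid = np.maximum(yy[None, :] - fy * fy / ff - ss_model, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss_model / np.maximum(ss_resid / df, 1e-300)
    F[degenerate] = 0.0
    F[:, yy <= 1e-20] = 0.0
    return F


def estimate_familial_variance(e: np.ndarray, kin: np.ndarray) -> tuple[float, float]:
    """Contamination-robust method-of-moments variance components.

    Fits E[e_i e_j] = 2 sigma2_g K_ij over related pairs, pooling
    contributions per family cluster (connected component of the kinship
    graph) and discarding clusters whose contribution is a gross outlier
    before re-pooling.  A genuine clade effect on the phenotype is a mean
    shift concentrated in a handful of families; without the rejection
    step it masquerades as familial variance, over-inflates the whitened
    permutation null, and costs power against exactly the effects the scan
    exists to find.  Var[e_i] = 2 sigma2_g K_ii + sigma2_e closes the
    system; both components are clipped at zero.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(e)
    K2 = 2.0 * kin
    d = np.diag(K2)
    off = K2 - np.diag(d)
    adj = csr_matrix(np.abs(off) > 1e-9)
    n_comp, labels = connected_components(adj, directed=False)

    nums = np.zeros(n_comp)
    dens = np.zeros(n_comp)
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            continue
        sub = off[np.ix_(idx, idx)]
        ec = e[idx]
        nums[c] = ec @ sub @ ec
        dens[c] = np.sum(sub * sub)
    use = dens > 1e-12
    if not use.any():
        sg2 = 0.0
    else:
        sg2 = max(float(nums[use].sum() / dens[use].sum()), 0.0)
        # one-step rejection of grossly outlying clusters
        z = (nums[use] - sg2 * dens[use]) / np.sqrt(dens[use])
        scale = 1.4826 * np.median(np.abs(z - np.median(z)))
        if scale > 0:
            keep = np.abs(z - np.median(z)) <= 6 * scale
            if keep.any() and not keep.all():
                nums_u, dens_u = nums[use][keep], dens[use][keep]
                if dens_u.sum() > 1e-12:
                    sg2 = max(float(nums_u.sum() / dens_u.sum()), 0.0)
    total = float(e @ e / n)
    se2 = max(total - sg2 * float(d.mean()), 1e-8 * max(total, 1e-8))
    return sg2, se2


def familial_whitener(e: np.ndarray, kin: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Cholesky colour/whiten pair for kinship-structured residuals.

    Returns (L, w) with Sigma-hat = 2 sg2 K + se2 I = L L' and w = L^-1 e,
    or None when no familial variance is detected (plain exchangeable
    residuals suffice).  Permuting w and re-colouring with L gives permuted
    residuals that carry the same familial correlation as the data, which
    keeps branch tests honest when clades coincide with families.
    """
    sg2, se2 = estimate_familial_variance(e, kin)
    if sg2 <= 0:
        return None
    n = len(e)
    sigma = 2.0 * sg2 * kin + se2 * np.eye(n)
    L = np.linalg.cholesky(sigma)
    w = np.linalg.solve(L, e)  # triangular; n is moderate
    return L, w


def fas_permutation_scan(
    y: np.ndarray,
    fixed_covariates: np.ndarray | None,
    alleles: np.ndarray,
    kinship0: np.ndarray,
    n_perm: int,
    rng: np.random.Generator | None = None,
    blocks: np.ndarray | None = None,
    perm_chunk: int = 2000,
    perm_indices: np.ndarray | None = None,
    denom_floor: float = 0.05,
    kinship_full: np.ndarray | None = None,
) -> PermutationScan:
    """Permutation scan with the familial adjustment score recomputed per
    permutation.

    ``kinship0`` is the kinship matrix over the analysed individuals with a
    zeroed diagonal (self term excluded).  Residuals of the model with the
    *fixed* covariates only are permuted (Freedman-Lane); each reconstructed
    response gets its own score before the partial F of each allele — given
    fixed covariates plus that score — is evaluated.  If ``kinship_full``
    (diagonal intact) is supplied, residuals are whitened by the estimated
    familial covariance before permutation and re-coloured afterwards, so
    the null preserves the within-family correlation that the score alone
    cannot remove.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    if perm_indices is None and rng is None:
        raise ParameterError("either rng or perm_indices is required")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if kinship0.shape != (n, n):
        raise ConsistencyError(
            f"kinship matrix is {kinship0.shape}, expected ({n}, {n})")
    alleles = np.asarray(alleles, dtype=float)
    if alleles.ndim == 1:
        alleles = alleles[:, None]
    cov = np.empty((n, 0)) if fixed_covariates is None \
        else np.asarray(fixed_covariates, float)
    X = _design(cov)
    Q, rank = _qr_basis(X)
    df = n - rank - 2  # fas + allele enter on top of the fixed design
    if df < 1:
        raise DegenerateInputError(f"no residual degrees of freedom (n={n})")
    A = _residualize(alleles, Q)
    aa = np.einsum("ij,ij->j", A, A)
    t_obs = _fas_stats(y[:, None], Q, A, aa, kinship0, df, denom_floor)[:, 0]

    fitted = y - _residualize(y[:, None], Q)[:, 0]
    e = y - fitted
    colour = None
    if kinship_full is not None:
        colour = familial_whitener(e, kinship_full)
    shuffle_src = e if colour is None else colour[1]

    B = alleles.shape[1]
    null = np.empty((B, n_perm))
    done = 0
    while done < n_perm:
        k = min(perm_chunk, n_perm - done)
        if perm_indices is not None:
            idx = perm_indices[:, done : done + k]
        else:
            idx = _permutation_indices(n, k, rng, blocks)
        E = shuffle_src[idx]
        if colour is not None:
            E = colour[0] @ E
        Y = fitted[:, None] + E
        null[:, done : done + k] = _fas_stats(Y, Q, A, aa, kinship0, df,
                                              denom_floor)
        done += k
    nominal = (1 + (null >= t_obs[:, None]).sum(axis=1)) / (n_perm + 1)
    return PermutationScan(t_obs, null, nominal, n_perm)


def stepdown_correction(t_obs: np.ndarray, null_matrix: np.ndarray,
                        standardize: bool = False) -> np.ndarray:
    """Step-down maxT corrected p-values (permutation step-down Bonferroni).

    Branches are ranked by decreasing observed statistic; the statistic of
    rank r is compared to the permutation distribution of the maximum over
    branches of rank >= r, and monotonicity is enforced down the ranking.

    With ``standardize=True`` each branch's statistic (observed and null)
    is first centred and scaled by its own permutation null moments and
    the step-down maximum is taken over the standardized statistics.
    Branch nulls here are heterogeneous — allelic classes that coincide
    with families have inflated nulls once the outcome-derived familial
    adjustment score enters the model — and a common raw-scale threshold
    would hand the whole family-wise budget to the most inflated branches;
    studentizing restores a balanced test at modest permutation counts.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    null_matrix = np.asarray(null_matrix, dtype=float)
    if null_matrix.shape[0] != t_obs.shape[0]:
        raise ConsistencyError(
            f"null matrix has {null_matrix.shape[0]} rows for {t_obs.shape[0]} branches")
    if standardize and t_obs.size:
        P = null_matrix.shape[1]
        mu = null_matrix.mean(axis=1)
        sd = np.maximum(null_matrix.std(axis=1), 1e-12)
        t_std = (t_obs - mu) / sd
        if P > 2:
            # each null column is standardized by the moments of the OTHER
            # columns: the observed statistic never enters its own reference
            # moments, and a null draw must not either, else extreme null
            # columns shrink themselves and the correction turns liberal
            s1 = null_matrix.sum(axis=1, keepdims=True)
            s2 = (null_matrix * null_matrix).sum(axis=1, keepdims=True)
            mu_loo = (s1 - null_matrix) / (P - 1)
            var_loo = (s2 - null_matrix**2) / (P - 1) - mu_loo**2
            sd_loo = np.maximum(np.sqrt(np.maximum(var_loo, 0.0)), 1e-12)
            null_matrix = (null_matrix - mu_loo) / sd_loo
        else:
            null_matrix = (null_matrix - mu[:, None]) / sd[:, None]
        t_obs = t_std
    n_perm = null_matrix.shape[1]
    order = np.argsort(-t_obs, kind="stable")
    succ_max = np.maximum.accumulate(null_matrix[order][::-1], axis=0)[::-1]
    p_sorted = (1 + (succ_max >= t_obs[order][:, None]).sum(axis=1)) / (n_perm + 1)
    p_sorted = np.maximum.accumulate(p_sorted)
    corrected = np.empty_like(p_sorted)
    corrected[order] = p_sorted
    return corrected


# ---------------------------------------------------------------------------
# Branch bookkeeping
# ---------------------------------------------------------------------------

def allele_vectors(branches: Sequence[Branch], membership: dict[str, str],
                   individuals: Sequence[str]) -> np.ndarray:
    """n x B matrix: 1 if the individual's haplotype is in the branch clade."""
    haps = [membership[i] for i in individuals]
    out = np.zeros((len(individuals), len(branches)))
    for b_idx, br in enumerate(branches):
        clade = br.side_a
        out[:, b_idx] = [h in clade for h in haps]
    return out


def filter_testable(branches: Sequence[Branch], alleles: np.ndarray,
                    min_class: int = MIN_CLASS_DEFAULT) -> np.ndarray:
    """Boolean mask over branches: both allelic classes >= min_class complete."""
    n1 = alleles.sum(axis=0)
    n0 = alleles.shape[0] - n1
    return (n1 >= min_class) & (n0 >= min_class)


# ---------------------------------------------------------------------------
# High-level scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-branch tests for every loop resolution, plus the conservative summary."""

    table: pd.DataFrame          # rounds 1, 1-cond and 2, one row per branch test
    summary: pd.DataFrame        # per-bipartition, max corrected p over resolutions
    seed: int
    n_perm: int
    min_class: int
    alpha: float
    n_resolutions: int
    n_complete: int
    n_individuals: int

    def significant(self) -> pd.DataFrame:
        """Round-1 bipartitions significant after the conservative summary."""
        return self.summary[self.summary["significant"]]


def _summarize(round1: pd.DataFrame, n_resolutions: int, alpha: float) -> pd.DataFrame:
    rows = []
    for sig, grp in round1.groupby("signature", sort=True):
        testable = grp["testable"].any()
        corrected = grp.loc[grp["testable"], "corrected_p"]
        corr = float(corrected.max()) if len(corrected) else np.nan
        present_everywhere = grp["resolution_id"].nunique() == n_resolutions
        rows.append({
            "signature": sig,
            "variants": grp["variants"].iloc[0],
            "n_resolutions_present": grp["resolution_id"].nunique(),
            "n_a": int(grp["n_a"].iloc[0]),
            "n_b": int(grp["n_b"].iloc[0]),
            "mean_a": float(grp["mean_a"].iloc[0]),
            "mean_b": float(grp["mean_b"].iloc[0]),
            "corrected_p": corr,
            "testable": bool(testable and grp["testable"].all()),
            # conservative call: must be significant in every resolution
            "significant": bool(testable and present_everywhere
                                and grp["testable"].all()
                                and len(corrected) == n_resolutions
                                and (corrected < alpha).all()),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["corrected_p", "signature"],
                            na_position="last").reset_index(drop=True)
    return df


def scan(
    hap_table: HaplotypeTable,
    pheno: PhenotypeTable,
    n_perm: int = 10000,
    seed: int = 0,
    min_class: int = MIN_CLASS_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    max_resolutions: int = 64,
    log_transform: bool = False,
    do_round2: bool = True,
    do_conditioning: bool = True,
    network: HaplotypeNetwork | None = None,
    kin: KinshipMatrix | None = None,
) -> ScanResult:
    """Full TreeScanning analysis: round 1, conditioning re-scan, round 2.

    If ``kin`` (a kinship matrix covering the phenotyped individuals) is
    supplied, the familial adjustment score is derived from the phenotype
    and recomputed inside every permutation; otherwise the phenotype
    table must carry a precomputed ``fas`` column, which is then treated
    as a fixed covariate.  The same permutation schedule (derived from
    ``seed``) is shared by all loop resolutions so their results are
    comparable; round-2 scans draw fresh, seed-derived schedules.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if network is None:
        network = build_network(hap_table)
    resolutions = enumerate_loop_resolutions(network, max_resolutions)

    membership = hap_table.membership()
    all_ids = sorted(membership)
    pheno_ids = [i for i in all_ids if i in pheno.data.index]
    complete_set = set(pheno.complete_ids(with_fas=kin is None))
    complete = [i for i in pheno_ids if i in complete_set]
    y = pheno.response(complete, log_transform).to_numpy()
    if kin is None:
        base_cov = pheno.data.loc[complete, ["age", "sex", "fas"]].to_numpy()
        K0 = None
    else:
        base_cov = pheno.data.loc[complete, ["age", "sex"]].to_numpy()
        K_full = kin.subset(complete).values.copy()
        K0 = K_full.copy()
        np.fill_diagonal(K0, 0.0)

    def run_perm(alleles_sub, extra_cov=None, blocks=None,
                 perm_indices=None, rng=None):
        cov_full = base_cov if extra_cov is None else \
            np.column_stack([base_cov, extra_cov])
        if K0 is None:
            return permutation_scan(y, cov_full, alleles_sub, n_perm,
                                    rng=rng, blocks=blocks,
                                    perm_indices=perm_indices)
        return fas_permutation_scan(y, cov_full, alleles_sub, K0, n_perm,
                                    rng=rng, blocks=blocks,
                                    perm_indices=perm_indices,
                                    kinship_full=K_full)

    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    rng_round1 = np.random.default_rng(seeds[0])
    rng_round2 = np.random.default_rng(seeds[2])

    # one permutation schedule, shared by every resolution (and by the
    # conditioning re-scans) so results are comparable across resolutions
    n = len(complete)
    perm_idx = _permutation_indices(n, n_perm, rng_round1)

    rows: list[dict] = []
    sig_branches: list[tuple[Branch, np.ndarray]] = []  # deduped by signature
    sig_seen: set[frozenset] = set()

    counts = hap_table.counts()
    total_members = {h: c for h, c in counts.items()}

    for tree in resolutions:
        branches = enumerate_branches(tree)
        alleles = allele_vectors(branches, membership, complete)
        testable = filter_testable(branches, alleles, min_class)
        t_idx = np.flatnonzero(testable)
        if len(t_idx):
            ps = run_perm(alleles[:, t_idx], perm_indices=perm_idx)
            corrected = stepdown_correction(ps.t_obs, ps.null_matrix, standardize=True)
        for k, br in enumerate(branches):
            in_clade = alleles[:, k].astype(bool)
            n_a_total = sum(total_members[h] for h in br.side_a)
            n_b_total = sum(total_members[h] for h in br.side_b)
            row = {
                "round": "1",
                "resolution_id": tree.resolution_id,
                "branch_id": br.branch_id,
                "signature": ";".join(sorted(br.signature)),
                "variants": br.variant_labels,
                "n_a": int(in_clade.sum()),
                "n_b": int((~in_clade).sum()),
                "n_a_members": n_a_total,
                "n_b_members": n_b_total,
                "missing_a": n_a_total - int(in_clade.sum()),
                "missing_b": n_b_total - int((~in_clade).sum()),
                "mean_a": float(y[in_clade].mean()) if in_clade.any() else np.nan,
                "mean_b": float(y[~in_clade].mean()) if (~in_clade).any() else np.nan,
                "F": np.nan,
                "nominal_p": np.nan,
                "corrected_p": np.nan,
                "testable": bool(testable[k]),
                "conditioned_on": "",
                "parent_branch": "",
            }
            if testable[k]:
                j = int(np.flatnonzero(t_idx == k)[0])
                row["F"] = float(ps.t_obs[j])
                row["nominal_p"] = float(ps.nominal_p[j])
                row["corrected_p"] = float(corrected[j])
                if corrected[j] < alpha and br.signature not in sig_seen:
                    sig_seen.add(br.signature)
                    sig_branches.append((br, alleles[:, k].copy()))
            rows.append(row)

    round1 = pd.DataFrame(rows)
    summary = _summarize(round1, len(resolutions), alpha)

    # conditioning re-scan: control each significant branch in turn
    if do_conditioning and sig_branches:
        for sig_br, sig_allele in sig_branches:
            for tree in resolutions:
                branches = enumerate_branches(tree)
                alleles = allele_vectors(branches, membership, complete)
                testable = filter_testable(branches, alleles, min_class)
                t_idx = np.flatnonzero(testable)
                if not len(t_idx):
                    continue
                ps = run_perm(alleles[:, t_idx], extra_cov=sig_allele,
                              perm_indices=perm_idx)
                corrected = stepdown_correction(ps.t_obs, ps.null_matrix, standardize=True)
                for j, k in enumerate(t_idx):
                    br = branches[k]
                    in_clade = alleles[:, k].astype(bool)
                    rows.append({
                        "round": "1-cond",
                        "resolution_id": tree.resolution_id,
                        "branch_id": br.branch_id,
                        "signature": ";".join(sorted(br.signature)),
                        "variants": br.variant_labels,
                        "n_a": int(in_clade.sum()),
                        "n_b": int((~in_clade).sum()),
                        "n_a_members": np.nan, "n_b_members": np.nan,
                        "missing_a": np.nan, "missing_b": np.nan,
                        "mean_a": float(y[in_clade].mean()),
                        "mean_b": float(y[~in_clade].mean()),
                        "F": float(ps.t_obs[j]),
                        "nominal_p": float(ps.nominal_p[j]),
                        "corrected_p": float(corrected[j]),
                        "testable": True,
                        "conditioned_on": ";".join(sorted(sig_br.signature)),
                        "parent_branch": "",
                    })

    # round 2: heterogeneity within the allelic classes of significant branches
    if do_round2 and sig_branches:
        for sig_br, sig_allele in sig_branches:
            tree = resolutions[0] if sig_br.resolution_id >= len(resolutions) else \
                next(t for t in resolutions if t.resolution_id == sig_br.resolution_id)
            branches = enumerate_branches(tree)
            rows.extend(
                _round2_rows(sig_br, sig_allele, branches, membership, complete,
                             y, run_perm, rng_round2, min_class))

    table = pd.DataFrame(rows)
    return ScanResult(
        table=table,
        summary=summary,
        seed=seed,
        n_perm=n_perm,
        min_class=min_class,
        alpha=alpha,
        n_resolutions=len(resolutions),
        n_complete=len(complete),
        n_individuals=len(all_ids),
    )


def _round2_rows(
    parent: Branch,
    parent_allele: np.ndarray,
    branches: Sequence[Branch],
    membership: dict[str, str],
    complete: Sequence[str],
    y: np.ndarray,
    run_perm,
    rng: np.random.Generator,
    min_class: int,
) -> list[dict]:
    """Conditional second-round tests nested inside one significant branch.

    Each allelic class of the parent branch is subdivided by every branch
    lying strictly within it (three-allele system); the other class is
    held constant by block-restricted permutation of the residuals of the
    model that already includes the parent's indicator.
    """
    haps = [membership[i] for i in complete]
    in_a = parent_allele.astype(bool)
    blocks = in_a.astype(int)  # two blocks: parent's classes

    sub_tests: list[tuple[Branch, str, np.ndarray, bool]] = []
    seen: set[tuple[str, frozenset]] = set()
    for br in branches:
        for cls_name, cls_haps in (("a", parent.side_a), ("b", parent.side_b)):
            for side in (br.side_a, br.side_b):
                if side < cls_haps:  # strictly within the class subtree
                    key = (cls_name, side)
                    if key in seen:
                        continue
                    seen.add(key)
                    sub = np.array([h in side for h in haps], dtype=float)
                    cls_mask = in_a if cls_name == "a" else ~in_a
                    n_sub = int(sub[cls_mask].sum())
                    n_rest = int(cls_mask.sum()) - n_sub
                    ok = n_sub >= min_class and n_rest >= min_class
                    sub_tests.append((br, cls_name, sub, ok))

    testable = [(br, cls, sub) for br, cls, sub, ok in sub_tests if ok]
    results: dict[int, tuple[float, float, float]] = {}
    if testable:
        alleles = np.column_stack([sub for _, _, sub in testable])
        ps = run_perm(alleles, extra_cov=parent_allele, blocks=blocks, rng=rng)
        corrected = stepdown_correction(ps.t_obs, ps.null_matrix, standardize=True)
        for j in range(len(testable)):
            results[j] = (float(ps.t_obs[j]), float(ps.nominal_p[j]),
                          float(corrected[j]))

    out = []
    j = 0
    for br, cls_name, sub, ok in sub_tests:
        cls_mask = in_a if cls_name == "a" else ~in_a
        sub_mask = sub.astype(bool) & cls_mask
        rest_mask = cls_mask & ~sub_mask
        row = {
            "round": "2",
            "resolution_id": parent.resolution_id,
            "branch_id": br.branch_id,
            "signature": ";".join(sorted(br.signature)),
            "variants": br.variant_labels,
            "n_a": int(sub_mask.sum()),
            "n_b": int(rest_mask.sum()),
            "n_a_members": np.nan, "n_b_members": np.nan,
            "missing_a": np.nan, "missing_b": np.nan,
            "mean_a": float(y[sub_mask].mean()) if sub_mask.any() else np.nan,
            "mean_b": float(y[rest_mask].mean()) if rest_mask.any() else np.nan,
            "F": np.nan,
            "nominal_p": np.nan,
            "corrected_p": np.nan,
            "testable": bool(ok),
            "conditioned_on": f"class_{cls_name}",
            "parent_branch": ";".join(sorted(parent.signature)),
        }
        if ok:
            row["F"], row["nominal_p"], row["corrected_p"] = results[j]
            j += 1
        out.append(row)
    return out
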
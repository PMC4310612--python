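"""Cis-window Spearman association mapping and multiple-testing machinery.

Five test families share one engine: genotype→expression (1 Mb window around
the TSS), genotype→methylation (5 kb around the CpG), methylation→expression
(50 kb around the TSS) and the two splicing families (genotype→link fraction,
1 Mb; methylation→link fraction, 50 kb). Significance uses either the
fixed-1000-permutation gene-level scheme with a nominal threshold at a target
FDR, or per-link adaptive permutations yielding empirical p-values that are
then passed to the Storey q-value procedure.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Spearman rank correlation


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1)


def _pearson(xr: np.ndarray, yr: np.ndarray) -> float:
    xr = xr - xr.mean()
    yr = yr - yr.mean()
    denom = math.sqrt((xr * xr).sum() * (yr * yr).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((xr * yr).sum() / denom, -1.0, 1.0))


def rho_to_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Spearman coefficient via the t approximation."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.minimum(p, 1.0)


def _exact_p(xr: np.ndarray, yr: np.ndarray, rho: float) -> float:
    """Exact permutation p by full enumeration of rank assignments (n < 10)."""
    n = len(xr)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = _pearson(xr, yr[list(perm)])
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks on ties) and two-sided nominal p.

    Exact permutation p for n < 10, t approximation otherwise. Pairs with
    missing values in either vector are dropped. Zero variance in either
    vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired non-missing observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    xr, yr = _rank(x), _rank(y)
    rho = _pearson(xr, yr)
    if n < 10:
        return rho, _exact_p(xr, yr, rho)
    return rho, float(rho_to_p(np.array([rho]), n)[0])


def spearman_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of each column of X (n x p) against y (n,). No missing."""
    Xr = stats.rankdata(X, axis=0)
    yr = stats.rankdata(y)
    Xr = Xr - Xr.mean(axis=0)
    yr = yr - yr.mean()
    xnorm = np.sqrt((Xr * Xr).sum(axis=0))
    ynorm = math.sqrt((yr * yr).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Xr.T @ yr) / (xnorm * ynorm)
    return np.clip(rho, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Covariate residualization


def residualize_covariates(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each phenotype column on the covariates.

    The column means are added back so downstream scaling is unchanged.
    Raises on rank-deficient covariate matrices, naming collinear columns.
    """
    C = np.column_stack([np.ones(len(covariates)), np.asarray(covariates, float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        _, r = np.linalg.qr(C)
        bad = [str(j - 1) for j in range(C.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"rank-deficient covariates (columns {', '.join(bad)})")
    Y = np.asarray(values, dtype=float)
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    resid = Y - C @ beta
    return resid + Y.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Cis mapping


def map_cis(
    regressors,
    phenotypes,
    gene_models: dict | None,
    window: int,
    anchor: str = "tss",
    maf_filter: bool = True,
) -> pd.DataFrame:
    """Test every (regressor, feature) pair within the cis window.

    ``regressors`` is a GenotypeMatrix (SNP dosages; the MAF > threshold
    inclusion rule applies) or a PhenotypeMatrix (CpG beta-values for the
    methylation→expression/splicing families). The window anchor is the
    feature's gene TSS (``anchor='tss'``) or the feature's own anchor
    coordinate (``anchor='feature'``, used for the 5 kb CpG-centred window).

    Returns one record per tested pair: feature_id, gene_id, regressor_id,
    signed distance_to_anchor (positive = downstream in transcription
    direction), rho, nominal_p.
    """
    from .types import GenotypeMatrix

    if isinstance(regressors, GenotypeMatrix):
        reg_values = regressors.dosages
        reg_meta = regressors.variants.assign(anchor=regressors.variants["pos"])
        keep = ~regressors.low_maf if maf_filter else np.ones(regressors.n_variants, bool)
    else:
        reg_values = regressors.values
        reg_meta = regressors.features.copy()
        keep = np.ones(len(reg_meta), dtype=bool)
    if list(getattr(regressors, "samples")) != list(phenotypes.samples):
        raise ValueError("regressor and phenotype sample lists differ")

    reg_pos = reg_meta["anchor"].to_numpy()
    reg_chrom = reg_meta["chrom"].to_numpy()
    reg_ids = reg_meta["id"].to_numpy()

    n = phenotypes.n_samples
    records = []
    skipped_zero_var = 0
    for j in range(phenotypes.n_features):
        feat = phenotypes.features.iloc[j]
        gene_id = feat["gene_id"]
        if anchor == "tss":
            if gene_models is None or gene_id not in gene_models:
                log.info("gene %s has no model; skipped", gene_id)
                continue
            gm = gene_models[gene_id]
            a, chrom, strand = gm.tss, gm.chrom, gm.strand
        else:
            a, chrom, strand = feat["anchor"], feat["chrom"], feat["strand"]
        in_win = (
            keep
            & (reg_chrom == chrom)
            & (np.abs(reg_pos - a) <= window)
        )
        idx = np.where(in_win)[0]
        if len(idx) == 0:
            continue
        y = phenotypes.values[:, j]
        if np.ptp(y[~np.isnan(y)]) == 0:
            skipped_zero_var += 1
            continue
        X = reg_values[:, idx]
        if np.isnan(X).any() or np.isnan(y).any():
            rhos = np.full(len(idx), np.nan)
            ps = np.full(len(idx), np.nan)
            for k, col in enumerate(idx):
                x = reg_values[:, col]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 3 or np.ptp(x[ok]) == 0:
                    continue
                rhos[k], ps[k] = spearman(x[ok], y[ok])
        else:
            sd = X.std(axis=0)
            rhos = np.full(len(idx), np.nan)
            nz = sd > 0
            if nz.any():
                rhos[nz] = spearman_matrix(X[:, nz], y)
            ps = rho_to_p(rhos, n)
        sign = 1 if strand == "+" else -1
        dist = (reg_pos[idx] - a) * sign
        for k in range(len(idx)):
            if np.isnan(rhos[k]):
                skipped_zero_var += 1
                continue
            records.append(
                (
                    feat["id"], gene_id, reg_ids[idx[k]], int(dist[k]),
                    rhos[k], ps[k],
                )
            )
    if skipped_zero_var:
        log.info("skipped %d zero-variance/degenerate pairs", skipped_zero_var)
    return pd.DataFrame(
        records,
        columns=[
            "feature_id", "gene_id", "regressor_id",
            "distance_to_anchor", "rho", "nominal_p",
        ],
    )


# ---------------------------------------------------------------------------
# Fixed 1000-permutation scheme with gene-level min-p


@dataclass
class FixedPermutationResult:
    threshold: float
    unit_min_p: pd.Series  # observed min nominal p per unit
    null_medians: np.ndarray  # rank-wise median null distribution
    significant_units: list
    n_perm: int
    scheme: str = "rank_median"


def _unit_min_p(records: pd.DataFrame, unit_col: str) -> pd.Series:
    return records.groupby(unit_col, sort=True)["nominal_p"].min()


def fixed_permutation_threshold(
    regressors,
    phenotypes,
    gene_models,
    window: int,
    anchor: str = "tss",
    unit_col: str = "gene_id",
    n_perm: int = 1000,
    subset_size: int = 1000,
    fdr: float = 0.10,
    rng: np.random.Generator | None = None,
    scheme: str = "rank_median",
    records: pd.DataFrame | None = None,
    maf_filter: bool = True,
) -> FixedPermutationResult:
    """Gene-level permutation null and nominal significance threshold.

    Phenotype sample labels are permuted ``n_perm`` times; in each round the
    per-unit minimum nominal p over that unit's cis pairs is recomputed on a
    random subset of units (default 1000; all units when fewer exist). The
    rank-wise median of the sorted per-round minima forms the null
    distribution (``scheme='pooled'`` pools all rounds instead). The nominal
    threshold is the largest observed unit-level p with estimated
    FDR(t) = E_null(t) / obs(t) <= fdr, where the expected null count uses a
    +1 pseudo-count, E(t) = (#null <= t + 1) * N_obs / (N_sub + 1), so that a
    single extreme observed unit cannot certify itself against an empty tail.
    """
    rng = np.random.default_rng(rng)
    if records is None:
        records = map_cis(
            regressors, phenotypes, gene_models, window, anchor, maf_filter
        )
    obs_min_p = _unit_min_p(records, unit_col)
    units = obs_min_p.index.to_numpy()
    n_units = len(units)
    if n_units == 0:
        return FixedPermutationResult(
            threshold=0.0, unit_min_p=obs_min_p, null_medians=np.array([]),
            significant_units=[], n_perm=n_perm, scheme=scheme,
        )
    sub = min(subset_size, n_units)
    if sub < subset_size:
        log.info("only %d units available; using all", n_units)
    unit_subset = rng.choice(units, size=sub, replace=False)
    subset_set = set(unit_subset)

    # Pre-group pair indices per unit for fast permutation recomputation.
    pair_groups: list[tuple[np.ndarray, np.ndarray]] = []
    from .types import GenotypeMatrix

    reg_values = (
        regressors.dosages
        if isinstance(regressors, GenotypeMatrix)
        else regressors.values
    )
    reg_ids = (
        regressors.variants["id"]
        if isinstance(regressors, GenotypeMatrix)
        else regressors.features["id"]
    )
    reg_index = pd.Series(np.arange(len(reg_ids)), index=reg_ids)
    feat_index = pd.Series(
        np.arange(phenotypes.n_features), index=phenotypes.features["id"]
    )
    grouped = records[records[unit_col].isin(subset_set)].groupby(unit_col)
    for _, grp in grouped:
        ridx = reg_index[grp["regressor_id"]].to_numpy()
        fidx = feat_index[grp["feature_id"]].to_numpy()
        pair_groups.append((ridx, fidx))

    n = phenotypes.n_samples
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    round_minima = np.ones((n_perm, len(pair_groups)))

    yr_all = stats.rankdata(phenotypes.values, axis=0)
    yr_all = yr_all - yr_all.mean(axis=0)
    ynorm = np.sqrt((yr_all * yr_all).sum(axis=0))

    for gi, (ridx, fidx) in enumerate(pair_groups):
        uniq_r, inv_r = np.unique(ridx, return_inverse=True)
        Xr = stats.rankdata(reg_values[:, uniq_r], axis=0)
        Xr = Xr - Xr.mean(axis=0)
        xnorm = np.sqrt((Xr * Xr).sum(axis=0))
        uniq_f = np.unique(fidx)
        for f in uniq_f:
            mask = fidx == f
            cols = inv_r[mask]
            yr = yr_all[:, f]
            if ynorm[f] == 0:
                continue
            Yp = yr[perms.T]  # n x n_perm
            R = (Xr[:, cols].T @ Yp) / (
                xnorm[cols, None] * ynorm[f]
            )  # pairs x n_perm
            max_abs = np.abs(R).max(axis=0)
            p = rho_to_p(max_abs, n)
            round_minima[:, gi] = np.minimum(round_minima[:, gi], p)

    sorted_rounds = np.sort(round_minima, axis=1)
    if scheme == "pooled":
        null = np.sort(round_minima.ravel())
        scale = sub * n_perm
    else:
        null = np.median(sorted_rounds, axis=0)
        scale = sub

    obs_sorted = np.sort(obs_min_p.to_numpy())
    n_null_le = np.searchsorted(null, obs_sorted, side="right")
    expected = (n_null_le + 1) * n_units / (scale + 1)
    observed = np.arange(1, n_units + 1)
    fdr_at = expected / observed
    ok = fdr_at <= fdr
    if ok.any():
        threshold = float(obs_sorted[np.where(ok)[0].max()])
    else:
        threshold = 0.0
    significant = [u for u, p in obs_min_p.items() if p <= threshold and threshold > 0]
    return FixedPermutationResult(
        threshold=threshold,
        unit_min_p=obs_min_p,
        null_medians=null,
        significant_units=significant,
        n_perm=n_perm,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# Adaptive permutations (splicing families)


def adaptive_empirical_p(
    phenotype: np.ndarray,
    regressor: np.ndarray,
    rng: np.random.Generator | int | None = None,
    target_hits: int = 100,
    min_perm: int = 100,
    max_perm: int = 100_000,
    pseudo_count: bool = False,
) -> tuple[float, float, int]:
    """Adaptive-permutation empirical p for one link-fraction/regressor pair.

    Permutes the phenotype 100 to ``max_perm`` times, stopping once
    ``target_hits`` permutation p-values fall below the observed nominal p;
    empirical p = hits / permutations performed (never below 1/permutations;
    ``pseudo_count`` switches to (hits+1)/(n+1)). Returns
    (empirical_p, nominal_p, n_perm).
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(regressor, float)
    y = np.asarray(phenotype, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 1.0, np.nan, min_perm
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho_obs = _pearson(xr, yr)
    nominal_p = float(rho_to_p(np.array([rho_obs]), n)[0])
    # Permutation preserves the tie structure of y, so p < nominal_p is
    # equivalent to |rho_perm| > |rho_obs|; compare on rho for stability.
    xr_c = xr - xr.mean()
    yr_c = yr - yr.mean()
    xnorm = math.sqrt((xr_c * xr_c).sum())
    ynorm = math.sqrt((yr_c * yr_c).sum())
    hits = 0
    n_done = 0
    batch = min_perm
    thresh = abs(rho_obs)
    while n_done < max_perm:
        batch = min(batch, max_perm - n_done)
        P = np.array([rng.permutation(n) for _ in range(batch)])
        R = (yr_c[P] @ xr_c) / (xnorm * ynorm)
        hits += int((np.abs(R) > thresh + 1e-12).sum())
        n_done += batch
        if hits >= target_hits and n_done >= min_perm:
            break
        batch = min(10 * batch, 10_000)
    if pseudo_count:
        emp = (hits + 1) / (n_done + 1)
    else:
        emp = max(hits, 1) / n_done
    return float(emp), nominal_p, n_done


# ---------------------------------------------------------------------------
# Storey q-values and pi0


LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray = LAMBDA_GRID) -> float:
    """Storey pi0: cubic smoother over the lambda grid evaluated at max lambda."""
    p = np.asarray(pvalues, float)
    p = p[~np.isnan(p)]
    m = len(p)
    if m == 0:
        raise ValueError("no p-values")
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(
    pvalues: np.ndarray,
    fdr: float = 0.10,
    pi0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Storey q-values; returns (q, significant mask at ``fdr``, pi0).

    With fewer than 100 tests pi0 falls back to 1 (Benjamini-Hochberg).
    Forcing ``pi0=1`` reproduces BH adjusted p-values exactly.
    """
    p = np.asarray(pvalues, float)
    m = len(p)
    if pi0 is None:
        if m < 100:
            log.info("fewer than 100 tests; using pi0=1 (BH)")
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= fdr, float(pi0)


def ase_fdr_estimate(n_tests: int, n_observed: int, alpha: float = 0.005) -> float:
    """Expected-over-observed FDR for the allelic-imbalance binomial screen."""
    if n_observed <= 0:
        raise ValueError("n_observed must be positive")
    return alpha * n_tests / n_observed
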
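"""Allele-specific expression: bias-corrected binomial tests and the
weighted allelic-ratio distance between samples.

Each heterozygous transcribed site in a sample carries REF/TOTAL read
counts. Sites with enough coverage are tested against a binomial null whose
success probability p0 absorbs reference-mapping and nucleotide-specific
bias, estimated per library and per ordered REF/ALT base pair. To remove the
depth dependence of rejection rates, coverage can be equalised by
hypergeometric down-sampling to exactly 30 reads. The allelic-ratio distance
between two samples is the weighted median of absolute REF/TOTAL ratio
differences over shared high-coverage sites; it does not assume the
over-expressed allele is the same in both samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import sample_id

log = logging.getLogger(__name__)

SITE_KEY = ["chrom", "pos", "ref", "alt"]


def filter_sites(
    records: pd.DataFrame,
    min_reads: int = 30,
    blacklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Keep sites with total coverage >= min_reads and not blacklisted."""
    out = records[records["total_count"] >= min_reads]
    if blacklist is not None and len(blacklist) > 0:
        bad = set(map(tuple, blacklist[["chrom", "pos"]].itertuples(index=False)))
        keep = [
            (c, p) not in bad
            for c, p in zip(out["chrom"], out["pos"])
        ]
        out = out[np.array(keep, dtype=bool)]
    return out.reset_index(drop=True)


def estimate_bias_p0(
    records: pd.DataFrame,
    min_sites_per_stratum: int = 200,
) -> pd.DataFrame:
    """Null reference probability per (library, ref/alt base pair) stratum.

    The library is the (individual, cell_type) pair. p0 is the pooled
    REF-read fraction over the stratum's sites; strata with fewer than
    ``min_sites_per_stratum`` sites fall back to the library-wide estimate.
    Returns the records with a ``p0`` column appended.
    """
    rec = records.copy()
    lib = rec["individual"].astype(str) + "." + rec["cell_type"].astype(str)
    rec["_lib"] = lib
    rec["_pair"] = rec["ref"].astype(str) + ">" + rec["alt"].astype(str)

    lib_tot = rec.groupby("_lib")[["ref_count", "total_count"]].sum()
    lib_p0 = (lib_tot["ref_count"] / lib_tot["total_count"]).rename("p0_lib")

    strat = rec.groupby(["_lib", "_pair"]).agg(
        refs=("ref_count", "sum"), totals=("total_count", "sum"), n=("pos", "size")
    )
    strat["p0_strat"] = strat["refs"] / strat["totals"]
    sparse = strat["n"] < min_sites_per_stratum
    if sparse.any():
        log.info(
            "%d/%d bias strata below %d sites; using library-wide p0",
            int(sparse.sum()), len(strat), min_sites_per_stratum,
        )
    rec = rec.join(strat["p0_strat"], on=["_lib", "_pair"])
    rec = rec.join(lib_p0, on="_lib")
    use_strat = rec.join(strat["n"].rename("_n"), on=["_lib", "_pair"])["_n"]
    rec["p0"] = np.where(
        use_strat >= min_sites_per_stratum, rec["p0_strat"], rec["p0_lib"]
    )
    return rec.drop(columns=["_lib", "_pair", "p0_strat", "p0_lib"])


def sample_to_depth(
    records: pd.DataFrame,
    depth: int = 30,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Down-sample each site to exactly ``depth`` reads without replacement.

    REF counts become hypergeometric draws from the observed REF/ALT pool.
    Sites below ``depth`` raise; filter first.
    """
    rng = np.random.default_rng(rng)
    if (records["total_count"] < depth).any():
        raise ValueError(f"sites with coverage below {depth}; filter first")
    out = records.copy()
    tot = out["total_count"].to_numpy()
    ref = out["ref_count"].to_numpy()
    at_depth = tot == depth
    new_ref = ref.copy()
    idx = ~at_depth
    if idx.any():
        new_ref[idx] = rng.hypergeometric(ref[idx], tot[idx] - ref[idx], depth)
    out["ref_count"] = new_ref
    out["total_count"] = depth
    return out


def binomial_ase_test(ref_count: int, total_count: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p: sum of pmf(k) over k with pmf(k) <= pmf(obs)."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    k = np.arange(total_count + 1)
    pmf = stats.binom.pmf(k, total_count, p0)
    p = pmf[pmf <= pmf[ref_count] * (1 + 1e-9)].sum()
    return float(min(p, 1.0))


def test_sites(
    records: pd.DataFrame,
    alpha: float = 0.005,
    default_p0: float | None = None,
) -> pd.DataFrame:
    """Binomial test every site; adds ratio, pvalue and is_ase columns.

    Uses the per-record ``p0`` column when present (see estimate_bias_p0),
    otherwise ``default_p0`` (0.5 if unset). Significance is p < alpha.
    """
    rec = records.copy()
    if "p0" not in rec.columns:
        rec["p0"] = 0.5 if default_p0 is None else default_p0
    elif default_p0 is not None:
        rec["p0"] = default_p0
    rec["ratio"] = rec["ref_count"] / rec["total_count"]
    # sites share (total, p0) heavily after depth equalisation; cache tests
    cache: dict[tuple[int, int, float], float] = {}
    pvals = np.empty(len(rec))
    for i, (r, t, p0) in enumerate(
        zip(rec["ref_count"], rec["total_count"], rec["p0"])
    ):
        key = (int(r), int(t), round(float(p0), 10))
        if key not in cache:
            cache[key] = binomial_ase_test(int(r), int(t), float(p0))
        pvals[i] = cache[key]
    rec["pvalue"] = pvals
    rec["is_ase"] = rec["pvalue"] < alpha
    return rec


def per_sample_summary(tested: pd.DataFrame, alpha: float = 0.005) -> pd.DataFrame:
    """Tested/significant site counts and expected-over-observed FDR per sample."""
    from .association import ase_fdr_estimate

    rows = []
    for (ind, ct), grp in tested.groupby(["individual", "cell_type"]):
        n_tests = len(grp)
        n_obs = int(grp["is_ase"].sum())
        rows.append(
            {
                "individual": ind,
                "cell_type": ct,
                "n_tested": n_tests,
                "n_ase": n_obs,
                "pct_ase": 100.0 * n_obs / n_tests if n_tests else np.nan,
                "fdr_estimate": (
                    ase_fdr_estimate(n_tests, n_obs, alpha) if n_obs else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median with midpoint interpolation at exact 50% mass."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half, side="left"))
    if np.isclose(cum[i], half) and i + 1 < len(v):
        return float((v[i] + v[i + 1]) / 2.0)
    return float(v[i])


@dataclass
class SampleDistanceRecord:
    sample_a: str
    sample_b: str
    n_shared_sites: int
    distance: float
    group: str


def _group_of(sample_a: str, sample_b: str) -> str:
    ind_a, _, ct_a = sample_a.rpartition(".")
    ind_b, _, ct_b = sample_b.rpartition(".")
    if ind_a == ind_b:
        return "same_individual"
    if ct_a == ct_b:
        return "same_cell_type"
    return "different"


def allelic_ratio_distance(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    min_depth: int = 40,
    min_shared_sites: int = 50,
) -> SampleDistanceRecord | None:
    """Weighted median |REF/TOTAL ratio difference| over shared het sites.

    Sites need >= ``min_depth`` reads in both samples; the weight of a site
    is the summed coverage of the two samples. Returns None when fewer than
    ``min_shared_sites`` qualifying shared sites exist.
    """
    a = records_a[records_a["total_count"] >= min_depth]
    b = records_b[records_b["total_count"] >= min_depth]
    merged = a.merge(b, on=SITE_KEY, suffixes=("_a", "_b"))
    sa = sample_id(str(a["individual"].iloc[0]), str(a["cell_type"].iloc[0])) if len(a) else "?"
    sb = sample_id(str(b["individual"].iloc[0]), str(b["cell_type"].iloc[0])) if len(b) else "?"
    if len(merged) < min_shared_sites:
        return None
    ratio_a = merged["ref_count_a"] / merged["total_count_a"]
    ratio_b = merged["ref_count_b"] / merged["total_count_b"]
    diffs = np.abs(ratio_a - ratio_b).to_numpy()
    weights = (merged["total_count_a"] + merged["total_count_b"]).to_numpy(float)
    return SampleDistanceRecord(
        sample_a=sa,
        sample_b=sb,
        n_shared_sites=len(merged),
        distance=weighted_median(diffs, weights),
        group=_group_of(sa, sb),
    )


def all_pairwise_distances(
    records: pd.DataFrame,
    min_depth: int = 40,
    min_shared_sites: int = 50,
) -> pd.DataFrame:
    """Allelic-ratio distances between every pair of (individual, cell-type)
    samples, labelled same_individual / same_cell_type / different.

    Equivalent to calling :func:`allelic_ratio_distance` on every sample
    pair, but computed on pivoted ratio/coverage matrices for speed.
    """
    rec = records.copy()
    rec["_sample"] = [
        sample_id(str(i), str(c))
        for i, c in zip(rec["individual"], rec["cell_type"])
    ]
    rec["_site"] = (
        rec["chrom"].astype(str) + ":" + rec["pos"].astype(str)
        + ":" + rec["ref"].astype(str) + ">" + rec["alt"].astype(str)
    )
    ratio = rec.pivot_table(
        index="_sample", columns="_site",
        values="ref_count", aggfunc="first",
    )
    total = rec.pivot_table(
        index="_sample", columns="_site",
        values="total_count", aggfunc="first",
    ).reindex_like(ratio)
    R = (ratio / total).to_numpy()
    T = total.to_numpy()
    samples = list(ratio.index)
    deep = ~np.isnan(T) & (T >= min_depth)
    rows = []
    for ia, ib in itertools.combinations(range(len(samples)), 2):
        ok = deep[ia] & deep[ib]
        if ok.sum() < min_shared_sites:
            continue
        diffs = np.abs(R[ia, ok] - R[ib, ok])
        weights = T[ia, ok] + T[ib, ok]
        rows.append(
            {
                "sample_a": samples[ia],
                "sample_b": samples[ib],
                "n_shared_sites": int(ok.sum()),
                "distance": weighted_median(diffs, weights),
                "group": _group_of(samples[ia], samples[ib]),
            }
        )
    return pd.DataFrame(rows)


def distance_group_comparison(distances: pd.DataFrame) -> pd.DataFrame:
    """Group medians and pairwise Wilcoxon rank-sum tests between the three
    sample-pair groups (same individual / same cell-type / different)."""
    rows = []
    groups = {g: grp["distance"].to_numpy() for g, grp in distances.groupby("group")}
    for ga, gb in itertools.combinations(sorted(groups), 2):
        da, db = groups[ga], groups[gb]
        if len(da) < 2 or len(db) < 2:
            log.warning("group %s or %s has <2 distances; comparison skipped", ga, gb)
            continue
        stat, p = stats.mannwhitneyu(da, db, alternative="two-sided")
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "median_a": float(np.median(da)),
                "median_b": float(np.median(db)),
                "n_a": len(da),
                "n_b": len(db),
                "wilcoxon_p": float(p),
            }
        )
    return pd.DataFrame(rows)
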
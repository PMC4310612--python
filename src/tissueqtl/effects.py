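"""Effect sizes on scaled phenotypes and cross-tissue sharing summaries.

Genotype effect sizes are the difference in medians of the scaled phenotype
between heterozygotes and major-allele homozygotes, i.e. phenotype standard
deviations changed by one allele; methylation effect sizes are the OLS slope
of the scaled response on scaled methylation (equal to Pearson r). Sharing
between cell-types is summarised by Storey's pi1 on the second tissue's
p-values at the first tissue's significant pairs, effect-size R² over the
union and the shared set, and the percentage of sign-discordant shared pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import estimate_pi0

log = logging.getLogger(__name__)


def scale(values: np.ndarray) -> np.ndarray:
    """Center to mean 0 and divide by the sample SD (ddof=1)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("cannot scale a constant vector")
    return (x - x.mean()) / sd


def genotype_effect_size(
    phenotype: np.ndarray,
    dosage: np.ndarray,
    min_group: int = 2,
) -> float:
    """median(scaled phenotype | het) - median(scaled phenotype | hom-major).

    The major allele is taken from the dosage frequencies; minor-allele
    homozygotes are excluded. Returns NaN when either group is smaller than
    ``min_group``.
    """
    d = np.asarray(dosage, float)
    y = np.asarray(phenotype, float)
    keep = ~(np.isnan(d) | np.isnan(y))
    d, y = d[keep], y[keep]
    ys = scale(y)
    alt_freq = d.mean() / 2.0
    hom_major = d == (0.0 if alt_freq <= 0.5 else 2.0)
    het = d == 1.0
    if het.sum() < min_group or hom_major.sum() < min_group:
        return np.nan
    return float(np.median(ys[het]) - np.median(ys[hom_major]))


def methylation_effect_size(response: np.ndarray, methylation: np.ndarray) -> float:
    """OLS slope of scaled response on scaled methylation (= Pearson r)."""
    y = np.asarray(response, float)
    m = np.asarray(methylation, float)
    keep = ~(np.isnan(y) | np.isnan(m))
    y, m = y[keep], m[keep]
    ys, ms = scale(y), scale(m)
    return float((ms @ ys) / (ms @ ms))


def pi1(pvalues: np.ndarray) -> float:
    """Storey estimate of the proportion of true positives, 1 - pi0."""
    p = np.asarray(pvalues, float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    if np.ptp(p) == 0:
        log.warning("pi1 on identical p-values is degenerate")
        return 1.0 if p[0] < 0.05 else 0.0
    if len(p) < 100:
        log.info("pi1 estimated from only %d p-values", len(p))
    return float(np.clip(1.0 - estimate_pi0(p), 0.0, 1.0))


@dataclass
class SharingSummary:
    tissue_a: str
    tissue_b: str
    pi1_a_in_b: float
    pi1_b_in_a: float
    r2_union: float
    r2_shared: float
    pct_discordant: float
    n_union: int
    n_shared: int


def _best_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Best (lowest nominal p) pair per feature."""
    idx = records.groupby("feature_id")["nominal_p"].idxmin()
    return records.loc[idx]


def cross_tissue_sharing(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    tissue_a: str = "A",
    tissue_b: str = "B",
    mode: str = "best_pair",
) -> SharingSummary:
    """Pairwise sharing summary between two tissues.

    Records must carry feature_id, regressor_id, nominal_p, effect_size and a
    boolean ``significant`` column. Pairs are matched on
    (regressor_id, feature_id); the union set is significant in either tissue
    and tested in both; the shared set is significant in both. pi1 is
    computed from tissue B's p-values at tissue A's significant pairs (best
    pair per feature by default, all pairs with ``mode='all_pairs'``) and
    vice versa.
    """
    keys = ["regressor_id", "feature_id"]
    merged = records_a.merge(records_b, on=keys, suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("fewer than 3 matched pairs between tissues")

    def _pi1_of(first: pd.DataFrame, suffix_first: str, suffix_second: str) -> float:
        sig = merged[merged[f"significant{suffix_first}"]]
        if mode == "best_pair":
            idx = sig.groupby("feature_id")[f"nominal_p{suffix_first}"].idxmin()
            sig = sig.loc[idx]
        if len(sig) == 0:
            return np.nan
        return pi1(sig[f"nominal_p{suffix_second}"].to_numpy())

    union = merged[merged["significant_a"] | merged["significant_b"]]
    shared = merged[merged["significant_a"] & merged["significant_b"]]

    def _r2(df: pd.DataFrame) -> float:
        if len(df) < 3:
            return np.nan
        ea = df["effect_size_a"].to_numpy()
        eb = df["effect_size_b"].to_numpy()
        ok = ~(np.isnan(ea) | np.isnan(eb))
        if ok.sum() < 3:
            return np.nan
        r, _ = stats.pearsonr(ea[ok], eb[ok])
        return float(r**2)

    if len(shared) > 0:
        opposite = (
            np.sign(shared["effect_size_a"]) * np.sign(shared["effect_size_b"]) < 0
        )
        pct_disc = 100.0 * opposite.sum() / len(shared)
    else:
        pct_disc = np.nan
    return SharingSummary(
        tissue_a=tissue_a,
        tissue_b=tissue_b,
        pi1_a_in_b=_pi1_of(records_a, "_a", "_b"),
        pi1_b_in_a=_pi1_of(records_b, "_b", "_a"),
        r2_union=_r2(union),
        r2_shared=_r2(shared),
        pct_discordant=float(pct_disc),
        n_union=len(union),
        n_shared=len(shared),
    )


def sharing_class_counts(records_per_tissue: dict[str, pd.DataFrame]) -> pd.Series:
    """Per feature, the number of tissues in which it is significant.

    Features significant nowhere are excluded. Input records need
    feature_id and significant columns.
    """
    counts: dict[str, int] = {}
    for _, rec in records_per_tissue.items():
        sig_features = set(rec.loc[rec["significant"], "feature_id"])
        for f in sig_features:
            counts[f] = counts.get(f, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def sharing_class_table(records_per_tissue: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Distribution of sharing classes (1/2/.. tissues) per discovery tissue."""
    classes = sharing_class_counts(records_per_tissue)
    rows = []
    for tissue, rec in records_per_tissue.items():
        sig_features = set(rec.loc[rec["significant"], "feature_id"])
        tally = {}
        for f in sig_features:
            tally[classes[f]] = tally.get(classes[f], 0) + 1
        for k in sorted(tally):
            rows.append({"tissue": tissue, "n_tissues": k, "n_features": tally[k]})
    return pd.DataFrame(rows)


def all_pairwise_sharing(
    records_per_tissue: dict[str, pd.DataFrame], mode: str = "best_pair"
) -> list[SharingSummary]:
    out = []
    for a, b in itertools.combinations(records_per_tissue, 2):
        out.append(
            cross_tissue_sharing(
                records_per_tissue[a], records_per_tissue[b], a, b, mode=mode
            )
        )
    return out
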
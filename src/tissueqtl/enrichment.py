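"""Genomic-context analysis: feature overlap, matched null sets, Fisher
enrichment, and positional profiles relative to TSS/TES.

Enrichment compares the best associated SNP (or CpG) per gene/site/link
against a matched null set drawn from a candidate pool at similar distance
to the anchor, minor allele frequency and phenotype level, excluding
candidates nominally associated (p < 0.01) to the relevant phenotype.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureSet, GeneModel

log = logging.getLogger(__name__)


def overlap(
    chroms, positions, features: FeatureSet
) -> np.ndarray:
    """Boolean per point: inside any half-open interval of the feature set."""
    return features.contains_many(list(chroms), list(positions))


def derive_gene_features(
    gene_models: dict[str, GeneModel],
    cpg_islands: FeatureSet | None = None,
    promoter_up: int = 1000,
    promoter_down: int = 2000,
    shore_width: int = 2000,
) -> dict[str, FeatureSet]:
    """Promoters (-1kb..+2kb around the TSS, transcription direction), gene
    bodies (+2kb..gene end) and CpG island shores (2kb flanks, island
    excluded)."""
    promoters, bodies = [], []
    for gm in gene_models.values():
        if gm.strand == "+":
            promoters.append((gm.chrom, gm.tss - promoter_up, gm.tss + promoter_down))
            body = (gm.chrom, gm.tss + promoter_down, gm.end)
        else:
            # strand reflection: -1kb..+2kb in transcription direction
            promoters.append((gm.chrom, gm.tss - promoter_down, gm.tss + promoter_up))
            body = (gm.chrom, gm.start, gm.tss - promoter_down)
        if body[2] > body[1]:
            bodies.append(body)
        else:
            log.info("gene %s shorter than %dbp: empty gene body", gm.gene_id, promoter_down)
    out = {
        "promoter": FeatureSet("promoter", promoters),
        "gene_body": FeatureSet("gene_body", bodies),
    }
    if cpg_islands is not None:
        shores = []
        for chrom, s, e in cpg_islands.intervals():
            shores.append((chrom, s - shore_width, s))
            shores.append((chrom, e, e + shore_width))
        out["shore"] = FeatureSet("shore", shores)
    return out


@dataclass
class NullMatchSpec:
    """Matching variables and bin widths for null-set construction.

    Candidates must not be nominally associated (p >= exclusion_p) to the
    relevant phenotype family; one null is drawn per query, without
    replacement, from the joint covariate bin (widened once, x2, when empty).
    """

    maf_bin: float = 0.05
    distance_bin: int = 10_000
    level_quartiles: bool = True
    exclusion_p: float = 0.01
    variables: tuple[str, ...] = ("distance_to_anchor", "maf", "phenotype_level")


def _bin_key(row, spec: NullMatchSpec, level_edges, widen: int = 1):
    key = []
    if "distance_to_anchor" in spec.variables:
        key.append(int(row["distance_to_anchor"] // (spec.distance_bin * widen)))
    if "maf" in spec.variables:
        key.append(int(row["maf"] // (spec.maf_bin * widen)))
    if "phenotype_level" in spec.variables and level_edges is not None:
        key.append(int(np.searchsorted(level_edges, row["phenotype_level"])))
    return tuple(key)


def match_nulls(
    query: pd.DataFrame,
    pool: pd.DataFrame,
    spec: NullMatchSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, int]:
    """One matched null per query row, drawn without replacement.

    Both frames need the columns named in ``spec.variables`` (plus whatever
    identifies the points). Pool rows with association p below
    ``exclusion_p`` must be filtered by the caller when applicable. Returns
    (null rows aligned to matched queries, number of unmatched queries).
    """
    spec = spec or NullMatchSpec()
    rng = np.random.default_rng(rng)
    level_edges = None
    if "phenotype_level" in spec.variables and spec.level_quartiles:
        if "phenotype_level" not in pool.columns:
            raise ValueError("pool lacks phenotype_level")
        level_edges = np.quantile(pool["phenotype_level"], [0.25, 0.5, 0.75])

    bins: dict[tuple, list[int]] = {}
    wide_bins: dict[tuple, list[int]] = {}
    for i, (_, row) in enumerate(pool.iterrows()):
        bins.setdefault(_bin_key(row, spec, level_edges), []).append(i)
        wide_bins.setdefault(_bin_key(row, spec, level_edges, widen=2), []).append(i)
    used = np.zeros(len(pool), dtype=bool)
    chosen, unmatched = [], 0
    for _, row in query.iterrows():
        picked = None
        for widen, table in ((1, bins), (2, wide_bins)):
            cands = [
                i for i in table.get(_bin_key(row, spec, level_edges, widen), [])
                if not used[i]
            ]
            if cands:
                picked = cands[rng.integers(len(cands))]
                break
        if picked is None:
            unmatched += 1
            continue
        used[picked] = True
        chosen.append(picked)
    if unmatched:
        log.info("%d queries could not be matched to a null", unmatched)
    return pool.iloc[chosen].reset_index(drop=True), unmatched


@dataclass
class EnrichmentResult:
    feature: str
    query_in: int
    query_n: int
    null_in: int
    null_n: int
    odds_ratio: float
    pvalue: float
    stars: str = field(init=False)

    def __post_init__(self):
        self.stars = (
            "**" if self.pvalue < 5e-4 else "*" if self.pvalue < 0.05 else ""
        )


def fisher_enrichment(
    query_overlaps: np.ndarray,
    null_overlaps: np.ndarray,
    feature_name: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the 2x2 in/out table."""
    q = np.asarray(query_overlaps, bool)
    u = np.asarray(null_overlaps, bool)
    table = [[int(q.sum()), int((~q).sum())], [int(u.sum()), int((~u).sum())]]
    orat, p = stats.fisher_exact(table, alternative="two-sided")
    if not np.isfinite(orat):
        log.info("degenerate margin for %s: OR=%s", feature_name, orat)
    return EnrichmentResult(
        feature=feature_name,
        query_in=table[0][0], query_n=len(q),
        null_in=table[1][0], null_n=len(u),
        odds_ratio=float(orat), pvalue=float(p),
    )


def positional_profile(
    records: pd.DataFrame,
    gene_models: dict[str, GeneModel],
    bin_bp: int = 10_000,
    flank: int = 100_000,
) -> pd.DataFrame:
    """Proportion of QTLs upstream of the TSS (10kb bins), in gene-length
    deciles, and downstream of the TES (10kb bins).

    Records need gene_id and a genomic ``pos`` column. Records outside the
    profiled range are excluded (counted in the returned attrs).
    """
    n_flank = flank // bin_bp
    labels = (
        [f"up{-(i + 1) * bin_bp // 1000}kb" for i in range(n_flank)][::-1]
        + [f"decile{i + 1}" for i in range(10)]
        + [f"down{(i + 1) * bin_bp // 1000}kb" for i in range(n_flank)]
    )
    counts = np.zeros(len(labels))
    excluded = 0
    for row in records.itertuples():
        gm = gene_models.get(row.gene_id)
        if gm is None:
            excluded += 1
            continue
        pos = row.pos
        # work in transcription direction
        d_tss = gm.signed_distance(pos)
        gene_len = gm.end - gm.start
        if d_tss < 0:  # upstream
            b = int((-d_tss - 1) // bin_bp)
            if b >= n_flank:
                excluded += 1
                continue
            counts[n_flank - 1 - b] += 1
        elif d_tss < gene_len:  # inside the gene, deciles
            decile = min(int(10 * d_tss / gene_len), 9)
            counts[n_flank + decile] += 1
        else:  # downstream of the TES
            b = int((d_tss - gene_len) // bin_bp)
            if b >= n_flank:
                excluded += 1
                continue
            counts[n_flank + 10 + b] += 1
    total = counts.sum()
    props = counts / total if total > 0 else counts
    out = pd.DataFrame({"bin": labels, "count": counts, "proportion": props})
    out.attrs["excluded"] = excluded
    return out


def distance_by_sharing_class(
    records: pd.DataFrame, class_col: str = "n_tissues"
) -> pd.DataFrame:
    """|distance| distributions per sharing class with pairwise rank-sum tests.

    Records need ``distance_to_anchor`` and a sharing-class column.
    """
    groups = {
        int(k): np.abs(grp["distance_to_anchor"].to_numpy())
        for k, grp in records.groupby(class_col)
    }
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        da, db = groups[a], groups[b]
        if len(da) < 2 or len(db) < 2:
            log.warning("sharing class %s or %s has <2 members; skipped", a, b)
            continue
        _, p = stats.mannwhitneyu(da, db, alternative="two-sided")
        rows.append(
            {
                "class_a": a, "class_b": b,
                "median_abs_dist_a": float(np.median(da)),
                "median_abs_dist_b": float(np.median(db)),
                "n_a": len(da), "n_b": len(db),
                "wilcoxon_p": float(p),
            }
        )
    return pd.DataFrame(rows)


def best_association_per_unit(
    records: pd.DataFrame, unit_col: str = "gene_id"
) -> pd.DataFrame:
    """Best SNP/CpG per unit: lowest nominal p, ties broken by smaller
    |distance| then lexicographic regressor id."""
    rec = records.copy()
    rec["_absd"] = rec["distance_to_anchor"].abs()
    rec = rec.sort_values(
        ["nominal_p", "_absd", "regressor_id"], kind="stable"
    )
    out = rec.groupby(unit_col, sort=True).head(1).drop(columns="_absd")
    return out.reset_index(drop=True)
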
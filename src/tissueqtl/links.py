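"""Relative splicing quantification from paired reads via exon-exon links.

A "link" is a read pair whose two mates fall in the unique portions of two
different exons of a gene. Overlapping exons are grouped into exon groups
and the unique portion of each exon (the sub-intervals overlapped by no
other exon in its group) is what reads are assigned to. Raw link counts are
normalised by removing the leading principal components, divided by the
probability of observing the link under the sample's empirical insert-size
distribution and the unique-portion geometry ("link coverage"), and finally
expressed as the fraction of one link's coverage over the summed coverages
of all links made by the primary exon — separately in the 5'→3' (forward,
primary = 5'-most exon) and 3'→5' (reverse, primary = 3'-most exon)
directions, capturing splice-acceptor and splice-donor effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Exon groups and unique portions


@dataclass
class ExonGroup:
    group_id: str
    gene_id: str
    exons: list[int]  # exon indices (genomic order within the gene)
    unique_portions: dict[int, list[tuple[int, int]]] = field(default_factory=dict)


def _subtract_intervals(
    interval: tuple[int, int], others: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Interval minus the union of others (all half-open)."""
    pieces = [interval]
    for os, oe in others:
        nxt = []
        for s, e in pieces:
            if oe <= s or os >= e:
                nxt.append((s, e))
                continue
            if s < os:
                nxt.append((s, os))
            if oe < e:
                nxt.append((oe, e))
        pieces = nxt
    return pieces


def build_exon_groups(gene: GeneModel) -> list[ExonGroup]:
    """Group overlapping exons (transitive closure) and extract unique portions.

    Exons with no unique portion (fully nested) are flagged via an empty
    portion list; they cannot anchor links.
    """
    exons = gene.exons
    groups: list[list[int]] = []
    cur = [0]
    cur_end = exons[0][1]
    for i in range(1, len(exons)):
        s, e = exons[i]
        if s < cur_end:  # overlap with the running group
            cur.append(i)
            cur_end = max(cur_end, e)
        else:
            groups.append(cur)
            cur, cur_end = [i], e
    groups.append(cur)

    out = []
    for gi, members in enumerate(groups):
        eg = ExonGroup(group_id=f"{gene.gene_id}_g{gi}", gene_id=gene.gene_id,
                       exons=members)
        for i in members:
            others = [exons[j] for j in members if j != i]
            portions = _subtract_intervals(exons[i], others)
            if not portions:
                log.info(
                    "exon %d of %s has no unique portion", i, gene.gene_id
                )
            eg.unique_portions[i] = portions
        out.append(eg)
    return out


def unique_portions_by_exon(gene: GeneModel) -> dict[int, list[tuple[int, int]]]:
    portions: dict[int, list[tuple[int, int]]] = {}
    for eg in build_exon_groups(gene):
        portions.update(eg.unique_portions)
    return portions


# ---------------------------------------------------------------------------
# Link counting


def _assign_read(
    start: int, end: int, portions: dict[int, list[tuple[int, int]]]
) -> int | None:
    """Exon index whose unique portion the read overlaps (>=1 bp).

    Returns None when unassigned, -1 when ambiguous (overlapping unique
    portions of two or more exons).
    """
    hits = []
    for exon_idx, ivs in portions.items():
        for s, e in ivs:
            if start < e and end > s:
                hits.append(exon_idx)
                break
    if not hits:
        return None
    if len(hits) > 1:
        return -1
    return hits[0]


@dataclass
class LinkCounts:
    gene_id: str
    links: pd.DataFrame  # columns: exon_a, exon_b (genomic order, a < b)
    counts: np.ndarray  # samples x links, raw
    samples: list[str]
    n_ambiguous: int = 0

    def link_ids(self, strand: str, direction: str) -> list[str]:
        ids = []
        for row in self.links.itertuples():
            ids.append(
                link_id(self.gene_id, row.exon_a, row.exon_b, direction)
            )
        return ids


def link_id(gene_id: str, exon_a: int, exon_b: int, direction: str) -> str:
    return f"{gene_id}:e{exon_a}-e{exon_b}:{direction}"


def count_links(
    read_pairs: pd.DataFrame,
    gene: GeneModel,
    samples: list[str] | None = None,
) -> LinkCounts:
    """Count exon-exon links for one gene from a paired-read placement table.

    Each read is assigned to the exon whose unique portion it overlaps; a
    pair with its two mates in different exons increments that exon pair's
    count. Reads overlapping unique portions of more than one exon are
    ambiguous and the pair is dropped (counted).
    """
    portions = unique_portions_by_exon(gene)
    if samples is None:
        samples = sorted(read_pairs["sample"].unique())
    sample_idx = {s: i for i, s in enumerate(samples)}
    pair_counts: dict[tuple[int, int], np.ndarray] = {}
    n_ambiguous = 0
    sub = read_pairs[read_pairs["chrom"] == gene.chrom]
    for row in sub.itertuples():
        a = _assign_read(row.r1_start, row.r1_end, portions)
        b = _assign_read(row.r2_start, row.r2_end, portions)
        if a == -1 or b == -1:
            n_ambiguous += 1
            continue
        if a is None or b is None or a == b:
            continue
        key = (min(a, b), max(a, b))
        if key not in pair_counts:
            pair_counts[key] = np.zeros(len(samples))
        pair_counts[key][sample_idx[row.sample]] += 1
    keys = sorted(pair_counts)
    links = pd.DataFrame(keys, columns=["exon_a", "exon_b"])
    counts = (
        np.stack([pair_counts[k] for k in keys], axis=1)
        if keys
        else np.empty((len(samples), 0))
    )
    return LinkCounts(
        gene_id=gene.gene_id, links=links, counts=counts,
        samples=list(samples), n_ambiguous=n_ambiguous,
    )


# ---------------------------------------------------------------------------
# PC normalisation


def normalize_link_counts(
    counts: np.ndarray, n_pcs: int = 15, log_scale: bool = True
) -> np.ndarray:
    """Residual counts after removing the top principal components.

    PCA runs on the (optionally log1p-transformed) centred sample x link
    matrix; residuals are re-centred to the original link means and
    back-transformed. Constant links are passed through untouched. When
    fewer than n_pcs+1 samples exist, min(n_samples - 1, n_pcs) components
    are removed (logged). ``n_pcs=0`` is the identity.
    """
    X = np.asarray(counts, dtype=float)
    n, p = X.shape
    k = min(n_pcs, max(n - 1, 0), p)
    if k < n_pcs:
        log.info("using %d principal components (requested %d)", k, n_pcs)
    if k == 0:
        return X.copy()
    L = np.log1p(X) if log_scale else X.copy()
    sd = L.std(axis=0)
    variable = sd > 0
    out = L.copy()
    if variable.sum() > 0:
        sub = L[:, variable]
        mean = sub.mean(axis=0)
        C = sub - mean
        kk = min(k, variable.sum())
        U, S, Vt = np.linalg.svd(C, full_matrices=False)
        proj = (U[:, :kk] * S[:kk]) @ Vt[:kk]
        out[:, variable] = C - proj + mean
    if log_scale:
        out = np.clip(np.expm1(out), 0.0, None)
    return out


# ---------------------------------------------------------------------------
# Link coverage: placement probability under the insert-size distribution


@dataclass
class InsertSizeDistribution:
    """Empirical probability mass over fragment (insert) sizes."""

    sizes: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.sizes <= 0).any():
            raise ValueError("insert sizes must be positive")
        if not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("insert-size probabilities must sum to 1")

    @classmethod
    def from_dict(cls, d: dict[int, float]) -> "InsertSizeDistribution":
        sizes = sorted(d)
        return cls(np.array(sizes), np.array([d[s] for s in sizes]))

    @classmethod
    def from_observed(cls, inserts: np.ndarray) -> "InsertSizeDistribution":
        vals, counts = np.unique(np.asarray(inserts, int), return_counts=True)
        return cls(vals, counts / counts.sum())


def _read_in_exon(
    read_start: int, read_end: int,
    exon_span: tuple[int, int],
    uniq: list[tuple[int, int]],
) -> bool:
    """Read fully inside the exon's transcript span and overlapping a unique
    portion by at least 1 bp (transcript coordinates)."""
    s, e = exon_span
    if read_start < s or read_end > e:
        return False
    return any(read_start < ue and read_end > us for us, ue in uniq)


def link_probability(
    len5: int,
    uniq5: list[tuple[int, int]],
    len3: int,
    uniq3: list[tuple[int, int]],
    insert_dist: InsertSizeDistribution,
    read_len: int,
) -> float:
    """Probability of observing a link between two exons.

    The two exons are concatenated in transcript order (5' exon then 3'
    exon); fragments of each insert size start uniformly over the spliced
    sequence; a placement yields the link when the upstream read lies fully
    within the 5' exon overlapping its unique portion and the downstream
    read likewise within the 3' exon. Unique-portion coordinates are local
    to each exon. Insert sizes longer than the concatenated sequence
    contribute no placements.
    """
    L = len5 + len3
    span5 = (0, len5)
    span3 = (len5, L)
    uniq3_t = [(len5 + s, len5 + e) for s, e in uniq3]
    prob = 0.0
    for size, mass in zip(insert_dist.sizes, insert_dist.probs):
        if size < read_len or size > L:
            continue
        n_total = L - size + 1
        n_valid = 0
        for f in range(n_total):
            r1 = (f, f + read_len)
            r2 = (f + size - read_len, f + size)
            if _read_in_exon(*r1, span5, uniq5) and _read_in_exon(*r2, span3, uniq3_t):
                n_valid += 1
        prob += mass * n_valid / n_total
    return prob


def link_coverage(normalized_count: float, probability: float) -> float:
    """Coverage = normalised count / placement probability.

    A zero probability means the geometry cannot produce the link; the
    coverage is undefined (NaN) and the link should be excluded.
    """
    if probability <= 0:
        log.warning("link with zero placement probability excluded")
        return np.nan
    return normalized_count / probability


def gene_link_coverages(
    lc: LinkCounts,
    gene: GeneModel,
    insert_dist: InsertSizeDistribution,
    read_len: int,
    normalized: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coverage matrix (samples x links) and per-link probabilities."""
    counts = lc.counts if normalized is None else normalized
    portions = unique_portions_by_exon(gene)
    exon_lens = [e - s for s, e in gene.exons]
    # unique portions local to each exon
    local = {
        i: [(s - gene.exons[i][0], e - gene.exons[i][0]) for s, e in portions[i]]
        for i in portions
    }
    probs = np.empty(len(lc.links))
    for li, row in enumerate(lc.links.itertuples()):
        a, b = row.exon_a, row.exon_b
        five, three = (a, b) if gene.strand == "+" else (b, a)
        probs[li] = link_probability(
            exon_lens[five], local[five], exon_lens[three], local[three],
            insert_dist, read_len,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(probs > 0, counts / probs, np.nan)
    return cov, probs


# ---------------------------------------------------------------------------
# Link fractions


def primary_exons(links: pd.DataFrame, strand: str, direction: str) -> np.ndarray:
    """Primary exon of each link: 5'-most in forward, 3'-most in reverse."""
    a = links["exon_a"].to_numpy()
    b = links["exon_b"].to_numpy()
    five = a if strand == "+" else b
    three = b if strand == "+" else a
    return five if direction == "forward" else three


def link_fractions(
    coverages: np.ndarray, links: pd.DataFrame, strand: str, direction: str
) -> np.ndarray:
    """Fraction of each link's coverage over the summed coverage of all links
    of its primary exon, per sample. Missing (NaN) when the sum is zero."""
    prim = primary_exons(links, strand, direction)
    frac = np.full_like(np.asarray(coverages, float), np.nan)
    for p in np.unique(prim):
        cols = prim == p
        sub = coverages[:, cols]
        tot = np.nansum(sub, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = sub / tot[:, None]
        f[tot == 0] = np.nan
        frac[:, cols] = f
    return frac


def filter_links(
    raw_counts: np.ndarray,
    fractions: np.ndarray,
    links: pd.DataFrame,
    gene: GeneModel,
    direction: str,
    min_group_links: int = 10,
    min_group_frac: float = 0.80,
    min_primary_links: int = 5,
    min_primary_frac: float = 0.30,
    max_nonvariable: float = 0.95,
) -> np.ndarray:
    """Boolean retention mask over links for one direction.

    A link is kept iff (1) its primary exon's exon group makes >=10 links in
    this direction in >=80% of individuals, (2) its primary exon makes >=5
    links in >=30% of individuals, and (3) at most 95% of individuals share
    the modal fraction value ("non-variable").
    """
    n = raw_counts.shape[0]
    prim = primary_exons(links, gene.strand, direction)
    group_of = {}
    for eg in build_exon_groups(gene):
        for i in eg.exons:
            group_of[i] = eg.group_id
    prim_group = np.array([group_of[p] for p in prim])

    keep = np.zeros(len(links), dtype=bool)
    for li in range(len(links)):
        grp_cols = prim_group == prim_group[li]
        grp_total = raw_counts[:, grp_cols].sum(axis=1)
        rule1 = (grp_total >= min_group_links).mean() >= min_group_frac
        prim_cols = prim == prim[li]
        prim_total = raw_counts[:, prim_cols].sum(axis=1)
        rule2 = (prim_total >= min_primary_links).mean() >= min_primary_frac
        vals = fractions[:, li]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            rule3 = False
        else:
            _, counts = np.unique(np.round(vals, 12), return_counts=True)
            rule3 = counts.max() / n <= max_nonvariable
        keep[li] = rule1 and rule2 and rule3
    return keep


def differential_link_usage(
    fractions_a: np.ndarray, fractions_b: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t-test on one link's fractions between two tissues."""
    a = np.asarray(fractions_a, float)
    b = np.asarray(fractions_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per tissue")
    if a.std() == 0 and b.std() == 0:
        log.warning("zero variance in both groups; p undefined")
        return np.nan, np.nan
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
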
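"""Shared domain containers for the multi-tissue QTL/QTM pipeline.

All genomic intervals are 0-based half-open internally. VCF positions are
converted by -1 on read; BED intervals are native. Sample identifiers are
``<individual>.<cell_type>`` so cross-tissue operations can join on the
individual part.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]
FEATURE_COLUMNS = ["chrom", "start", "end", "id", "gene_id", "strand"]

PHENOTYPE_KINDS = ("expression", "methylation", "link_fraction")


def sample_id(individual: str, cell_type: str) -> str:
    return f"{individual}.{cell_type}"


def split_sample_id(sample: str) -> tuple[str, str]:
    individual, _, cell_type = sample.rpartition(".")
    return individual, cell_type


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (ALT-allele counts) for a set of samples.

    ``dosages`` is samples x variants, float with NaN for missing calls.
    ``maf`` is computed from non-missing dosages; variants failing the
    MAF > 0.05 inclusion rule are flagged (``low_maf``), not dropped —
    mapping operations apply the filter.
    """

    samples: list[str]
    variants: pd.DataFrame  # columns: chrom, pos (0-based), ref, alt, id
    dosages: np.ndarray
    maf: np.ndarray = field(default=None)
    low_maf: np.ndarray = field(default=None)
    maf_threshold: float = 0.05

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or missing")
        if self.maf is None:
            self.maf = compute_maf(self.dosages)
        if self.low_maf is None:
            self.low_maf = self.maf <= self.maf_threshold

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor allele frequency per variant from non-missing 0/1/2 dosages."""
    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(alt_freq, 1.0 - alt_freq)


@dataclass
class PhenotypeMatrix:
    """Sample x feature quantitative matrix with genomic anchors.

    ``kind`` is one of expression / methylation / link_fraction. The anchor
    of a feature is the TSS for gene-level features and the site position for
    CpG features; ``anchor`` may be supplied explicitly, otherwise it
    defaults to the strand-aware start of the feature interval.
    """

    samples: list[str]
    features: pd.DataFrame  # columns: chrom, start, end, id, gene_id, strand [, anchor]
    values: np.ndarray
    kind: str

    def __post_init__(self):
        if self.kind not in PHENOTYPE_KINDS:
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        ids = self.features["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.kind == "methylation":
            bad = ~np.isnan(self.values) & ((self.values < 0) | (self.values > 1))
            if bad.any():
                culprit = ids.iloc[np.where(bad.any(axis=0))[0][0]]
                raise ValueError(
                    f"methylation beta-values outside [0,1] (feature {culprit!r})"
                )
        if "anchor" not in self.features.columns:
            plus = self.features["strand"].to_numpy() != "-"
            self.features = self.features.assign(
                anchor=np.where(plus, self.features["start"], self.features["end"] - 1)
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def anchors(self) -> np.ndarray:
        return self.features["anchor"].to_numpy()


@dataclass
class GeneModel:
    """Strand-aware gene with exons (0-based half-open intervals)."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        if any(s >= e for s, e in self.exons):
            raise ValueError(f"gene {self.gene_id}: empty exon interval")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost base on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def signed_distance(self, pos: int) -> int:
        """Signed bp from the TSS; positive = downstream in transcription direction."""
        d = pos - self.tss
        return d if self.strand == "+" else -d


class FeatureSet:
    """Named set of genomic intervals, point-queryable.

    Intervals are 0-based half-open; a point overlaps iff it lies inside one.
    """

    def __init__(self, name: str, intervals: Sequence[tuple[str, int, int]]):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for chrom, start, end in intervals:
            if end <= start:
                continue
            self._trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
            n += 1
        self.n_intervals = n

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlaps_point(int(pos))) if tree is not None else False

    def contains_many(self, chroms: Sequence[str], positions: Sequence[int]) -> np.ndarray:
        return np.array(
            [self.contains(c, p) for c, p in zip(chroms, positions)], dtype=bool
        )

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom, tree in self._trees.items():
            for iv in tree:
                out.append((chrom, iv.begin, iv.end))
        return sorted(out)


@dataclass
class RunConfig:
    """Pipeline-wide settings: cis windows per test family, FDR, permutations.

    Window defaults: 1 Mb around the TSS for genotype-vs-expression and
    genotype-vs-splicing tests, 5 kb around the CpG for genotype-vs-
    methylation, 50 kb around the TSS for methylation-vs-expression and
    methylation-vs-splicing.
    """

    window_eqtl: int = 1_000_000
    window_mqtl: int = 5_000
    window_eqtm: int = 50_000
    window_asqtl: int = 1_000_000
    window_asqtm: int = 50_000
    fdr: float = 0.10
    n_permutations: int = 1000
    adaptive_min_perm: int = 100
    adaptive_max_perm: int = 100_000
    maf_threshold: float = 0.05
    ase_min_reads: int = 30
    ase_sample_depth: int = 30
    ase_alpha: float = 0.005
    seed: int = 0

    def __post_init__(self):
        for name in ("window_eqtl", "window_mqtl", "window_eqtm",
                     "window_asqtl", "window_asqtm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0,1)")

    def window_for(self, family: str) -> int:
        return {
            "eqtl": self.window_eqtl,
            "mqtl": self.window_mqtl,
            "eqtm": self.window_eqtm,
            "asqtl": self.window_asqtl,
            "asqtm": self.window_asqtm,
        }[family]


ASSOCIATION_COLUMNS = [
    "feature_id",
    "gene_id",
    "regressor_id",
    "distance_to_anchor",
    "rho",
    "nominal_p",
    "empirical_p",
    "effect_size",
    "significant",
]
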
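"""Synthetic multi-tissue cohort generator with planted ground truth.

Emulates a newborn-cord cohort design: three cell types (fibroblast F,
lymphoblastoid L, T-cell T) sharing genotyped individuals, with planted
cis effects of genotype on expression (eQTL, in phenotype-SD units per
allele), of genotype on methylation (mQTL, logit scale), of methylation on
expression (eQTM, signed coupling), planted isoform-usage effects feeding
the splicing families, and allelic-count tables with reference bias and an
individual-dominant allele-specific-expression structure. Every planted
effect is registered in a truth table keyed by (family, gene/site,
regressor, tissue) so downstream recovery can be scored. All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt as math_sqrt

import numpy as np
import pandas as pd

from .links import InsertSizeDistribution, link_probability, unique_portions_by_exon
from .types import GeneModel, GenotypeMatrix, PhenotypeMatrix

DEFAULT_CELL_TYPES = ("F", "L", "T")


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic cohort.

    Sample sizes follow the emulated design: ~185 individuals for genotype
    tests, ~110 for methylation tests (the methylation assay covered fewer
    individuals). Effect sizes are in phenotype SD units per allele (eQTL),
    logit units per allele (mQTL), and logit units per expression SD (eQTM).
    """

    n_individuals: int = 185
    n_individuals_methylation: int = 110
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_genes: int = 100
    exons_per_gene: int = 3
    exon_len: int = 150
    intron_len: int = 5000
    gene_spacing: int = 2_500_000
    n_snps_per_gene: int = 20
    snp_span: int = 100_000
    maf_range: tuple[float, float] = (0.10, 0.50)
    frac_eqtl: float = 0.30
    eqtl_effect_choices: tuple[float, ...] = (0.25, 0.5, 1.0)
    eqtl_snp_tss_scale: float = 25_000.0  # eQTL SNPs concentrate near the TSS
    noise_sd: float = 1.0
    n_cpgs_per_gene: int = 2
    frac_mqtl: float = 0.30
    mqtl_effect_choices: tuple[float, ...] = (0.5, 1.0)
    frac_eqtm: float = 0.30
    eqtm_coupling: float = 1.0
    methyl_noise_sd: float = 0.5
    sharing_class_probs: tuple[float, float, float] = (0.45, 0.25, 0.30)
    ase_p0: float = 0.52
    ase_fraction: float = 0.20
    ase_individual_sd: float = 0.15
    ase_background_sd: float = 0.10
    ase_tissue_sd: float = 0.04
    ase_depth: int = 60
    ase_n_sites: int = 300
    insert_dist: dict = field(
        default_factory=lambda: {180: 0.25, 200: 0.50, 220: 0.25}
    )
    read_len: int = 49
    n_fragments: int = 300
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.05 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0.05, 0.5]")
        for name in ("n_individuals", "n_genes", "exons_per_gene",
                     "n_snps_per_gene", "ase_n_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def individual_ids(n: int) -> list[str]:
    return [f"ind{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Gene models and genotypes


def simulate_gene_models(spec: SimulationSpec, rng: np.random.Generator) -> dict[str, GeneModel]:
    """Toy genes on one chromosome, alternating strand, evenly spaced."""
    models = {}
    for g in range(spec.n_genes):
        origin = spec.gene_spacing * (g + 1)
        exons = [
            (
                origin + i * (spec.exon_len + spec.intron_len),
                origin + i * (spec.exon_len + spec.intron_len) + spec.exon_len,
            )
            for i in range(spec.exons_per_gene)
        ]
        strand = "+" if g % 2 == 0 else "-"
        gid = f"gene{g:04d}"
        models[gid] = GeneModel(gene_id=gid, chrom="chr1", strand=strand, exons=exons)
    return models


def simulate_genotypes(
    spec: SimulationSpec,
    gene_models: dict[str, GeneModel],
    rng: np.random.Generator,
    n_individuals: int | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes, shared across an individual's cell types.

    Each gene gets ``n_snps_per_gene`` SNPs placed uniformly within
    +/- ``snp_span`` of its TSS; dosages are Binomial(2, ALT frequency)
    draws with ALT frequency = the drawn MAF.
    """
    n = n_individuals or spec.n_individuals
    if n < 25:
        import logging

        logging.getLogger(__name__).warning(
            "n=%d is small for MAF resolution in (%.2f, %.2f)", n, *spec.maf_range
        )
    rows, dosage_cols = [], []
    bases = np.array(list("ACGT"))
    for gid, gm in gene_models.items():
        offsets = np.sort(
            rng.integers(-spec.snp_span, spec.snp_span + 1, size=spec.n_snps_per_gene)
        )
        mafs = rng.uniform(*spec.maf_range, size=spec.n_snps_per_gene)
        for k, (off, maf) in enumerate(zip(offsets, mafs)):
            ref, alt = rng.choice(bases, size=2, replace=False)
            rows.append(
                {
                    "chrom": gm.chrom,
                    "pos": int(gm.tss + off),
                    "ref": ref,
                    "alt": alt,
                    "id": f"{gid}_snp{k:03d}",
                }
            )
            dosage_cols.append(rng.binomial(2, maf, size=n).astype(float))
    variants = pd.DataFrame(rows)
    order = np.argsort(variants["pos"].to_numpy(), kind="stable")
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = np.stack(dosage_cols, axis=1)[:, order]
    return GenotypeMatrix(
        samples=individual_ids(n), variants=variants, dosages=dosages
    )


# ---------------------------------------------------------------------------
# Planted effect registry


def _draw_sharing(spec: SimulationSpec, rng: np.random.Generator) -> tuple[str, ...]:
    k = 1 + rng.choice(3, p=np.asarray(spec.sharing_class_probs))
    idx = rng.choice(len(spec.cell_types), size=k, replace=False)
    return tuple(spec.cell_types[i] for i in sorted(idx))


def plant_effects(
    spec: SimulationSpec,
    gene_models: dict[str, GeneModel],
    genotypes: GenotypeMatrix,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Effect registry: one row per (family, gene, regressor, tissue)."""
    rows = []
    snps_by_gene = {
        gid: genotypes.variants[
            genotypes.variants["id"].str.startswith(gid + "_")
        ]["id"].tolist()
        for gid in gene_models
    }
    pos_by_id = genotypes.variants.set_index("id")["pos"]
    for gid in gene_models:
        if rng.random() < spec.frac_eqtl:
            snps = snps_by_gene[gid]
            dist = np.abs(pos_by_id[snps].to_numpy() - gene_models[gid].tss)
            w = np.exp(-dist / spec.eqtl_snp_tss_scale)
            snp = rng.choice(snps, p=w / w.sum())
            beta = rng.choice(spec.eqtl_effect_choices) * rng.choice([-1, 1])
            for t in _draw_sharing(spec, rng):
                rows.append(
                    {"family": "eqtl", "gene_id": gid, "feature_id": f"{gid}_exon1",
                     "regressor_id": snp, "tissue": t, "effect": float(beta)}
                )
        for c in range(spec.n_cpgs_per_gene):
            cpg = f"{gid}_cpg{c}"
            if rng.random() < spec.frac_mqtl:
                snp = rng.choice(snps_by_gene[gid])
                beta = rng.choice(spec.mqtl_effect_choices) * rng.choice([-1, 1])
                for t in _draw_sharing(spec, rng):
                    rows.append(
                        {"family": "mqtl", "gene_id": gid, "feature_id": cpg,
                         "regressor_id": snp, "tissue": t, "effect": float(beta)}
                    )
            if rng.random() < spec.frac_eqtm:
                sign = rng.choice([-1.0, 1.0])
                for t in _draw_sharing(spec, rng):
                    rows.append(
                        {"family": "eqtm", "gene_id": gid,
                         "feature_id": f"{gid}_exon1", "regressor_id": cpg,
                         "tissue": t, "effect": float(sign * spec.eqtm_coupling)}
                    )
    return pd.DataFrame(
        rows, columns=["family", "gene_id", "feature_id", "regressor_id",
                       "tissue", "effect"]
    )


def _effects_lookup(truth: pd.DataFrame, family: str) -> dict:
    sub = truth[truth["family"] == family]
    out: dict = {}
    for row in sub.itertuples():
        out.setdefault((row.feature_id, row.tissue), []).append(
            (row.regressor_id, row.effect)
        )
    return out


# ---------------------------------------------------------------------------
# Expression and methylation


def simulate_expression(
    spec: SimulationSpec,
    gene_models: dict[str, GeneModel],
    genotypes: GenotypeMatrix,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, PhenotypeMatrix]:
    """Per-tissue expression: one gene-centric exon feature per gene.

    value = beta * dosage + N(0, residual SD), where the residual variance is
    shrunk by the planted genetic variance (b^2 * var(dosage)) so the total
    phenotype SD stays at ``noise_sd`` and the planted beta is recoverable in
    phenotype-SD units by the median-difference estimator. The effect is
    zeroed in tissues outside the planted sharing pattern.
    """
    snp_idx = pd.Series(
        np.arange(genotypes.n_variants), index=genotypes.variants["id"]
    )
    eff = _effects_lookup(truth, "eqtl")
    n = genotypes.n_samples
    feats = []
    for gid, gm in gene_models.items():
        s, e = gm.exons[0]
        feats.append(
            {"chrom": gm.chrom, "start": s, "end": e, "id": f"{gid}_exon1",
             "gene_id": gid, "strand": gm.strand, "anchor": gm.tss}
        )
    features = pd.DataFrame(feats)
    out = {}
    for t in spec.cell_types:
        vals = rng.normal(0.0, 1.0, size=(n, len(features)))
        for j, fid in enumerate(features["id"]):
            genetic_var = 0.0
            genetic = np.zeros(n)
            for snp, beta in eff.get((fid, t), []):
                dos = genotypes.dosages[:, snp_idx[snp]]
                genetic += beta * dos
                genetic_var += beta**2 * dos.var()
            resid_var = max(spec.noise_sd**2 - genetic_var, 0.04 * spec.noise_sd**2)
            vals[:, j] = genetic + vals[:, j] * math_sqrt(resid_var)
        out[t] = PhenotypeMatrix(
            samples=list(genotypes.samples), features=features.copy(),
            values=vals, kind="expression",
        )
    return out


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    spec: SimulationSpec,
    gene_models: dict[str, GeneModel],
    genotypes: GenotypeMatrix,
    expression: dict[str, PhenotypeMatrix],
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, PhenotypeMatrix]:
    """Per-tissue beta-values: inverse-logit of an additive latent.

    logit(beta) = a + b*dosage + c*scaled(expression) + N(0, sd); mQTL
    effects b and eQTM couplings c are taken from the truth registry and
    zeroed in non-carrier tissues. Sites sit within the mQTL window of
    their SNP and the 50 kb TSS window of their gene.
    """
    snp_idx = pd.Series(
        np.arange(genotypes.n_variants), index=genotypes.variants["id"]
    )
    mqtl = _effects_lookup(truth, "mqtl")
    eqtm = {}  # (cpg, tissue) -> coupling
    for row in truth[truth["family"] == "eqtm"].itertuples():
        eqtm[(row.regressor_id, row.tissue)] = row.effect
    n = genotypes.n_samples
    feats = []
    intercepts = []
    for gid, gm in gene_models.items():
        for c in range(spec.n_cpgs_per_gene):
            cpg = f"{gid}_cpg{c}"
            # place near the planted mQTL SNP when one exists (5 kb window),
            # otherwise near the TSS
            planted = [
                (s, b) for (fid, t), lst in mqtl.items() if fid == cpg
                for s, b in lst
            ]
            if planted:
                snp_pos = genotypes.variants.loc[
                    snp_idx[planted[0][0]], "pos"
                ]
                pos = int(snp_pos + rng.integers(-2000, 2001))
            else:
                pos = int(gm.tss + rng.integers(-20_000, 20_001))
            feats.append(
                {"chrom": gm.chrom, "start": pos, "end": pos + 1, "id": cpg,
                 "gene_id": gid, "strand": gm.strand, "anchor": pos}
            )
            intercepts.append(rng.uniform(-1.5, 1.5))
    features = pd.DataFrame(feats)
    out = {}
    for t in spec.cell_types:
        expr = expression[t]
        expr_scaled = (expr.values - expr.values.mean(axis=0)) / expr.values.std(
            axis=0, ddof=1
        )
        expr_col = pd.Series(
            np.arange(expr.n_features), index=expr.features["id"]
        )
        latent = rng.normal(0.0, spec.methyl_noise_sd, size=(n, len(features)))
        for j, (cpg, gid) in enumerate(zip(features["id"], features["gene_id"])):
            latent[:, j] += intercepts[j]
            for snp, b in mqtl.get((cpg, t), []):
                latent[:, j] += b * genotypes.dosages[:, snp_idx[snp]]
            c = eqtm.get((cpg, t))
            if c is not None:
                latent[:, j] += c * expr_scaled[:, expr_col[f"{gid}_exon1"]]
        out[t] = PhenotypeMatrix(
            samples=list(genotypes.samples), features=features.copy(),
            values=_invlogit(latent), kind="methylation",
        )
    return out


# ---------------------------------------------------------------------------
# Paired-read placement tables (splicing substrate)


def default_isoforms(gene: GeneModel) -> list[tuple[int, ...]]:
    """Full inclusion plus middle-exon skipping (genomic exon indices)."""
    n = len(gene.exons)
    if n < 3:
        return [tuple(range(n))]
    skip = n // 2
    return [tuple(range(n)), tuple(i for i in range(n) if i != skip)]


def _transcript_layout(gene: GeneModel, isoform: tuple[int, ...]):
    """Exon order and transcript offsets in transcription direction."""
    order = list(isoform) if gene.strand == "+" else list(isoform)[::-1]
    offsets, lens = [], []
    off = 0
    for i in order:
        s, e = gene.exons[i]
        offsets.append(off)
        lens.append(e - s)
        off += e - s
    return order, offsets, lens, off


def _map_read(
    gene: GeneModel, order, offsets, lens, t_start: int, t_end: int
) -> tuple[int, int, int] | None:
    """Map a transcript-interval read to (exon, genome start, genome end);
    None when the read spans a junction (unmappable without split mapping)."""
    for exon, off, ln in zip(order, offsets, lens):
        if t_start >= off and t_end <= off + ln:
            s, e = gene.exons[exon]
            local_s, local_e = t_start - off, t_end - off
            if gene.strand == "+":
                return exon, s + local_s, s + local_e
            return exon, e - local_e, e - local_s
    return None


def simulate_read_pairs(
    gene: GeneModel,
    usage: dict[str, float],
    insert_dist: InsertSizeDistribution,
    read_len: int,
    n_fragments: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Paired-read placements for one gene across samples.

    ``usage`` maps sample -> probability of the skipping isoform (the last
    isoform of :func:`default_isoforms`). Inserts longer than the chosen
    transcript are redrawn (counted); reads that would span an exon-exon
    junction make the whole pair unmappable and it is dropped (counted).
    Returns the placement table and a QC dict with per-sample counts.
    """
    isoforms = default_isoforms(gene)
    layouts = [_transcript_layout(gene, iso) for iso in isoforms]
    rows = []
    qc = {"n_redrawn": 0, "n_junction_dropped": 0}
    for sample, p_skip in usage.items():
        p_iso = np.array([1.0 - p_skip, p_skip]) if len(isoforms) == 2 else np.array([1.0])
        iso_draws = rng.choice(len(isoforms), size=n_fragments, p=p_iso)
        for iso in iso_draws:
            order, offsets, lens, L = layouts[iso]
            for _ in range(100):
                size = int(rng.choice(insert_dist.sizes, p=insert_dist.probs))
                if size <= L:
                    break
                qc["n_redrawn"] += 1
            else:
                continue
            f = int(rng.integers(0, L - size + 1))
            r1 = _map_read(gene, order, offsets, lens, f, f + read_len)
            r2 = _map_read(gene, order, offsets, lens, f + size - read_len, f + size)
            if r1 is None or r2 is None:
                qc["n_junction_dropped"] += 1
                continue
            rows.append(
                {
                    "sample": sample, "chrom": gene.chrom,
                    "r1_start": r1[1], "r1_end": r1[2],
                    "r2_start": r2[1], "r2_end": r2[2],
                }
            )
    return pd.DataFrame(rows), qc


def expected_link_counts(
    gene: GeneModel,
    isoform_usage: dict[tuple[int, ...], float],
    insert_dist: InsertSizeDistribution,
    read_len: int,
) -> dict[tuple[int, int], float]:
    """Exact expected link frequencies per fragment, by enumeration.

    For each isoform, insert size (renormalised to sizes that fit the
    transcript) and fragment start, the placement is classified exactly as
    the counting stage would classify the simulated pair: both reads fully
    inside single exons, each overlapping its exon's unique portion, the two
    exons different. Keys are genomic exon-index pairs (a < b).
    """
    portions = unique_portions_by_exon(gene)
    local = {
        i: [(s - gene.exons[i][0], e - gene.exons[i][0]) for s, e in portions[i]]
        for i in portions
    }
    expected: dict[tuple[int, int], float] = {}
    for isoform, u in isoform_usage.items():
        if u == 0:
            continue
        order, offsets, lens, L = _transcript_layout(gene, isoform)
        fit = insert_dist.sizes <= L
        mass = insert_dist.probs[fit] / insert_dist.probs[fit].sum()
        for size, pm in zip(insert_dist.sizes[fit], mass):
            n_total = L - size + 1
            for f in range(n_total):
                e1 = _exon_of(order, offsets, lens, local, f, f + read_len)
                e2 = _exon_of(
                    order, offsets, lens, local, f + size - read_len, f + size
                )
                if e1 is None or e2 is None or e1 == e2:
                    continue
                key = (min(e1, e2), max(e1, e2))
                expected[key] = expected.get(key, 0.0) + u * pm / n_total
    return expected


def _exon_of(order, offsets, lens, local, t_start, t_end):
    for exon, off, ln in zip(order, offsets, lens):
        if t_start >= off and t_end <= off + ln:
            ls, le = t_start - off, t_end - off
            if any(ls < ue and le > us for us, ue in local[exon]):
                return exon
            return None
    return None


def expected_link_fractions(
    gene: GeneModel,
    isoform_usage: dict[tuple[int, ...], float],
    insert_dist: InsertSizeDistribution,
    read_len: int,
    direction: str = "forward",
) -> dict[tuple[int, int], float]:
    """Truth link fractions: expected counts -> coverage -> fractions.

    Runs the enumeration oracle through the same coverage division and
    primary-exon normalisation the estimator applies.
    """
    counts = expected_link_counts(gene, isoform_usage, insert_dist, read_len)
    portions = unique_portions_by_exon(gene)
    local = {
        i: [(s - gene.exons[i][0], e - gene.exons[i][0]) for s, e in portions[i]]
        for i in portions
    }
    exon_lens = [e - s for s, e in gene.exons]
    cov = {}
    for (a, b), cnt in counts.items():
        five, three = (a, b) if gene.strand == "+" else (b, a)
        prob = link_probability(
            exon_lens[five], local[five], exon_lens[three], local[three],
            insert_dist, read_len,
        )
        if prob > 0:
            cov[(a, b)] = cnt / prob
    fractions = {}
    for (a, b), c in cov.items():
        five, three = (a, b) if gene.strand == "+" else (b, a)
        prim = five if direction == "forward" else three
        denom = 0.0
        for (a2, b2), c2 in cov.items():
            f2, t2 = (a2, b2) if gene.strand == "+" else (b2, a2)
            p2 = f2 if direction == "forward" else t2
            if p2 == prim:
                denom += c2
        fractions[(a, b)] = c / denom
    return fractions


# ---------------------------------------------------------------------------
# Allelic counts


def simulate_allelic_counts(
    spec: SimulationSpec,
    rng: np.random.Generator,
    n_individuals: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample REF/TOTAL counts at shared heterozygous sites.

    Every (individual, site) carries a baseline allelic shift shared across
    cell types (phase-driven genetic background, SD ``ase_background_sd``);
    ASE sites add a larger individual-specific shift (SD
    ``ase_individual_sd``); cell types add a smaller tissue-specific
    component (SD ``ase_tissue_sd``). Because the individual components
    dominate the tissue component, allelic-ratio distances order
    same-individual < same-cell-type < different. REF counts are binomial
    around the reference-bias probability p0 plus these shifts. Returns
    (records, truth) where truth flags the ASE sites.
    """
    n = n_individuals or spec.n_individuals
    inds = individual_ids(n)
    bases = np.array(list("ACGT"))
    is_ase = rng.random(spec.ase_n_sites) < spec.ase_fraction
    site_meta = []
    for s in range(spec.ase_n_sites):
        ref, alt = rng.choice(bases, size=2, replace=False)
        site_meta.append(("chr1", 1000 + 100 * s, ref, alt))
    ind_shift = rng.normal(
        0.0, spec.ase_background_sd, size=(n, spec.ase_n_sites)
    ) + np.where(
        is_ase[None, :],
        rng.normal(0.0, spec.ase_individual_sd, size=(n, spec.ase_n_sites)),
        0.0,
    )
    tissue_shift = rng.normal(
        0.0, spec.ase_tissue_sd, size=(len(spec.cell_types), spec.ase_n_sites)
    )
    rows = []
    for i, ind in enumerate(inds):
        for t, ct in enumerate(spec.cell_types):
            p = np.clip(spec.ase_p0 + ind_shift[i] + tissue_shift[t], 0.02, 0.98)
            refs = rng.binomial(spec.ase_depth, p)
            for s, (chrom, pos, ref, alt) in enumerate(site_meta):
                rows.append(
                    (ind, ct, chrom, pos, ref, alt, int(refs[s]), spec.ase_depth)
                )
    records = pd.DataFrame(
        rows,
        columns=["individual", "cell_type", "chrom", "pos", "ref", "alt",
                 "ref_count", "total_count"],
    )
    truth = pd.DataFrame(
        {
            "chrom": [m[0] for m in site_meta],
            "pos": [m[1] for m in site_meta],
            "is_ase": is_ase,
        }
    )
    return records, truth


# ---------------------------------------------------------------------------
# Cohort orchestrator


@dataclass
class Cohort:
    spec: SimulationSpec
    gene_models: dict[str, GeneModel]
    genotypes: GenotypeMatrix
    expression: dict[str, PhenotypeMatrix]
    methylation: dict[str, PhenotypeMatrix]
    truth: pd.DataFrame


def simulate_cohort(spec: SimulationSpec) -> Cohort:
    """Full deterministic cohort under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    gene_models = simulate_gene_models(spec, rng)
    genotypes = simulate_genotypes(spec, gene_models, rng)
    truth = plant_effects(spec, gene_models, genotypes, rng)
    expression = simulate_expression(spec, gene_models, genotypes, truth, rng)
    methylation = simulate_methylation(
        spec, gene_models, genotypes, expression, truth, rng
    )
    return Cohort(
        spec=spec, gene_models=gene_models, genotypes=genotypes,
        expression=expression, methylation=methylation, truth=truth,
    )
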
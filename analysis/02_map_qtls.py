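"""Map cis associations in each tissue for three test families.

Reads the simulated cohort from results/cohort/ and runs Spearman cis
mapping with the family-specific windows (eQTL: genotype vs expression,
1 Mb around the TSS; mQTL: genotype vs methylation, 5 kb around the CpG;
eQTM: methylation vs expression, 50 kb around the TSS), then applies the
1000-permutation gene/site-level threshold at 10% FDR. Genotype tests use
all 185 individuals; methylation tests use the 110-individual assay subset.
Association records with significance flags and effect sizes go to
results/associations/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tissueqtl import association as assoc
from tissueqtl import io
from tissueqtl.effects import genotype_effect_size, methylation_effect_size
from tissueqtl.types import GenotypeMatrix, PhenotypeMatrix, RunConfig

N_METHYLATION = 110


def _subset(obj, n):
    """First-n-samples view of a genotype or phenotype matrix."""
    if isinstance(obj, GenotypeMatrix):
        return GenotypeMatrix(
            samples=obj.samples[:n], variants=obj.variants,
            dosages=obj.dosages[:n], maf=obj.maf, low_maf=obj.low_maf,
        )
    return PhenotypeMatrix(
        samples=obj.samples[:n], features=obj.features,
        values=obj.values[:n], kind=obj.kind,
    )

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20260930


def _attach_effects(records, regressors, phenotypes, kind):
    reg_vals, reg_ids = regressors
    reg_idx = pd.Series(np.arange(len(reg_ids)), index=reg_ids)
    feat_idx = pd.Series(
        np.arange(phenotypes.n_features), index=phenotypes.features["id"]
    )
    effects = []
    for row in records.itertuples():
        y = phenotypes.values[:, feat_idx[row.feature_id]]
        x = reg_vals[:, reg_idx[row.regressor_id]]
        try:
            if kind == "genotype":
                effects.append(genotype_effect_size(y, x))
            else:
                effects.append(methylation_effect_size(y, x))
        except ValueError:
            effects.append(np.nan)
    return records.assign(effect_size=effects)


def main() -> None:
    cfg = RunConfig(seed=SEED)
    cohort_dir = BASE / "cohort"
    out = BASE / "associations"
    out.mkdir(parents=True, exist_ok=True)

    genotypes = io.read_genotypes(cohort_dir / "genotypes.vcf")
    gene_models = {
        g.gene_id: g for g in io.read_gene_models_bed12(cohort_dir / "genes.bed12")
    }
    tissues = ("F", "L", "T")
    summary = []
    for tissue in tissues:
        expr = io.read_phenotypes(
            cohort_dir / f"expression_{tissue}.bed", "expression",
            samples=genotypes.samples,
        )
        meth = io.read_phenotypes(
            cohort_dir / f"methylation_{tissue}.bed", "methylation",
            samples=genotypes.samples,
        )
        gt_m = _subset(genotypes, N_METHYLATION)
        expr_m = _subset(expr, N_METHYLATION)
        meth_m = _subset(meth, N_METHYLATION)
        families = {
            "eqtl": (genotypes, expr, gene_models, cfg.window_eqtl, "tss", "genotype"),
            "mqtl": (gt_m, meth_m, None, cfg.window_mqtl, "feature", "genotype"),
            "eqtm": (meth_m, expr_m, gene_models, cfg.window_eqtm, "tss", "methylation"),
        }
        for fi, (family, (reg, phen, gm_, window, anchor, kind)) in enumerate(
            families.items()
        ):
            rng = np.random.default_rng(
                SEED + 100 * fi + list(tissues).index(tissue)
            )
            records = assoc.map_cis(reg, phen, gm_, window, anchor)
            unit = "gene_id" if family in ("eqtl", "eqtm") else "feature_id"
            res = assoc.fixed_permutation_threshold(
                reg, phen, gm_, window, anchor, unit_col=unit,
                n_perm=cfg.n_permutations, fdr=cfg.fdr, rng=rng, records=records,
            )
            sig_units = set(res.significant_units)
            records["significant"] = (
                records[unit].isin(sig_units)
                & (records["nominal_p"] <= res.threshold)
            )
            if kind == "genotype":
                reg_pack = (reg.dosages, reg.variants["id"])
            else:
                reg_pack = (reg.values, reg.features["id"])
            records = _attach_effects(records, reg_pack, phen, kind)
            io.write_associations(
                records, out / f"{family}_{tissue}.tsv", seed=SEED,
                config={"family": family, "tissue": tissue, "window": window,
                        "fdr": cfg.fdr, "threshold": res.threshold},
            )
            summary.append(
                {"family": family, "tissue": tissue,
                 "tested_pairs": len(records),
                 "significant_units": len(sig_units),
                 "nominal_threshold": res.threshold}
            )
            print(f"{family} {tissue}: {len(sig_units)} significant units "
                  f"(threshold {res.threshold:.3g}, {len(records)} pairs)")
    pd.DataFrame(summary).to_csv(out / "summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
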
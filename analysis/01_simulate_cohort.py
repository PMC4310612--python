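"""Simulate the three-cell-type cohort and write its files.

Generates 185 genotyped individuals with 100 genes, planted eQTL/mQTL/eQTM
effects and their tissue-sharing pattern (the cohort is enriched for
planted eQTLs so the gene-level permutation scheme has discoveries to
summarise at this scale), and writes VCF genotypes, BED12 gene models,
per-tissue expression and methylation BEDs, an allelic-count table and the
planted-truth registry under results/cohort/.
"""

from pathlib import Path

import numpy as np

from tissueqtl import io
from tissueqtl import simulate as sim

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20260930


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = sim.SimulationSpec(
        n_individuals=185, n_genes=100, frac_eqtl=0.6, seed=SEED
    )
    cohort = sim.simulate_cohort(spec)

    io.write_genotypes_vcf(cohort.genotypes, OUT / "genotypes.vcf")
    io.write_gene_models_bed12(list(cohort.gene_models.values()), OUT / "genes.bed12")
    for tissue in spec.cell_types:
        io.write_phenotypes(cohort.expression[tissue], OUT / f"expression_{tissue}.bed")
        io.write_phenotypes(cohort.methylation[tissue], OUT / f"methylation_{tissue}.bed")
    cohort.truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)

    ase_records, ase_truth = sim.simulate_allelic_counts(
        sim.SimulationSpec(n_individuals=50, ase_n_sites=300, seed=SEED),
        np.random.default_rng(SEED + 1),
    )
    ase_records.to_csv(OUT / "allelic_counts.tsv", sep="\t", index=False)
    ase_truth.to_csv(OUT / "ase_truth.tsv", sep="\t", index=False)

    print(f"cohort written to {OUT}")
    print(f"  individuals: {spec.n_individuals}, genes: {spec.n_genes}")
    print(f"  planted effects: {len(cohort.truth)} "
          f"({cohort.truth.family.value_counts().to_dict()})")


if __name__ == "__main__":
    main()
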
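"""Cross-tissue sharing of the mapped associations.

For each test family, compares every tissue pair: pi1 (fraction of the
first tissue's significant pairs replicating in the second's p-value
distribution), effect-size R² over the union and the shared set, percent of
sign-discordant shared pairs, and the 1/2/3-tissue sharing-class table.
Writes results/sharing/.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from tissueqtl import io
from tissueqtl.effects import all_pairwise_sharing, sharing_class_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = BASE / "sharing"
    out.mkdir(parents=True, exist_ok=True)
    tissues = ("F", "L", "T")
    rows = []
    class_tables = []
    for family in ("eqtl", "mqtl", "eqtm"):
        records = {
            t: io.read_associations(BASE / "associations" / f"{family}_{t}.tsv")
            for t in tissues
        }
        for summary in all_pairwise_sharing(records):
            d = asdict(summary)
            d["family"] = family
            rows.append(d)
            print(
                f"{family} {summary.tissue_a}-{summary.tissue_b}: "
                f"pi1={summary.pi1_a_in_b:.2f}/{summary.pi1_b_in_a:.2f} "
                f"R2 union={summary.r2_union:.2f} shared={summary.r2_shared:.2f} "
                f"discordant={summary.pct_discordant:.1f}%"
            )
        ct = sharing_class_table(records)
        ct["family"] = family
        class_tables.append(ct)
    pd.DataFrame(rows).to_csv(out / "pairwise_sharing.tsv", sep="\t", index=False)
    pd.concat(class_tables).to_csv(out / "sharing_classes.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
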
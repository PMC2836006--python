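#!/usr/bin/env python
"""Within-family age analysis: subfamily divergence vs. class tag density.

For Alu and L1, each subfamily's mean element-to-consensus divergence
(an insertion-age proxy) is correlated with its length-normalised active
and repressive tag densities.  Writes subfamily_age.tsv and
age_correlations.tsv under results/demo/.
"""

from pathlib import Path

import pandas as pd

from temark import pipeline
from temark.age_distance import age_density_correlation, subfamily_age_table
from temark.cli import _class_pools, _load_run_inputs
from temark.io_formats import write_table

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def main() -> None:
    config, _sizes, tes, _genes, libraries, _gl = _load_run_inputs(OUT)
    active, repressive = _class_pools(OUT, libraries)
    table = subfamily_age_table(tes, active, repressive, families=config.age_families)
    write_table(table, OUT / "subfamily_age.tsv")
    rows = []
    for fam in config.age_families:
        sub = table[table["family"] == fam]
        for klass in ("active", "repressive"):
            corr = age_density_correlation(sub, klass)
            rows.append(pipeline._corr_row(corr, family=fam, klass=klass))
            print(f"{fam} {klass}: divergence-density rho = {corr.coefficient:+.2f} "
                  f"over {corr.n} subfamilies (p = {corr.p:.2g})")
    write_table(pd.DataFrame(rows), OUT / "age_correlations.tsv")


if __name__ == "__main__":
    main()
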
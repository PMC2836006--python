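#!/usr/bin/env python
"""Classify each modification active or repressive by expression enrichment.

For every modification, the expression of genes whose promoters carry it
is compared with genes whose promoters do not: a fold above 1 marks an
active modification, below 1 a repressive one.  Writes
results/demo/classification.tsv.
"""

from pathlib import Path

from temark.cli import _load_run_inputs
from temark.io_formats import read_table, write_table
from temark.promoters import classify_modifications

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def main() -> None:
    config, _sizes, _tes, genes, _libs, _gl = _load_run_inputs(OUT)
    calls = read_table(OUT / "calls.tsv", required=["gene_id", "modification", "present"])
    by_mod = {m: sub for m, sub in calls.groupby("modification")}
    table = classify_modifications(by_mod, genes, log_scale=config.log_scale_expression)
    write_table(table, OUT / "classification.tsv")
    n_active = int((table["klass"] == "active").sum())
    print(f"{n_active} active / {len(table) - n_active} repressive modifications")
    ranked = table.sort_values("fold", ascending=False)
    top, bottom = ranked.iloc[0], ranked.iloc[-1]
    print(f"strongest active: {top['modification']} (fold {top['fold']:.2f}); "
          f"strongest repressive: {bottom['modification']} (fold {bottom['fold']:.2f})")
    print(f"-> {OUT / 'classification.tsv'}")


if __name__ == "__main__":
    main()
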
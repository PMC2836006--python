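#!/usr/bin/env python
"""Call each histone modification present/absent in every gene promoter.

Promoters are 1,000 bp upstream to 200 bp downstream of the TSS; a
modification is present when the promoter tag count reaches the
Bonferroni-corrected Poisson threshold for the library's genomic
background rate.  Writes results/demo/calls.tsv.
"""

from pathlib import Path

import pandas as pd

from temark.cli import _load_run_inputs
from temark.io_formats import write_table
from temark.promoters import call_presence, count_tags_in_intervals, define_promoters

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def main() -> None:
    config, sizes, _tes, genes, libraries, genome_length = _load_run_inputs(OUT)
    promoters = define_promoters(genes, sizes, up=config.promoter_up, down=config.promoter_down)
    n_tests = len(promoters) * len(libraries)
    frames = []
    for mod, lib in libraries.items():
        counts = count_tags_in_intervals(lib, promoters)
        frames.append(call_presence(counts, promoters, lib, genome_length,
                                    alpha=config.alpha, n_tests=n_tests))
    calls = pd.concat(frames, ignore_index=True)
    write_table(calls, OUT / "calls.tsv")
    frac = calls["present"].mean()
    thr = calls["threshold"].mode().iat[0]
    print(f"{len(calls):,} promoter x modification tests "
          f"(Bonferroni over {n_tests:,}); typical presence threshold {thr} tags")
    print(f"{int(calls['present'].sum()):,} present calls "
          f"({100 * frac:.1f}%) -> {OUT / 'calls.tsv'}")


if __name__ == "__main__":
    main()
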
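import numpy as np
import pandas as pd
import pytest

from temark.io_formats import TagLibrary
from temark.models import Gene, GenomeModel, TEInsertion


def make_tags(positions, chrom="chr1", modification="H3K4me3", unique=True):
    """Build a TagLibrary from raw positions (helper for hand-built fixtures)."""
    pos = np.asarray(positions, dtype=np.int64)
    uniq = np.full(len(pos), unique) if isinstance(unique, bool) else np.asarray(unique, bool)
    df = pd.DataFrame({
        "chrom": chrom if isinstance(chrom, str) else list(chrom),
        "pos": pos,
        "strand": "+",
        "unique": uniq,
    })
    return TagLibrary(modification=modification, tags=df)


@pytest.fixture
def tiny_genome():
    """A hand-built 200 kb single-chromosome genome with two genes and four TEs."""
    genes = [
        Gene("gA", "chr1", 50_000, "+", 50_000, 60_000, 8.0),
        Gene("gB", "chr1", 120_000, "-", 110_000, 120_001, 2.0),
    ]
    tes = [
        TEInsertion("chr1", 10_000, 10_300, "+", "Alu", "AluY", 2.0),
        TEInsertion("chr1", 30_000, 30_300, "-", "Alu", "AluSx", 9.0),
        TEInsertion("chr1", 55_000, 55_800, "+", "L1", "L1HS", 1.5),
        TEInsertion("chr1", 150_000, 150_250, "+", "MIR", "MIRb", 20.0),
    ]
    return GenomeModel(chromosomes=[("chr1", 200_000)], te_insertions=tes, genes=genes)
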
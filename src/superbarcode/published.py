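"""Published comparison inputs shipped with the package.

The pairwise base-difference counts among the nine *Echinacea* chloroplast
genomes, as printed in the source comparison (data/echinacea_diff_counts.tsv),
are a valid analysis input in their own right: a distance tree built from them
tests species delimitation without any sequence download.
"""

from __future__ import annotations

import numpy as np

from .divergence import DiffMatrix

__all__ = ["echinacea_diff_matrix", "ECHINACEA_ALIGNMENT_LENGTH"]

#: approximate whole-genome alignment length behind the printed percentages
#: (the genomes are 151,837-151,935 bp); only the scale, never the topology,
#: depends on it
ECHINACEA_ALIGNMENT_LENGTH = 152_000


def echinacea_diff_matrix() -> DiffMatrix:
    """The printed 9x9 pairwise base-difference count matrix."""
    from importlib.resources import files

    import pandas as pd

    path = files("superbarcode").joinpath("data/echinacea_diff_counts.tsv")
    df = pd.read_csv(str(path), sep="\t", comment="#", index_col=0)
    counts = df.to_numpy(dtype=np.int64)
    taxa = list(df.index)
    denom = np.full(counts.shape, float(ECHINACEA_ALIGNMENT_LENGTH))
    percents = np.round(100.0 * counts / denom, 2)
    return DiffMatrix(
        taxa=taxa,
        counts=counts,
        percents=percents,
        denominator_mode="alignment_length",
        denominators=denom,
    )
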
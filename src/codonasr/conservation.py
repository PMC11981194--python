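"""Per-column information content for sequence-logo style conservation plots.

For each alignment column the observed symbol frequencies f (gaps excluded,
no pseudocount) give the entropy H = -sum f log2 f; the column information
content is IC = log2(|alphabet|) - H, and each symbol contributes
f(symbol) * IC bits.  An all-gap column is undefined under a zero
pseudocount and is emitted as zeros with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import DNA, GAP, PROTEIN, Alignment

logger = logging.getLogger(__name__)

_SYMBOLS = {
    DNA: tuple("ACGT"),
    PROTEIN: tuple("ACDEFGHIKLMNPQRSTVWY"),
}


def information_matrix(aln: Alignment, alphabet: str | None = None) -> pd.DataFrame:
    """Information-content matrix (columns x symbols, in bits).

    Rows are 1-based alignment columns; cell (c, s) holds
    f_c(s) * (log2 |alphabet| - H_c).  Ambiguity symbols (N/X) and gaps are
    excluded from the frequencies.
    """
    alphabet = alphabet or aln.alphabet
    if alphabet not in _SYMBOLS:
        raise ValueError(f"no logo alphabet defined for {alphabet!r}")
    symbols = _SYMBOLS[alphabet]
    idx = {s: i for i, s in enumerate(symbols)}
    max_bits = np.log2(len(symbols))
    out = np.zeros((aln.n_columns, len(symbols)))
    warned = False
    for j in range(aln.n_columns):
        counts = np.zeros(len(symbols))
        for c in aln.column(j):
            if c in idx:
                counts[idx[c]] += 1
        total = counts.sum()
        if total == 0:
            if not warned:
                logger.warning("all-gap column %d emitted as zeros (pseudocount=0)", j + 1)
                warned = True
            continue
        f = counts / total
        nz = f > 0
        entropy = -np.sum(f[nz] * np.log2(f[nz]))
        out[j] = f * (max_bits - entropy)
    return pd.DataFrame(out, index=pd.RangeIndex(1, aln.n_columns + 1, name="column"),
                        columns=list(symbols))
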
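"""Count and FPKM normalization.

Tag counts are scaled to tags per million (TPM): ``tpm = count / N * 1e6``
where N is the library total.  FPKM matrices are log2-transformed with a
recorded pseudocount.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, FpkmMatrix, TpmMatrix

__all__ = ["tpm_normalize", "log2_transform"]


def tpm_normalize(counts: CountMatrix) -> TpmMatrix:
    """Scale each library to tags per million of its total mapped tags.

    Raises ``ValueError`` naming the offending library if any library size
    is zero (or negative).
    """
    sizes = counts.library_sizes
    bad = sizes[sizes <= 0]
    if len(bad):
        raise ValueError(f"zero or negative library size for library {bad.index[0]!r}")
    tpm = counts.counts.astype(float).div(sizes, axis=1) * 1e6
    return TpmMatrix(tpm)


def log2_transform(fpkm: FpkmMatrix | pd.DataFrame, pseudocount: float = 1.0) -> FpkmMatrix:
    """Return an :class:`FpkmMatrix` whose log2 view uses ``pseudocount``.

    ``log2_values = log2(fpkm + pseudocount)``; zeros stay finite whenever
    ``pseudocount > 0``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    df = fpkm.fpkm if isinstance(fpkm, FpkmMatrix) else fpkm
    if (np.asarray(df) < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return FpkmMatrix(df.copy(), pseudocount=pseudocount)
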
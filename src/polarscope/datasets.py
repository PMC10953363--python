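"""Bundled reference tables.

``myeloid_activation_log2fc`` returns the published mean log2 fold
changes (each polarized subtype vs. the unstimulated MØ control) for the
20 cell-surface proteins of the GO term "myeloid cell activation involved
in immune response" from a four-subtype primary human macrophage
surfaceome study.  It is a compact, real-valued input for demonstrating
threshold-based polarity classification.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["myeloid_activation_log2fc"]

_MYELOID_ROWS = [
    # gene, M1, M2a, M2c (mean log2FC vs MØ)
    ("CR1", -3.02, 0.58, -3.36),
    ("ITGAL", 0.66, -0.84, -4.02),
    ("ITGAM", -1.51, 0.69, -2.26),
    ("CD44", -1.31, -0.86, -1.78),
    ("CD58", -0.59, -0.73, -1.43),
    ("CD63", 1.44, -0.60, 1.48),
    ("LAMP2", 0.36, -0.64, 1.43),
    ("SLC2A3", 0.89, -0.61, -1.42),
    ("IGF2R", 1.04, -0.48, -0.58),
    ("NCSTN", -0.46, -0.05, -0.52),
    ("GLIPR1", 0.07, 1.08, 0.08),
    ("C5AR1", -1.83, -2.05, 0.79),
    ("FCGR2A", -1.42, -2.99, 1.12),
    ("NFAM1", 0.22, -1.31, -0.36),
    ("PTPRC", -0.79, -1.35, -0.56),
    ("CYBB", -0.49, -2.16, -0.07),
    ("DSC1", -0.65, -0.91, 1.06),
    ("PTPRJ", -1.02, -0.34, -0.16),
    ("MILR1", -1.37, -0.85, 0.50),
    ("ADAM10", -1.13, -0.11, 0.80),
]


def myeloid_activation_log2fc() -> pd.DataFrame:
    """Mean log2FC (M1/M2a/M2c vs MØ) for 20 myeloid-activation surface proteins."""
    return pd.DataFrame(
        [(m1, m2a, m2c) for _, m1, m2a, m2c in _MYELOID_ROWS],
        index=pd.Index([g for g, *_ in _MYELOID_ROWS], name="gene"),
        columns=["M1", "M2a", "M2c"],
    )
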
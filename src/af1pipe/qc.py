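"""Replicate-reproducibility QC on log-scale normalized counts."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .diffexpr import compute_size_factors


def qc_replicate_correlation(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series | None = None,
    r2_floor: float = 0.95,
) -> pd.DataFrame:
    """Pairwise R^2 of log2(normalized count + 1) within each condition.

    R^2 is the squared Pearson correlation across genes for every replicate
    pair of a condition; pairs below ``r2_floor`` are flagged. Conditions
    with a single replicate are skipped.
    """
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    sf = size_factors.loc[counts.columns].to_numpy(float)
    logn = np.log2(counts.to_numpy(float) / sf[None, :] + 1.0)
    col_idx = {s: i for i, s in enumerate(counts.columns)}

    rows = []
    for (cl, tr), g in design.groupby(["cell_line", "treatment"]):
        ids = [s for s in g["sample_id"] if s in col_idx]
        if len(ids) < 2:
            continue
        for a, b in itertools.combinations(ids, 2):
            r = np.corrcoef(logn[:, col_idx[a]], logn[:, col_idx[b]])[0, 1]
            rows.append(
                {
                    "cell_line": cl,
                    "treatment": tr,
                    "sample_a": a,
                    "sample_b": b,
                    "r2": r**2,
                    "flagged": bool(r**2 < r2_floor),
                }
            )
    return pd.DataFrame(rows)
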
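"""Estrogen-progestin co-regulation calls: synergy, antagonism, modulation.

All fold changes are anchored at vehicle within one cell line. A gene is
called ``SYNERGY`` when the combined treatment is significant against
vehicle (BH-adjusted genome-wide), against E2 alone and against R5020 alone
(raw p on the secondary contrasts, which condition on an already-discovered
gene), its magnitude exceeds both single-agent magnitudes by the gain
factor (default 1.2x), and its sign matches the stronger single agent. Among E2-regulated genes the combined
response is ``ANTAG_REVERSED`` when its sign flips relative to E2 alone and
``ANTAG_ATTENUATED`` when it retains the sign but loses more than the loss
factor (default falls below 0.8x). A combined per-gene caller evaluates
synergy first and emits exactly one call, which makes the
synergy/antagonism calls mutually exclusive by construction.

``assess_e2_modulation`` compares the E2 response between the EV and
PR-expressing lines to quantify repression of estrogen-regulated genes by
the unliganded receptor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .taxonomy import Thresholds

INTERPLAY_COLUMNS = [
    "gene_id",
    "call",
    "lfc_e2",
    "lfc_r",
    "lfc_combo",
    "padj_combo_veh",
    "p_combo_e2",
    "p_combo_r",
    "padj_e2",
]


def is_synergy(
    lfc_e2: float,
    lfc_r: float,
    lfc_combo: float,
    padj_combo_veh: float,
    p_combo_e2: float,
    p_combo_r: float,
    th: Thresholds | None = None,
) -> bool:
    """Synergy predicate: three significances + magnitude + sign agreement."""
    th = th or Thresholds()
    significant = (
        padj_combo_veh < th.alpha_regulated
        and p_combo_e2 < th.secondary_p
        and p_combo_r < th.secondary_p
    )
    if not significant:
        return False
    strongest = lfc_e2 if abs(lfc_e2) >= abs(lfc_r) else lfc_r
    if strongest == 0.0:
        return False
    magnitude = abs(lfc_combo) > th.interplay_gain * max(abs(lfc_e2), abs(lfc_r))
    return magnitude and np.sign(lfc_combo) == np.sign(strongest)


def classify_antagonism(
    lfc_e2: float,
    lfc_combo: float,
    padj_e2: float,
    th: Thresholds | None = None,
) -> str:
    """Antagonism call for one E2-regulated gene: REVERSED, ATTENUATED or NONE."""
    th = th or Thresholds()
    if not padj_e2 < th.alpha_regulated:
        raise ValueError("antagonism applies to E2-regulated genes only")
    if lfc_e2 == 0.0:
        return "AMBIGUOUS"
    if np.sign(lfc_combo) != np.sign(lfc_e2):
        return "ANTAG_REVERSED"
    if abs(lfc_combo) < th.interplay_loss * abs(lfc_e2):
        return "ANTAG_ATTENUATED"
    return "NONE"


def call_interplay(
    e2_de: pd.DataFrame,
    r_de: pd.DataFrame,
    combo_de: pd.DataFrame,
    combo_vs_e2_de: pd.DataFrame,
    combo_vs_r_de: pd.DataFrame,
    th: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-gene interplay calls within one cell line.

    Inputs are DE tables for the five contrasts (E2 vs VEH, R5020 vs VEH,
    E2+R5020 vs VEH, E2+R5020 vs E2, E2+R5020 vs R5020), each BH-adjusted
    within its own contrast. Exactly one call per gene: SYNERGY takes
    precedence, antagonism is evaluated only for E2-regulated genes, all
    others are NONE.
    """
    th = th or Thresholds()
    merged = e2_de[["gene_id", "log2FoldChange", "padj"]].rename(
        columns={"log2FoldChange": "lfc_e2", "padj": "padj_e2"}
    )
    for de, lfc_name, p_col, p_name in (
        (r_de, "lfc_r", "padj", "padj_r"),
        (combo_de, "lfc_combo", "padj", "padj_combo_veh"),
        (combo_vs_e2_de, "lfc_combo_e2", "pvalue", "p_combo_e2"),
        (combo_vs_r_de, "lfc_combo_r", "pvalue", "p_combo_r"),
    ):
        merged = merged.merge(
            de[["gene_id", "log2FoldChange", p_col]].rename(
                columns={"log2FoldChange": lfc_name, p_col: p_name}
            ),
            on="gene_id",
            how="inner",
        )

    calls = []
    for _, g in merged.iterrows():
        if is_synergy(
            g["lfc_e2"],
            g["lfc_r"],
            g["lfc_combo"],
            g["padj_combo_veh"],
            g["p_combo_e2"],
            g["p_combo_r"],
            th,
        ):
            calls.append("SYNERGY")
        elif g["padj_e2"] < th.alpha_regulated and g["lfc_e2"] != 0.0:
            calls.append(classify_antagonism(g["lfc_e2"], g["lfc_combo"], g["padj_e2"], th))
        else:
            calls.append("NONE")
    merged["call"] = calls
    return merged[INTERPLAY_COLUMNS]


def assess_e2_modulation(
    e2_in_ev: pd.DataFrame,
    e2_in_prb: pd.DataFrame,
    th: Thresholds | None = None,
) -> pd.DataFrame:
    """Flag how the PR-expressing line modulates each EV E2-regulated gene.

    Ratio ``q = lfc_PRB / lfc_EV`` on same-sign responses: REPRESSED when
    q < interplay_loss, ENHANCED when q > interplay_gain, otherwise NEUTRAL.
    Opposite signs count as maximal repression. Genes whose EV fold change
    sits at the engine's pseudo-floor (lfc 0) are flagged AMBIGUOUS.
    """
    th = th or Thresholds()
    merged = e2_in_ev.merge(e2_in_prb, on="gene_id", suffixes=("_ev", "_prb"))
    reg = merged[merged["padj_ev"] < th.alpha_regulated].copy() if "padj_ev" in merged else None
    if reg is None:
        raise ValueError("merged DE tables lack padj columns")
    flags = []
    for _, g in reg.iterrows():
        lfc_ev = g["log2FoldChange_ev"]
        lfc_prb = g["log2FoldChange_prb"]
        if lfc_ev == 0.0:
            flags.append("AMBIGUOUS")
            continue
        if np.sign(lfc_prb) != np.sign(lfc_ev):
            flags.append("REPRESSED")
            continue
        q = lfc_prb / lfc_ev
        if q < th.interplay_loss:
            flags.append("REPRESSED")
        elif q > th.interplay_gain:
            flags.append("ENHANCED")
        else:
            flags.append("NEUTRAL")
    out = reg[["gene_id"]].copy()
    out["flag"] = flags
    out["lfc_ev"] = reg["log2FoldChange_ev"].to_numpy()
    out["lfc_prb"] = reg["log2FoldChange_prb"].to_numpy()
    return out.reset_index(drop=True)
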
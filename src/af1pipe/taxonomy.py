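"""Mutant-vs-wild-type regulation taxonomy and ligand-independent gene calls.

Given per-gene DE results for the same treatment contrast in the wild-type
receptor line and in a mutant line, each wild-type-regulated gene
(padj < ``alpha_regulated``) is placed in exactly one category by a decision
ladder on the mutant significance and on the ratio of log2 fold changes
``r = lfc_mut / lfc_wt``:

1. ``LOST``                mutant padj > alpha_lost (regulation not retained)
2. ``OPPOSITE``            retained but sign(lfc_mut) != sign(lfc_wt)
3. ``HYPO``                r < hypo_ratio            (default < 0.8)
4. ``INTERMEDIATE_LOW``    hypo_ratio <= r < band lo (default [0.8, 0.9))
5. ``UNAFFECTED``          r within the band         (default [0.9, 1.1])
6. ``INTERMEDIATE_HIGH``   band hi < r <= hyper_ratio (default (1.1, 1.2])
7. ``HYPER``               r > hyper_ratio           (default > 1.2)

The ratio is taken on log2 fold changes, anchored by the convention that a
0.7-vs-1.05 log2FC pair is a 33% reduction. The intermediate bands make the
partition exhaustive: the plain ">20% hypo" and "<10% unaffected" rules
alone would leave a 10-20% band unclassified. Genes significant in the
mutant but not the wild type are the complementary ``GAINED`` set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = (
    "LOST",
    "OPPOSITE",
    "HYPO",
    "INTERMEDIATE_LOW",
    "UNAFFECTED",
    "INTERMEDIATE_HIGH",
    "HYPER",
)

ATTENUATED_CATEGORIES = ("LOST", "HYPO", "INTERMEDIATE_LOW")

TAXONOMY_COLUMNS = [
    "gene_id",
    "category",
    "lfc_wt",
    "lfc_mut",
    "ratio",
    "padj_wt",
    "padj_mut",
]


@dataclass(frozen=True)
class Thresholds:
    """Significance and fold-change-band thresholds for all classifiers."""

    alpha_regulated: float = 0.05   # padj: a gene counts as regulated
    alpha_lost: float = 0.1         # padj above this in the mutant: LOST
    relaxed_p: float = 0.01         # raw p for the relaxed ligand-independent tier
    hypo_ratio: float = 0.8         # r below this: HYPO (>20% weaker)
    hyper_ratio: float = 1.2        # r above this: HYPER (>20% stronger)
    unaffected_low: float = 0.9     # |band| within 10% of wild type
    unaffected_high: float = 1.1
    interplay_gain: float = 1.2     # combo must exceed 1.2x both single agents
    interplay_loss: float = 0.8     # combo below 0.8x E2 alone: antagonized
    secondary_p: float = 0.05       # raw p for combo-vs-single-agent contrasts

    def __post_init__(self):
        if not 0 < self.alpha_regulated <= self.alpha_lost < 1:
            raise ValueError("need 0 < alpha_regulated <= alpha_lost < 1")
        if not self.hypo_ratio < 1 < self.hyper_ratio:
            raise ValueError("need hypo_ratio < 1 < hyper_ratio")
        if not (
            self.hypo_ratio <= self.unaffected_low < 1 < self.unaffected_high <= self.hyper_ratio
        ):
            raise ValueError("unaffected band must lie inside (hypo_ratio, hyper_ratio)")


def call_regulated(de: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Genes with padj strictly below alpha, sorted by gene_id."""
    if "padj" not in de.columns:
        raise ValueError("DE result lacks padj")
    hits = de.loc[de["padj"] < alpha, "gene_id"]
    return sorted(hits)


def classify_mutant_effect(
    lfc_wt: float,
    lfc_mut: float,
    padj_wt: float,
    padj_mut: float,
    th: Thresholds | None = None,
) -> str:
    """Classify one wild-type-regulated gene's behaviour in the mutant line."""
    th = th or Thresholds()
    if not padj_wt < th.alpha_regulated:
        raise ValueError("classification applies to wild-type-regulated genes only")
    if lfc_wt == 0.0:
        return "AMBIGUOUS"
    if not padj_mut <= th.alpha_lost:
        return "LOST"
    if np.sign(lfc_mut) != np.sign(lfc_wt):
        return "OPPOSITE"
    r = lfc_mut / lfc_wt
    if r < th.hypo_ratio:
        return "HYPO"
    if r < th.unaffected_low:
        return "INTERMEDIATE_LOW"
    if r <= th.unaffected_high:
        return "UNAFFECTED"
    if r <= th.hyper_ratio:
        return "INTERMEDIATE_HIGH"
    return "HYPER"


def classify_mutant_table(
    wt_de: pd.DataFrame,
    mut_de: pd.DataFrame,
    th: Thresholds | None = None,
) -> pd.DataFrame:
    """Taxonomy table over all wild-type-regulated genes.

    Joins the two DE tables on gene_id, restricts to genes with
    ``padj_wt < alpha_regulated``, and emits exactly one category per gene.
    """
    th = th or Thresholds()
    merged = wt_de.merge(mut_de, on="gene_id", suffixes=("_wt", "_mut"))
    reg = merged[merged["padj_wt"] < th.alpha_regulated].copy()
    rows = []
    for _, g in reg.iterrows():
        lfc_wt = g["log2FoldChange_wt"]
        lfc_mut = g["log2FoldChange_mut"]
        category = classify_mutant_effect(lfc_wt, lfc_mut, g["padj_wt"], g["padj_mut"], th)
        same_sign = lfc_wt != 0 and np.sign(lfc_mut) == np.sign(lfc_wt)
        rows.append(
            {
                "gene_id": g["gene_id"],
                "category": category,
                "lfc_wt": lfc_wt,
                "lfc_mut": lfc_mut,
                "ratio": lfc_mut / lfc_wt if same_sign else np.nan,
                "padj_wt": g["padj_wt"],
                "padj_mut": g["padj_mut"],
            }
        )
    return pd.DataFrame(rows, columns=TAXONOMY_COLUMNS)


def call_gained(
    wt_de: pd.DataFrame,
    mut_de: pd.DataFrame,
    th: Thresholds | None = None,
) -> list[str]:
    """Genes regulated by the mutant (padj < alpha) but not by the wild type."""
    th = th or Thresholds()
    merged = wt_de.merge(mut_de, on="gene_id", suffixes=("_wt", "_mut"))
    mask = (merged["padj_mut"] < th.alpha_regulated) & ~(
        merged["padj_wt"] < th.alpha_regulated
    )
    return sorted(merged.loc[mask, "gene_id"])


def call_ligand_independent(
    de_prb_vs_ev_vehicle: pd.DataFrame,
    th: Thresholds | None = None,
    tier: str = "STRICT",
) -> pd.DataFrame:
    """Genes regulated by unliganded receptor (PR-line vs EV, both vehicle).

    ``STRICT`` uses padj < alpha_regulated; ``RELAXED`` uses raw
    p < relaxed_p. Since BH guarantees padj >= p, the strict set is a subset
    of the relaxed set whenever ``relaxed_p >= ...`` holds gene-wise.
    Returns a DataFrame (gene_id, direction) with direction up/down by lfc
    sign, sorted by gene_id.
    """
    th = th or Thresholds()
    de = de_prb_vs_ev_vehicle
    if tier == "STRICT":
        mask = de["padj"] < th.alpha_regulated
    elif tier == "RELAXED":
        mask = de["pvalue"] < th.relaxed_p
    else:
        raise ValueError("tier must be STRICT or RELAXED")
    hits = de.loc[mask, ["gene_id", "log2FoldChange"]].copy()
    hits["direction"] = np.where(hits["log2FoldChange"] >= 0, "up", "down")
    return (
        hits[["gene_id", "direction"]]
        .sort_values("gene_id", ignore_index=True)
    )


def summarize_taxonomy(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Category counts and fractions over the classified (regulated) genes."""
    n = len(taxonomy)
    counts = taxonomy["category"].value_counts()
    rows = [
        {
            "category": cat,
            "count": int(counts.get(cat, 0)),
            "fraction": (counts.get(cat, 0) / n) if n else 0.0,
        }
        for cat in CATEGORIES + ("AMBIGUOUS",)
    ]
    return pd.DataFrame(rows)
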
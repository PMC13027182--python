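"""Factorial experimental design: cell lines x hormone treatments x replicates.

The study design is a 4 x 4 factorial in MCF-7-derived lines: an empty-vector
control (EV, no progesterone receptor) and three PR-B expressing lines (WT,
and the AF1 triple mutants FFF and QQQ), each treated with vehicle, the
progestin R5020, estradiol (E2), or both hormones (E2R). RNA-Seq uses
biological duplicates per condition; ChIP-Seq uses biological triplicates.
"""

from __future__ import annotations

import itertools

import pandas as pd

CELL_LINES = ("EV", "WT", "FFF", "QQQ")
TREATMENTS = ("VEH", "R5020", "E2", "E2R")
ASSAYS = ("RNA", "CHIP")

DESIGN_COLUMNS = ["sample_id", "cell_line", "treatment", "replicate", "assay"]


def factorial_design(
    assay: str = "RNA",
    n_replicates: int = 2,
    cell_lines: tuple[str, ...] = CELL_LINES,
    treatments: tuple[str, ...] = TREATMENTS,
) -> pd.DataFrame:
    """Build a sample sheet for a full factorial design.

    Sample ids are ``{assay}_{cell}_{treatment}_r{rep}``, deterministic and
    unique by construction.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = [
        {
            "sample_id": f"{assay}_{cl}_{tr}_r{rep}",
            "cell_line": cl,
            "treatment": tr,
            "replicate": rep,
            "assay": assay,
        }
        for cl, tr, rep in itertools.product(
            cell_lines, treatments, range(1, n_replicates + 1)
        )
    ]
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def validate_design(design: pd.DataFrame, min_replicates: int | None = None) -> None:
    """Raise ValueError on a malformed sample sheet."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design sheet missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dupes = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids: {dupes}")
    bad_cl = set(design["cell_line"]) - set(CELL_LINES)
    if bad_cl:
        raise ValueError(f"unknown cell lines: {sorted(bad_cl)}")
    bad_tr = set(design["treatment"]) - set(TREATMENTS)
    if bad_tr:
        raise ValueError(f"unknown treatments: {sorted(bad_tr)}")
    bad_assay = set(design["assay"]) - set(ASSAYS)
    if bad_assay:
        raise ValueError(f"unknown assays: {sorted(bad_assay)}")
    if (design["replicate"] < 1).any():
        raise ValueError("replicate indices must be positive")
    if min_replicates is not None:
        counts = design.groupby(["cell_line", "treatment"]).size()
        low = counts[counts < min_replicates]
        if len(low):
            raise ValueError(
                f"conditions with fewer than {min_replicates} replicates: "
                f"{low.index.tolist()}"
            )


def condition_labels(design: pd.DataFrame) -> pd.Series:
    """Per-sample condition label ``cell_line:treatment`` (indexed by sample_id)."""
    lab = design["cell_line"].str.cat(design["treatment"], sep=":")
    lab.index = design["sample_id"].to_numpy()
    return lab


def samples_for(design: pd.DataFrame, cell_line: str, treatment: str) -> list[str]:
    mask = (design["cell_line"] == cell_line) & (design["treatment"] == treatment)
    return design.loc[mask, "sample_id"].tolist()
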
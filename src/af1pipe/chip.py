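"""ChIP-Seq consensus peaks, TSS profiling, differential binding, integration.

All intervals are 0-based half-open on the BED convention. The consensus
rule is base-pair majority coverage: positions covered by at least
``min_support`` replicate peak sets are kept, merged into maximal runs, and
runs shorter than ``min_width`` are discarded. Peak position for distance
and annotation purposes is the interval midpoint. Signed peak-TSS distance
is orientation-corrected: positive means the peak lies upstream of the TSS
in the gene's transcriptional direction.

Differential occupancy reuses the negative-binomial Wald engine on per-peak
fragment counts; integration assigns each differential peak to its nearest
TSS within a window and summarizes how the associated genes behave in the
mutant-regulation taxonomy (the occupancy/transactivation uncoupling
summary). ``qpcr_enrichment`` implements the comparative-Ct percent-input
calculation used to validate binding at single loci.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import ContrastSpec, run_de
from .taxonomy import ATTENUATED_CATEGORIES

PEAK_COLUMNS = ["chrom", "start", "end"]


def sort_and_merge(peaks: pd.DataFrame) -> pd.DataFrame:
    """Sort intervals by (chrom, start) and merge overlapping/adjacent ones."""
    out = []
    for chrom, sub in peaks.groupby("chrom"):
        arr = sub[["start", "end"]].to_numpy(np.int64)
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        merged: list[list[int]] = []
        for a, b in arr:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([int(a), int(b)])
        for a, b in merged:
            out.append({"chrom": chrom, "start": a, "end": b})
    return (
        pd.DataFrame(out, columns=PEAK_COLUMNS)
        .sort_values(["chrom", "start"], ignore_index=True)
        .astype({"start": np.int64, "end": np.int64})
    )


def build_consensus(
    replicate_peaks: list[pd.DataFrame],
    min_support: int = 2,
    min_width: int = 50,
) -> pd.DataFrame:
    """Consensus peak set by per-base replicate support.

    Each replicate set is sorted and merged individually, then base pairs
    covered by >= ``min_support`` replicates are retained as maximal runs;
    runs shorter than ``min_width`` are dropped. The output is sorted,
    non-overlapping and half-open.
    """
    if len(replicate_peaks) < 1:
        raise ValueError("need at least one replicate peak set")
    if not 1 <= min_support <= len(replicate_peaks):
        raise ValueError(
            f"min_support={min_support} outside [1, {len(replicate_peaks)} replicates]"
        )
    merged_reps = [sort_and_merge(p) for p in replicate_peaks]
    chroms = sorted({c for rep in merged_reps for c in rep["chrom"].unique()})
    out = []
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for rep in merged_reps:
            sub = rep[rep["chrom"] == chrom]
            for a, b in sub[["start", "end"]].to_numpy():
                events.append((int(a), 1))
                events.append((int(b), -1))
        if not events:
            continue
        pos = np.array(sorted(e[0] for e in events))
        # coverage change at each breakpoint
        deltas: dict[int, int] = {}
        for p, d in events:
            deltas[p] = deltas.get(p, 0) + d
        uniq = np.unique(pos)
        cov = np.cumsum([deltas[p] for p in uniq])
        run_start = None
        for i, p in enumerate(uniq):
            covered = cov[i] >= min_support
            if covered and run_start is None:
                run_start = p
            elif not covered and run_start is not None:
                if uniq[i] - run_start >= min_width:
                    out.append({"chrom": chrom, "start": int(run_start), "end": int(uniq[i])})
                run_start = None
        # coverage always returns to 0 after the last breakpoint
    res = pd.DataFrame(out, columns=PEAK_COLUMNS)
    if len(res) == 0:
        return res.astype({"start": np.int64, "end": np.int64}, errors="ignore")
    return res.sort_values(["chrom", "start"], ignore_index=True).astype(
        {"start": np.int64, "end": np.int64}
    )


def nearest_tss(
    peaks: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Assign each peak to its nearest TSS by midpoint distance.

    Ties break to the lexicographically lower gene_id. Peaks on chromosomes
    absent from the annotation get ``gene_id = ''`` and NaN distance.
    Returns a per-peak DataFrame with gene_id, distance (absolute bp) and
    ``signed_distance`` (positive = peak upstream of the TSS in gene
    orientation).
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    results = []
    ann_by_chrom = {
        chrom: sub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for chrom, sub in annotation.groupby("chrom")
    }
    for _, p in peaks.iterrows():
        center = (int(p["start"]) + int(p["end"])) // 2
        sub = ann_by_chrom.get(p["chrom"])
        if sub is None:
            results.append({"gene_id": "", "distance": np.nan, "signed_distance": np.nan})
            continue
        tss = sub["tss"].to_numpy(np.int64)
        d = np.abs(tss - center)
        best = d.min()
        cand = np.flatnonzero(d == best)
        # ties: lower gene_id
        gidx = cand[np.argmin(sub["gene_id"].to_numpy()[cand])]
        g = sub.iloc[gidx]
        signed = (g["tss"] - center) if g["strand"] == "+" else (center - g["tss"])
        results.append(
            {"gene_id": g["gene_id"], "distance": int(best), "signed_distance": int(signed)}
        )
    out = peaks.reset_index(drop=True).copy()
    assign = pd.DataFrame(results)
    return pd.concat([out, assign], axis=1)


def tss_distance_profile(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    bins: np.ndarray | list[int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of signed peak-TSS distances over the given bin edges.

    Returns ``(per_peak_assignment, histogram)``; the histogram has one row
    per bin plus an ``unassigned`` row for peaks on chromosomes missing from
    the annotation, and its counts sum to the number of peaks (out-of-range
    distances are clipped into the terminal bins).
    """
    assign = nearest_tss(peaks, annotation)
    edges = np.asarray(bins, dtype=float)
    assigned = assign["signed_distance"].dropna().to_numpy(float)
    clipped = np.clip(assigned, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    rows = [
        {"bin_low": edges[i], "bin_high": edges[i + 1], "count": int(counts[i])}
        for i in range(len(counts))
    ]
    rows.append(
        {
            "bin_low": np.nan,
            "bin_high": np.nan,
            "count": int(assign["signed_distance"].isna().sum()),
        }
    )
    return assign, pd.DataFrame(rows)


def tss_enrichment_ratio(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    genome_length: int,
    window: int = 5_000,
) -> float:
    """Peak density inside +/-window of the nearest TSS vs outside.

    Density is peaks per base pair, with the inside span taken as the merged
    TSS-window footprint and the outside span as the rest of the genome.
    """
    assign = nearest_tss(peaks, annotation)
    inside = (assign["distance"] <= window).sum()
    outside = (assign["distance"] > window).sum()
    # merged footprint of the windows
    span = 0
    for _, sub in annotation.groupby("chrom"):
        tss = np.sort(sub["tss"].to_numpy(np.int64))
        lo, hi = tss - window, tss + window
        cur_lo, cur_hi = lo[0], hi[0]
        for a, b in zip(lo[1:], hi[1:]):
            if a <= cur_hi:
                cur_hi = max(cur_hi, b)
            else:
                span += cur_hi - cur_lo
                cur_lo, cur_hi = a, b
        span += cur_hi - cur_lo
    outside_span = genome_length - span
    if inside == 0 or outside_span <= 0 or span <= 0:
        return np.nan
    if outside == 0:
        return np.inf
    return (inside / span) / (outside / outside_span)


def annotate_regions(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    promoter_upstream: int = 2_000,
    promoter_downstream: int = 500,
) -> pd.Series:
    """Classify each peak midpoint as promoter, gene_body or intergenic.

    The promoter window is [TSS - upstream, TSS + downstream) in the gene's
    orientation; precedence is promoter > gene_body > intergenic across all
    genes.
    """
    if promoter_upstream <= 0 or promoter_downstream <= 0:
        raise ValueError("promoter window sizes must be positive")
    promoters: dict[str, list[tuple[int, int]]] = {}
    bodies: dict[str, list[tuple[int, int]]] = {}
    for _, g in annotation.iterrows():
        if g["strand"] == "+":
            pa, pb = g["tss"] - promoter_upstream, g["tss"] + promoter_downstream
        else:
            pa, pb = g["tss"] - promoter_downstream + 1, g["tss"] + promoter_upstream + 1
        promoters.setdefault(g["chrom"], []).append((int(pa), int(pb)))
        bodies.setdefault(g["chrom"], []).append((int(g["start"]), int(g["end"])))

    def _covered(intervals: list[tuple[int, int]] | None, x: int) -> bool:
        if not intervals:
            return False
        return any(a <= x < b for a, b in intervals)

    labels = []
    for _, p in peaks.iterrows():
        center = (int(p["start"]) + int(p["end"])) // 2
        if _covered(promoters.get(p["chrom"]), center):
            labels.append("promoter")
        elif _covered(bodies.get(p["chrom"]), center):
            labels.append("gene_body")
        else:
            labels.append("intergenic")
    return pd.Series(labels, index=peaks.index, name="feature")


def differential_binding(
    peak_counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: ContrastSpec,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential occupancy test on per-peak counts via the NB engine.

    Returns ``(full DE table, significant subset)`` with the significant set
    at ``padj < fdr``; the direction is the sign of the log2 fold change
    (positive = greater occupancy in the numerator condition).
    """
    de = run_de(peak_counts, design, contrast)
    de = de.rename(columns={"gene_id": "peak_id"})
    sig = de[de["padj"] < fdr].copy()
    return de, sig


def integrate_expression(
    db_peaks: pd.DataFrame,
    peak_locations: pd.DataFrame,
    annotation: pd.DataFrame,
    taxonomy: pd.DataFrame,
    window: int = 50_000,
) -> tuple[pd.DataFrame, dict]:
    """Associate differential peaks with the regulation taxonomy.

    ``db_peaks`` is the significant differential-binding table (peak_id,
    log2FoldChange, padj); ``peak_locations`` maps peak_id to chrom/start/
    end. Each peak is assigned to its nearest TSS within ``window`` bp; the
    summary reports the fraction of differential peaks associated with
    wild-type-regulated genes (those present in the taxonomy) and, among
    those, the fraction in attenuated categories (LOST, HYPO,
    INTERMEDIATE_LOW) and per-category counts.
    """
    if len(taxonomy) == 0:
        raise ValueError("empty taxonomy")
    if len(db_peaks) == 0:
        empty = pd.DataFrame(
            columns=[
                "peak_id",
                "gene_id",
                "signed_distance",
                "db_log2fc",
                "db_fdr",
                "regulation_category",
            ]
        )
        summary = {
            "n_differential_peaks": 0,
            "n_associated": 0,
            "frac_associated": 0.0,
            "n_attenuated": 0,
            "frac_attenuated_among_associated": 0.0,
            "category_counts": {},
        }
        return empty, summary

    located = db_peaks.drop(columns=["chrom", "start", "end"], errors="ignore").merge(
        peak_locations[["peak_id", "chrom", "start", "end"]], on="peak_id"
    )
    assign = nearest_tss(located, annotation)
    assign["in_window"] = assign["distance"] <= window
    cat = taxonomy.set_index("gene_id")["category"]
    records = []
    for _, p in assign.iterrows():
        gene = p["gene_id"] if p["in_window"] else ""
        category = cat.get(gene, "") if gene else ""
        records.append(
            {
                "peak_id": p["peak_id"],
                "gene_id": gene,
                "signed_distance": p["signed_distance"] if gene else np.nan,
                "db_log2fc": p["log2FoldChange"],
                "db_fdr": p["padj"],
                "regulation_category": category,
            }
        )
    rec = pd.DataFrame(records)
    associated = rec[rec["regulation_category"] != ""]
    n_assoc = len(associated)
    n_atten = int(associated["regulation_category"].isin(ATTENUATED_CATEGORIES).sum())
    counts = associated["regulation_category"].value_counts().to_dict()
    summary = {
        "n_differential_peaks": int(len(rec)),
        "n_associated": n_assoc,
        "frac_associated": n_assoc / len(rec),
        "n_attenuated": n_atten,
        "frac_attenuated_among_associated": (n_atten / n_assoc) if n_assoc else 0.0,
        "category_counts": {k: int(v) for k, v in sorted(counts.items())},
    }
    return rec, summary


def qpcr_enrichment(
    ct_ip_treated: float,
    ct_input_treated: float,
    ct_ip_vehicle: float,
    ct_input_vehicle: float,
    input_fraction: float = 0.01,
) -> float:
    """ChIP-qPCR fold enrichment over vehicle by the comparative-Ct method.

    Percent input per condition is
    ``100 * 2^((ct_input - log2(1/input_fraction)) - ct_ip)`` (the input Ct
    is first adjusted for the fraction of lysate reserved as input); the
    fold enrichment is the treated-to-vehicle ratio of percent inputs.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    for ct in (ct_ip_treated, ct_input_treated, ct_ip_vehicle, ct_input_vehicle):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    adjust = np.log2(1.0 / input_fraction)
    pct_treated = 100.0 * 2.0 ** ((ct_input_treated - adjust) - ct_ip_treated)
    pct_vehicle = 100.0 * 2.0 ** ((ct_input_vehicle - adjust) - ct_ip_vehicle)
    return pct_treated / pct_vehicle
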
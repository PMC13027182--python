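"""Synthetic factorial RNA-Seq and ChIP-Seq data with known ground truth.

Every downstream stage of the pipeline (NB differential expression, the
mutant-regulation taxonomy, hormone-interplay calls, and ChIP integration) is
exercised against fixtures produced here, so that recovery can be measured
against a truth table rather than against irreproducible external data.

Gene archetypes
---------------
Each simulated gene carries one archetype that fully determines the expected
log2 shift of its mean count in every (cell_line, treatment) cell of the
factorial design:

``NULL``
    no response anywhere.
``LIGAND_UP`` / ``LIGAND_DOWN``
    progestin (R5020) response of fixed sign in every PR-expressing line.
``ATTENUATED_FFF``
    R5020 response; the FFF mutant line retains only ``attenuation_factor``
    of the wild-type log2 effect (hypoactive AF1).
``HYPER_QQQ``
    R5020 response; the QQQ mutant line shows ``hyper_factor`` times the
    wild-type log2 effect (hyperactive AF1).
``LIGAND_INDEP_UP`` / ``LIGAND_INDEP_DOWN``
    constitutive shift (``lfc_li``) of PR-expressing lines relative to EV,
    present under every treatment (unliganded-receptor activity). The QQQ
    mutation abolishes ligand-independent up-regulation but not
    down-regulation, mirroring the distinct mechanism of unliganded activity.
``E2_ONLY``
    estradiol response in every line (ER alpha is endogenous); an optional
    ``e2_mod_factor`` < 1 models repression of the E2 response by unliganded
    PR in the receptor-expressing lines.
``SYNERGY``
    equal E2 and R5020 responses; the combined treatment exceeds either
    single agent by ``synergy_factor`` on the log2 scale.
``ANTAG_ATTEN``
    E2 response whose combined-treatment effect is shrunk to
    ``antag_atten_factor`` of the E2-alone effect.
``ANTAG_REVERSED``
    E2 response whose combined-treatment effect flips sign
    (``antag_reversed_factor`` < 0), driven by an opposing R5020 response.

Counts are negative binomial with ``Var = mu + alpha * mu^2``; ``alpha = 0``
degenerates to Poisson. Each gene consumes an independent, counter-derived
random substream, so enlarging a fixture never perturbs the draws of
previously simulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import validate_design

ARCHETYPES = (
    "NULL",
    "LIGAND_UP",
    "LIGAND_DOWN",
    "ATTENUATED_FFF",
    "HYPER_QQQ",
    "LIGAND_INDEP_UP",
    "LIGAND_INDEP_DOWN",
    "E2_ONLY",
    "SYNERGY",
    "ANTAG_ATTEN",
    "ANTAG_REVERSED",
)

PR_LINES = ("WT", "FFF", "QQQ")

TRUTH_COLUMNS = [
    "gene_id",
    "archetype",
    "base_mean",
    "lfc_r5020",
    "lfc_e2",
    "lfc_combo",
    "lfc_li",
    "attenuation_factor",
    "hyper_factor",
    "e2_mod_factor",
    "dispersion",
]

PEAK_TRUTH_COLUMNS = [
    "peak_id",
    "chrom",
    "start",
    "end",
    "occupancy",
    "is_differential",
    "log2fc_occupancy",
    "target_gene_id",
    "near_tss",
]

# Fixed offsets keeping the simulator's independent substreams apart.
_STREAM_SIZE_FACTORS = 1_000_003
_STREAM_TRUTH = 2_000_003
_STREAM_ANNOTATION = 3_000_003
_STREAM_CHIP = 4_000_003
_STREAM_GENES = 5_000_000  # gene i uses substream _STREAM_GENES + i
_STREAM_PEAKS = 8_000_000


@dataclass
class EffectConfig:
    """Effect-size settings for the truth-table generator.

    Magnitudes are log2 fold changes. Defaults model strongly responsive
    primary hormone target genes (4-8 fold), so that recovery tests measure
    classifier behaviour rather than borderline detection power; see the
    methods note for the power analysis behind this choice.
    """

    lfc_low: float = 2.0
    lfc_high: float = 3.0
    lfc_li_low: float = 1.5       # ligand-independent archetypes
    lfc_li_high: float = 2.5
    attenuation_factor: float = 0.5
    hyper_factor: float = 1.5
    synergy_factor: float = 1.5
    antag_atten_factor: float = 0.6
    antag_reversed_factor: float = -0.5
    antag_r5020_factor: float = -0.75  # R5020-alone response of reversed genes
    e2_mod_factor: float = 1.0         # <1: unliganded PR represses E2 response
    e2_mod_fraction: float = 0.0       # fraction of E2_ONLY genes modulated
    base_mean_log2_mean: float = 9.0   # ~500 counts at the median
    base_mean_log2_sd: float = 2.5
    base_mean_min: float = 20.0
    # Effect-carrying genes are floored higher: curated regulated-gene sets
    # are detection-conditioned, and a strong down-regulation of a gene at
    # ~30 baseline counts is statistically invisible at replicate depth 2-3,
    # so such genes cannot occur in the lists the archetypes emulate.
    base_mean_min_effect: float = 150.0
    dispersion: float = 0.05


def generate_truth(
    n_genes: int,
    archetype_fractions: dict[str, float],
    effect_config: EffectConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a truth table of gene archetypes and effect sizes.

    Archetype counts follow the requested proportions by largest-remainder
    rounding, so they match to rounding error exactly and sum to ``n_genes``.
    Identical ``(n_genes, fractions, config, seed)`` give identical tables.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    unknown = set(archetype_fractions) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    total = sum(archetype_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"archetype fractions sum to {total}, expected 1")
    cfg = effect_config or EffectConfig()

    names = sorted(archetype_fractions)
    quotas = np.array([archetype_fractions[a] * n_genes for a in names])
    counts = np.floor(quotas).astype(int)
    remainder = n_genes - int(counts.sum())
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1

    rng = np.random.default_rng([seed, _STREAM_TRUTH])
    rows: list[dict] = []
    gi = 0
    for name, k in zip(names, counts):
        for _ in range(k):
            rows.append(_draw_gene(f"g{gi:05d}", name, cfg, rng))
            gi += 1
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return truth.sort_values("gene_id", ignore_index=True)


def _draw_gene(gene_id: str, archetype: str, cfg: EffectConfig, rng) -> dict:
    floor = cfg.base_mean_min if archetype == "NULL" else max(
        cfg.base_mean_min, cfg.base_mean_min_effect
    )
    base_mean = float(
        max(floor, 2.0 ** rng.normal(cfg.base_mean_log2_mean, cfg.base_mean_log2_sd))
    )
    mag = float(rng.uniform(cfg.lfc_low, cfg.lfc_high))
    mag_li = float(rng.uniform(cfg.lfc_li_low, cfg.lfc_li_high))
    sign = float(rng.choice([-1.0, 1.0]))
    modulated = bool(rng.uniform() < cfg.e2_mod_fraction)

    row = dict.fromkeys(TRUTH_COLUMNS, 0.0)
    row.update(
        gene_id=gene_id,
        archetype=archetype,
        base_mean=base_mean,
        attenuation_factor=1.0,
        hyper_factor=1.0,
        e2_mod_factor=1.0,
        dispersion=cfg.dispersion,
    )
    if archetype == "LIGAND_UP":
        row["lfc_r5020"] = mag
    elif archetype == "LIGAND_DOWN":
        row["lfc_r5020"] = -mag
    elif archetype == "ATTENUATED_FFF":
        row["lfc_r5020"] = sign * mag
        row["attenuation_factor"] = cfg.attenuation_factor
    elif archetype == "HYPER_QQQ":
        row["lfc_r5020"] = sign * mag
        row["hyper_factor"] = cfg.hyper_factor
    elif archetype == "LIGAND_INDEP_UP":
        row["lfc_li"] = mag_li
    elif archetype == "LIGAND_INDEP_DOWN":
        row["lfc_li"] = -mag_li
    elif archetype == "E2_ONLY":
        row["lfc_e2"] = sign * mag
        row["lfc_combo"] = row["lfc_e2"]
        if modulated:
            row["e2_mod_factor"] = cfg.e2_mod_factor
    elif archetype == "SYNERGY":
        row["lfc_r5020"] = sign * mag
        row["lfc_e2"] = sign * mag
        row["lfc_combo"] = cfg.synergy_factor * sign * mag
    elif archetype == "ANTAG_ATTEN":
        row["lfc_e2"] = sign * mag
        row["lfc_combo"] = cfg.antag_atten_factor * sign * mag
    elif archetype == "ANTAG_REVERSED":
        row["lfc_e2"] = sign * mag
        row["lfc_r5020"] = cfg.antag_r5020_factor * sign * mag
        row["lfc_combo"] = cfg.antag_reversed_factor * sign * mag
    return row


def expected_log2_shift(truth: pd.DataFrame, cell_line: str, treatment: str) -> np.ndarray:
    """True log2 shift of the mean count vs the global baseline, per gene.

    This single function defines the generative model for every design cell;
    the simulator and the recovery tests both consume it.

    Composition rules: PR-expressing lines carry the constitutive
    ligand-independent shift under every treatment (QQQ loses the positive
    ones); EV has no R5020 response and no interplay, so its combined
    treatment equals E2 alone. For archetypes without an explicit interplay
    effect the combined treatment is additive in the single-agent responses.
    """
    arche = truth["archetype"].to_numpy()
    r5020 = truth["lfc_r5020"].to_numpy(float)
    e2 = truth["lfc_e2"].to_numpy(float)
    combo = truth["lfc_combo"].to_numpy(float)
    li = truth["lfc_li"].to_numpy(float)

    pr_line = cell_line in PR_LINES

    # Constitutive (ligand-independent) component.
    shift = np.zeros(len(truth))
    if pr_line:
        li_eff = li.copy()
        if cell_line == "QQQ":
            li_eff[(arche == "LIGAND_INDEP_UP")] = 0.0
        shift += li_eff

    # R5020 component, with mutant-specific scaling.
    r_eff = r5020.copy()
    if cell_line == "FFF":
        r_eff = np.where(
            arche == "ATTENUATED_FFF", r_eff * truth["attenuation_factor"].to_numpy(float), r_eff
        )
    elif cell_line == "QQQ":
        r_eff = np.where(
            arche == "HYPER_QQQ", r_eff * truth["hyper_factor"].to_numpy(float), r_eff
        )
    if not pr_line:
        r_eff = np.zeros(len(truth))

    # E2 component: present in every line; unliganded PR can modulate it.
    e_eff = e2.copy()
    if pr_line:
        e_eff = e_eff * truth["e2_mod_factor"].to_numpy(float)

    # Combined-treatment component.
    has_interplay = np.isin(arche, ("E2_ONLY", "SYNERGY", "ANTAG_ATTEN", "ANTAG_REVERSED"))
    if pr_line:
        c_eff = np.where(has_interplay, combo, r_eff + e_eff)
    else:
        c_eff = e_eff  # no PR: combined == E2 alone

    if treatment == "VEH":
        return shift
    if treatment == "R5020":
        return shift + r_eff
    if treatment == "E2":
        return shift + e_eff
    if treatment == "E2R":
        return shift + c_eff
    raise ValueError(f"unknown treatment {treatment!r}")


def simulate_size_factors(
    design: pd.DataFrame, library_size_spread: float = 0.2, seed: int = 0
) -> pd.Series:
    """Per-sample true size factors, log-normal around 1."""
    rng = np.random.default_rng([seed, _STREAM_SIZE_FACTORS])
    sf = np.exp(rng.normal(0.0, library_size_spread, size=len(design)))
    return pd.Series(sf, index=design["sample_id"].to_numpy(), name="size_factor")


def _nb_draw(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2; alpha=0 -> Poisson."""
    mu = np.asarray(mu, float)
    if alpha < 0:
        raise ValueError("dispersion must be nonnegative")
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_expression_counts(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    library_size_spread: float = 0.2,
    seed: int = 0,
    size_factors: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a gene x sample NB count matrix for an RNA design.

    Returns ``(counts, true_size_factors)``. The counts DataFrame is indexed
    by gene_id with one column per sample_id, in design order.
    """
    validate_design(design)
    if not (design["assay"] == "RNA").all():
        raise ValueError("expression simulation requires an RNA design")
    if (truth["base_mean"] <= 0).any():
        raise ValueError("base_mean must be positive")
    if (truth["dispersion"] < 0).any():
        raise ValueError("dispersion must be nonnegative")

    if size_factors is None:
        size_factors = simulate_size_factors(design, library_size_spread, seed)
    sf = size_factors.loc[design["sample_id"]].to_numpy(float)

    # Expected log2 shift per (gene, sample).
    shifts = np.empty((len(truth), len(design)))
    for j, (cl, tr) in enumerate(zip(design["cell_line"], design["treatment"])):
        shifts[:, j] = expected_log2_shift(truth, cl, tr)

    base = truth["base_mean"].to_numpy(float)[:, None]
    mu = base * (2.0 ** shifts) * sf[None, :]

    counts = np.empty((len(truth), len(design)), dtype=np.int64)
    disp = truth["dispersion"].to_numpy(float)
    for i in range(len(truth)):
        rng = np.random.default_rng([seed, _STREAM_GENES + i])
        counts[i] = _nb_draw(rng, mu[i], disp[i])

    counts_df = pd.DataFrame(
        counts, index=pd.Index(truth["gene_id"], name="gene_id"), columns=design["sample_id"].to_numpy()
    )
    return counts_df, size_factors


# ---------------------------------------------------------------------------
# ChIP-Seq simulation
# ---------------------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Toy genome: chromosome name -> length (bp)."""

    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self):
        if self.chrom_lengths is None:
            self.chrom_lengths = {"chr1": 10_000_000, "chr2": 10_000_000}
        for name, ln in self.chrom_lengths.items():
            if ln <= 0:
                raise ValueError(f"chromosome {name} has nonpositive length")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class ChipConfig:
    """Settings for the ChIP peak/count simulator."""

    n_peaks: int = 500
    frac_differential: float = 0.3
    frac_diff_to_attenuated: float = 0.8  # differential peaks near attenuated genes
    tss_enrichment: float = 5.0           # density ratio inside +/-5 kb of TSS
    tss_window: int = 5_000
    peak_width_low: int = 200
    peak_width_high: int = 400
    jitter: int = 25                      # replicate boundary jitter (bp)
    dropout: float = 0.1                  # per-replicate peak dropout probability
    occupancy_log2_mean: float = 7.0      # ~128 fragments per peak
    occupancy_log2_sd: float = 0.5
    diff_log2fc: float = 1.5              # FFF-vs-WT occupancy shift at true sites
    dispersion: float = 0.05


def generate_annotation(
    truth: pd.DataFrame,
    genome: GenomeSpec | None = None,
    seed: int = 0,
    gene_length_low: int = 2_000,
    gene_length_high: int = 20_000,
) -> pd.DataFrame:
    """Random BED6-style gene annotation (0-based half-open) for the truth genes.

    TSS = start for + strand genes and end - 1 for - strand genes.
    """
    genome = genome or GenomeSpec()
    rng = np.random.default_rng([seed, _STREAM_ANNOTATION])
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    n = len(truth)
    chrom_idx = rng.choice(len(chroms), size=n, p=probs)
    gene_len = rng.integers(gene_length_low, gene_length_high + 1, size=n)
    strand = np.where(rng.uniform(size=n) < 0.5, "+", "-")
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        limit = genome.chrom_lengths[chroms[chrom_idx[i]]] - gene_len[i]
        starts[i] = rng.integers(0, max(1, limit))
    ann = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in chrom_idx],
            "start": starts,
            "end": starts + gene_len,
            "gene_id": truth["gene_id"].to_numpy(),
            "score": 0,
            "strand": strand,
        }
    )
    ann["tss"] = np.where(ann["strand"] == "+", ann["start"], ann["end"] - 1)
    return ann.sort_values(["chrom", "start"], ignore_index=True)


def _merged_tss_windows(ann: pd.DataFrame, half_width: int, genome: GenomeSpec):
    """Merged +/-half_width windows around TSSs, per chromosome."""
    windows: dict[str, np.ndarray] = {}
    for chrom, sub in ann.groupby("chrom"):
        lo = np.maximum(0, sub["tss"].to_numpy() - half_width)
        hi = np.minimum(genome.chrom_lengths[chrom], sub["tss"].to_numpy() + half_width)
        order = np.argsort(lo)
        merged = []
        for a, b in zip(lo[order], hi[order]):
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        windows[chrom] = np.array(merged, dtype=np.int64).reshape(-1, 2)
    return windows


def simulate_chip_data(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    genome: GenomeSpec | None = None,
    config: ChipConfig | None = None,
    seed: int = 0,
) -> dict:
    """Simulate replicate peak sets and per-peak occupancy counts.

    Latent peak centres are drawn with ``tss_enrichment``-fold excess density
    inside the merged +/-``tss_window`` TSS windows. Differential peaks (true
    FFF-vs-WT occupancy shifts) are placed next to the TSS of attenuated
    genes (fraction ``frac_diff_to_attenuated``) or of non-attenuated
    regulated genes (the remainder), modelling the observed uncoupling of
    occupancy and transactivation. Replicate peak sets are dropout/jitter
    corrupted copies of the latent set; per-peak counts are NB around the
    latent occupancy.

    Returns a dict with keys ``latent_peaks`` (peak truth table),
    ``replicate_peaks`` (sample_id -> BED-like DataFrame), ``peak_counts``
    (peaks x ChIP samples), and ``annotation``.
    """
    genome = genome or GenomeSpec()
    cfg = config or ChipConfig()
    validate_design(design)
    if not (design["assay"] == "CHIP").all():
        raise ValueError("ChIP simulation requires a CHIP design")
    if cfg.peak_width_high >= min(genome.chrom_lengths.values()):
        raise ValueError("peak width exceeds chromosome length")
    if annotation is None:
        annotation = generate_annotation(truth, genome, seed)

    rng = np.random.default_rng([seed, _STREAM_CHIP])
    chroms = list(genome.chrom_lengths)

    n_diff = int(round(cfg.n_peaks * cfg.frac_differential))
    n_bg = cfg.n_peaks - n_diff

    atten = annotation.merge(truth[["gene_id", "archetype"]], on="gene_id")
    atten_genes = atten[atten["archetype"] == "ATTENUATED_FFF"]
    other_regulated = atten[atten["archetype"].isin(("LIGAND_UP", "LIGAND_DOWN", "HYPER_QQQ"))]

    rows = []
    # Differential peaks: near target-gene TSSs (within +/-1 kb).
    n_to_atten = int(round(n_diff * cfg.frac_diff_to_attenuated))
    for k in range(n_diff):
        pool = atten_genes if k < n_to_atten else other_regulated
        if len(pool) == 0:
            # fall back to whichever regulated pool exists
            pool = other_regulated if len(other_regulated) else atten_genes
        if len(pool) == 0:
            raise ValueError(
                "truth table lacks regulated archetypes to place differential peaks"
            )
        g = pool.iloc[int(rng.integers(len(pool)))]
        width = int(rng.integers(cfg.peak_width_low, cfg.peak_width_high + 1))
        center = int(g["tss"] + rng.integers(-1_000, 1_001))
        center = int(np.clip(center, width // 2, genome.chrom_lengths[g["chrom"]] - width // 2 - 1))
        rows.append(
            {
                "chrom": g["chrom"],
                "start": center - width // 2,
                "end": center - width // 2 + width,
                "is_differential": True,
                "log2fc_occupancy": cfg.diff_log2fc,
                "target_gene_id": g["gene_id"],
                "near_tss": True,
            }
        )

    # Background peaks: TSS-enriched placement.
    windows = _merged_tss_windows(annotation, cfg.tss_window, genome)
    inside_bp = sum(int((w[:, 1] - w[:, 0]).sum()) for w in windows.values())
    outside_bp = genome.total_length - inside_bp
    if outside_bp <= 0:
        raise ValueError("TSS windows cover the whole genome; enlarge it or shrink the window")
    e = cfg.tss_enrichment
    p_inside = e * inside_bp / (e * inside_bp + outside_bp)

    def _in_windows(chrom: str, x: int) -> bool:
        w = windows.get(chrom)
        if w is None or len(w) == 0:
            return False
        i = int(np.searchsorted(w[:, 0], x, side="right")) - 1
        return i >= 0 and x < w[i, 1]

    chrom_lengths_arr = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    for _ in range(n_bg):
        width = int(rng.integers(cfg.peak_width_low, cfg.peak_width_high + 1))
        if rng.uniform() < p_inside:
            # uniform position within the merged TSS windows
            chrom_weights = np.array(
                [float((windows[c][:, 1] - windows[c][:, 0]).sum()) if c in windows else 0.0 for c in chroms]
            )
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_weights / chrom_weights.sum()))]
            w = windows[chrom]
            seg_len = w[:, 1] - w[:, 0]
            seg = int(rng.choice(len(w), p=seg_len / seg_len.sum()))
            center = int(rng.integers(w[seg, 0], w[seg, 1]))
        else:
            # uniform over the genome OUTSIDE the TSS windows (rejection sampled)
            while True:
                chrom = chroms[int(rng.choice(len(chroms), p=chrom_lengths_arr / chrom_lengths_arr.sum()))]
                center = int(rng.integers(0, genome.chrom_lengths[chrom]))
                if not _in_windows(chrom, center):
                    break
        center = int(np.clip(center, width // 2, genome.chrom_lengths[chrom] - width // 2 - 1))
        rows.append(
            {
                "chrom": chrom,
                "start": center - width // 2,
                "end": center - width // 2 + width,
                "is_differential": False,
                "log2fc_occupancy": 0.0,
                "target_gene_id": "",
                "near_tss": False,
            }
        )

    latent = pd.DataFrame(rows).sort_values(["chrom", "start"], ignore_index=True)
    latent.insert(0, "peak_id", [f"peak{i:05d}" for i in range(len(latent))])
    latent["occupancy"] = 2.0 ** rng.normal(
        cfg.occupancy_log2_mean, cfg.occupancy_log2_sd, size=len(latent)
    )
    latent = latent[PEAK_TRUTH_COLUMNS]

    # Replicate peak sets: dropout + boundary jitter.
    replicate_peaks: dict[str, pd.DataFrame] = {}
    for _, srow in design.iterrows():
        keep = rng.uniform(size=len(latent)) >= cfg.dropout
        sub = latent.loc[keep, ["chrom", "start", "end", "peak_id"]].copy()
        if cfg.jitter > 0:
            sub["start"] = sub["start"] + rng.integers(-cfg.jitter, cfg.jitter + 1, size=len(sub))
            sub["end"] = sub["end"] + rng.integers(-cfg.jitter, cfg.jitter + 1, size=len(sub))
            sub["start"] = sub["start"].clip(lower=0)
            sub["end"] = np.maximum(sub["end"], sub["start"] + 1)
        sub["score"] = 1.0
        replicate_peaks[srow["sample_id"]] = sub.reset_index(drop=True)

    # Per-peak NB counts encoding the occupancy ratios (FFF gains binding).
    mu = np.tile(latent["occupancy"].to_numpy(float)[:, None], (1, len(design)))
    is_fff = (design["cell_line"] == "FFF").to_numpy()
    shift = latent["log2fc_occupancy"].to_numpy(float)[:, None] * is_fff[None, :]
    mu = mu * (2.0 ** shift)
    counts = np.empty(mu.shape, dtype=np.int64)
    for i in range(len(latent)):
        prng = np.random.default_rng([seed, _STREAM_PEAKS + i])
        counts[i] = _nb_draw(prng, mu[i], cfg.dispersion)
    peak_counts = pd.DataFrame(
        counts,
        index=pd.Index(latent["peak_id"], name="peak_id"),
        columns=design["sample_id"].to_numpy(),
    )

    return {
        "latent_peaks": latent,
        "replicate_peaks": replicate_peaks,
        "peak_counts": peak_counts,
        "annotation": annotation,
    }
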
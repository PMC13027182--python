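"""Self-contained negative-binomial differential-expression engine.

Implements the standard count-based DE chain on a gene x sample matrix:
median-of-ratios size factors, gene-wise method-of-moments dispersion with
trend shrinkage, per-condition NB mean fits, a Wald test on the log2 fold
change, and Benjamini-Hochberg adjustment. The model is
``K_gj ~ NB(mean = s_j * q_gc, Var = mu + alpha_g * mu^2)`` with sample size
factor ``s_j`` and condition mean ``q_gc`` on the normalized-count scale.

This is a deliberately fully-specified engine: gene-wise MoM dispersion with
50% shrinkage toward a fitted mean-dispersion trend (no empirical-Bayes MAP),
no independent filtering, no LFC shrinkage, two-sided normal p-values.
Downstream classifiers consume only ``(log2FoldChange, pvalue, padj)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DE_COLUMNS = [
    "gene_id",
    "baseMean",
    "log2FoldChange",
    "lfcSE",
    "stat",
    "pvalue",
    "padj",
    "status",
]

LN2 = np.log(2.0)

STATUS_OK = "ok"
STATUS_LOW_COUNT = "low_count"      # both condition means at the pseudo-floor
STATUS_UNTESTABLE = "untestable"    # all-zero across the contrast; excluded from BH


@dataclass(frozen=True)
class ContrastSpec:
    """A two-condition contrast within the factorial design.

    Either a within-line treatment contrast (``cell_line`` fixed,
    ``numerator``/``denominator`` are treatments) or a cross-line contrast at
    fixed ``treatment`` (``numerator``/``denominator`` are cell lines).
    """

    numerator: str
    denominator: str
    cell_line: str | None = None
    treatment: str | None = None

    def __post_init__(self):
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator must differ")
        if (self.cell_line is None) == (self.treatment is None):
            raise ValueError("specify exactly one of cell_line or treatment")

    def select(self, design: pd.DataFrame) -> tuple[list[str], list[str]]:
        """Return (numerator sample_ids, denominator sample_ids)."""
        if self.cell_line is not None:
            base = design[design["cell_line"] == self.cell_line]
            num = base[base["treatment"] == self.numerator]
            den = base[base["treatment"] == self.denominator]
        else:
            base = design[design["treatment"] == self.treatment]
            num = base[base["cell_line"] == self.numerator]
            den = base[base["cell_line"] == self.denominator]
        num_ids = num["sample_id"].tolist()
        den_ids = den["sample_id"].tolist()
        if not num_ids or not den_ids:
            raise ValueError(f"contrast {self} selects an empty condition")
        return num_ids, den_ids

    def label(self) -> str:
        fixed = self.cell_line if self.cell_line is not None else self.treatment
        return f"{fixed}:{self.numerator}_vs_{self.denominator}"


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over genes (restricted to
    genes with a finite log geometric mean, i.e. positive in every sample)
    of ``counts[g, j] / geomean_g``.
    """
    mat = counts.to_numpy(float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    with np.errstate(divide="ignore"):
        log_counts = np.log(mat)
    log_geomeans = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomeans)
    if not usable.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter all-zero-containing "
            "genes or provide size factors externally"
        )
    ratios = log_counts[usable] - log_geomeans[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    if not np.all(np.isfinite(sf) & (sf > 0)):
        raise ValueError("size factors must be finite and positive")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _condition_groups(design: pd.DataFrame, sample_ids) -> dict[str, list[str]]:
    sub = design[design["sample_id"].isin(sample_ids)]
    groups: dict[str, list[str]] = {}
    for (cl, tr), g in sub.groupby(["cell_line", "treatment"]):
        groups[f"{cl}:{tr}"] = g["sample_id"].tolist()
    return groups


def mom_dispersion(q: np.ndarray, inv_sf_mean: float = 1.0, clip: bool = True) -> float:
    """Raw method-of-moments dispersion from normalized replicate counts.

    ``alpha = (var - mean * xi) / mean^2`` with ``xi`` the mean of ``1/s_j``
    within the condition (the shot-noise term of normalized counts); clipped
    at 0 unless ``clip`` is False. With unit size factors this is the
    plug-in ``(s^2 - m) / m^2``.
    """
    m = float(np.mean(q))
    if m <= 0 or len(q) < 2:
        return np.nan
    v = float(np.var(q, ddof=1))
    a = (v - m * inv_sf_mean) / m**2
    return max(0.0, a) if clip else a


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: pd.DataFrame,
    shrink_weight: float = 0.8,
) -> pd.DataFrame:
    """Gene-wise MoM dispersions pooled across conditions, shrunk to a trend.

    Per condition with >=2 replicates the raw MoM estimate is computed on
    normalized counts; estimates are pooled across conditions weighted by
    residual degrees of freedom, then shrunk toward the fitted
    mean-dispersion trend ``a0 + a1 / mean`` with weight ``shrink_weight``.
    Pooling and the trend fit use the signed (unclipped) estimates so that
    sampling noise below zero cancels instead of accumulating as upward
    bias; only the final shrunk value is clipped at zero. This keeps the
    null test calibrated when the data are Poisson.

    Returns a DataFrame with columns ``dispersion`` (final), ``dispersion_gw``
    (raw pooled gene-wise), ``mean`` (overall normalized mean) and ``status``
    (``ok``, ``trend_only`` when no condition has replicates, ``untestable``
    for all-zero genes).
    """
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValueError("shrink_weight must be in [0, 1]")
    sf = size_factors.loc[counts.columns].to_numpy(float)
    q = counts.to_numpy(float) / sf[None, :]
    mu = q.mean(axis=1)

    groups = _condition_groups(design, counts.columns)
    col_idx = {s: i for i, s in enumerate(counts.columns)}

    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    any_replicated = False
    for ids in groups.values():
        if len(ids) < 2:
            continue
        any_replicated = True
        idx = [col_idx[s] for s in ids]
        qc = q[:, idx]
        xi = float(np.mean(1.0 / sf[idx]))
        m = qc.mean(axis=1)
        v = qc.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m * xi) / m**2
        ok = m > 0
        w = len(ids) - 1
        num[ok] += w * a[ok]
        den[ok] += w

    gw = np.full(len(counts), np.nan)
    has = den > 0
    gw[has] = num[has] / den[has]

    # Parametric trend alpha(mean) = a0 + a1/mean, fitted to the signed
    # gene-wise estimates by two-pass weighted least squares. The sampling
    # variance of a MoM dispersion is ~ 2 (xi/mu + alpha)^2 / df, so the
    # second pass weights by its inverse; this keeps noisy low-count genes
    # from inflating the slope. Falls back to the plain mean for tiny panels.
    fit_mask = has & np.isfinite(gw) & (mu > 0)
    if fit_mask.sum() >= 10:
        y = gw[fit_mask]
        x = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        a0, a1 = np.clip(coef, 0.0, None)
        pred = np.clip(a0 + a1 / mu[fit_mask], 0.0, None)
        wts = 1.0 / (1.0 / mu[fit_mask] + pred) ** 2
        sw = np.sqrt(wts)[:, None]
        coef, *_ = np.linalg.lstsq(x * sw, y * np.sqrt(wts), rcond=None)
        a0, a1 = np.clip(coef, 0.0, None)
    elif has.any():
        a0, a1 = max(0.0, float(np.nanmean(gw[has]))), 0.0
    else:
        a0, a1 = 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.inf)

    final = np.where(has, (1 - shrink_weight) * gw + shrink_weight * trend, trend)
    final = np.clip(final, 0.0, None)

    status = np.full(len(counts), "ok", dtype=object)
    if not any_replicated:
        status[:] = "trend_only"
    else:
        status[~has] = "trend_only"
    status[mu == 0] = STATUS_UNTESTABLE
    final[mu == 0] = 0.0

    return pd.DataFrame(
        {
            "dispersion": final,
            "dispersion_gw": gw,
            "mean": mu,
            "status": status,
        },
        index=counts.index,
    )


def _fit_group_means(
    counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 8
) -> np.ndarray:
    """Per-gene NB MLE of the condition mean on the normalized scale.

    Starts from the Poisson MLE ``sum K / sum s`` (exact for alpha = 0 and
    for equal size factors) and refines by Newton steps on the NB score when
    size factors are unequal.
    """
    mu = counts.sum(axis=1) / sf.sum()
    if counts.shape[1] == 1 or np.allclose(sf, sf[0]):
        return mu
    active = (alpha > 0) & (mu > 0)
    if not active.any():
        return mu
    r = 1.0 / alpha[active]
    k = counts[active]
    m = mu[active]
    for _ in range(n_iter):
        sm = sf[None, :] * m[:, None]
        score = (k / m[:, None] - (k + r[:, None]) * sf[None, :] / (sm + r[:, None])).sum(axis=1)
        hess = (
            -k / m[:, None] ** 2
            + (k + r[:, None]) * sf[None, :] ** 2 / (sm + r[:, None]) ** 2
        ).sum(axis=1)
        step = np.where(hess != 0, -score / hess, 0.0)
        m = np.clip(m + step, 1e-12, None)
    mu[active] = m
    return mu


def wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series | np.ndarray | float,
    design: pd.DataFrame,
    contrast: ContrastSpec,
    mean_floor: float = 0.5,
) -> pd.DataFrame:
    """Wald test of the log2 fold change between two conditions.

    Per gene, the NB mean is fitted per condition on the normalized scale;
    ``log2FoldChange = log2(mu_num / mu_den)`` with both means floored at
    ``mean_floor`` normalized counts, the standard error comes from expected
    Fisher information via the delta method, and the two-sided p-value from
    the normal tail of ``stat = log2FoldChange / lfcSE``.

    Genes with all-zero counts across the contrast are flagged
    ``untestable`` (``pvalue`` NaN, excluded from BH); genes whose both
    condition means sit at the floor are flagged ``low_count`` with
    ``log2FoldChange = 0`` and ``pvalue = 1``. The ``padj`` column is filled
    by BH over the testable genes.
    """
    num_ids, den_ids = contrast.select(design)
    sf_all = size_factors.loc[counts.columns].to_numpy(float)
    if isinstance(dispersions, (int, float)):
        alpha = np.full(len(counts), float(dispersions))
    elif isinstance(dispersions, pd.Series):
        alpha = dispersions.loc[counts.index].to_numpy(float)
    else:
        alpha = np.asarray(dispersions, float)
    if (alpha < 0).any():
        raise ValueError("dispersions must be nonnegative")

    col_idx = {s: i for i, s in enumerate(counts.columns)}
    idx_num = [col_idx[s] for s in num_ids]
    idx_den = [col_idx[s] for s in den_ids]
    mat = counts.to_numpy(float)
    k_num, s_num = mat[:, idx_num], sf_all[idx_num]
    k_den, s_den = mat[:, idx_den], sf_all[idx_den]

    mu_num = _fit_group_means(k_num, s_num, alpha)
    mu_den = _fit_group_means(k_den, s_den, alpha)

    untestable = (k_num.sum(axis=1) + k_den.sum(axis=1)) == 0
    low = (mu_num <= mean_floor) & (mu_den <= mean_floor) & ~untestable

    mu_num_f = np.maximum(mu_num, mean_floor)
    mu_den_f = np.maximum(mu_den, mean_floor)
    log2fc = np.log2(mu_num_f / mu_den_f)

    def var_log_mu(mu_f: np.ndarray, s: np.ndarray) -> np.ndarray:
        # Expected Fisher information for mu; Var(ln mu_hat) by delta method.
        m = mu_f[:, None] * s[None, :]
        info = (s[None, :] ** 2 / (m + alpha[:, None] * m**2)).sum(axis=1)
        return 1.0 / (mu_f**2 * info)

    v = var_log_mu(mu_num_f, s_num) + var_log_mu(mu_den_f, s_den)
    se = np.sqrt(v) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    log2fc[low] = 0.0
    stat[low] = 0.0
    pvalue[low] = 1.0
    log2fc[untestable] = 0.0
    stat[untestable] = np.nan
    pvalue[untestable] = np.nan
    se[untestable] = np.nan

    status = np.full(len(counts), STATUS_OK, dtype=object)
    status[low] = STATUS_LOW_COUNT
    status[untestable] = STATUS_UNTESTABLE

    all_idx = idx_num + idx_den
    base_mean = (mat[:, all_idx] / sf_all[all_idx][None, :]).mean(axis=1)

    res = pd.DataFrame(
        {
            "gene_id": counts.index.to_numpy(),
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": np.nan,
            "status": status,
        },
        columns=DE_COLUMNS,
    )
    testable = res["status"] != STATUS_UNTESTABLE
    res.loc[testable, "padj"] = adjust_bh(res.loc[testable, "pvalue"].to_numpy())
    return res


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``padj_(i) = min_{j >= i} (m / j) * p_(j)`` on the sorted p-values,
    capped at 1; monotone nondecreasing in p.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values; exclude untestable genes before BH")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def run_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: ContrastSpec,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    shrink_weight: float = 0.8,
    mean_floor: float = 0.5,
) -> pd.DataFrame:
    """Full DE chain for one contrast: normalize, estimate dispersion, test."""
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(
            counts, size_factors, design, shrink_weight=shrink_weight
        )["dispersion"]
    return wald_test(counts, size_factors, dispersions, design, contrast, mean_floor=mean_floor)
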
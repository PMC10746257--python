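"""Normalization and simplified differential tests for RNA counts and
protein intensities, plus the five-level regulation grouping.

The RNA test is a negative-binomial Wald test: counts are scaled by
median-of-ratios size factors, per-gene dispersion is estimated by method
of moments pooled across the two conditions and moderated toward the
across-gene median (empirical-Bayes weighting, default prior strength
``d0 = 20`` pseudo-degrees of freedom), and the Wald statistic
``log2FC / SE`` with a delta-method standard error is referred to the
normal distribution.  The protein test is a moderated two-sample t on
log2 intensities after upper-quartile normalization, with limma-style
variance squeezing: the prior ``(d0, s0^2)`` is fitted by moment matching
on the distribution of log sample variances and the posterior variance is
``(d0 s0^2 + d s^2) / (d0 + d)`` with ``d0 + d`` t degrees of freedom.

Regulation groups follow the volcano-plot thresholds: RNA calls are
strong when ``padj < 0.05`` and ``|log2FC| >= 1`` (moderate otherwise,
down to any nonzero fold change); protein calls use the sign of the fold
change only, with no magnitude threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special, optimize
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OmicsMatrix",
    "tpm",
    "size_factors",
    "rna_de_test",
    "protein_de_test",
    "bh_adjust",
    "classify_regulation",
    "de_table",
    "upper_quartile_normalize",
]

REGULATION_LEVELS = ["strong_up", "up", "ns", "down", "strong_down"]


@dataclass
class OmicsMatrix:
    """Genes x samples abundance matrix with its condition/replicate design.

    ``values``: non-negative reals (RNA: counts; protein: intensities,
    NaN = not observed).  ``design``: per-sample rows with ``condition``
    and ``replicate`` columns, indexed by sample name.  ``lengths``: gene
    lengths in nt (required for TPM).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    kind: str  # "rna" | "protein"
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rna", "protein"):
            raise ValueError(f"kind must be rna or protein, got {self.kind!r}")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"design does not cover samples: {sorted(missing)}")
        if "Ctrl" not in set(self.design["condition"]):
            raise ValueError("design must include a Ctrl condition")
        if self.lengths is not None and (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    def condition_samples(self, condition: str, keep: list[str] | None = None) -> list[str]:
        samples = self.design.index[self.design["condition"] == condition]
        samples = [s for s in samples if s in self.values.columns]
        if keep is not None:
            samples = [s for s in samples if s in keep]
        return samples


def tpm(counts: OmicsMatrix) -> pd.DataFrame:
    """Transcripts-per-million: reads per kilobase, rescaled so every
    sample sums to one million."""
    if counts.lengths is None:
        raise ValueError("gene lengths are required for TPM")
    lengths_kb = counts.lengths.reindex(counts.values.index) / 1000.0
    if lengths_kb.isna().any():
        raise ValueError("lengths missing for some genes")
    rpk = counts.values.div(lengths_kb, axis=0)
    totals = rpk.sum(axis=0)
    out = rpk * 1e6 / totals.replace(0, np.nan)
    return out.fillna(0.0)


def size_factors(counts: OmicsMatrix, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios normalization factors, geometric-mean 1.

    Per sample, the factor is the median over genes of
    ``count / geometric-mean count of that gene``, restricted to genes
    with all-positive counts (after adding ``pseudocount``).
    """
    vals = counts.values.to_numpy(dtype=float) + pseudocount
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "retry with a pseudocount"
        )
    sub = vals[positive]
    log_gm = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.log(sub) - log_gm
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_regulation(log2fc: float, padj: float, kind: str) -> str:
    """Volcano-plot regulation group for one gene/contrast."""
    if not 0.0 <= padj <= 1.0:
        raise ValueError("padj must lie in [0, 1]")
    if padj >= 0.05 or np.isnan(log2fc):
        return "ns"
    if kind == "rna":
        if log2fc >= 1:
            return "strong_up"
        if log2fc > 0:
            return "up"
        if log2fc <= -1:
            return "strong_down"
        if log2fc < 0:
            return "down"
        return "ns"
    if kind == "protein":
        if log2fc > 0:
            return "up"
        if log2fc < 0:
            return "down"
        return "ns"
    raise ValueError(f"unknown kind {kind!r}")


def _fit_f_dist(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed sample variances.

    Given ``s^2 ~ s0^2 F(df, d0)``, matches mean and variance of
    ``log s^2`` using digamma/trigamma identities and returns
    ``(d0, s0^2)``; ``d0 = inf`` when the observed spread is no larger
    than the sampling spread.
    """
    v = variances[np.isfinite(variances) & (variances > 0)]
    if v.size < 2:
        return np.inf, float(np.nanmean(variances))
    z = np.log(v)
    e_z = z.mean()
    var_z = z.var(ddof=1)
    target = var_z - special.polygamma(1, df / 2.0)
    if target <= 1e-8:
        d0 = np.inf
        s0_log = e_z - special.digamma(df / 2.0) + np.log(df / 2.0)
        return d0, float(np.exp(s0_log))

    def f(d0half: float) -> float:
        return special.polygamma(1, d0half) - target

    # trigamma is decreasing; bracket the root
    lo, hi = 1e-4, 1e6
    d0half = optimize.brentq(f, lo, hi)
    d0 = 2.0 * d0half
    s0_log = (
        e_z
        - special.digamma(df / 2.0)
        + np.log(df / 2.0)
        + special.digamma(d0half)
        - np.log(d0half)
    )
    return float(d0), float(np.exp(s0_log))


def rna_de_test(
    counts: OmicsMatrix,
    contrast: str,
    control: str = "Ctrl",
    keep_samples: list[str] | None = None,
    c0: float = 0.5,
    dispersion_prior_df: float = 20.0,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test of one stress condition against control.

    Returns a frame with log2FC (``log2((mean_cond + c0)/(mean_ctrl +
    c0))`` on size-factor-scaled counts), Wald p, BH padj, and regulation
    group.  Genes with zero counts in both conditions are omitted.
    """
    s_cond = counts.condition_samples(contrast, keep_samples)
    s_ctrl = counts.condition_samples(control, keep_samples)
    if len(s_cond) < 2 or len(s_ctrl) < 2:
        raise ValueError("need at least 2 replicates per condition")
    if factors is None:
        factors = size_factors(counts)
    scaled = counts.values / factors
    a = scaled[s_cond].to_numpy(dtype=float)
    b = scaled[s_ctrl].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]

    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    keep = (m1 > 0) | (m2 > 0)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)

    # per-gene MoM dispersion pooled across the two conditions,
    # moderated toward the across-gene median
    with np.errstate(divide="ignore", invalid="ignore"):
        disp1 = (v1 - m1) / m1**2
        disp2 = (v2 - m2) / m2**2
    w1, w2 = n1 - 1, n2 - 1
    disp = np.where(
        np.isfinite(disp1) & np.isfinite(disp2),
        (w1 * disp1 + w2 * disp2) / (w1 + w2),
        np.where(np.isfinite(disp1), disp1, disp2),
    )
    disp = np.clip(disp, 0.0, None)
    central = float(np.nanmedian(disp[keep])) if keep.any() else 0.0
    d_resid = w1 + w2
    d0 = dispersion_prior_df
    disp = (d0 * central + d_resid * disp) / (d0 + d_resid)
    disp = np.clip(np.nan_to_num(disp, nan=central), 1e-8, None)

    log2fc = np.log2((m1 + c0) / (m2 + c0))
    ln2sq = np.log(2.0) ** 2
    var_mean1 = (m1 + disp * m1**2) / n1
    var_mean2 = (m2 + disp * m2**2) / n2
    se = np.sqrt(
        var_mean1 / ((m1 + c0) ** 2 * ln2sq) + var_mean2 / ((m2 + c0) ** 2 * ln2sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(se > 0, p, 1.0)

    out = pd.DataFrame(
        {
            "gene_id": counts.values.index,
            "contrast": contrast,
            "baseMean": (m1 + m2) / 2.0,
            "log2FC": log2fc,
            "se": se,
            "stat": wald,
            "p": p,
        }
    )[keep]
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["group"] = [
        classify_regulation(l, q, "rna") for l, q in zip(out["log2FC"], out["padj"])
    ]
    return out.reset_index(drop=True)


def upper_quartile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (log2 scale, additive shift) so its 75th
    percentile of observed values matches the across-sample mean."""
    q = values.quantile(0.75, axis=0)
    return values - q + q.mean()


def protein_de_test(
    intensities: OmicsMatrix,
    contrast: str,
    control: str = "Ctrl",
    keep_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t-test on log2 protein intensities.

    Intensities are log2-transformed and upper-quartile normalized;
    per-gene pooled variances are squeezed toward a moment-matched
    scaled-F prior and the t statistic uses ``d0 + d`` degrees of
    freedom.  Genes observed in fewer than 2 samples in either group are
    omitted.
    """
    s_cond = intensities.condition_samples(contrast, keep_samples)
    s_ctrl = intensities.condition_samples(control, keep_samples)
    logged = np.log2(intensities.values.where(intensities.values > 0))
    logged = upper_quartile_normalize(logged)
    a = logged[s_cond].to_numpy(dtype=float)
    b = logged[s_ctrl].to_numpy(dtype=float)

    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    keep = (na >= 2) & (nb >= 2)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
    df_resid = na + nb - 2
    pooled = ((na - 1) * v1 + (nb - 1) * v2) / np.where(df_resid > 0, df_resid, 1)

    d_typical = float(np.median(df_resid[keep])) if keep.any() else 2.0
    d0, s0 = _fit_f_dist(pooled[keep], d_typical)
    if np.isinf(d0):
        s2_post = np.full_like(pooled, s0)
        df_total = np.full_like(pooled, np.inf)
    else:
        s2_post = (d0 * s0 + df_resid * pooled) / (d0 + df_resid)
        df_total = d0 + df_resid

    log2fc = m1 - m2
    se = np.sqrt(s2_post * (1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df_total), df_total, 1.0)),
    )
    p = np.where(se > 0, p, 1.0)

    out = pd.DataFrame(
        {
            "gene_id": intensities.values.index,
            "contrast": contrast,
            "log2FC": log2fc,
            "se": se,
            "stat": t,
            "p": p,
            "df": df_total,
        }
    )[keep]
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["group"] = [
        classify_regulation(l, q, "protein")
        for l, q in zip(out["log2FC"], out["padj"])
    ]
    return out.reset_index(drop=True)


def de_table(
    matrix: OmicsMatrix,
    contrasts: list[str] | None = None,
    keep_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Run the appropriate test for every contrast and stack the results."""
    if contrasts is None:
        contrasts = [c for c in matrix.design["condition"].unique() if c != "Ctrl"]
    test = rna_de_test if matrix.kind == "rna" else protein_de_test
    frames = [test(matrix, c, keep_samples=keep_samples) for c in contrasts]
    return pd.concat(frames, ignore_index=True)
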
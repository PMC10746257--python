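"""Length-bias-aware functional category enrichment.

Gene-length bias (longer genes are more likely to be called
differentially expressed at fixed effect size) is corrected the way goseq
does: a probability weighting function (PWF) — a monotone nondecreasing
function of gene length giving each gene's propensity to be DE — is
fitted to the DE indicator, and category overrepresentation is tested
with the Wallenius noncentral hypergeometric distribution, whose odds
parameter is the mean PWF weight inside the category over the mean weight
outside.  Here the PWF is a binned isotonic (pool-adjacent-violators)
fit, which carries the same monotone contract as goseq's spline without a
smoothing parameter.  Up- and downregulated sets are tested separately
against a background of all detected genes, thresholding raw p at 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "PWF",
    "fit_pwf",
    "wallenius_pmf",
    "wallenius_tail",
    "arcog_enrichment",
]


@dataclass
class PWF:
    """Per-gene DE-propensity weights, monotone nondecreasing in length,
    rescaled to mean 1."""

    weights: pd.Series
    bin_lengths: np.ndarray
    bin_rates: np.ndarray
    flat: bool = False


def fit_pwf(
    de_indicator: pd.Series,
    lengths: pd.Series,
    n_bins: int = 20,
    floor: float = 1e-6,
) -> PWF:
    """Fit the probability weighting function by binned isotonic regression.

    Genes are binned by length quantiles; per-bin DE fractions are made
    monotone nondecreasing by pool-adjacent-violators; per-gene weights
    interpolate the bin fit at the gene's length and are rescaled to mean
    1 (floored at ``floor``).  Constant lengths give a flat PWF.
    """
    de = de_indicator.astype(float)
    lengths = lengths.reindex(de.index)
    if de.sum() < 1 or (1 - de).sum() < 1:
        raise ValueError("need at least one DE and one non-DE gene")
    if lengths.nunique() == 1:
        w = pd.Series(1.0, index=de.index)
        return PWF(w, np.array([lengths.iloc[0]]), np.array([de.mean()]), flat=True)

    ranks = lengths.rank(method="first")
    bins = np.minimum((ranks - 1) // math.ceil(len(de) / n_bins), n_bins - 1).astype(int)
    grouped = pd.DataFrame({"bin": bins, "de": de, "length": lengths}).groupby("bin")
    bin_len = grouped["length"].median().to_numpy()
    bin_rate = grouped["de"].mean().to_numpy()
    bin_n = grouped.size().to_numpy()

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(bin_len, bin_rate, sample_weight=bin_n)
    w = np.interp(lengths.to_numpy(dtype=float), bin_len, fitted)
    w = np.maximum(w, floor)
    w = w / w.mean()
    w = np.maximum(w, floor)
    return PWF(pd.Series(w, index=de.index), bin_len, fitted)


def _wallenius_dist(n_cat: int, n_de: int, n_total: int, odds: float) -> np.ndarray:
    """Exact distribution of the Wallenius noncentral hypergeometric count.

    ``n_de`` balls are drawn sequentially without replacement from an urn
    of ``n_cat`` category balls (weight ``odds``) and ``n_total - n_cat``
    others (weight 1), each draw weight-proportional among the remaining
    balls.  Evaluated by the exact recursion over draws: after ``j``
    draws with ``i`` category balls taken, the next draw is a category
    ball with probability ``odds*(n_cat - i) / (odds*(n_cat - i) +
    (m2 - (j - i)))``.  Returns P(X = x) for x = 0..min(n_cat, n_de).
    """
    if odds <= 0:
        raise ValueError("odds must be positive")
    if not 0 <= n_cat <= n_total or not 0 <= n_de <= n_total:
        raise ValueError("inconsistent urn sizes")
    m2 = n_total - n_cat
    hi = min(n_cat, n_de)
    f = np.zeros(hi + 1)
    f[0] = 1.0
    for j in range(n_de):
        new = np.zeros(hi + 1)
        i_lo = max(0, j - m2)
        for i in range(i_lo, min(j, hi) + 1):
            if f[i] == 0.0:
                continue
            w_cat = odds * (n_cat - i)
            w_other = m2 - (j - i)
            denom = w_cat + w_other
            if denom <= 0:
                continue
            if w_cat > 0 and i + 1 <= hi:
                new[i + 1] += f[i] * w_cat / denom
            if w_other > 0:
                new[i] += f[i] * w_other / denom
        f = new
    return f


def wallenius_pmf(x: int, n_cat: int, n_de: int, n_total: int, odds: float) -> float:
    """P(X = x) of the Wallenius noncentral hypergeometric distribution."""
    if x < 0 or x > min(n_cat, n_de):
        return 0.0
    return float(_wallenius_dist(n_cat, n_de, n_total, odds)[x])


def wallenius_tail(x: int, n_cat: int, n_de: int, n_total: int, odds: float) -> float:
    """Upper-tail probability P(X >= x) of the Wallenius distribution."""
    dist = _wallenius_dist(n_cat, n_de, n_total, odds)
    if x < 0:
        return 1.0
    if x > min(n_cat, n_de):
        return 0.0
    return float(min(max(dist[x:].sum(), 0.0), 1.0))


def arcog_enrichment(
    groups: pd.Series,
    categories: pd.Series,
    lengths: pd.Series,
    direction: str,
    alpha: float = 0.05,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Category overrepresentation among up- or downregulated genes.

    ``groups`` holds per-gene regulation labels (strong_up/up/ns/down/
    strong_down) over the background of all detected genes; the DE set
    for ``direction`` "up" is strong_up+up (and correspondingly for
    "down") — the direction pools strong and moderate calls.  Empty
    categories are skipped.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    wanted = {"up": ("up", "strong_up"), "down": ("down", "strong_down")}[direction]
    de = groups.isin(wanted)
    if de.sum() == 0:
        raise ValueError(f"no genes regulated in direction {direction!r}")

    pwf = fit_pwf(de, lengths, n_bins=n_bins)
    w = pwf.weights
    n_total = len(groups)
    n_de = int(de.sum())

    rows = []
    for cat in sorted(categories.dropna().unique()):
        in_cat = categories == cat
        n_cat = int(in_cat.sum())
        if n_cat == 0:
            continue
        x = int((de & in_cat).sum())
        mean_in = w[in_cat].mean()
        mean_out = w[~in_cat].mean() if (~in_cat).any() else mean_in
        odds = float(mean_in / mean_out) if mean_out > 0 else 1.0
        p = wallenius_tail(x, n_cat, n_de, n_total, odds)
        rows.append(
            {
                "category": cat,
                "direction": direction,
                "n_de_in_cat": x,
                "n_cat": n_cat,
                "n_de": n_de,
                "n_total": n_total,
                "odds": odds,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
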
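"""Dissemination-cascade accounting and limiting-dilution estimation.

Compartment-level %CSC accounting along the metastatic cascade
(bulk primary → TMEM-proximal → circulation → lung arrival →
micro-metastases by size class), fold-enrichment with a multiplicative
decomposition, lesion-size classification with exact integer
boundaries (small ≤ 10 cells, medium 11–300, large > 300), single-hit
limiting-dilution frequency estimation by maximum likelihood with
profile-likelihood intervals, the ΔCt fold-expression formula, and
score–marker correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

__all__ = [
    "CompartmentTable",
    "DilutionFit",
    "compartment_table",
    "fold_enrichment",
    "decompose_enrichment",
    "round_to_sig",
    "segment_lesions",
    "classify_lesions",
    "fit_single_hit",
    "frequency_ratio",
    "delta_ct_fold",
    "marker_correlation",
]

LESION_SMALL_MAX = 10  # cells
LESION_MEDIUM_MAX = 300


# ----------------------------------------------------------- compartments

def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI; safe for the small-n compartments."""
    if n == 0:
        return (float("nan"), float("nan"))
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


@dataclass
class CompartmentTable:
    """Per-compartment positive/total counts with %CSC and exact CIs."""

    frame: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int]]) -> "CompartmentTable":
        rows = []
        for name, (pos, total) in counts.items():
            if not 0 <= pos <= total:
                raise ValueError(
                    f"compartment {name!r}: need 0 <= positive <= total"
                )
            if total <= 0:
                raise ValueError(f"compartment {name!r}: total must be > 0")
            lo, hi = _clopper_pearson(pos, total)
            rows.append(
                dict(
                    compartment=name,
                    positive=pos,
                    total=total,
                    pct_csc=100.0 * pos / total,
                    ci_low_pct=100.0 * lo,
                    ci_high_pct=100.0 * hi,
                )
            )
        return cls(pd.DataFrame(rows).set_index("compartment"))

    def pct(self, compartment: str) -> float:
        return float(self.frame.loc[compartment, "pct_csc"])


def compartment_table(counts: dict[str, tuple[int, int]]) -> CompartmentTable:
    """Build the cascade table from ``{compartment: (positive, total)}``."""
    return CompartmentTable.from_counts(counts)


def fold_enrichment(table: CompartmentTable, reference: str) -> dict[str, float]:
    """Fold %CSC of each compartment relative to a reference compartment."""
    ref = table.pct(reference)
    if ref == 0:
        raise ValueError("reference compartment has 0% CSC; folds undefined")
    return {
        name: float(row.pct_csc / ref) for name, row in table.frame.iterrows()
    }


def round_to_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (58.8 -> 60 at sig=1)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + sig - 1)


def decompose_enrichment(factors: Sequence[float]) -> dict[str, float]:
    """Product of independent enrichment factors, order-invariant.

    Returns the exact product and its one-significant-figure rounding
    (the convention used to report the combined cascade enrichment).
    """
    f = np.asarray(factors, dtype=float)
    if np.any(f <= 0):
        raise ValueError("all enrichment factors must be > 0")
    product = float(np.prod(f))
    return {"product": product, "rounded": round_to_sig(product, 1)}


# ---------------------------------------------------------------- lesions

def segment_lesions(
    cells: pd.DataFrame, linkage_radius_um: float = 25.0
) -> pd.Series:
    """Group cells into lesions by single-linkage within a radius.

    Returns a lesion id per cell. Cells whose centroids are within
    ``linkage_radius_um`` (directly or transitively) share a lesion.
    """
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    n = len(xy)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if n:
        pairs = cKDTree(xy).query_pairs(linkage_radius_um)
        for i, j in pairs:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    _, ids = np.unique(roots, return_inverse=True)
    return pd.Series(ids, index=cells.index, name="lesion_id")


def classify_lesions(
    lesions: pd.DataFrame,
    count_col: str = "n_cells",
    positive_col: Optional[str] = "n_positive",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Size-classify lesions and summarize per-class %sensor-positive.

    Boundaries are exact integers: small ≤ 10 cells, medium 11–300,
    large > 300. Returns the lesion table with a ``size_class`` column
    and a per-class summary (lesion count, cells, positives, pct_csc).
    """
    if (lesions[count_col] < 1).any():
        raise ValueError("every lesion must contain at least 1 cell")
    out = lesions.copy()
    counts = out[count_col].to_numpy()
    cls = np.where(
        counts <= LESION_SMALL_MAX,
        "small",
        np.where(counts <= LESION_MEDIUM_MAX, "medium", "large"),
    )
    out["size_class"] = cls
    if positive_col is not None and positive_col in out.columns:
        agg = out.groupby("size_class").agg(
            n_lesions=(count_col, "size"),
            n_cells=(count_col, "sum"),
            n_positive=(positive_col, "sum"),
        )
        agg["pct_csc"] = 100.0 * agg["n_positive"] / agg["n_cells"]
    else:
        agg = out.groupby("size_class").agg(
            n_lesions=(count_col, "size"), n_cells=(count_col, "sum")
        )
    order = [c for c in ("small", "medium", "large") if c in agg.index]
    return out, agg.loc[order]


# ------------------------------------------------------- limiting dilution

@dataclass
class DilutionFit:
    """Single-hit tumor-initiating frequency fit.

    Under the single-hit model each injected cell initiates a tumor
    independently, so P(take at dose d) = 1 - exp(-f d); ``frequency``
    is the MLE of f (cells^-1) with a profile-likelihood CI.
    """

    frequency: float
    ci_low: float
    ci_high: float
    log_likelihood: float
    table: pd.DataFrame  # observed vs fitted take rates per dose
    boundary: Optional[str] = None  # "all_negative" / "all_positive" / None

    @property
    def one_in(self) -> float:
        return 1.0 / self.frequency if self.frequency > 0 else float("inf")


def _loglik(f: float, dose: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    if f < 0:
        return -np.inf
    p = 1.0 - np.exp(-f * dose)
    ll = 0.0
    for d, ni, ki in zip(dose, n, k):
        pi = 1.0 - math.exp(-f * d)
        if ki > 0:
            if pi <= 0:
                return -np.inf
            ll += ki * math.log(pi)
        ll += (ni - ki) * (-f * d)
    return ll


def fit_single_hit(table: pd.DataFrame, alpha: float = 0.05) -> DilutionFit:
    """Maximum-likelihood single-hit frequency from a take table.

    ``table`` needs columns ``dose, n_injections, n_tumors``. Boundary
    tables are handled explicitly: an all-negative arm gives a point
    estimate 0 with a one-sided upper bound; an all-positive arm gives
    a lower bound with an infinite point estimate proxyed by the bound.
    """
    for col in ("dose", "n_injections", "n_tumors"):
        if col not in table.columns:
            raise ValueError(f"dilution table missing column {col!r}")
    dose = table["dose"].to_numpy(float)
    n = table["n_injections"].to_numpy(int)
    k = table["n_tumors"].to_numpy(int)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("0 <= n_tumors <= n_injections violated")
    target = stats.chi2.ppf(1 - alpha, df=1) / 2.0  # profile-LR drop

    def fitted_frame(f: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": dose,
                "n_injections": n,
                "n_tumors": k,
                "observed_rate": k / n,
                "fitted_rate": 1.0 - np.exp(-f * dose),
            }
        )

    if k.sum() == 0:
        # all negative: L(f) = exp(-f * sum(n*d)); upper bound where it drops
        total = float((n * dose).sum())
        hi = target * 2 / 2 / total * 2  # solve f*total = target -> see below
        hi = target / total
        return DilutionFit(0.0, 0.0, hi, 0.0, fitted_frame(0.0), "all_negative")
    if k.sum() == n.sum():
        # all positive: likelihood increases with f; report the lower bound
        ll_inf = 0.0

        def drop(logf: float) -> float:
            return _loglik(10**logf, dose, n, k) - (ll_inf - target)

        lo = 10 ** optimize.brentq(drop, -12, math.log10(10.0 / dose.min()))
        return DilutionFit(
            float("inf"), lo, float("inf"), ll_inf,
            fitted_frame(1.0 / dose.min()), "all_positive",
        )

    res = optimize.minimize_scalar(
        lambda logf: -_loglik(10**logf, dose, n, k),
        bounds=(-12.0, 0.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    f_hat = 10**res.x
    ll_hat = -res.fun

    def drop(logf: float) -> float:
        return _loglik(10**logf, dose, n, k) - (ll_hat - target)

    lo_bracket = -14.0
    lo = (
        10 ** optimize.brentq(drop, lo_bracket, math.log10(f_hat))
        if drop(lo_bracket) < 0
        else 0.0
    )
    hi_bracket = 2.0
    hi = (
        10 ** optimize.brentq(drop, math.log10(f_hat), hi_bracket)
        if drop(hi_bracket) < 0
        else float("inf")
    )
    return DilutionFit(float(f_hat), lo, hi, float(ll_hat), fitted_frame(f_hat))


def frequency_ratio(fit_a: DilutionFit, fit_b: DilutionFit) -> dict:
    """Ratio of two fitted frequencies with a propagated CI.

    The CI treats log f as approximately normal with a standard error
    read off each profile-likelihood interval; the two arms are
    independent, so the log-ratio variance is the sum.
    """
    if fit_b.frequency == 0:
        raise ValueError("denominator arm has zero frequency estimate")
    ratio = fit_a.frequency / fit_b.frequency
    z = stats.norm.ppf(0.975)

    def log_se(fit: DilutionFit) -> float:
        if fit.ci_low <= 0 or not np.isfinite(fit.ci_high):
            return float("nan")
        return (math.log(fit.ci_high) - math.log(fit.ci_low)) / (2 * z)

    se = math.sqrt(
        sum(s**2 for s in (log_se(fit_a), log_se(fit_b)))
    ) if all(np.isfinite([log_se(fit_a), log_se(fit_b)])) else float("nan")
    if np.isnan(se) or ratio in (0.0, float("inf")):
        ci = (float("nan"), float("nan"))
    else:
        ci = (
            float(ratio * math.exp(-z * se)),
            float(ratio * math.exp(z * se)),
        )
    return {"ratio": float(ratio), "ci": ci}


# ------------------------------------------------------------------- misc

def delta_ct_fold(delta_ct: float) -> float:
    """Fold expression from the comparative Ct method: 2^(-ΔCt)."""
    if not np.isfinite(delta_ct):
        raise ValueError("delta Ct must be finite")
    return float(2.0 ** (-delta_ct))


def marker_correlation(
    tmem_scores: np.ndarray,
    marker_fractions: np.ndarray,
    log_scores: bool = False,
) -> dict:
    """Pearson correlation of doorway scores with stem-marker fractions.

    Returns r and the two-sided p; with ``log_scores`` the natural log
    of the scores is used instead (reported alongside raw in
    sensitivity analyses). Zero variance in either variable is flagged
    and yields NaN rather than an exception.
    """
    x = np.asarray(tmem_scores, dtype=float)
    y = np.asarray(marker_fractions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and fractions must be paired 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if log_scores:
        if np.any(x <= 0):
            raise ValueError("log transform requires positive scores")
        x = np.log(x)
    if x.std() == 0 or y.std() == 0:
        return {"r": float("nan"), "p": float("nan"), "flag": "zero variance"}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "flag": None}
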
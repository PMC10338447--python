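"""Automatic normalizing-transformation selection.

Each variable entering the network stage is passed through the candidate
transform whose output looks most Gaussian, judged by a Pearson chi-square
normality statistic (per-class normalized, lower is better). Candidates, in
tie-break order: identity, Yeo-Johnson, Box-Cox (positive data only),
log10(x+a), sqrt(x+a), arcsinh, and ordered quantile normalization. All
candidates are strictly monotone on the training range, so ranks are
preserved. Outputs are standardized with training statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

METHOD_ORDER = [
    "identity",
    "yeo_johnson",
    "box_cox",
    "log10_shift",
    "sqrt_shift",
    "arcsinh",
    "ordered_quantile",
]
_SHIFT_EPS = 1e-3


def pearson_normality_stat(x: np.ndarray) -> float:
    """Pearson chi-square test statistic for normality, per-class normalized.

    The sample is standardized and binned into B = ceil(2 n^0.4) classes that
    are equiprobable under the standard normal; the statistic is
    sum((O_b - n/B)^2 / (n/B)) / B. A standard-normal sample scores near 1;
    zero-variance input scores +inf (worst possible).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        return float("inf")
    z = (x - x.mean()) / sd
    n = z.size
    n_bins = int(np.ceil(2.0 * n**0.4))
    edges = stats.norm.ppf(np.linspace(0.0, 1.0, n_bins + 1))
    counts, _ = np.histogram(z, bins=edges)
    expected = n / n_bins
    return float(np.sum((counts - expected) ** 2 / expected) / n_bins)


@dataclass
class TransformChoice:
    """A fitted normalizing transform for one variable."""

    method: str
    params: dict = field(default_factory=dict)
    normality_stat: float = float("nan")
    mean_: float = 0.0
    sd_: float = 1.0

    def raw(self, x: np.ndarray) -> np.ndarray:
        """Transform without the final standardization."""
        x = np.asarray(x, dtype=float)
        m = self.method
        p = self.params
        if m == "identity":
            return x
        if m == "yeo_johnson":
            return stats.yeojohnson(x, lmbda=p["lmbda"])
        if m == "box_cox":
            # Box-Cox is fitted on positive data; clip new values to the
            # smallest positive training value to stay in-domain.
            return stats.boxcox(np.maximum(x, p["min_positive"]), lmbda=p["lmbda"])
        if m == "log10_shift":
            return np.log10(np.maximum(x + p["a"], _SHIFT_EPS * 1e-6))
        if m == "sqrt_shift":
            return np.sqrt(np.maximum(x + p["a"], 0.0))
        if m == "arcsinh":
            return np.arcsinh(x)
        if m == "ordered_quantile":
            return _orq_apply(x, p["xs"], p["qs"])
        raise ValueError(f"unknown method {m!r}")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (self.raw(x) - self.mean_) / self.sd_

    def to_dict(self) -> dict:
        params = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.params.items()
        }
        return {
            "method": self.method,
            "params": params,
            "normality_stat": self.normality_stat,
            "mean": self.mean_,
            "sd": self.sd_,
        }


def _orq_fit(x: np.ndarray, plotting_position: str = "blom0.5") -> tuple[np.ndarray, np.ndarray]:
    """Ordered-quantile map: training values -> normal quantiles.

    Mid-ranks for ties; plotting position (r - 0.5) / n by default, r/(n+1)
    as the alternative convention.
    """
    n = x.size
    ranks = stats.rankdata(x, method="average")
    if plotting_position == "blom0.5":
        pp = (ranks - 0.5) / n
    elif plotting_position == "vdw":
        pp = ranks / (n + 1.0)
    else:
        raise ValueError(f"unknown plotting position {plotting_position!r}")
    q = stats.norm.ppf(pp)
    xs, inverse = np.unique(x, return_inverse=True)
    qs = np.zeros_like(xs)
    counts = np.zeros_like(xs)
    np.add.at(qs, inverse, q)
    np.add.at(counts, inverse, 1.0)
    qs /= counts
    return xs, qs


def _orq_apply(x: np.ndarray, xs: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """Monotone interpolation of the fitted quantile map with linear tails."""
    xs = np.asarray(xs, float)
    qs = np.asarray(qs, float)
    if xs.size == 1:
        return np.zeros_like(x)
    out = np.interp(x, xs, qs)
    lo_slope = (qs[1] - qs[0]) / max(xs[1] - xs[0], 1e-300)
    hi_slope = (qs[-1] - qs[-2]) / max(xs[-1] - xs[-2], 1e-300)
    below = x < xs[0]
    above = x > xs[-1]
    out[below] = qs[0] + lo_slope * (x[below] - xs[0])
    out[above] = qs[-1] + hi_slope * (x[above] - xs[-1])
    return out


def _fit_candidate(method: str, x: np.ndarray, orq_plotting: str) -> TransformChoice:
    if method == "identity":
        return TransformChoice("identity")
    if method == "yeo_johnson":
        _, lmbda = stats.yeojohnson(x)
        return TransformChoice("yeo_johnson", {"lmbda": float(lmbda)})
    if method == "box_cox":
        if np.min(x) <= 0:
            raise ValueError("Box-Cox requires positive data")
        _, lmbda = stats.boxcox(x)
        return TransformChoice(
            "box_cox", {"lmbda": float(lmbda), "min_positive": float(np.min(x))}
        )
    if method == "log10_shift":
        a = max(_SHIFT_EPS, _SHIFT_EPS - float(np.min(x)))
        return TransformChoice("log10_shift", {"a": a})
    if method == "sqrt_shift":
        a = max(_SHIFT_EPS, _SHIFT_EPS - float(np.min(x)))
        return TransformChoice("sqrt_shift", {"a": a})
    if method == "arcsinh":
        return TransformChoice("arcsinh")
    if method == "ordered_quantile":
        xs, qs = _orq_fit(x, orq_plotting)
        return TransformChoice("ordered_quantile", {"xs": xs, "qs": qs})
    raise ValueError(f"unknown method {method!r}")


def fit_best_transform(
    x: np.ndarray,
    candidates: list[str] | None = None,
    orq_plotting: str = "blom0.5",
) -> TransformChoice:
    """Fit every admissible candidate and keep the most normal-looking one.

    Each candidate is fitted on the training vector, its output standardized,
    and scored with :func:`pearson_normality_stat`; the argmin wins, with
    ties broken toward the earlier (simpler) method in ``METHOD_ORDER``. If
    every candidate fails to fit, the identity is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    if candidates is None:
        candidates = METHOD_ORDER
    best: TransformChoice | None = None
    for method in candidates:
        try:
            choice = _fit_candidate(method, x, orq_plotting)
            t = choice.raw(x)
            if not np.all(np.isfinite(t)):
                continue
            sd = t.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                stat = float("inf")
                choice.mean_, choice.sd_ = float(t.mean()), 1.0
            else:
                choice.mean_, choice.sd_ = float(t.mean()), float(sd)
                stat = pearson_normality_stat(t)
            choice.normality_stat = stat
        except (ValueError, FloatingPointError):
            continue
        if best is None or stat < best.normality_stat:
            best = choice
    if best is None or not np.isfinite(best.normality_stat):
        warnings.warn("all normalizing candidates failed; returning identity")
        fallback = TransformChoice("identity", normality_stat=float("inf"))
        sd = x.std(ddof=1)
        fallback.mean_ = float(x.mean())
        fallback.sd_ = float(sd) if sd > 0 else 1.0
        if best is None or fallback.normality_stat <= best.normality_stat:
            return fallback
    return best
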
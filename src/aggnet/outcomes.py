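"""Outcome construction and their correlation structure.

General psychopathology (the "p-factor") is the first principal component of
the z-scored symptom-scale totals, oriented so that a higher score means more
symptoms. Proneness to aggression is the sum of the twelve BPAQ short-form
items, with physical, verbal, anger and hostility subfactor sums. Pairwise
Pearson correlations between the two outcome families are reported with
Benjamini-Hochberg FDR control over the whole grid of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import BPAQ_SUBFACTORS


@dataclass
class GeneralPsychopathology:
    """First-PC p-factor over symptom-scale totals."""

    score: pd.Series
    loadings: pd.Series
    variance_explained: float
    eigenvalue: float
    # training statistics needed to project new participants
    means: np.ndarray
    sds: np.ndarray
    scale_names: list[str]

    def project(self, scale_scores: pd.DataFrame) -> pd.Series:
        """Score new participants with the fitted loadings and z-statistics."""
        X = scale_scores[self.scale_names].to_numpy(dtype=float)
        Z = (X - self.means) / self.sds
        return pd.Series(Z @ self.loadings.to_numpy(), index=scale_scores.index)


def compute_general_psychopathology(
    scale_scores: pd.DataFrame,
) -> GeneralPsychopathology:
    """PCA-based p-factor: projection on the leading eigenvector.

    PCA is run on the correlation matrix (columns z-scored), the natural
    choice when scales have heterogeneous ranges. The eigenvector is flipped
    when its loading sum is negative so all-positive loadings mean "more
    symptoms scores higher"; scores are the (uncentered-loading) projection,
    hence have mean zero and variance equal to the leading eigenvalue.
    """
    X = scale_scores.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2 or n < 3:
        raise ValueError("need at least 2 scales and 3 participants")
    if np.isnan(X).any():
        raise ValueError("missing values must be handled before PCA")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [c for c, s in zip(scale_scores.columns, sds) if s == 0]
        raise ValueError(f"zero-variance scale(s): {bad}")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    lead = eigvals[-1]
    v = eigvecs[:, -1]
    if v.sum() < 0:
        v = -v
    score = Z @ v
    return GeneralPsychopathology(
        score=pd.Series(score, index=scale_scores.index, name="gpsy"),
        loadings=pd.Series(v, index=scale_scores.columns),
        variance_explained=float(lead / p),
        eigenvalue=float(lead),
        means=means,
        sds=sds,
        scale_names=list(scale_scores.columns),
    )


@dataclass
class AggressionScore:
    """BPAQ total and subfactor sums."""

    total: pd.Series
    subfactors: pd.DataFrame  # physical, verbal, anger, hostility

    def as_frame(self) -> pd.DataFrame:
        out = self.subfactors.copy()
        out.insert(0, "total", self.total)
        return out


def compute_bpaq(
    items: pd.DataFrame, subfactor_map: dict[str, list[str]] | None = None
) -> AggressionScore:
    """Sum the 12 BPAQ items into the total and the four subfactors."""
    if subfactor_map is None:
        subfactor_map = BPAQ_SUBFACTORS
    cols = [c for group in subfactor_map.values() for c in group]
    if len(cols) != 12 or len(set(cols)) != 12:
        raise ValueError("subfactor map must cover 12 distinct items, 3 per factor")
    missing_cols = [c for c in cols if c not in items.columns]
    if missing_cols:
        raise ValueError(f"missing BPAQ items: {missing_cols}")
    if items[cols].isna().any().any():
        raise ValueError("BPAQ items contain missing values; exclude upstream")
    total = items[cols].sum(axis=1)
    total.name = "aggression_total"
    sub = pd.DataFrame(
        {name: items[group].sum(axis=1) for name, group in subfactor_map.items()}
    )
    return AggressionScore(total=total, subfactors=sub)


@dataclass
class CorrelationReport:
    """Pairwise Pearson r with BH-adjusted q-values over the full grid."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame
    alpha: float

    def to_csv(self, path_prefix: str) -> None:
        self.r.to_csv(f"{path_prefix}_r.csv")
        self.p.to_csv(f"{path_prefix}_p.csv")
        self.q.to_csv(f"{path_prefix}_q.csv")
        self.significant.to_csv(f"{path_prefix}_mask.csv")


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p-value from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_with_fdr(
    left: pd.DataFrame, right: pd.DataFrame, alpha: float = 0.05
) -> CorrelationReport:
    """All pairwise correlations between two score families, BH-corrected.

    The FDR family is the full left x right grid. Cells with a constant
    column are flagged NaN and excluded from the family.
    """
    if len(left) != len(right):
        raise ValueError("row counts differ")
    if len(left) < 4:
        raise ValueError("need at least 4 participants")
    r = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    p = r.copy()
    for lc in left.columns:
        for rc in right.columns:
            r.loc[lc, rc], p.loc[lc, rc] = pearson_with_p(
                left[lc].to_numpy(), right[rc].to_numpy()
            )
    q = p.copy()
    flat = p.to_numpy().ravel()
    valid = ~np.isnan(flat)
    qvals = np.full_like(flat, np.nan)
    if valid.any():
        _, q_adj, _, _ = multipletests(flat[valid], method="fdr_bh")
        qvals[valid] = q_adj
    q[:] = qvals.reshape(p.shape)
    sig = q < alpha
    return CorrelationReport(r=r, p=p, q=q, significant=sig, alpha=alpha)
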
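"""Filtering, encoding, imputation, scaling and data splitting.

All fitted statistics (dummy category lists, kept columns, means, standard
deviations, the kNN-imputation reference matrix) come from training rows only
and are carried forward unchanged to test and holdout rows, so nothing a
downstream model sees about unseen participants can leak back into the fit.

The rules implemented here:

* items with strictly more than ``item_missing_threshold`` missing values are
  dropped, as are free-text (string) items;
* participants missing any outcome item, age or sex, or strictly more than
  ``participant_missing_threshold`` of the remaining feature items, are
  excluded;
* nominal items are expanded into one indicator column per category (a full
  indicator set, not reference coding);
* zero-variance training columns are removed;
* every design column is centered and scaled with training statistics;
* remaining missing cells are imputed as the unweighted mean of the k=20
  nearest training rows, with distances computed over mutually observed
  standardized features and rescaled by the fraction observed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from ._utils import check_positive

NUMERIC = "numeric"
NOMINAL = "nominal"
STRING = "string"


@dataclass(frozen=True)
class ItemMeta:
    """Data-dictionary entry for one survey item."""

    scale: str
    type: str  # numeric | nominal | string
    role: str  # feature | outcome


@dataclass
class FeatureTable:
    """Participants x items table with a data dictionary.

    ``values`` holds raw responses (floats for numeric items, labels for
    nominal ones, NaN/None for missing). Every column must appear in the
    dictionary exactly once.
    """

    values: pd.DataFrame
    dictionary: dict[str, ItemMeta]

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.dictionary]
        if missing:
            raise ValueError(f"items absent from dictionary: {missing[:5]}")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def items(self) -> list[str]:
        return list(self.values.columns)

    def subset_rows(self, index) -> "FeatureTable":
        return FeatureTable(self.values.loc[index], self.dictionary)

    def subset_items(self, items: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.values[items], {c: self.dictionary[c] for c in items}
        )

    def items_of_type(self, type_: str) -> list[str]:
        return [c for c in self.values.columns if self.dictionary[c].type == type_]

    def to_csv(self, path) -> None:
        self.values.to_csv(path, na_rep="NA", index=False)

    def dictionary_to_yaml(self, path) -> None:
        import yaml

        payload = {
            item: {"scale": m.scale, "type": m.type, "role": m.role}
            for item, m in self.dictionary.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_csv(cls, csv_path, dictionary_path) -> "FeatureTable":
        import yaml

        with open(dictionary_path) as fh:
            raw = yaml.safe_load(fh)
        dictionary = {k: ItemMeta(**v) for k, v in raw.items()}
        nominal = [k for k, m in dictionary.items() if m.type != NUMERIC]
        values = pd.read_csv(csv_path, na_values=["NA"], keep_default_na=True)
        for col in values.columns:
            if col in nominal:
                values[col] = values[col].astype(object)
        return cls(values, dictionary)


@dataclass(frozen=True)
class PreprocessPlan:
    """Thresholds and knobs for the preprocessing stage."""

    item_missing_threshold: float = 0.25
    participant_missing_threshold: float = 0.05
    knn_k: int = 20
    drop_string_items: bool = True
    min_participants: int = 50

    def __post_init__(self) -> None:
        for name in ("item_missing_threshold", "participant_missing_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        check_positive(self.knn_k, "knn_k")


def filter_items(
    table: FeatureTable, plan: PreprocessPlan
) -> tuple[FeatureTable, dict]:
    """Drop high-missingness and free-text items.

    An item is removed when its missing fraction strictly exceeds
    ``plan.item_missing_threshold`` (so an item at exactly the threshold is
    retained) or when it is a string item and ``plan.drop_string_items``.
    Returns the reduced table and a removal log.
    """
    frac = table.missing_mask.mean(axis=0)
    high_missing = [c for c in table.items if frac[c] > plan.item_missing_threshold]
    string_items = (
        table.items_of_type(STRING) if plan.drop_string_items else []
    )
    removed = set(high_missing) | set(string_items)
    kept = [c for c in table.items if c not in removed]
    if not kept:
        raise ValueError("item filtering removed every item")
    log = {
        "removed_high_missing": high_missing,
        "removed_string": string_items,
        "n_kept": len(kept),
    }
    return table.subset_items(kept), log


def filter_participants(
    table: FeatureTable,
    outcomes: pd.DataFrame,
    plan: PreprocessPlan,
    critical_items: tuple[str, ...] = ("age", "sex"),
) -> tuple[FeatureTable, pd.DataFrame, dict]:
    """Exclude participants with missing outcomes/critical items or sparse rows.

    A participant is excluded when any outcome item is missing, any critical
    item (age, sex) is missing, or strictly more than
    ``plan.participant_missing_threshold`` of the remaining feature items are
    missing.
    """
    if len(table.values) != len(outcomes):
        raise ValueError("feature table and outcomes have different row counts")
    crit = [c for c in critical_items if c in table.values.columns]
    bad_outcome = outcomes.isna().any(axis=1).to_numpy()
    bad_critical = (
        table.values[crit].isna().any(axis=1).to_numpy()
        if crit
        else np.zeros(len(table.values), bool)
    )
    feature_cols = [c for c in table.items if c not in crit]
    sparse = (
        table.values[feature_cols].isna().mean(axis=1)
        > plan.participant_missing_threshold
    ).to_numpy()
    keep = ~(bad_outcome | bad_critical | sparse)
    if keep.sum() < plan.min_participants:
        raise ValueError(
            f"only {int(keep.sum())} participants survive exclusion "
            f"(minimum {plan.min_participants})"
        )
    idx = table.values.index[keep]
    log = {
        "n_excluded": int((~keep).sum()),
        "n_missing_outcome": int(bad_outcome.sum()),
        "n_missing_critical": int(bad_critical.sum()),
        "n_sparse": int(sparse.sum()),
        "n_kept": int(keep.sum()),
    }
    return table.subset_rows(idx), outcomes.loc[idx], log


# ---------------------------------------------------------------------------
# Splitting


@dataclass
class SplitPlan:
    """Fixed discovery/holdout partition plus repeated inner train/test splits."""

    discovery_idx: np.ndarray
    holdout_idx: np.ndarray
    repeat_splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_splits)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "discovery_idx": self.discovery_idx.tolist(),
            "holdout_idx": self.holdout_idx.tolist(),
            "repeat_splits": [
                {"train": tr.tolist(), "test": te.tolist()}
                for tr, te in self.repeat_splits
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            np.asarray(payload["discovery_idx"], dtype=int),
            np.asarray(payload["holdout_idx"], dtype=int),
            [
                (np.asarray(d["train"], dtype=int), np.asarray(d["test"], dtype=int))
                for d in payload["repeat_splits"]
            ],
            payload["seed"],
        )


def make_splits(
    n: int,
    discovery_frac: float = 0.75,
    inner_train_frac: float = 0.75,
    n_repeats: int = 100,
    seed: int = 0,
) -> SplitPlan:
    """One fixed discovery/holdout partition and repeated inner partitions.

    The smaller block of each partition takes the floor of its fractional
    size, so n=2184 with the default 3/4 split yields discovery 1638 and
    holdout 546. Inner train/test splits are drawn independently per repeat;
    everything is reproducible from ``seed``.
    """
    if n < 8:
        raise ValueError("need at least 8 participants to split")
    for name, frac in (("discovery_frac", discovery_frac), ("inner_train_frac", inner_train_frac)):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {frac!r}")
    n_holdout = int(np.floor(n * (1.0 - discovery_frac)))
    rng = np.random.default_rng([seed, 0x0D15C])
    perm = rng.permutation(n)
    holdout = np.sort(perm[:n_holdout])
    discovery = np.sort(perm[n_holdout:])
    n_disc = len(discovery)
    n_test = int(np.floor(n_disc * (1.0 - inner_train_frac)))
    repeat_splits = []
    for r in range(n_repeats):
        rng_r = np.random.default_rng([seed, 1 + r])
        inner = rng_r.permutation(n_disc)
        test = np.sort(inner[:n_test])
        train = np.sort(inner[n_test:])
        repeat_splits.append((train, test))
    return SplitPlan(discovery, holdout, repeat_splits, seed)


# ---------------------------------------------------------------------------
# Encoding, scaling, imputation


def encode(
    table: FeatureTable, dummy_map: dict[str, list] | None = None
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Expand nominal items into full indicator sets; keep numerics as floats.

    Missing nominal responses produce NaN across the item's indicator columns
    (to be imputed later); categories unseen in the fitted ``dummy_map`` map to
    all-zero indicators.
    """
    cols: dict[str, np.ndarray] = {}
    fitted_map: dict[str, list] = {}
    for item in table.items:
        meta = table.dictionary[item]
        col = table.values[item]
        if meta.type == NOMINAL:
            if dummy_map is not None and item in dummy_map:
                cats = dummy_map[item]
            else:
                cats = sorted(col.dropna().unique().tolist(), key=str)
            fitted_map[item] = list(cats)
            isna = col.isna().to_numpy()
            for cat in cats:
                ind = (col == cat).to_numpy(dtype=float)
                ind[isna] = np.nan
                cols[f"{item}={cat}"] = ind
        elif meta.type == NUMERIC:
            cols[item] = col.to_numpy(dtype=float)
        else:  # string items should have been filtered; refuse silently casting
            raise ValueError(f"cannot encode string item {item!r}")
    return pd.DataFrame(cols, index=table.values.index), fitted_map


@dataclass
class FittedTransform:
    """Training-derived statistics for the full preprocessing transform."""

    dummy_map: dict[str, list]
    kept_items: list[str]
    center: np.ndarray
    scale: np.ndarray
    imputer: KNNImputer | None
    dropped_items: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.kept_items)


def _fit_scaler(X: pd.DataFrame) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Identify kept columns and training center/scale from observed entries."""
    kept, dropped = [], []
    centers, scales = [], []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        obs = v[~np.isnan(v)]
        if obs.size == 0:
            warnings.warn(f"column {col!r} observed in zero training rows; dropped")
            dropped.append(col)
            continue
        sd = obs.std(ddof=1) if obs.size > 1 else 0.0
        if sd == 0.0 or not np.isfinite(sd):
            dropped.append(col)
            continue
        kept.append(col)
        centers.append(obs.mean())
        scales.append(sd)
    if not kept:
        raise ValueError("all design columns are constant or unobserved")
    return kept, dropped, np.asarray(centers), np.asarray(scales)


def fit_transform(
    train: FeatureTable,
    plan: PreprocessPlan,
    dummy_map: dict[str, list] | None = None,
) -> tuple[FittedTransform, pd.DataFrame]:
    """Fit the dummy-coding / zero-variance / scaling / imputation transform.

    Returns the fitted transform and the fully processed training design
    matrix (standardized, imputed). ``dummy_map`` may be supplied to pin the
    indicator layout to categories fitted elsewhere (e.g. at discovery level)
    so per-repeat designs stay column-aligned.
    """
    X_raw, fitted_map = encode(train, dummy_map)
    kept, dropped, center, scale = _fit_scaler(X_raw)
    Z = (X_raw[kept].to_numpy(dtype=float) - center) / scale
    imputer = None
    if np.isnan(Z).any():
        k = min(plan.knn_k, max(1, Z.shape[0] - 1))
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        Z = imputer.fit_transform(Z)
        if Z.shape[1] != len(kept):  # a column with no observed values slipped in
            raise RuntimeError("imputer dropped columns unexpectedly")
    ft = FittedTransform(fitted_map, kept, center, scale, imputer, dropped)
    return ft, pd.DataFrame(Z, index=train.values.index, columns=kept)


def apply_transform(ft: FittedTransform, table: FeatureTable) -> pd.DataFrame:
    """Apply a fitted transform to new rows, reusing all training statistics."""
    X_raw, _ = encode(table, ft.dummy_map)
    for col in ft.kept_items:
        if col not in X_raw.columns:
            raise ValueError(f"fitted column {col!r} absent from new data")
    Z = (X_raw[ft.kept_items].to_numpy(dtype=float) - ft.center) / ft.scale
    if np.isnan(Z).any():
        if ft.imputer is None:
            # training data were complete; fall back to training means (zeros)
            Z = np.nan_to_num(Z, nan=0.0)
        else:
            Z = ft.imputer.transform(Z)
    return pd.DataFrame(Z, index=table.values.index, columns=ft.kept_items)


@dataclass
class OutcomeScaler:
    """Center/scale for an outcome, fitted on training rows."""

    mean: float
    sd: float

    @classmethod
    def fit(cls, y: np.ndarray) -> "OutcomeScaler":
        y = np.asarray(y, dtype=float)
        sd = y.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("outcome has zero variance")
        return cls(float(y.mean()), float(sd))

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mean) / self.sd
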
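"""Synthetic community-youth cohort generator.

Emulates the statistical structure the analysis pipeline assumes: a battery of
survey items organised into scales, driven by a small set of latent factors;
two outcomes — general psychopathology (delivered as eight symptom-scale
totals, so the first-principal-component stage is exercised) and proneness to
aggression (delivered as twelve Likert items summing to a BPAQ-style total) —
whose latent determinants overlap through a controllable set of shared
factors; MCAR missingness with a boosted-missingness participant minority; a
minority of nominal and free-text items; and a block of high-missingness items
destined for the 25% item filter.

The generative model, per participant:

* latent factors  z ~ N(0, I_K);
* numeric item i assigned to factor f(i):  x_i = λ_i z_f(i) + sqrt(1-λ_i²) ε,
  unit variance by construction;
* nominal items threshold such a latent continuous variable into 3-5 labeled
  categories at equiprobable normal quantiles;
* outcome signals are linear in disjoint-or-overlapping factor subsets:
  y1 = Σ_{j∈A} w1_j z_j + σ η1,  y2 = Σ_{j∈B} w2_j z_j + σ η2, where
  |A∩B| = round(f · |A|) for shared-factor fraction f;
* symptom-scale totals load on standardized y1; BPAQ items load on
  standardized y2 and are discretized to a right-skewed 1-5 Likert scale.

Every draw comes from one ``numpy.random.default_rng(seed)`` stream, so
generation is byte-identical given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._utils import check_positive, check_proportion
from .preprocess import NUMERIC, NOMINAL, STRING, FeatureTable, ItemMeta

BPAQ_SUBFACTORS = {
    "physical": ["bpaq_01", "bpaq_02", "bpaq_03"],
    "verbal": ["bpaq_04", "bpaq_05", "bpaq_06"],
    "anger": ["bpaq_07", "bpaq_08", "bpaq_09"],
    "hostility": ["bpaq_10", "bpaq_11", "bpaq_12"],
}
SYMPTOM_SCALES = [
    "depression",
    "mania",
    "hypomania",
    "general_anxiety",
    "social_anxiety",
    "ocd",
    "psychotic_like",
    "prodromal",
]
# cumulative category probabilities for the skewed 1-5 Likert BPAQ items
_LIKERT_CUM = np.array([0.60, 0.82, 0.94, 0.985])


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic cohort.

    Defaults emulate the study regime: 2184 participants, 300 items over 29
    scales (of which 60 high-missingness and 10 string items are destined for
    the item filter, leaving 230 features), ~1% of rows made sparse enough to
    trip the participant filter, and two outcomes correlated through shared
    latent factors.
    """

    n_participants: int = 2184
    n_scales: int = 29
    items_per_scale: int = 10
    n_items_total: int | None = 300
    n_latent_factors: int = 12
    loading_range: tuple[float, float] = (0.4, 0.8)
    shared_factor_fraction: float = 0.75
    n_outcome_factors: int = 4
    outcome_weight_range: tuple[float, float] = (0.5, 1.0)
    outcome_noise_sd: float = 0.3
    item_missing_rate: float = 0.001
    participant_missing_boost: float = 0.10
    boosted_participant_fraction: float = 0.05
    outcome_missing_rate: float = 0.005
    n_nominal_items: int = 20
    n_string_items: int = 10
    n_high_missing_items: int = 60
    high_missing_range: tuple[float, float] = (0.30, 0.60)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_scales", "items_per_scale", "n_latent_factors", "n_outcome_factors"):
            check_positive(getattr(self, name), name)
        for name in (
            "shared_factor_fraction",
            "item_missing_rate",
            "participant_missing_boost",
            "boosted_participant_fraction",
            "outcome_missing_rate",
        ):
            check_proportion(getattr(self, name), name)
        lo, hi = self.loading_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("loading_range must be an interval within [0, 1]")
        if self.n_latent_factors > self.total_items:
            raise ValueError("more latent factors than items")
        s = self.n_shared_factors
        if 2 * self.n_outcome_factors - s > self.n_latent_factors:
            raise ValueError(
                "not enough latent factors for the requested outcome subsets"
            )

    @property
    def total_items(self) -> int:
        if self.n_items_total is not None:
            return self.n_items_total
        return self.n_scales * self.items_per_scale

    @property
    def n_shared_factors(self) -> int:
        # round-half-away-from-zero so f=0.5 with 4 relevant factors shares 2
        return int(np.floor(self.shared_factor_fraction * self.n_outcome_factors + 0.5))

    def replace(self, **kwargs) -> "SyntheticConfig":
        payload = asdict(self)
        payload.update(kwargs)
        for key in ("loading_range", "outcome_weight_range", "high_missing_range"):
            payload[key] = tuple(payload[key])
        return SyntheticConfig(**payload)


@dataclass
class GroundTruth:
    """Generative parameters kept for recovery tests."""

    factor_loadings: np.ndarray  # items x factors (numeric+nominal latent loadings)
    item_names: list[str]
    outcome_weights_y1: np.ndarray  # over all K factors, zero off-support
    outcome_weights_y2: np.ndarray
    y1_factors: list[int]
    y2_factors: list[int]
    true_shared_factors: list[int]
    missing_mask: np.ndarray  # participants x items, True where removed
    y1_latent: np.ndarray = field(repr=False, default=None)
    y2_latent: np.ndarray = field(repr=False, default=None)
    factor_scores: np.ndarray = field(repr=False, default=None)

    @property
    def shared_item_names(self) -> list[str]:
        """Items loading on a shared outcome-relevant factor."""
        shared = set(self.true_shared_factors)
        out = []
        for i, name in enumerate(self.item_names):
            j = int(np.argmax(np.abs(self.factor_loadings[i])))
            if j in shared and np.abs(self.factor_loadings[i, j]) > 0:
                out.append(name)
        return out

    def to_json(self, path) -> None:
        payload = {
            "item_names": self.item_names,
            "factor_loadings": self.factor_loadings.tolist(),
            "outcome_weights_y1": self.outcome_weights_y1.tolist(),
            "outcome_weights_y2": self.outcome_weights_y2.tolist(),
            "y1_factors": self.y1_factors,
            "y2_factors": self.y2_factors,
            "true_shared_factors": self.true_shared_factors,
            "missing_mask": self.missing_mask.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _distribute(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + 1 if i < rem else base for i in range(k)]


def _outcome_factor_sets(config: SyntheticConfig) -> tuple[list[int], list[int], list[int]]:
    k = config.n_outcome_factors
    s = config.n_shared_factors
    shared = list(range(s))
    y1 = shared + list(range(s, k))
    y2 = shared + list(range(k, 2 * k - s))
    return y1, y2, shared


def _draw_outcome_signals(config: SyntheticConfig, z: np.ndarray, rng: np.random.Generator):
    """Latent outcome variables (before packaging into scale totals/items)."""
    k = config.n_outcome_factors
    y1_f, y2_f, shared = _outcome_factor_sets(config)
    lo, hi = config.outcome_weight_range
    K = config.n_latent_factors
    w1 = np.zeros(K)
    w2 = np.zeros(K)
    w1[y1_f] = rng.uniform(lo, hi, size=k)
    w2[y2_f] = rng.uniform(lo, hi, size=k)
    # shared factors carry identical weights in both outcomes, so full sharing
    # with zero noise makes the two signals coincide exactly
    w2[shared] = w1[shared]
    n = z.shape[0]
    y1 = z @ w1 + config.outcome_noise_sd * rng.standard_normal(n)
    y2 = z @ w2 + config.outcome_noise_sd * rng.standard_normal(n)
    return y1, y2, w1, w2, y1_f, y2_f, shared


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[FeatureTable, pd.DataFrame, GroundTruth]:
    """Generate one cohort: features, outcome items, and ground truth.

    Returns the feature table (age, sex, and the item battery; raw responses
    with NaN for missing), an outcome frame with the eight symptom-scale
    totals and the twelve BPAQ items, and the generative ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    K = config.n_latent_factors
    z = rng.standard_normal((n, K))

    # --- outcomes ---------------------------------------------------------
    y1, y2, w1, w2, y1_f, y2_f, shared = _draw_outcome_signals(config, z, rng)
    y1_std = (y1 - y1.mean()) / y1.std()
    y2_std = (y2 - y2.mean()) / y2.std()

    outcome_cols: dict[str, np.ndarray] = {}
    scale_loadings = rng.uniform(0.42, 0.58, size=len(SYMPTOM_SCALES))
    for name, c in zip(SYMPTOM_SCALES, scale_loadings):
        eps = rng.standard_normal(n)
        outcome_cols[name] = c * y1_std + np.sqrt(1.0 - c * c) * eps
    bpaq_items = [f"bpaq_{i:02d}" for i in range(1, 13)]
    item_loadings = rng.uniform(0.5, 0.8, size=12)
    cuts = np.array([_ppf(p) for p in _LIKERT_CUM])
    for name, b in zip(bpaq_items, item_loadings):
        latent = b * y2_std + np.sqrt(1.0 - b * b) * rng.standard_normal(n)
        outcome_cols[name] = (np.searchsorted(cuts, latent) + 1).astype(float)
    outcomes = pd.DataFrame(outcome_cols)

    # --- feature battery --------------------------------------------------
    n_items = config.total_items
    n_battery = n_items - 2  # age and sex occupy two of the item slots
    per_scale = _distribute(n_battery, config.n_scales)
    item_names: list[str] = []
    item_scale: list[str] = []
    item_factor: list[int] = []
    for s_idx, count in enumerate(per_scale):
        scale = f"scale_{s_idx + 1:02d}"
        for j in range(count):
            item_names.append(f"s{s_idx + 1:02d}_item{j + 1:02d}")
            item_scale.append(scale)
            item_factor.append(s_idx % K)

    lo, hi = config.loading_range
    lam = rng.uniform(lo, hi, size=n_battery)
    X = np.empty((n, n_battery))
    for i in range(n_battery):
        f = item_factor[i]
        X[:, i] = lam[i] * z[:, f] + np.sqrt(1.0 - lam[i] ** 2) * rng.standard_normal(n)

    # choose string, nominal, and high-missingness items (disjoint groups)
    order = rng.permutation(n_battery)
    str_idx = set(order[: config.n_string_items].tolist())
    nom_idx = set(
        order[config.n_string_items : config.n_string_items + config.n_nominal_items].tolist()
    )
    hm_start = config.n_string_items + config.n_nominal_items
    hm_idx = set(order[hm_start : hm_start + config.n_high_missing_items].tolist())

    values: dict[str, np.ndarray] = {}
    dictionary: dict[str, ItemMeta] = {}
    # sociodemographics: age ~ N(19.9, 2.8) clipped to [15, 24]; sex 41% male
    age = np.clip(rng.normal(19.9, 2.8, size=n), 15.0, 24.9)
    sex = np.where(rng.random(n) < 0.412, "male", "female").astype(object)
    values["age"] = age
    values["sex"] = sex
    dictionary["age"] = ItemMeta("scale_01", NUMERIC, "feature")
    dictionary["sex"] = ItemMeta("scale_01", NOMINAL, "feature")

    loadings_full = np.zeros((n_battery, K))
    for i, name in enumerate(item_names):
        scale = item_scale[i]
        loadings_full[i, item_factor[i]] = lam[i]
        if i in str_idx:
            tokens = rng.integers(0, 10_000, size=n)
            values[name] = np.array([f"txt{t}" for t in tokens], dtype=object)
            dictionary[name] = ItemMeta(scale, STRING, "feature")
        elif i in nom_idx:
            n_cat = int(rng.integers(3, 6))
            cuts = [_ppf(q) for q in np.linspace(0, 1, n_cat + 1)[1:-1]]
            codes = np.searchsorted(np.asarray(cuts), X[:, i])
            values[name] = np.array([f"c{c}" for c in codes], dtype=object)
            dictionary[name] = ItemMeta(scale, NOMINAL, "feature")
        else:
            values[name] = X[:, i].copy()
            dictionary[name] = ItemMeta(scale, NUMERIC, "feature")

    table = pd.DataFrame(values)

    # --- missingness ------------------------------------------------------
    feature_cols = list(table.columns)
    rate = np.full(len(feature_cols), config.item_missing_rate)
    name_to_pos = {nm: p for p, nm in enumerate(feature_cols)}
    for i in hm_idx:
        rate[name_to_pos[item_names[i]]] = rng.uniform(*config.high_missing_range)
    mask = rng.random((n, len(feature_cols))) < rate[None, :]
    boosted = rng.random(n) < config.boosted_participant_fraction
    extra = rng.random((n, len(feature_cols))) < config.participant_missing_boost
    mask |= boosted[:, None] & extra
    for p, col in enumerate(feature_cols):
        col_mask = mask[:, p]
        if col_mask.any():
            if table[col].dtype == object:
                table.loc[col_mask, col] = None
            else:
                table.loc[col_mask, col] = np.nan
    out_mask = rng.random(outcomes.shape) < config.outcome_missing_rate
    outcomes = outcomes.mask(out_mask)

    truth = GroundTruth(
        factor_loadings=loadings_full,
        item_names=item_names,
        outcome_weights_y1=w1,
        outcome_weights_y2=w2,
        y1_factors=y1_f,
        y2_factors=y2_f,
        true_shared_factors=shared,
        missing_mask=mask,
        y1_latent=y1,
        y2_latent=y2,
        factor_scores=z,
    )
    return FeatureTable(table, dictionary), outcomes, truth


def _ppf(p: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(p))


def simulated_outcome_r(config: SyntheticConfig, n_probe: int, seed: int) -> float:
    """Correlation between delivered outcome scores at probe size.

    Uses the mean of standardized symptom-scale totals as a light proxy for
    the first principal component (the scales are positively loaded on a
    single construct, where PC1 and the standardized mean nearly coincide)
    against the BPAQ total.
    """
    probe = config.replace(
        n_participants=n_probe,
        seed=seed,
        item_missing_rate=0.0,
        outcome_missing_rate=0.0,
        participant_missing_boost=0.0,
        n_items_total=max(config.n_latent_factors, 40) + 2,
        n_string_items=0,
        n_nominal_items=0,
        n_high_missing_items=0,
    )
    _, outcomes, _ = generate_cohort(probe)
    scales = outcomes[SYMPTOM_SCALES].to_numpy()
    proxy = ((scales - scales.mean(0)) / scales.std(0)).mean(axis=1)
    bpaq = outcomes[[c for c in outcomes if c.startswith("bpaq_")]].sum(axis=1)
    return float(np.corrcoef(proxy, bpaq)[0, 1])


def tune_overlap_for_target_r(
    config: SyntheticConfig,
    target_r: float,
    n_probe: int = 5000,
    tol: float = 0.05,
    max_iter: int = 30,
) -> SyntheticConfig:
    """Calibrate shared-factor fraction and outcome noise to a target r.

    The shared-factor count is discrete, so the search first picks the
    smallest shared fraction whose simulated outcome correlation reaches the
    target, then bisects on ``outcome_noise_sd`` to land within ``tol``.
    Raises when the target is not bracketed by any attainable configuration.
    """
    if not 0.0 <= target_r < 1.0:
        raise ValueError("target_r must lie in [0, 1)")
    if target_r == 0.0:
        return config.replace(shared_factor_fraction=0.0)
    k = config.n_outcome_factors

    def probe_r(cfg: SyntheticConfig) -> float:
        rs = [simulated_outcome_r(cfg, n_probe, seed) for seed in (11, 12, 13)]
        return float(np.mean(rs))

    chosen = None
    for s in range(1, k + 1):
        cand = config.replace(shared_factor_fraction=s / k)
        r = probe_r(cand)
        if r >= target_r - tol:
            chosen, r_at = cand, r
            break
    if chosen is None:
        raise RuntimeError(
            f"target r={target_r} unattainable: even full sharing at "
            f"noise sd {config.outcome_noise_sd} stays below it"
        )
    if abs(r_at - target_r) <= tol:
        return chosen
    # too correlated: increase noise. Bracket then bisect.
    lo_sd, hi_sd = chosen.outcome_noise_sd, max(1.0, chosen.outcome_noise_sd * 2)
    r_hi = probe_r(chosen.replace(outcome_noise_sd=hi_sd))
    tries = 0
    while r_hi > target_r and tries < 8:
        hi_sd *= 2.0
        r_hi = probe_r(chosen.replace(outcome_noise_sd=hi_sd))
        tries += 1
    if r_hi > target_r:
        raise RuntimeError("bracketing failure: noise cannot pull r down to target")
    for _ in range(max_iter):
        mid = 0.5 * (lo_sd + hi_sd)
        r_mid = probe_r(chosen.replace(outcome_noise_sd=mid))
        if abs(r_mid - target_r) <= tol * 0.6:
            return chosen.replace(outcome_noise_sd=mid)
        if r_mid > target_r:
            lo_sd = mid
        else:
            hi_sd = mid
    return chosen.replace(outcome_noise_sd=0.5 * (lo_sd + hi_sd))
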
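"""Four-selector biomarker nexus: point-biserial, chi-square, ANOVA, RFE.

Three classical univariate tests plus recursive feature elimination with a
random-forest backend are run against a binary-labelled cohort; their
selected sets can be combined by union, intersection or k-of-m voting.
Zero-variance features are dropped with a warning in every selector
rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from statsmodels.stats.multitest import multipletests

from .cigt import CIGTDataset

logger = logging.getLogger(__name__)

CombineMode = Literal["union", "intersection", "vote_k"]


class EmptySelectionError(ValueError):
    """No feature survived the requested combination of selectors."""


@dataclass(frozen=True)
class SelectorResult:
    """Per-feature output of one selector.

    ``statistic``/``p_value`` are NaN for features the selector excluded
    (zero variance). RFE carries ranks instead of p-values; rank 1 means
    kept.
    """

    selector: str
    feature_names: tuple[str, ...]
    statistic: np.ndarray
    p_value: np.ndarray | None
    rank: np.ndarray | None
    selected: frozenset[str]
    excluded: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.feature_names, "statistic": self.statistic})
        if self.p_value is not None:
            df["p_value"] = self.p_value
        if self.rank is not None:
            df["rank"] = self.rank
        df["selected"] = [f in self.selected for f in self.feature_names]
        return df


@dataclass(frozen=True)
class FeatureSet:
    """Combined biomarker list with per-feature selector provenance."""

    features: tuple[str, ...]
    provenance: dict[str, frozenset[str]]
    combine_mode: str

    def __post_init__(self) -> None:
        if not self.features:
            raise EmptySelectionError("a FeatureSet cannot be empty")

    def __len__(self) -> int:
        return len(self.features)


def _variance_mask(ds: CIGTDataset, selector: str) -> np.ndarray:
    """True for features with nonzero variance; warn about the rest."""
    var = ds.values.var(axis=0)
    mask = var > 0
    dropped = [f for f, ok in zip(ds.feature_names, mask) if not ok]
    if dropped:
        logger.warning("%s: excluding %d zero-variance feature(s): %s",
                       selector, len(dropped), dropped)
    if not mask.any():
        raise ValueError(f"{selector}: all features have zero variance")
    return mask


def pearson_select(ds: CIGTDataset, alpha: float = 0.05) -> SelectorResult:
    """Point-biserial screen: Pearson r of each feature against the 0/1 label.

    Significance uses the exact t transform t = r*sqrt((n-2)/(1-r^2)) on
    n-2 degrees of freedom, two-sided, identical to the usual Pearson
    correlation test for a dichotomous variate.
    """
    n = ds.n_samples
    if n < 3:
        raise ValueError(f"need >=3 samples for a correlation test; got {n}")
    mask = _variance_mask(ds, "pearson")
    y = ds.labels.astype(float)
    yc = y - y.mean()
    X = ds.values
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 0.0, p)  # |r| == 1 -> t = inf -> p = 0
    r[~mask] = np.nan
    p[~mask] = np.nan
    selected = frozenset(
        f for f, ok, pv in zip(ds.feature_names, mask, p) if ok and pv < alpha
    )
    return SelectorResult(
        selector="pearson",
        feature_names=tuple(ds.feature_names),
        statistic=r,
        p_value=p,
        rank=None,
        selected=selected,
        excluded=tuple(f for f, ok in zip(ds.feature_names, mask) if not ok),
    )


def chi2_select(ds: CIGTDataset, alpha: float = 0.05) -> SelectorResult:
    """Pearson chi-square contingency test of each feature against the label.

    Expression is continuous (and can be negative after upstream
    normalization), so each feature is dichotomized at its pooled mean —
    a monotone, label-free cut — and the resulting 2 x n_classes
    contingency table of low/high counts is tested with the classic
    Pearson chi-square statistic (no continuity correction) on
    n_classes - 1 degrees of freedom. Counts keep the test's null
    distribution honest where raw continuous totals would not, and the
    pooled-mean cut leaves the table margin random rather than pinned at
    n/2, which keeps the rejection rate close to nominal. A table
    [[20, 10], [10, 20]] scores 6.667 (expected count 15 per cell).

    Features whose dichotomization leaves an empty level (all values on
    one side of the mean) are excluded with a warning alongside
    zero-variance features.
    """
    mask = _variance_mask(ds, "chi2")
    statistic = np.full(ds.n_features, np.nan)
    p_value = np.full(ds.n_features, np.nan)
    y = ds.labels
    degenerate: list[str] = []
    for j in np.flatnonzero(mask):
        x = ds.values[:, j]
        high = x > x.mean()
        table = np.array(
            [
                [(~high)[y == 0].sum(), high[y == 0].sum()],
                [(~high)[y == 1].sum(), high[y == 1].sum()],
            ],
            dtype=float,
        )
        if (table.sum(axis=0) == 0).any():
            degenerate.append(ds.feature_names[j])
            mask[j] = False
            continue
        expected = table.sum(1, keepdims=True) * table.sum(0, keepdims=True) / table.sum()
        statistic[j] = ((table - expected) ** 2 / expected).sum()
        p_value[j] = stats.chi2.sf(statistic[j], df=len(np.unique(y)) - 1)
    if degenerate:
        logger.warning("chi2: excluding %d feature(s) with a degenerate mean "
                       "split: %s", len(degenerate), degenerate)
    selected = frozenset(
        f for f, ok, pv in zip(ds.feature_names, mask, p_value) if ok and pv < alpha
    )
    return SelectorResult(
        selector="chi2",
        feature_names=tuple(ds.feature_names),
        statistic=statistic,
        p_value=p_value,
        rank=None,
        selected=selected,
        excluded=tuple(f for f, ok in zip(ds.feature_names, mask) if not ok),
    )


def anova_select(ds: CIGTDataset, alpha: float = 0.05) -> SelectorResult:
    """One-way ANOVA F test between case and control groups per feature.

    With two groups the F statistic equals the square of the pooled
    two-sample t statistic; p-values come from F(1, n-2).
    """
    for cls in (0, 1):
        if (ds.labels == cls).sum() < 2:
            raise ValueError(f"class {cls} has <2 samples; ANOVA needs >=2 per group")
    mask = _variance_mask(ds, "anova")
    F, p = stats.f_oneway(
        ds.values[ds.labels == 1][:, mask], ds.values[ds.labels == 0][:, mask]
    )
    statistic = np.full(ds.n_features, np.nan)
    p_value = np.full(ds.n_features, np.nan)
    statistic[mask] = F
    p_value[mask] = p
    # zero within-group variance with zero between-group variance -> NaN F;
    # treat as excluded (already caught by the variance mask for constants)
    selected = frozenset(
        f
        for f, ok, pv in zip(ds.feature_names, mask, p_value)
        if ok and np.isfinite(pv) and pv < alpha
    )
    return SelectorResult(
        selector="anova",
        feature_names=tuple(ds.feature_names),
        statistic=statistic,
        p_value=p_value,
        rank=None,
        selected=selected,
        excluded=tuple(f for f, ok in zip(ds.feature_names, mask) if not ok),
    )


def default_n_keep(n_features: int, fraction: float = 0.10) -> int:
    """Default RFE retention: the top ~10% of features, at least one."""
    return max(1, round(fraction * n_features))


def rfe_select(
    ds: CIGTDataset, n_keep: int | None = None, seed: int = 0
) -> SelectorResult:
    """Recursive feature elimination with a random-forest importance backend.

    One feature is removed per iteration (step=1) until ``n_keep`` remain;
    ranks are 1 for kept features and increase in elimination order.
    Deterministic given the seed.
    """
    if n_keep is None:
        n_keep = default_n_keep(ds.n_features)
    if not 1 <= n_keep <= ds.n_features:
        raise ValueError(f"n_keep must be in [1, {ds.n_features}]; got {n_keep}")
    estimator = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    rfe = RFE(estimator, n_features_to_select=n_keep, step=1)
    rfe.fit(ds.values, ds.labels)
    ranks = rfe.ranking_.astype(int)
    selected = frozenset(f for f, r in zip(ds.feature_names, ranks) if r == 1)
    return SelectorResult(
        selector="rfe",
        feature_names=tuple(ds.feature_names),
        statistic=(-ranks).astype(float),  # higher = kept earlier
        p_value=None,
        rank=ranks,
        selected=selected,
    )


def apply_bh(result: SelectorResult, alpha: float = 0.05) -> SelectorResult:
    """Re-threshold a statistical selector with Benjamini-Hochberg FDR control."""
    if result.p_value is None:
        raise ValueError("BH correction needs p-values; RFE has none")
    finite = np.isfinite(result.p_value)
    reject = np.zeros(len(result.feature_names), dtype=bool)
    if finite.any():
        reject[finite] = multipletests(result.p_value[finite], alpha=alpha, method="fdr_bh")[0]
    selected = frozenset(f for f, rj in zip(result.feature_names, reject) if rj)
    return SelectorResult(
        selector=result.selector,
        feature_names=result.feature_names,
        statistic=result.statistic,
        p_value=result.p_value,
        rank=result.rank,
        selected=selected,
        excluded=result.excluded,
    )


def combine_selections(
    results: Sequence[SelectorResult],
    feature_order: Sequence[str],
    mode: CombineMode = "union",
    vote_k: int = 2,
    force_include: Sequence[str] = (),
) -> FeatureSet:
    """Combine selector outputs into one ordered biomarker list.

    ``feature_order`` (normally the CIGT column order) fixes the output
    ordering. ``force_include`` features are appended regardless of votes
    (e.g. demographics a user always wants carried into the model).
    """
    if not results:
        raise ValueError("need at least one SelectorResult")
    if mode == "vote_k" and vote_k > len(results):
        raise ValueError(f"vote_k={vote_k} exceeds the {len(results)} selectors supplied")
    votes: dict[str, set[str]] = {}
    for res in results:
        for f in res.selected:
            votes.setdefault(f, set()).add(res.selector)
    if mode == "union":
        chosen = set(votes)
    elif mode == "intersection":
        chosen = {f for f, v in votes.items() if len(v) == len(results)}
    elif mode == "vote_k":
        chosen = {f for f, v in votes.items() if len(v) >= vote_k}
    else:
        raise ValueError(f"unknown combine mode: {mode!r}")
    chosen |= set(force_include)
    ordered = tuple(f for f in feature_order if f in chosen)
    if not ordered:
        raise EmptySelectionError(
            f"no features survive mode={mode!r} over {len(results)} selectors; "
            "relax alpha, switch to union, or lower vote_k"
        )
    provenance = {f: frozenset(votes.get(f, set())) for f in ordered}
    return FeatureSet(features=ordered, provenance=provenance, combine_mode=mode)


def selection_table(results: Sequence[SelectorResult], fs: FeatureSet) -> pd.DataFrame:
    """Assemble the biomarker-list table written by the `select` stage."""
    rows = []
    by_name = {r.selector: r for r in results}
    for f in fs.features:
        row: dict[str, object] = {"feature": f}
        for name, res in by_name.items():
            j = res.feature_names.index(f)
            row[f"{name}_statistic"] = res.statistic[j]
            if res.p_value is not None:
                row[f"{name}_p_value"] = res.p_value[j]
            if res.rank is not None:
                row[f"{name}_rank"] = res.rank[j]
        row["selectors"] = "|".join(sorted(fs.provenance[f]))
        rows.append(row)
    return pd.DataFrame(rows)
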
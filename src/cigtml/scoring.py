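"""I-Gene scores: concentration-weighted aggregation of feature attributions.

The I-Gene score of a biomarker summarizes how much the prediction
ensemble relies on it, weighting each classifier by how *concentrated*
that classifier's reliance is:

1. For each base classifier, per-feature importance is the mean absolute
   attribution over evaluation samples, normalized to shares summing to 1.
2. Each classifier's Herfindahl-Hirschman index, HHI = sum of squared
   shares, measures concentration (1/n for uniform reliance, 1 when a
   single biomarker carries everything). Classifiers whose predictions
   rest on few biomarkers receive proportionally greater weight.
3. The raw I-Gene score of a feature is the HHI-weight-averaged share
   across classifiers; raw scores sum to 1 over features by construction,
   and displayed scores are rescaled so the top feature prints 100.

Each feature also receives a direction label — overexpressed,
underexpressed or neutral — describing whether high or low values push
the ensemble toward a case call. Voters (soft/hard) are excluded from
attribution aggregation: majority voting has no probabilistic output of
its own to explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import AttributionMatrix, compute_attributions
from .cigt import CIGTDataset
from .ensemble import EnsembleModel

logger = logging.getLogger(__name__)

OVEREXPRESSED = "overexpressed"
UNDEREXPRESSED = "underexpressed"
NEUTRAL = "neutral"

#: default directionality threshold on the weighted value-attribution
#: correlation; below it a feature is labelled neutral rather than
#: over/underexpressed, avoiding direction calls on noise-level features
DEFAULT_TAU = 0.1

#: default cap on background rows handed to the explainers
DEFAULT_BACKGROUND_SIZE = 100


class DegenerateAttributionError(ValueError):
    """Every classifier produced all-zero attributions; nothing to score."""


def importance_shares(att: AttributionMatrix) -> np.ndarray | None:
    """Normalized global importance of each feature for one classifier.

    Raw importance is the mean |phi| over samples; shares are raw values
    divided by their sum. Returns None (degenerate) when every
    attribution is zero, e.g. for a constant model.
    """
    raw = att.mean_abs()
    total = raw.sum()
    if total == 0:
        logger.warning("%s: all-zero attributions; classifier flagged degenerate",
                       att.classifier)
        return None
    return raw / total


def hhi(shares: Sequence[float]) -> float:
    """Herfindahl-Hirschman concentration of a share vector.

    Shares must be non-negative and sum to 1 (within 1e-9); the result
    lies in [1/n, 1] — 1/n for perfectly uniform shares, 1 when one
    feature holds all importance. The unit-interval convention is used,
    not the x10,000 economics scale.
    """
    shares = np.asarray(shares, dtype=float)
    if (shares < 0).any():
        raise ValueError("shares must be non-negative")
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError(f"shares must sum to 1; got {shares.sum()!r}")
    return float((shares**2).sum())


def classifier_weights(hhis: Mapping[str, float]) -> dict[str, float]:
    """HHI-proportional weights over non-degenerate classifiers.

    weight_c = HHI_c / sum(HHI); monotone in HHI, summing to 1.
    """
    if not hhis:
        raise DegenerateAttributionError(
            "no non-degenerate classifier available; I-Gene scoring impossible"
        )
    total = sum(hhis.values())
    return {name: h / total for name, h in hhis.items()}


def igene_scores(
    shares_by_classifier: Mapping[str, np.ndarray],
    weights: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate per-classifier shares into raw and displayed I-Gene scores.

    raw_f = sum_c weight_c * share_{c,f}; since weights and each share
    vector sum to 1, raw scores sum to 1 across features. Displayed
    scores rescale raw by its maximum onto 0-100.
    Returns ``(raw, displayed)``.
    """
    if set(shares_by_classifier) != set(weights):
        raise ValueError(
            f"classifier sets differ: shares {sorted(shares_by_classifier)} "
            f"vs weights {sorted(weights)}"
        )
    lengths = {len(s) for s in shares_by_classifier.values()}
    if len(lengths) != 1:
        raise ValueError(f"classifiers disagree on feature count: {sorted(lengths)}")
    (d,) = lengths
    raw = np.zeros(d)
    for name, shares in shares_by_classifier.items():
        raw += weights[name] * np.asarray(shares, dtype=float)
    top = raw.max()
    displayed = 100.0 * raw / top if top > 0 else np.zeros_like(raw)
    return raw, displayed


DirectionMethod = Literal["correlation", "positive_mean_compare"]


def direction(
    att_by_classifier: Mapping[str, AttributionMatrix],
    X: np.ndarray,
    labels: np.ndarray | None,
    weights: Mapping[str, float],
    tau: float = DEFAULT_TAU,
    method: DirectionMethod = "correlation",
) -> tuple[list[str], np.ndarray]:
    """Direction labels for each feature, plus the underlying statistic.

    ``correlation`` (default): per classifier, the Pearson correlation
    between feature values and per-sample attributions, weight-averaged
    across classifiers. A positive weighted correlation means high values
    push toward a case call — the feature is overexpressed in cases; a
    negative one means low values do — underexpressed. |statistic| <= tau
    is labelled neutral.

    ``positive_mean_compare``: restricted to samples whose attribution for
    the feature is positive (i.e. pushes toward a case call), compare mean
    feature values of cases against controls, standardized by the overall
    feature SD and weight-averaged; positive means cases sit higher —
    overexpressed. Requires ``labels``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    stat = np.zeros(d)
    sd = X.std(axis=0)
    for j in range(d):
        if sd[j] == 0:
            logger.warning("feature column %d has zero variance; direction neutral", j)
            stat[j] = 0.0
            continue
        acc = 0.0
        for name, w in weights.items():
            phi_j = att_by_classifier[name].phi[:, j]
            if method == "correlation":
                if phi_j.std() == 0:
                    contrib = 0.0
                else:
                    contrib = float(np.corrcoef(X[:, j], phi_j)[0, 1])
            elif method == "positive_mean_compare":
                if labels is None:
                    raise ValueError("positive_mean_compare requires labels")
                pos = phi_j > 0
                case = pos & (labels == 1)
                ctrl = pos & (labels == 0)
                if case.any() and ctrl.any():
                    contrib = float(
                        (X[case, j].mean() - X[ctrl, j].mean()) / sd[j]
                    )
                else:
                    contrib = 0.0
            else:
                raise ValueError(f"unknown direction method: {method!r}")
            acc += w * contrib
        stat[j] = acc
    names = [
        OVEREXPRESSED if s > tau else UNDEREXPRESSED if s < -tau else NEUTRAL
        for s in stat
    ]
    return names, stat


@dataclass(frozen=True)
class IGeneProfile:
    """Full per-biomarker scoring table plus the per-classifier weights."""

    table: pd.DataFrame
    weights: dict[str, float]
    hhis: dict[str, float]
    degenerate: tuple[str, ...]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_igene_profile(
    model: EnsembleModel,
    eval_ds: CIGTDataset,
    seed: int = 0,
    tau: float = DEFAULT_TAU,
    direction_method: DirectionMethod = "correlation",
    background_size: int = DEFAULT_BACKGROUND_SIZE,
    n_permutations: int = 20,
    algorithm: str = "auto",
) -> IGeneProfile:
    """End-to-end I-Gene scoring of a fitted ensemble on an evaluation cohort.

    Attributions are computed for the five probabilistic base members on
    the standardized evaluation matrix, against a background of training
    rows subsampled (seeded) to ``background_size``. Classifiers whose
    explainer fails or degenerates are excluded with a warning, never
    silently zero-filled.
    """
    X_eval = model.transform(eval_ds)
    if model.train_matrix_ is None:
        raise ValueError("model carries no training matrix to use as background")
    background = model.train_matrix_
    if len(background) > background_size:
        rng = np.random.default_rng(seed)
        background = background[
            rng.choice(len(background), size=background_size, replace=False)
        ]

    atts: dict[str, AttributionMatrix] = {}
    shares: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    for name, clf in model.members.items():
        try:
            att = compute_attributions(
                clf,
                X_eval,
                background,
                classifier=name,
                algorithm=algorithm,
                n_permutations=n_permutations,
                seed=seed,
            )
        except Exception as exc:  # pragma: no cover - defensive path
            logger.warning("%s: explainer failed (%s); excluded from scoring", name, exc)
            degenerate.append(name)
            continue
        s = importance_shares(att)
        if s is None:
            degenerate.append(name)
            continue
        atts[name] = att
        shares[name] = s

    hhis = {name: hhi(s) for name, s in shares.items()}
    weights = classifier_weights(hhis)
    raw, displayed = igene_scores(shares, weights)
    labels, stat = direction(
        atts, X_eval, eval_ds.labels, weights, tau=tau, method=direction_method
    )

    order = np.argsort(-raw, kind="stable")
    ranks = np.empty(len(raw), dtype=int)
    ranks[order] = np.arange(1, len(raw) + 1)

    table = pd.DataFrame(
        {
            "feature": list(model.feature_names),
            "igene_score": displayed,
            "raw_score": raw,
            "direction": labels,
            "direction_statistic": stat,
            "rank": ranks,
        }
    )
    for name in sorted(shares):
        table[f"share_{name}"] = shares[name]
        table[f"weight_{name}"] = weights[name]
    table = table.sort_values("rank", kind="stable").reset_index(drop=True)
    return IGeneProfile(
        table=table, weights=weights, hhis=hhis, degenerate=tuple(degenerate)
    )
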
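"""Reproducible recovery benchmarks on synthetic cohorts.

Two standard studies back the package's claims about itself: a
planted-signal recovery study (can the pipeline re-find genes whose
class-conditional means were shifted by a known effect size, rank them on
top, and call their polarity?) and a null calibration study (do the
statistical selectors reject at their nominal rate when no signal
exists?). Both are deterministic given their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cigt import split_dataset
from .ensemble import evaluate, train_ensemble
from .pipeline import PipelineConfig, _substream_seeds, run_selection
from .scoring import OVEREXPRESSED, UNDEREXPRESSED, compute_igene_profile
from .select import anova_select, chi2_select, pearson_select
from .simulate import UP, SynthConfig, generate_cigt


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of one planted-signal replicate."""

    seed: int
    selection_recall: float
    heldout_accuracy: float  # soft-vote accuracy on the 30% held-out split
    planted_in_top10: bool  # all planted genes within the top-10 I-Gene ranks
    direction_agreement: float  # planted genes whose direction label matches truth
    n_selected: int


def recovery_replicate(
    seed: int,
    cfg: SynthConfig | None = None,
    test_fraction: float = 0.3,
    background_size: int = 50,
    n_permutations: int = 10,
) -> RecoveryResult:
    """Run select -> train -> evaluate -> score once on a fresh cohort."""
    cfg = cfg or SynthConfig(seed=seed)
    if cfg.seed != seed:
        cfg = SynthConfig(**{**cfg.__dict__, "seed": seed})
    ds, truth = generate_cigt(cfg)
    seeds = _substream_seeds(seed)
    train, test = split_dataset(ds, test_fraction, seed=seeds["split"])
    _, fs = run_selection(train, PipelineConfig(seed=seed), seeds["rfe"])
    planted = set(truth.informative_genes)
    recall = len(planted & set(fs.features)) / len(planted)
    model = train_ensemble(train, fs, seed=seeds["ensemble"])
    _, metrics = evaluate(model, test)
    soft_acc = float(
        metrics.loc[metrics["classifier"] == "soft_vote", "accuracy"].iloc[0]
    )
    profile = compute_igene_profile(
        model,
        test,
        seed=seeds["explainer"],
        background_size=background_size,
        n_permutations=n_permutations,
    )
    table = profile.table
    top10 = set(table.nsmallest(min(10, len(table)), "rank")["feature"])
    scored = planted & set(table["feature"])
    in_top = planted <= top10
    by_feature = table.set_index("feature")["direction"]
    agree = sum(
        by_feature[g] == (OVEREXPRESSED if truth.directions[g] == UP else UNDEREXPRESSED)
        for g in scored
    )
    return RecoveryResult(
        seed=seed,
        selection_recall=recall,
        heldout_accuracy=soft_acc,
        planted_in_top10=in_top,
        direction_agreement=agree / len(planted),
        n_selected=len(fs),
    )


def null_selection_rates(
    seed: int, n_features: int = 1000, n_per_class: int = 100, alpha: float = 0.05
) -> dict[str, float]:
    """Per-selector selection rate on a cohort with no true signal."""
    ds, _ = generate_cigt(
        SynthConfig(
            n_cases=n_per_class,
            n_controls=n_per_class,
            n_genes=n_features,
            n_informative=0,
            effect_size=0.0,
            seed=seed,
        )
    )
    rates = {}
    for select in (pearson_select, chi2_select, anova_select):
        res = select(ds, alpha=alpha)
        rates[res.selector] = len(res.selected) / n_features
    return rates
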
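"""Pipeline orchestration: select -> classify -> score, with file outputs.

One seed fans out to named substreams (split, RFE, ensemble, explainer,
plot jitter) so a single integer reproduces every stochastic stage.
Outputs are written deterministically: two runs with the same config and
seed produce byte-identical CSVs.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from . import __version__
from .cigt import CIGTDataset, read_cigt, split_dataset
from .ensemble import BASE_MEMBERS, EnsembleConfig, evaluate, train_ensemble
from .plots import summary_plot
from .scoring import DEFAULT_BACKGROUND_SIZE, DEFAULT_TAU, compute_igene_profile
from .select import (
    anova_select,
    apply_bh,
    chi2_select,
    combine_selections,
    pearson_select,
    rfe_select,
    selection_table,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for error reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; serializes to flat key=value text."""

    input_path: str = ""
    output_dir: str = "cigtml_out"
    id_column: str = "ID"
    label_column: str = "Type"
    alpha: float = 0.05
    combine_mode: str = "union"
    vote_k: int = 2
    n_keep: int = 0  # 0 -> default 10% rule
    use_bh: bool = False
    enabled_members: str = ",".join(BASE_MEMBERS)
    test_fraction: float = 0.3
    tau: float = DEFAULT_TAU
    direction_method: str = "correlation"
    background_size: int = DEFAULT_BACKGROUND_SIZE
    n_permutations: int = 20
    top_fraction: float = 0.10
    plot_top_n: int = 10
    seed: int = 42

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name}={getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.strip().lower() in ("1", "true", "yes")
            else:
                kwargs[key] = type(current)(value.strip())
        return cls(**kwargs)


def _substream_seeds(seed: int) -> dict[str, int]:
    """Named, decorrelated 31-bit seeds fanned out from one base seed."""
    names = ("split", "rfe", "ensemble", "explainer", "plot")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_selection(ds: CIGTDataset, cfg: PipelineConfig, seed_rfe: int):
    """Run the four selectors and combine them per the config."""
    results = [
        pearson_select(ds, alpha=cfg.alpha),
        chi2_select(ds, alpha=cfg.alpha),
        anova_select(ds, alpha=cfg.alpha),
        rfe_select(ds, n_keep=cfg.n_keep or None, seed=seed_rfe),
    ]
    if cfg.use_bh:
        results = [apply_bh(r, alpha=cfg.alpha) if r.p_value is not None else r
                   for r in results]
    fs = combine_selections(
        results, ds.feature_names, mode=cfg.combine_mode, vote_k=cfg.vote_k
    )
    return results, fs


def run_pipeline(cfg: PipelineConfig, dataset: CIGTDataset | None = None) -> dict[str, Path]:
    """Execute select -> classify -> score and write all outputs.

    Returns a mapping of output names to written paths. On a stage
    failure a MANIFEST file marks the run incomplete and a
    :class:`StageError` propagates with the stage name.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    seeds = _substream_seeds(cfg.seed)
    manifest = out / "MANIFEST"

    def finish_manifest(status: str) -> None:
        lines = [f"status: {status}"] + [f"{k}: {v.name}" for k, v in written.items()]
        manifest.write_text("\n".join(lines) + "\n")

    try:
        try:
            ds = dataset if dataset is not None else read_cigt(
                cfg.input_path, id_column=cfg.id_column, label_column=cfg.label_column
            )
        except Exception as exc:
            raise StageError("read", exc) from exc

        try:
            train, test = split_dataset(ds, cfg.test_fraction, seed=seeds["split"])
        except Exception as exc:
            raise StageError("split", exc) from exc

        try:
            results, fs = run_selection(train, cfg, seeds["rfe"])
            sel_df = selection_table(results, fs)
            written["selected_features"] = out / "selected_features.csv"
            sel_df.to_csv(written["selected_features"], index=False)
        except Exception as exc:
            raise StageError("select", exc) from exc

        try:
            members = tuple(m for m in cfg.enabled_members.split(",") if m)
            model = train_ensemble(
                train, fs, seed=seeds["ensemble"], config=EnsembleConfig(enabled=members)
            )
            preds, metrics = evaluate(model, test)
            written["predictions"] = out / "predictions.csv"
            preds.to_csv(written["predictions"])
            written["metrics"] = out / "metrics.csv"
            metrics.to_csv(written["metrics"], index=False)
        except Exception as exc:
            raise StageError("classify", exc) from exc

        try:
            profile = compute_igene_profile(
                model,
                test,
                seed=seeds["explainer"],
                tau=cfg.tau,
                direction_method=cfg.direction_method,  # type: ignore[arg-type]
                background_size=cfg.background_size,
                n_permutations=cfg.n_permutations,
            )
            written["igene_profile"] = out / "igene_profile.csv"
            profile.to_csv(written["igene_profile"])
            n_top = max(1, round(cfg.top_fraction * len(profile.table)))
            written["igene_top"] = out / "igene_top.csv"
            profile.table.head(n_top).to_csv(written["igene_top"], index=False)
        except Exception as exc:
            raise StageError("score", exc) from exc

        try:
            # plots for the highest-HHI-weight classifier (most concentrated)
            best = max(profile.weights, key=profile.weights.get)
            from .attribution import compute_attributions

            X_eval = model.transform(test)
            bg = model.train_matrix_
            rng = np.random.default_rng(seeds["explainer"])
            if len(bg) > cfg.background_size:
                bg = bg[rng.choice(len(bg), cfg.background_size, replace=False)]
            att = compute_attributions(
                model.members[best], X_eval, bg, classifier=best,
                n_permutations=cfg.n_permutations, seed=seeds["explainer"],
            )
            top_n = min(cfg.plot_top_n, len(model.feature_names))
            written["summary_beeswarm"] = summary_plot(
                att, X_eval, list(model.feature_names),
                out / "summary_beeswarm.png", top_n=top_n, kind="beeswarm",
                seed=seeds["plot"],
            )
            written["summary_bar"] = summary_plot(
                att, X_eval, list(model.feature_names),
                out / "summary_bar.png", top_n=top_n, kind="bar",
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("plot", exc) from exc

        written["run_log"] = out / "run_log.txt"
        log_lines = [
            f"cigtml {__version__} on python {platform.python_version()}",
            f"n_samples={ds.n_samples} n_features={ds.n_features}",
            f"train={train.n_samples} test={test.n_samples}",
            f"selected={len(fs)} combine_mode={fs.combine_mode}",
            f"classifier_weights={profile.weights}",
            f"degenerate_members={list(profile.degenerate)}",
            "substream_seeds=" + str(seeds),
            "config:",
            cfg.to_text(),
        ]
        written["run_log"].write_text("\n".join(log_lines))
        finish_manifest("complete")
        return written
    except StageError:
        finish_manifest("incomplete")
        raise
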
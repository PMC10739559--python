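"""Shared fixtures: synthetic cohorts and one fitted ensemble.

Heavyweight objects (the benchmark cohort, its trained ensemble and
I-Gene profile) are session-scoped so the many tests that inspect them
share a single fit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from cigtml import (
    CIGTDataset,
    SynthConfig,
    compute_igene_profile,
    evaluate,
    generate_cigt,
    split_dataset,
    train_ensemble,
)
from cigtml.pipeline import PipelineConfig, run_selection

warnings.filterwarnings(
    "ignore", message="The `probability` parameter", category=FutureWarning
)


@pytest.fixture(scope="session")
def benchmark_cohort():
    """Balanced 100/100 cohort, 50 genes, 5 informative at d=2."""
    return generate_cigt(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def fitted(benchmark_cohort):
    """Selection + ensemble + evaluation + I-Gene profile on the benchmark."""
    ds, truth = benchmark_cohort
    train, test = split_dataset(ds, 0.3, seed=7)
    results, fs = run_selection(train, PipelineConfig(), seed_rfe=3)
    model = train_ensemble(train, fs, seed=11)
    preds, metrics = evaluate(model, test)
    profile = compute_igene_profile(model, test, seed=5)
    return {
        "ds": ds,
        "truth": truth,
        "train": train,
        "test": test,
        "results": results,
        "feature_set": fs,
        "model": model,
        "predictions": preds,
        "metrics": metrics,
        "profile": profile,
    }


def make_dataset(values, labels, names=None, kinds=None, ids=None) -> CIGTDataset:
    """Small hand-built cohort for oracle tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, d = values.shape
    return CIGTDataset(
        sample_ids=ids or [f"S{i}" for i in range(n)],
        labels=np.asarray(labels, dtype=int),
        feature_names=names or [f"f{j}" for j in range(d)],
        values=values,
        feature_kinds=kinds or ["expression"] * d,
    )


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    """Minimal 4-patient CIGT table with two genes."""
    return pd.DataFrame(
        {
            "ID": ["P1", "P2", "P3", "P4"],
            "Type": [0, 0, 1, 1],
            "g1": [1.0, 2.0, 3.0, 4.0],
            "g2": [4.0, 3.0, 2.0, 1.0],
        }
    )
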
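"""Tiered model benchmarking: fit a learner library per feature tier, score
held-out data with Harrell and Uno concordance plus bootstrap CIs, and flag
significant improvements over a designated baseline model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import FeatureSet, SurvivalDataset
from .impute import IterativeForestImputer
from .learners import LearnerSpec, fit_learner
from .metrics import bootstrap_ci, compare_models

__all__ = ["BenchmarkConfig", "run_benchmark"]


@dataclass
class BenchmarkConfig:
    """What to benchmark: named models, feature tiers, train/test data.

    ``models`` maps a display name to a LearnerSpec; ``baseline`` names the
    reference model for the significance flag (CI-disjointness rule).  If the
    train covariates contain missing cells an iterative-forest imputer is fit
    on the train set per tier and applied, frozen, to the test set.
    """

    train: SurvivalDataset
    test: SurvivalDataset
    models: dict[str, LearnerSpec]
    tiers: list[FeatureSet] = field(default_factory=list)
    baseline: str | None = None
    B: int = 1000
    seed: int = 0
    imputer_trees: int = 50


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """Run the tier x model grid; returns a tidy results table.

    Columns: tier, model, metric, estimate, ci_low, ci_high,
    significant_vs_baseline.
    """
    tiers = config.tiers or [
        FeatureSet("all", tuple(config.train.covariate_names))
    ]
    if config.baseline is not None and config.baseline not in config.models:
        raise ValueError(f"baseline {config.baseline!r} is not among the models")
    rows = []
    for tier in tiers:
        try:
            train = config.train.select(list(tier.covariate_names))
            test = config.test.select(list(tier.covariate_names))
            train_X, test_X = train.covariates, test.covariates
            if np.isnan(train_X).any() or np.isnan(test_X).any():
                imp = IterativeForestImputer(
                    n_trees=config.imputer_trees, random_state=config.seed
                )
                train_X = imp.fit_transform(train_X)
                test_X = imp.transform(test_X)
            train = SurvivalDataset(train_X, train.times, train.events,
                                    list(tier.covariate_names))
            risks = {}
            for name, spec in config.models.items():
                m = fit_learner(spec, train, None, seed=config.seed)
                risks[name] = m.predict(test_X)
        except Exception as err:
            raise RuntimeError(f"benchmark failed at tier {tier.name!r}: {err}") from err
        base_risk = risks.get(config.baseline) if config.baseline else None
        for name, r in risks.items():
            try:
                for metric in ("harrell", "uno"):
                    res = bootstrap_ci(r, test.times, test.events, metric=metric,
                                       B=config.B, seed=config.seed)
                    significant = False
                    if base_risk is not None and name != config.baseline and metric == "harrell":
                        cmp = compare_models(r, base_risk, test.times, test.events,
                                             B=config.B, seed=config.seed)
                        significant = bool(cmp.ci_overlap_significant and cmp.delta > 0)
                    rows.append({
                        "tier": tier.name,
                        "model": name,
                        "metric": metric,
                        "estimate": res.estimate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "significant_vs_baseline": significant,
                    })
            except Exception as err:
                raise RuntimeError(
                    f"benchmark failed at (tier {tier.name!r}, model {name!r}): {err}"
                ) from err
    return pd.DataFrame(rows)
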
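"""Permutation feature importance and pairwise joint-shuffle interaction.

Importance of a feature is the increase in MSE when its weekly series is
temporally shuffled — permuted across the whole evaluation period *before*
window construction, so all five lag copies of the feature are disrupted
coherently — averaged over independent repeats. The interaction between two
features A and B is

    I = FI_AB - FI_A - FI_B

where FI_AB is the MSE increase with both series shuffled in the same repeat
(each under its own independent permutation) and FI_A, FI_B are the
single-feature increases computed under the same per-(feature, repeat)
permutation draws. I is positive when the model exploits joint structure of
the pair beyond their additive effects.

The evaluator is any callable ``predict_fn(table) -> (observed, predicted)``;
the walk-forward harness supplies one over its pooled test rows, and tests
plug in deterministic oracle predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .columns import INPUT_COLUMNS

__all__ = ["ImportanceRecord", "InteractionRecord", "permutation_importance",
           "interaction", "importance_report"]


@dataclass(frozen=True)
class ImportanceRecord:
    """Single-feature permutation importance (ΔMSE = FI for that feature)."""

    feature: str
    baseline_mse: float
    mean_shuffled_mse: float
    delta_mse: float
    se: float
    n_repeats: int
    seed: int

    @property
    def significant(self) -> bool:
        """The reported-significance rule: shuffling raised MSE above baseline."""
        return self.mean_shuffled_mse > self.baseline_mse


@dataclass(frozen=True)
class InteractionRecord:
    """Pairwise interaction I = FI_AB - FI_A - FI_B."""

    feature_a: str
    feature_b: str
    fi_a: float
    fi_b: float
    fi_ab: float
    se_ab: float
    n_repeats: int
    seed: int

    @property
    def interaction(self) -> float:
        return self.fi_ab - self.fi_a - self.fi_b


def _feature_index(feature: str) -> int:
    try:
        return INPUT_COLUMNS.index(feature)
    except ValueError:
        raise ValueError(f"unknown feature {feature!r}; not one of the 22 inputs") from None


def _permutation(seed: int, feature: str, repeat: int, n: int) -> np.ndarray:
    """The permutation draw for (seed, feature, repeat) — shared by the
    single-feature and joint computations so Eq.-style components line up."""
    rng = np.random.default_rng([seed, _feature_index(feature), repeat])
    return rng.permutation(n)


def _mse(obs: np.ndarray, pred: np.ndarray) -> float:
    return float(np.mean((np.asarray(obs, float) - np.asarray(pred, float)) ** 2))


def _shuffled_mses(predict_fn, table: pd.DataFrame, features: list[str],
                   n_repeats: int, seed: int) -> np.ndarray:
    n = len(table)
    out = np.empty(n_repeats)
    for r in range(n_repeats):
        shuffled = table.copy()
        for f in features:
            perm = _permutation(seed, f, r, n)
            shuffled[f] = table[f].to_numpy()[perm]
        out[r] = _mse(*predict_fn(shuffled))
    return out


def permutation_importance(
    predict_fn,
    table: pd.DataFrame,
    feature: str,
    n_repeats: int = 30,
    seed: int = 0,
) -> ImportanceRecord:
    """ΔMSE from temporally shuffling one feature's weekly series.

    ``predict_fn(table)`` must return (observed, predicted) on the evaluation
    rows; the baseline MSE is computed once on the unshuffled table.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    _feature_index(feature)
    baseline = _mse(*predict_fn(table))
    mses = _shuffled_mses(predict_fn, table, [feature], n_repeats, seed)
    se = float(mses.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0
    return ImportanceRecord(
        feature=feature, baseline_mse=baseline,
        mean_shuffled_mse=float(mses.mean()),
        delta_mse=float(mses.mean() - baseline),
        se=se, n_repeats=n_repeats, seed=seed,
    )


def interaction(
    predict_fn,
    table: pd.DataFrame,
    feature_a: str,
    feature_b: str,
    n_repeats: int = 30,
    seed: int = 0,
) -> InteractionRecord:
    """I = FI_AB - FI_A - FI_B with shared per-(feature, repeat) permutations.

    In the joint term both features are shuffled within the same repeat,
    each under its own independent permutation, destroying the pair's joint
    structure as the additive-null reading requires.
    """
    if feature_a == feature_b:
        raise ValueError("interaction requires two distinct features")
    baseline = _mse(*predict_fn(table))
    mses_a = _shuffled_mses(predict_fn, table, [feature_a], n_repeats, seed)
    mses_b = _shuffled_mses(predict_fn, table, [feature_b], n_repeats, seed)
    mses_ab = _shuffled_mses(predict_fn, table, [feature_a, feature_b], n_repeats, seed)
    se_ab = float(mses_ab.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0
    return InteractionRecord(
        feature_a=feature_a, feature_b=feature_b,
        fi_a=float(mses_a.mean() - baseline),
        fi_b=float(mses_b.mean() - baseline),
        fi_ab=float(mses_ab.mean() - baseline),
        se_ab=se_ab, n_repeats=n_repeats, seed=seed,
    )


def importance_report(
    records: list[ImportanceRecord],
    interactions: list[InteractionRecord] | None = None,
) -> dict:
    """Tidy report tables: per-feature importance sorted by ΔMSE with the
    significance flag (mean shuffled MSE above baseline), and a symmetric
    pairwise interaction matrix."""
    if not records:
        raise ValueError("no importance records")
    imp = pd.DataFrame(
        {
            "feature": [r.feature for r in records],
            "baseline_mse": [r.baseline_mse for r in records],
            "delta_mse": [r.delta_mse for r in records],
            "se": [r.se for r in records],
            "significant": [r.significant for r in records],
        }
    ).sort_values("delta_mse", ascending=False, ignore_index=True)

    matrix = None
    if interactions:
        feats = sorted({x for r in interactions for x in (r.feature_a, r.feature_b)})
        matrix = pd.DataFrame(0.0, index=feats, columns=feats)
        for r in interactions:
            matrix.loc[r.feature_a, r.feature_b] = r.interaction
            matrix.loc[r.feature_b, r.feature_a] = r.interaction
    return {"importance": imp, "interaction_matrix": matrix}
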
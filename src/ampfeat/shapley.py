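"""Shapley-value explanations of fitted models.

A model prediction f(x) is attributed to the individual features as
Shapley values φ_i of the cooperative game whose value for a feature
subset S is the interventional expectation v(S) = E[f(z) | z_S = x_S]:
features in S are fixed to the instance's values and the rest are
marginalized by averaging over an explicit background sample.  The base
value φ₀ = v(∅) is the mean model output over the background, and local
accuracy φ₀ + Σ φ_i = f(x) holds by construction.

Two estimators are provided: exact subset enumeration with the classical
combinatorial weights (practical up to ~16 features; the verification
tool), and permutation sampling (unbiased Monte-Carlo average of marginal
contributions over random feature orderings, rescaled so local accuracy
holds exactly) for high-dimensional feature sets.  Any third-party
explainer can be plugged in through :func:`validate_adapter`, which checks
its output against the local-accuracy property.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ShapleyExplanation",
    "GlobalImportance",
    "exact_shapley",
    "sampled_shapley",
    "global_importance",
    "export_explanations",
    "validate_adapter",
]

logger = logging.getLogger(__name__)


@dataclass
class ShapleyExplanation:
    """Additive attribution of one prediction to named features."""

    base_value: float
    contributions: dict[str, float]
    prediction: float
    instance_id: str = ""
    feature_values: dict[str, float] | None = None

    def local_accuracy_gap(self) -> float:
        """|base_value + Σ φ_i − prediction|; ~0 for a valid explanation."""
        return abs(self.base_value + sum(self.contributions.values()) - self.prediction)


@dataclass
class GlobalImportance:
    """Mean absolute contribution per feature over a set of instances."""

    values: dict[str, float]
    n_instances: int

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.values.items(), key=lambda kv: -kv[1])


def _as_names_and_array(x) -> tuple[list[str], np.ndarray]:
    if isinstance(x, dict):
        names = list(x.keys())
        return names, np.array([x[n] for n in names], dtype=float)
    if isinstance(x, pd.Series):
        return list(x.index), x.to_numpy(dtype=float)
    arr = np.asarray(x, dtype=float)
    return [f"x{i}" for i in range(arr.size)], arr


def _subset_value_fn(model_fn, x: np.ndarray, background: np.ndarray):
    """v(S): fix features in S to x, average model_fn over background rows."""

    def value(subset: tuple[int, ...]) -> float:
        z = background.copy()
        if subset:
            z[:, list(subset)] = x[list(subset)]
        return float(np.mean(model_fn(z)))

    return value


def exact_shapley(
    model_fn,
    x,
    background,
    max_features: int = 16,
    instance_id: str = "",
) -> ShapleyExplanation:
    """Exact Shapley values by full subset enumeration.

    ``model_fn`` maps a 2-D array of instances to a 1-D array of scores;
    ``x`` is one instance (array, Series or name->value dict);
    ``background`` is the 2-D sample used for marginalization.  Cost is
    O(2^d · |background|) model evaluations, so ``max_features`` guards
    against accidental blow-up — use :func:`sampled_shapley` beyond it.
    """
    names, xv = _as_names_and_array(x)
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.shape[0] == 0:
        raise ValueError("background must be nonempty")
    d = xv.size
    if d > max_features:
        raise ValueError(
            f"{d} features exceed max_features={max_features}; use sampled_shapley"
        )
    value = _subset_value_fn(model_fn, xv, bg)
    others = list(range(d))
    cache: dict[tuple[int, ...], float] = {}

    def v(subset: frozenset[int]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = value(key)
        return cache[key]

    fact = math.factorial
    phi = np.zeros(d)
    for i in range(d):
        rest = [j for j in others if j != i]
        for r in range(len(rest) + 1):
            for subset in itertools.combinations(rest, r):
                s = frozenset(subset)
                weight = fact(len(s)) * fact(d - len(s) - 1) / fact(d)
                phi[i] += weight * (v(s | {i}) - v(s))
    base = v(frozenset())
    prediction = v(frozenset(range(d)))
    return ShapleyExplanation(
        base_value=base,
        contributions=dict(zip(names, phi.tolist())),
        prediction=prediction,
        instance_id=instance_id,
        feature_values=dict(zip(names, xv.tolist())),
    )


def sampled_shapley(
    model_fn,
    x,
    background,
    n_permutations: int = 100,
    seed: int = 0,
    instance_id: str = "",
) -> ShapleyExplanation:
    """Monte-Carlo Shapley values by permutation sampling.

    For each sampled feature ordering the features are switched from
    background to instance values one at a time; the change in v is the
    marginal contribution credited to the switched feature.  The average
    over orderings is unbiased; the estimate is then shifted uniformly so
    that local accuracy (base + Σ φ = f(x)) holds exactly (the residual is
    logged).  Deterministic for a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    names, xv = _as_names_and_array(x)
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    d = xv.size
    rng = np.random.default_rng(seed)
    phi = np.zeros(d)
    base = float(np.mean(model_fn(bg)))
    prediction = float(np.mean(model_fn(xv[None, :])))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        z = bg.copy()
        prev = base
        for i in order:
            z[:, i] = xv[i]
            cur = float(np.mean(model_fn(z)))
            phi[i] += cur - prev
            prev = cur
    phi /= n_permutations
    residual = prediction - base - phi.sum()
    if abs(residual) > 0:
        logger.debug("permutation-sampling residual %.3g spread over %d features", residual, d)
        phi += residual / d
    return ShapleyExplanation(
        base_value=base,
        contributions=dict(zip(names, phi.tolist())),
        prediction=prediction,
        instance_id=instance_id,
        feature_values=dict(zip(names, xv.tolist())),
    )


def global_importance(explanations: list[ShapleyExplanation]) -> GlobalImportance:
    """Per-feature mean absolute Shapley value over a set of explanations."""
    if not explanations:
        raise ValueError("no explanations supplied")
    names = list(explanations[0].contributions)
    for expl in explanations:
        if list(expl.contributions) != names:
            raise ValueError("explanations do not share a feature-name set")
    values = {
        name: float(np.mean([abs(e.contributions[name]) for e in explanations]))
        for name in names
    }
    return GlobalImportance(values=values, n_instances=len(explanations))


def export_explanations(
    explanations: list[ShapleyExplanation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular exports: a waterfall table and a scatter table.

    The waterfall table lists, per instance, the features sorted by |φ|
    descending with the cumulative sum running from the base value to the
    prediction.  The scatter table pairs each feature's value with its φ
    across instances (the trend view).
    """
    waterfall_rows = []
    scatter_rows = []
    for expl in explanations:
        ordered = sorted(expl.contributions.items(), key=lambda kv: -abs(kv[1]))
        cumulative = expl.base_value
        for rank, (name, phi) in enumerate(ordered):
            cumulative += phi
            waterfall_rows.append(
                {
                    "instance_id": expl.instance_id,
                    "rank": rank,
                    "feature": name,
                    "phi": phi,
                    "cumulative": cumulative,
                    "base_value": expl.base_value,
                    "prediction": expl.prediction,
                }
            )
        for name, phi in expl.contributions.items():
            scatter_rows.append(
                {
                    "feature": name,
                    "value": (expl.feature_values or {}).get(name, float("nan")),
                    "phi": phi,
                    "instance_id": expl.instance_id,
                }
            )
    columns_w = ["instance_id", "rank", "feature", "phi", "cumulative", "base_value", "prediction"]
    columns_s = ["feature", "value", "phi", "instance_id"]
    return (
        pd.DataFrame(waterfall_rows, columns=columns_w),
        pd.DataFrame(scatter_rows, columns=columns_s),
    )


def validate_adapter(explanation: ShapleyExplanation, tolerance: float = 1e-6) -> None:
    """Check a (possibly third-party) explanation for local accuracy.

    Raises ``ValueError`` when base + Σ φ deviates from the prediction by
    more than ``tolerance`` — the contract any plugged-in explainer must
    meet before its output is accepted.
    """
    gap = explanation.local_accuracy_gap()
    if gap > tolerance:
        raise ValueError(
            f"explanation for {explanation.instance_id!r} violates local accuracy "
            f"(gap {gap:.3g} > {tolerance:.3g})"
        )
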
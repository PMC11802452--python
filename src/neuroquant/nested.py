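"""Animal-nested two-group statistics.

Experimental designs here measure several cells or slices (technical
replicates) per animal, with the animal as the independent biological unit.
The workhorse comparison is the *nested Student's t-test*: a one-way nested
(hierarchical) ANOVA with genotype as a fixed effect and animals random
within genotype.  The group effect is tested against the between-animal
(within-group) mean square, which for any pattern of replicate counts gives
a denominator with ``n_animals - 2`` degrees of freedom — the convention
printed in every figure legend of studies using this design.

For unbalanced replicate counts the test uses the unweighted-means
formulation: each animal contributes its replicate mean with equal weight,
so the F ratio equals the one computed from the ANOVA on per-animal means.
With one replicate per animal the test collapses exactly to the classical
two-sample equal-variance t-test.  A REML mixed-model mode (statsmodels
``MixedLM``) is provided as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NestedTestResult",
    "nested_t_test",
    "aggregate_to_animals",
    "type1_simulation",
]


@dataclass(frozen=True)
class NestedTestResult:
    """Result of an animal-nested two-group comparison.

    Attributes
    ----------
    F : float
        Variance ratio (group mean square over between-animal mean square).
    t : float
        Signed square root of ``F``; the sign follows the difference of group
        means (first group minus second, in sorted label order unless an
        explicit order was given).
    df_num, df_den : int
        Numerator df (always 1) and denominator df (``n_animals - 2``).
    p : float
        Two-sided probability.
    group_means : dict
        Unweighted group means (mean of per-animal means).
    var_between_animal, var_within_animal : float
        Method-of-moments variance components; ``var_within_animal`` is NaN
        when no animal has more than one replicate.
    degenerate : bool
        True when the between-animal mean square is zero (all animal means
        identical within groups); ``p`` is then reported as 1.
    """

    F: float
    t: float
    df_num: int
    df_den: int
    p: float
    group_means: dict = field(default_factory=dict)
    var_between_animal: float = float("nan")
    var_within_animal: float = float("nan")
    degenerate: bool = False
    method: str = "anova"


def _check_columns(data: pd.DataFrame, group: str, animal: str, value: str) -> None:
    missing = {group, animal, value} - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns: {sorted(missing)}")
    counts = data.groupby(animal)[group].nunique()
    if (counts > 1).any():
        bad = counts[counts > 1].index.tolist()
        raise ValueError(f"animals assigned to more than one group: {bad}")


def aggregate_to_animals(
    data: pd.DataFrame,
    group: str = "group",
    animal: str = "animal",
    value: str = "value",
) -> pd.DataFrame:
    """Collapse technical replicates to one mean value per animal.

    Returns a frame with one row per animal (columns ``group``, ``animal``,
    ``value`` holding the replicate mean, and ``n_replicates``), the input
    expected by delegated animal-level tests (two-way factorial ANOVA,
    rank-sum tests).  Already animal-level data pass through unchanged.
    """
    _check_columns(data, group, animal, value)
    agg = (
        data.groupby([group, animal], sort=True)[value]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": value, "size": "n_replicates"})
    )
    return agg


def nested_t_test(
    data: pd.DataFrame,
    group: str = "group",
    animal: str = "animal",
    value: str = "value",
    group_order: tuple | None = None,
    method: str = "anova",
) -> NestedTestResult:
    """Nested Student's t-test: two groups, animals random within group.

    Parameters
    ----------
    data
        Long-format table with one row per technical replicate.
    group, animal, value
        Column names.
    group_order
        Optional pair fixing which group is "first" for the sign of ``t``;
        defaults to sorted label order.
    method
        ``"anova"`` (default, unweighted-means nested ANOVA) or ``"mixed"``
        (REML mixed model cross-check via statsmodels; same df convention).
    """
    _check_columns(data, group, animal, value)
    levels = sorted(data[group].unique()) if group_order is None else list(group_order)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")

    per_animal = aggregate_to_animals(data, group, animal, value)
    n_by_group = per_animal.groupby(group, sort=False).size()
    for g in levels:
        if n_by_group.get(g, 0) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 animals")

    n_animals = len(per_animal)
    df_den = n_animals - 2

    if method == "mixed":
        return _mixed_model_test(data, per_animal, group, animal, value, levels, df_den)
    if method != "anova":
        raise ValueError(f"unknown method {method!r}")

    m = {g: per_animal.loc[per_animal[group] == g, value].to_numpy() for g in levels}
    means = {g: float(v.mean()) for g, v in m.items()}
    grand = float(per_animal[value].mean())

    ss_group = sum(len(m[g]) * (means[g] - grand) ** 2 for g in levels)
    ss_animal = sum(float(((m[g] - means[g]) ** 2).sum()) for g in levels)

    ms_animal = ss_animal / df_den
    sign = 1.0 if means[levels[0]] >= means[levels[1]] else -1.0

    var_within = _pooled_replicate_variance(data, animal, value)
    var_between = _between_animal_component(per_animal, ms_animal, var_within, group)

    if ms_animal == 0.0:
        return NestedTestResult(
            F=0.0, t=0.0, df_num=1, df_den=df_den, p=1.0,
            group_means=means, var_between_animal=var_between,
            var_within_animal=var_within, degenerate=True, method="anova",
        )

    F = ss_group / ms_animal
    t = sign * math.sqrt(F)
    p = float(2.0 * stats.t.sf(abs(t), df_den))
    return NestedTestResult(
        F=float(F), t=float(t), df_num=1, df_den=df_den, p=p,
        group_means=means, var_between_animal=var_between,
        var_within_animal=var_within, degenerate=False, method="anova",
    )


def _pooled_replicate_variance(data: pd.DataFrame, animal: str, value: str) -> float:
    """Within-animal (replicate) variance pooled across animals."""
    g = data.groupby(animal)[value]
    n = g.size()
    if (n <= 1).all():
        return float("nan")
    ss = float((g.var(ddof=1) * (n - 1)).dropna().sum())
    df = int((n - 1).sum())
    return ss / df if df > 0 else float("nan")


def _between_animal_component(
    per_animal: pd.DataFrame, ms_animal: float, var_within: float, group: str
) -> float:
    """Method-of-moments between-animal variance (floored at zero)."""
    if math.isnan(var_within):
        return max(ms_animal, 0.0)
    n_rep = per_animal["n_replicates"].to_numpy(dtype=float)
    n_h = len(n_rep) / float((1.0 / n_rep).sum())  # harmonic mean replicates
    return max(ms_animal - var_within / n_h, 0.0)


def _mixed_model_test(data, per_animal, group, animal, value, levels, df_den):
    import statsmodels.formula.api as smf

    frame = data[[group, animal, value]].copy()
    frame.columns = ["g", "a", "y"]
    frame["g"] = pd.Categorical(frame["g"], categories=levels)
    model = smf.mixedlm("y ~ g", frame, groups=frame["a"])
    fit = model.fit(reml=True)
    # fixed-effect coefficient for the second level relative to the first
    coef_name = [n for n in fit.params.index if n.startswith("g[")][0]
    coef = float(fit.params[coef_name])
    se = float(fit.bse[coef_name])
    # sign convention: first group minus second
    t = -coef / se
    p = float(2.0 * stats.t.sf(abs(t), df_den))
    means = {
        g: float(per_animal.loc[per_animal[group] == g, value].mean()) for g in levels
    }
    var_between = float(fit.cov_re.iloc[0, 0])
    var_within = float(fit.scale)
    return NestedTestResult(
        F=float(t * t), t=float(t), df_num=1, df_den=df_den, p=p,
        group_means=means, var_between_animal=var_between,
        var_within_animal=var_within, degenerate=False, method="mixed",
    )


def type1_simulation(
    spec,
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the nested test under a null generator spec.

    ``spec`` is a :class:`neuroquant.synth.NestedDataSpec` with equal group
    means.  Returns the rejection fraction at ``alpha`` together with a
    Clopper–Pearson 99% binomial interval.
    """
    from .synth.nested import generate_nested_dataset

    if spec.group_means[0] != spec.group_means[1]:
        raise ValueError("type-I simulation requires equal group means")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        sub = int(rng.integers(0, 2**31 - 1))
        table = generate_nested_dataset(replace(spec, seed=sub))
        res = nested_t_test(table)
        if res.p < alpha:
            rejections += 1
    rate = rejections / n_reps
    lo, hi = _clopper_pearson(rejections, n_reps, 0.99)
    return {"rate": rate, "n_reps": n_reps, "alpha": alpha, "ci99": (lo, hi)}


def _clopper_pearson(k: int, n: int, conf: float) -> tuple[float, float]:
    a = (1.0 - conf) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lo, hi
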
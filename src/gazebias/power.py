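"""Study-design computations: paired-t power, sample size, sequential looks.

The study design rests on one-tailed paired t-tests: with Cohen's d = 0.4
and alpha = .05 one-sided, power is 92% at N = 60 and 80% at the N = 40
interim.  Power uses the exact noncentral-t distribution (the normal
approximation is visibly off at these sample sizes).  A generic two-or-more
look solver finds the common Pocock-style nominal level by multivariate
normal integration over the correlated look statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PowerSpec",
    "power_paired_t",
    "required_n",
    "sequential_nominal_alpha",
    "audit_randomization",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design for a paired (one-sample difference) t-test."""

    effect_size_d: float
    n: int
    alpha: float = 0.05
    tails: str = "one"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2")
        if not 0.0 < self.alpha <= 0.5:
            raise ValueError("alpha must lie in (0, 0.5]")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


def power_paired_t(spec: PowerSpec) -> float:
    """Exact power of the paired t-test via the noncentral t distribution.

    With ``df = n - 1`` and noncentrality ``d * sqrt(n)``, power is
    ``P(T' > t_crit)`` where ``t_crit`` is the upper-alpha Student quantile
    (alpha/2 per tail for two-sided; the wrong-direction tail is ignored,
    which is negligible for d > 0).  At d = 0 the one-sided power equals
    alpha exactly.
    """
    alpha = spec.alpha if spec.tails == "one" else spec.alpha / 2.0
    df = spec.n - 1
    nc = spec.effect_size_d * math.sqrt(spec.n)
    t_crit = stats.t.ppf(1.0 - alpha, df)
    power = float(stats.nct.sf(t_crit, df, nc))
    if spec.tails == "two":
        power += float(stats.nct.cdf(-t_crit, df, nc))
    return power


def required_n(d: float, target_power: float, alpha: float = 0.05,
               tails: str = "one", n_max: int = 100000) -> int:
    """Smallest n whose paired-t power reaches ``target_power``."""
    if d == 0:
        raise ValueError("power cannot exceed alpha at d = 0")
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must lie in (0, 1)")
    # bracket geometrically, then binary-search the monotone power curve
    lo, hi = 2, 2
    while power_paired_t(PowerSpec(d, hi, alpha, tails)) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("required n exceeds n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_paired_t(PowerSpec(d, mid, alpha, tails)) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def sequential_nominal_alpha(k_looks: int, overall_alpha: float,
                             sidedness: str = "two",
                             info_fractions=None) -> float:
    """Common per-look nominal level for a K-look group-sequential design.

    Look statistics are treated as standard normal with correlation
    ``sqrt(t_i / t_j)`` (information fractions t).  Solves for the constant
    nominal level c such that the overall probability of rejecting at any
    look equals ``overall_alpha``, by multivariate-normal integration
    (the classical Pocock construction; K = 2, two-sided 5% gives the
    textbook 0.0294).  K = 1 degenerates to ``overall_alpha``.
    """
    if k_looks < 1:
        raise ValueError("need at least one look")
    if not 0 < overall_alpha < 1:
        raise ValueError("overall_alpha must lie in (0, 1)")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    if k_looks == 1:
        return float(overall_alpha)
    if info_fractions is None:
        info_fractions = np.arange(1, k_looks + 1) / k_looks
    t = np.asarray(info_fractions, dtype=float)
    if t.size != k_looks or np.any(np.diff(t) <= 0) or not math.isclose(t[-1], 1.0):
        raise ValueError("info_fractions must increase to 1")
    corr = np.sqrt(np.minimum.outer(t, t) / np.maximum.outer(t, t))
    mvn = stats.multivariate_normal(mean=np.zeros(k_looks), cov=corr,
                                    allow_singular=True)

    def spent(c: float) -> float:
        z = stats.norm.ppf(1.0 - (c / 2.0 if sidedness == "two" else c))
        if sidedness == "two":
            accept = mvn.cdf(np.full(k_looks, z),
                             lower_limit=np.full(k_looks, -z))
        else:
            accept = mvn.cdf(np.full(k_looks, z))
        return 1.0 - float(accept) - overall_alpha

    lo, hi = overall_alpha / (2.0 * k_looks), overall_alpha
    if spent(lo) > 0 or spent(hi) < 0:
        raise RuntimeError(
            f"bracketing failed: spent({lo:.4g})={spent(lo):.4g}, "
            f"spent({hi:.4g})={spent(hi):.4g}")
    sol = optimize.brentq(spent, lo, hi, xtol=1e-7)
    return float(sol)


def audit_randomization(assignments) -> dict:
    """Audit a balanced-shuffle group assignment list.

    Reports group counts, the maximum imbalance over every even-sized
    prefix, and whether the balanced-shuffle contract holds at n = 40
    (equal groups).  Unknown labels are an error.
    """
    labels = list(assignments)
    allowed = {"left", "right"}
    bad = sorted(set(labels) - allowed)
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    arr = np.array([1 if s == "right" else -1 for s in labels])
    cum = np.cumsum(arr)
    even_prefix_imbalance = (np.abs(cum[1::2]).max() if arr.size >= 2 else 0)
    counts = {"left": int((arr == -1).sum()), "right": int((arr == 1).sum())}
    imbalance = abs(counts["left"] - counts["right"])
    report = {
        "counts": counts,
        "imbalance": imbalance,
        "max_even_prefix_imbalance": int(even_prefix_imbalance),
        "balanced": imbalance <= (len(labels) % 2),
    }
    if len(labels) >= 40:
        first40 = arr[:40]
        report["balanced_at_40"] = bool(first40.sum() == 0)
    return report
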
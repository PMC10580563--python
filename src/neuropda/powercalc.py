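"""Repeated-measures ANOVA power via the noncentral F distribution.

For a within-subject factor with ``m`` measurement occasions, correlation
``rho`` between repeated measures, nonsphericity correction ``epsilon``,
and Cohen's effect size ``f``, the noncentrality parameter is

    lambda = f^2 * N * m / (1 - rho) * epsilon

with numerator df (m - 1) * epsilon (times (groups - 1) for a
group-by-time interaction) and denominator df (N - groups) * (m - 1) *
epsilon.  Power is P(F'(df1, df2, lambda) > F_crit(alpha)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from scipy import stats


@dataclass
class PowerSpec:
    effect_size_f: float = 0.19
    alpha: float = 0.05
    target_power: float = 0.80
    n_groups: int = 1
    n_measurements: int = 2
    rho: float = 0.3
    nonsphericity_epsilon: float = 1.0
    design: str = "within"  # "within" | "within_between_interaction"

    def __post_init__(self) -> None:
        if self.effect_size_f <= 0:
            raise ValueError("effect_size_f must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.target_power < 1):
            raise ValueError("target_power must lie in (0, 1)")
        if self.n_groups < 1 or self.n_measurements < 2:
            raise ValueError("need >= 1 group and >= 2 measurements")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if not (0 < self.nonsphericity_epsilon <= 1):
            raise ValueError("epsilon must lie in (0, 1]")
        if self.design not in ("within", "within_between_interaction"):
            raise ValueError("design must be 'within' or "
                             "'within_between_interaction'")
        if self.design == "within_between_interaction" and self.n_groups < 2:
            raise ValueError("interaction design needs >= 2 groups")


def rm_power(n_total: int, spec: PowerSpec) -> float:
    """Analytic power of the repeated-measures F test at total sample N."""
    if n_total < spec.n_groups + 1:
        raise ValueError("n_total must exceed the number of groups")
    m, rho, eps = spec.n_measurements, spec.rho, spec.nonsphericity_epsilon
    lam = spec.effect_size_f ** 2 * n_total * m / (1.0 - rho) * eps
    df1 = (m - 1) * eps
    if spec.design == "within_between_interaction":
        df1 *= spec.n_groups - 1
    df2 = (n_total - spec.n_groups) * (m - 1) * eps
    f_crit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def power_report(n_total: int, spec: PowerSpec) -> Dict[str, float]:
    """Power plus the auditable intermediates (lambda, dfs, critical F)."""
    m, rho, eps = spec.n_measurements, spec.rho, spec.nonsphericity_epsilon
    lam = spec.effect_size_f ** 2 * n_total * m / (1.0 - rho) * eps
    df1 = (m - 1) * eps
    if spec.design == "within_between_interaction":
        df1 *= spec.n_groups - 1
    df2 = (n_total - spec.n_groups) * (m - 1) * eps
    return {
        "n_total": n_total,
        "lambda": lam,
        "df1": df1,
        "df2": df2,
        "f_critical": float(stats.f.isf(spec.alpha, df1, df2)),
        "power": rm_power(n_total, spec),
    }


def required_n(spec: PowerSpec) -> int:
    """Smallest total N achieving the target power (doubling then bisection).

    For grouped designs the result is rounded up to a multiple of the
    group count so per-group sizes are integral.
    """
    lo = spec.n_groups + 1
    hi = max(lo + 1, 4)
    while rm_power(hi, spec) < spec.target_power:
        hi *= 2
        if hi > 10_000_000:
            raise ValueError("target power unreachable at feasible N")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mid <= spec.n_groups:
            lo = mid
            continue
        if rm_power(mid, spec) >= spec.target_power:
            hi = mid
        else:
            lo = mid
    n = hi
    if spec.n_groups > 1 and n % spec.n_groups:
        n += spec.n_groups - n % spec.n_groups
    return n
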
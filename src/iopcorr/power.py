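"""Sample-size computation for a two-sided paired (one-sample) t-test.

Power is evaluated with the exact noncentral t distribution; the search
starts from the normal-approximation seed ((z_{1-a/2} + z_power)/d)^2 and
scans to the smallest n whose power reaches the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import NumericError


@dataclass(frozen=True)
class PowerSpec:
    """Design of a paired t-test power/sample-size computation.

    ``delta`` is the mean paired difference to detect (mmHg), ``sd`` the
    within-subject SD of the differences; the standardized effect is
    d = delta/sd.
    """

    alpha: float = 0.05
    power: float = 0.80
    delta: float = 0.5
    sd: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise NumericError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise NumericError(f"power must be in (0,1), got {self.power}")
        if not self.sd > 0.0:
            raise NumericError(f"sd must be > 0, got {self.sd}")
        if self.delta == 0.0:
            raise NumericError("delta must be nonzero")

    @property
    def d(self) -> float:
        """Standardized effect size delta/sd."""
        return self.delta / self.sd


def power_at(n: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided one-sample t-test at sample size n.

    The test statistic follows a noncentral t with df = n-1 and
    noncentrality d*sqrt(n); power is the probability of exceeding the
    two-sided critical value.
    """
    if n < 2:
        raise NumericError(f"t-test needs n >= 2, got {n}")
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = abs(d) * math.sqrt(n)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def _normal_seed(d: float, alpha: float, power: float) -> int:
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    return max(2, math.ceil(((za + zb) / abs(d)) ** 2))


def required_n(spec: PowerSpec, cap: int = 1_000_000) -> int:
    """Smallest n >= 2 whose exact noncentral-t power reaches spec.power.

    Raises
    ------
    NumericError
        If the required n exceeds ``cap``.
    """
    d = spec.d
    n = _normal_seed(d, spec.alpha, spec.power)
    if n > cap:
        raise NumericError(f"required sample size exceeds cap {cap} for d={d:g}")
    # walk down while the target still holds one step below
    while n > 2 and power_at(n - 1, d, spec.alpha) >= spec.power:
        n -= 1
    # walk up until it holds
    while power_at(n, d, spec.alpha) < spec.power:
        n += 1
        if n > cap:
            raise NumericError(
                f"required sample size exceeds cap {cap} for d={d:g}"
            )
    return n


__all__ = ["PowerSpec", "power_at", "required_n"]
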
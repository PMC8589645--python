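"""Two-cohort inverse-variance meta-analysis with heterogeneity gating.

Cohort estimates (log scale) are pooled with fixed-effect inverse-variance
weights; Cochran's Q and I-squared quantify between-cohort heterogeneity,
and when it is considerable (I-squared above the gate, default 50%) pooling
switches to a DerSimonian-Laird random-effects model. An alternative gate
on the Q-test p-value is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MetaInput",
    "MetaResult",
    "meta_fixed",
    "heterogeneity",
    "meta_auto",
]


@dataclass(frozen=True)
class MetaInput:
    """One cohort's contribution: estimate on the log scale and its SE."""

    estimate: float
    se: float
    cohort: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")


@dataclass
class MetaResult:
    estimate: float
    se: float
    p: float
    Q: float
    I2: float          # percent in [0, 100)
    tau2: float
    model_used: str    # "fixed" | "random"
    n_cohorts: int

    @property
    def ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se,
                self.estimate + 1.96 * self.se)

    @property
    def ci95_ratio(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))

    @property
    def marker(self) -> str:
        """Forest-plot marker convention: circle = fixed, triangle = random."""
        return "circle" if self.model_used == "fixed" else "triangle"


def _validate(inputs: Sequence[MetaInput]) -> tuple[np.ndarray, np.ndarray]:
    if len(inputs) < 2:
        raise ValueError("meta-analysis needs at least 2 cohorts")
    beta = np.array([i.estimate for i in inputs], dtype=float)
    se = np.array([i.se for i in inputs], dtype=float)
    return beta, se


def _pool(beta: np.ndarray, var: np.ndarray) -> tuple[float, float]:
    w = 1.0 / var
    est = float(np.sum(w * beta) / np.sum(w))
    return est, float(1.0 / np.sqrt(np.sum(w)))


def heterogeneity(inputs: Sequence[MetaInput]) -> tuple[float, float, float]:
    """Cochran's Q, I-squared (percent), and DerSimonian-Laird tau-squared.

    Q = sum w_i (beta_i - pooled_FE)^2 with w_i = 1/se_i^2;
    I2 = max(0, (Q - df) / Q) * 100; tau2 = max(0, (Q - df) / (S1 - S2/S1))
    with S1 = sum w_i, S2 = sum w_i^2.
    """
    beta, se = _validate(inputs)
    w = 1.0 / se**2
    pooled, _ = _pool(beta, se**2)
    Q = float(np.sum(w * (beta - pooled) ** 2))
    df = len(inputs) - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    s1, s2 = float(np.sum(w)), float(np.sum(w**2))
    tau2 = max(0.0, (Q - df) / (s1 - s2 / s1))
    return Q, I2, tau2


def meta_fixed(inputs: Sequence[MetaInput]) -> MetaResult:
    """Fixed-effect inverse-variance pooling."""
    beta, se = _validate(inputs)
    est, pooled_se = _pool(beta, se**2)
    Q, I2, tau2 = heterogeneity(inputs)
    p = 2 * stats.norm.sf(abs(est / pooled_se))
    return MetaResult(est, pooled_se, float(p), Q, I2, tau2, "fixed",
                      len(inputs))


def _meta_random(inputs: Sequence[MetaInput]) -> MetaResult:
    beta, se = _validate(inputs)
    Q, I2, tau2 = heterogeneity(inputs)
    est, pooled_se = _pool(beta, se**2 + tau2)
    p = 2 * stats.norm.sf(abs(est / pooled_se))
    return MetaResult(est, pooled_se, float(p), Q, I2, tau2, "random",
                      len(inputs))


def meta_auto(
    inputs: Sequence[MetaInput],
    i2_threshold: float = 50.0,
    gate: str = "i2",
    q_alpha: float = 0.10,
) -> MetaResult:
    """Heterogeneity-gated pooling: random effects iff heterogeneity is
    considerable, else fixed.

    ``gate='i2'`` (default) switches when I-squared exceeds
    ``i2_threshold`` percent; ``gate='q_pvalue'`` when the Q-test p-value
    falls below ``q_alpha``. Random-effects pooling weights by
    1/(se_i^2 + tau2); with tau2 = 0 it coincides with the fixed model.
    """
    if gate not in ("i2", "q_pvalue"):
        raise ValueError(f"unknown heterogeneity gate {gate!r}")
    Q, I2, tau2 = heterogeneity(inputs)
    if gate == "i2":
        use_random = I2 > i2_threshold
    else:
        df = len(inputs) - 1
        use_random = stats.chi2.sf(Q, df) < q_alpha
    return _meta_random(inputs) if use_random else meta_fixed(inputs)
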
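"""Inverse-variance meta-analysis: fixed effect and DerSimonian–Laird random effects.

Study estimates are pooled with weights proportional to inverse variance.
The fixed-effect model uses sampling variances alone; the random-effects
model adds the DerSimonian–Laird moment estimate of between-study variance,
τ² = max(0, (Q − df)/C) with C = Σw − Σw²/Σw computed on the fixed-effect
weights (classic, non-iterated DL).  Heterogeneity is summarized by
Cochran's Q, I² = max(0, (Q − df)/Q)·100, and a conventional four-band
reading of I²: [0, 25) none, [25, 50) moderate, [50, 75) significant,
[75, 100] extreme (boundary values assigned to the higher band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: two-sided 95% normal quantile, at the precision that round-trips printed CIs
Z95 = 1.959964


class MetaError(ValueError):
    pass


@dataclass(frozen=True)
class StudyEstimate:
    """One cohort-level effect estimate entering a meta-analysis."""

    label: str
    beta: float
    se: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise MetaError(f"{self.label}: standard error must be positive, got {self.se}")

    @classmethod
    def from_ci(cls, label: str, beta: float, lo: float, hi: float,
                level: float = 0.95, n: int | None = None) -> "StudyEstimate":
        return cls(label=label, beta=beta, se=se_from_ci(lo, hi, level), n=n)


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with weights and heterogeneity statistics."""

    model: str                      # "fixed" | "random"
    beta: float
    se: float
    lo: float
    hi: float
    weights_pct: dict[str, float]   # per study, sums to 100
    Q: float
    df: int
    p_Q: float
    tau2: float
    i2_pct: float

    @property
    def band(self) -> str:
        return heterogeneity_band(self.i2_pct)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.lo, self.hi)


def se_from_ci(lo: float, hi: float, level: float = 0.95) -> float:
    """Recover a standard error from a symmetric normal confidence interval."""
    if hi <= lo:
        raise MetaError(f"need hi > lo, got ({lo}, {hi})")
    q = Z95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2.0)
    return (hi - lo) / (2.0 * q)


def _heterogeneity(betas: np.ndarray, w: np.ndarray) -> tuple[float, int, float, float]:
    """Q, df, p_Q and I² from fixed-effect weights."""
    beta_f = float((w * betas).sum() / w.sum())
    Q = float((w * (betas - beta_f) ** 2).sum())
    df = len(betas) - 1
    p_Q = float(stats.chi2.sf(Q, df)) if df > 0 else float("nan")
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Q, df, p_Q, i2


def _pooled(studies: list[StudyEstimate], w: np.ndarray, model: str,
            Q: float, df: int, p_Q: float, tau2: float, i2: float) -> MetaResult:
    betas = np.array([s.beta for s in studies])
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    weights = {s.label: float(100.0 * wi / w.sum()) for s, wi in zip(studies, w)}
    return MetaResult(model=model, beta=beta, se=se,
                      lo=beta - Z95 * se, hi=beta + Z95 * se,
                      weights_pct=weights, Q=Q, df=df, p_Q=p_Q, tau2=tau2, i2_pct=i2)


def pool_fixed(studies: list[StudyEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance pooling."""
    if not studies:
        raise MetaError("no studies to pool")
    betas = np.array([s.beta for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    Q, df, p_Q, i2 = _heterogeneity(betas, w)
    return _pooled(studies, w, "fixed", Q, df, p_Q, 0.0, i2)


def pool_random_dl(studies: list[StudyEstimate]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    With a single study (or τ² truncating to zero) this coincides with the
    fixed-effect result apart from the model label.
    """
    if not studies:
        raise MetaError("no studies to pool")
    betas = np.array([s.beta for s in studies])
    se2 = np.array([s.se**2 for s in studies])
    w = 1.0 / se2
    Q, df, p_Q, i2 = _heterogeneity(betas, w)
    if df == 0:
        tau2 = 0.0
    else:
        C = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - df) / C)
    w_star = 1.0 / (se2 + tau2)
    return _pooled(studies, w_star, "random", Q, df, p_Q, float(tau2), i2)


def heterogeneity_band(i2_pct: float) -> str:
    """Four-band reading of I²; boundary values go to the higher band."""
    if not 0.0 <= i2_pct <= 100.0:
        raise MetaError(f"I² must lie in [0, 100], got {i2_pct}")
    if i2_pct < 25.0:
        return "no"
    if i2_pct < 50.0:
        return "moderate"
    if i2_pct < 75.0:
        return "significant"
    return "extreme"


def forest_table(studies: list[StudyEstimate], pooled: MetaResult) -> str:
    """Plain-text forest-style summary, one row per study plus the pooled row."""
    lines = [f"{'study':<12}{'beta':>10}{'95% CI':>22}{'weight%':>10}"]
    for s in studies:
        lo, hi = s.beta - Z95 * s.se, s.beta + Z95 * s.se
        lines.append(f"{s.label:<12}{s.beta:>10.2f}{f'({lo:.2f}; {hi:.2f})':>22}"
                     f"{pooled.weights_pct[s.label]:>10.2f}")
    lines.append(f"{'pooled':<12}{pooled.beta:>10.2f}{f'({pooled.lo:.2f}; {pooled.hi:.2f})':>22}{100.0:>10.2f}")
    lines.append(f"Q={pooled.Q:.2f} (df={pooled.df}, p={pooled.p_Q:.3f})  "
                 f"tau^2={pooled.tau2:.2f}  I^2={pooled.i2_pct:.1f}% ({pooled.band})")
    return "\n".join(lines)
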
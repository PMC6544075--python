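"""Count-evidence statistics: Yeo-Johnson normalization and the per-category
null-hypothesis test of an index read count against control transcriptomes.

The abnormal-read count of the index case is compared with the counts of
the same category in control samples.  Control counts are Yeo-Johnson
transformed with a maximum-likelihood λ (fit on the controls only, so the
null model stays independent of the value under test), the index count is
transformed with the same λ, standardized against the control mean and
standard deviation, and the upper tail of the standard normal gives the
probability that the index count is consistent with normal splicing.  The
alternative is always an excess of abnormal reads, hence one-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

DEFAULT_ALPHA = 0.05
#: "highly significant" evidence threshold used by the classifier
STRONG_ALPHA = 0.005
#: reporting threshold for screenshot-grade evidence
REPORT_ALPHA = 0.01

LAMBDA_BOUNDS = (-5.0, 5.0)


@dataclass
class EvidenceTest:
    """Result of one evidence-category test for one case."""

    category: str | None
    index_count: float
    control_counts: tuple[float, ...]
    lambda_hat: float
    z: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value)


def significance_tier(p: float) -> str:
    if p <= STRONG_ALPHA:
        return "highly significant"
    if p <= REPORT_ALPHA:
        return "significant (p<=0.01)"
    if p <= DEFAULT_ALPHA:
        return "significant"
    return "not significant"


def yeo_johnson(x, lam: float):
    """Yeo-Johnson power transformation, defined for all real x.

    x >= 0: ((x+1)^λ − 1)/λ       (log(x+1) at λ = 0)
    x <  0: −((−x+1)^(2−λ) − 1)/(2−λ)   (−log(−x+1) at λ = 2)
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lam) < 1e-12:
        out[pos] = np.log1p(x[pos])
    else:
        out[pos] = (np.power(x[pos] + 1.0, lam) - 1.0) / lam
    neg = ~pos
    if abs(lam - 2.0) < 1e-12:
        out[neg] = -np.log1p(-x[neg])
    else:
        out[neg] = -(np.power(-x[neg] + 1.0, 2.0 - lam) - 1.0) / (2.0 - lam)
    if out.ndim == 0:
        return float(out)
    return out


def yj_log_likelihood(lam: float, x: np.ndarray) -> float:
    """Profile normal log-likelihood of the Yeo-Johnson transformed sample."""
    x = np.asarray(x, dtype=float)
    y = yeo_johnson(x, lam)
    var = np.var(y)
    if var <= 0.0 or not np.isfinite(var):
        return -np.inf
    n = x.size
    jacobian = np.sum(np.sign(x) * np.log1p(np.abs(x)))
    return -n / 2.0 * np.log(var) + (lam - 1.0) * jacobian


def fit_lambda(counts: Sequence[float], bounds: tuple[float, float] = LAMBDA_BOUNDS) -> float:
    """Maximum-likelihood Yeo-Johnson λ over a bounded interval.

    Degenerate input (all values identical) yields λ = 1 (identity) with a
    warning, since the likelihood is then flat in λ.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 values are required to fit lambda")
    if np.ptp(x) == 0.0:
        warnings.warn("all values identical; Yeo-Johnson lambda set to 1", stacklevel=2)
        return 1.0
    res = optimize.minimize_scalar(
        lambda lam: -yj_log_likelihood(lam, x),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def evidence_p_value(
    index_count: float,
    control_counts: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    category: str | None = None,
) -> EvidenceTest:
    """Test whether the index count exceeds normal splicing in controls.

    λ is fit on the control counts alone; z standardizes the transformed
    index count by the control mean and (ddof=1) standard deviation; the
    p-value is the one-sided upper-tail standard-normal probability.

    Degenerate rule: when the transformed controls have zero spread, p = 0
    if the index count exceeds the controls' common value, else p = 1.
    """
    controls = np.asarray(control_counts, dtype=float)
    if controls.size < 3:
        raise ValueError("at least 3 control counts are required")
    if np.ptp(controls) == 0.0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = fit_lambda(controls) if controls.size else 1.0
    else:
        lam = fit_lambda(controls)
    t_controls = yeo_johnson(controls, lam)
    t_index = float(yeo_johnson(index_count, lam))
    sd = float(np.std(t_controls, ddof=1))
    mean = float(np.mean(t_controls))
    if sd == 0.0:
        z = np.inf if t_index > mean else (-np.inf if t_index < mean else 0.0)
        p = 0.0 if t_index > mean else 1.0
    else:
        z = (t_index - mean) / sd
        p = float(stats.norm.sf(z))
    return EvidenceTest(
        category=category,
        index_count=float(index_count),
        control_counts=tuple(float(c) for c in controls),
        lambda_hat=lam,
        z=float(z),
        p_value=p,
        significant=p <= alpha,
    )


def evaluate_categories(
    counts, alpha: float = DEFAULT_ALPHA
) -> list[EvidenceTest]:
    """Run the evidence test for every category of an EvidenceCounts record."""
    return [
        evidence_p_value(
            counts.index_counts[cat], counts.control_counts[cat], alpha=alpha, category=cat
        )
        for cat in counts.index_counts
    ]
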
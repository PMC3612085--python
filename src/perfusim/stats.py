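"""Chemotaxis statistics: paired two-tailed test on displacements.

The chamber validation compares per-cell displacements along the
gradient axis between the attractant run and its matched control (same
seed, same initial positions).  Significance is assessed with a paired
two-tailed Student t test at alpha = 0.05; a paired Wilcoxon signed-rank
alternative is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = ["ChemotaxisStats", "paired_two_tailed_test", "one_sample_two_tailed_test",
           "chemotaxis_report"]

ALPHA = 0.05


@dataclass
class ChemotaxisStats:
    """Result of the paired displacement comparison (lengths in metres)."""

    test_displacements: np.ndarray
    control_displacements: np.ndarray
    statistic: float
    p_value: float
    significant: bool
    method: str = "paired-t"
    extra: dict = field(default_factory=dict)

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.test_displacements - self.control_displacements))


def _paired_t(diffs: np.ndarray) -> tuple[float, float]:
    n = diffs.size
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0   # all pairs identical
        return float(np.sign(mean)) * np.inf, 0.0  # hard zero-variance limit
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return t, p


def paired_two_tailed_test(
    x, y, *, alpha: float = ALPHA, method: str = "t"
) -> ChemotaxisStats:
    """Paired two-tailed test of H0: mean(x - y) = 0.

    ``method='t'`` (default) computes the Student t statistic on the
    paired differences with n-1 degrees of freedom; ``method='wilcoxon'``
    uses the signed-rank test instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("paired samples must be 1-D and equal length")
    if x.size < 3:
        raise ConfigurationError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigurationError("samples must be finite")
    d = x - y
    if method == "t":
        t, p = _paired_t(d)
        name = "paired-t"
    elif method == "wilcoxon":
        if np.all(d == 0):
            t, p = 0.0, 1.0
        else:
            res = sps.wilcoxon(d)
            t, p = float(res.statistic), float(res.pvalue)
        name = "paired-wilcoxon"
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    return ChemotaxisStats(
        test_displacements=x,
        control_displacements=y,
        statistic=t,
        p_value=p,
        significant=bool(p < alpha),
        method=name,
    )


def one_sample_two_tailed_test(x, *, alpha: float = ALPHA) -> ChemotaxisStats:
    """Two-tailed one-sample t test of H0: mean(x) = 0 (used to check that
    the control migration is unbiased)."""
    x = np.asarray(x, dtype=float)
    t, p = _paired_t(x)
    return ChemotaxisStats(
        test_displacements=x,
        control_displacements=np.zeros_like(x),
        statistic=t,
        p_value=p,
        significant=bool(p < alpha),
        method="one-sample-t",
    )


def chemotaxis_report(test_disp, control_disp, *, alpha: float = ALPHA) -> ChemotaxisStats:
    """Paired comparison plus the control's own bias test in ``extra``."""
    res = paired_two_tailed_test(test_disp, control_disp, alpha=alpha)
    ctrl = one_sample_two_tailed_test(control_disp, alpha=alpha)
    res.extra["control_p_value"] = ctrl.p_value
    res.extra["control_significant"] = ctrl.significant
    res.extra["mean_test_um"] = float(np.mean(res.test_displacements)) * 1e6
    res.extra["mean_control_um"] = float(np.mean(res.control_displacements)) * 1e6
    return res
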
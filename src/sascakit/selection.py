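"""Nested-model selection: one vs two exponential uptake components.

The two-exponential model nests the one-exponential model (set C = 0),
so the extra-sum-of-squares F-test applies:

    F = ((RSS_1 - RSS_2) / 2) / (RSS_2 / (n - 4)),

with 2 numerator degrees of freedom (the two extra parameters C, D) and
n - 4 denominator degrees of freedom.  A small upper-tail p-value means
the second uptake component earns its keep — the expected outcome for
efflux-pump-active resistant cells, but not for drug-sensitive cells.

The test assumes independent homoscedastic residuals; autocorrelation
induced by the windowed duty-cycle sampling is ignored, a documented
limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinetics import FitError, KineticFit, fit_one_exp, fit_two_exp
from .trace import ProcessedTrace

__all__ = ["FTestResult", "ModelSelection", "f_test_nested", "select_model"]

DEFAULT_ALPHA = 0.05


@dataclass
class FTestResult:
    """Extra-sum-of-squares F-test record for one- vs two-exponential fits."""

    F_stat: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float
    selected: str
    flags: list[str] = field(default_factory=list)


@dataclass
class ModelSelection:
    """Full selection record: both fits are retained, never discarded."""

    fit_one: KineticFit
    fit_two: KineticFit
    ftest: FTestResult

    @property
    def selected_fit(self) -> KineticFit:
        return self.fit_two if self.ftest.selected == "two_exp" else self.fit_one


def f_test_nested(fit1: KineticFit, fit2: KineticFit, alpha: float = DEFAULT_ALPHA) -> FTestResult:
    """Compare a one-exponential fit against the nesting two-exponential fit.

    Both fits must be on the identical observation vector.  When the
    two-exponential residual is exactly zero the statistic is
    undefined; the richer model is then selected with p = 0 and a
    ``'degenerate-perfect-fit'`` flag.
    """
    if fit1.model_kind != "one_exp" or fit2.model_kind != "two_exp":
        raise ValueError("f_test_nested expects (one_exp fit, two_exp fit)")
    if fit1.n_obs != fit2.n_obs:
        raise ValueError("fits must share the same observation vector")
    n = fit1.n_obs
    df_num, df_den = 2, n - 4
    if df_den <= 0:
        raise ValueError(f"need n > 4 observations for the F-test, got {n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    flags: list[str] = []
    rss1 = fit1.rss
    rss2 = fit2.rss if fit2.rss_unconstrained is None else fit2.rss_unconstrained
    scale1 = float(np.mean(np.square(fit1.fitted_values))) if fit1.fitted_values.size else 0.0
    scale2 = float(np.mean(np.square(fit2.fitted_values))) if fit2.fitted_values.size else 0.0
    if rss2 <= max(1e-24 * n * scale2, 0.0):
        if rss1 <= max(1e-24 * n * scale1, 0.0):
            # Both models reproduce the data to numerical precision:
            # parsimony keeps the simple one.
            flags.append("degenerate-both-perfect")
            return FTestResult(0.0, df_num, df_den, 1.0, alpha, "one_exp", flags)
        flags.append("degenerate-perfect-fit")
        return FTestResult(float("inf"), df_num, df_den, 0.0, alpha, "two_exp", flags)
    if rss1 < rss2:
        # Numerically the nested model should never win; clamp at F = 0.
        flags.append("rss-order-clamped")
        rss1 = rss2
    F = ((rss1 - rss2) / df_num) / (rss2 / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    selected = "two_exp" if p < alpha else "one_exp"
    return FTestResult(float(F), df_num, df_den, p, alpha, selected, flags)


def select_model(trace: ProcessedTrace | tuple, alpha: float = DEFAULT_ALPHA) -> ModelSelection:
    """Fit both uptake models and pick one by the nested F-test.

    Accepts a :class:`ProcessedTrace` or a ``(times, f)`` pair.  If the
    two-exponential fit collapsed to its one-exponential reduction
    (rates unidentifiable), selection falls to the simple model with a
    ``'rate-collapse'`` flag.  A non-convergent fit aborts selection
    with both diagnostics attached.
    """
    args = (trace,) if isinstance(trace, ProcessedTrace) else tuple(trace)
    fit1 = fit_one_exp(*args)
    fit2 = fit_two_exp(*args)
    if not (fit1.converged and fit2.converged):
        raise FitError(
            "selection aborted: non-convergent fit "
            f"(one_exp flags={fit1.flags}, two_exp flags={fit2.flags})"
        )
    if fit2.model_kind == "one_exp":  # rate-collapse reduction
        ftest = FTestResult(0.0, 2, fit1.n_obs - 4, 1.0, alpha, "one_exp", list(fit2.flags))
        return ModelSelection(fit1, fit2, ftest)
    ftest = f_test_nested(fit1, fit2, alpha)
    return ModelSelection(fit1, fit2, ftest)
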
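"""One-sample Kolmogorov-Smirnov machinery for tiny samples.

Sessions are compared by testing, per code, whether the n=6 per-session
percentages are consistent with a reference distribution fitted to the
sample itself: a normal with the sample mean and n-1 SD, or an
exponential with rate 1/mean.  The statistic is the sup-distance

    D = max_i max( F_n(x_i) - F(x_i),  F(x_i) - F_n(x_i^-) )

with the left limit ``F_n(x^-)`` handling ties (repeated zeros are the
norm in sparse affect codes).  Two p-value conventions are provided:
the classical exact null P(D_n >= D), which ignores that the reference
parameters were estimated, and a parametric bootstrap (fit, simulate,
refit) that accounts for estimation, in the spirit of the Lilliefors
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REFERENCES = ("normal_fitted", "exponential_fitted")


@dataclass(frozen=True)
class KSResult:
    D: float
    n: int
    reference: str
    p_value: float | None = None
    method: str | None = None
    flag: str = ""

    def __post_init__(self) -> None:
        if self.flag:
            return
        if not 0.0 <= self.D <= 1.0:
            raise ValueError(f"D={self.D} outside [0, 1]")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p={self.p_value} outside [0, 1]")


def _fitted_cdf(values: np.ndarray, reference: str):
    if reference == "normal_fitted":
        mean = values.mean()
        sd = values.std(ddof=1)
        if sd == 0:
            raise ValueError(
                "constant sample: cannot fit a normal reference (zero SD)"
            )
        return lambda x: stats.norm.cdf(x, loc=mean, scale=sd)
    if reference == "exponential_fitted":
        if np.any(values < 0):
            raise ValueError(
                "negative values: exponential reference requires x >= 0"
            )
        mean = values.mean()
        if mean <= 0:
            raise ValueError("exponential reference requires mean > 0")
        return lambda x: -np.expm1(-np.asarray(x, dtype=float) / mean)
    raise ValueError(f"unknown reference {reference!r}; use one of {REFERENCES}")


def _sup_distance(values: np.ndarray, cdf) -> float:
    x = np.sort(values)
    n = len(x)
    F = np.asarray(cdf(x), dtype=float)
    ecdf_right = np.searchsorted(x, x, side="right") / n  # F_n(x)
    ecdf_left = np.searchsorted(x, x, side="left") / n  # F_n(x^-)
    return float(max(np.max(ecdf_right - F), np.max(F - ecdf_left)))


def ks_D(values: Sequence[float], reference: str) -> KSResult:
    """Sup-distance D between the empirical CDF and a fitted reference."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d sample with n >= 2")
    cdf = _fitted_cdf(x, reference)
    return KSResult(D=_sup_distance(x, cdf), n=len(x), reference=reference)


def ks_pvalue(
    D: float,
    n: int,
    reference: str | None = None,
    method: str = "exact_kolmogorov",
    reps: int = 2000,
    seed: int | None = None,
) -> float:
    """P-value for an observed one-sample KS distance.

    ``exact_kolmogorov`` is the classical exact finite-n null
    P(D_n >= D) for a fully specified reference (no estimated
    parameters).  ``monte_carlo`` is a parametric bootstrap under the
    named fitted reference: simulate ``reps`` samples of size n from the
    reference family, refit on each, and return the fraction with a
    distance >= D.  Both references are (location-)scale families, so
    the bootstrap null does not depend on the fitted parameter values.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"D={D} outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if method == "exact_kolmogorov":
        return float(np.clip(stats.kstwo.sf(D, n), 0.0, 1.0))
    if method == "monte_carlo":
        if reference not in REFERENCES:
            raise ValueError(
                f"monte_carlo needs a reference in {REFERENCES}, got {reference!r}"
            )
        if reps < 100:
            raise ValueError("monte_carlo requires reps >= 100")
        rng = np.random.default_rng(seed)
        if reference == "normal_fitted":
            draws = rng.standard_normal((reps, n))
        else:
            draws = rng.standard_exponential((reps, n))
        exceed = 0
        for sample in draws:
            if reference == "normal_fitted" and sample.std(ddof=1) == 0:
                continue
            cdf = _fitted_cdf(sample, reference)
            if _sup_distance(np.sort(sample), cdf) >= D:
                exceed += 1
        return exceed / reps
    raise ValueError(f"unknown method {method!r}")


def ks_scan(
    percent_by_variable: Mapping[str, Sequence[float]],
    reference: str,
    pvalue_method: str | None = "exact_kolmogorov",
    reps: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the fitted-reference KS test on each variable's session values.

    ``percent_by_variable`` maps a code or meta-state name to its
    per-session percentages (one value per session).  Variables that are
    identically zero (never observed) or constant under a normal
    reference are flagged degenerate and get no D.
    """
    rows = []
    for name, values in percent_by_variable.items():
        x = np.asarray(values, dtype=float)
        if len(x) < 2:
            raise ValueError(f"{name}: need at least 2 sessions")
        if np.all(x == 0):
            rows.append(
                {"variable": name, "D": np.nan, "p_value": np.nan,
                 "flag": "degenerate (all zero)"}
            )
            continue
        if reference == "normal_fitted" and x.std(ddof=1) == 0:
            rows.append(
                {"variable": name, "D": np.nan, "p_value": np.nan,
                 "flag": "degenerate (constant)"}
            )
            continue
        result = ks_D(x, reference)
        p = (
            ks_pvalue(result.D, result.n, reference, pvalue_method, reps, seed)
            if pvalue_method
            else np.nan
        )
        rows.append({"variable": name, "D": result.D, "p_value": p, "flag": ""})
    return pd.DataFrame(rows, columns=["variable", "D", "p_value", "flag"])
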
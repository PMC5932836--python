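"""Method-agreement statistics for measured vs simulated hemodynamics.

Implements the validation protocol used to compare CFD-derived peak systolic
velocity/pressure against TTE and catheter references: Bland–Altman limits of
agreement, Pearson correlation with an ordinary least-squares fit, and
normality-gated paired comparisons (paired t when the differences pass a
composite Kolmogorov–Smirnov/Lilliefors normality check, Wilcoxon signed-rank
otherwise, with Levene's variance-homogeneity p reported alongside).

The reference 25-case cohort tables (TTE/catheter/CFD measurements and
reconstructed-vs-measured lumen diameters) ship with the package and are
loadable via :func:`load_reference_measurements` and
:func:`load_reference_diameters`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "AgreementReport",
    "PairedTestResult",
    "bland_altman",
    "correlation_and_fit",
    "paired_compare",
    "summarize_cohort",
    "load_reference_measurements",
    "load_reference_diameters",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman + linear-fit summary of a new method against a reference.

    Differences are ``new − ref``; ``loa_low``/``loa_high`` are
    ``bias ∓/± 1.96·sd_diff`` with the sample (n−1) standard deviation.
    ``r_squared`` is the coefficient of determination of the OLS fit of new on
    ref (the square of ``pearson_r``).
    """

    n: int
    mean_ref: float
    sd_ref: float
    mean_new: float
    sd_new: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of a normality-gated paired comparison."""

    test_name: str  # "paired-t" or "wilcoxon"
    statistic: float
    p: float
    normality_p: float
    levene_p: float
    degenerate: bool = False


def _paired_arrays(ref, new, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    new = np.asarray(new, dtype=float)
    if ref.shape != new.shape or ref.ndim != 1:
        raise ValueError(f"paired series must be 1-D and equal length, got {ref.shape} vs {new.shape}")
    if len(ref) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(ref)}")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(new))):
        raise ValueError("paired series contain non-finite values")
    return ref, new


def correlation_and_fit(ref, new) -> tuple[float, float, float, float]:
    """Pearson r and OLS fit of ``new`` on ``ref``.

    Returns ``(r, slope, intercept, p)`` with the two-sided p-value for r.
    Exactly collinear non-constant input gives ``r = ±1``; constant input is
    an error (the correlation is undefined).
    """
    ref, new = _paired_arrays(ref, new)
    if np.ptp(ref) == 0 or np.ptp(new) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    fit = stats.linregress(ref, new)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept), float(fit.pvalue)


def bland_altman(ref, new) -> AgreementReport:
    """Bland–Altman agreement of ``new`` against ``ref`` (paired by case).

    Identical non-constant series report zero bias, degenerate (0, 0) limits
    of agreement and r = 1; identical constant series are an error.
    """
    ref, new = _paired_arrays(ref, new)
    diff = new - ref
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    r, slope, intercept, p = correlation_and_fit(ref, new)
    return AgreementReport(
        n=len(ref),
        mean_ref=float(ref.mean()),
        sd_ref=float(ref.std(ddof=1)),
        mean_new=float(new.mean()),
        sd_new=float(new.std(ddof=1)),
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - 1.96 * sd_diff,
        loa_high=bias + 1.96 * sd_diff,
        pearson_r=r,
        r_squared=r * r,
        slope=slope,
        intercept=intercept,
        p_value=p,
    )


def paired_compare(x, y, alpha: float = NORMALITY_ALPHA) -> PairedTestResult:
    """Normality-gated paired comparison of two matched series.

    The Lilliefors (composite Kolmogorov–Smirnov) test on the paired
    differences decides the test: paired Student's t if normality is not
    rejected at ``alpha``, Wilcoxon signed-rank otherwise.  Levene's
    variance-homogeneity p between the two series is reported alongside.
    All-zero differences are degenerate and reported with p = 1.
    """
    x, y = _paired_arrays(x, y)
    diff = x - y
    levene_p = float(stats.levene(x, y).pvalue)
    if np.all(diff == 0):
        return PairedTestResult("paired-t", 0.0, 1.0, 1.0, levene_p, degenerate=True)
    if np.ptp(diff) == 0:
        # constant nonzero shift: KS on a point mass is degenerate; the sign
        # is certain, so fall through to Wilcoxon which handles ties exactly.
        norm_p = 0.0
    else:
        norm_p = float(lilliefors(diff, dist="norm")[1])
    if norm_p > alpha:
        res = stats.ttest_rel(x, y)
        return PairedTestResult("paired-t", float(res.statistic), float(res.pvalue), norm_p, levene_p)
    res = stats.wilcoxon(x, y)
    return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue), norm_p, levene_p)


def summarize_cohort(records: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Mean ± sample SD of every numeric column of a per-case table.

    Returns a frame indexed by column with ``mean``, ``sd`` and a formatted
    ``mean_sd`` string rounded to ``decimals``.  A single-record table reports
    the record itself with SD marked not-applicable (NaN).
    """
    num = records.select_dtypes("number")
    if num.shape[1] == 0 or len(num) < 1:
        raise ValueError("need at least one record with numeric columns")
    mean = num.mean()
    sd = num.std(ddof=1) if len(num) > 1 else pd.Series(np.nan, index=num.columns)
    out = pd.DataFrame({"mean": mean, "sd": sd})
    out["mean_sd"] = [
        f"{m:.{decimals}f} ± {s:.{decimals}f}" if np.isfinite(s) else f"{m:.{decimals}f} ± n/a"
        for m, s in zip(out["mean"], out["sd"])
    ]
    return out


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("aortohemo.data").joinpath(name).open() as f:
        return pd.read_csv(f, comment="#")


def load_reference_measurements() -> pd.DataFrame:
    """Packaged 25-case PSV (TTE vs CFD) and PSP (catheter vs CFD) table."""
    df = _load_packaged("table3_psv_psp.csv")
    assert len(df) == 25
    return df


def load_reference_diameters() -> pd.DataFrame:
    """Packaged 25-case reconstructed-vs-measured diameter table (long form)."""
    df = _load_packaged("table2_diameters.csv")
    assert len(df) == 75
    return df
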
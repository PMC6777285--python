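"""Method-comparison statistics between criterion and tracker heart rate.

Implements the agreement battery used in wearable validation work:

* ICC(2,1) — two-way, single-measure, absolute-agreement intraclass
  correlation computed from ANOVA mean squares, with Shrout–Fleiss F-based
  95% confidence intervals, and the conventional qualitative bands
  (weak < 0.50 ≤ moderate < 0.75 ≤ strong < 0.90 ≤ very strong);
* MAE and MAPE (|error|/criterion × 100) with a 10% MAPE validity cutoff;
* mean bias (tracker − criterion) and Bland–Altman 95% limits of agreement;
* a per-participant Pearson-r outlier screen (r < 0.3 on laboratory pairs)
  for sensitivity reanalysis.

Epochs are pooled across participants by default — rows are matched epochs,
columns the two devices — which mirrors how pooled validation studies report
a single ICC with very tight CIs; the within-participant correlation this
ignores is discussed in the package docs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .streams import MatchedPairs

MAPE_VALIDITY_CUTOFF_PCT = 10.0
OUTLIER_PEARSON_R = 0.3

ICC_BANDS = (
    (0.90, "very strong"),
    (0.75, "strong"),
    (0.50, "moderate"),
)


def _as_arrays(pairs: MatchedPairs | list[MatchedPairs]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, MatchedPairs):
        pairs = [pairs]
    if not pairs:
        return np.array([]), np.array([])
    crit = np.concatenate([m.criterion for m in pairs])
    trck = np.concatenate([m.tracker for m in pairs])
    return crit, trck


def label_icc(icc: float) -> str:
    """Qualitative agreement band; boundaries belong to the upper band."""
    if not np.isfinite(icc):
        raise ValueError("icc must be finite")
    for cut, name in ICC_BANDS:
        if icc >= cut:
            return name
    return "weak"


def icc_absolute_agreement(
    pairs: MatchedPairs | list[MatchedPairs] | np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    Rows are matched epochs, columns the two devices. From the two-way ANOVA
    decomposition with n rows and k = 2 columns:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

    The CI is the Shrout–Fleiss F-based interval. Degenerate input with no
    variance anywhere returns 0.0 with a warning rather than crashing.
    """
    if isinstance(pairs, np.ndarray):
        X = np.asarray(pairs, dtype=float)
    else:
        crit, trck = _as_arrays(pairs)
        X = np.column_stack([crit, trck])
    n, k = X.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 matched epochs")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((X - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-12:
        warnings.warn("degenerate input (no variance): ICC defined as 0.0")
        return 0.0, (0.0, 0.0)
    icc = (msr - mse) / denom

    if mse <= 0:
        # perfect agreement: residual variance zero, CI collapses
        return icc, (icc, icc)
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (
        k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
    ) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (
        n * (1 + (k - 1) * icc) - k * icc
    ) ** 2
    v = vn / vd
    f_lower = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_upper = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_lower * mse) / (
        f_lower * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_upper * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_upper * msr
    )
    return float(icc), (float(lower), float(upper))


@dataclass(frozen=True)
class ErrorMetrics:
    mae_bpm: float
    mae_ci: tuple[float, float]
    mape_percent: float
    mean_diff_bpm: float  # tracker − criterion; negative = underestimation
    mean_diff_ci: tuple[float, float]
    n_pairs: int


def error_metrics(pairs: MatchedPairs | list[MatchedPairs]) -> ErrorMetrics:
    """MAE, MAPE and mean bias over matched epochs.

    MAPE = mean(|tracker − criterion| / criterion) × 100; criterion values
    are strictly positive by the matching contract. 95% CIs use the normal
    approximation on the epoch-level mean (mean ± 1.96·SD/√n).
    """
    crit, trck = _as_arrays(pairs)
    if len(crit) == 0:
        raise ValueError("no matched pairs")
    if np.any(crit <= 0):
        raise ValueError("criterion values must be positive")
    diff = trck - crit
    abs_err = np.abs(diff)
    n = len(diff)

    def _ci(x: np.ndarray) -> tuple[float, float]:
        m = float(x.mean())
        if n < 2:
            return (m, m)
        half = 1.96 * float(x.std(ddof=1)) / np.sqrt(n)
        return (m - half, m + half)

    return ErrorMetrics(
        mae_bpm=float(abs_err.mean()),
        mae_ci=_ci(abs_err),
        mape_percent=float((abs_err / crit).mean() * 100.0),
        mean_diff_bpm=float(diff.mean()),
        mean_diff_ci=_ci(diff),
        n_pairs=n,
    )


@dataclass(frozen=True)
class BlandAltman:
    mean_diff_bpm: float
    sd_diff_bpm: float
    loa: tuple[float, float]  # mean ± 1.96·SD of the differences
    table: "np.ndarray"  # columns: mean of pair, tracker − criterion


def bland_altman(pairs: MatchedPairs | list[MatchedPairs]) -> BlandAltman:
    """Bland–Altman mean difference and 95% limits of agreement.

    With zero spread the limits collapse onto the mean difference.
    """
    crit, trck = _as_arrays(pairs)
    if len(crit) < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    diff = trck - crit
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    table = np.column_stack([(crit + trck) / 2.0, diff])
    return BlandAltman(
        mean_diff_bpm=mean,
        sd_diff_bpm=sd,
        loa=(mean - 1.96 * sd, mean + 1.96 * sd),
        table=table,
    )


@dataclass(frozen=True)
class AgreementResult:
    """The full agreement battery for one phase × tracker pairing."""

    icc: float
    icc_ci: tuple[float, float]
    icc_label: str
    mae_bpm: float
    mae_ci: tuple[float, float]
    mape_percent: float
    mean_diff_bpm: float
    mean_diff_ci: tuple[float, float]
    loa: tuple[float, float]
    n_pairs: int

    @property
    def meets_validity_cutoff(self) -> bool:
        """True when MAPE is at or below the 10% validity threshold."""
        return self.mape_percent <= MAPE_VALIDITY_CUTOFF_PCT

    def summary(self) -> dict:
        """Report-precision view: ICC to 2 decimals, MAPE to 1 (half-up)."""

        def _round(x: float, d: int) -> float:
            return float(
                Decimal(repr(float(x))).quantize(
                    Decimal(1).scaleb(-d), rounding=ROUND_HALF_UP
                )
            )

        return {
            "icc": _round(self.icc, 2),
            "icc_ci_lo": _round(self.icc_ci[0], 2),
            "icc_ci_hi": _round(self.icc_ci[1], 2),
            "icc_label": self.icc_label,
            "mae_bpm": _round(self.mae_bpm, 1),
            "mae_ci_lo": _round(self.mae_ci[0], 1),
            "mae_ci_hi": _round(self.mae_ci[1], 1),
            "mape_percent": _round(self.mape_percent, 1),
            "mean_diff_bpm": _round(self.mean_diff_bpm, 1),
            "loa_lower": _round(self.loa[0], 1),
            "loa_upper": _round(self.loa[1], 1),
            "n_pairs": self.n_pairs,
            "meets_validity_cutoff": self.meets_validity_cutoff,
        }


def compute_agreement(pairs: MatchedPairs | list[MatchedPairs]) -> AgreementResult:
    """Run the whole battery (ICC, errors, Bland–Altman) on matched pairs."""
    icc, ci = icc_absolute_agreement(pairs)
    em = error_metrics(pairs)
    ba = bland_altman(pairs)
    return AgreementResult(
        icc=icc,
        icc_ci=ci,
        icc_label=label_icc(icc),
        mae_bpm=em.mae_bpm,
        mae_ci=em.mae_ci,
        mape_percent=em.mape_percent,
        mean_diff_bpm=em.mean_diff_bpm,
        mean_diff_ci=em.mean_diff_ci,
        loa=ba.loa,
        n_pairs=em.n_pairs,
    )


def flag_outliers(
    lab_pairs_by_participant: dict[str, MatchedPairs],
    r_threshold: float = OUTLIER_PEARSON_R,
) -> dict[str, str]:
    """Screen participants by tracker-vs-criterion Pearson r on lab pairs.

    Returns a status per participant: 'ok', 'flagged' (r < threshold, or r
    undefined because one device is constant), or 'not_evaluable' (< 3
    pairs). Flagged participants can then be dropped for the sensitivity
    reanalysis.
    """
    status: dict[str, str] = {}
    for pid, m in lab_pairs_by_participant.items():
        if len(m) < 3:
            status[pid] = "not_evaluable"
            continue
        crit, trck = m.criterion, m.tracker
        if np.std(crit) == 0 or np.std(trck) == 0:
            status[pid] = "flagged"
            continue
        r = float(stats.pearsonr(crit, trck).statistic)
        status[pid] = "flagged" if r < r_threshold else "ok"
    return status
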
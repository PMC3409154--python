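"""Mutant-null ChIP-qPCR occupancy quantification.

The design exploits a genotype that lacks the immunoprecipitated factor:
the mutant (MUT) precipitate measures, amplicon by amplicon, the full
background of the pull-down with the identical antibody preparation. The
wild-type (WT) precipitate is put on the mutant chromatin scale with the
normalization coefficient

    k = mean(WT input signals) / mean(MUT input signals),

then the factor-specific signal is the background-subtracted difference

    specific = WT_ppt_mean / k - MUT_ppt_mean,

and the fraction of genomes occupied at the site is

    percent = 100 * specific / input_avg,

where ``input_avg`` pools the k-normalized WT input signals with the MUT
input signals. Errors are propagated first-order (differences add
variances, ratios add relative variances) from the triplicate standard
deviations, with k treated as a fixed plug-in constant. Evidence of
occupancy is a classical two-sample equal-variance t-test between the
k-normalized WT and the raw MUT precipitate signals, coded

    p < 0.0001 -> ****   p < 0.01 -> ***   p < 0.05 -> **
    p < 0.1    -> *      p < 0.3  -> +-    otherwise  ne

with "nd" for groups where amplification failed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crmchip.errors import DegenerateInputError, NotDetectedError
from crmchip.qpcr import (
    QpcrTriplicate,
    SignalSummary,
    plate_to_triplicates,
    signals_of,
    summarize_triplicate,
)

#: Two-tailed p-value thresholds and their codes, most stringent first.
SIGNIFICANCE_LEVELS = (
    (0.0001, "****"),
    (0.01, "***"),
    (0.05, "**"),
    (0.1, "*"),
    (0.3, "+-"),
)

#: Plausibility envelope for the normalization coefficient; values outside
#: warn (never error) — well-matched extract pairs should differ by less
#: than 2-fold in chromatin amount.
K_PLAUSIBLE = (0.5, 2.0)


def significance_code(p_value: float) -> str:
    """Map a two-tailed p-value to the fixed asterisk code."""
    for threshold, code in SIGNIFICANCE_LEVELS:
        if p_value < threshold:
            return code
    return "ne"


def normalization_coefficient(wt_input: SignalSummary, mut_input: SignalSummary) -> float:
    """Ratio of mean WT to mean MUT input signal (chromatin-amount scale factor)."""
    if not (wt_input.detected and mut_input.detected):
        raise NotDetectedError("input triplicate not detected")
    if wt_input.mean_signal <= 0 or mut_input.mean_signal <= 0:
        raise DegenerateInputError("input mean signals must be positive")
    k = wt_input.mean_signal / mut_input.mean_signal
    if not (K_PLAUSIBLE[0] <= k <= K_PLAUSIBLE[1]):
        warnings.warn(
            f"normalization coefficient {k:.3g} outside plausible range {K_PLAUSIBLE}",
            stacklevel=2,
        )
    return k


def max_fold_deviation(coefficients) -> float:
    """Largest fold difference from unity over a set of normalization coefficients."""
    ks = np.asarray(list(coefficients), dtype=float)
    if np.any(ks <= 0):
        raise DegenerateInputError("coefficients must be positive")
    return float(np.max(np.maximum(ks, 1.0 / ks)))


def specific_signal(
    wt_ppt: SignalSummary, mut_ppt: SignalSummary, k: float
) -> tuple[float, float]:
    """Background-subtracted factor-specific signal with propagated SD.

    Returns ``(wt_mean/k - mut_mean, sqrt((wt_sd/k)^2 + mut_sd^2))``.
    The value may be negative; it is never clamped.
    """
    if not (wt_ppt.detected and mut_ppt.detected):
        raise NotDetectedError("precipitate triplicate not detected")
    value = wt_ppt.mean_signal / k - mut_ppt.mean_signal
    sd = math.hypot(wt_ppt.sd_signal / k, mut_ppt.sd_signal)
    return value, sd


def percent_occupancy(
    specific: tuple[float, float],
    wt_input_signals,
    mut_input_signals,
    k: float,
    include_input_error: bool = True,
) -> tuple[float, float]:
    """Percent of genomes occupied, with first-order ratio error propagation.

    ``input_avg`` is the mean of the k-normalized WT input signals pooled
    with the raw MUT input signals. ``include_input_error`` adds the
    pooled-input variance term to the propagated SD (on by default; turn
    off to propagate from the precipitate triplicates alone).
    """
    value, sd = specific
    pooled = np.concatenate(
        [np.asarray(wt_input_signals, dtype=float) / k, np.asarray(mut_input_signals, dtype=float)]
    )
    input_avg = float(np.mean(pooled))
    if input_avg <= 0:
        raise DegenerateInputError("pooled input mean must be positive")
    percent = 100.0 * value / input_avg
    var = (sd / input_avg) ** 2
    if include_input_error and len(pooled) > 1:
        sd_input = float(np.std(pooled, ddof=1))
        var += (value * sd_input / input_avg**2) ** 2
    return percent, 100.0 * math.sqrt(var)


def _two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Equal-variance two-sample t; degenerate zero-variance cases handled."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dof = len(x) + len(y) - 2
    if np.var(x) == 0 and np.var(y) == 0:
        # degenerate zero-variance case; means compared to float round-off
        if math.isclose(float(np.mean(x)), float(np.mean(y)), rel_tol=1e-9, abs_tol=0.0):
            return 0.0, dof, 1.0
        return math.inf, dof, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), dof, float(p)


def occupancy_significance(wt_norm_signals, mut_signals) -> tuple[float, str]:
    """Two-tailed equal-variance t-test of k-normalized WT vs MUT precipitate signals."""
    _, _, p = _two_sample_t(wt_norm_signals, mut_signals)
    return p, significance_code(p)


def hdac_differential(
    wt_ppt: QpcrTriplicate, mut_ppt: QpcrTriplicate, k: float
) -> tuple[float, str]:
    """WT-vs-MUT difference in co-factor (e.g. HDAC) occupancy.

    Same statistical machinery as :func:`occupancy_significance`; no
    background subtraction, since the co-factor is present in both
    genotypes. "nd" propagates.
    """
    if not (summarize_triplicate(wt_ppt).detected and summarize_triplicate(mut_ppt).detected):
        raise NotDetectedError("precipitate triplicate not detected")
    return occupancy_significance(signals_of(wt_ppt) / k, signals_of(mut_ppt))


@dataclass(frozen=True)
class OccupancyResult:
    """Per-amplicon occupancy quantification for one extract pair."""

    amplicon_id: str
    antibody: str
    pair_id: str
    k: float
    wtppt_norm: float
    mutppt: float
    specific_signal: float
    specific_sd: float
    input_avg: float
    percent_occupancy: float
    percent_sd: float
    t: float
    df: int
    p_value: float
    code: str
    primary: bool = True


_ND = dict(
    k=float("nan"),
    wtppt_norm=float("nan"),
    mutppt=float("nan"),
    specific_signal=float("nan"),
    specific_sd=float("nan"),
    input_avg=float("nan"),
    percent_occupancy=float("nan"),
    percent_sd=float("nan"),
    t=float("nan"),
    df=0,
    p_value=float("nan"),
    code="nd",
)


def analyze_extract_pair(
    triplicates: list[QpcrTriplicate],
    pair_id: str = "",
    antibody: str | None = None,
    include_input_error: bool = True,
) -> list[OccupancyResult]:
    """Quantify occupancy per amplicon from one extract pair's triplicates.

    Expects, per amplicon, four well groups: (WT, MUT) x (input,
    precipitate). An amplicon with any undetected group is reported with
    code "nd" and NaN quantities.
    """
    by_amp: dict[str, dict[tuple[str, str], QpcrTriplicate]] = {}
    for trip in triplicates:
        if antibody is not None and trip.fraction == "precipitate" and trip.antibody != antibody:
            continue
        by_amp.setdefault(trip.amplicon_id, {})[(trip.genotype, trip.fraction)] = trip

    results = []
    for amplicon_id in sorted(by_amp):
        groups = by_amp[amplicon_id]
        try:
            wt_in = groups[("WT", "input")]
            mut_in = groups[("MUT", "input")]
            wt_ppt = groups[("WT", "precipitate")]
            mut_ppt = groups[("MUT", "precipitate")]
        except KeyError as exc:
            raise DegenerateInputError(
                f"amplicon {amplicon_id!r} is missing well group {exc.args[0]}"
            ) from None
        ab = wt_ppt.antibody
        try:
            k = normalization_coefficient(
                summarize_triplicate(wt_in), summarize_triplicate(mut_in)
            )
            wt_ppt_sum = summarize_triplicate(wt_ppt)
            mut_ppt_sum = summarize_triplicate(mut_ppt)
            value, sd = specific_signal(wt_ppt_sum, mut_ppt_sum, k)
            wt_sig = signals_of(wt_ppt)
            mut_sig = signals_of(mut_ppt)
            percent, percent_sd = percent_occupancy(
                (value, sd),
                signals_of(wt_in),
                signals_of(mut_in),
                k,
                include_input_error=include_input_error,
            )
            t, dof, p = _two_sample_t(wt_sig / k, mut_sig)
            input_avg = float(
                np.mean(np.concatenate([signals_of(wt_in) / k, signals_of(mut_in)]))
            )
            results.append(
                OccupancyResult(
                    amplicon_id=amplicon_id,
                    antibody=ab,
                    pair_id=pair_id,
                    k=k,
                    wtppt_norm=wt_ppt_sum.mean_signal / k,
                    mutppt=mut_ppt_sum.mean_signal,
                    specific_signal=value,
                    specific_sd=sd,
                    input_avg=input_avg,
                    percent_occupancy=percent,
                    percent_sd=percent_sd,
                    t=t,
                    df=dof,
                    p_value=p,
                    code=significance_code(p),
                )
            )
        except NotDetectedError:
            results.append(
                OccupancyResult(amplicon_id=amplicon_id, antibody=ab, pair_id=pair_id, **_ND)
            )
    return results


def analyze_plates(
    plates: list[pd.DataFrame],
    antibody: str | None = None,
    include_input_error: bool = True,
) -> list[OccupancyResult]:
    """Run the occupancy quantification over one or more plate tables.

    Each plate's ``sample`` column names the extract pair. When an
    amplicon was measured in several pairs, all results are reported and
    the one with the lowest p-value is flagged primary.
    """
    results: list[OccupancyResult] = []
    for df in plates:
        for pair_id, pair_df in df.groupby("sample", sort=True):
            trips = plate_to_triplicates(pair_df)
            results.extend(
                analyze_extract_pair(
                    trips, pair_id=str(pair_id), antibody=antibody,
                    include_input_error=include_input_error,
                )
            )
    return mark_primary(results)


def mark_primary(results: list[OccupancyResult]) -> list[OccupancyResult]:
    """Flag, per amplicon, the extract pair with the lowest p-value as primary."""
    best: dict[str, int] = {}
    for i, r in enumerate(results):
        p = r.p_value if math.isfinite(r.p_value) else math.inf
        j = best.get(r.amplicon_id)
        if j is None or p < (
            results[j].p_value if math.isfinite(results[j].p_value) else math.inf
        ):
            best[r.amplicon_id] = i
    out = []
    for i, r in enumerate(results):
        out.append(
            OccupancyResult(**{**r.__dict__, "primary": best[r.amplicon_id] == i})
        )
    return out


def results_table(results: list[OccupancyResult]) -> pd.DataFrame:
    """Tidy per-amplicon table in the standard column order."""
    cols = [
        "amplicon_id", "antibody", "pair_id", "k", "wtppt_norm", "mutppt",
        "specific_signal", "specific_sd", "input_avg", "percent_occupancy",
        "percent_sd", "t", "df", "p_value", "code", "primary",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
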
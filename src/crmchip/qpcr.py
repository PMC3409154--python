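"""qPCR threshold-cycle handling: the efficiency model and triplicate summaries.

Threshold cycles are logarithmic in template amount and must not be
averaged directly. Each cycle is first converted to a linear-scale
signal (arbitrary units) under the per-cycle amplification efficiency
``E`` (between 1 and 2; 2 = perfect doubling):

    signal = 1e10 * E ** (-ct)

Triplicates are then summarised by the arithmetic mean and sample
standard deviation of the signals. A well group with fewer than two
amplified wells is "nd" (not detected) and carries no numeric summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from crmchip.errors import ParameterError

#: Fixed prefactor putting signals on a convenient arbitrary-unit scale.
#: All downstream ratios (k, percent occupancy, fold changes) are
#: invariant to it.
SIGNAL_PREFACTOR = 1e10

PLATE_COLUMNS = ["well", "sample", "genotype", "fraction", "antibody", "amplicon", "ct", "efficiency"]


def _check_efficiency(efficiency: float) -> None:
    if not (1.0 < efficiency <= 2.0):
        raise ParameterError(f"efficiency must lie in (1, 2], got {efficiency}")


def ct_to_signal(ct, efficiency: float = 2.0):
    """Convert threshold cycle(s) to linear signal: ``1e10 * E**(-ct)``.

    Accepts a scalar or array; strictly decreasing in ``ct`` and, for
    positive ``ct``, in ``efficiency``.
    """
    _check_efficiency(efficiency)
    return SIGNAL_PREFACTOR * np.power(float(efficiency), -np.asarray(ct, dtype=float))[()]


def signal_to_ct(signal, efficiency: float = 2.0):
    """Inverse of :func:`ct_to_signal` (used by the simulators)."""
    _check_efficiency(efficiency)
    sig = np.asarray(signal, dtype=float)
    return (-np.log(sig / SIGNAL_PREFACTOR) / np.log(float(efficiency)))[()]


@dataclass(frozen=True)
class QpcrTriplicate:
    """Up to three threshold cycles for one well group.

    ``ct_values`` may contain ``None``/NaN for undetermined wells
    (no amplification before the cycle limit).
    """

    ct_values: tuple
    efficiency: float = 2.0
    amplicon_id: str = ""
    genotype: str = ""
    fraction: str = ""
    antibody: str = ""

    def __post_init__(self) -> None:
        _check_efficiency(self.efficiency)
        if len(self.ct_values) > 3:
            raise ParameterError("a technical triplicate has at most 3 wells")
        for ct in self.present_cts():
            if ct <= 0:
                raise ParameterError(f"threshold cycles must be positive, got {ct}")

    def present_cts(self) -> list[float]:
        return [
            float(ct)
            for ct in self.ct_values
            if ct is not None and math.isfinite(float(ct))
        ]


@dataclass(frozen=True)
class SignalSummary:
    """Mean/SD of the linear-scale signals of one triplicate."""

    mean_signal: float
    sd_signal: float
    n: int
    detected: bool

    def __post_init__(self) -> None:
        if self.detected and self.sd_signal < 0:
            raise ParameterError("sd_signal must be >= 0")


def summarize_triplicate(trip: QpcrTriplicate) -> SignalSummary:
    """Convert each amplified well to a signal, then average on the linear scale.

    ``detected`` requires at least two amplified wells; otherwise the
    group is "nd" and mean/SD are NaN. The SD uses the n-1 denominator.
    Cycles are never averaged before conversion.
    """
    cts = trip.present_cts()
    if len(cts) < 2:
        return SignalSummary(mean_signal=float("nan"), sd_signal=float("nan"), n=len(cts), detected=False)
    signals = ct_to_signal(np.array(cts), trip.efficiency)
    return SignalSummary(
        mean_signal=float(np.mean(signals)),
        sd_signal=float(np.std(signals, ddof=1)),
        n=len(cts),
        detected=True,
    )


def signals_of(trip: QpcrTriplicate) -> np.ndarray:
    """Linear signals of the amplified wells (order preserved)."""
    return np.atleast_1d(ct_to_signal(np.array(trip.present_cts()), trip.efficiency))


def read_plate_csv(path_or_buffer) -> pd.DataFrame:
    """Read a plate table; empty ``ct`` fields mark undetermined wells."""
    df = pd.read_csv(path_or_buffer, dtype={"ct": float, "efficiency": float})
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"plate CSV is missing columns {missing}")
    return df


def plate_to_triplicates(df: pd.DataFrame) -> list[QpcrTriplicate]:
    """Group plate rows into triplicates by (genotype, fraction, antibody, amplicon)."""
    trips = []
    for (genotype, fraction, antibody, amplicon), grp in df.groupby(
        ["genotype", "fraction", "antibody", "amplicon"], sort=True, dropna=False
    ):
        cts = tuple(None if pd.isna(ct) else float(ct) for ct in grp["ct"])
        eff = float(grp["efficiency"].iloc[0])
        trips.append(
            QpcrTriplicate(
                ct_values=cts,
                efficiency=eff,
                amplicon_id=str(amplicon),
                genotype=str(genotype),
                fraction=str(fraction),
                antibody=str(antibody),
            )
        )
    return trips


def write_plate_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=PLATE_COLUMNS)
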
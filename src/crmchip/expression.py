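"""Genotype-contrast expression analysis.

Fold changes between wild-type and mutant arrays use a signed
convention: the ratio r = mean(MUT)/mean(WT) is reported as r when
r >= 1 (higher in mutants: genetic repression by the factor) and as
-1/r when r < 1 (lower in mutants: genetic activation), so
|signed_fold| >= 1 always and swapping the genotype labels flips the
sign. Per-gene evidence is a two-sample Student t-test on log2
intensities; p-values are reported unadjusted.

The false-discovery rate as a function of fold cutoff ("fold scanning")
compares the number of probe sets beyond +/-cutoff in the true contrast
with the mean of the same count over balanced relabelings of the arrays
that mix genotypes: mixing destroys the true contrast while preserving
per-array noise, so the null counts estimate how many calls the noise
alone produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from crmchip.errors import DegenerateInputError, NotDetectedError, ParameterError
from crmchip.qpcr import QpcrTriplicate, summarize_triplicate


@dataclass(frozen=True)
class FoldRecord:
    """Signed fold change with delta-method SD and a per-gene t-test p-value."""

    probe_id: str
    signed_fold: float
    fold_sd: float
    p_value: float

    def __post_init__(self) -> None:
        if abs(self.signed_fold) < 1.0 - 1e-12:
            raise ParameterError("signed fold magnitude must be >= 1")


@dataclass(frozen=True)
class FoldScanPoint:
    """One point of the fold-scanning FDR curve."""

    cutoff: float
    n_observed: int
    n_null: float

    @property
    def fdr(self) -> float:
        """n_null / n_observed; NaN when nothing is observed beyond the cutoff."""
        if self.n_observed == 0:
            return float("nan")
        return self.n_null / self.n_observed


def signed_fold(wt_values, mut_values, probe_id: str = "") -> FoldRecord:
    """Signed MUT-vs-WT fold change for one probe set.

    r = mean(MUT)/mean(WT); signed_fold = r if r >= 1 else -1/r. The SD
    comes from first-order propagation of the two group means through
    the ratio; the p-value from an equal-variance t-test on log2 values.
    """
    wt = np.asarray(wt_values, dtype=float)
    mut = np.asarray(mut_values, dtype=float)
    m_wt, m_mut = float(np.mean(wt)), float(np.mean(mut))
    if m_wt <= 0 or m_mut <= 0:
        raise DegenerateInputError("group mean intensities must be positive")
    r = m_mut / m_wt
    # relative variance of the ratio of the two means
    rel_var = 0.0
    if len(wt) > 1:
        rel_var += np.var(wt, ddof=1) / (len(wt) * m_wt**2)
    if len(mut) > 1:
        rel_var += np.var(mut, ddof=1) / (len(mut) * m_mut**2)
    sd_r = r * math.sqrt(rel_var)
    if r >= 1.0:
        fold, fold_sd = r, sd_r
    else:
        fold, fold_sd = -1.0 / r, sd_r / r**2
    if len(wt) > 1 and len(mut) > 1:
        lw, lm = np.log2(wt), np.log2(mut)
        if np.var(lw) == 0 and np.var(lm) == 0:
            # degenerate zero-variance groups: decided by the means alone
            p = 1.0 if math.isclose(float(lw.mean()), float(lm.mean()), rel_tol=1e-12, abs_tol=1e-12) else 0.0
        else:
            _, p = stats.ttest_ind(lm, lw, equal_var=True)
            p = float(p) if math.isfinite(p) else 1.0
    else:
        p = float("nan")
    return FoldRecord(probe_id=probe_id, signed_fold=fold, fold_sd=fold_sd, p_value=p)


def fold_magnitudes(matrix: pd.DataFrame, wt_cols, mut_cols) -> pd.Series:
    """|signed_fold| per probe, vectorized (max of the ratio and its inverse)."""
    m_wt = matrix[list(wt_cols)].mean(axis=1)
    m_mut = matrix[list(mut_cols)].mean(axis=1)
    if (m_wt <= 0).any() or (m_mut <= 0).any():
        raise DegenerateInputError("group mean intensities must be positive")
    r = m_mut / m_wt
    return np.maximum(r, 1.0 / r)


def collapse_probe_sets(matrix: pd.DataFrame, probe_to_gene: dict) -> pd.DataFrame:
    """One row per gene: keep the probe set with the highest mean intensity.

    The mean is taken over all arrays; exact ties break lexicographically
    by probe id. Probes absent from the map pass through under their own id.
    """
    gene = matrix.index.to_series().map(lambda p: probe_to_gene.get(p, p))
    mean_intensity = matrix.mean(axis=1)
    order = pd.DataFrame({"gene": gene, "mean": mean_intensity, "probe": matrix.index})
    order = order.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    keep = order.drop_duplicates("gene", keep="first")["probe"]
    collapsed = matrix.loc[keep].copy()
    collapsed.index = [probe_to_gene.get(p, p) for p in collapsed.index]
    collapsed.index.name = "gene"
    return collapsed


def balanced_null_splits(wt_cols, mut_cols) -> list[tuple[tuple, tuple]]:
    """Balanced relabelings of the arrays that mix genotypes.

    Every way of assigning the arrays to two pseudo-groups of the
    original sizes, excluding the true labeling and its mirror, with each
    split counted once (a split and its mirror give identical
    |signed_fold|). For 3 vs 3 arrays this yields 9 mixed splits.
    """
    wt_cols, mut_cols = tuple(wt_cols), tuple(mut_cols)
    arrays = wt_cols + mut_cols
    true_set = frozenset(wt_cols)
    seen = set()
    splits = []
    for combo in combinations(arrays, len(wt_cols)):
        group = frozenset(combo)
        mirror = frozenset(arrays) - group
        if group in (true_set, frozenset(mut_cols)):
            continue
        key = frozenset((group, mirror))
        if key in seen:
            continue
        seen.add(key)
        splits.append((tuple(sorted(group)), tuple(sorted(mirror))))
    return splits


def fold_scan_fdr(
    matrix: pd.DataFrame, wt_cols, mut_cols, cutoffs
) -> list[FoldScanPoint]:
    """Fold-scanning FDR curve for the WT-vs-MUT contrast.

    For each cutoff c: n_observed = #probes with |signed_fold| > c under
    the true labeling; n_null = mean of that count over the balanced
    mixed relabelings; fdr = n_null / n_observed (NaN when n_observed=0).
    """
    cutoffs = [float(c) for c in cutoffs]
    if any(c < 1 for c in cutoffs):
        raise ParameterError("fold cutoffs must be >= 1")
    observed = fold_magnitudes(matrix, wt_cols, mut_cols)
    null_counts = {c: [] for c in cutoffs}
    for g1, g2 in balanced_null_splits(wt_cols, mut_cols):
        null_mag = fold_magnitudes(matrix, g1, g2)
        for c in cutoffs:
            null_counts[c].append(int((null_mag > c).sum()))
    return [
        FoldScanPoint(
            cutoff=c,
            n_observed=int((observed > c).sum()),
            n_null=float(np.mean(null_counts[c])) if null_counts[c] else float("nan"),
        )
        for c in cutoffs
    ]


def fraction_regulated(n_regulated: int, n_total: int) -> int:
    """Integer percentage of regulated probe sets, rounded half-up."""
    if n_total <= 0:
        raise ParameterError("n_total must be positive")
    if not (0 <= n_regulated <= n_total):
        raise ParameterError("n_regulated must lie in [0, n_total]")
    return int(math.floor(100.0 * n_regulated / n_total + 0.5))


def qpcr_relative_abundance(
    target_wt: QpcrTriplicate,
    target_mut: QpcrTriplicate,
    reference_wt: QpcrTriplicate,
    reference_mut: QpcrTriplicate,
) -> float:
    """MUT-vs-WT expression fold of a target, normalized to a reference gene.

    fold = [sig_MUT(target)/sig_MUT(ref)] / [sig_WT(target)/sig_WT(ref)],
    with signals from the efficiency model — the efficiency-corrected
    delta-delta-Ct estimate. Raises :class:`NotDetectedError` if any
    component is nd.
    """
    summaries = {
        name: summarize_triplicate(trip)
        for name, trip in [
            ("target WT", target_wt),
            ("target MUT", target_mut),
            ("reference WT", reference_wt),
            ("reference MUT", reference_mut),
        ]
    }
    for name, s in summaries.items():
        if not s.detected:
            raise NotDetectedError(f"{name} triplicate not detected")
    return (summaries["target MUT"].mean_signal / summaries["reference MUT"].mean_signal) / (
        summaries["target WT"].mean_signal / summaries["reference WT"].mean_signal
    )


def fold_table(records: list[FoldRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "signed_fold": [r.signed_fold for r in records],
            "fold_sd": [r.fold_sd for r in records],
            "p_value": [r.p_value for r in records],
        }
    )


def foldscan_table(points: list[FoldScanPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cutoff": [p.cutoff for p in points],
            "n_observed": [p.n_observed for p in points],
            "n_null": [p.n_null for p in points],
            "fdr": [p.fdr for p in points],
        }
    )
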
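"""Synthetic-data generators with known ground truth.

Each generator is a pure function of its seed and emulates the
statistical structure the corresponding analysis stage assumes:

* :func:`simulate_chip_pair` — a WT/MUT ChIP-qPCR plate built from an
  additive copy-number model: the precipitate captures a nonspecific
  background fraction ``b`` of genomes in both genotypes plus, in WT
  only, the specifically occupied fraction ``f``; the mutant genotype
  lacks the factor, so its precipitate measures background alone.
  Copy numbers are converted to ideal threshold cycles by inverting the
  efficiency model and Gaussian noise is added per well on the Ct scale
  (the natural scale of qPCR measurement error). A chromatin-amount
  imbalance between the two extracts is drawn so the realized
  normalization coefficient falls in a configurable interval.
* :func:`simulate_expression` — a probe-by-array intensity matrix with
  log-normal baselines, three replicate arrays per genotype,
  multiplicative noise at a configured CV, a planted regulated subset,
  and an optional outlier replicate set with inflated noise.
* :func:`simulate_alignment` — a multi-species alignment block with
  TAATCY motifs planted in controlled species subsets and a background
  kept free of accidental motif matches, plus a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crmchip.alignment import AlignmentBlock, reverse_complement
from crmchip.errors import ConfigError
from crmchip.motifs import iupac_regex
from crmchip.qpcr import PLATE_COLUMNS, signal_to_ct

#: Sheared-chromatin fragment-length envelope recorded in plate metadata
#: (bp); documentation realism only — it never enters the signal math.
FRAGMENT_LENGTH_RANGE = (200, 500)
FRAGMENT_LENGTH_CENTER = 300


@dataclass(frozen=True)
class ChipSimConfig:
    """Conditions for one simulated WT/MUT ChIP-qPCR extract pair.

    ``true_occupancy`` is the fraction of genomes carrying the factor at
    a site in WT tissue; ``background`` the fraction of genomes
    nonspecifically precipitated at any site. Defaults put the WT/MUT
    precipitate ratio near 2.4 at 2% occupancy, the regime the assay
    was designed for. ``ct_noise_sd`` is the per-well Gaussian SD on the
    Ct scale, in cycles.
    """

    true_occupancy: float = 0.02
    background: float = 0.014
    genomes_per_reaction: float = 1e6
    ct_noise_sd: float = 0.15
    efficiency: float = 2.0
    capture: float = 1.0
    input_fraction: float = 1.0
    k_interval: tuple[float, float] = (0.6, 1.55)
    antibody: str = "Pitx2"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_occupancy <= 1.0):
            raise ConfigError("true_occupancy must lie in [0, 1]")
        if self.background <= 0:
            raise ConfigError("background must be positive")
        if self.genomes_per_reaction <= 0:
            raise ConfigError("genomes_per_reaction must be positive")
        if self.ct_noise_sd < 0:
            raise ConfigError("ct_noise_sd must be >= 0")
        if not (1.0 < self.efficiency <= 2.0):
            raise ConfigError("efficiency must lie in (1, 2]")
        if not (0 < self.k_interval[0] <= self.k_interval[1]):
            raise ConfigError("k_interval must be positive and ordered")


def simulate_chip_pair(
    cfg: ChipSimConfig, amplicons: dict[str, float] | None = None, pair_id: str = "pair1"
) -> tuple[pd.DataFrame, dict]:
    """Simulate one extract pair's plate table.

    ``amplicons`` maps amplicon id to its true WT occupancy fraction
    (default: one amplicon at ``cfg.true_occupancy``). Returns the plate
    table (standard column dialect) and a metadata dict holding the
    drawn chromatin imbalance and fragment-length envelope.
    """
    if amplicons is None:
        amplicons = {"amp1": cfg.true_occupancy}
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.k_interval
    imbalance = float(rng.uniform(lo, hi))  # WT/MUT chromatin-amount ratio
    n_wt = cfg.genomes_per_reaction * imbalance
    n_mut = cfg.genomes_per_reaction

    rows = []
    well = 0
    for amplicon_id, f in sorted(amplicons.items()):
        if not (0.0 <= f <= 1.0):
            raise ConfigError(f"occupancy for {amplicon_id!r} must lie in [0, 1]")
        expected = {
            ("WT", "input", "none"): n_wt * cfg.input_fraction,
            ("MUT", "input", "none"): n_mut * cfg.input_fraction,
            ("WT", "precipitate", cfg.antibody): n_wt * (cfg.background + f * cfg.capture),
            ("MUT", "precipitate", cfg.antibody): n_mut * cfg.background,
        }
        for (genotype, fraction, antibody), copies in expected.items():
            ideal_ct = signal_to_ct(copies, cfg.efficiency)
            for _ in range(3):
                well += 1
                ct = ideal_ct + rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd > 0 else ideal_ct
                rows.append(
                    {
                        "well": f"W{well:03d}",
                        "sample": pair_id,
                        "genotype": genotype,
                        "fraction": fraction,
                        "antibody": antibody,
                        "amplicon": amplicon_id,
                        "ct": float(ct),
                        "efficiency": cfg.efficiency,
                    }
                )
    plate = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    meta = {
        "pair_id": pair_id,
        "chromatin_imbalance": imbalance,
        "fragment_length_range_bp": FRAGMENT_LENGTH_RANGE,
        "fragment_length_center_bp": FRAGMENT_LENGTH_CENTER,
        "true_occupancy": dict(sorted(amplicons.items())),
    }
    return plate, meta


@dataclass(frozen=True)
class ExprSimConfig:
    """Conditions for a simulated genotype-contrast expression matrix.

    Defaults mirror the pooled-replicate design of the assay being
    emulated: three replicate arrays per genotype, ~10% multiplicative
    intensity CV, log-normal baselines. ``planted_folds`` pins specific
    genes (by index) to exact signed folds; ``regulated_fraction`` plants
    additional random regulation with magnitudes drawn log-uniformly
    from ``fold_range`` and random sign.
    """

    n_genes: int = 1000
    n_replicates: int = 3
    regulated_fraction: float = 0.0
    fold_range: tuple[float, float] = (1.5, 4.0)
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    cv: float = 0.10
    outlier_set: int | None = None
    outlier_factor: float = 3.0
    planted_folds: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicate arrays per genotype")
        if not (0.0 <= self.regulated_fraction <= 1.0):
            raise ConfigError("regulated_fraction must lie in [0, 1]")
        if self.cv < 0:
            raise ConfigError("cv must be >= 0")
        for idx, f in self.planted_folds.items():
            if not (0 <= idx < self.n_genes):
                raise ConfigError(f"planted gene index {idx} out of range")
            if abs(f) < 1.0:
                raise ConfigError(f"planted fold magnitude must be >= 1, got {f}")


def _apply_signed_fold(base: np.ndarray, folds: np.ndarray) -> np.ndarray:
    """Mutant means under the signed convention: f>=1 multiplies, f<=-1 divides."""
    out = base.copy()
    up = folds >= 1.0
    down = folds <= -1.0
    out[up] = base[up] * folds[up]
    out[down] = base[down] / np.abs(folds[down])
    return out


def simulate_expression(cfg: ExprSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an expression matrix and its truth table.

    Returns ``(matrix, truth)``: matrix indexed by probe id with columns
    ``WT_1..WT_n, MUT_1..MUT_n``; truth lists each gene's planted signed
    fold (+1 = unregulated).
    """
    rng = np.random.default_rng(cfg.seed)
    base = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes))

    folds = np.ones(cfg.n_genes)
    n_reg = int(round(cfg.regulated_fraction * cfg.n_genes))
    free = np.setdiff1d(np.arange(cfg.n_genes), np.array(list(cfg.planted_folds), dtype=int))
    if n_reg > 0:
        chosen = rng.choice(free, size=min(n_reg, len(free)), replace=False)
        mags = np.exp(rng.uniform(np.log(cfg.fold_range[0]), np.log(cfg.fold_range[1]), len(chosen)))
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        folds[chosen] = np.where(signs > 0, mags, -mags)
    for idx, f in cfg.planted_folds.items():
        folds[idx] = f

    mut_mean = _apply_signed_fold(base, folds)
    sigma = np.sqrt(np.log1p(cfg.cv**2))  # log-scale SD giving the requested CV

    columns = {}
    for genotype, means in (("WT", base), ("MUT", mut_mean)):
        for rep in range(1, cfg.n_replicates + 1):
            s = sigma * (cfg.outlier_factor if rep == cfg.outlier_set else 1.0)
            noise = np.exp(rng.normal(0.0, s, cfg.n_genes)) if s > 0 else 1.0
            columns[f"{genotype}_{rep}"] = means * noise

    probes = [f"probe{i:05d}" for i in range(cfg.n_genes)]
    matrix = pd.DataFrame(columns, index=pd.Index(probes, name="probe_id"))
    truth = pd.DataFrame({"probe_id": probes, "planted_fold": folds}).set_index("probe_id")
    return matrix, truth


@dataclass(frozen=True)
class AlnSimConfig:
    """Conditions for a simulated multi-species alignment.

    ``planted_sites`` maps a reference position to the species subset
    (reference included) that conserves a TAATCY motif planted there.
    The background is rejection-sampled to contain no accidental motif
    on either strand of the reference, so the truth table is exact.
    """

    species: tuple[str, ...] = (
        "mouse", "rat", "human", "chimp", "dog", "cow",
        "horse", "opossum", "platypus", "chicken", "frog", "zebrafish",
    )
    seq_length: int = 6000
    planted_sites: tuple[tuple[int, tuple[str, ...]], ...] = ()
    motif: str = "TAATCC"
    substitution_rate: float = 0.10
    gap_rate: float = 0.03
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) < 1 or len(self.species) > 20:
            raise ConfigError("between 1 and 20 species required")
        if len(set(self.species)) != len(self.species):
            raise ConfigError("species names must be unique")
        width = len(self.motif)
        spans = sorted(pos for pos, _ in self.planted_sites)
        for a, b in zip(spans, spans[1:]):
            if b < a + width:
                raise ConfigError("planted sites overlap")
        ref = self.species[0]
        for pos, subset in self.planted_sites:
            if pos < 0 or pos + width > self.seq_length:
                raise ConfigError(f"planted site at {pos} outside the sequence")
            if ref not in subset:
                raise ConfigError("every planted species subset must include the reference")
            unknown = set(subset) - set(self.species)
            if unknown:
                raise ConfigError(f"unknown species in subset: {sorted(unknown)}")


_BASES = np.array(list("ACGT"))


def _scrub_accidental_motifs(
    seq: np.ndarray, scan_patterns, protected: list[tuple[int, int]], width: int = 6
) -> np.ndarray:
    """Destroy every motif match (either strand) outside the protected intervals.

    A match is broken by rewriting one of its bases that does not fall in
    a protected interval; rescans until clean so junction-created matches
    are also removed.
    """

    def protected_pos(i: int) -> bool:
        return any(lo <= i < hi for lo, hi in protected)

    for _ in range(200):
        text = "".join(seq)
        hits = sorted(
            {
                m.start()
                for pat in scan_patterns
                for m in pat.finditer(text)
                if m.start() not in {lo for lo, _ in protected}
            }
        )
        if not hits:
            return seq
        for start in hits:
            for i in range(start, start + width):
                if not protected_pos(i):
                    seq[i] = "C" if seq[i] != "C" else "G"
                    break
            else:  # fully inside protection: cannot happen for equal-width motifs
                raise ConfigError("motif match fully inside a protected interval")
    raise ConfigError("could not scrub accidental motifs from the background")


def simulate_alignment(cfg: AlnSimConfig) -> tuple[AlignmentBlock, pd.DataFrame]:
    """Simulate an alignment block with planted conserved motifs.

    Returns the block and a truth table (BED-like: chrom, start, end,
    strand, intended conserving-species count). Non-subset species have
    the motif explicitly destroyed at the planted columns; subset
    species carry it exactly, with no gaps, regardless of the background
    substitution and gap processes.
    """
    rng = np.random.default_rng(cfg.seed)
    width = len(cfg.motif)
    # scrub the scanner's default targets (both strands) so the truth
    # table lists every reference site exactly
    scan = [iupac_regex("TAATCY"), iupac_regex("RGATTA")]

    ref = rng.choice(_BASES, size=cfg.seq_length)
    motif_chars = np.array(list(cfg.motif))
    protected = [(pos, pos + width) for pos, _ in cfg.planted_sites]
    for pos, _ in cfg.planted_sites:
        ref[pos : pos + width] = motif_chars
    ref = _scrub_accidental_motifs(ref, scan, protected, width=width)

    ref_species = cfg.species[0]
    rows = [(ref_species, "".join(ref))]
    for sp in cfg.species[1:]:
        row = ref.copy()
        # background divergence: substitutions then gaps, iid per column
        sub_mask = rng.random(cfg.seq_length) < cfg.substitution_rate
        if sub_mask.any():
            shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
            idx = (np.searchsorted(_BASES, row[sub_mask]) + shifts) % 4
            row[sub_mask] = _BASES[idx]
        gap_mask = rng.random(cfg.seq_length) < cfg.gap_rate
        row[gap_mask] = "-"
        for pos, subset in cfg.planted_sites:
            if sp in subset:
                row[pos : pos + width] = motif_chars
            else:
                # destroy: T->G at the first motif base cannot recreate
                # TAATCY on either strand
                row[pos : pos + width] = motif_chars
                row[pos] = "G"
        rows.append((sp, "".join(row)))

    block = AlignmentBlock(
        ref_species=ref_species, ref_chrom=cfg.chrom, ref_start=0, rows=tuple(rows)
    )
    truth = pd.DataFrame(
        {
            "chrom": [cfg.chrom] * len(cfg.planted_sites),
            "start": [pos for pos, _ in cfg.planted_sites],
            "end": [pos + width for pos, _ in cfg.planted_sites],
            "strand": ["+"] * len(cfg.planted_sites),
            "n_species": [len(set(subset)) for _, subset in cfg.planted_sites],
        }
    ).sort_values("start", ignore_index=True)
    return block, truth


def demo_alignment_config(seed: int = 0) -> AlnSimConfig:
    """The bundled demo alignment: three planted sites conserved in 4, 6 and 7 species."""
    species = AlnSimConfig().species
    return AlnSimConfig(
        seq_length=6000,
        planted_sites=(
            (800, species[:4]),
            (2600, species[:6]),
            (4400, species[:7]),
        ),
        seed=seed,
    )
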
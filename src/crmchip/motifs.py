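"""Bicoid core-motif scanning, conservation scoring, and amplicon design.

The core motif of bicoid-class homeodomain factors (Pitx2 among them) is
the hexamer TAATCY (Y = C or T). Because homeodomain cores are
orientation-independent, both strands are scanned by default: a match of
the reverse complement RGATTA on the reference strand is reported as a
minus-strand site. Conservation of a site in another species is decided
column-wise on the alignment — the species' characters at the six
reference columns must match the pattern with no gaps and no Ns — rather
than by re-searching nearby sequence.

Candidate cis-regulatory modules are sites conserved in at least
``min_species`` species (default 6); around each, a PCR amplicon window
of 70–150 bp is designed, and motif-free control regions are selected at
least 1 kb away from any site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

from crmchip.alignment import AlignmentBlock, reverse_complement
from crmchip.errors import (
    CoordinateError,
    InfeasibleWindowError,
    ParameterError,
    PatternError,
)

DEFAULT_MOTIF = "TAATCY"
MIN_AMPLICON = 70
MAX_AMPLICON = 150

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "[AG]",
    "Y": "[CT]",
    "S": "[CG]",
    "W": "[AT]",
    "K": "[GT]",
    "M": "[AC]",
    "B": "[CGT]",
    "D": "[AGT]",
    "H": "[ACT]",
    "V": "[ACG]",
    "N": "[ACGT]",
}


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC consensus into a regex (exact match, no ambiguity scoring)."""
    if not motif:
        raise PatternError("empty motif pattern")
    try:
        return re.compile("".join(IUPAC[c] for c in motif.upper()))
    except KeyError as exc:
        raise PatternError(f"invalid IUPAC character {exc.args[0]!r} in {motif!r}") from None


@dataclass(frozen=True)
class MotifSite:
    """A core-motif occurrence on the reference, with conservation evidence.

    Coordinates are 0-based half-open on the reference chromosome.
    ``matched_hexamer`` is always the reference-strand text; for a
    minus-strand site its reverse complement matches the motif.
    ``conserved_species`` contains every species (reference included)
    whose aligned characters spell the motif at the orthologous columns.
    """

    chrom: str
    start: int
    end: int
    strand: str
    matched_hexamer: str
    conserved_species: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched_hexamer):
            raise CoordinateError("site span does not match its hexamer length")
        if self.strand not in ("+", "-"):
            raise CoordinateError("strand must be '+' or '-'")

    @property
    def n_species(self) -> int:
        return len(self.conserved_species)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class AmpliconWindow:
    """A qPCR amplicon window containing one motif site (70–150 bp)."""

    chrom: str
    start: int
    end: int
    site: MotifSite

    def __post_init__(self) -> None:
        if not (MIN_AMPLICON <= self.length <= MAX_AMPLICON):
            raise CoordinateError(f"amplicon length {self.length} outside [70, 150]")
        if not (self.start <= self.site.start and self.site.end <= self.end):
            raise CoordinateError("amplicon window does not contain its motif site")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ControlRegion:
    """A motif-free region used for background primers."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_reference_motifs(
    block: AlignmentBlock,
    motif: str = DEFAULT_MOTIF,
    forward_only: bool = False,
) -> list[MotifSite]:
    """Find every motif occurrence on the gap-free reference sequence.

    Both strands are scanned unless ``forward_only``: a site whose
    reference-strand text matches the reverse complement of ``motif`` is
    reported with strand ``-``. Overlapping occurrences are all reported.
    Sites are sorted by start, then strand (``+`` before ``-``). Each
    returned site carries the reference species as its only conserving
    species; run :func:`annotate_conservation` to add the rest.
    """
    fwd = iupac_regex(motif)
    rev = iupac_regex(reverse_complement(motif))
    seq = block.ref_seq
    width = len(motif)
    ref_only = frozenset({block.ref_species})
    sites: list[MotifSite] = []
    patterns = [(fwd, "+")] if forward_only else [(fwd, "+"), (rev, "-")]
    for pattern, strand in patterns:
        # lookahead so overlapping matches are all found
        for m in re.finditer(f"(?=({pattern.pattern}))", seq):
            start = m.start()
            sites.append(
                MotifSite(
                    chrom=block.ref_chrom,
                    start=block.ref_start + start,
                    end=block.ref_start + start + width,
                    strand=strand,
                    matched_hexamer=seq[start : start + width],
                    conserved_species=ref_only,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def annotate_conservation(
    block: AlignmentBlock, sites: list[MotifSite], motif: str = DEFAULT_MOTIF
) -> list[MotifSite]:
    """Add, per site, the species whose aligned columns spell the motif.

    A species conserves a site iff its characters at the site's alignment
    columns, read on the site's strand, contain no gap and no N and match
    the motif pattern. The reference matches by construction.
    """
    pattern = iupac_regex(motif)
    cols = block.ref_columns()
    annotated = []
    for site in sites:
        lo = site.start - block.ref_start
        hi = site.end - block.ref_start
        if lo < 0 or hi > block.ref_length:
            raise CoordinateError(
                f"site {site.start}-{site.end} outside block span "
                f"{block.ref_start}-{block.ref_end}"
            )
        site_cols = cols[lo:hi]
        conserved = set()
        for sp, row in block.rows:
            chars = "".join(row[c] for c in site_cols)
            if "-" in chars or "N" in chars:
                continue
            if site.strand == "-":
                chars = reverse_complement(chars)
            if pattern.fullmatch(chars):
                conserved.add(sp)
        conserved.add(block.ref_species)
        annotated.append(replace(site, conserved_species=frozenset(conserved)))
    return annotated


def select_candidate_sites(sites: list[MotifSite], min_species: int = 6) -> list[MotifSite]:
    """Retain sites conserved in at least ``min_species`` species (coordinate order kept)."""
    if min_species < 1:
        raise ParameterError(f"min_species must be >= 1, got {min_species}")
    return [s for s in sites if s.n_species >= min_species]


def design_amplicon_window(
    site: MotifSite, seq_length: int, target_len: int = 110, ref_start: int = 0
) -> AmpliconWindow:
    """Center a 70–150 bp amplicon window on the motif, clipped to the sequence.

    The window is centered on the site (left flank rounded down when the
    flank split is odd) and shifted inward — preserving ``target_len`` —
    when it would run off either end of the sequence.
    """
    if not (MIN_AMPLICON <= target_len <= MAX_AMPLICON):
        raise ParameterError(f"target_len {target_len} outside [70, 150]")
    if seq_length < MIN_AMPLICON:
        raise InfeasibleWindowError(f"sequence of {seq_length} bp cannot hold a 70 bp amplicon")
    lo, hi = ref_start, ref_start + seq_length
    if not (lo <= site.start and site.end <= hi):
        raise CoordinateError("site lies outside the sequence")
    flank = target_len - (site.end - site.start)
    start = site.start - flank // 2
    end = start + target_len
    if start < lo:
        start, end = lo, min(lo + target_len, hi)
    if end > hi:
        end = hi
        start = max(lo, hi - target_len)
    return AmpliconWindow(chrom=site.chrom, start=start, end=end, site=site)


def select_control_regions(
    seq_length: int,
    all_sites: list[MotifSite],
    region_len: int = 110,
    exclusion: int = 1000,
    n: int = 1,
    ref_start: int = 0,
    chrom: str = "",
) -> list[ControlRegion]:
    """Greedy left-to-right selection of motif-free control regions.

    Returns up to ``n`` non-overlapping regions of ``region_len`` bp with
    no motif site (any strand, any conservation level) within
    ``exclusion`` bp on either side. Returns fewer than ``n`` when the
    sequence is exhausted.
    """
    regions: list[ControlRegion] = []
    starts = sorted((s.start, s.end) for s in all_sites)
    pos = ref_start
    limit = ref_start + seq_length
    while len(regions) < n and pos + region_len <= limit:
        lo = pos - exclusion
        hi = pos + region_len + exclusion
        violating = [e for s, e in starts if s < hi and e > lo]
        if violating:
            pos = max(violating) + exclusion
        else:
            regions.append(ControlRegion(chrom=chrom, start=pos, end=pos + region_len))
            pos += region_len
    return regions


def sites_to_bed(sites: list[MotifSite]) -> pd.DataFrame:
    """BED6 table of sites: score column carries the conserving-species count."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "name": [s.matched_hexamer for s in sites],
            "score": [s.n_species for s in sites],
            "strand": [s.strand for s in sites],
        }
    )


def amplicons_to_table(windows: list[AmpliconWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "length": [w.length for w in windows],
            "site_start": [w.site.start for w in windows],
            "site_end": [w.site.end for w in windows],
            "site_strand": [w.site.strand for w in windows],
            "n_species": [w.site.n_species for w in windows],
        }
    )


def controls_to_table(regions: list[ControlRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "length": [r.length for r in regions],
        }
    )
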
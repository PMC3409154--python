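"""Multi-species alignment blocks anchored to a reference genome.

An :class:`AlignmentBlock` is the in-memory form of one locus of a
multiple alignment: every species row spans the same alignment columns,
and the reference row is gap-free in genome space (its non-gap characters
enumerate consecutive reference positions starting at ``ref_start``).
Blocks can be read from MAF files or aligned multi-FASTA; a MAF covering
one locus is concatenated into a single block in reference order, with
uncovered reference stretches represented as ``N`` runs that no species
aligns to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import AlignIO

from crmchip.errors import CoordinateError

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn-", "TGCAYRMKVBHDNtgcayrmkvbhdn-")

VALID_CHARS = frozenset("ACGTN-")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned locus: equal-length rows, reference coordinates known.

    Parameters
    ----------
    ref_species:
        Species identifier of the reference row (must be present in ``rows``).
    ref_chrom:
        Reference chromosome name.
    ref_start:
        0-based reference coordinate of the first reference base.
    rows:
        Ordered ``(species, aligned_sequence)`` pairs over ``{A,C,G,T,N,-}``.
    ref_strand:
        Strand of the reference row; ``+`` in normal use.
    """

    ref_species: str
    ref_chrom: str
    ref_start: int
    rows: tuple[tuple[str, str], ...]
    ref_strand: str = "+"

    def __post_init__(self) -> None:
        rows = tuple((sp, seq.upper()) for sp, seq in self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise CoordinateError("alignment block has no rows")
        ncol = len(rows[0][1])
        species = [sp for sp, _ in rows]
        if len(set(species)) != len(species):
            raise CoordinateError("species identifiers must be unique within a block")
        if self.ref_species not in species:
            raise CoordinateError(f"reference species {self.ref_species!r} not in block")
        for sp, seq in rows:
            if len(seq) != ncol:
                raise CoordinateError(f"row {sp!r} has {len(seq)} columns, expected {ncol}")
            bad = set(seq) - VALID_CHARS
            if bad:
                raise CoordinateError(f"row {sp!r} contains invalid characters {sorted(bad)}")
        if self.ref_strand not in ("+", "-"):
            raise CoordinateError("ref_strand must be '+' or '-'")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sp for sp, _ in self.rows)

    @property
    def ref_row(self) -> str:
        """Aligned (gapped) reference sequence."""
        return dict(self.rows)[self.ref_species]

    @property
    def ref_seq(self) -> str:
        """Gap-free reference sequence."""
        return self.ref_row.replace("-", "")

    @property
    def ref_length(self) -> int:
        return len(self.ref_seq)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_length

    def ref_columns(self) -> list[int]:
        """Alignment column index of each gap-free reference position."""
        return [i for i, ch in enumerate(self.ref_row) if ch != "-"]

    def row(self, species: str) -> str:
        return dict(self.rows)[species]

    def reverse_complemented(self) -> "AlignmentBlock":
        """The same block read on the opposite strand (used for symmetry checks)."""
        new_rows = tuple((sp, reverse_complement(seq)) for sp, seq in self.rows)
        strand = "-" if self.ref_strand == "+" else "+"
        return replace(self, rows=new_rows, ref_strand=strand)

    def drop_species(self, species: str) -> "AlignmentBlock":
        if species == self.ref_species:
            raise CoordinateError("cannot drop the reference row")
        return replace(self, rows=tuple(r for r in self.rows if r[0] != species))


def _species_and_chrom(record_id: str) -> tuple[str, str]:
    # MAF convention: "mm9.chr6" -> species assembly "mm9", chromosome "chr6"
    if "." in record_id:
        sp, chrom = record_id.split(".", 1)
        return sp, chrom
    return record_id, ""


def read_maf(path: str, ref_species: str) -> AlignmentBlock:
    """Read a MAF file covering one locus and concatenate its blocks.

    Blocks are ordered by reference start. Reference positions between
    consecutive blocks are filled with ``N`` in the reference row (no
    motif can match there) and gaps in every other row, so uncovered
    stretches are treated as unaligned.
    """
    blocks = []
    for aln in AlignIO.parse(path, "maf"):
        rows = {}
        ref_start = None
        ref_chrom = None
        for rec in aln:
            sp, chrom = _species_and_chrom(rec.id)
            rows[sp] = str(rec.seq).upper()
            if sp == ref_species:
                ref_start = int(rec.annotations["start"])
                ref_chrom = chrom
        if ref_start is None:
            continue  # block without the reference row: nothing anchors it
        blocks.append((ref_start, ref_chrom, rows))
    if not blocks:
        raise CoordinateError(f"no MAF block contains reference species {ref_species!r}")
    blocks.sort(key=lambda b: b[0])

    all_species: list[str] = []
    for _, _, rows in blocks:
        for sp in rows:
            if sp not in all_species:
                all_species.append(sp)
    # reference first for readability
    all_species.sort(key=lambda sp: (sp != ref_species,))

    parts: dict[str, list[str]] = {sp: [] for sp in all_species}
    origin, chrom0, _ = blocks[0]
    cursor = origin
    for start, chrom, rows in blocks:
        if chrom != chrom0:
            raise CoordinateError("MAF blocks span multiple reference chromosomes")
        if start < cursor:
            raise CoordinateError("MAF blocks overlap on the reference")
        if start > cursor:
            pad = start - cursor
            for sp in all_species:
                parts[sp].append("N" * pad if sp == ref_species else "-" * pad)
        ncol = len(next(iter(rows.values())))
        for sp in all_species:
            parts[sp].append(rows.get(sp, "-" * ncol))
        cursor = start + len(rows[ref_species].replace("-", ""))
    joined = tuple((sp, "".join(parts[sp])) for sp in all_species)
    return AlignmentBlock(
        ref_species=ref_species, ref_chrom=chrom0 or "", ref_start=origin, rows=joined
    )


def read_fasta_alignment(
    path: str,
    ref_species: str | None = None,
    ref_chrom: str = "",
    ref_start: int = 0,
) -> AlignmentBlock:
    """Read an aligned multi-FASTA; the first record is the reference by default."""
    aln = AlignIO.read(path, "fasta")
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    if ref_species is None:
        ref_species = rows[0][0]
    return AlignmentBlock(
        ref_species=ref_species, ref_chrom=ref_chrom, ref_start=ref_start, rows=rows
    )
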
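"""In-silico SmaI/XmaI digestion of genome sequence.

SmaI and XmaI are isoschizomers recognizing CCCGGG; SmaI cuts blunt between
CCC and GGG (methylation sensitive), XmaI leaves a 4-nt overhang (methylation
insensitive).  The serial SmaI->XmaI digest underlying the MSAM assay
interrogates the genomic spans between consecutive CCCGGG sites, so the unit
of analysis everywhere downstream is the *restriction interval*: the stretch
from one blunt cut position to the next on the same contig.  Only intervals
in an informative length range (amplifiable and array-designable) are kept.

Coordinates are 0-based half-open throughout; BED output follows the BED
convention natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

MOTIF = "CCCGGG"
MOTIF_LEN = len(MOTIF)
#: offset of the SmaI blunt cut within the recognition motif (CCC^GGG)
CUT_OFFSET = 3

VALID_ALPHABET = frozenset("ACGTN")

INTERVAL_COLUMNS = ["interval_id", "contig", "start", "end", "length"]


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T, N}."""


@dataclass(frozen=True)
class RecognitionSite:
    """One CCCGGG occurrence; ``cut_pos`` is the SmaI blunt cut coordinate."""

    contig: str
    motif_start: int

    @property
    def cut_pos(self) -> int:
        return self.motif_start + CUT_OFFSET


@dataclass(frozen=True)
class RestrictionInterval:
    """Span between the cut positions of two consecutive CCCGGG sites."""

    contig: str
    start: int  # cut_pos of left site, inclusive
    end: int  # cut_pos of right site, exclusive

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate interval {self.contig}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    @property
    def left_motif_start(self) -> int:
        """Start of the left flanking CCCGGG motif (protrudes 3 bp upstream)."""
        return self.start - CUT_OFFSET

    @property
    def right_motif_start(self) -> int:
        return self.end - CUT_OFFSET


@dataclass(frozen=True)
class DigestConfig:
    """Informative-length bounds for restriction intervals, in bp (inclusive)."""

    min_len: int = 60
    max_len: int = 1500

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(f"require 0 < min_len <= max_len, got {self.min_len}, {self.max_len}")


def validate_sequence(sequence: str, contig: str = "?") -> str:
    """Upper-case and validate a nucleotide sequence; reject empty/bad alphabet."""
    seq = sequence.upper()
    if not seq:
        raise AlphabetError(f"contig {contig}: empty sequence")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        offset = next(i for i, c in enumerate(seq) if c in bad)
        raise AlphabetError(
            f"contig {contig}: invalid character {seq[offset]!r} at offset {offset}"
        )
    return seq


def find_sites(sequence: str, contig: str = "contig") -> list[RecognitionSite]:
    """All exact CCCGGG occurrences in ascending order.

    The motif is palindromic, so a single-strand scan is complete.  Motifs
    overlapping an N never match (``str.find`` is exact).
    """
    seq = validate_sequence(sequence, contig)
    sites = []
    pos = seq.find(MOTIF)
    while pos != -1:
        sites.append(RecognitionSite(contig, pos))
        pos = seq.find(MOTIF, pos + 1)
    return sites


def enumerate_intervals(
    sites: Iterable[RecognitionSite], config: DigestConfig | None = None
) -> list[RestrictionInterval]:
    """Intervals between consecutive cut sites, filtered to the length bounds.

    Bounds are inclusive on both ends.  Sites must be sorted within each
    contig; consecutive pairs spanning different contigs are never paired.
    """
    config = config or DigestConfig()
    out: list[RestrictionInterval] = []
    prev: RecognitionSite | None = None
    for site in sites:
        if prev is not None and prev.contig == site.contig:
            if site.motif_start <= prev.motif_start:
                raise ValueError(
                    f"sites out of order on {site.contig}: "
                    f"{prev.motif_start} then {site.motif_start}"
                )
            iv = RestrictionInterval(site.contig, prev.cut_pos, site.cut_pos)
            if config.min_len <= iv.length <= config.max_len:
                out.append(iv)
        prev = site
    return out


def _iter_fasta(fasta_path: str | Path) -> Iterator[tuple[str, str]]:
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    if len(fasta.keys()) == 0:
        raise ValueError(f"{path}: no sequences")
    for name in fasta.keys():
        yield name, str(fasta[name][:])


def intervals_to_frame(intervals: Iterable[RestrictionInterval]) -> pd.DataFrame:
    records = [
        (iv.interval_id, iv.contig, iv.start, iv.end, iv.length) for iv in intervals
    ]
    return pd.DataFrame(records, columns=INTERVAL_COLUMNS)


def digest_genome(
    fasta_path: str | Path, config: DigestConfig | None = None
) -> pd.DataFrame:
    """Digest every contig of a FASTA file into informative restriction intervals.

    Returns a table with columns ``interval_id contig start end length``,
    contigs in file order, intervals sorted within contig.  Deterministic:
    the same file always yields a byte-identical table.
    """
    config = config or DigestConfig()
    frames = []
    n_sites = 0
    for contig, seq in _iter_fasta(fasta_path):
        sites = find_sites(seq, contig)
        n_sites += len(sites)
        frames.append(intervals_to_frame(enumerate_intervals(sites, config)))
    table = pd.concat(frames, ignore_index=True) if frames else intervals_to_frame([])
    logger.info(
        "digest: %d recognition sites, %d informative intervals (%d-%d bp)",
        n_sites, len(table), config.min_len, config.max_len,
    )
    return table


def write_interval_table(table: pd.DataFrame, out_path: str | Path) -> None:
    table.to_csv(out_path, sep="\t", index=False)


def write_interval_bed(table: pd.DataFrame, out_path: str | Path) -> None:
    """6-column BED (name = interval_id, score = length, strand = '.')."""
    bed = pd.DataFrame(
        {
            "chrom": table["contig"],
            "chromStart": table["start"],
            "chromEnd": table["end"],
            "name": table["interval_id"],
            "score": table["length"],
            "strand": ".",
        }
    )
    bed.to_csv(out_path, sep="\t", index=False, header=False)


def read_interval_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(INTERVAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing interval columns {sorted(missing)}")
    return table
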
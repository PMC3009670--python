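"""Genetic-variant annotation and exclusion cascade for restriction intervals.

A restriction-based methylation screen cannot distinguish a methylation
difference from a genetic difference that changes the digestion pattern: a
SNP that destroys a CCCGGG site, a SNP that creates a new one inside an
interval, or a copy-number difference spanning the interval all mimic a
methylation signal.  This module annotates intervals with those hazards,
runs the two-stage exclusion cascade over a candidate list (SNP flags first,
then CNV/segmental-duplication flags, with an explicit allow-list for
candidates whose methylation variation was independently validated), and
tests whether screen hits are enriched for a hazard class relative to
background.

"Disrupts" is positional: any catalogued SNP falling inside either flanking
CCCGGG motif flags the interval, whether or not the specific alt allele
destroys the motif — the conservative, track-style reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .digest import CUT_OFFSET, MOTIF, MOTIF_LEN

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["interval_id", "disrupts_site", "creates_site", "in_cnv", "in_segdup"]

REGION_CLASSES = ("CNV", "segdup")


@dataclass(frozen=True)
class SequenceVariant:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"only single-nucleotide variants supported: {self}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.contig}:{self.pos}")


@dataclass(frozen=True)
class StructuralRegion:
    contig: str
    start: int
    end: int
    region_class: Literal["CNV", "segdup"]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate region {self.contig}:{self.start}-{self.end}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")


@dataclass
class EnrichmentResult:
    observed_flagged: int
    n_hits: int
    background_flagged: int
    n_background: int
    chi_square: float
    p_value: float


@dataclass
class CascadeResult:
    """Stage-by-stage accounting of the exclusion cascade."""

    n_input: int
    removed_snp: list[str]
    n_after_snp: int
    removed_structural: list[str]
    n_after_structural: int
    rescued: list[str]
    surviving: list[str]

    @property
    def n_final(self) -> int:
        return len(self.surviving)


def empty_annotations(interval_ids: Iterable[str]) -> pd.DataFrame:
    ids = list(interval_ids)
    return pd.DataFrame(
        {
            "interval_id": ids,
            "disrupts_site": False,
            "creates_site": False,
            "in_cnv": False,
            "in_segdup": False,
        }
    )


def _check_variants(
    variants: Sequence[SequenceVariant], genome: Mapping[str, str]
) -> list[SequenceVariant]:
    """Drop (with a logged count) variants whose ref disagrees with the genome."""
    ok, skipped = [], 0
    for v in variants:
        seq = genome.get(v.contig)
        if seq is None or v.pos >= len(seq) or seq[v.pos] != v.ref:
            skipped += 1
            continue
        ok.append(v)
    if skipped:
        logger.warning("skipped %d variants with ref mismatch", skipped)
    return ok


def flag_site_snps(
    intervals: pd.DataFrame,
    variants: Sequence[SequenceVariant],
    genome: Mapping[str, str],
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Set ``disrupts_site`` where a SNP falls inside a flanking CCCGGG motif.

    Each interval runs cut-to-cut, so its flank motifs span
    [start-3, start+3) and [end-3, end+3).  Consecutive intervals share a cut
    site; a SNP in the shared motif flags both.
    """
    ann = annotations if annotations is not None else empty_annotations(intervals["interval_id"])
    ann = ann.set_index("interval_id")
    variants = _check_variants(variants, genome)
    by_contig: dict[str, list[SequenceVariant]] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append(v)
    for row in intervals.itertuples(index=False):
        for v in by_contig.get(row.contig, []):
            in_left = row.start - CUT_OFFSET <= v.pos < row.start + CUT_OFFSET
            in_right = row.end - CUT_OFFSET <= v.pos < row.end + CUT_OFFSET
            if in_left or in_right:
                ann.loc[row.interval_id, "disrupts_site"] = True
                break
    return ann.reset_index()


def variant_creates_motif(variant: SequenceVariant, genome: Mapping[str, str]) -> list[int]:
    """Motif start positions newly created by applying ``variant`` to the genome.

    Only the 11-bp window around the variant can gain a motif; returns starts
    of CCCGGG matches present in the mutated sequence but absent from the
    reference.
    """
    seq = genome[variant.contig]
    lo = max(0, variant.pos - (MOTIF_LEN - 1))
    hi = min(len(seq), variant.pos + MOTIF_LEN)
    window = seq[lo:hi]
    mutated = window[: variant.pos - lo] + variant.alt + window[variant.pos - lo + 1 :]
    created = []
    for i in range(len(window) - MOTIF_LEN + 1):
        if mutated[i : i + MOTIF_LEN] == MOTIF and window[i : i + MOTIF_LEN] != MOTIF:
            created.append(lo + i)
    return created


def flag_creating_snps(
    intervals: pd.DataFrame,
    variants: Sequence[SequenceVariant],
    genome: Mapping[str, str],
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Set ``creates_site`` where a SNP's alt allele creates a CCCGGG motif
    lying entirely inside the interval body [start, end)."""
    ann = annotations if annotations is not None else empty_annotations(intervals["interval_id"])
    ann = ann.set_index("interval_id")
    variants = _check_variants(variants, genome)
    created_by_contig: dict[str, list[int]] = {}
    for v in variants:
        for m in variant_creates_motif(v, genome):
            created_by_contig.setdefault(v.contig, []).append(m)
    for row in intervals.itertuples(index=False):
        for m in created_by_contig.get(row.contig, []):
            if m >= row.start and m + MOTIF_LEN <= row.end:
                ann.loc[row.interval_id, "creates_site"] = True
                break
    return ann.reset_index()


def flag_structural_overlap(
    intervals: pd.DataFrame,
    regions: Sequence[StructuralRegion],
    annotations: pd.DataFrame | None = None,
    containment: Literal["any", "full"] = "any",
) -> pd.DataFrame:
    """Set ``in_cnv`` / ``in_segdup`` for intervals overlapping a region.

    ``containment='any'`` flags any >=1 bp overlap (half-open abutment does
    not overlap); ``'full'`` requires the interval to lie entirely inside a
    single region.
    """
    ann = annotations if annotations is not None else empty_annotations(intervals["interval_id"])
    ann = ann.set_index("interval_id")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for r in regions:
        trees.setdefault((r.contig, r.region_class), IntervalTree()).addi(r.start, r.end)
    for row in intervals.itertuples(index=False):
        for region_class, col in (("CNV", "in_cnv"), ("segdup", "in_segdup")):
            tree = trees.get((row.contig, region_class))
            if tree is None:
                continue
            hits = tree.overlap(row.start, row.end)
            if containment == "full":
                hits = {h for h in hits if h.begin <= row.start and h.end >= row.end}
            if hits:
                ann.loc[row.interval_id, col] = True
    return ann.reset_index()


def filter_candidates(
    candidate_ids: Sequence[str],
    annotations: pd.DataFrame,
    retain_ids: Sequence[str] = (),
) -> CascadeResult:
    """Two-stage exclusion cascade over screen candidates.

    Stage 1 removes candidates whose interval carries a SNP flag (disrupts or
    creates a site); stage 2 removes remaining candidates inside a CNV or
    segmental duplication.  ``retain_ids`` names candidates to re-add at the
    end regardless of flags (loci whose methylation variation was validated
    independently of the flags).  Idempotent on its own output.
    """
    candidates = list(candidate_ids)
    unknown_retain = set(retain_ids) - set(candidates)
    if unknown_retain:
        raise ValueError(f"retain ids not among candidates: {sorted(unknown_retain)}")
    ann = annotations.set_index("interval_id")
    missing = set(candidates) - set(ann.index)
    if missing:
        raise ValueError(f"candidates without annotation: {sorted(missing)[:5]} ...")

    snp_flag = ann["disrupts_site"] | ann["creates_site"]
    struct_flag = ann["in_cnv"] | ann["in_segdup"]

    removed_snp = [c for c in candidates if snp_flag[c]]
    after_snp = [c for c in candidates if not snp_flag[c]]
    removed_struct = [c for c in after_snp if struct_flag[c]]
    after_struct = [c for c in after_snp if not struct_flag[c]]
    rescued = [c for c in retain_ids if c in removed_snp or c in removed_struct]
    surviving = after_struct + [c for c in rescued if c not in after_struct]
    result = CascadeResult(
        n_input=len(candidates),
        removed_snp=removed_snp,
        n_after_snp=len(after_snp),
        removed_structural=removed_struct,
        n_after_structural=len(after_struct),
        rescued=rescued,
        surviving=surviving,
    )
    logger.info(
        "cascade: %d -> %d (SNP) -> %d (CNV/segdup) -> %d (with %d rescued)",
        result.n_input, result.n_after_snp, result.n_after_structural,
        result.n_final, len(rescued),
    )
    return result


def enrichment_test(
    observed_flagged: int,
    n_hits: int,
    background_flagged: int,
    n_background: int,
    correction: bool = False,
) -> EnrichmentResult:
    """Pearson chi-square on the 2x2 hits-vs-background x flagged-vs-not table.

    The background counts are totals for the comparison set (hits are not
    subtracted here; pass disjoint sets if strict disjointness is wanted).
    No continuity correction by default.
    """
    if observed_flagged > n_hits or background_flagged > n_background:
        raise ValueError("flagged count exceeds set size")
    table = np.array(
        [
            [observed_flagged, n_hits - observed_flagged],
            [background_flagged, n_background - background_flagged],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"zero margin in 2x2 table {table.tolist()}")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return EnrichmentResult(
        observed_flagged=observed_flagged,
        n_hits=n_hits,
        background_flagged=background_flagged,
        n_background=n_background,
        chi_square=float(chi2),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# I/O adapters


def read_snv_table(path) -> list[SequenceVariant]:
    """4-column TSV (contig, pos, ref, alt) or VCF (SNV records only)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_vcf_snvs(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["contig", "pos", "ref", "alt"],
                     header=0 if first.startswith("contig") else None)
    return [
        SequenceVariant(str(r.contig), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples(index=False)
    ]


def _read_vcf_snvs(path) -> list[SequenceVariant]:
    out = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alts = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            for alt in alts.split(","):
                if len(ref) == 1 and len(alt) == 1 and alt in "ACGT":
                    out.append(SequenceVariant(chrom, pos - 1, ref, alt))
                else:
                    n_skipped += 1
    if n_skipped:
        logger.info("VCF: skipped %d non-SNV allele records", n_skipped)
    return out


def read_region_bed(path) -> list[StructuralRegion]:
    """BED with a 4th column giving the region class (CNV or segdup)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["contig", "start", "end", "region_class"])
    return [
        StructuralRegion(str(r.contig), int(r.start), int(r.end), str(r.region_class))
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return df
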
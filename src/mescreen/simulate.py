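"""Seeded synthetic-data generators with ground truth for every pipeline stage.

Each generator is a pure function of its config (which carries the seed) and
returns both the data in the exact schema the pipeline consumes and a truth
table sufficient to score downstream calls.  Defaults emulate the study
conditions of the screen they feed:

* genome — a contig with CCCGGG sites planted to realize requested
  restriction-interval lengths, plus too-short and too-long decoys;
* probe arrays — mostly invariant intervals, tissue-specific variation more
  common than systemic, planted systemic loci and SNP/CNV artifact loci,
  lognormal probe noise, ~2.3 probes per interval, dye swap on one tissue;
* cohorts — locus- and individual-level random effects with season
  increments at ME loci only (defaults: 12 percentage points at PAX8 and
  ZFYVE28, 6 at the other three MEs, 0 at controls; n = 25/season over four
  years);
* twin panels — bivariate-normal co-twin values at a configurable
  intra-pair correlation, plus technical replicates;
* genotype panels — 48 Hardy-Weinberg SNPs at MAF 0.3 for MZ (duplicate,
  with optional genotyping-error flips) and unrelated pairs.

Latent methylation states at ME-like loci can be drawn from a beta
distribution to mimic the wide, sometimes U-shaped interindividual ranges
seen at such loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import CONTROL_LOCI, ME_LOCI
from .digest import CUT_OFFSET, MOTIF, MOTIF_LEN

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome generator

@dataclass(frozen=True)
class GenomeConfig:
    seed: int = 0
    n_eligible: int = 100
    n_short_decoys: int = 10
    n_long_decoys: int = 10
    min_len: int = 60
    max_len: int = 1500
    pad: int = 200
    contig_name: str = "chr_sim"


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def _scrub_motifs(seq: np.ndarray, protected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Destroy every CCCGGG occurrence not covered by a protected span.

    Replacing one motif base with A can only remove motifs (CCCGGG contains
    no A), so the loop terminates.
    """
    text = "".join(seq)
    pos = text.find(MOTIF)
    while pos != -1:
        span = np.arange(pos, pos + MOTIF_LEN)
        free = span[~protected[span]]
        if len(free):
            seq[rng.choice(free)] = "A"
            text = "".join(seq)
            pos = text.find(MOTIF, max(pos - MOTIF_LEN, 0))
        else:
            pos = text.find(MOTIF, pos + 1)
    return seq


def gen_genome(config: GenomeConfig = GenomeConfig()) -> tuple[dict, pd.DataFrame]:
    """Genome with planted restriction intervals.

    Returns ``({contig_name: sequence}, truth)`` where truth has one row per
    planted interval (eligible and decoy) with its cut-to-cut coordinates,
    length and eligibility under the configured bounds.
    """
    if config.min_len < MOTIF_LEN:
        raise ValueError("min_len below motif length makes plants overlap")
    rng = np.random.default_rng(config.seed)
    lengths = []
    lengths += list(rng.integers(config.min_len, config.max_len + 1, config.n_eligible))
    if config.n_short_decoys:
        if config.min_len <= MOTIF_LEN:
            raise ValueError("no room for short decoys below min_len")
        lengths += list(rng.integers(MOTIF_LEN, config.min_len, config.n_short_decoys))
    lengths += list(rng.integers(config.max_len + 1, 2 * config.max_len, config.n_long_decoys))
    lengths = [int(x) for x in lengths]
    rng.shuffle(lengths)

    if lengths:
        first_start = config.pad
        starts = np.concatenate([[first_start], first_start + np.cumsum(lengths)])
        total = int(starts[-1]) + MOTIF_LEN + config.pad
    else:
        starts = np.array([], dtype=int)
        total = 2 * config.pad
    seq = _random_sequence(rng, total)
    protected = np.zeros(total, dtype=bool)
    for s in starts:
        seq[s : s + MOTIF_LEN] = list(MOTIF)
        protected[s : s + MOTIF_LEN] = True
    seq = _scrub_motifs(seq, protected, rng)

    rows = []
    for left, length in zip(starts[:-1], lengths):
        start = int(left) + CUT_OFFSET
        end = start + length
        rows.append(
            (
                f"{config.contig_name}:{start}-{end}",
                config.contig_name, start, end, length,
                config.min_len <= length <= config.max_len,
            )
        )
    truth = pd.DataFrame(rows, columns=["interval_id", "contig", "start", "end", "length", "eligible"])
    return {config.contig_name: "".join(seq)}, truth


def write_fasta(genome: dict, path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# probe-array generator

COMPARISONS = ("A", "B", "C", "D")
CLASSES = ("invariant", "tissue_specific", "systemic_ME", "snp_artifact", "cnv_artifact")


@dataclass(frozen=True)
class MsamConfig:
    seed: int = 0
    n_invariant: int = 900
    n_tissue_specific: int = 60
    n_systemic: int = 10
    n_snp_artifact: int = 0
    n_cnv_artifact: int = 0
    mean_probes: float = 2.3  # per interval, minimum 1
    contrast: float = 3.0  # linear interindividual signal ratio at variable loci
    noise_sd: float = 0.15  # per-probe log-ratio noise
    tissues: tuple = ("PBL", "HF")
    dye_swapped_tissue: str = "HF"


def default_design(config: MsamConfig = MsamConfig()) -> pd.DataFrame:
    rows = []
    for comp in COMPARISONS:
        for tissue in config.tissues:
            rows.append(
                (comp, tissue, f"{comp}_1", f"{comp}_2", tissue == config.dye_swapped_tissue)
            )
    return pd.DataFrame(
        rows, columns=["comparison", "tissue", "individual_1", "individual_2", "dye_swapped"]
    )


def gen_msam(config: MsamConfig = MsamConfig()) -> dict:
    """Probe table + design + truth for the two-tissue screen.

    Every variable locus gets one contrasted comparison (random direction);
    systemic and artifact loci show the contrast in both tissues,
    tissue-specific loci in one random tissue only.  Probe ratios are
    lognormal around the latent contrast; the per-probe P comes from a
    two-sample noise model (two-sided normal tail of the observed log ratio
    against the known probe noise), so it is uniform for null probes.
    Probe ratios are emitted in hybridization orientation: the dye-swapped
    tissue's ratios are inverted, to be undone by orientation harmonization.
    """
    rng = np.random.default_rng(config.seed)
    if config.mean_probes < 1:
        raise ValueError("mean_probes must be >= 1")
    counts = {
        "invariant": config.n_invariant,
        "tissue_specific": config.n_tissue_specific,
        "systemic_ME": config.n_systemic,
        "snp_artifact": config.n_snp_artifact,
        "cnv_artifact": config.n_cnv_artifact,
    }
    n_total = sum(counts.values())
    if n_total == 0:
        raise ValueError("no intervals requested")
    classes = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(classes)
    ids = np.array([f"iv{i:05d}" for i in range(n_total)])
    design = default_design(config)

    variable = classes != "invariant"
    systemic_like = np.isin(classes, ("systemic_ME", "snp_artifact", "cnv_artifact"))
    comp = np.where(variable, rng.choice(COMPARISONS, n_total), "")
    direction = np.where(variable, rng.choice([-1.0, 1.0], n_total), 0.0)
    spec_tissue = np.where(classes == "tissue_specific", rng.choice(config.tissues, n_total), "")
    truth = pd.DataFrame(
        {
            "interval_id": ids,
            "planted_class": classes,
            "affected_comparison": comp,
            "true_ratio": np.where(variable, direction * config.contrast, 1.0),
            "affected_tissue": spec_tissue,
        }
    )

    n_probes = 1 + rng.poisson(config.mean_probes - 1.0, n_total)
    iv_idx = np.repeat(np.arange(n_total), n_probes)  # probe -> interval
    n_p = len(iv_idx)
    probe_ids = np.char.add("p", np.arange(1, n_p + 1).astype(str))

    frames = []
    for c in COMPARISONS:
        for tissue in config.tissues:
            active = variable & (comp == c) & (systemic_like | (spec_tissue == tissue))
            lam = np.where(active, direction * np.log(config.contrast), 0.0)[iv_idx]
            log_ratio = lam + rng.normal(0.0, config.noise_sd, n_p)
            p = np.maximum(2.0 * norm.sf(np.abs(log_ratio) / config.noise_sd), 1e-300)
            ratio = np.exp(log_ratio)
            if tissue == config.dye_swapped_tissue:
                ratio = 1.0 / ratio  # hybridization orientation
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probe_ids,
                        "interval_id": ids[iv_idx],
                        "comparison": c,
                        "tissue": tissue,
                        "ratio": ratio,
                        "p_value": p,
                    }
                )
            )
    probes = pd.concat(frames, ignore_index=True)
    return {"probes": probes, "design": design, "truth": truth}


# ---------------------------------------------------------------------------
# cohort generator

def default_me_increments() -> dict:
    return {"BOLA3": 6.0, "FLJ20433": 6.0, "PAX8": 12.0, "SLITRK1": 6.0, "ZFYVE28": 12.0}


@dataclass(frozen=True)
class CohortConfig:
    seed: int = 0
    n_per_season: int = 25
    years: tuple = (1991, 1994, 1995, 1998)
    me_increments: tuple = tuple(sorted(default_me_increments().items()))
    control_loci: tuple = CONTROL_LOCI
    baseline: float = 50.0
    individual_sd: float = 5.0
    locus_sd: float = 8.0
    residual_sd: float = 3.0
    aberrant_year: int | None = None  # season increment reversed in this year
    age_mean: float = 8.9
    age_sd: float = 1.0
    beta_latent: bool = False  # beta-distributed locus baselines (wide/U-shaped)


def gen_cohort(config: CohortConfig = CohortConfig()) -> tuple[pd.DataFrame, dict]:
    """Cohort table + truth for the season-of-conception model.

    Percent methylation = locus baseline + individual effect + season
    increment (rainy only; reversed in the aberrant year if set) + residual,
    clipped to [0, 100] with a logged count.
    """
    for sd in (config.individual_sd, config.locus_sd, config.residual_sd):
        if sd < 0:
            raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(config.seed)
    increments = dict(config.me_increments)
    loci = list(increments) + list(config.control_loci)
    locus_type = {**{l: "ME" for l in increments}, **{l: "control" for l in config.control_loci}}
    increments.update({l: 0.0 for l in config.control_loci})

    if config.beta_latent:
        locus_base = config.baseline + 100.0 * (rng.beta(0.4, 0.4, len(loci)) - 0.5) * (
            config.locus_sd / 25.0
        )
    else:
        locus_base = config.baseline + rng.normal(0.0, config.locus_sd, len(loci))
    locus_base = dict(zip(loci, locus_base))

    rows = []
    n_ind = 2 * config.n_per_season
    seasons = ["dry"] * config.n_per_season + ["rainy"] * config.n_per_season
    years = [config.years[i % len(config.years)] for i in range(config.n_per_season)] * 2
    ind_effects = rng.normal(0.0, config.individual_sd, n_ind)
    ages = rng.normal(config.age_mean, config.age_sd, n_ind)
    n_clipped = 0
    for i in range(n_ind):
        ind = f"G{i + 1:03d}"
        sex = "M" if i % 2 == 0 else "F"
        for locus in loci:
            inc = increments[locus]
            if config.aberrant_year is not None and years[i] == config.aberrant_year:
                inc = -inc
            value = (
                locus_base[locus]
                + ind_effects[i]
                + (inc if seasons[i] == "rainy" else 0.0)
                + rng.normal(0.0, config.residual_sd)
            )
            clipped = min(max(value, 0.0), 100.0)
            n_clipped += clipped != value
            rows.append(
                (ind, sex, years[i], seasons[i], round(float(ages[i]), 1),
                 locus, locus_type[locus], clipped)
            )
    if n_clipped:
        logger.warning("gen_cohort: clipped %d values to [0, 100]", n_clipped)
        if n_clipped > 0.01 * len(rows):
            logger.warning("gen_cohort: >1%% of values clipped; check variance settings")
    records = pd.DataFrame(
        rows, columns=["individual", "sex", "year", "season", "age", "locus", "locus_type", "percent"]
    )
    truth = {
        "increments": increments,
        "locus_type": locus_type,
        "locus_baselines": locus_base,
        "individual_sd": config.individual_sd,
        "locus_sd": config.locus_sd,
        "residual_sd": config.residual_sd,
        "n_clipped": int(n_clipped),
        "aberrant_year": config.aberrant_year,
    }
    return records, truth


# ---------------------------------------------------------------------------
# twin generator

@dataclass(frozen=True)
class TwinsConfig:
    seed: int = 0
    n_pairs: int = 23
    intra_pair_r: tuple = (("BOLA3", 0.0), ("FLJ20433", 0.0), ("PAX8", 0.5))
    biological_mean: float = 50.0
    biological_sd: float = 10.0
    technical_sd: float = 2.0
    population: str = "Malawian"


def gen_twins(config: TwinsConfig = TwinsConfig()) -> dict:
    """Twin-pair and technical-replicate methylation tables, with truth.

    Co-twin latent values are bivariate normal at the configured intra-pair
    correlation per locus; every individual is measured twice with
    independent technical noise.  ``pair_measurements`` carries the
    replicate average per individual; ``replicate_measurements`` the two
    raw replicates (for the technical-floor correlation).
    """
    corr = dict(config.intra_pair_r)
    for locus, r in corr.items():
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"intra-pair correlation at {locus} outside [-1, 1]")
    rng = np.random.default_rng(config.seed)
    pair_rows, rep_rows = [], []
    for locus, r in corr.items():
        cov = np.array([[1.0, r], [r, 1.0]]) * config.biological_sd**2
        latent = rng.multivariate_normal([config.biological_mean] * 2, cov, size=config.n_pairs)
        latent = np.clip(latent, 0.0, 100.0)
        for i in range(config.n_pairs):
            pid = f"T{i + 1:03d}"
            for member in (1, 2):
                sid = f"{pid}_{member}"
                reps = np.clip(
                    latent[i, member - 1] + rng.normal(0.0, config.technical_sd, 2), 0.0, 100.0
                )
                for j, v in enumerate(reps, start=1):
                    rep_rows.append((sid, config.population, "buccal", locus, j, float(v)))
                pair_rows.append((pid, sid, locus, float(reps.mean())))
    pair_measurements = pd.DataFrame(pair_rows, columns=["pair_id", "sample_id", "locus", "percent"])
    replicate_measurements = pd.DataFrame(
        rep_rows, columns=["sample_id", "population", "tissue", "locus", "replicate", "percent"]
    )
    truth = {
        "intra_pair_r": corr,
        "biological_sd": config.biological_sd,
        "technical_sd": config.technical_sd,
    }
    return {
        "pair_measurements": pair_measurements,
        "replicate_measurements": replicate_measurements,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# genotype-panel generator

@dataclass(frozen=True)
class GenotypeConfig:
    seed: int = 0
    n_markers: int = 48
    maf: float = 0.3
    n_mz_pairs: int = 5
    n_unrelated_pairs: int = 5
    error_rate: float = 0.0


def _hwe_genotypes(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    return rng.binomial(1, freqs, (n, len(freqs))) + rng.binomial(1, freqs, (n, len(freqs)))


def gen_genotype_panel(config: GenotypeConfig = GenotypeConfig()) -> dict:
    """SNP-panel genotypes for MZ and unrelated pairs, with allele frequencies.

    Genotypes are 0/1/2 B-allele counts under Hardy-Weinberg at the panel
    MAF.  MZ co-twins duplicate each other; with a nonzero error rate each
    duplicated genotype is independently flipped to one of the other two
    genotypes (uniformly), so the expected number of discordant markers per
    pair is n_markers * error_rate.
    """
    if not 0.0 < config.maf < 1.0:
        raise ValueError("MAF must be in (0, 1)")
    rng = np.random.default_rng(config.seed)
    freqs = np.full(config.n_markers, config.maf)
    rows, truth_rows = [], []
    pairs = [("MZ", i) for i in range(config.n_mz_pairs)] + [
        ("unrelated", i) for i in range(config.n_unrelated_pairs)
    ]
    genotypes = {}
    for rel, i in pairs:
        pid = f"{rel}{i + 1:03d}"
        g1 = _hwe_genotypes(rng, freqs, 1)[0]
        if rel == "MZ":
            g2 = g1.copy()
            if config.error_rate > 0:
                flip = rng.random(config.n_markers) < config.error_rate
                shift = rng.integers(1, 3, config.n_markers)
                g2[flip] = (g2[flip] + shift[flip]) % 3
        else:
            g2 = _hwe_genotypes(rng, freqs, 1)[0]
        genotypes[pid] = (g1, g2)
        truth_rows.append((pid, rel))
        for member, g in ((1, g1), (2, g2)):
            for m in range(config.n_markers):
                rows.append((pid, member, f"snp{m + 1:03d}", ["AA", "AB", "BB"][g[m]]))
    genotype_table = pd.DataFrame(rows, columns=["pair_id", "member", "snp_id", "genotype"])
    freq_table = pd.DataFrame(
        {"snp_id": [f"snp{m + 1:03d}" for m in range(config.n_markers)], "freq_b": freqs}
    )
    truth = pd.DataFrame(truth_rows, columns=["pair_id", "relationship"])
    return {
        "genotypes": genotype_table,
        "pairs": genotypes,
        "allele_freqs": freq_table,
        "truth": truth,
    }
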
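"""Validation statistics on bisulfite-pyrosequencing percent-methylation data.

Covers the downstream checks applied to candidate loci once probe-level
screening is done: linearity of each pyrosequencing assay against mixing
standards, inter-tissue correlation of interindividual variation (the
signature of a systemic locus), monozygotic-twin concordance versus
technical replication error, association of methylation with a nearby
genotype (the genetic-confounding check), and cross-population range
comparison.

Replicate measurements are averaged per individual before any correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["sample_id", "population", "tissue", "locus", "replicate", "percent"]


@dataclass
class LinearityFit:
    slope: float
    intercept: float
    r: float
    n: int


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass
class TwinConcordance:
    intra_pair_r: float
    intra_pair_p: float
    n_pairs: int
    technical_r: float
    n_replicate_pairs: int
    nonshared_fraction: float


@dataclass
class GenotypeAssociation:
    group_means: dict
    group_sizes: dict
    f_statistic: float
    p_value: float
    r_squared: float


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    bad = (df["percent"] < 0) | (df["percent"] > 100)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} percent-methylation values outside [0, 100]")
    return df


def assay_linearity(standards: pd.DataFrame) -> LinearityFit:
    """Least-squares line of measured percent on expected methylated fraction.

    ``standards`` needs columns ``expected_fraction`` (0-1) and
    ``measured_percent`` (0-100); >=3 distinct expected fractions required.
    A perfectly quantitative assay gives slope 100, intercept 0, r = 1.
    """
    x = standards["expected_fraction"].to_numpy(dtype=float)
    y = standards["measured_percent"].to_numpy(dtype=float)
    if (x < 0).any() or (x > 1).any():
        raise ValueError("expected_fraction outside [0, 1]")
    if len(np.unique(x)) < 3:
        raise ValueError("need >=3 distinct expected fractions")
    if np.allclose(y, y[0]):
        # zero-variance response: degenerate flat line, r undefined -> 0
        return LinearityFit(slope=0.0, intercept=float(y[0]), r=0.0, n=len(x))
    fit = sps.linregress(x, y)
    return LinearityFit(slope=float(fit.slope), intercept=float(fit.intercept),
                        r=float(fit.rvalue), n=len(x))


def _individual_means(measurements: pd.DataFrame, locus: str, tissue: str) -> pd.Series:
    sub = measurements[(measurements["locus"] == locus) & (measurements["tissue"] == tissue)]
    return sub.groupby("sample_id")["percent"].mean()


def inter_tissue_correlation(
    measurements: pd.DataFrame, locus: str, tissue_pair: tuple[str, str]
) -> CorrelationResult:
    """Pearson r of individual mean methylation between two tissues.

    Requires >=3 individuals measured in both tissues.  Zero variance in
    either tissue leaves r undefined; the result is flagged degenerate.
    """
    validate_measurements(measurements)
    a = _individual_means(measurements, locus, tissue_pair[0])
    b = _individual_means(measurements, locus, tissue_pair[1])
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(
            f"need >=3 individuals in both tissues for {locus}, have {len(common)}"
        )
    x, y = a[common].to_numpy(), b[common].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("inter_tissue_correlation: zero variance at %s", locus)
        return CorrelationResult(r=float("nan"), p_value=float("nan"),
                                 n=len(common), degenerate=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=len(common))


def twin_concordance(
    pair_measurements: pd.DataFrame,
    replicate_measurements: pd.DataFrame,
    locus: str,
    seed: int = 0,
    double_entry: bool = False,
) -> TwinConcordance:
    """Intra-pair correlation vs technical-replicate correlation at one locus.

    ``pair_measurements`` columns: pair_id, sample_id, locus, percent
    (replicates already averaged per individual, or multiple rows per
    sample_id which are averaged here).  Pairs without exactly 2 members are
    excluded and logged.  Member order within a pair is arbitrary, so it is
    randomized under ``seed`` before the Pearson correlation (or both orders
    are entered when ``double_entry``).

    ``replicate_measurements`` columns: sample_id, locus, replicate, percent
    with exactly 2 replicates per sample; their correlation estimates the
    technical measurement floor.

    ``nonshared_fraction`` = 1 - clip(intra-pair r, 0, 1): the share of
    interindividual variance not shared by co-twins under this definition.
    """
    sub = pair_measurements[pair_measurements["locus"] == locus]
    member_means = sub.groupby(["pair_id", "sample_id"])["percent"].mean().reset_index()
    counts = member_means.groupby("pair_id").size()
    bad_pairs = counts[counts != 2].index
    for pid in bad_pairs:
        logger.warning("twin_concordance: pair %s has %d members, excluded", pid, counts[pid])
    member_means = member_means[~member_means["pair_id"].isin(bad_pairs)]
    pairs = member_means.groupby("pair_id")["percent"].agg(list)
    if len(pairs) < 3:
        raise ValueError(f"need >=3 complete twin pairs at {locus}, have {len(pairs)}")
    arr = np.array(pairs.tolist(), dtype=float)
    if double_entry:
        x = np.concatenate([arr[:, 0], arr[:, 1]])
        y = np.concatenate([arr[:, 1], arr[:, 0]])
    else:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(arr)) < 0.5
        x = np.where(flip, arr[:, 1], arr[:, 0])
        y = np.where(flip, arr[:, 0], arr[:, 1])
    r_twin, p_twin = sps.pearsonr(x, y)

    rep = replicate_measurements[replicate_measurements["locus"] == locus]
    rep_wide = rep.pivot_table(index="sample_id", columns="replicate", values="percent")
    rep_wide = rep_wide.dropna()
    if rep_wide.shape[1] != 2 or len(rep_wide) < 3:
        raise ValueError("need >=3 samples with exactly 2 replicates")
    r_tech, _ = sps.pearsonr(rep_wide.iloc[:, 0], rep_wide.iloc[:, 1])

    nonshared = float(1.0 - np.clip(r_twin, 0.0, 1.0))
    return TwinConcordance(
        intra_pair_r=float(r_twin), intra_pair_p=float(p_twin), n_pairs=len(arr),
        technical_r=float(r_tech), n_replicate_pairs=len(rep_wide),
        nonshared_fraction=nonshared,
    )


def genotype_association(
    measurements: pd.DataFrame, genotypes: pd.DataFrame, locus: str, snp_id: str
) -> GenotypeAssociation:
    """Per-genotype methylation means with one-way ANOVA F, P and R^2.

    ``genotypes`` columns: sample_id, snp_id, genotype.  Requires >=2
    genotype groups with >=2 samples each.  R^2 is the between-group share
    of the total sum of squares — the fraction of interindividual variation
    explained by the genotype.
    """
    validate_measurements(measurements)
    meth = measurements[measurements["locus"] == locus].groupby("sample_id")["percent"].mean()
    geno = genotypes[genotypes["snp_id"] == snp_id].set_index("sample_id")["genotype"]
    joined = pd.DataFrame({"percent": meth, "genotype": geno}).dropna()
    groups = {g: sub["percent"].to_numpy() for g, sub in joined.groupby("genotype")}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >=2 genotype groups with >=2 samples")
    values = list(groups.values())
    f, p = sps.f_oneway(*values)
    allv = np.concatenate(values)
    ss_total = float(((allv - allv.mean()) ** 2).sum())
    ss_between = float(sum(len(v) * (v.mean() - allv.mean()) ** 2 for v in values))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return GenotypeAssociation(
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_sizes={g: len(v) for g, v in groups.items()},
        f_statistic=float(f), p_value=float(p), r_squared=r2,
    )


def population_compare(measurements: pd.DataFrame, locus: str) -> pd.DataFrame:
    """Box-plot summary per population: median, quartiles, 5th/95th percentiles."""
    validate_measurements(measurements)
    sub = measurements[measurements["locus"] == locus]
    means = sub.groupby(["population", "sample_id"])["percent"].mean().reset_index()
    rows = []
    for pop, g in means.groupby("population"):
        q = np.percentile(g["percent"], [5, 25, 50, 75, 95])
        rows.append((pop, len(g), *q))
    return pd.DataFrame(
        rows, columns=["population", "n", "p5", "q1", "median", "q3", "p95"]
    )
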
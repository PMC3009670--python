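"""Two-tissue candidate calling from two-channel probe signals.

The screen cohybridizes amplified methylated fragments from two individuals
on one array, in two tissues from different germ layers (peripheral blood
leukocytes, PBL, and hair follicles, HF), for four individual pairs
(comparisons A-D).  A locus whose methylation state was set before
gastrulation varies *systemically*: the same interindividual contrast shows
up in both tissues.  Calling proceeds in two stages:

1. primary hits — intervals whose probe-average signal ratio is extreme
   (> ratio_hi or < ratio_lo) with median probe P below p_max in *both*
   tissues of some comparison, on the same side of 1;
2. concordance filter — for every comparison, the PBL:HF ratio of the two
   tissue signal ratios must stay close to 1 (strictly inside
   (rr_lo, rr_hi)), eliminating tissue-specific contrasts.

The ratio-of-ratios is rounded to 3 significant figures before the strict
bound comparison, so that the bound's defining configuration (1.5 in one
tissue vs 0.667 in the other, i.e. 2.25) is itself excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ["probe_id", "interval_id", "comparison", "tissue", "ratio", "p_value"]
DESIGN_COLUMNS = ["comparison", "tissue", "individual_1", "individual_2", "dye_swapped"]
STAT_COLUMNS = [
    "interval_id", "comparison", "tissue",
    "mean_ratio", "median_ratio", "median_p", "n_probes",
]

TISSUE_PAIR = ("PBL", "HF")


@dataclass(frozen=True)
class ScreenConfig:
    """Selection thresholds; all comparisons are strict, as printed."""

    ratio_hi: float = 1.8
    ratio_lo: float = 0.556
    p_max: float = 0.0002
    rr_hi: float = 2.25
    rr_lo: float = 0.445
    mean_mode: str = "arithmetic"  # or "geometric"

    def __post_init__(self) -> None:
        if not (self.ratio_lo < 1 < self.ratio_hi):
            raise ValueError("need ratio_lo < 1 < ratio_hi")
        if not (self.rr_lo < 1 < self.rr_hi):
            raise ValueError("need rr_lo < 1 < rr_hi")
        if self.mean_mode not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown mean_mode {self.mean_mode!r}")


def round_sig(x, digits: int = 3):
    """Round to ``digits`` significant figures (vectorized)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        mag = np.where(x == 0, 0, np.floor(np.log10(np.abs(np.where(x == 0, 1, x)))))
    factor = 10.0 ** (digits - 1 - mag)
    return np.round(x * factor) / factor


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design missing columns {sorted(missing)}")
    dup = design.duplicated(subset=["comparison", "tissue"])
    if dup.any():
        raise ValueError("design has duplicate comparison x tissue rows")
    # parallel design: the same individual pair in every tissue of a comparison
    pairs = design.groupby("comparison")[["individual_1", "individual_2"]].nunique()
    if (pairs > 1).any().any():
        raise ValueError("comparison uses different individual pairs across tissues")
    return design


def orient_ratios(probes: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Express every probe ratio as individual_1/individual_2.

    Dye-swapped hybridizations carry the reciprocal orientation and are
    inverted; applying twice returns the input.
    """
    validate_design(design)
    merged = probes.merge(
        design[["comparison", "tissue", "dye_swapped"]],
        on=["comparison", "tissue"], how="left", indicator=True,
    )
    unknown = merged["_merge"] == "left_only"
    if unknown.any():
        bad = merged.loc[unknown, ["comparison", "tissue"]].drop_duplicates()
        raise ValueError(f"probes reference unknown hybridizations:\n{bad}")
    out = probes.copy()
    swap = merged["dye_swapped"].astype(bool).to_numpy()
    out["ratio"] = np.where(swap, 1.0 / probes["ratio"].to_numpy(), probes["ratio"].to_numpy())
    return out


def summarize_intervals(probes: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Per interval x comparison x tissue: mean/median ratio, median P, n probes.

    The probe-average ratio is the arithmetic mean of linear per-probe ratios
    (geometric selectable); the median of an even number of P values is the
    mean of the central two.
    """
    config = config or ScreenConfig()
    if probes.empty:
        return pd.DataFrame(columns=STAT_COLUMNS)
    if (probes["ratio"] <= 0).any():
        raise ValueError("probe ratios must be positive")
    grouped = probes.groupby(["interval_id", "comparison", "tissue"], sort=True)
    if config.mean_mode == "arithmetic":
        mean_ratio = grouped["ratio"].mean()
    else:
        mean_ratio = np.exp(grouped["ratio"].apply(lambda r: np.log(r).mean()))
    stats = pd.DataFrame(
        {
            "mean_ratio": mean_ratio,
            "median_ratio": grouped["ratio"].median(),
            "median_p": grouped["p_value"].median(),
            "n_probes": grouped.size(),
        }
    ).reset_index()
    return stats[STAT_COLUMNS]


def _tissue_pivot(stats: pd.DataFrame, column: str, tissue_pair=TISSUE_PAIR) -> pd.DataFrame:
    wide = stats.pivot_table(
        index=["interval_id", "comparison"], columns="tissue", values=column, aggfunc="first"
    )
    for t in tissue_pair:
        if t not in wide.columns:
            wide[t] = np.nan
    return wide[list(tissue_pair)]


def call_primary_hits(
    stats: pd.DataFrame, config: ScreenConfig | None = None, tissue_pair=TISSUE_PAIR
) -> pd.DataFrame:
    """Intervals extreme and significant in both tissues of a comparison.

    Requires the same side of 1 in both tissues (directional concordance);
    intervals with a missing tissue are not callable and are logged.
    Returns columns ``interval_id comparison direction``.
    """
    config = config or ScreenConfig()
    ratios = _tissue_pivot(stats, "mean_ratio", tissue_pair)
    ps = _tissue_pivot(stats, "median_p", tissue_pair)
    t1, t2 = tissue_pair
    complete = ratios[t1].notna() & ratios[t2].notna()
    n_incomplete = int((~complete).sum())
    if n_incomplete:
        logger.info("primary hits: %d interval x comparison cells missing a tissue", n_incomplete)
    up = (ratios[t1] > config.ratio_hi) & (ratios[t2] > config.ratio_hi)
    down = (ratios[t1] < config.ratio_lo) & (ratios[t2] < config.ratio_lo)
    sig = (ps[t1] < config.p_max) & (ps[t2] < config.p_max)
    hit = complete & sig & (up | down)
    out = ratios.index[hit].to_frame(index=False)
    out["direction"] = np.where(up[hit].to_numpy(), "up", "down")
    return out.reset_index(drop=True)


COMPARISONS = ("A", "B", "C", "D")


def concordance_filter(
    hits: pd.DataFrame,
    stats: pd.DataFrame,
    config: ScreenConfig | None = None,
    tissue_pair=TISSUE_PAIR,
    comparisons=COMPARISONS,
) -> pd.DataFrame:
    """Retain hits whose PBL:HF ratio-of-ratios is near 1 in EVERY comparison.

    A hit interval must have both tissues measured in all comparisons present
    in ``stats``; the ratio-of-ratios, rounded to 3 significant figures, must
    lie strictly inside (rr_lo, rr_hi).  Returns one row per surviving
    interval with its triggering comparisons, direction and per-comparison
    ratio-of-ratios.
    """
    config = config or ScreenConfig()
    if hits.empty:
        return pd.DataFrame(columns=["interval_id", "triggering_comparison", "direction"])
    t1, t2 = tissue_pair
    ratios = _tissue_pivot(stats, "mean_ratio", tissue_pair)
    rr = (ratios[t1] / ratios[t2]).unstack("comparison")
    comparisons = list(comparisons)
    rr = rr.reindex(columns=comparisons)  # absent comparisons -> NaN -> dropped
    rr_rounded = pd.DataFrame(round_sig(rr.to_numpy(), 3), index=rr.index, columns=rr.columns)
    ok = (
        rr_rounded.notna().all(axis=1)
        & (rr_rounded > config.rr_lo).all(axis=1)
        & (rr_rounded < config.rr_hi).all(axis=1)
    )
    dropped = hits.loc[~hits["interval_id"].map(ok).fillna(False).astype(bool), "interval_id"]
    for iid in dropped.unique():
        logger.info("concordance filter: dropped %s", iid)
    surviving = hits[hits["interval_id"].map(ok).fillna(False).astype(bool)]
    calls = (
        surviving.groupby("interval_id")
        .agg(
            triggering_comparison=("comparison", lambda c: ",".join(sorted(set(c)))),
            direction=("direction", lambda d: ",".join(sorted(set(d)))),
        )
        .reset_index()
    )
    for comp in comparisons:
        calls[f"rr_{comp}"] = calls["interval_id"].map(rr_rounded[comp])
    return calls


def variability_summary(
    stats: pd.DataFrame, config: ScreenConfig | None = None, tissue_pair=TISSUE_PAIR
) -> pd.DataFrame:
    """Counts of intervals by where they show interindividual variation.

    An interval "varies" in a tissue if any comparison passes the
    single-tissue thresholds (extreme mean ratio and median P < p_max) there.
    Classes: invariant, <tissue>_only (tissue-specific), both_tissues.
    """
    config = config or ScreenConfig()
    extreme = (
        ((stats["mean_ratio"] > config.ratio_hi) | (stats["mean_ratio"] < config.ratio_lo))
        & (stats["median_p"] < config.p_max)
    )
    var_by_tissue = (
        stats.assign(variable=extreme)
        .groupby(["interval_id", "tissue"])["variable"]
        .any()
        .unstack("tissue")
    )
    t1, t2 = tissue_pair
    for t in tissue_pair:
        if t not in var_by_tissue.columns:
            var_by_tissue[t] = False
    v1 = var_by_tissue[t1].fillna(False)
    v2 = var_by_tissue[t2].fillna(False)
    counts = {
        "invariant": int((~v1 & ~v2).sum()),
        f"{t1}_only": int((v1 & ~v2).sum()),
        f"{t2}_only": int((~v1 & v2).sum()),
        "both_tissues": int((v1 & v2).sum()),
    }
    return pd.DataFrame(sorted(counts.items()), columns=["class", "n_intervals"])


def run_screen(
    probes: pd.DataFrame,
    design: pd.DataFrame,
    config: ScreenConfig | None = None,
    tissue_pair=TISSUE_PAIR,
) -> dict:
    """Full screen: orient, summarize, call, concordance-filter, summarize.

    Returns a dict with ``candidates`` (final calls), ``primary_hits``,
    ``stats`` (per interval x comparison x tissue) and ``summary``
    (variability class counts).  Deterministic and invariant to probe-row
    order.
    """
    config = config or ScreenConfig()
    missing = set(PROBE_COLUMNS) - set(probes.columns)
    if missing:
        raise ValueError(f"probe table missing columns {sorted(missing)}")
    oriented = orient_ratios(probes, design)
    stats = summarize_intervals(oriented, config)
    hits = call_primary_hits(stats, config, tissue_pair)
    candidates = concordance_filter(
        hits, stats, config, tissue_pair, comparisons=tuple(sorted(design["comparison"].unique()))
    )
    summary = variability_summary(stats, config, tissue_pair)
    logger.info(
        "screen: %d intervals, %d primary hits, %d candidates",
        stats["interval_id"].nunique(), hits["interval_id"].nunique(), len(candidates),
    )
    return {"candidates": candidates, "primary_hits": hits, "stats": stats, "summary": summary}


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing probe columns {sorted(missing)}")
    return df


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["dye_swapped"] = df["dye_swapped"].astype(bool)
    return validate_design(df)
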
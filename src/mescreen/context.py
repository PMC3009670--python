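"""Genomic-context profiling around candidate intervals.

Murine metastable epialleles are typically associated with nearby
retrotransposons, so a natural question about candidate loci is whether any
annotation class — CpG islands (CGI) or repeat families — sits at a biased
position around them relative to control intervals.  Profiles record the
signed distance from each interval's midpoint to the midpoint of every
annotation within a +/-window (default 3000 bp); negative distances are
upstream in coordinate terms (intervals are unstranded).  Distributional
differences between the candidate and control sets are tested by one-way
ANOVA on the signed distances, with a binomial upstream/downstream split as
a secondary statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("CGI", "SINE", "Alu", "LINE", "LTR", "simple_repeat", "low_complexity")

ANNOTATION_COLUMNS = ["contig", "start", "end", "feature_class"]
PROFILE_COLUMNS = ["interval_id", "set_label", "feature_class", "signed_distance", "window"]


@dataclass
class SetComparison:
    feature_class: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    mean_distance_me: float
    mean_distance_control: float
    updown_me: tuple[int, int]  # (upstream, downstream) counts
    updown_control: tuple[int, int]
    binomial_p_me: float
    binomial_p_control: float


def _midpoints(df: pd.DataFrame) -> np.ndarray:
    return (df["start"].to_numpy() + df["end"].to_numpy()) // 2


def distance_profile(
    intervals: pd.DataFrame,
    annotations: pd.DataFrame,
    window: int = 3000,
    set_label: str = "ME",
    mode: Literal["midpoint", "edge"] = "midpoint",
) -> pd.DataFrame:
    """One record per (interval, annotation-in-window) pair.

    ``mode='midpoint'`` measures midpoint-to-midpoint; ``'edge'`` measures
    midpoint to the nearest annotation edge (0 if the midpoint falls inside
    the annotation).  Records with |distance| <= window are kept.
    """
    missing = set(ANNOTATION_COLUMNS) - set(annotations.columns)
    if missing:
        raise ValueError(f"annotations missing columns {sorted(missing)}")
    records = []
    for contig, ivs in intervals.groupby("contig", sort=False):
        anns = annotations[annotations["contig"] == contig]
        if anns.empty:
            continue
        iv_mid = _midpoints(ivs)
        if mode == "midpoint":
            ann_pos = _midpoints(anns)
            dist = ann_pos[None, :] - iv_mid[:, None]
        else:
            starts = anns["start"].to_numpy()[None, :]
            ends = anns["end"].to_numpy()[None, :] - 1
            mid = iv_mid[:, None]
            left = starts - mid   # >0 when annotation entirely downstream
            right = ends - mid    # <0 when annotation entirely upstream
            dist = np.where(left > 0, left, np.where(right < 0, right, 0))
        keep_i, keep_j = np.nonzero(np.abs(dist) <= window)
        ids = ivs["interval_id"].to_numpy()
        classes = anns["feature_class"].to_numpy()
        for i, j in zip(keep_i, keep_j):
            records.append((ids[i], set_label, classes[j], int(dist[i, j]), window))
    return pd.DataFrame(records, columns=PROFILE_COLUMNS)


def compare_sets(
    me_profiles: pd.DataFrame, control_profiles: pd.DataFrame, feature_class: str
) -> SetComparison:
    """One-way ANOVA of signed distance with set (candidate vs control) as factor."""
    me = me_profiles.loc[me_profiles["feature_class"] == feature_class, "signed_distance"]
    ctrl = control_profiles.loc[
        control_profiles["feature_class"] == feature_class, "signed_distance"
    ]
    for name, values in (("ME", me), ("control", ctrl)):
        if len(values) < 2:
            raise ValueError(f"set {name!r} has <2 records for class {feature_class!r}")
    f, p = sps.f_oneway(me, ctrl)

    def updown(v):
        return int((v < 0).sum()), int((v > 0).sum())

    def binom_p(ud):
        n = ud[0] + ud[1]
        return float(sps.binomtest(ud[1], n, 0.5).pvalue) if n else 1.0

    ud_me, ud_ctrl = updown(me), updown(ctrl)
    return SetComparison(
        feature_class=feature_class,
        f_statistic=float(f),
        df_between=1,
        df_within=len(me) + len(ctrl) - 2,
        p_value=float(p),
        mean_distance_me=float(me.mean()),
        mean_distance_control=float(ctrl.mean()),
        updown_me=ud_me,
        updown_control=ud_ctrl,
        binomial_p_me=binom_p(ud_me),
        binomial_p_control=binom_p(ud_ctrl),
    )


def cgi_feature_compare(
    me_cgis: pd.DataFrame, control_cgis: pd.DataFrame,
    attributes: tuple[str, ...] = ("length", "signed_distance", "percent_gc"),
) -> pd.DataFrame:
    """Per-attribute one-way ANOVA between candidate- and control-associated CGIs.

    ``length`` is derived from start/end when absent.  Attributes missing
    from either table are skipped with a warning.  Returns a table of group
    means, F and P per attribute.
    """
    rows = []
    for attr in attributes:
        me, ctrl = me_cgis.copy(), control_cgis.copy()
        for df in (me, ctrl):
            if attr == "length" and "length" not in df.columns and {"start", "end"} <= set(df.columns):
                df["length"] = df["end"] - df["start"]
        if attr not in me.columns or attr not in ctrl.columns:
            logger.warning("cgi_feature_compare: attribute %r missing, skipped", attr)
            continue
        a, b = me[attr].dropna(), ctrl[attr].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"attribute {attr!r}: need >=2 values per group")
        f, p = sps.f_oneway(a, b)
        rows.append((attr, float(a.mean()), float(b.mean()), float(f), float(p)))
    return pd.DataFrame(rows, columns=["attribute", "mean_me", "mean_control", "F", "p_value"])


def read_annotation_bed(path) -> pd.DataFrame:
    """BED-like TSV: contig, start, end, feature_class[, percent_gc]."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = ANNOTATION_COLUMNS + (["percent_gc"] if df.shape[1] == 5 else [])[: df.shape[1] - 4]
    unknown = set(df["feature_class"]) - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"{path}: unknown feature classes {sorted(unknown)}")
    return df
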
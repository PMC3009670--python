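"""Season-of-conception cohort analysis and twin-panel kinship estimation.

The cohort design compares percent methylation (averaged over replicate
measurements) between children conceived in the rainy vs the dry season,
at candidate metastable-epiallele (ME) loci and at control loci, with
repeated measures per individual across loci.  The model is a REML
variance-components ANOVA on arcsine-transformed methylation:

    arcsin(sqrt(p)) ~ locus_type + season:locus_type
                      + (1 | individual) + (1 | locus in locus_type)

Random intercepts absorb individual-level and locus-level baseline
differences; the a-priori question is the season effect within each locus
type, reported both on the transformed scale and back-transformed to
percentage points.  Supporting screens: per-group Shapiro-Wilk normality
with Holm (sequential Bonferroni) correction, and a season x year
interaction screen with leave-one-year-out diagnostics to spot years where
seasonality behaved aberrantly.

Twin-cohort zygosity is verified from a small SNP panel by a
method-of-moments IBD estimator: expected identity-by-state (IBS) counts
given 0/1/2 alleles shared identical-by-descent follow from Hardy-Weinberg
allele frequencies; constrained least squares recovers (p0, p1, p2) on the
probability simplex and the kinship coefficient is phi = p1/4 + p2/2
(0.5 for true MZ twins, 0 for unrelated pairs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ME_LOCI = ("BOLA3", "FLJ20433", "PAX8", "SLITRK1", "ZFYVE28")
CONTROL_LOCI = ("LINE1", "IGF2", "GNASAS", "IL10")
SEASONS = ("dry", "rainy")

COHORT_COLUMNS = [
    "individual", "sex", "year", "season", "age", "locus", "locus_type", "percent",
]

#: REML convergence tolerance on the restricted log-likelihood
REML_TOL = 1e-8


# ---------------------------------------------------------------------------
# transform

def arcsine_transform(percent):
    """Variance-stabilizing arcsin(sqrt(p/100)), radians in [0, pi/2]."""
    p = np.asarray(percent, dtype=float)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percent methylation outside [0, 100]")
    out = np.arcsin(np.sqrt(p / 100.0))
    return float(out) if np.isscalar(percent) else out


def inverse_arcsine(value):
    """Back-transform radians to percent: 100 * sin(t)^2."""
    t = np.asarray(value, dtype=float)
    out = 100.0 * np.sin(t) ** 2
    return float(out) if np.isscalar(value) else out


# ---------------------------------------------------------------------------
# normality screen

def normality_screen(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk per locus x season group with Holm step-down correction.

    Groups with fewer than 3 observations are skipped with a warning.
    Returns a table with W, raw P, Holm-adjusted P and family-level
    rejection flags at ``alpha``.
    """
    rows = []
    for (locus, season), g in records.groupby(["locus", "season"]):
        if len(g) < 3:
            logger.warning("normality_screen: %s/%s has n=%d < 3, skipped", locus, season, len(g))
            continue
        w, p = sps.shapiro(arcsine_transform(g["percent"].to_numpy()))
        rows.append((locus, season, len(g), float(w), float(p)))
    out = pd.DataFrame(rows, columns=["locus", "season", "n", "W", "p_value"])
    if len(out):
        reject, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha, method="holm")
        out["p_holm"] = p_adj
        out["reject"] = reject
    return out


# ---------------------------------------------------------------------------
# season mixed model

@dataclass
class SeasonModelFit:
    variance_components: dict  # individual, locus, residual (variances, transformed scale)
    season_effect: dict        # locus_type -> effect on arcsine scale (rainy - dry)
    season_effect_percent: dict  # locus_type -> back-transformed, percentage points
    season_p: dict             # locus_type -> within-type Wald P
    overall_season_p: float    # joint test: any season effect (2 df)
    season_by_type_p: float    # a-priori interaction: effects differ between types
    per_locus: pd.DataFrame    # descriptive per-locus season effects
    n_obs: int
    converged: bool
    season_by_year_p: float | None = None


def _validate_cohort(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    bad_season = set(records["season"]) - set(SEASONS)
    if bad_season:
        raise ValueError(f"unknown seasons {sorted(bad_season)}")
    per_locus_types = records.groupby("locus")["locus_type"].nunique()
    if (per_locus_types > 1).any():
        raise ValueError("locus_type must be constant per locus")
    return records


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = _validate_cohort(records).copy()
    df["y"] = arcsine_transform(df["percent"].to_numpy())
    df["season_rainy"] = (df["season"] == "rainy").astype(float)
    return df


def _fit_mixedlm(df: pd.DataFrame, formula: str):
    model = smf.mixedlm(
        formula, df, groups=np.ones(len(df)), re_formula="0",
        vc_formula={"individual": "0 + C(individual)", "locus": "0 + C(locus)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method=["lbfgs", "powell"])
    if not result.converged:
        raise RuntimeError(
            "REML fit did not converge; "
            f"params={dict(zip(result.model.exog_names, result.fe_params))}"
        )
    return result


def _wald_contrast(result, rows: np.ndarray) -> float:
    """P value for H0: rows @ params = 0, padding zeros over variance params."""
    k_total = len(result.params)
    r = np.zeros((rows.shape[0], k_total))
    r[:, : rows.shape[1]] = rows
    return float(np.squeeze(result.wald_test(r, scalar=True).pvalue))


def fit_season_model(records: pd.DataFrame) -> SeasonModelFit:
    """REML variance-components fit of the season-of-conception model.

    Fixed effects: locus_type and season nested within locus_type, so the
    two season coefficients are directly the within-type rainy-dry contrasts
    on the arcsine scale.  Random intercepts: individual, and locus (nested
    in locus_type by construction since each locus has one type).  The
    back-transformed effect is the difference of back-transformed season
    means evaluated at the type's dry-season mean.

    Degenerate input with zero response variance returns a null fit (all
    effects and variance components zero) rather than failing.
    """
    df = _prepare(records)
    for lt, g in df.groupby("locus_type"):
        if g["locus"].nunique() < 2:
            raise ValueError(f"locus_type {lt!r} needs >=2 loci")
    if df.groupby("season")["individual"].nunique().min() < 2:
        raise ValueError("need >=2 individuals per season")

    types = sorted(df["locus_type"].unique())
    if np.allclose(df["y"].var(ddof=0), 0.0):
        per_locus = _per_locus_effects(df)
        return SeasonModelFit(
            variance_components={"individual": 0.0, "locus": 0.0, "residual": 0.0},
            season_effect={t: 0.0 for t in types},
            season_effect_percent={t: 0.0 for t in types},
            season_p={t: 1.0 for t in types},
            overall_season_p=1.0, season_by_type_p=1.0,
            per_locus=per_locus, n_obs=len(df), converged=True,
        )

    result = _fit_mixedlm(df, "y ~ C(locus_type) + C(locus_type):season_rainy")
    fe = result.fe_params
    exog_names = list(result.model.exog_names)

    season_effect, season_p, season_effect_percent = {}, {}, {}
    k_fe = len(fe)
    for lt in types:
        name = f"C(locus_type)[{lt}]:season_rainy"
        idx = exog_names.index(name)
        beta = float(fe.iloc[idx])
        season_effect[lt] = beta
        season_p[lt] = float(result.pvalues.iloc[idx])
        m_dry = df.loc[(df["locus_type"] == lt) & (df["season_rainy"] == 0), "y"].mean()
        season_effect_percent[lt] = float(
            inverse_arcsine(m_dry + beta) - inverse_arcsine(m_dry)
        )

    idxs = [exog_names.index(f"C(locus_type)[{lt}]:season_rainy") for lt in types]
    joint = np.zeros((len(types), k_fe))
    for row, i in enumerate(idxs):
        joint[row, i] = 1.0
    overall_p = _wald_contrast(result, joint)
    diff = np.zeros((1, k_fe))
    diff[0, idxs[0]], diff[0, idxs[1]] = 1.0, -1.0
    interaction_p = _wald_contrast(result, diff)

    vc = {n: float(v) for n, v in zip(result.model.exog_vc.names, result.vcomp)}
    vc["residual"] = float(result.scale)

    return SeasonModelFit(
        variance_components=vc,
        season_effect=season_effect,
        season_effect_percent=season_effect_percent,
        season_p=season_p,
        overall_season_p=overall_p,
        season_by_type_p=interaction_p,
        per_locus=_per_locus_effects(df),
        n_obs=len(df),
        converged=bool(result.converged),
    )


def _per_locus_effects(df: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-locus season contrasts (transformed and percent scales)."""
    rows = []
    for locus, g in df.groupby("locus"):
        m_rainy = g.loc[g["season_rainy"] == 1, "y"].mean()
        m_dry = g.loc[g["season_rainy"] == 0, "y"].mean()
        effect_t = m_rainy - m_dry
        effect_pct = inverse_arcsine(m_rainy) - inverse_arcsine(m_dry)
        a = g.loc[g["season_rainy"] == 1, "y"]
        b = g.loc[g["season_rainy"] == 0, "y"]
        if len(a) >= 2 and len(b) >= 2 and (a.var() + b.var()) > 0:
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append((locus, g["locus_type"].iloc[0], len(a), len(b),
                     float(effect_t), float(effect_pct), p))
    return pd.DataFrame(
        rows,
        columns=["locus", "locus_type", "n_rainy", "n_dry",
                 "effect_transformed", "effect_percent", "welch_p"],
    )


# ---------------------------------------------------------------------------
# season x year interaction screen

@dataclass
class InteractionScreen:
    interaction_p: float
    leave_one_out: pd.DataFrame  # year, interaction_p_without
    recommended_exclusion: int | None
    flagged_years: list = field(default_factory=list)


def _interaction_p(df: pd.DataFrame) -> float:
    result = _fit_mixedlm(
        df, "y ~ C(locus_type) + C(locus_type):season_rainy + C(year) + season_rainy:C(year)"
    )
    exog_names = list(result.model.exog_names)
    idxs = [i for i, n in enumerate(exog_names) if n.startswith("season_rainy:C(year)")]
    rows = np.zeros((len(idxs), len(result.fe_params)))
    for row, i in enumerate(idxs):
        rows[row, i] = 1.0
    return _wald_contrast(result, rows)


def interaction_screen(records: pd.DataFrame) -> InteractionScreen:
    """Season x year interaction test with leave-one-year-out diagnostics.

    Fits the season model augmented with year and season x year fixed terms
    (joint Wald test on the interaction).  The leave-one-out table reports
    the interaction P after removing each year in turn; the recommended
    exclusion is the year whose removal maximizes that P (i.e. the year
    most responsible for heterogeneity of the season effect).
    """
    df = _prepare(records)
    years = sorted(df["year"].unique())
    if len(years) < 2:
        raise ValueError("interaction screen needs >=2 years of conception")
    flagged = [
        int(y) for y in years
        if df.loc[df["year"] == y, "season"].nunique() < 2
    ]
    for y in flagged:
        logger.warning(
            "interaction_screen: year %d lacks one season; excluded from the fit", y
        )
    df = df[~df["year"].isin(flagged)]
    years = sorted(df["year"].unique())
    if len(years) < 2:
        raise ValueError("fewer than 2 complete years after flagging")

    full_p = _interaction_p(df)
    rows = []
    for y in years:
        sub = df[df["year"] != y]
        if sub["year"].nunique() < 2:
            rows.append((int(y), float("nan")))
            continue
        rows.append((int(y), _interaction_p(sub)))
    loo = pd.DataFrame(rows, columns=["year_excluded", "interaction_p_without"])
    best = loo.dropna().sort_values("interaction_p_without", ascending=False)
    recommended = int(best.iloc[0]["year_excluded"]) if len(best) else None
    return InteractionScreen(
        interaction_p=full_p, leave_one_out=loo,
        recommended_exclusion=recommended, flagged_years=flagged,
    )


# ---------------------------------------------------------------------------
# kinship from a SNP panel

@dataclass
class IBDEstimate:
    pair_id: str
    p0: float
    p1: float
    p2: float
    phi: float
    n_markers: int


def kinship_phi(p1: float, p2: float) -> float:
    """Kinship coefficient from IBD-sharing probabilities: phi = p1/4 + p2/2."""
    return 0.25 * p1 + 0.5 * p2


_GENO_CODE = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}


def _code_genotypes(g) -> np.ndarray:
    arr = np.asarray(g)
    if arr.dtype.kind in "iuf":
        return arr.astype(int)
    return np.array([_GENO_CODE[str(x)] for x in arr], dtype=int)


def ibs_expectations(freqs: np.ndarray) -> np.ndarray:
    """3x3 matrix A[i, j] = sum over markers of P(IBS=i | IBD=j) under HWE.

    ``freqs`` are per-marker frequencies of the B allele.
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    a00 = 2 * p**2 * q**2
    a10 = 4 * p**3 * q + 4 * p * q**3
    a20 = p**4 + q**4 + 4 * p**2 * q**2
    a11 = 2 * p**2 * q + 2 * p * q**2
    a21 = 1.0 - a11
    zeros = np.zeros_like(p)
    per_marker = np.array([
        [a00, zeros, zeros],
        [a10, a11, zeros],
        [a20, a21, np.ones_like(p)],
    ])
    return per_marker.sum(axis=2)


def estimate_ibd_pair(
    genotypes_1,
    genotypes_2,
    allele_freqs,
    pair_id: str = "pair",
    min_markers: int = 10,
) -> IBDEstimate:
    """Method-of-moments IBD-sharing estimate for one pair from a SNP panel.

    Genotypes are AA/AB/BB strings or 0/1/2 B-allele counts, one per marker;
    ``allele_freqs`` are the population B-allele frequencies.  Monomorphic
    markers (frequency 0 or 1) are excluded with a log message.  Observed
    IBS counts (N0, N1, N2) are matched to their expectations given
    (p0, p1, p2) by least squares constrained to the probability simplex;
    phi = p1/4 + p2/2.
    """
    g1 = _code_genotypes(genotypes_1)
    g2 = _code_genotypes(genotypes_2)
    freqs = np.asarray(allele_freqs, dtype=float)
    if not (len(g1) == len(g2) == len(freqs)):
        raise ValueError("genotype vectors and frequencies differ in length")
    poly = (freqs > 0) & (freqs < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("estimate_ibd_pair: excluded %d monomorphic markers", n_mono)
    g1, g2, freqs = g1[poly], g2[poly], freqs[poly]
    if len(g1) < min_markers:
        raise ValueError(f"need >={min_markers} co-typed polymorphic markers, have {len(g1)}")

    ibs = 2 - np.abs(g1 - g2)
    counts = np.array([(ibs == 0).sum(), (ibs == 1).sum(), (ibs == 2).sum()], dtype=float)
    a = ibs_expectations(freqs)

    # least squares on the simplex: min ||A p - counts||^2, p >= 0, sum p = 1
    def objective(p):
        return float(((a @ p - counts) ** 2).sum())

    res = optimize.minimize(
        objective,
        x0=np.array([1 / 3, 1 / 3, 1 / 3]),
        bounds=[(0, 1)] * 3,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
        method="SLSQP",
    )
    p0, p1, p2 = np.clip(res.x, 0.0, 1.0)
    total = p0 + p1 + p2
    p0, p1, p2 = p0 / total, p1 / total, p2 / total
    return IBDEstimate(
        pair_id=pair_id, p0=float(p0), p1=float(p1), p2=float(p2),
        phi=kinship_phi(p1, p2), n_markers=len(g1),
    )


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _validate_cohort(df)
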
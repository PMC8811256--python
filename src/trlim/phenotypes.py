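"""Tier-1 analysis of the aquaporin-inhibitor transpiration screen.

A de-rooted shoot is weighed before and after a timed interval, first while
transpiring deionized water and then after uptake of the aquaporin inhibitor
AgNO3.  The drop in transpiration rate (TR) between the two phases measures
aquaporin-mediated hydraulic conductance: genotypes insensitive to the
inhibitor are candidates for the limited-transpiration (TRlim), slow-wilting
phenotype.

This module turns raw flask-weighing records into the full index suite
(TR_H2O, TR_AgNO3, DTR, RTR, NDTR and the six parent-relative derivatives),
genotype least-square means, summary statistics, broad-sense heritability
from ANOVA variance components, trait correlations, and the slow / moderate
/ fast wilting classification.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AnalysisWarning,
    InvalidInputError,
    InvalidRecordError,
    MeasurementWarning,
    RankDeficiencyError,
    UndefinedDivisionError,
)

__all__ = [
    "Phase",
    "TranspirationMeasurement",
    "DecreaseIndices",
    "TraitSummary",
    "HeritabilityEstimate",
    "WiltingClass",
    "transpiration_rate",
    "decrease_indices",
    "relative_indices",
    "classify_wilting",
    "genotype_lsm",
    "trait_summary",
    "variance_components",
    "heritability",
    "correlation_matrix",
    "quadratic_fit",
    "read_weighing_csv",
    "compute_index_table",
    "summary_report",
]


class Phase(str, enum.Enum):
    """Measurement phase of a weighing record."""

    WATER = "water"
    AGNO3 = "agno3"


class WiltingClass(str, enum.Enum):
    """Wilting speed class from a parent-relative decrease index."""

    SLOW = "slow"
    MODERATE = "moderate"
    FAST = "fast"


@dataclass(frozen=True)
class TranspirationMeasurement:
    """One flask weighing: genotype x set x replicate x phase.

    Masses are in grams, the interval in minutes; ``leaf_temp`` (degC) and
    ``leaf_area`` (m2) are optional.
    """

    genotype_id: str
    set_id: str
    replicate: int
    phase: Phase
    mass_initial: float
    mass_final: float
    interval: float
    leaf_temp: float | None = None
    leaf_area: float | None = None

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise InvalidRecordError(
                f"nonpositive interval ({self.interval} min) for genotype "
                f"{self.genotype_id!r}, set {self.set_id!r}, rep {self.replicate}, "
                f"phase {Phase(self.phase).value}"
            )
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "replicate", int(self.replicate))


@dataclass(frozen=True)
class DecreaseIndices:
    """The three inhibitor-response indices of one genotype.

    dtr is a percent decrease, rtr a ratio (NaN when TR_AgNO3 = 0), ndtr a
    normalized decrease in [-1, 1].
    """

    dtr: float
    rtr: float
    ndtr: float


@dataclass(frozen=True)
class TraitSummary:
    """Distribution summary of one trait across genotypes (Fisher conventions)."""

    mean: float
    sd: float
    sem: float
    upper95: float
    lower95: float
    n: int
    variance: float
    skewness: float
    kurtosis: float
    cv_percent: float


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Broad-sense heritability and the variance components behind it."""

    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    n_env: int
    n_rep: int
    h2: float


def transpiration_rate(m: TranspirationMeasurement) -> float:
    """Transpiration rate from one weighing record.

    Returns mg water per minute (mass loss in grams times 1000 over the
    interval).  When ``leaf_area`` is present the rate is additionally
    divided by the area and converted to per-second, giving mg m-2 s-1.
    Negative rates (mass gain: condensation or weighing error) are returned
    but flagged with a :class:`MeasurementWarning`.
    """
    loss_mg = (m.mass_initial - m.mass_final) * 1000.0
    rate = loss_mg / m.interval
    if rate < 0:
        warnings.warn(
            f"negative transpiration rate ({rate:.4g} mg/min) for genotype "
            f"{m.genotype_id!r}, set {m.set_id!r}, rep {m.replicate}, "
            f"phase {m.phase.value}",
            MeasurementWarning,
            stacklevel=2,
        )
    if m.leaf_area is not None:
        if m.leaf_area <= 0:
            raise InvalidRecordError(
                f"nonpositive leaf_area ({m.leaf_area}) for genotype {m.genotype_id!r}"
            )
        rate = rate / m.leaf_area / 60.0
    return rate


def decrease_indices(tr_h2o: float, tr_agno3: float) -> DecreaseIndices:
    """DTR, RTR and NDTR from the water-phase and inhibitor-phase rates.

    dtr  = 100 * (TR_H2O - TR_AgNO3) / TR_H2O        (percent decrease)
    rtr  = TR_H2O / TR_AgNO3                          (ratio)
    ndtr = (TR_H2O - TR_AgNO3) / (TR_H2O + TR_AgNO3)  (normalized decrease)

    TR_H2O must be positive.  When TR_AgNO3 is zero, rtr is undefined and
    returned as NaN with an :class:`AnalysisWarning`; dtr and ndtr are still
    computed.
    """
    if tr_h2o <= 0 or not math.isfinite(tr_h2o):
        raise InvalidInputError(f"tr_h2o must be positive and finite, got {tr_h2o}")
    if tr_agno3 < 0 or not math.isfinite(tr_agno3):
        raise InvalidInputError(f"tr_agno3 must be nonnegative and finite, got {tr_agno3}")
    dtr = 100.0 * (tr_h2o - tr_agno3) / tr_h2o
    ndtr = (tr_h2o - tr_agno3) / (tr_h2o + tr_agno3)
    if tr_agno3 == 0:
        warnings.warn(
            "tr_agno3 is zero: RTR undefined (NaN); DTR and NDTR still returned",
            AnalysisWarning,
            stacklevel=2,
        )
        rtr = math.nan
    else:
        rtr = tr_h2o / tr_agno3
    return DecreaseIndices(dtr=dtr, rtr=rtr, ndtr=ndtr)


def relative_indices(
    value: float, ref_jackson: float, ref_ks4895: float
) -> tuple[float, float]:
    """A genotype's index relative to each reference parent.

    Returns ``(value/ref_jackson, value/ref_ks4895)``.  Applied identically
    to DTR, RTR and NDTR this yields the six parent-relative traits
    (RDTR_J/K, RRTR_J/K, RNDTR_J/K).
    """
    if ref_jackson == 0:
        raise UndefinedDivisionError("reference parent 'Jackson' index is zero")
    if ref_ks4895 == 0:
        raise UndefinedDivisionError("reference parent 'KS4895' index is zero")
    return value / ref_jackson, value / ref_ks4895


def classify_wilting(value: float) -> WiltingClass:
    """Wilting class of a nonnegative parent-relative decrease index.

    value <= 0.50 -> slow; 0.50 < value <= 1.00 -> moderate; value > 1.00
    -> fast.  The half-open boundaries resolve the gap between the stated
    0.00-0.50 and 0.51-1.00 ranges for continuous values.
    """
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"wilting index must be finite and >= 0, got {value}")
    if value <= 0.50:
        return WiltingClass.SLOW
    if value <= 1.00:
        return WiltingClass.MODERATE
    return WiltingClass.FAST


def genotype_lsm(
    df: pd.DataFrame,
    value_col: str,
    genotype_col: str = "genotype",
    set_col: str = "set",
) -> pd.Series:
    """Genotype least-square means from an additive genotype + set model.

    The design is genotype indicators plus sum-to-zero set contrasts,
    solved by ordinary least squares; replicates enter as observations.
    Because set effects sum to zero, each genotype coefficient is its mean
    adjusted to the average set, and on balanced data the LSM equals the
    arithmetic genotype mean.

    Rows with missing values are dropped; a genotype with no observations
    simply does not appear in the output.  A singular design (e.g. a set
    confounded with a genotype) raises :class:`RankDeficiencyError`.
    """
    d = df[[genotype_col, set_col, value_col]].dropna()
    if d.empty:
        raise InvalidInputError("no complete observations for LSM")
    genos = pd.Index(sorted(d[genotype_col].astype(str).unique()))
    sets = pd.Index(sorted(d[set_col].astype(str).unique()))
    g_idx = genos.get_indexer(d[genotype_col].astype(str))
    s_idx = sets.get_indexer(d[set_col].astype(str))
    n, G, S = len(d), len(genos), len(sets)

    X = np.zeros((n, G + max(S - 1, 0)))
    X[np.arange(n), g_idx] = 1.0
    for j in range(S - 1):
        X[s_idx == j, G + j] = 1.0
        X[s_idx == S - 1, G + j] = -1.0
    y = d[value_col].to_numpy(dtype=float)

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            "genotype + set design is rank deficient (a set is confounded "
            "with genotypes or a factor level has no independent information)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(beta[:G], index=genos, name=value_col)


def trait_summary(values) -> TraitSummary:
    """Summary statistics of a trait vector.

    Sample SD uses the n-1 denominator; the 95% bounds are the two-sided
    t-interval on the mean; skewness is Fisher's bias-corrected g1 and
    kurtosis the bias-corrected excess (zero for a normal sample).
    Dispersion statistics of an n<2 or constant vector are NaN markers,
    never zero-filled (except SD/variance of a constant vector, which are
    genuinely 0).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        raise InvalidInputError("empty trait vector")
    mean = float(np.mean(v))
    if n < 2:
        nan = math.nan
        return TraitSummary(mean, nan, nan, nan, nan, n, nan, nan, nan, nan)
    sd = float(np.std(v, ddof=1))
    var = sd * sd
    sem = sd / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    if sd == 0:
        skew = kurt = math.nan
        cv = 0.0 if mean != 0 else math.nan
    else:
        skew = float(stats.skew(v, bias=False))
        kurt = float(stats.kurtosis(v, fisher=True, bias=False)) if n > 3 else math.nan
        cv = 100.0 * sd / mean if mean > 0 else math.nan
    return TraitSummary(
        mean=mean,
        sd=sd,
        sem=sem,
        upper95=mean + tcrit * sem,
        lower95=mean - tcrit * sem,
        n=n,
        variance=var,
        skewness=skew,
        kurtosis=kurt,
        cv_percent=cv,
    )


def variance_components(
    df: pd.DataFrame,
    value_col: str,
    genotype_col: str = "genotype",
    set_col: str = "set",
) -> dict[str, float]:
    """Method-of-moments variance components from two-way ANOVA mean squares.

    For a balanced genotype x set layout with r replicates per cell the
    expected mean squares give

        sigma_e2  = MS_error
        sigma_ge2 = (MS_GxS - MS_error) / r
        sigma_g2  = (MS_G - MS_GxS) / (S * r)

    Negative moment estimates are truncated to zero with a warning.  Every
    genotype x set cell must be occupied; mildly unbalanced designs use the
    mean cell count for r (warned).
    """
    d = df[[genotype_col, set_col, value_col]].dropna()
    cells = d.groupby([genotype_col, set_col], observed=True)[value_col]
    counts = cells.size()
    G = d[genotype_col].nunique()
    S = d[set_col].nunique()
    if G < 2 or S < 1:
        raise InvalidInputError("need >= 2 genotypes and >= 1 set")
    if len(counts) < G * S:
        full = pd.MultiIndex.from_product(
            [sorted(d[genotype_col].unique()), sorted(d[set_col].unique())]
        )
        missing = full.difference(counts.index)
        raise InvalidInputError(
            f"missing genotype x set cells make EMS coefficients undefined: "
            f"{list(missing[:5])}{'...' if len(missing) > 5 else ''}"
        )
    r = float(counts.mean())
    if counts.nunique() > 1:
        warnings.warn(
            f"unbalanced cells (sizes {counts.min()}..{counts.max()}); "
            f"using mean cell count r={r:.3g} in EMS coefficients",
            AnalysisWarning,
            stacklevel=2,
        )

    y = d[value_col].to_numpy(dtype=float)
    grand = y.mean()
    cell_mean = cells.mean()
    g_mean = d.groupby(genotype_col, observed=True)[value_col].mean()
    s_mean = d.groupby(set_col, observed=True)[value_col].mean()

    ss_g = float(r * S * ((g_mean - grand) ** 2).sum())
    ss_s = float(r * G * ((s_mean - grand) ** 2).sum())
    inter = (
        cell_mean
        - g_mean.reindex(cell_mean.index.get_level_values(0)).to_numpy()
        - s_mean.reindex(cell_mean.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_gs = float(r * (inter**2).sum())
    resid = d[value_col].to_numpy(dtype=float) - cells.transform("mean").to_numpy()
    ss_e = float((resid**2).sum())

    df_g = G - 1
    df_gs = (G - 1) * (S - 1)
    df_e = len(d) - G * S
    ms_g = ss_g / df_g
    ms_gs = ss_gs / df_gs if df_gs > 0 else 0.0
    ms_e = ss_e / df_e if df_e > 0 else 0.0

    sigma_e2 = ms_e
    sigma_ge2 = (ms_gs - ms_e) / r if df_gs > 0 else 0.0
    sigma_g2 = (ms_g - (ms_gs if df_gs > 0 else ms_e)) / (S * r)
    out = {}
    for name, val in [
        ("sigma_g2", sigma_g2),
        ("sigma_ge2", sigma_ge2),
        ("sigma_e2", sigma_e2),
    ]:
        if val < 0:
            warnings.warn(
                f"negative moment estimate {name}={val:.4g} truncated to 0",
                AnalysisWarning,
                stacklevel=2,
            )
            val = 0.0
        out[name] = float(val)
    out["ss_set"] = ss_s  # kept for reporting; not a component of H2
    return out


def heritability(vc: dict[str, float], n_env: int, n_rep: int) -> HeritabilityEstimate:
    """Broad-sense heritability on an entry-mean basis.

    H2 = sigma_g2 / (sigma_g2 + sigma_ge2/E + sigma_e2/(E*R))

    with E environments (experiment sets) and R replicates per environment.
    """
    if n_env < 1 or n_rep < 1:
        raise InvalidInputError("n_env and n_rep must be >= 1")
    sg, sge, se = vc["sigma_g2"], vc.get("sigma_ge2", 0.0), vc["sigma_e2"]
    if min(sg, sge, se) < 0:
        raise InvalidInputError("variance components must be nonnegative")
    denom = sg + sge / n_env + se / (n_env * n_rep)
    if denom == 0:
        raise UndefinedDivisionError("all variance components are zero; H2 undefined")
    return HeritabilityEstimate(
        sigma_g2=sg,
        sigma_ge2=sge,
        sigma_e2=se,
        n_env=int(n_env),
        n_rep=int(n_rep),
        h2=sg / denom,
    )


def correlation_matrix(
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with p-values, pairwise-complete.

    Returns ``(r, p)`` symmetric DataFrames with unit diagonal.  A trait
    with zero variance (over the complete pairs) gets NaN in its row and
    column.
    """
    cols = list(traits.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            pair = traits[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                continue
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def quadratic_fit(x, y) -> dict:
    """Degree-2 least-squares polynomial with R^2.

    Used to describe how a parent-relative decrease index varies with leaf
    temperature.  Returns ``{"coefficients": (c2, c1, c0), "r_squared": R2}``
    with coefficients in descending degree.  A constant response has R^2 = 0
    by convention (TSS = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise InvalidInputError(f"need >= 4 points for a quadratic fit, got {x.size}")
    if np.unique(x).size < 3:
        raise RankDeficiencyError("fewer than 3 distinct x values; quadratic is singular")
    coef = np.polyfit(x, y, 2)
    resid = y - np.polyval(coef, x)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((resid**2).sum())
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return {"coefficients": tuple(float(c) for c in coef), "r_squared": r2}


# ---------------------------------------------------------------------------
# Tabular layer: weighing CSV -> per-genotype index table -> summary report
# ---------------------------------------------------------------------------

WEIGHING_COLUMNS = [
    "genotype",
    "set",
    "rep",
    "phase",
    "mass_initial_g",
    "mass_final_g",
    "interval_min",
]

INDEX_TRAITS = [
    "tr_h2o",
    "tr_agno3",
    "dtr",
    "rtr",
    "ndtr",
    "rdtr_j",
    "rdtr_k",
    "rrtr_j",
    "rrtr_k",
    "rndtr_j",
    "rndtr_k",
    "lt",
]


def read_weighing_csv(path) -> pd.DataFrame:
    """Read and validate a flask-weighing CSV.

    Required header: genotype,set,rep,phase,mass_initial_g,mass_final_g,
    interval_min; optional leaf_temp_c and leaf_area_m2.  phase must be
    'water' or 'agno3'.
    """
    df = pd.read_csv(path, dtype={"genotype": str, "set": str})
    missing = [c for c in WEIGHING_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidRecordError(f"weighing CSV missing columns: {missing}")
    bad = set(df["phase"].unique()) - {"water", "agno3"}
    if bad:
        raise InvalidRecordError(f"unknown phase values: {sorted(bad)}")
    if (df["interval_min"] <= 0).any():
        idx = df.index[df["interval_min"] <= 0][0]
        row = df.loc[idx]
        raise InvalidRecordError(
            f"nonpositive interval at row {idx} "
            f"(genotype {row['genotype']!r}, set {row['set']!r}, rep {row['rep']})"
        )
    if (df["mass_final_g"] > df["mass_initial_g"]).any():
        n_bad = int((df["mass_final_g"] > df["mass_initial_g"]).sum())
        warnings.warn(
            f"{n_bad} record(s) gained mass (final > initial); retained but flagged",
            MeasurementWarning,
            stacklevel=2,
        )
    return df


def _rates_long(weighing: pd.DataFrame, drop_negative: bool) -> pd.DataFrame:
    df = weighing.copy()
    df["rate"] = (df["mass_initial_g"] - df["mass_final_g"]) * 1000.0 / df["interval_min"]
    if "leaf_area_m2" in df.columns and df["leaf_area_m2"].notna().all():
        df["rate"] = df["rate"] / df["leaf_area_m2"] / 60.0
    if drop_negative:
        neg = df["rate"] < 0
        if neg.any():
            warnings.warn(
                f"excluding {int(neg.sum())} negative-rate record(s) from indices",
                MeasurementWarning,
                stacklevel=3,
            )
            df = df[~neg]
    return df


def compute_index_table(
    weighing: pd.DataFrame,
    parent_jackson: str = "Jackson",
    parent_ks4895: str = "KS4895",
    drop_negative: bool = True,
    classify_on: str = "rdtr_k",
) -> pd.DataFrame:
    """Per-genotype index table from raw weighing records.

    Per-plant rates are computed per phase, genotype least-square means of
    TR_H2O, TR_AgNO3 (and leaf temperature when present) are taken across
    sets, the decrease indices are computed from the genotype means, and the
    six parent-relative traits are scaled by the two reference parents.
    A wilting class from ``classify_on`` (default RDTR_K) is appended.
    """
    rates = _rates_long(weighing, drop_negative=drop_negative)
    out = {}
    for phase, col in [("water", "tr_h2o"), ("agno3", "tr_agno3")]:
        sub = rates[rates["phase"] == phase]
        if sub.empty:
            raise InvalidRecordError(f"no usable records for phase {phase!r}")
        out[col] = genotype_lsm(sub, "rate")
    table = pd.DataFrame(out)
    if "leaf_temp_c" in rates.columns and rates["leaf_temp_c"].notna().any():
        lt = rates.dropna(subset=["leaf_temp_c"])
        table["lt"] = genotype_lsm(lt, "leaf_temp_c")
    else:
        table["lt"] = np.nan

    dropped = table.index[~(table["tr_h2o"] > 0)]
    if len(dropped):
        warnings.warn(
            f"excluding genotypes with nonpositive TR_H2O mean: {list(dropped)}",
            AnalysisWarning,
            stacklevel=2,
        )
        table = table.drop(index=dropped)

    idx = table.apply(
        lambda row: decrease_indices(row["tr_h2o"], row["tr_agno3"]), axis=1
    )
    table["dtr"] = [i.dtr for i in idx]
    table["rtr"] = [i.rtr for i in idx]
    table["ndtr"] = [i.ndtr for i in idx]

    for parent in (parent_jackson, parent_ks4895):
        if parent not in table.index:
            raise InvalidInputError(
                f"reference parent {parent!r} absent from the genotype table"
            )
    for trait, (jcol, kcol) in {
        "dtr": ("rdtr_j", "rdtr_k"),
        "rtr": ("rrtr_j", "rrtr_k"),
        "ndtr": ("rndtr_j", "rndtr_k"),
    }.items():
        ref_j = table.at[parent_jackson, trait]
        ref_k = table.at[parent_ks4895, trait]
        rel = table[trait].apply(lambda v: relative_indices(v, ref_j, ref_k))
        table[jcol] = [t[0] for t in rel]
        table[kcol] = [t[1] for t in rel]

    table["wilting_class"] = [
        classify_wilting(v).value if math.isfinite(v) and v >= 0 else None
        for v in table[classify_on]
    ]
    table.index.name = "genotype"
    return table[INDEX_TRAITS[:5] + INDEX_TRAITS[5:11] + ["lt", "wilting_class"]]


def summary_report(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait summary table (one row per statistic, one column per trait)."""
    traits = traits or [c for c in INDEX_TRAITS if c in table.columns]
    rows = {}
    for t in traits:
        s = trait_summary(table[t].dropna())
        rows[t] = {
            "Mean": s.mean,
            "SD": s.sd,
            "SEM": s.sem,
            "Upper 95% mean": s.upper95,
            "Lower 95% mean": s.lower95,
            "N": s.n,
            "Variance": s.variance,
            "Skewness": s.skewness,
            "Kurtosis": s.kurtosis,
            "CV": s.cv_percent,
        }
    return pd.DataFrame(rows)
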
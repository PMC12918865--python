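"""Group statistics: normality/heteroscedasticity checks, the conditional
+1 log10 transform for frequency data, two-way genotype x age ANOVA with
Sidak pairwise comparisons, and geometric-mean [95 CI] summaries.

Synaptic-current frequencies are log-normal, so frequency measures are
log10-transformed before ANOVA; when any data point in the dataset is
<= 1.0 Hz a constant of 1.0 is first added to *every* point so the
transformed values stay positive.  Geometric means are always reported on
the raw (untransformed) values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

GENOTYPES = ("WT", "DS")
AGES = ("2W", "4W", "8W")


@dataclass
class GroupDataset:
    """Per-mouse (or per-cell) values with genotype and age factor labels."""

    values: np.ndarray
    genotype: np.ndarray  # labels, e.g. WT / DS
    age: np.ndarray  # labels, e.g. 2W / 4W / 8W
    measure: str = ""
    units: str = ""
    transform_applied: str = "none"  # none | log10 | log10_plus1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genotype = np.asarray(self.genotype)
        self.age = np.asarray(self.age)
        if not (self.values.size == self.genotype.size == self.age.size):
            raise ValueError("values and factor labels must have equal length")
        if self.transform_applied not in ("none", "log10", "log10_plus1"):
            raise ValueError(f"unknown transform {self.transform_applied!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "genotype": self.genotype, "age": self.age})

    @property
    def genotype_levels(self) -> list:
        return sorted(set(self.genotype.tolist()))

    @property
    def age_levels(self) -> list:
        return sorted(set(self.age.tolist()))


@dataclass
class AnovaResult:
    """Two-way (or one-way) ANOVA output with Sidak pairwise comparisons."""

    effects: dict = field(default_factory=dict)  # name -> {"F", "df_num", "df_den", "p"}
    residual_ms: float = float("nan")
    residual_df: float = float("nan")
    pairwise: dict = field(default_factory=dict)  # age -> {"t", "p_raw", "p_adj"}
    group_summary: pd.DataFrame | None = None
    degenerate: bool = False  # zero residual variance


def dagostino_pearson(values) -> tuple[float, float]:
    """Omnibus K² normality test combining skewness and kurtosis z-scores,
    with p from chi²(2).  Requires n >= 8."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError(f"need n >= 8 for the omnibus normality test, got {x.size}")
    k2, p = sps.normaltest(x)
    return float(k2), float(p)


def spearman_heteroscedasticity(residuals, fitted) -> tuple[float, float]:
    """Spearman rank correlation between |residual| and fitted value.

    A significant positive correlation indicates variance growing with the
    mean (heteroscedasticity).
    """
    r = np.asarray(residuals, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if r.size != f.size:
        raise ValueError("residuals and fitted values must have equal length")
    if r.size < 5:
        raise ValueError(f"need n >= 5, got {r.size}")
    if np.ptp(f) == 0:
        raise ValueError("fitted values are constant; heteroscedasticity test undefined")
    rho, p = sps.spearmanr(np.abs(r), f)
    return float(rho), float(p)


def conditional_log_transform(dataset: GroupDataset) -> GroupDataset:
    """log10 transform for frequency data, adding 1.0 to every point first
    when any point in the dataset is <= 1.0 (so all transformed values are
    positive).  The rule is evaluated over the full dataset, not per group.
    """
    v = dataset.values
    if np.any(v <= 0):
        raise ValueError("frequencies must be positive before log transform")
    if v.min() <= 1.0:
        return replace(dataset, values=np.log10(v + 1.0), transform_applied="log10_plus1")
    return replace(dataset, values=np.log10(v), transform_applied="log10")


def _check_design(df: pd.DataFrame, min_cell_n: int = 2) -> None:
    for g in sorted(df["genotype"].unique()):
        for a in sorted(df["age"].unique()):
            n = ((df["genotype"] == g) & (df["age"] == a)).sum()
            if n < min_cell_n:
                raise ValueError(f"cell genotype={g}, age={a} has n={n} (< {min_cell_n})")


def group_summary(dataset: GroupDataset, raw_values: np.ndarray | None = None) -> pd.DataFrame:
    """Per-group mean (SD) plus geometric mean [95 CI] of the raw values."""
    raw = dataset.values if raw_values is None else np.asarray(raw_values, dtype=float)
    rows = []
    for g in dataset.genotype_levels:
        for a in dataset.age_levels:
            sel = (dataset.genotype == g) & (dataset.age == a)
            v, rv = dataset.values[sel], raw[sel]
            row = {"genotype": g, "age": a, "n": int(sel.sum()),
                   "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if sel.sum() > 1 else float("nan")}
            if np.all(rv > 0) and rv.size >= 2:
                gm, lo, hi = geometric_mean_ci(rv)
                row.update({"geomean": gm, "geomean_ci_lo": lo, "geomean_ci_hi": hi})
            rows.append(row)
    return pd.DataFrame(rows)


def two_way_anova(dataset: GroupDataset, ss_type: int = 3) -> AnovaResult:
    """Genotype x age factorial ANOVA (Type III sums of squares with
    sum-to-zero contrasts by default; Type II configurable), tolerant of
    unbalanced cells.  Every cell needs n >= 2."""
    df = dataset.to_frame()
    _check_design(df)
    model = ols("value ~ C(genotype, Sum) * C(age, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    resid_row = table.loc["Residual"]
    residual_df = float(resid_row["df"])
    residual_ms = float(resid_row["sum_sq"] / resid_row["df"])
    scale = max(1.0, float(np.max(np.abs(dataset.values))) ** 2)
    degenerate = residual_ms <= 1e-12 * scale
    name_map = {
        "C(genotype, Sum)": "genotype",
        "C(age, Sum)": "age",
        "C(genotype, Sum):C(age, Sum)": "interaction",
    }
    effects = {}
    for raw_name, name in name_map.items():
        row = table.loc[raw_name]
        effects[name] = {
            "F": float(row["F"]) if not degenerate else float("nan"),
            "df_num": float(row["df"]),
            "df_den": residual_df,
            "p": float(row["PR(>F)"]) if not degenerate else float("nan"),
        }
    result = AnovaResult(effects=effects, residual_ms=residual_ms, residual_df=residual_df,
                         group_summary=group_summary(dataset), degenerate=degenerate)
    return result


def one_way_anova(dataset: GroupDataset) -> AnovaResult:
    """One-way ANOVA across the six genotype x age groups (the figure-legend
    variant), with the same residual pooling for pairwise tests."""
    df = dataset.to_frame()
    _check_design(df, min_cell_n=2)
    df["group"] = df["genotype"].astype(str) + ":" + df["age"].astype(str)
    model = ols("value ~ C(group)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    resid = table.loc["Residual"]
    residual_df = float(resid["df"])
    residual_ms = float(resid["sum_sq"] / resid["df"])
    degenerate = residual_ms <= 1e-300
    row = table.loc["C(group)"]
    effects = {"group": {"F": float(row["F"]), "df_num": float(row["df"]), "df_den": residual_df,
                         "p": float(row["PR(>F)"])}}
    return AnovaResult(effects=effects, residual_ms=residual_ms, residual_df=residual_df,
                       group_summary=group_summary(dataset), degenerate=degenerate)


def sidak_adjust(p_raw: float, m: int) -> float:
    """Sidak multiplicity adjustment: 1 - (1 - p)^m, clipped to [0, 1]."""
    return float(min(1.0, 1.0 - (1.0 - p_raw) ** m))


def sidak_pairwise(dataset: GroupDataset, anova: AnovaResult, m: int | None = None) -> dict:
    """Genotype contrast at each age with Sidak-adjusted p-values.

    Uses a t statistic with the ANOVA pooled residual mean square and its
    degrees of freedom; adjusted p = 1 - (1 - p_raw)^m with m the number of
    age levels.  Results are stored on ``anova.pairwise`` and returned.
    """
    genos = dataset.genotype_levels
    if len(genos) != 2:
        raise ValueError("pairwise genotype contrasts need exactly two genotype levels")
    ages = dataset.age_levels
    if m is None:
        m = len(ages)
    out = {}
    for a in ages:
        s1 = (dataset.genotype == genos[0]) & (dataset.age == a)
        s2 = (dataset.genotype == genos[1]) & (dataset.age == a)
        n1, n2 = int(s1.sum()), int(s2.sum())
        diff = float(np.mean(dataset.values[s1]) - np.mean(dataset.values[s2]))
        se = np.sqrt(anova.residual_ms * (1.0 / n1 + 1.0 / n2))
        if se == 0:
            t, p_raw = float("inf") if diff != 0 else 0.0, 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p_raw = float(2.0 * sps.t.sf(abs(t), anova.residual_df))
        out[a] = {"t": float(t), "df": anova.residual_df, "p_raw": p_raw, "p_adj": sidak_adjust(p_raw, m)}
    anova.pairwise = out
    return out


def geometric_mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Geometric mean with a back-transformed t confidence interval.

    The mean and t-interval are computed on log10 values and exponentiated;
    requires all values > 0 and n >= 2.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    if x.size < 2:
        raise ValueError("need at least 2 values")
    logs = np.log10(x)
    m = logs.mean()
    s = logs.std(ddof=1)
    half = sps.t.ppf(0.5 + level / 2.0, x.size - 1) * s / np.sqrt(x.size)
    return float(10**m), float(10 ** (m - half)), float(10 ** (m + half))


def analyze_group_dataset(dataset: GroupDataset, design: str = "two-way",
                          log_frequency: bool = True) -> tuple[AnovaResult, GroupDataset]:
    """The full reporting path for one measure.

    Frequency-like measures (``log_frequency=True``) get the conditional
    +1 log10 transform before ANOVA; geometric means in the group summary are
    computed on the raw values regardless.  Returns the ANOVA result (with
    Sidak pairwise contrasts filled in) and the transformed dataset.
    """
    raw = dataset.values.copy()
    work = conditional_log_transform(dataset) if log_frequency else dataset
    anova = two_way_anova(work) if design == "two-way" else one_way_anova(work)
    anova.group_summary = group_summary(work, raw_values=raw)
    sidak_pairwise(work, anova)
    return anova, work
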
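"""Direct standardization, trend and geographic inequality summaries.

Direct standardization replaces a township's own population structure
with a fixed standard (here, a census-style age-sex distribution):
standardized rate = sum over strata of weight_s x rate_s, with weights
summing to 1. Absolute geographic inequality is the gap between the 90th
and 10th percentiles of township rates; relative inequality is their
ratio. Township rate maps are classified into rank-based deciles, the top
decile marking high-rate areas.

Printed precision follows epidemiological convention: rates and percent
changes to 1 decimal, ratios to 1 decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._common import AGE_GROUPS, ConfigError


@dataclass
class StandardWeights:
    """Standard population proportions per (sex, age_group), summing to 1."""

    weights: pd.DataFrame  # sex, age_group, weight

    def validate(self) -> None:
        w = self.weights["weight"]
        if (w < 0).any():
            raise ConfigError("standard weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("standard weights must sum to 1")

    def sex_specific(self, sex: str) -> pd.DataFrame:
        """Weights renormalized within one sex (for age-standardization)."""
        w = self.weights[self.weights["sex"] == sex].copy()
        if w.empty:
            raise ConfigError(f"no weights for sex {sex!r}")
        w["weight"] = w["weight"] / w["weight"].sum()
        return w

    @classmethod
    def from_person_years(cls, person_years: pd.DataFrame) -> "StandardWeights":
        """Standard derived from a population table's own age-sex structure."""
        g = person_years.groupby(["sex", "age_group"], as_index=False)[
            "person_years"
        ].sum()
        g["weight"] = g["person_years"] / g["person_years"].sum()
        return cls(weights=g[["sex", "age_group", "weight"]])


@dataclass
class InequalitySummary:
    p10: float
    p90: float
    absolute_gap: float
    relative_ratio: float | None
    median: float
    q1: float
    q3: float


def direct_standardize(stratum_rates: pd.DataFrame, weights: pd.DataFrame) -> float:
    """Weighted average of stratum rates under the standard population.

    `stratum_rates` must cover every weighted stratum (merge keys are the
    weight table's non-weight columns, e.g. sex and age_group); a missing
    stratum raises. Rates are per 100,000; the result is on the same scale.
    """
    keys = [c for c in weights.columns if c != "weight"]
    m = weights.merge(stratum_rates, on=keys, how="left")
    if m["rate"].isna().any():
        missing = m.loc[m["rate"].isna(), keys].to_dict(orient="records")
        raise ConfigError(f"missing stratum rates for {missing[:5]}")
    return float((m["weight"] * m["rate"]).sum())


def standardized_township_rates(
    rate_table: pd.DataFrame,
    standard: StandardWeights,
    sex: str | None = None,
) -> pd.DataFrame:
    """Per-township standardized rates for one period-set of stratum rates.

    With `sex=None` both sexes are combined using age-and-sex weights;
    with a sex given, only that sex's strata enter, with age weights
    renormalized within the sex.
    """
    standard.validate()
    w = standard.weights if sex is None else standard.sex_specific(sex)
    tab = rate_table if sex is None else rate_table[rate_table["sex"] == sex]
    rows = []
    for (township, period), sub in tab.groupby(["township_id", "period"]):
        rows.append(
            (township, period, direct_standardize(sub, w))
        )
    return pd.DataFrame(rows, columns=["township_id", "period", "rate"])


def percent_change(rate_start: float, rate_end: float) -> float:
    """Relative change in percent, rounded to 1 decimal."""
    if rate_start <= 0:
        raise ConfigError("percent change needs a positive starting rate")
    return round(100.0 * (rate_end - rate_start) / rate_start, 1)


def inequality_metrics(rates) -> InequalitySummary:
    """Percentile-based geographic inequality across township rates.

    10th/90th percentiles use linear interpolation between order
    statistics. If the 10th percentile is 0 the relative ratio is
    undefined and returned as None. Requires at least 10 townships.
    """
    x = np.asarray(rates, dtype=float)
    if len(x) < 10:
        raise ConfigError("inequality metrics need at least 10 townships")
    p10, q1, med, q3, p90 = np.quantile(x, [0.10, 0.25, 0.50, 0.75, 0.90])
    if p10 == 0:
        import warnings

        warnings.warn("10th percentile is 0; relative ratio undefined", stacklevel=2)
        ratio = None
    else:
        ratio = round(p90 / p10, 1)
    return InequalitySummary(
        p10=round(p10, 1),
        p90=round(p90, 1),
        absolute_gap=round(p90 - p10, 1),
        relative_ratio=ratio,
        median=round(med, 1),
        q1=round(q1, 1),
        q3=round(q3, 1),
    )


def decile_classify(rates: pd.Series) -> pd.Series:
    """Rank-based decile label (1..10) per township, 10 = highest rates.

    Bin sizes differ by at most one; ties are broken by stable township-id
    order so the classification is deterministic.
    """
    if len(rates) < 10:
        raise ConfigError("decile classification needs at least 10 townships")
    s = rates.sort_index()
    order = np.lexsort((np.arange(len(s)), s.to_numpy()))
    n = len(s)
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) * 10 // n + 1
    return pd.Series(labels, index=s.index, name="decile")


# ---------------------------------------------------------------------------
# Publication-shaped tables
# ---------------------------------------------------------------------------


def summarize_table1(
    rate_table: pd.DataFrame,
    standard: StandardWeights,
    age_groups: tuple[str, ...] = AGE_GROUPS,
) -> pd.DataFrame:
    """Median (IQR) of township rates per stratum and period.

    Row layout mirrors the conventional incidence table: an age-sex-
    standardized Total row, then per sex an age-standardized row followed
    by one row per age group. Columns: one median and one IQR pair per
    period.
    """
    periods = sorted(rate_table["period"].unique())
    sexes = [s for s in ("male", "female") if s in set(rate_table["sex"])]

    def med_iqr(values) -> tuple[float, float, float]:
        q1, med, q3 = np.quantile(np.asarray(values, dtype=float), [0.25, 0.5, 0.75])
        return round(med, 1), round(q1, 1), round(q3, 1)

    rows = []

    def add_row(label: str, per_period: dict[str, tuple[float, float, float]]):
        row: dict[str, object] = {"characteristic": label}
        for p in periods:
            med, q1, q3 = per_period[p]
            row[f"{p}_median"] = med
            row[f"{p}_q1"] = q1
            row[f"{p}_q3"] = q3
        rows.append(row)

    std_total = standardized_township_rates(rate_table, standard, sex=None)
    add_row(
        "Total",
        {p: med_iqr(std_total.loc[std_total["period"] == p, "rate"]) for p in periods},
    )
    for sex in sexes:
        std_sex = standardized_township_rates(rate_table, standard, sex=sex)
        add_row(
            sex.capitalize(),
            {p: med_iqr(std_sex.loc[std_sex["period"] == p, "rate"]) for p in periods},
        )
        for age in age_groups:
            sub = rate_table[(rate_table["sex"] == sex) & (rate_table["age_group"] == age)]
            if sub.empty:
                raise ConfigError(f"empty stratum ({sex}, {age})")
            add_row(
                f"{sex.capitalize()} {age}",
                {p: med_iqr(sub.loc[sub["period"] == p, "rate"]) for p in periods},
            )
    return pd.DataFrame(rows)


def summarize_table2(
    rate_table: pd.DataFrame,
    standard: StandardWeights,
    age_groups: tuple[str, ...] = AGE_GROUPS,
) -> pd.DataFrame:
    """Geographic inequality table: p10, p90, gap and ratio per stratum-period.

    Same row layout as :func:`summarize_table1`; columns are p10, p90, gap
    and ratio per period.
    """
    periods = sorted(rate_table["period"].unique())
    sexes = [s for s in ("male", "female") if s in set(rate_table["sex"])]
    rows = []

    def add_row(label: str, series_by_period: dict[str, pd.Series]):
        row: dict[str, object] = {"characteristic": label}
        for p in periods:
            s = inequality_metrics(series_by_period[p])
            row[f"{p}_p10"] = s.p10
            row[f"{p}_p90"] = s.p90
            row[f"{p}_gap"] = s.absolute_gap
            row[f"{p}_ratio"] = s.relative_ratio
        rows.append(row)

    std_total = standardized_township_rates(rate_table, standard, sex=None)
    add_row(
        "Total",
        {p: std_total.loc[std_total["period"] == p, "rate"] for p in periods},
    )
    for sex in sexes:
        std_sex = standardized_township_rates(rate_table, standard, sex=sex)
        add_row(
            sex.capitalize(),
            {p: std_sex.loc[std_sex["period"] == p, "rate"] for p in periods},
        )
        for age in age_groups:
            sub = rate_table[(rate_table["sex"] == sex) & (rate_table["age_group"] == age)]
            add_row(
                f"{sex.capitalize()} {age}",
                {p: sub.loc[sub["period"] == p, "rate"] for p in periods},
            )
    return pd.DataFrame(rows)


def percent_change_table(
    rate_table: pd.DataFrame,
    standard: StandardWeights,
    age_groups: tuple[str, ...] = AGE_GROUPS,
) -> pd.DataFrame:
    """Per-township percent change, first period -> last period, per stratum."""
    periods = sorted(rate_table["period"].unique())
    first, last = periods[0], periods[-1]
    frames = []

    def changes(df: pd.DataFrame, label: str) -> pd.DataFrame:
        wide = df.pivot(index="township_id", columns="period", values="rate")
        out = pd.DataFrame(
            {
                "township_id": wide.index,
                "stratum": label,
                "rate_start": wide[first].round(1),
                "rate_end": wide[last].round(1),
                "percent_change": [
                    percent_change(a, b) for a, b in zip(wide[first], wide[last])
                ],
            }
        )
        return out.reset_index(drop=True)

    frames.append(changes(standardized_township_rates(rate_table, standard), "Total"))
    for sex in ("male", "female"):
        if sex not in set(rate_table["sex"]):
            continue
        frames.append(
            changes(
                standardized_township_rates(rate_table, standard, sex=sex),
                sex.capitalize(),
            )
        )
        for age in age_groups:
            sub = rate_table[
                (rate_table["sex"] == sex) & (rate_table["age_group"] == age)
            ][["township_id", "period", "rate"]]
            frames.append(changes(sub, f"{sex.capitalize()} {age}"))
    return pd.concat(frames, ignore_index=True)
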
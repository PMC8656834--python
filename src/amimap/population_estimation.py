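"""Person-years estimation and population-source agreement checks.

Township populations are published only as sex totals; age structure is
published at the district level. Person-years by township x sex x age
group are therefore estimated by proportional allocation: each township
inherits its district's age distribution within sex. Disaggregation
conserves the township totals exactly.

A Bland-Altman comparison of two population sources (e.g. statistical
yearbook vs census) flags districts whose paired difference falls outside
the mean difference +/- 1.96 SD limits of agreement; a flagged district
can be excluded end-to-end as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._common import DEFAULT_PERIODS, ConfigError, period_label, validate_periods


@dataclass
class BlandAltmanResult:
    table: pd.DataFrame  # district_id, mean, diff
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    flagged: list[str]


def disaggregate_population(
    township_totals: pd.DataFrame,
    district_distribution: pd.DataFrame,
    district_of: dict[str, str],
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Estimate person-years per township x sex x age_group x period.

    Parameters
    ----------
    township_totals
        Columns township_id, year, sex, population (or total): annual
        denominator population per township and sex.
    district_distribution
        Columns district_id, sex, age_group, proportion; proportions must
        sum to 1 within each district-sex (tolerance 1e-9).
    district_of
        Township -> district membership.
    periods
        3-year analysis periods; person-years for a period are the sum of
        its three annual populations.
    """
    validate_periods(periods)
    tt = township_totals.rename(columns={"total": "population"}).copy()
    sums = district_distribution.groupby(["district_id", "sex"])["proportion"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        raise ConfigError(
            f"district age distributions must sum to 1; offending: {list(bad.index)[:5]}"
        )
    missing_d = sorted(
        {district_of.get(t) for t in tt["township_id"].unique()}
        - set(district_distribution["district_id"].unique())
        - {None}
    )
    unknown_t = sorted(set(tt["township_id"].unique()) - set(district_of))
    if unknown_t:
        raise ConfigError(f"townships without district membership: {unknown_t[:10]}")
    if missing_d:
        raise ConfigError(f"no age distribution for districts: {missing_d}")

    pmap = {y: period_label(p) for p in periods for y in range(p[0], p[1] + 1)}
    tt["period"] = tt["year"].map(pmap)
    tt = tt.dropna(subset=["period"])
    by_period = tt.groupby(["township_id", "sex", "period"], as_index=False)[
        "population"
    ].sum()
    by_period["district_id"] = by_period["township_id"].map(district_of)
    merged = by_period.merge(district_distribution, on=["district_id", "sex"], how="left")
    merged["person_years"] = merged["population"] * merged["proportion"]
    out = merged[["township_id", "sex", "age_group", "period", "person_years"]]
    if (out["person_years"] < 0).any():
        raise ConfigError("negative person-years produced; check inputs")
    return out.sort_values(["township_id", "sex", "age_group", "period"]).reset_index(
        drop=True
    )


def bland_altman(
    source_a: pd.DataFrame,
    source_b: pd.DataFrame,
    district_of: dict[str, str],
) -> BlandAltmanResult:
    """Bland-Altman agreement between two population sources at district level.

    Both sources carry township-level totals (township_id, population/total,
    optionally year and sex, which are summed over); they are aggregated to
    districts and paired. Differences are a - b. Districts with
    |difference - mean difference| > 1.96 SD are flagged.
    """

    def per_district(df: pd.DataFrame) -> pd.Series:
        d = df.rename(columns={"total": "population"}).copy()
        d["district_id"] = d["township_id"].map(district_of)
        if d["district_id"].isna().any():
            bad = sorted(d.loc[d["district_id"].isna(), "township_id"].unique())
            raise ConfigError(f"townships without district membership: {bad[:10]}")
        return d.groupby("district_id")["population"].sum()

    a = per_district(source_a)
    b = per_district(source_b)
    if set(a.index) != set(b.index):
        raise ConfigError("sources cover different districts")
    if len(a) < 3:
        raise ConfigError("Bland-Altman needs at least 3 districts")
    b = b.reindex(a.index)
    diff = a - b
    mean = (a + b) / 2
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    lower = mean_diff - 1.96 * sd_diff
    upper = mean_diff + 1.96 * sd_diff
    flagged = sorted(diff.index[(diff < lower) | (diff > upper)])
    table = pd.DataFrame(
        {"district_id": a.index, "mean": mean.to_numpy(), "diff": diff.to_numpy()}
    ).reset_index(drop=True)
    return BlandAltmanResult(table, mean_diff, sd_diff, lower, upper, list(flagged))


def exclude_district(
    district_id: str,
    map_,
    counts: pd.DataFrame | None = None,
    person_years: pd.DataFrame | None = None,
    *extra_tables: pd.DataFrame,
):
    """Drop a district's townships from the map and any township-keyed tables.

    Returns (pruned map, pruned counts, pruned person_years, *pruned extras);
    tables passed as None come back as None. Adjacency is pruned so
    downstream spatial fits see only the remaining townships.
    """
    if district_id not in map_.districts:
        raise ConfigError(f"unknown district {district_id!r}")
    keep = {t for t in map_.townships if map_.district_of[t] != district_id}
    new_map = map_.subset(keep)

    def prune(df):
        if df is None:
            return None
        return df[df["township_id"].isin(keep)].reset_index(drop=True)

    out = [new_map, prune(counts), prune(person_years)]
    out.extend(prune(t) for t in extra_tables)
    return tuple(out)
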
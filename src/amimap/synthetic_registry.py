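"""Synthetic city generator for small-area AMI surveillance.

Builds a fully synthetic study region — a lattice of townships grouped into
districts — together with annual populations, true incidence surfaces drawn
from the same spatial model family the analysis fits (log-rate = stratum
baseline + spatially structured field + unstructured noise), and
individual-level hospital-discharge and death-registration records with
injected record-keeping pathologies (same-day transfers, spurious <=1-day
stays, 28-day readmissions, in-hospital deaths recorded in both streams).

Because the ground truth (true rates and true unique event counts per
township stratum) is retained, every downstream stage — record linkage,
population disaggregation, Bayesian smoothing, inequality metrics — can be
tested end-to-end without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._common import (
    AGE_GROUPS,
    DEFAULT_PERIODS,
    SEXES,
    ConfigError,
    parse_age_group,
    period_label,
    validate_periods,
)

# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Median township incidence per 100,000 person-years by (sex, age group),
#: one value per 3-year period. These serve as the generator's stratum
#: baselines and reflect published township-level AMI incidence in a large
#: Chinese megacity over 2007-2018.
DEFAULT_BASELINE_RATES: dict[tuple[str, str], tuple[float, ...]] = {
    ("male", "35-49"): (96.5, 118.8, 137.0, 148.8),
    ("male", "50-64"): (279.8, 317.5, 336.1, 372.6),
    ("male", "65-79"): (686.2, 729.6, 669.3, 645.2),
    ("male", "80+"): (1282.0, 1378.0, 1262.0, 1301.0),
    ("female", "35-49"): (12.2, 12.3, 12.6, 12.3),
    ("female", "50-64"): (85.3, 100.3, 87.2, 83.1),
    ("female", "65-79"): (525.5, 562.9, 500.6, 445.9),
    ("female", "80+"): (1220.0, 1372.0, 1317.0, 1192.0),
}

DX_CODES = ("I21.0", "I21.1", "I21.4", "I21.9", "I22.0", "I22.1", "I22.9")


@dataclass(frozen=True)
class DupProbs:
    """Per-event probabilities of injecting each record-level pathology.

    transfer
        split a hospitalization into a same-day discharge/readmission pair.
    short_stay
        add a spurious <=1-day stay for a new person (not a real event).
    readmission
        add an extra admission <=28 days after a real event's onset.
    dual_death
        record an in-hospital death in the death stream as well as the
        discharge stream (the normal situation in linked registries).

    Defaults for the first three follow the relative frequencies reported
    for a 12-year metropolitan registry (roughly 2.6%, 1.3% and 2.2% of
    events respectively).
    """

    transfer: float = 0.026
    short_stay: float = 0.013
    readmission: float = 0.022
    dual_death: float = 1.0

    def validate(self) -> None:
        for name in ("transfer", "short_stay", "readmission", "dual_death"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"dup_probs.{name}={p} outside [0, 1]")


def _default_log_rates() -> dict[tuple[str, str], tuple[float, ...]]:
    return {
        k: tuple(float(np.log(r / 1e5)) for r in v)
        for k, v in DEFAULT_BASELINE_RATES.items()
    }


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic city.

    baseline_log_rates maps (sex, age_group) to one log-rate per period,
    in events per person-year on the natural-log scale.
    """

    n_districts: int = 16
    townships_per_district: int = 19
    years: tuple[int, int] = (2007, 2018)
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS
    age_groups: tuple[str, ...] = AGE_GROUPS
    sexes: tuple[str, ...] = SEXES
    baseline_log_rates: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=_default_log_rates
    )
    sd_spatial: float = 0.3
    sd_unstructured: float = 0.1
    dup_probs: DupProbs = field(default_factory=DupProbs)
    # case mix
    fatal_fraction: float = 0.3
    out_of_hospital_fatal_fraction: float = 0.3
    # population
    pop_median: float = 33903.0
    pop_sigma: float = 0.82
    male_share: float = 0.5
    age_shares: tuple[float, ...] = (0.55, 0.27, 0.13, 0.05)
    district_age_jitter: float = 0.05
    census_noise_sd: float = 0.01
    discordant_district: str | None = "D01"
    discordant_factor: float = 1.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_districts < 1:
            raise ConfigError("need at least one district")
        if self.n_districts * self.townships_per_district < 2:
            raise ConfigError("need at least 2 townships in total")
        if self.townships_per_district < 2:
            raise ConfigError("need at least 2 townships per district")
        if self.sd_spatial < 0 or self.sd_unstructured < 0:
            raise ConfigError("random-effect standard deviations must be >= 0")
        self.dup_probs.validate()
        for p in (self.fatal_fraction, self.out_of_hospital_fatal_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"fraction {p} outside [0, 1]")
        if len(self.age_shares) != len(self.age_groups):
            raise ConfigError("age_shares must match age_groups")
        if min(self.age_shares) < 0 or abs(sum(self.age_shares) - 1.0) > 1e-9:
            raise ConfigError("age_shares must be non-negative and sum to 1")
        validate_periods(self.periods)
        if (self.years[0], self.years[1]) != (self.periods[0][0], self.periods[-1][1]):
            raise ConfigError("years must span exactly the analysis periods")
        for key, rates in self.baseline_log_rates.items():
            if len(rates) != len(self.periods):
                raise ConfigError(f"baseline_log_rates[{key}] needs one value per period")


# ---------------------------------------------------------------------------
# Township map
# ---------------------------------------------------------------------------


@dataclass
class TownshipMap:
    """Townships on a planar lattice with district membership and adjacency.

    Adjacency is rook (4-neighbour) contiguity between occupied lattice
    cells; it is symmetric and free of self-loops by construction.
    """

    townships: list[str]
    district_of: dict[str, str]
    neighbors: dict[str, set[str]]
    grid: dict[str, tuple[int, int]]

    @property
    def n(self) -> int:
        return len(self.townships)

    @property
    def districts(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.townships:
            seen.setdefault(self.district_of[t], None)
        return list(seen)

    def validate(self) -> None:
        for t, nbrs in self.neighbors.items():
            if t in nbrs:
                raise ConfigError(f"self-loop at {t}")
            for u in nbrs:
                if t not in self.neighbors[u]:
                    raise ConfigError(f"asymmetric adjacency {t}->{u}")

    def adjacency_matrix(self):
        """Symmetric 0/1 adjacency as a scipy CSR matrix in township order."""
        import scipy.sparse as sp

        idx = {t: i for i, t in enumerate(self.townships)}
        rows, cols = [], []
        for t, nbrs in self.neighbors.items():
            for u in nbrs:
                rows.append(idx[t])
                cols.append(idx[u])
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def connected_components(self) -> list[set[str]]:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.townships)
        for t, nbrs in self.neighbors.items():
            g.add_edges_from((t, u) for u in nbrs)
        return [set(c) for c in nx.connected_components(g)]

    def subset(self, keep: set[str]) -> "TownshipMap":
        """Restrict the map to `keep`, pruning adjacency accordingly."""
        ts = [t for t in self.townships if t in keep]
        return TownshipMap(
            townships=ts,
            district_of={t: self.district_of[t] for t in ts},
            neighbors={t: self.neighbors[t] & keep for t in ts},
            grid={t: self.grid[t] for t in ts},
        )

    def to_edgelist(self) -> pd.DataFrame:
        rows = []
        for t in self.townships:
            for u in sorted(self.neighbors[t]):
                if t < u:
                    rows.append((t, u))
        return pd.DataFrame(rows, columns=["township_a", "township_b"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "township_id": self.townships,
                "district_id": [self.district_of[t] for t in self.townships],
                "row": [self.grid[t][0] for t in self.townships],
                "col": [self.grid[t][1] for t in self.townships],
            }
        )


def generate_township_map(config: SyntheticConfig) -> TownshipMap:
    """Lay townships out on a near-square lattice, districts as contiguous runs.

    Cells are filled in boustrophedon (snake) order so that consecutive
    townships — and therefore each district's block of consecutive
    townships — form a connected, contiguous region, and the whole map is
    one connected component.
    """
    config.validate()
    n = config.n_districts * config.townships_per_district
    ncol = int(np.ceil(np.sqrt(n)))
    townships = [f"T{i + 1:03d}" for i in range(n)]
    grid: dict[str, tuple[int, int]] = {}
    occupied: dict[tuple[int, int], str] = {}
    for i, t in enumerate(townships):
        r, k = divmod(i, ncol)
        c = k if r % 2 == 0 else ncol - 1 - k  # snake rows
        grid[t] = (r, c)
        occupied[(r, c)] = t
    neighbors: dict[str, set[str]] = {t: set() for t in townships}
    for (r, c), t in occupied.items():
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            u = occupied.get((r + dr, c + dc))
            if u is not None:
                neighbors[t].add(u)
    district_of = {
        t: f"D{i // config.townships_per_district + 1:02d}"
        for i, t in enumerate(townships)
    }
    m = TownshipMap(townships, district_of, neighbors, grid)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# True incidence surfaces
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """True rates (per 100,000 person-years) and, after event generation,
    true unique event counts per township x sex x age_group x period."""

    rates: pd.DataFrame  # township_id, sex, age_group, period, true_rate
    u: pd.Series  # structured spatial effect per township
    v: pd.Series  # unstructured effect per township
    counts: pd.DataFrame | None = None  # filled by generate_events
    person_years: pd.DataFrame | None = None


def simulate_icar_field(map_: TownshipMap, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a zero-mean spatially correlated field over the map.

    The field is sampled from the intrinsic CAR distribution restricted to
    the non-null eigenspace of the graph Laplacian (covariance = Laplacian
    pseudo-inverse), then rescaled so its empirical standard deviation
    equals `sd` and recentred to sum to zero. With sd = 0 the field is
    identically zero.
    """
    n = map_.n
    if sd == 0 or n < 2:
        return np.zeros(n)
    if len(map_.connected_components()) != 1:
        raise ConfigError("ICAR field simulation requires a connected map")
    a = map_.adjacency_matrix().toarray()
    lap = np.diag(a.sum(axis=1)) - a
    lam, vec = np.linalg.eigh(lap)
    keep = lam > 1e-8  # drop the null (constant) eigenvector
    z = rng.standard_normal(keep.sum())
    u = vec[:, keep] @ (z / np.sqrt(lam[keep]))
    u -= u.mean()
    s = u.std()
    if s > 0:
        u *= sd / s
    return u


def generate_true_rates(config: SyntheticConfig, map_: TownshipMap) -> GroundTruth:
    """True log-rate = stratum baseline + u_i + v_i.

    A single structured field u and unstructured field v are shared across
    strata, so the geographic risk pattern is common to all age-sex groups
    — the analogue of a city whose high-risk areas are high-risk for
    everyone. Both fields sum to zero and have empirical standard
    deviations sd_spatial and sd_unstructured exactly.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 101])
    rng = np.random.default_rng(ss)
    u = simulate_icar_field(map_, config.sd_spatial, rng)
    if config.sd_unstructured > 0 and map_.n > 1:
        v = rng.standard_normal(map_.n)
        v -= v.mean()
        s = v.std()
        if s > 0:
            v *= config.sd_unstructured / s
    else:
        v = np.zeros(map_.n)
    rows = []
    for (sex, age), logr in config.baseline_log_rates.items():
        for p_i, period in enumerate(config.periods):
            rate = np.exp(logr[p_i] + u + v) * 1e5
            for t_i, t in enumerate(map_.townships):
                rows.append((t, sex, age, period_label(period), rate[t_i]))
    rates = pd.DataFrame(
        rows, columns=["township_id", "sex", "age_group", "period", "true_rate"]
    )
    return GroundTruth(
        rates=rates,
        u=pd.Series(u, index=map_.townships, name="u"),
        v=pd.Series(v, index=map_.townships, name="v"),
    )


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


@dataclass
class PopulationData:
    """Yearbook-style township totals, district age-sex distributions, and a
    census-like second source for agreement checking."""

    township_year_sex: pd.DataFrame  # township_id, year, sex, population
    district_age_sex: pd.DataFrame  # district_id, sex, age_group, proportion
    census_township_year_sex: pd.DataFrame  # same schema, census year only
    census_year: int = 2010


def generate_population(config: SyntheticConfig, map_: TownshipMap) -> PopulationData:
    """Draw township populations and district age structures.

    Township totals (residents aged >=35, the study's denominator
    population) are log-normal around `pop_median`; sex split near
    `male_share`; the district age distribution applies exactly within
    every township of the district, so proportional disaggregation is
    exact by construction. A census-like copy of the totals is perturbed
    by small multiplicative noise and one deliberately discordant district
    whose yearbook total is `discordant_factor` times its census total.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = map_.n
    totals = config.pop_median * np.exp(config.pop_sigma * rng.standard_normal(n))
    male = np.clip(config.male_share + 0.01 * rng.standard_normal(n), 0.3, 0.7)
    years = range(config.years[0], config.years[1] + 1)
    rows = []
    for t_i, t in enumerate(map_.townships):
        for year in years:
            for sex, share in (("male", male[t_i]), ("female", 1 - male[t_i])):
                rows.append((t, year, sex, totals[t_i] * share))
    tys = pd.DataFrame(rows, columns=["township_id", "year", "sex", "population"])

    shares = np.asarray(config.age_shares)
    drows = []
    for d in map_.districts:
        for sex in config.sexes:
            s = shares * np.exp(config.district_age_jitter * rng.standard_normal(len(shares)))
            s /= s.sum()
            for age, prop in zip(config.age_groups, s):
                drows.append((d, sex, age, prop))
    das = pd.DataFrame(drows, columns=["district_id", "sex", "age_group", "proportion"])

    cen = tys[tys["year"] == 2010].copy()
    if config.census_noise_sd > 0:
        cen["population"] *= np.exp(
            config.census_noise_sd * rng.standard_normal(len(cen))
        )
    if config.discordant_district is not None:
        if config.discordant_district not in map_.districts:
            raise ConfigError(
                f"discordant district {config.discordant_district!r} not on the map"
            )
        in_d = cen["township_id"].map(map_.district_of) == config.discordant_district
        cen.loc[in_d, "population"] /= config.discordant_factor
    return PopulationData(tys, das, cen.reset_index(drop=True), census_year=2010)


def true_person_years(
    config: SyntheticConfig, map_: TownshipMap, pop: PopulationData
) -> pd.DataFrame:
    """Exact person-years per township x sex x age_group x period.

    Townships inherit their district's age distribution exactly, so this is
    both the generator's truth and what proportional disaggregation yields.
    """
    tys = pop.township_year_sex.copy()
    pmap = {y: period_label(p) for p in config.periods for y in range(p[0], p[1] + 1)}
    tys["period"] = tys["year"].map(pmap)
    by_period = (
        tys.groupby(["township_id", "sex", "period"], as_index=False)["population"].sum()
    )
    by_period["district_id"] = by_period["township_id"].map(map_.district_of)
    merged = by_period.merge(pop.district_age_sex, on=["district_id", "sex"])
    merged["person_years"] = merged["population"] * merged["proportion"]
    return merged[["township_id", "sex", "age_group", "period", "person_years"]]


# ---------------------------------------------------------------------------
# Individual records
# ---------------------------------------------------------------------------


def _uniform_dates(rng, period: tuple[int, int], size: int) -> np.ndarray:
    start = np.datetime64(f"{period[0]}-01-01")
    end = np.datetime64(f"{period[1]}-12-31")
    span = int((end - start) / np.timedelta64(1, "D")) + 1
    return start + rng.integers(0, span, size=size).astype("timedelta64[D]")


def generate_events(
    config: SyntheticConfig,
    truth: GroundTruth,
    pop: PopulationData,
    map_: TownshipMap,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Materialise disease events as hospital and death records.

    Per stratum the number of distinct disease events is Poisson(true_rate
    x person-years). Each event becomes:

    * non-fatal           -> one hospitalization (length of stay >= 2 days);
    * fatal, in hospital  -> hospitalization with died status, plus (with
      probability dup_probs.dual_death) a matching in-hospital death record;
    * fatal, out of hospital -> a death record only.

    Record-level noise is then injected per dup_probs: same-day transfer
    splits, spurious <=1-day stays for phantom persons, and readmissions
    within 28 days of onset. Ground-truth unique event counts (and the
    person-years used) are stored on `truth`.

    Returns (hospital_records, death_records, true_counts).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    py = true_person_years(config, map_, pop)
    strat = truth.rates.merge(
        py, on=["township_id", "sex", "age_group", "period"], how="left"
    )
    if strat["person_years"].isna().any() or (strat["person_years"] <= 0).any():
        raise ConfigError("person-years must be positive for every stratum")
    mu = strat["true_rate"] / 1e5 * strat["person_years"]
    strat["count"] = rng.poisson(mu)
    truth.counts = strat[
        ["township_id", "sex", "age_group", "period", "count"]
    ].rename(columns={"count": "true_unique_event_count"})
    truth.person_years = py

    # expand strata into one row per event
    ev = strat.loc[strat.index.repeat(strat["count"])].reset_index(drop=True)
    n_ev = len(ev)
    per_label = {period_label(p): p for p in config.periods}
    onset = np.empty(n_ev, dtype="datetime64[D]")
    for lbl, p in per_label.items():
        m = (ev["period"] == lbl).to_numpy()
        onset[m] = _uniform_dates(rng, p, int(m.sum()))
    bounds = {g: parse_age_group(g) for g in config.age_groups}
    lo = ev["age_group"].map(lambda g: bounds[g][0]).to_numpy()
    hi = ev["age_group"].map(lambda g: min(bounds[g][1], 95)).to_numpy()
    age = rng.integers(lo, hi + 1)
    fatal = rng.random(n_ev) < config.fatal_fraction
    ooh = fatal & (rng.random(n_ev) < config.out_of_hospital_fatal_fraction)
    los = 2 + rng.poisson(6.0, n_ev)  # true events always stay >1 day
    person = np.array([f"P{i + 1:07d}" for i in range(n_ev)])
    dx = rng.choice(DX_CODES, size=n_ev)

    hosp_mask = ~ooh
    hosp_rows = {
        "person_id": person[hosp_mask],
        "admission_date": onset[hosp_mask],
        "discharge_date": onset[hosp_mask] + los[hosp_mask].astype("timedelta64[D]"),
        "discharge_status": np.where(fatal[hosp_mask], "died", "alive"),
        "dx_code": dx[hosp_mask],
        "age": age[hosp_mask],
        "sex": ev["sex"].to_numpy()[hosp_mask],
        "township_id": ev["township_id"].to_numpy()[hosp_mask],
    }
    hospital = pd.DataFrame(hosp_rows)

    death_frames = []
    # out-of-hospital deaths: death record only
    death_frames.append(
        pd.DataFrame(
            {
                "person_id": person[ooh],
                "death_date": onset[ooh],
                "place": "out_of_hospital",
                "cause_code": dx[ooh],
                "age": age[ooh],
                "sex": ev["sex"].to_numpy()[ooh],
                "township_id": ev["township_id"].to_numpy()[ooh],
            }
        )
    )
    # dual-recorded in-hospital deaths
    inhosp_fatal = fatal & ~ooh
    dual = inhosp_fatal & (rng.random(n_ev) < config.dup_probs.dual_death)
    death_frames.append(
        pd.DataFrame(
            {
                "person_id": person[dual],
                "death_date": onset[dual] + los[dual].astype("timedelta64[D]"),
                "place": "in_hospital",
                "cause_code": dx[dual],
                "age": age[dual],
                "sex": ev["sex"].to_numpy()[dual],
                "township_id": ev["township_id"].to_numpy()[dual],
            }
        )
    )

    extra_hosp = [hospital]

    # transfers: split a stay into a same-day discharge/readmission pair
    tr = rng.random(len(hospital)) < config.dup_probs.transfer
    if tr.any():
        idx = np.flatnonzero(tr)
        h = hospital.iloc[idx]
        stay = (
            (h["discharge_date"].to_numpy() - h["admission_date"].to_numpy())
            / np.timedelta64(1, "D")
        ).astype(int)
        cut = rng.integers(1, stay)  # stay >= 2 guaranteed for true events
        mid = h["admission_date"].to_numpy() + cut.astype("timedelta64[D]")
        first = h.copy()
        first["discharge_date"] = mid
        first["discharge_status"] = "alive"
        second = h.copy()
        second["admission_date"] = mid
        hospital = pd.concat(
            [hospital.drop(index=hospital.index[idx])], ignore_index=True
        )
        extra_hosp = [hospital, first, second]

    # spurious <=1-day stays for phantom persons: pass eligibility, carry no
    # death and no readmission, so linkage must exclude them
    n_spur = rng.binomial(n_ev, config.dup_probs.short_stay) if n_ev else 0
    if n_spur > 0:
        pick = rng.integers(0, n_ev, n_spur)
        adm = onset[pick] + rng.integers(-30, 31, n_spur).astype("timedelta64[D]")
        extra_hosp.append(
            pd.DataFrame(
                {
                    "person_id": np.array([f"S{i + 1:07d}" for i in range(n_spur)]),
                    "admission_date": adm,
                    "discharge_date": adm
                    + rng.integers(0, 2, n_spur).astype("timedelta64[D]"),
                    "discharge_status": "alive",
                    "dx_code": rng.choice(DX_CODES, size=n_spur),
                    "age": age[pick],
                    "sex": ev["sex"].to_numpy()[pick],
                    "township_id": ev["township_id"].to_numpy()[pick],
                }
            )
        )

    # readmissions within 28 days of a hospitalized event's onset
    re_mask = hosp_mask & (rng.random(n_ev) < config.dup_probs.readmission)
    if re_mask.any():
        gap = rng.integers(2, 29, int(re_mask.sum())).astype("timedelta64[D]")
        adm = onset[re_mask] + gap
        extra_hosp.append(
            pd.DataFrame(
                {
                    "person_id": person[re_mask],
                    "admission_date": adm,
                    "discharge_date": adm
                    + (2 + rng.poisson(3.0, int(re_mask.sum()))).astype(
                        "timedelta64[D]"
                    ),
                    "discharge_status": "alive",
                    "dx_code": dx[re_mask],
                    "age": age[re_mask],
                    "sex": ev["sex"].to_numpy()[re_mask],
                    "township_id": ev["township_id"].to_numpy()[re_mask],
                }
            )
        )

    hospital = pd.concat(extra_hosp, ignore_index=True)
    deaths = pd.concat(death_frames, ignore_index=True)
    # shuffle so downstream code cannot rely on generation order
    hospital = hospital.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    deaths = deaths.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    return hospital, deaths, truth.counts.copy()


# ---------------------------------------------------------------------------
# One-call generation and writers
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCity:
    config: SyntheticConfig
    map: TownshipMap
    truth: GroundTruth
    population: PopulationData
    hospital: pd.DataFrame
    deaths: pd.DataFrame


def generate_city(config: SyntheticConfig) -> SyntheticCity:
    """Generate map, truth, population and records in one deterministic call."""
    map_ = generate_township_map(config)
    truth = generate_true_rates(config, map_)
    pop = generate_population(config, map_)
    hospital, deaths, _ = generate_events(config, truth, pop, map_)
    return SyntheticCity(config, map_, truth, pop, hospital, deaths)


def map_to_geojson(map_: TownshipMap, properties: pd.DataFrame | None = None) -> dict:
    """Unit-square lattice cells as a GeoJSON FeatureCollection.

    `properties` (indexed by township_id) adds per-township attributes such
    as decile classes to each feature.
    """
    props = properties if properties is not None else pd.DataFrame(index=map_.townships)
    features = []
    for t in map_.townships:
        r, c = map_.grid[t]
        ring = [[c, -r], [c + 1, -r], [c + 1, -r - 1], [c, -r - 1], [c, -r]]
        p = {"township_id": t, "district_id": map_.district_of[t]}
        if t in props.index:
            p.update({k: _jsonable(v) for k, v in props.loc[t].items()})
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": p,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def _jsonable(v):
    if isinstance(v, np.bool_):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return v


def write_city(city: SyntheticCity, outdir: str | Path) -> dict[str, Path]:
    """Write all synthetic inputs as plain-text files; returns path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hospital": out / "hospital_records.csv",
        "deaths": out / "death_records.csv",
        "population": out / "population.csv",
        "district_distribution": out / "district_distribution.csv",
        "census_population": out / "census_population.csv",
        "adjacency": out / "adjacency.csv",
        "townships": out / "townships.csv",
        "geojson": out / "map.geojson",
        "ground_truth": out / "ground_truth.json",
    }
    city.hospital.to_csv(paths["hospital"], index=False)
    city.deaths.to_csv(paths["deaths"], index=False)
    city.population.township_year_sex.rename(columns={"population": "total"}).to_csv(
        paths["population"], index=False
    )
    city.population.district_age_sex.to_csv(paths["district_distribution"], index=False)
    city.population.census_township_year_sex.rename(
        columns={"population": "total"}
    ).to_csv(paths["census_population"], index=False)
    city.map.to_edgelist().to_csv(paths["adjacency"], index=False)
    city.map.to_frame().to_csv(paths["townships"], index=False)
    with open(paths["geojson"], "w") as fh:
        json.dump(map_to_geojson(city.map), fh)
    gt = {
        "seed": city.config.seed,
        "rates": city.truth.rates.to_dict(orient="list"),
        "counts": city.truth.counts.to_dict(orient="list"),
        "u": city.truth.u.to_dict(),
        "v": city.truth.v.to_dict(),
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(gt, fh)
    return paths


def morans_i(values: np.ndarray, adjacency) -> float:
    """Moran's I spatial autocorrelation with binary weights."""
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    w = adjacency
    num = float(z @ (w @ z))
    den = float(z @ z)
    s0 = float(w.sum())
    return len(x) / s0 * num / den
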
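"""Record linkage: raw hospitalization + death records -> unique AMI events.

Four deduplication rules, applied in order:

1. same-day merge — records where one discharge date equals the next
   admission date for the same person (transfers) are collapsed into a
   single continuous care episode;
2. short-stay exclusion — single-record episodes with a total length of
   stay <= 1 day, no death on the same day and no chained readmission are
   excluded as unlikely true AMI;
3. in-hospital death linkage — a death record falling inside an episode's
   stay window for the same person is absorbed into that episode (one
   hospitalized fatal case, not two events); unmatched death records
   become out-of-hospital (death-only) events;
4. 28-day collapse — following the WHO-MONICA convention, any admission or
   death for the same person with onset within 28 days of an index event's
   onset counts as the same coronary event. The window is anchored at the
   index onset, not rolled forward.

Eligibility (principal diagnosis / underlying cause ICD-10 I21-I22, age
>= 35) is applied per stream before any merging. Every rule reports how
many records it removed or merged (the audit trail).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._common import (
    AGE_GROUPS,
    DEFAULT_PERIODS,
    LinkageError,
    age_group_of,
    period_of,
)

ELIGIBLE_PREFIXES = ("I21", "I22")

HOSPITAL_COLUMNS = [
    "person_id",
    "admission_date",
    "discharge_date",
    "discharge_status",
    "dx_code",
    "age",
    "sex",
    "township_id",
]
DEATH_COLUMNS = [
    "person_id",
    "death_date",
    "place",
    "cause_code",
    "age",
    "sex",
    "township_id",
]


@dataclass
class LinkageAudit:
    """Counts of what each deduplication rule removed or merged."""

    n_input_hospital: int = 0
    n_input_death: int = 0
    n_dropped_by_reason: dict = field(default_factory=dict)
    n_merged_same_day: int = 0
    n_overlap_flagged: int = 0
    n_excluded_short_stay: int = 0
    n_dual_recorded_deaths: int = 0
    n_ambiguous_death_links: int = 0
    n_collapsed_28day: int = 0
    n_final_events: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LinkageResult:
    events: pd.DataFrame
    episodes: pd.DataFrame
    audit: LinkageAudit


# ---------------------------------------------------------------------------
# IO helpers (tolerant of extra columns)
# ---------------------------------------------------------------------------


def read_hospital_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["admission_date", "discharge_date"])
    missing = set(HOSPITAL_COLUMNS) - set(df.columns)
    if missing:
        raise LinkageError(f"hospital file missing columns: {sorted(missing)}")
    return df


def read_death_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["death_date"])
    missing = set(DEATH_COLUMNS) - set(df.columns)
    if missing:
        raise LinkageError(f"death file missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Rule 0: eligibility
# ---------------------------------------------------------------------------


def _code_ok(codes: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Return (eligible, malformed) boolean masks for an ICD-10 code column."""
    s = codes.astype("string")
    wellformed = s.str.match(r"^[A-Z]\d{2}", na=False)
    eligible = wellformed & s.str.startswith(ELIGIBLE_PREFIXES, na=False)
    return eligible.fillna(False).astype(bool), (~wellformed).astype(bool)


def filter_eligible(
    hospital: pd.DataFrame, deaths: pd.DataFrame, min_age: int = 35
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Keep I21-I22 records for residents aged >= `min_age`.

    Each stream is filtered on its own code field (principal discharge
    diagnosis / underlying cause); no cross-stream veto. Malformed codes
    are rejected and counted separately.
    """
    drops: dict[str, int] = {}
    h_ok, h_bad = _code_ok(hospital["dx_code"])
    d_ok, d_bad = _code_ok(deaths["cause_code"])
    h_age = hospital["age"] >= min_age
    d_age = deaths["age"] >= min_age
    drops["hospital_malformed_code"] = int(h_bad.sum())
    drops["hospital_not_i21_i22"] = int((~h_ok & ~h_bad).sum())
    drops["hospital_under_age"] = int((h_ok & ~h_age).sum())
    drops["death_malformed_code"] = int(d_bad.sum())
    drops["death_not_i21_i22"] = int((~d_ok & ~d_bad).sum())
    drops["death_under_age"] = int((d_ok & ~d_age).sum())
    return (
        hospital[h_ok & h_age].reset_index(drop=True),
        deaths[d_ok & d_age].reset_index(drop=True),
        drops,
    )


# ---------------------------------------------------------------------------
# Rule 1: same-day transfer merge
# ---------------------------------------------------------------------------


def merge_same_day_episodes(hospital: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-day discharge/readmission chains into episodes.

    Per person, records sorted by admission date chain together whenever
    the next admission is on or before the running maximum discharge date
    (equality = transfer; strictly before = overlapping stays, which are
    merged and flagged). total_los is the sum of the constituent stays'
    lengths in days; fatal if any constituent record has died status.
    """
    cols = [
        "episode_id",
        "person_id",
        "onset_date",
        "end_date",
        "total_los",
        "fatal",
        "n_records",
        "overlap",
        "township_id",
        "age",
        "sex",
        "source",
    ]
    if hospital.empty:
        return pd.DataFrame(columns=cols)
    h = hospital.sort_values(
        ["person_id", "admission_date", "discharge_date"], kind="mergesort"
    ).reset_index(drop=True)
    if (h["discharge_date"] < h["admission_date"]).any():
        raise LinkageError("discharge before admission")
    run_max = h.groupby("person_id", sort=False)["discharge_date"].cummax()
    prev_max = run_max.shift(1)
    new_person = h["person_id"].ne(h["person_id"].shift(1))
    new_episode = new_person | (h["admission_date"] > prev_max)
    h["episode_id"] = new_episode.cumsum()
    h["overlap"] = ~new_episode & (h["admission_date"] < prev_max)
    h["los"] = (h["discharge_date"] - h["admission_date"]).dt.days
    h["died"] = h["discharge_status"].eq("died")
    ep = h.groupby("episode_id", sort=True).agg(
        person_id=("person_id", "first"),
        onset_date=("admission_date", "min"),
        end_date=("discharge_date", "max"),
        total_los=("los", "sum"),
        fatal=("died", "any"),
        n_records=("los", "size"),
        overlap=("overlap", "any"),
        township_id=("township_id", "first"),
        age=("age", "first"),
        sex=("sex", "first"),
    )
    ep["source"] = "hospital"
    return ep.reset_index()


# ---------------------------------------------------------------------------
# Rule 2: short-stay exclusion
# ---------------------------------------------------------------------------


def exclude_short_stays(
    episodes: pd.DataFrame, deaths: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Drop episodes with total stay <= 1 day, no death, no readmission.

    An episode survives if it is fatal, has a death record dated inside
    its stay window, or was chained from more than one record (i.e. it had
    a readmission) — only isolated, non-fatal <=1-day stays are excluded.
    """
    if episodes.empty:
        return episodes, 0
    has_death = _death_within_window(episodes, deaths)
    drop = (
        (episodes["total_los"] <= 1)
        & ~episodes["fatal"]
        & ~has_death
        & (episodes["n_records"] == 1)
    )
    return episodes[~drop].reset_index(drop=True), int(drop.sum())


def _death_within_window(episodes: pd.DataFrame, deaths: pd.DataFrame) -> pd.Series:
    """Boolean per episode: person has a death record dated within the stay."""
    if deaths.empty:
        return pd.Series(False, index=episodes.index)
    m = episodes[["episode_id", "person_id", "onset_date", "end_date"]].merge(
        deaths[["person_id", "death_date"]], on="person_id", how="left"
    )
    hit = (m["death_date"] >= m["onset_date"]) & (m["death_date"] <= m["end_date"])
    by_ep = hit.groupby(m["episode_id"]).any()
    return episodes["episode_id"].map(by_ep).fillna(False).astype(bool)


# ---------------------------------------------------------------------------
# Rule 3: in-hospital death linkage
# ---------------------------------------------------------------------------


def link_in_hospital_deaths(
    episodes: pd.DataFrame, deaths: pd.DataFrame
) -> tuple[pd.DataFrame, int, int]:
    """Absorb in-window death records; unmatched deaths become events.

    Returns (unified episodes, n_absorbed, n_ambiguous). A death record
    whose date lies within [onset, end] of an episode of the same person
    marks that episode fatal and is not counted separately. Each remaining
    death record becomes a death-only episode with onset = death date.
    """
    cols = list(episodes.columns)
    if deaths.empty:
        return episodes.copy(), 0, 0
    d = deaths.reset_index(drop=True).rename_axis("death_idx").reset_index()
    if episodes.empty:
        matched = pd.DataFrame(columns=["death_idx", "episode_id"])
    else:
        m = d.merge(
            episodes[["episode_id", "person_id", "onset_date", "end_date"]],
            on="person_id",
            how="inner",
        )
        inside = (m["death_date"] >= m["onset_date"]) & (
            m["death_date"] <= m["end_date"]
        )
        matched = m[inside].sort_values(["death_idx", "onset_date"])
    n_ambiguous = int(matched.duplicated("death_idx").sum())
    matched = matched.drop_duplicates("death_idx", keep="first")
    n_absorbed = len(matched)

    out = episodes.copy()
    fatal_eps = set(matched["episode_id"]) if n_absorbed else set()
    if fatal_eps:
        out.loc[out["episode_id"].isin(fatal_eps), "fatal"] = True

    unmatched = d[~d["death_idx"].isin(matched["death_idx"])]
    if len(unmatched):
        next_id = int(out["episode_id"].max()) + 1 if len(out) else 1
        extra = pd.DataFrame(
            {
                "episode_id": np.arange(next_id, next_id + len(unmatched)),
                "person_id": unmatched["person_id"].to_numpy(),
                "onset_date": unmatched["death_date"].to_numpy(),
                "end_date": unmatched["death_date"].to_numpy(),
                "total_los": 0,
                "fatal": True,
                "n_records": 1,
                "overlap": False,
                "township_id": unmatched["township_id"].to_numpy(),
                "age": unmatched["age"].to_numpy(),
                "sex": unmatched["sex"].to_numpy(),
                "source": "death_only",
            }
        )
        out = (
            extra[cols]
            if out.empty
            else pd.concat([out[cols], extra[cols]], ignore_index=True)
        )
    return out.reset_index(drop=True), n_absorbed, n_ambiguous


# ---------------------------------------------------------------------------
# Rule 4: 28-day collapse (WHO-MONICA)
# ---------------------------------------------------------------------------


def apply_28day_rule(
    episodes: pd.DataFrame, window_days: int = 28
) -> tuple[pd.DataFrame, int]:
    """Greedy anchored collapse of episodes into events.

    Per person, the earliest episode opens an event; every later episode
    whose onset is within `window_days` of the open event's onset merges
    into it (the event is fatal if any member is). An episode starting
    more than `window_days` after the anchor opens a new event. Event
    attributes (onset, township, age, sex) come from the anchor episode.
    """
    cols = ["person_id", "onset_date", "fatal", "township_id", "age", "sex", "source"]
    if episodes.empty:
        return pd.DataFrame(columns=cols), 0
    ep = episodes.sort_values(["person_id", "onset_date"], kind="mergesort").reset_index(
        drop=True
    )
    counts = ep["person_id"].value_counts()
    multi_persons = set(counts[counts > 1].index)
    single = ep[~ep["person_id"].isin(multi_persons)]
    events = [single[cols]]

    n_collapsed = 0
    if multi_persons:
        multi = ep[ep["person_id"].isin(multi_persons)].reset_index(drop=True)
        onset_days = multi["onset_date"].to_numpy().astype("datetime64[D]").astype(int)
        pid = multi["person_id"].to_numpy()
        fatal = multi["fatal"].to_numpy()
        attrs = multi[cols].to_numpy(dtype=object)
        rows = []
        i, n = 0, len(multi)
        while i < n:
            j = i
            any_fatal = False
            while j < n and pid[j] == pid[i] and onset_days[j] - onset_days[i] <= window_days:
                any_fatal = bool(any_fatal or fatal[j])
                j += 1
            rec = attrs[i].copy()
            rec[2] = any_fatal
            rows.append(rec)
            n_collapsed += j - i - 1
            i = j
        events.append(pd.DataFrame(rows, columns=cols))
    out = pd.concat(events, ignore_index=True)[cols]
    return out.sort_values(["person_id", "onset_date"]).reset_index(drop=True), n_collapsed


# ---------------------------------------------------------------------------
# Full pipeline and aggregation
# ---------------------------------------------------------------------------


def link_events(
    hospital: pd.DataFrame,
    deaths: pd.DataFrame,
    window_days: int = 28,
    min_age: int = 35,
) -> LinkageResult:
    """Run eligibility + all four deduplication rules, with audit trail."""
    audit = LinkageAudit(n_input_hospital=len(hospital), n_input_death=len(deaths))
    h, d, drops = filter_eligible(hospital, deaths, min_age=min_age)
    audit.n_dropped_by_reason = drops
    episodes = merge_same_day_episodes(h)
    audit.n_merged_same_day = len(h) - len(episodes)
    audit.n_overlap_flagged = int(episodes["overlap"].sum()) if len(episodes) else 0
    episodes, n_short = exclude_short_stays(episodes, d)
    audit.n_excluded_short_stay = n_short
    episodes, n_dual, n_amb = link_in_hospital_deaths(episodes, d)
    audit.n_dual_recorded_deaths = n_dual
    audit.n_ambiguous_death_links = n_amb
    events, n_collapsed = apply_28day_rule(episodes, window_days=window_days)
    audit.n_collapsed_28day = n_collapsed
    audit.n_final_events = len(events)
    return LinkageResult(events=events, episodes=episodes, audit=audit)


def aggregate_events(
    events: pd.DataFrame,
    townships: list[str],
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS,
    age_groups: tuple[str, ...] = AGE_GROUPS,
    sexes: tuple[str, ...] = ("male", "female"),
) -> pd.DataFrame:
    """Count events per township x sex x age_group x period (full grid).

    Events reference the map's townships; unknown township ids raise a
    LinkageError listing them. Events with onset outside every analysis
    period raise as well — the caller decides what to drop, not this
    function.
    """
    known = set(townships)
    full = pd.MultiIndex.from_product(
        [townships, sexes, age_groups, [f"{a}-{b}" for a, b in periods]],
        names=["township_id", "sex", "age_group", "period"],
    )
    if events.empty:
        return full.to_frame(index=False).assign(count=0)
    bad = sorted(set(events["township_id"]) - known)
    if bad:
        raise LinkageError(f"events reference unknown townships: {bad[:10]}")
    ev = events.copy()
    ev["age_group"] = ev["age"].map(lambda a: age_group_of(int(a), age_groups))
    ev["period"] = pd.to_datetime(ev["onset_date"]).dt.year.map(
        lambda y: period_of(int(y), periods)
    )
    if ev["period"].isna().any():
        n = int(ev["period"].isna().sum())
        raise LinkageError(f"{n} events fall outside every analysis period")
    if ev["age_group"].isna().any():
        n = int(ev["age_group"].isna().sum())
        raise LinkageError(f"{n} events fall outside every age group")
    counts = (
        ev.groupby(["township_id", "sex", "age_group", "period"])
        .size()
        .reindex(full, fill_value=0)
        .rename("count")
        .reset_index()
    )
    return counts
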
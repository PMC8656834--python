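"""Brute-force reference implementation of the four deduplication rules.

Deliberately naive and structurally independent of the pipeline: episodes
are built by fixed-point merging over the interval-connectivity graph of a
person's stays, and the 28-day collapse is a recursive removal of the
anchored window, not a sort-and-scan. Used only as a test oracle.
"""

from __future__ import annotations

import datetime as dt


def _eligible(code: str, age: int, min_age: int) -> bool:
    if not isinstance(code, str) or len(code) < 3:
        return False
    if not (code[0].isalpha() and code[1:3].isdigit()):
        return False
    return code.startswith(("I21", "I22")) and age >= min_age


def brute_force_event_count(
    hosp_rows, death_rows, window_days: int = 28, min_age: int = 35
) -> int:
    """Number of unique events for ONE person's records.

    hosp_rows: (person, adm, disch, status, code, age) tuples (ISO dates);
    death_rows: (person, date, place, code, age) tuples.
    """

    def d(s):
        return dt.date.fromisoformat(str(s)[:10])

    stays = [
        {"adm": d(r[1]), "dis": d(r[2]), "died": r[3] == "died"}
        for r in hosp_rows
        if _eligible(r[4], r[5], min_age)
    ]
    deaths = [{"day": d(r[1])} for r in death_rows if _eligible(r[3], r[4], min_age)]

    # rule 1: merge stays whose intervals touch or overlap, to a fixed point
    episodes = [
        {"stays": [s], "onset": s["adm"], "end": s["dis"], "fatal": s["died"]}
        for s in stays
    ]
    changed = True
    while changed:
        changed = False
        for i in range(len(episodes)):
            for j in range(i + 1, len(episodes)):
                a, b = episodes[i], episodes[j]
                if a["onset"] <= b["end"] and b["onset"] <= a["end"]:
                    a["stays"] += b["stays"]
                    a["onset"] = min(a["onset"], b["onset"])
                    a["end"] = max(a["end"], b["end"])
                    a["fatal"] = a["fatal"] or b["fatal"]
                    del episodes[j]
                    changed = True
                    break
            if changed:
                break

    # rule 2: drop isolated non-fatal <=1-day episodes without same-day death
    def keep(ep):
        los = sum((s["dis"] - s["adm"]).days for s in ep["stays"])
        if los > 1 or ep["fatal"] or len(ep["stays"]) > 1:
            return True
        return any(ep["onset"] <= x["day"] <= ep["end"] for x in deaths)

    episodes = [ep for ep in episodes if keep(ep)]

    # rule 3: absorb in-window deaths, leftover deaths become episodes
    for x in deaths:
        hit = [ep for ep in episodes if ep["onset"] <= x["day"] <= ep["end"]]
        if hit:
            hit[0]["fatal"] = True
        else:
            episodes.append(
                {"stays": [], "onset": x["day"], "end": x["day"], "fatal": True}
            )

    # rule 4: recursively strip the anchored 28-day window
    def collapse(onsets):
        if not onsets:
            return 0
        anchor = min(onsets)
        rest = [o for o in onsets if (o - anchor).days > window_days]
        return 1 + collapse(rest)

    return collapse([ep["onset"] for ep in episodes])
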
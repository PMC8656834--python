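"""Shared vocabulary: age groups, sexes, analysis periods, error types."""

from __future__ import annotations

AGE_GROUPS: tuple[str, ...] = ("35-49", "50-64", "65-79", "80+")
SEXES: tuple[str, ...] = ("male", "female")

#: Four consecutive 3-year analysis periods covering 2007-2018.
DEFAULT_PERIODS: tuple[tuple[int, int], ...] = (
    (2007, 2009),
    (2010, 2012),
    (2013, 2015),
    (2016, 2018),
)


class ConfigError(ValueError):
    """Invalid configuration or malformed input tables."""


class LinkageError(ValueError):
    """Record streams violate a linkage precondition."""


def period_label(period: tuple[int, int]) -> str:
    return f"{period[0]}-{period[1]}"


def parse_age_group(label: str) -> tuple[int, int]:
    """Return the inclusive (low, high) bounds of an age-group label.

    Open-ended groups such as ``"80+"`` get an upper bound of 120.
    """
    label = label.strip()
    if label.endswith("+"):
        return int(label[:-1]), 120
    lo, hi = label.split("-")
    return int(lo), int(hi)


def age_group_of(age: int, groups: tuple[str, ...] = AGE_GROUPS) -> str | None:
    """Map an age in years to its group label, or None if outside all groups."""
    for g in groups:
        lo, hi = parse_age_group(g)
        if lo <= age <= hi:
            return g
    return None


def period_of(year: int, periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS) -> str | None:
    """Map a calendar year to its period label, or None if outside the study window."""
    for p in periods:
        if p[0] <= year <= p[1]:
            return period_label(p)
    return None


def validate_periods(periods: tuple[tuple[int, int], ...]) -> None:
    """Periods must be non-overlapping, contiguous and in ascending order."""
    if not periods:
        raise ConfigError("at least one analysis period is required")
    for a, b in periods:
        if b < a:
            raise ConfigError(f"period {a}-{b} ends before it starts")
    for (a0, b0), (a1, b1) in zip(periods, periods[1:]):
        if a1 != b0 + 1:
            raise ConfigError(
                f"periods must be contiguous and ordered: {a0}-{b0} followed by {a1}-{b1}"
            )
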
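"""Grouped fate tables, loss fractions, hazard ratios and the 2x2 chi-square.

These are the bespoke summaries of the tracking output: per-group
died/survived counts, per-week loss fractions on the at-risk population,
two hazard-ratio variants (cumulative and weekly-rate), and the Pearson
chi-square on the died/survived x group 2x2 table, computed without
continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import NeuronTrack


@dataclass
class FateGroup:
    """Fate counts of one group of tracked neurons."""

    label: str
    n_total: int
    died_by_week: dict  # week -> count

    @property
    def n_died(self) -> int:
        return sum(self.died_by_week.values())

    def at_risk(self, week: int) -> int:
        """Neurons alive at the start of ``week`` (before its deaths)."""
        return self.n_total - sum(d for w, d in self.died_by_week.items() if w < week)

    def __post_init__(self) -> None:
        if self.n_died > self.n_total:
            raise ValueError("died count exceeds group size")


@dataclass
class FateTable:
    """Grouped fate counts over the candidate death weeks."""

    groups: dict  # label -> FateGroup
    weeks: tuple  # candidate death weeks, e.g. (2, 3, 4)

    @classmethod
    def from_tracks(
        cls,
        tracks: list[NeuronTrack],
        key=None,
        include_fiducials: bool = True,
    ) -> "FateTable":
        """Build a fate table from called tracks.

        ``key`` maps a track to its group label; the default groups by
        ever-tangled status.  Ambiguous tracks are excluded entirely.
        """
        if key is None:
            key = lambda t: "tangle" if t.ever_tangled else "non-tangle"
        usable = [
            t
            for t in tracks
            if t.fate != "ambiguous" and (include_fiducials or not t.fiducial)
        ]
        if not usable:
            raise ValueError("no unambiguous tracks")
        # a disappearance can be called from the second session up to the
        # final session week
        last_week = max(max(t.positions) for t in usable)
        first_week = min(t.first_week for t in usable)
        weeks = tuple(range(first_week + 1, last_week + 1))
        groups: dict[str, FateGroup] = {}
        for t in usable:
            label = key(t)
            g = groups.setdefault(label, FateGroup(label, 0, {}))
            g.n_total += 1
            if t.fate == "disappeared":
                g.died_by_week[t.death_week] = g.died_by_week.get(t.death_week, 0) + 1
        return cls(groups=groups, weeks=weeks)


@dataclass
class TwoByTwo:
    """Died/survived x group contingency cells (all non-negative)."""

    died_a: int
    survived_a: int
    died_b: int
    survived_b: int

    def __post_init__(self) -> None:
        if min(self.died_a, self.survived_a, self.died_b, self.survived_b) < 0:
            raise ValueError("cells must be non-negative")

    @classmethod
    def from_fate_table(cls, table: FateTable, label_a: str, label_b: str) -> "TwoByTwo":
        a, b = table.groups[label_a], table.groups[label_b]
        return cls(a.n_died, a.n_total - a.n_died, b.n_died, b.n_total - b.n_died)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------


def loss_fraction(table: FateTable, label: str) -> float:
    """Percent of the group that disappeared: ``100 * n_died / n_total``."""
    g = table.groups[label]
    if g.n_total == 0:
        raise ZeroDivisionError(f"group {label!r} is empty")
    return 100.0 * g.n_died / g.n_total


def weekly_loss(table: FateTable) -> pd.DataFrame:
    """Per-group, per-week loss percent on the at-risk population.

    Week-``w`` loss is ``died_w / at_risk(w)`` where the at-risk count is
    taken at the start of the week.
    """
    rows = []
    for label, g in table.groups.items():
        for w in table.weeks:
            at_risk = g.at_risk(w)
            died = g.died_by_week.get(w, 0)
            pct = 100.0 * died / at_risk if at_risk > 0 else np.nan
            rows.append({"group": label, "week": w, "percent": pct})
    return pd.DataFrame(rows)


def weekly_loss_summary(per_week: pd.DataFrame) -> tuple[float, float]:
    """Mean and SE across groups of each group's mean weekly loss percent.

    With one table per animal this is the across-animal mean +/- SE.
    """
    means = per_week.groupby("group")["percent"].mean()
    mean = float(means.mean())
    se = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else float("nan")
    return mean, se


def hazard_ratio(table: FateTable, label_a: str, label_b: str) -> dict:
    """Death-rate ratio of group ``a`` over reference group ``b``.

    Returns both variants:

    * ``cumulative`` — ``(died_a/n_a) / (died_b/n_b)`` over the whole
      observation;
    * ``weekly`` — ratio of the two groups' mean per-week loss rates on
      the at-risk population.

    A reference group with zero deaths yields ``inf`` with a warning.
    """
    a, b = table.groups[label_a], table.groups[label_b]
    if a.n_total == 0 or b.n_total == 0:
        raise ZeroDivisionError("both groups must be non-empty")
    out = {}
    if b.n_died == 0:
        warnings.warn(f"reference group {label_b!r} has zero deaths", stacklevel=2)
        out["cumulative"] = float("inf")
    else:
        out["cumulative"] = (a.n_died / a.n_total) / (b.n_died / b.n_total)
    rates_a = [a.died_by_week.get(w, 0) / a.at_risk(w) for w in table.weeks if a.at_risk(w) > 0]
    rates_b = [b.died_by_week.get(w, 0) / b.at_risk(w) for w in table.weeks if b.at_risk(w) > 0]
    mean_b = float(np.mean(rates_b)) if rates_b else 0.0
    if mean_b == 0:
        out["weekly"] = float("inf")
    else:
        out["weekly"] = float(np.mean(rates_a)) / mean_b
    return out


def chi_square_2x2(table: TwoByTwo) -> tuple[float, int]:
    """Pearson chi-square of a 2x2 table, no continuity correction.

    ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with 1 degree of freedom.
    """
    a, b = float(table.died_a), float(table.survived_a)
    c, d = float(table.died_b), float(table.survived_b)
    margins = [a + b, c + d, a + c, b + d]
    if min(margins) <= 0:
        raise ZeroDivisionError("all margins must be positive")
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / np.prod(margins)
    return float(stat), 1


def snapshot_loss_projection(
    flagged_fraction: float,
    per_period_death_rate: float,
    periods_per_year: float,
) -> float:
    """Annualised loss percent projected from a single-snapshot flag count.

    A simple proportional projection: the flagged (at-risk) fraction dies
    at ``per_period_death_rate`` per period and is replenished from the
    remaining population, giving
    ``100 * flagged_fraction * rate * periods_per_year`` percent per year.
    Both inputs are fractions in [0, 1].
    """
    if not 0.0 <= flagged_fraction <= 1.0 or not 0.0 <= per_period_death_rate <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    if periods_per_year <= 0:
        raise ValueError("periods_per_year must be positive")
    return 100.0 * flagged_fraction * per_period_death_rate * periods_per_year
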
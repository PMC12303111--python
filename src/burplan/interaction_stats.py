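"""Behavioural statistics from camera-trap interaction logs.

One record per animal–gate encounter: which behaviours were shown (look,
pause, sniff — not mutually exclusive), whether the animal appeared
attracted or repelled, whether it passed through the gate, the trail type
at the site and an optional 1–3 reaction rating for passes.  The analyses
here are the standard neophobia/habituation readouts: early-vs-late
passage contrasts with the Yates continuity-corrected chi-square,
behaviour-category proportions, trail-type association and reaction-rating
summaries.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deployment import DeploymentWindow, round_half_away

__all__ = [
    "EVENT_COLUMNS",
    "TRAIL_TYPES",
    "BEHAVIOUR_COLUMNS",
    "validate_events",
    "load_events",
    "split_early_late",
    "passage_table",
    "yates_chi2",
    "behaviour_proportions",
    "trail_association",
    "reaction_summary",
]

TRAIL_TYPES = ("none", "faint", "well_used")

BEHAVIOUR_COLUMNS = ("looked", "paused", "sniffed")

#: canonical column order of an events.csv interaction log
EVENT_COLUMNS = (
    "site",
    "timestamp",
    "species",
    "looked",
    "paused",
    "sniffed",
    "attracted",
    "repelled",
    "passed_through",
    "within_tagging_distance",
    "trail_type",
    "baited",
    "reaction_rating",
)

_BOOL_COLUMNS = BEHAVIOUR_COLUMNS + (
    "attracted",
    "repelled",
    "passed_through",
    "within_tagging_distance",
    "baited",
)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an interaction log.

    Checks the schema, the trail-type vocabulary, that no event is both
    attracted and repelled, and that reaction ratings (where present) are
    in {1, 2, 3}.  Returns a copy with parsed timestamps and boolean flags.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table is missing columns: {missing}")
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    for col in _BOOL_COLUMNS:
        ev[col] = ev[col].astype(bool)
    bad_trail = set(ev["trail_type"]) - set(TRAIL_TYPES)
    if bad_trail:
        raise ValueError(f"unknown trail_type values: {sorted(bad_trail)}")
    both = ev["attracted"] & ev["repelled"]
    if both.any():
        raise ValueError(
            f"{int(both.sum())} events are flagged both attracted and repelled"
        )
    ratings = pd.to_numeric(ev["reaction_rating"], errors="coerce")
    known = ratings.dropna()
    if not known.isin([1, 2, 3]).all():
        bad = sorted(known[~known.isin([1, 2, 3])].unique())
        raise ValueError(f"reaction_rating must be 1, 2 or 3; found {bad}")
    ev["reaction_rating"] = ratings.astype("Int64")
    return ev


def load_events(path) -> pd.DataFrame:
    """Read and validate an events.csv interaction log (booleans as 0/1)."""
    return validate_events(pd.read_csv(path))


def split_early_late(
    events: pd.DataFrame, window: DeploymentWindow
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split events at the half-way point of the deployment window.

    Events strictly before the midpoint are early; midpoint-boundary
    events go to the late half.  Events outside the window raise, listing
    the offending timestamps.
    """
    ts = pd.to_datetime(events["timestamp"])
    outside = events[(ts < window.start) | (ts > window.end)]
    if len(outside):
        raise ValueError(
            "events outside the deployment window: "
            f"{outside['timestamp'].astype(str).tolist()}"
        )
    early = events[ts < window.midpoint]
    late = events[ts >= window.midpoint]
    return early, late


def passage_table(
    early: pd.DataFrame, late: pd.DataFrame, species: str
) -> pd.DataFrame:
    """2×2 early/late × passed/not-passed counts for one species."""

    def _row(df: pd.DataFrame) -> list[int]:
        sp = df[df["species"] == species]
        passed = int(sp["passed_through"].astype(bool).sum())
        return [passed, len(sp) - passed]

    return pd.DataFrame(
        [_row(early), _row(late)],
        index=pd.Index(["early", "late"], name="period"),
        columns=pd.Index(["passed", "not_passed"], name="outcome"),
    )


def yates_chi2(table, *, correction: bool = True) -> tuple[float, int, float]:
    """Chi-square test of association on a 2×2 table, Yates-corrected.

    Expected counts come from the marginal products; each deviation
    |O − E| is reduced by 0.5 and clamped at zero before squaring
    (uncorrected Pearson available via ``correction=False``).  Returns
    (statistic, df=1, p-value from the χ²₁ upper tail).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("passage table must be 2×2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: every row and column total must be > 0")
    expected = np.outer(row, col) / n
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(0.0, dev - 0.5)
    statistic = float((dev**2 / expected).sum())
    return statistic, 1, float(stats.chi2.sf(statistic, df=1))


def behaviour_proportions(events: pd.DataFrame) -> dict[str, float]:
    """Behaviour-category percentages over all interactions.

    Categories are not mutually exclusive (one animal may look, pause and
    sniff), so percentages need not sum to 100; the denominator is the
    total number of interactions.  Values are rounded to the nearest
    integer percent.
    """
    if events.empty:
        raise ValueError("empty interaction log")
    n = len(events)
    out = {}
    for label, col in [
        ("look", "looked"),
        ("pause", "paused"),
        ("sniff", "sniffed"),
        ("attracted", "attracted"),
        ("repelled", "repelled"),
        ("passed_through", "passed_through"),
    ]:
        out[label] = round_half_away(100.0 * events[col].astype(bool).sum() / n)
    return out


def trail_association(
    events: pd.DataFrame,
    species: str,
    categories: Sequence[str] = ("well_used", "none"),
) -> tuple[float, int, float]:
    """Association of one species' events with trail visibility.

    Compares the species' event counts across the chosen trail categories
    against equal expected exposure.  For two categories the statistic is
    continuity-corrected (df = 1); with more it is an uncorrected Pearson
    goodness-of-fit over the categories.  Categories with zero events are
    dropped with a warning; at least two populated categories are needed.
    """
    import warnings

    unknown = set(categories) - set(TRAIL_TYPES)
    if unknown:
        raise ValueError(f"unknown trail categories: {sorted(unknown)}")
    sp = events[events["species"] == species]
    counts = {c: int((sp["trail_type"] == c).sum()) for c in categories}
    empty = [c for c, k in counts.items() if k == 0]
    if empty:
        warnings.warn(f"trail categories with zero events dropped: {empty}", stacklevel=2)
    observed = np.array([k for k in counts.values() if k > 0], dtype=float)
    if observed.size < 2:
        raise ValueError("need >= 2 trail categories with events")
    expected = np.full(observed.size, observed.sum() / observed.size)
    dev = np.abs(observed - expected)
    if observed.size == 2:
        dev = np.maximum(0.0, dev - 0.5)
    statistic = float((dev**2 / expected).sum())
    df = observed.size - 1
    return statistic, df, float(stats.chi2.sf(statistic, df=df))


def reaction_summary(
    events: pd.DataFrame, group_by: str = "species"
) -> pd.DataFrame:
    """Per-group percentages of reaction ratings 1/2/3 for rated passes.

    Rating 1 = no observable reaction; 2 = mild (brief pause <1 s,
    flinching, minor speed change); 3 = strong (extended pause, change of
    trajectory, severe flinching, squatting, speed change).  Percentages
    are rounded to the nearest integer and may therefore sum to 100 ± 1.
    """
    rated = events.dropna(subset=["reaction_rating"])
    if rated.empty:
        raise ValueError("no events with reaction ratings")
    ratings = pd.to_numeric(rated["reaction_rating"])
    if not ratings.isin([1, 2, 3]).all():
        raise ValueError("reaction_rating must be 1, 2 or 3")
    rows = []
    for group, sub in rated.groupby(group_by, sort=True):
        n = len(sub)
        counts = pd.to_numeric(sub["reaction_rating"]).value_counts()
        row = {group_by: group, "n_passes": n}
        for r in (1, 2, 3):
            row[f"pct_rating_{r}"] = round_half_away(100.0 * counts.get(r, 0) / n)
        rows.append(row)
    return pd.DataFrame(rows)
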
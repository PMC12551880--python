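"""Camera-trap photo records -> independent events -> monthly response matrices.

Photographs of the same species at the same crossing structure (all
cameras pooled) are chained into one independent event while consecutive
gaps are at most 30 minutes; a strictly larger gap starts a new event.
Per-individual interaction codes classify each event:

    A  successful crossing (capped at two per event, one per direction)
    B  entry/exit on the same side
    C  approach without entry
    D  detection without interaction
    E  day bed (long same-side occupancy; counted once per event)

Three monthly response matrices are built per site-month and species,
normalised to events per day: total detections (all events), successful
crossings (sum of A) and failed crossings (B + C + E).  D interactions
contribute to the total only.  Events from excluded monitoring periods
(e.g. an active construction period, when interactions were not
assessed) are kept in the total-detections matrix but dropped from the
successful and failed matrices, as are events lacking interaction codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "ResponseMatrix",
    "group_independent_events",
    "classify_codes",
    "build_response_matrices",
]

CATEGORIES = ("A", "B", "C", "D", "E")
DEFAULT_GAP_MINUTES = 30.0

_REQUIRED_COLUMNS = ["site_id", "camera_id", "timestamp", "species", "n_individuals"]


@dataclass
class ResponseMatrix:
    """Monthly per-day detection rates, one of the three response categories.

    ``data`` is indexed by (site_id, month) with one column per species;
    ``days`` gives the per-row denominator (days monitored that month).
    """

    data: pd.DataFrame
    days: pd.Series
    category: str  # total | successful | failed

    @property
    def observation_ids(self) -> list[str]:
        return [f"{s}|{m}" for s, m in self.data.index]

    def flat(self) -> pd.DataFrame:
        out = self.data.copy()
        out.index = pd.Index(self.observation_ids, name="observation")
        return out


def _parse_codes(raw, n_individuals: int, row_label) -> list[str] | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    if isinstance(raw, str):
        codes = [c for c in raw.replace(",", ";").split(";") if c.strip()]
        codes = [c.strip().upper() for c in codes]
    else:
        codes = [str(c).strip().upper() for c in raw]
    if not codes:
        return None
    bad = [c for c in codes if c not in CATEGORIES]
    if bad:
        raise ValueError(f"unknown interaction code(s) {bad} at row {row_label}")
    return codes


def classify_codes(code_lists: list[list[str]]) -> dict[str, int]:
    """Aggregate per-photo individual codes into event category counts.

    Codes are summed over the photos that carry annotations, then A is
    capped at 2 (one crossing per direction; further back-and-forth
    crossings within the event are ignored) and E at 1 (a day bed counts
    once however long it lasts).
    """
    counts = {c: 0 for c in CATEGORIES}
    for codes in code_lists:
        for c in codes:
            counts[c] += 1
    counts["A"] = min(counts["A"], 2)
    counts["E"] = min(counts["E"], 1)
    return counts


def group_independent_events(
    photos: pd.DataFrame, gap_minutes: float = DEFAULT_GAP_MINUTES
) -> pd.DataFrame:
    """Chain photos into independent events per (site, species).

    Photos of one species at one site are sorted by time and chained
    while the gap between consecutive photos is <= ``gap_minutes``;
    cameras are pooled within a site and different species are never
    merged.  Returns one row per event with category counts, the period
    label of its first photo, and ``has_codes`` marking whether any photo
    carried interaction codes.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in photos.columns]
    if missing:
        raise KeyError(f"photo table lacks required columns: {missing}")
    df = photos.copy()
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = df.index[ts.isna()]
    if len(bad):
        raise ValueError(f"unparseable timestamp at row(s) {list(bad[:5])}")
    df["timestamp"] = ts
    if "period_label" not in df.columns:
        df["period_label"] = ""
    df["period_label"] = df["period_label"].fillna("")
    if "interaction_codes" not in df.columns:
        df["interaction_codes"] = None

    rows = []
    for (site, species), grp in df.groupby(["site_id", "species"], sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        times = grp["timestamp"].to_numpy()
        gaps = np.diff(times) / np.timedelta64(1, "s") / 60.0
        # a strictly larger gap than the threshold starts a new event
        breaks = np.concatenate([[0], np.cumsum(gaps > gap_minutes)])
        for _, ev in grp.groupby(breaks):
            code_lists = []
            for label, photo in ev.iterrows():
                codes = _parse_codes(
                    photo["interaction_codes"], int(photo["n_individuals"]), label
                )
                if codes is not None:
                    code_lists.append(codes)
            counts = classify_codes(code_lists)
            rows.append(
                {
                    "site_id": site,
                    "species": species,
                    "start": ev["timestamp"].iloc[0],
                    "end": ev["timestamp"].iloc[-1],
                    "n_photos": len(ev),
                    "has_codes": bool(code_lists),
                    "period_label": ev["period_label"].iloc[0],
                    **{f"count_{c}": counts[c] for c in CATEGORIES},
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "species",
            "start",
            "end",
            "n_photos",
            "has_codes",
            "period_label",
        ]
        + [f"count_{c}" for c in CATEGORIES],
    )


def _event_count(events: pd.DataFrame, category: str) -> pd.Series:
    if category == "total":
        return pd.Series(1, index=events.index)
    if category == "successful":
        return events["count_A"]
    if category == "failed":
        return events["count_B"] + events["count_C"] + events["count_E"]
    raise ValueError(f"unknown category {category!r}")


def build_response_matrices(
    events: pd.DataFrame,
    calendar: pd.DataFrame,
    exclude_period_labels: list[str] | None = None,
    exclude_for: tuple[str, ...] = ("successful", "failed"),
) -> dict[str, ResponseMatrix]:
    """Build the total / successful / failed monthly rate matrices.

    Parameters
    ----------
    events : DataFrame
        Output of :func:`group_independent_events`.
    calendar : DataFrame
        One row per monitored (site_id, month); ``month`` is anything
        coercible to a monthly pandas Period.  An optional
        ``days_monitored`` column overrides the days-in-month
        denominator for partially monitored months.
    exclude_period_labels : list of str
        Events whose period label is listed are dropped from the
        categories named in ``exclude_for`` (default: the successful and
        failed matrices, keeping them in total only).

    Site-months with no detections stay as all-zero rows; an event in a
    month missing from the calendar is a coverage error.
    """
    cal = calendar.copy()
    cal["month"] = pd.PeriodIndex(cal["month"], freq="M")
    if "days_monitored" in cal.columns:
        days = cal["days_monitored"].astype(float).to_numpy()
    else:
        days = cal["month"].dt.days_in_month.astype(float).to_numpy()
    index = pd.MultiIndex.from_frame(cal[["site_id", "month"]])
    if index.has_duplicates:
        raise ValueError("calendar has duplicate (site, month) rows")
    days = pd.Series(days, index=index, name="days")

    ev = events.copy()
    if len(ev):
        ev["month"] = pd.PeriodIndex(pd.DatetimeIndex(ev["start"]), freq="M")
        ev_index = pd.MultiIndex.from_frame(ev[["site_id", "month"]])
        outside = ~ev_index.isin(index)
        if outside.any():
            missing = sorted(set(ev_index[outside]))[:5]
            raise ValueError(f"events outside the calendar for site-months {missing}")
    species = sorted(ev["species"].unique()) if len(ev) else []
    excluded = set(exclude_period_labels or [])

    out = {}
    for category in ("total", "successful", "failed"):
        sub = ev
        if len(ev):
            keep = np.ones(len(ev), dtype=bool)
            if category in exclude_for and excluded:
                keep &= ~ev["period_label"].isin(excluded).to_numpy()
            if category in ("successful", "failed"):
                keep &= ev["has_codes"].to_numpy()
            sub = ev[keep]
        counts = pd.DataFrame(0.0, index=index, columns=species)
        if len(sub):
            weights = _event_count(sub, category)
            tallied = (
                sub.assign(_w=weights)
                .groupby(["site_id", "month", "species"], observed=True)["_w"]
                .sum()
            )
            for (site, month, sp), v in tallied.items():
                counts.loc[(site, month), sp] = v
        rates = counts.div(days, axis=0)
        out[category] = ResponseMatrix(data=rates, days=days, category=category)
    return out
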
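"""City/time aggregation of labeled documents into trend tables.

A trend table is tidy: one row per (city, period, category) with the tweet
count and the within-(city, period) percentage.  Periods are the calendar
month or year of the UTC timestamp.  Categories are topic ids or emotion
labels; every category level appears in every non-empty (city, period)
group so that zero counts are explicit, while (city, period) groups with no
documents at all are omitted.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import TokenizedDoc
from .emotion import LABELS as EMOTION_LABELS

__all__ = [
    "label_frame",
    "aggregate",
    "peak_detection",
    "plot_trends",
]


def label_frame(
    docs: Sequence[TokenizedDoc],
    topic_labels: Sequence[int] | None = None,
    emotion_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-document label table consumed by ``aggregate``."""
    df = pd.DataFrame(
        {
            "doc_id": [d.id for d in docs],
            "city": [d.city for d in docs],
            "timestamp": pd.to_datetime([d.timestamp for d in docs], utc=True),
        }
    )
    if topic_labels is not None:
        df["topic"] = list(topic_labels)
    if emotion_labels is not None:
        df["emotion"] = [str(e) for e in emotion_labels]
    return df


def _periods(ts: pd.Series, granularity: str) -> pd.Series:
    if granularity == "month":
        return ts.dt.strftime("%Y-%m")
    if granularity == "year":
        return ts.dt.strftime("%Y")
    raise ValueError("granularity must be 'month' or 'year'")


def aggregate(
    df: pd.DataFrame,
    granularity: str = "month",
    dimension: str = "topic",
    categories: Sequence | None = None,
    exclude: Sequence | None = None,
) -> pd.DataFrame:
    """Count documents per (city, period, category) with group percentages.

    ``exclude`` removes categories (e.g. pruned topics) before counting:
    excluded documents contribute to neither counts nor group totals of this
    table.  Raises if any document's ``dimension`` label is missing.
    """
    if dimension not in df.columns:
        raise ValueError(f"column {dimension!r} missing from label table")
    missing = df[df[dimension].isna()]
    if len(missing):
        ids = ", ".join(missing["doc_id"].astype(str).head(10))
        raise ValueError(f"unlabeled documents for {dimension!r}: {ids}")
    work = df.copy()
    if exclude is not None:
        work = work[~work[dimension].isin(set(exclude))]
    if categories is None:
        if dimension == "emotion":
            categories = list(EMOTION_LABELS)
        else:
            categories = sorted(work[dimension].unique())
    if exclude is not None:
        categories = [c for c in categories if c not in set(exclude)]
    work = work.assign(period=_periods(work["timestamp"], granularity))
    counts = (
        work.groupby(["city", "period", dimension], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    # expand to the full category level set within each non-empty group
    groups = counts[["city", "period"]].drop_duplicates()
    full = groups.merge(pd.DataFrame({dimension: categories}), how="cross")
    table = full.merge(counts, on=["city", "period", dimension], how="left")
    table["count"] = table["count"].fillna(0).astype(int)
    totals = table.groupby(["city", "period"])["count"].transform("sum")
    table["pct"] = np.where(totals > 0, 100.0 * table["count"] / totals, 0.0)
    table = table.rename(columns={dimension: "category"})
    table.insert(2, "dimension", dimension)
    return table.sort_values(["city", "period", "category"], kind="stable").reset_index(drop=True)


def peak_detection(
    table: pd.DataFrame,
    category=None,
) -> list[tuple[str, str]]:
    """Local maxima of the monthly count series, per city.

    A month is a peak when its count strictly exceeds both neighbors;
    endpoints are compared to their single neighbor.  ``category=None``
    sums counts over all categories (total volume).  Cities with fewer than
    two months yield nothing.
    """
    work = table if category is None else table[table["category"] == category]
    series = work.groupby(["city", "period"])["count"].sum().reset_index()
    peaks: list[tuple[str, str]] = []
    for city, sub in series.groupby("city", sort=True):
        sub = sub.sort_values("period")
        vals = sub["count"].to_numpy()
        months = sub["period"].tolist()
        n = len(vals)
        if n < 2:
            continue
        for i in range(n):
            left_ok = i == 0 or vals[i] > vals[i - 1]
            right_ok = i == n - 1 or vals[i] > vals[i + 1]
            if left_ok and right_ok:
                peaks.append((city, months[i]))
    return peaks


def plot_trends(table: pd.DataFrame, out_path, value: str = "count") -> None:
    """Static per-city line plot of counts or percentages over periods."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cities = sorted(table["city"].unique())
    fig, axes = plt.subplots(len(cities), 1, figsize=(8, 2.6 * len(cities)), squeeze=False)
    for ax, city in zip(axes[:, 0], cities):
        sub = table[table["city"] == city]
        for cat, grp in sub.groupby("category"):
            grp = grp.sort_values("period")
            ax.plot(grp["period"], grp[value], marker="o", ms=2.5, label=str(cat))
        ax.set_title(city)
        ax.set_ylabel(value)
        ax.tick_params(axis="x", rotation=60, labelsize=6)
    axes[0, 0].legend(fontsize=6, ncol=4)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
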
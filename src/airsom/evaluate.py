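"""Map summaries: frequencies, persistence, seasonality, covariates, quality.

Everything here is keyed by map node (day type) so results can be laid out
on the trained grid: how often each day type occurs, how long it persists,
when in the year and study period it appears, what weather and pollutant
levels accompany it, how reliable (low-dispersion) each class is, and how
the grid layout relates to feature-space structure (codebook dendrogram
and Sammon projection).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compare import MergeTree, sammon_map, ward_clustering
from .data import CovariateTable, IntegrityError, SchemaError
from .som import SOMModel
from scipy.spatial.distance import cdist

__all__ = [
    "class_reliability",
    "frequency_table",
    "persistence",
    "seasonal_frequencies",
    "period_frequencies",
    "covariate_summary",
    "codebook_dendrogram",
    "codebook_sammon",
    "grid_summary_export",
    "DEFAULT_SEASONS",
]

#: Meteorological seasons: month -> season name.
DEFAULT_SEASONS = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}


def class_reliability(
    Z_std: np.ndarray, model: SOMModel, se_convention: str = "as_printed"
) -> pd.DataFrame:
    """Within-class dispersion of each day type, as a coefficient of variation.

    For each class the member dissimilarities are the Euclidean distances
    from member days to the assigned codebook (the same quantity QE
    averages). CV = 100 * SE / mean where the standard error of the mean is
    sd / n under ``se_convention="as_printed"`` and the conventional
    sd / sqrt(n) under ``"conventional"``. The two differ by a factor
    sqrt(n_c); both conventions appear in applied reports, so the one used
    is recorded in the output. Classes with fewer than 2 members are
    flagged rather than scored.
    """
    if se_convention not in ("as_printed", "conventional"):
        raise ValueError("se_convention must be 'as_printed' or 'conventional'")
    Z_std = np.asarray(Z_std, dtype=float)
    dist = np.sqrt(
        np.sum((Z_std - model.codebooks[model.assignments]) ** 2, axis=1)
    )
    rows = []
    for c in range(model.k):
        d = dist[model.assignments == c]
        n_c = d.size
        if n_c < 2:
            rows.append(
                {"class": c, "n": n_c, "mean_dissimilarity": d.mean() if n_c else np.nan,
                 "sd": np.nan, "se": np.nan, "cv_percent": np.nan, "flagged": True}
            )
            continue
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        se = sd / n_c if se_convention == "as_printed" else sd / np.sqrt(n_c)
        cv = 0.0 if mean == 0 else 100.0 * se / mean
        rows.append(
            {"class": c, "n": n_c, "mean_dissimilarity": mean, "sd": sd,
             "se": se, "cv_percent": cv, "flagged": False}
        )
    out = pd.DataFrame(rows).set_index("class")
    out.attrs["se_convention"] = se_convention
    return out


def frequency_table(labels, classes=None) -> pd.DataFrame:
    """Counts and percentages per class, including zero-count classes.

    ``classes`` fixes the class universe (e.g. ``range(model.k)`` so empty
    map nodes appear with count 0); by default the realized labels are used.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    counts = pd.Series(
        {c: int(np.sum(labels == c)) for c in classes}, name="count"
    ).rename_axis("class")
    out = counts.to_frame()
    out["percent"] = 100.0 * out["count"] / labels.size
    return out


def persistence(labels, dates) -> pd.DataFrame:
    """Run-length (duration) statistics of each day type.

    A run is a maximal stretch of consecutive calendar days with the same
    label; a gap of 2 or more days between successive observations breaks a
    run even if the label matches, since persistence across unobserved days
    is undefined. Per class: number of runs and mean/min/max run length.
    The per-class run lengths always sum to the class's day count.
    """
    labels = np.asarray(labels)
    dates = pd.DatetimeIndex(dates)
    if len(labels) != len(dates):
        raise ValueError("labels and dates must align")
    if len(dates) > 1 and not dates.is_monotonic_increasing:
        raise IntegrityError("dates must be strictly increasing")
    runs: dict = {}
    run_label, run_len = labels[0], 1
    for i in range(1, len(labels)):
        gap = (dates[i] - dates[i - 1]).days
        if labels[i] == run_label and gap == 1:
            run_len += 1
        else:
            runs.setdefault(run_label, []).append(run_len)
            run_label, run_len = labels[i], 1
    runs.setdefault(run_label, []).append(run_len)
    rows = []
    for c, lens in sorted(runs.items()):
        arr = np.array(lens)
        rows.append(
            {"class": c, "n_runs": arr.size, "total_days": int(arr.sum()),
             "mean_length": float(arr.mean()), "min_length": int(arr.min()),
             "max_length": int(arr.max())}
        )
    return pd.DataFrame(rows).set_index("class")


def seasonal_frequencies(labels, dates, season_def=None, classes=None) -> pd.DataFrame:
    """Class x season contingency table (default meteorological seasons)."""
    season_def = DEFAULT_SEASONS if season_def is None else season_def
    missing = [m for m in range(1, 13) if m not in season_def]
    if missing:
        raise ValueError(f"season definition missing months {missing}")
    dates = pd.DatetimeIndex(dates)
    seasons = np.array([season_def[m] for m in dates.month])
    return _contingency(labels, seasons, "season", classes)


def period_frequencies(labels, dates, breaks, classes=None) -> pd.DataFrame:
    """Class x period contingency table for user-defined date ranges.

    ``breaks`` is a list of (start, end) inclusive date ranges (or
    (name, start, end) triples). Ranges must be disjoint and jointly cover
    every observed date; a date outside all ranges raises.
    """
    dates = pd.DatetimeIndex(dates)
    parsed = []
    for b in breaks:
        if len(b) == 3:
            name, start, end = b
        else:
            start, end = b
            name = f"{pd.Timestamp(start).date()}..{pd.Timestamp(end).date()}"
        parsed.append((name, pd.Timestamp(start), pd.Timestamp(end)))
    for i, (_, s1, e1) in enumerate(parsed):
        if s1 > e1:
            raise ValueError(f"period {parsed[i][0]!r} has start after end")
        for _, s2, e2 in parsed[i + 1:]:
            if s1 <= e2 and s2 <= e1:
                raise ValueError("period ranges overlap")
    period = np.empty(len(dates), dtype=object)
    covered = np.zeros(len(dates), dtype=bool)
    for name, start, end in parsed:
        inside = (dates >= start) & (dates <= end)
        period[inside] = name
        covered |= np.asarray(inside)
    if not covered.all():
        d = dates[~covered][0]
        raise ValueError(f"date {d.date()} falls outside every period")
    return _contingency(labels, period, "period", classes)


def _contingency(labels, groups, group_name, classes=None) -> pd.DataFrame:
    labels = np.asarray(labels)
    table = pd.crosstab(
        pd.Series(labels, name="class"), pd.Series(groups, name=group_name)
    )
    if classes is not None:
        table = table.reindex(list(classes), fill_value=0)
    return table


def covariate_summary(labels, dates, covariates: CovariateTable) -> pd.DataFrame:
    """Per-class mean and sample sd of each covariate, joined on dates.

    Covariates (meteorology, or pollutants held out of training) are joined
    to labeled days by date; missing covariate entries are excluded
    pairwise. A class with a single non-missing value reports its mean but
    a flagged (NaN) sd; a class with no values at all is flagged entirely.
    """
    labels = np.asarray(labels)
    dates = pd.DatetimeIndex(dates)
    lab = pd.Series(labels, index=dates, name="class")
    cov = covariates.to_frame()
    joined = cov.join(lab, how="inner").dropna(subset=["class"])
    if joined.empty:
        raise SchemaError("no joinable dates between labels and covariates")
    grouped = joined.groupby("class")
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    counts = grouped.count()
    out = pd.concat({"mean": means, "sd": sds, "n": counts}, axis=1)
    out.columns = out.columns.set_names(["stat", "covariate"])
    return out.swaplevel(axis=1).sort_index(axis=1)


def codebook_dendrogram(model: SOMModel) -> MergeTree:
    """Ward dendrogram of the k class profiles, leaves labeled by (x, y).

    On a well-organized map the early merges join grid-adjacent nodes: the
    dendrogram is the standard check that similar day types ended up as map
    neighbors.
    """
    _, tree = ward_clustering(
        model.codebooks, k=1, leaf_labels=model.grid.labels
    )
    return tree


def codebook_sammon(model: SOMModel, seed: int = 0, jitter: float = 0.0):
    """Sammon projection of the class profiles (map-distortion display)."""
    D = cdist(model.codebooks, model.codebooks)
    return sammon_map(D, dims=2, seed=seed, jitter=jitter)


def grid_summary_export(model: SOMModel, tables: dict, path=None) -> pd.DataFrame:
    """Flatten per-class summary tables into one grid-keyed table.

    One row per map node: (x, y, node id) followed by every column of every
    supplied table, prefixed by the table's name. All tables must be keyed
    by class id covering 0..k-1 (missing classes are an error). When
    ``path`` is given the table is also written as CSV.
    """
    base = pd.DataFrame(
        {
            "node": range(model.k),
            "x": [x for x, _ in model.grid.labels],
            "y": [y for _, y in model.grid.labels],
        }
    ).set_index("node")
    out = base.copy()
    for name, table in tables.items():
        if isinstance(table, pd.Series):
            table = table.to_frame()
        flat = table.copy()
        if isinstance(flat.columns, pd.MultiIndex):
            flat.columns = ["_".join(map(str, c)) for c in flat.columns]
        missing = set(range(model.k)) - set(flat.index)
        if missing:
            raise SchemaError(
                f"table {name!r} missing classes {sorted(missing)}; "
                "reindex with fill values first"
            )
        flat = flat.loc[list(range(model.k))]
        flat.columns = [f"{name}_{c}" for c in flat.columns]
        flat.index = out.index
        out = out.join(flat)
    if path is not None:
        out.reset_index().to_csv(path, index=False)
    return out
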
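"""Count-data ingestion, validation and the signed direction convention.

A tower-mounted time-lapse camera photographs a small stream in short
multi-frame bursts around the clock.  Reviewers count fish crossing white
contrast panels in each burst, separately for upstream and downstream
movement, and the burst counts are summed into hourly totals.  (Fish that
hold position over the panels are excluded by the reviewers in the field
protocol — by convention a fish is counted only once it has moved at least
half the panel length — so the software only ever sees already-enumerated
passage counts.)

All downstream modelling uses a *signed* representation of direction: an
hour contributes two observations, ``+upstream`` and ``-downstream``, so
that a single through-origin regression can treat movement into and out of
the stream on one axis.  Net passage for an hour is the sum of the two
signed values.

File formats (all plain CSV with a header row, ISO-8601 timestamps):

* hourly counts: ``hour,upstream,downstream``
* burst counts: ``timestamp,upstream,downstream``
* paired subsample: ``hour,direction,photo,video`` with ``direction`` in
  ``{up, down}`` and non-negative magnitudes (signs are applied on read).

Hours are left-closed intervals labelled by their start.  Missing hours are
retained as explicit gaps and reported, never silently zero-filled; callers
that want zero-fill must ask for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HOURLY_COLUMNS = ("hour", "upstream", "downstream")
BURST_COLUMNS = ("timestamp", "upstream", "downstream")
PAIRED_COLUMNS = ("hour", "direction", "photo", "video")

#: canonical column names of the signed long-format observation frame
SIGNED_COLUMNS = ("hour", "direction", "photo_signed", "video_signed")


class CountDataError(ValueError):
    """An input counts file or frame violates the format contract."""


@dataclass
class HourlySeries:
    """A validated hourly count series plus its gap report.

    ``counts`` has columns ``hour`` (datetime64), ``upstream`` and
    ``downstream`` (non-negative integers), sorted and duplicate-free.
    ``gaps`` lists the hours between the first and last record that have no
    observation (camera outages, card swaps).
    """

    counts: pd.DataFrame
    gaps: pd.DatetimeIndex

    def zero_filled(self) -> pd.DataFrame:
        """Return counts with gap hours inserted as explicit zero rows."""
        if len(self.gaps) == 0:
            return self.counts.reset_index(drop=True)
        fill = pd.DataFrame(
            {"hour": self.gaps, "upstream": 0, "downstream": 0}
        )
        out = (
            pd.concat([self.counts, fill], ignore_index=True)
            .sort_values("hour")
            .reset_index(drop=True)
        )
        return out


def _parse_times(raw: pd.Series, col: str) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce")
    bad = parsed.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CountDataError(
            f"unparseable {col} value {raw.iloc[row]!r} at data row {row + 1}"
        )
    return parsed


def _check_counts(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    df = df.copy()
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise CountDataError(
                f"non-numeric {col} value {df[col].iloc[row]!r} at data row {row + 1}"
            )
        if (vals < 0).any():
            row = int(np.flatnonzero((vals < 0).to_numpy())[0])
            raise CountDataError(
                f"negative {col} count {vals.iloc[row]} at data row {row + 1}"
            )
        if (vals != vals.round()).any():
            row = int(np.flatnonzero((vals != vals.round()).to_numpy())[0])
            raise CountDataError(
                f"non-integer {col} count {vals.iloc[row]} at data row {row + 1}"
            )
        df[col] = vals.astype(int)
    return df


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CountDataError(f"{what} is missing column(s) {missing}; expected {list(cols)}")


def find_gaps(hours: pd.Series | pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Hours absent between the first and last observed hour."""
    idx = pd.DatetimeIndex(hours)
    if len(idx) < 2:
        return pd.DatetimeIndex([])
    full = pd.date_range(idx.min(), idx.max(), freq="h")
    return full.difference(idx)


def read_hourly_counts(path) -> HourlySeries:
    """Read and validate an hourly counts CSV (``hour,upstream,downstream``).

    Returns the sorted, duplicate-free series together with a gap report.
    Raises :class:`CountDataError` on malformed timestamps, negative or
    non-integer counts, or duplicated hours (the error names the offender).
    """
    df = pd.read_csv(path)
    _require_columns(df, HOURLY_COLUMNS, f"hourly counts file {path}")
    df["hour"] = _parse_times(df["hour"], "hour").dt.floor("h")
    df = _check_counts(df, ("upstream", "downstream"))
    dupes = df["hour"][df["hour"].duplicated()]
    if not dupes.empty:
        raise CountDataError(f"duplicated hour {dupes.iloc[0]} in {path}")
    df = df.sort_values("hour").reset_index(drop=True)
    return HourlySeries(counts=df[list(HOURLY_COLUMNS)], gaps=find_gaps(df["hour"]))


def write_hourly_counts(counts: pd.DataFrame, path) -> None:
    """Write an hourly counts frame in the canonical CSV dialect."""
    out = counts.copy()
    out["hour"] = pd.DatetimeIndex(out["hour"]).strftime("%Y-%m-%dT%H:%M:%S")
    out[list(HOURLY_COLUMNS)].to_csv(path, index=False)


def read_burst_counts(path) -> pd.DataFrame:
    """Read a burst-level counts CSV (``timestamp,upstream,downstream``)."""
    df = pd.read_csv(path)
    _require_columns(df, BURST_COLUMNS, f"burst counts file {path}")
    df["timestamp"] = _parse_times(df["timestamp"], "timestamp")
    df = _check_counts(df, ("upstream", "downstream"))
    dupes = df["timestamp"][df["timestamp"].duplicated()]
    if not dupes.empty:
        raise CountDataError(f"duplicated burst timestamp {dupes.iloc[0]} in {path}")
    return df.sort_values("timestamp").reset_index(drop=True)


def aggregate_bursts(bursts: pd.DataFrame) -> pd.DataFrame:
    """Sum burst counts into hourly totals, separately per direction.

    Hours with no bursts simply do not appear in the output; gap handling is
    the caller's job (see :func:`find_gaps`).  Totals are conserved:
    the column sums of the input equal the column sums of the output.
    """
    _require_columns(bursts, BURST_COLUMNS, "burst frame")
    if len(bursts) == 0:
        return pd.DataFrame(
            {
                "hour": pd.DatetimeIndex([]),
                "upstream": pd.Series([], dtype=int),
                "downstream": pd.Series([], dtype=int),
            }
        )
    hour = pd.DatetimeIndex(bursts["timestamp"]).floor("h")
    out = (
        bursts.assign(hour=hour)
        .groupby("hour", as_index=False)[["upstream", "downstream"]]
        .sum()
        .sort_values("hour")
        .reset_index(drop=True)
    )
    return out[list(HOURLY_COLUMNS)]


def to_signed_observations(
    hour, upstream_photo: int, downstream_photo: int, video_up: float, video_down: float
) -> pd.DataFrame:
    """Split one hour into its two signed observations.

    Upstream movement is positive, downstream negative (fish leaving the
    stream), so the pair is ``(+photo_up, +video_up)`` and
    ``(-photo_down, -video_down)``.  Zero counts are retained.
    """
    for name, v in (
        ("upstream_photo", upstream_photo),
        ("downstream_photo", downstream_photo),
        ("video_up", video_up),
        ("video_down", video_down),
    ):
        if v < 0:
            raise CountDataError(f"{name} must be a non-negative magnitude, got {v}")
    return pd.DataFrame(
        {
            "hour": [pd.Timestamp(hour)] * 2,
            "direction": ["up", "down"],
            "photo_signed": [int(upstream_photo), -int(downstream_photo)],
            "video_signed": [float(video_up), -float(video_down)],
        }
    )


def pair_observations(photo: pd.DataFrame, video: pd.DataFrame) -> pd.DataFrame:
    """Join hourly photo counts with video truth into the signed long format.

    Both frames need columns ``hour,upstream,downstream``; only hours present
    in both contribute.  Each joined hour yields exactly two rows.
    """
    _require_columns(photo, HOURLY_COLUMNS, "photo frame")
    _require_columns(video, HOURLY_COLUMNS, "video frame")
    merged = photo.merge(video, on="hour", suffixes=("_photo", "_video"))
    if merged.empty:
        raise CountDataError("photo and video frames share no hours")
    frames = [
        pd.DataFrame(
            {
                "hour": merged["hour"],
                "direction": "up",
                "photo_signed": merged["upstream_photo"].astype(int),
                "video_signed": merged["upstream_video"].astype(float),
            }
        ),
        pd.DataFrame(
            {
                "hour": merged["hour"],
                "direction": "down",
                "photo_signed": -merged["downstream_photo"].astype(int),
                "video_signed": -merged["downstream_video"].astype(float),
            }
        ),
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["hour", "direction"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return out[list(SIGNED_COLUMNS)]


def read_paired_observations(path) -> pd.DataFrame:
    """Read a paired subsample CSV (``hour,direction,photo,video``).

    Magnitudes in the file are non-negative; the sign convention
    (up positive, down negative) is applied here.  Each (hour, direction)
    pair may appear at most once.
    """
    df = pd.read_csv(path)
    _require_columns(df, PAIRED_COLUMNS, f"paired subsample file {path}")
    df["hour"] = _parse_times(df["hour"], "hour").dt.floor("h")
    bad_dir = ~df["direction"].isin(["up", "down"])
    if bad_dir.any():
        row = int(np.flatnonzero(bad_dir.to_numpy())[0])
        raise CountDataError(
            f"direction must be 'up' or 'down', got {df['direction'].iloc[row]!r}"
            f" at data row {row + 1}"
        )
    for col in ("photo", "video"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any():
            raise CountDataError(f"column {col} must hold non-negative magnitudes")
        df[col] = vals
    dupes = df.duplicated(subset=["hour", "direction"])
    if dupes.any():
        row = int(np.flatnonzero(dupes.to_numpy())[0])
        raise CountDataError(
            f"duplicated observation for hour {df['hour'].iloc[row]}"
            f" direction {df['direction'].iloc[row]!r}"
        )
    sign = np.where(df["direction"] == "up", 1.0, -1.0)
    out = pd.DataFrame(
        {
            "hour": df["hour"],
            "direction": df["direction"],
            "photo_signed": (sign * df["photo"]).astype(int),
            "video_signed": sign * df["video"].astype(float),
        }
    )
    return out[list(SIGNED_COLUMNS)]


def write_paired_observations(signed: pd.DataFrame, path) -> None:
    """Write a signed observation frame back to the unsigned CSV dialect."""
    _require_columns(signed, SIGNED_COLUMNS, "signed observation frame")
    out = pd.DataFrame(
        {
            "hour": pd.DatetimeIndex(signed["hour"]).strftime("%Y-%m-%dT%H:%M:%S"),
            "direction": signed["direction"],
            "photo": signed["photo_signed"].abs(),
            "video": signed["video_signed"].abs(),
        }
    )
    out.to_csv(path, index=False)
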
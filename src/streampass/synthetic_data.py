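"""Ground-truthed salmon-run and camera simulator.

Generates the kind of data the field system produces — pulsed,
bidirectional hourly passage with diel structure, observed through a
thinned photo-detection process — together with complete ground truth
(per-fish entry days and lifetimes, true hourly passage, true daily
abundance, true escapement), so that every stage of the estimation
pipeline can be exercised and scored without field data.

The run model: fish enter in one or more pulses (entry days normal around
a pulse peak, truncated to the season), at an entry hour drawn from a diel
activity profile concentrated in the afternoon/evening, and remain until
death after a stream-life drawn from the survival distribution.  While
alive, a fish may make same-day downstream-then-upstream excursions
(predator avoidance, milling) at a fixed per-day rate; excursions create
matched down/up hourly movements and leave net passage equal to entries.

The camera model: reviewed video is treated as exact truth (the subsample
protocol restricts to hours with essentially perfect detection), while
each fish passing in an hour appears in the time-lapse photo record
independently with a per-direction detection probability — binomial
thinning of the true hourly passage.  Thinning reproduces the
linear photo↔video relationship the double-sampling estimator assumes,
with slope ≈ 1/p; direction-dependent p yields a segmented relationship.

Default scenario values mirror the published proof-of-concept conditions:
a 75-day summer season, 30,000 entries in two pulses, 80% of movement
between 12:00 and 20:00, detection probabilities 0.065 (up) / 0.053 (down)
— the reciprocals of the published segmented slopes 15.2/18.9 — a 7.1-day
mean stream life with SD = 0.499·mean, and a 70-hour paired subsample
(140 signed values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import count_data
from .streamlife import _lifetime_distribution


def default_diel_profile() -> np.ndarray:
    """Hourly movement weights: 80% of activity between 12:00 and 20:00."""
    w = np.full(24, 0.2 / 16)
    w[12:20] = 0.8 / 8
    return w


@dataclass
class RunScenario:
    """Parameters of a simulated salmon run and its camera observation.

    ``pulses`` is a sequence of ``(peak_day, total_entries, spread_days)``
    tuples (days are 1-based within the season).  ``excursion_rate`` is the
    per-fish per-alive-day probability of a down-then-up excursion.
    Detection probabilities are per passing fish per direction.
    """

    season_days: int = 75
    start: str = "2015-06-15"
    pulses: tuple = ((18, 20_000, 2.0), (40, 10_000, 2.5))
    diel_profile: np.ndarray = field(default_factory=default_diel_profile)
    excursion_rate: float = 0.08
    stream_life_mean: float = 7.1
    stream_life_sd: float = 3.543
    stream_life_family: str = "truncnorm"
    p_up: float = 0.065
    p_down: float = 0.053
    subsample_hours: int = 70
    seed: int | None = None

    def validate(self) -> None:
        if self.season_days < 1:
            raise ValueError("season must be at least one day")
        if not self.pulses:
            raise ValueError("at least one entry pulse is required")
        for peak, total, spread in self.pulses:
            if total <= 0:
                raise ValueError("pulse totals must be positive")
            if spread < 0:
                raise ValueError("pulse spread must be non-negative")
        prof = np.asarray(self.diel_profile, dtype=float)
        if prof.shape != (24,) or (prof < 0).any() or not np.isclose(prof.sum(), 1.0):
            raise ValueError("diel profile must be 24 non-negative weights summing to 1")
        for name, p in (("p_up", self.p_up), ("p_down", self.p_down),
                        ("excursion_rate", self.excursion_rate)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.stream_life_mean <= 0 or self.stream_life_sd < 0:
            raise ValueError("stream-life mean must be > 0 and SD >= 0")
        if self.subsample_hours < 1:
            raise ValueError("subsample must contain at least one hour")

    def to_dict(self) -> dict:
        return {
            "season_days": self.season_days,
            "start": str(self.start),
            "pulses": [list(p) for p in self.pulses],
            "diel_profile": [float(v) for v in np.asarray(self.diel_profile)],
            "excursion_rate": self.excursion_rate,
            "stream_life_mean": self.stream_life_mean,
            "stream_life_sd": self.stream_life_sd,
            "stream_life_family": self.stream_life_family,
            "p_up": self.p_up,
            "p_down": self.p_down,
            "subsample_hours": self.subsample_hours,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunScenario":
        d = dict(d)
        if "pulses" in d:
            d["pulses"] = tuple(tuple(p) for p in d["pulses"])
        if "diel_profile" in d:
            d["diel_profile"] = np.asarray(d["diel_profile"], dtype=float)
        return cls(**d)


@dataclass
class TrueRun:
    """Simulator ground truth.

    ``hourly`` holds the true hourly passage (columns
    ``hour,upstream,downstream``); ``daily_abundance`` the true living-fish
    head count per day (``date,living``); ``true_escapement`` equals total
    entries, since every excursion is a matched down/up pair.
    """

    entry_day: np.ndarray
    entry_hour: np.ndarray
    lifetime_days: np.ndarray
    hourly: pd.DataFrame
    daily_abundance: pd.DataFrame
    true_escapement: int
    scenario: RunScenario


def _sample_lifetimes(scenario: RunScenario, n: int, rng: np.random.Generator) -> np.ndarray:
    mean, sd = scenario.stream_life_mean, scenario.stream_life_sd
    if sd == 0.0:
        return np.full(n, mean)
    dist = _lifetime_distribution(mean, sd, scenario.stream_life_family)
    draws = np.asarray(dist.rvs(size=n, random_state=rng), dtype=float)
    if scenario.stream_life_family == "normal_clamped":
        draws = np.clip(draws, 1e-3, None)
    return draws


def simulate_true_run(scenario: RunScenario, seed: int | None = None) -> TrueRun:
    """Draw a ground-truthed run: entries, lifetimes, true hourly passage.

    All randomness flows from ``seed`` (falling back to ``scenario.seed``),
    so identical seeds give identical runs.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    prof = np.asarray(scenario.diel_profile, dtype=float)
    prof = prof / prof.sum()

    days = []
    for peak, total, spread in scenario.pulses:
        raw = rng.normal(loc=peak, scale=max(spread, 1e-12), size=int(total))
        days.append(np.clip(np.rint(raw), 1, scenario.season_days).astype(int))
    entry_day = np.concatenate(days)
    n_fish = entry_day.size
    entry_hour = rng.choice(24, size=n_fish, p=prof)
    lifetime = _sample_lifetimes(scenario, n_fish, rng)

    H = scenario.season_days * 24
    up_idx = (entry_day - 1) * 24 + entry_hour
    up_counts = np.bincount(up_idx, minlength=H)
    down_counts = np.zeros(H, dtype=int)

    # same-day down-then-up excursions while alive, within the season
    alive_days = np.maximum(np.ceil(lifetime).astype(int), 1)
    n_exc = rng.binomial(alive_days, scenario.excursion_rate)
    total_exc = int(n_exc.sum())
    if total_exc:
        fish = np.repeat(np.arange(n_fish), n_exc)
        offset = rng.integers(0, alive_days[fish])
        exc_day = np.minimum(entry_day[fish] + offset, scenario.season_days)
        h1 = rng.choice(24, size=total_exc, p=prof)
        h2 = rng.choice(24, size=total_exc, p=prof)
        down_hour = np.minimum(h1, h2)
        up_hour = np.maximum(h1, h2)
        down_counts = np.bincount((exc_day - 1) * 24 + down_hour, minlength=H)
        up_counts = up_counts + np.bincount((exc_day - 1) * 24 + up_hour, minlength=H)

    start = pd.Timestamp(scenario.start)
    hours = start + pd.to_timedelta(np.arange(H), unit="h")
    hourly = pd.DataFrame(
        {"hour": hours, "upstream": up_counts, "downstream": down_counts}
    )

    # true daily head count: alive on day d iff entry_day <= d < entry_day + lifetime
    last_alive = entry_day + np.ceil(lifetime).astype(int) - 1
    horizon = int(max(scenario.season_days, last_alive.max())) + 1
    events = np.zeros(horizon + 2)
    np.add.at(events, entry_day, 1)
    np.add.at(events, last_alive + 1, -1)
    living = np.cumsum(events)[1 : horizon + 1]
    dates = start.normalize() + pd.to_timedelta(np.arange(horizon), unit="D")
    daily_abundance = pd.DataFrame({"date": dates, "living": living})

    return TrueRun(
        entry_day=entry_day,
        entry_hour=entry_hour,
        lifetime_days=lifetime,
        hourly=hourly,
        daily_abundance=daily_abundance,
        true_escapement=n_fish,
        scenario=scenario,
    )


def simulate_camera(
    run: TrueRun, scenario: RunScenario | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observe a true run through the camera system.

    Returns ``(photo, video)`` hourly frames (columns
    ``hour,upstream,downstream``): photo counts are binomial thinnings of
    the true passage with the per-direction detection probabilities; video
    counts equal the true passage (reviewed video is treated as exact).
    """
    scenario = scenario or run.scenario
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    video = run.hourly.copy()
    photo = pd.DataFrame(
        {
            "hour": run.hourly["hour"],
            "upstream": rng.binomial(run.hourly["upstream"].to_numpy(), scenario.p_up),
            "downstream": rng.binomial(
                run.hourly["downstream"].to_numpy(), scenario.p_down
            ),
        }
    )
    return photo, video


def make_paired_subsample(
    photo: pd.DataFrame,
    video: pd.DataFrame,
    n_hours: int = 70,
    strategy: str = "span",
    seed: int | None = None,
) -> pd.DataFrame:
    """Choose subsample hours and emit signed paired observations.

    ``strategy="span"`` stratifies the hours over quantiles of the signed
    net photo count (upstream − downstream) and picks one hour per stratum,
    always including the extreme hours — emulating a reviewer choosing
    video hours that span the full range of time-lapse counts, from strong
    downstream to strong upstream movement.  ``strategy="random"`` is a
    simple random draw for comparison.  Each chosen hour contributes two
    signed observations.
    """
    merged = photo.merge(video, on="hour", suffixes=("_photo", "_video"))
    H = len(merged)
    if n_hours > H:
        raise ValueError(f"requested {n_hours} subsample hours but only {H} available")
    rng = np.random.default_rng(seed)
    if strategy == "span":
        net = (merged["upstream_photo"] - merged["downstream_photo"]).to_numpy()
        order = np.argsort(net, kind="stable")
        bins = np.array_split(order, n_hours)
        chosen = np.array([rng.choice(b) for b in bins])
        chosen[0] = order[0]  # force the extreme hours in
        chosen[-1] = order[-1]
    elif strategy == "random":
        chosen = rng.choice(H, size=n_hours, replace=False)
    else:
        raise ValueError(f"unknown subsample strategy {strategy!r}")
    sub = merged.iloc[np.sort(chosen)]
    photo_sub = sub[["hour", "upstream_photo", "downstream_photo"]].rename(
        columns={"upstream_photo": "upstream", "downstream_photo": "downstream"}
    )
    video_sub = sub[["hour", "upstream_video", "downstream_video"]].rename(
        columns={"upstream_video": "upstream", "downstream_video": "downstream"}
    )
    return count_data.pair_observations(photo_sub, video_sub)


def simulate_dataset(
    scenario: RunScenario, seed: int | None = None
) -> tuple[TrueRun, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full simulator: truth, camera, and paired subsample.

    Returns ``(run, photo, video, paired)``.  A single seed drives all
    three stages (independent child seeds are spawned internally).
    """
    root = np.random.SeedSequence(scenario.seed if seed is None else seed)
    s_run, s_cam, s_sub = root.spawn(3)
    run = simulate_true_run(scenario, seed=s_run)
    photo, video = simulate_camera(run, scenario, seed=s_cam)
    paired = make_paired_subsample(
        photo, video, n_hours=scenario.subsample_hours, seed=s_sub
    )
    return run, photo, video, paired
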
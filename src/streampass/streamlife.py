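"""Stream-life estimation and daily survival curves.

Spawning salmon die in the stream within days of entry — by senescence,
predation (largely bears in the focal systems) or stranding — and the time
from stream entry to death is the fish's *stream life*.  Narrow, shallow
streams expose fish to heavier predation and select for faster reproductive
schedules, so stream life shortens with stream size.  This module

1. collapses a per-stream, per-mechanism stream-life table into a single
   weighted mean stream life per stream (weights = fish dying by each
   mechanism),
2. regresses that weighted stream life on stream morphology (depth or
   width; the two are strongly collinear, so one predictor is chosen by
   AICc), and
3. converts a predicted mean stream life into a daily survival curve
   S_t = P(stream life > t), evaluated at whole days with S_0 ≡ 1.

The stream-life SD is tied to the mean (SD = ``sd_ratio`` · mean, default
0.499) rather than modelled separately, reflecting the strong mean–SD
correlation in published stream-life data.  The survival distribution
family is configurable — the default is a normal truncated below at zero
(lifetimes cannot be negative), with an untruncated-but-clamped normal and
a gamma as alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .passage_models import gaussian_aicc

DEFAULT_SD_RATIO = 0.499

STREAMLIFE_COLUMNS = ("stream", "width_m", "depth_cm", "mech", "mean_days", "n_dead")

SURVIVAL_FAMILIES = ("truncnorm", "normal_clamped", "gamma")


def weighted_stream_life(mean_days, n_dead) -> float:
    """Death-count-weighted mean stream life, Σ(meanᵢ·countᵢ)/Σcountᵢ."""
    means = np.asarray(mean_days, dtype=float)
    counts = np.asarray(n_dead, dtype=float)
    if means.shape != counts.shape:
        raise ValueError("mean_days and n_dead must have the same length")
    if (means < 0).any() or (counts < 0).any():
        raise ValueError("stream lives and death counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all death counts are zero; weighted stream life undefined")
    return float((means * counts).sum() / total)


def read_streamlife_table(path) -> pd.DataFrame:
    """Read a long-format stream-life table CSV.

    Columns: ``stream,width_m,depth_cm,mech,mean_days,n_dead`` — one row per
    stream × mortality mechanism (senescence, predation, stranding, ...).
    """
    df = pd.read_csv(path)
    missing = [c for c in STREAMLIFE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stream-life table missing column(s) {missing}")
    return df


def streamlife_records(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format table to one record per stream.

    Returns columns ``stream, width_m, depth_cm, stream_life`` where
    ``stream_life`` is the death-weighted mean across mechanisms.
    """
    rows = []
    for stream, grp in table.groupby("stream", sort=False):
        rows.append(
            {
                "stream": stream,
                "width_m": float(grp["width_m"].iloc[0]),
                "depth_cm": float(grp["depth_cm"].iloc[0]),
                "stream_life": weighted_stream_life(grp["mean_days"], grp["n_dead"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StreamLifeModel:
    """Simple linear regression of weighted stream life on one morphology
    predictor, with the AICc of both candidate predictors recorded."""

    predictor: str  # "depth_cm" or "width_m"
    intercept: float
    slope: float
    sd_ratio: float
    aicc_by_predictor: dict
    predictor_correlation: float
    n: int
    rss: float
    result: object = field(repr=False, default=None)  # statsmodels fit

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "intercept": float(self.intercept),
            "slope": float(self.slope),
            "sd_ratio": float(self.sd_ratio),
            "aicc_by_predictor": {
                k: (None if v is None else float(v))
                for k, v in self.aicc_by_predictor.items()
            },
            "predictor_correlation": float(self.predictor_correlation),
            "n": int(self.n),
            "rss": float(self.rss),
        }


@dataclass
class PredictedStreamLife:
    """Predicted mean stream life (days), the ratio-based SD, and the
    regression prediction standard error of the mean."""

    mean: float
    sd: float
    regression_se: float


def fit_streamlife_model(
    records: pd.DataFrame,
    predictor: str | None = None,
    sd_ratio: float = DEFAULT_SD_RATIO,
) -> StreamLifeModel:
    """Fit stream life ~ intercept + slope·predictor by OLS.

    Width and depth are usually too collinear to enter together, so the
    model is simple (one predictor).  If ``predictor`` is None the
    depth-only and width-only fits are compared by AICc (K = 3: intercept,
    slope, residual variance) and the lower-AICc predictor is selected;
    both AICc values and the width–depth correlation are reported either
    way.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 stream records to fit a regression")
    y = records["stream_life"].to_numpy(dtype=float)
    fits = {}
    aiccs: dict[str, float | None] = {}
    for cand in ("depth_cm", "width_m"):
        xv = records[cand].to_numpy(dtype=float)
        if np.allclose(xv, xv[0]):
            raise ValueError(f"predictor {cand!r} is constant; regression undefined")
        res = sm.OLS(y, sm.add_constant(xv)).fit()
        fits[cand] = res
        n = len(y)
        aiccs[cand] = gaussian_aicc(float(res.ssr), n, 3) if n >= 5 else None
    corr = float(np.corrcoef(records["depth_cm"], records["width_m"])[0, 1])
    if predictor is None:
        if any(v is None for v in aiccs.values()):
            raise ValueError(
                "too few records for AICc-based predictor selection; "
                "pass predictor='depth_cm' or 'width_m' explicitly"
            )
        predictor = min(aiccs, key=aiccs.get)  # type: ignore[arg-type]
    elif predictor not in fits:
        raise ValueError(f"predictor must be 'depth_cm' or 'width_m', got {predictor!r}")
    res = fits[predictor]
    return StreamLifeModel(
        predictor=predictor,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        sd_ratio=sd_ratio,
        aicc_by_predictor=aiccs,
        predictor_correlation=corr,
        n=len(y),
        rss=float(res.ssr),
        result=res,
    )


def predict_stream_life(model: StreamLifeModel, value: float) -> PredictedStreamLife:
    """Predict mean stream life (and its SD) at a morphology value.

    ``value`` is depth in cm or width in m, matching ``model.predictor``.
    The SD is ``sd_ratio · mean``; the regression prediction SE of the mean
    is reported separately (published stream-life SEs may reflect either
    convention).  A warning is issued outside the 0–200 sanity range.
    """
    if not (0 <= value <= 200):
        warnings.warn(
            f"{model.predictor} value {value} is outside the 0-200 sanity range",
            stacklevel=2,
        )
    mean = model.intercept + model.slope * value
    if mean <= 0:
        raise ValueError(
            f"predicted mean stream life {mean:.3g} d is non-positive at "
            f"{model.predictor}={value}; truncating the survival distribution "
            "cannot rescue a non-positive mean — refit on relevant streams"
        )
    se = float("nan")
    if model.result is not None:
        se = float(model.result.get_prediction([1.0, value]).se_mean[0])
    return PredictedStreamLife(mean=float(mean), sd=float(model.sd_ratio * mean), regression_se=se)


@dataclass
class SurvivalCurve:
    """Daily survival proportions S_t for t = 0..N.

    ``S[t]`` is the proportion of a cohort still alive t days after entry;
    S_0 ≡ 1, S is non-increasing, and N is the first day at which survival
    has effectively reached zero (S_N < eps).
    """

    S: np.ndarray
    mean: float
    sd: float
    family: str
    N: int
    eps: float

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S[0] != 1.0:
            raise ValueError("S_0 must be 1")
        if np.any(np.diff(self.S) > 1e-12):
            raise ValueError("survival must be non-increasing")


def _lifetime_distribution(mean: float, sd: float, family: str):
    """The continuous stream-life distribution for a family/mean/sd."""
    if family == "truncnorm":
        a = (0.0 - mean) / sd
        return stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    if family == "normal_clamped":
        return stats.norm(loc=mean, scale=sd)
    if family == "gamma":
        shape = (mean / sd) ** 2
        return stats.gamma(shape, scale=sd * sd / mean)
    raise ValueError(f"unknown survival family {family!r}; expected {SURVIVAL_FAMILIES}")


def survival_curve(
    mean: float,
    sd: float,
    family: str = "truncnorm",
    eps: float = 1e-4,
) -> SurvivalCurve:
    """Daily survival curve S_t = 1 − F(t) from a stream-life mean and SD.

    F is the CDF of the chosen lifetime distribution.  S_0 is forced to 1
    (every fish is alive on its entry day) and N is the smallest integer t
    with S_t < ``eps`` — the practical end of the cohort.  ``sd = 0``
    degenerates to a step: S_t = 1 for t < mean, 0.5 at t = mean (if mean
    is an integer day), 0 beyond.
    """
    if mean <= 0:
        raise ValueError("mean stream life must be positive")
    if sd < 0:
        raise ValueError("stream-life SD must be non-negative")
    if sd == 0.0:
        ts = np.arange(int(np.ceil(mean)) + 2)
        S = np.where(
            ts < mean, 1.0, np.where(ts == mean, 0.5, 0.0)
        ).astype(float)
        N = int(np.flatnonzero(S < eps)[0])
        return SurvivalCurve(S=S[: N + 1], mean=mean, sd=sd, family="step", N=N, eps=eps)

    dist = _lifetime_distribution(mean, sd, family)
    # horizon from the distribution's own tail quantile, so heavy-tailed
    # families (small-shape gamma) still reach S < eps
    horizon = int(np.ceil(dist.isf(eps * 0.5))) + 2
    ts = np.arange(horizon + 1)
    S = np.clip(dist.sf(ts), 0.0, 1.0)
    S[0] = 1.0
    S = np.minimum.accumulate(S)  # guard monotonicity against rounding
    below = np.flatnonzero(S < eps)
    if below.size == 0:
        raise ValueError(
            f"survival did not fall below eps={eps} within {horizon} days; "
            "check mean/sd"
        )
    N = int(below[0])
    return SurvivalCurve(S=S[: N + 1], mean=mean, sd=sd, family=family, N=N, eps=eps)


def write_survival_curve(curve: SurvivalCurve, path) -> None:
    """Write the curve as a two-column CSV ``t,S``."""
    pd.DataFrame({"t": np.arange(curve.N + 1), "S": curve.S}).to_csv(path, index=False)
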
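"""Season-long passage prediction and bootstrap escapement intervals.

Given a fitted photo→passage model and the full season of hourly photo
counts, each hour's net passage is predicted as
``f(+upstream_photo) + f(−downstream_photo)`` — the same signed model
applied to both directions — and the season total of these net predictions
is the escapement estimate (net fish that entered the stream to spawn).

Because the modelling subsample is chosen non-randomly (to span the range
of photo counts), design-based variance formulas do not apply.  The
confidence interval instead comes from a case-resampling bootstrap: redraw
the signed observations with replacement (same size as the original
subsample), refit the selected model form, re-predict the season total,
and take the 2.5/97.5 percentiles of the replicated totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .count_data import HOURLY_COLUMNS, SIGNED_COLUMNS
from .passage_models import FitError, ModelForm, PassageModelFit, fit_model


def predict_passage(fit: PassageModelFit, season: pd.DataFrame) -> pd.DataFrame:
    """Per-hour signed passage predictions for a season of photo counts.

    ``season`` has columns ``hour,upstream,downstream``.  Returns a frame
    with ``hour``, the upstream prediction (``up_pred``, ≥ 0 for sane fits),
    the downstream prediction (``down_pred``, signed negative), and their
    sum ``net``.
    """
    for col in HOURLY_COLUMNS:
        if col not in season.columns:
            raise ValueError(f"season frame is missing column {col!r}")
    up = fit.predict(season["upstream"].to_numpy(dtype=float))
    down = fit.predict(-season["downstream"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "hour": season["hour"].reset_index(drop=True),
            "up_pred": up,
            "down_pred": down,
            "net": up + down,
        }
    )


def total_escapement(predictions: pd.DataFrame) -> float:
    """Season escapement: the sum of signed net hourly predictions."""
    return float(predictions["net"].sum())


def model_spread_pct(estimates: Sequence[float]) -> float:
    """Maximum relative spread among candidate-model escapement estimates.

    ``100 · (max − min) / min`` — how much the choice of model form can move
    the answer, relative to the smallest estimate.
    """
    est = np.asarray(list(estimates), dtype=float)
    if est.size < 2:
        raise ValueError("need at least two estimates to compute a spread")
    lo = est.min()
    if lo <= 0:
        raise ValueError("spread undefined for non-positive estimates")
    return float(100.0 * (est.max() - lo) / lo)


@dataclass
class EscapementEstimate:
    """A point escapement estimate with bootstrap percentile interval.

    ``ci_half_width`` is half the percentile-interval width; because
    percentile intervals are generally asymmetric about the point estimate,
    ``ci_max_dev`` (the larger deviation of either bound from the point
    estimate) is reported as well.
    """

    total: float
    ci_low: float
    ci_high: float
    ci_half_width: float
    ci_max_dev: float
    n_boot: int
    seed: int | None
    form_name: str
    coefficients: np.ndarray
    n_degenerate: int
    boot_totals: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "total": float(self.total),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "ci_half_width": float(self.ci_half_width),
            "ci_max_dev": float(self.ci_max_dev),
            "n_boot": int(self.n_boot),
            "seed": self.seed,
            "form": self.form_name,
            "coefficients": [float(c) for c in self.coefficients],
            "n_degenerate_resamples": int(self.n_degenerate),
        }


def _season_basis_totals(form: ModelForm, season: pd.DataFrame) -> np.ndarray:
    """Sum of basis vectors over the season (both signed directions).

    The predicted season total is linear in the coefficients, so the whole
    season collapses to one vector ``s`` with total = coef · s.
    """
    up = form.basis(season["upstream"].to_numpy(dtype=float))
    down = form.basis(-season["downstream"].to_numpy(dtype=float))
    return up.sum(axis=0) + down.sum(axis=0)


def _solve_ls(X: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Normal-equations solve; None signals a degenerate resample."""
    if np.any((X != 0.0).sum(axis=0) == 0):
        return None
    gram = X.T @ X
    try:
        coef = np.linalg.solve(gram, X.T @ y)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(coef)):
        return None
    return coef


def bootstrap_escapement(
    sample: pd.DataFrame,
    form: ModelForm,
    season: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | None = None,
    resample_unit: str = "observation",
    max_degenerate_frac: float = 0.5,
) -> EscapementEstimate:
    """Bootstrap the subsample, refit, re-predict; percentile 95% CI.

    ``resample_unit`` is ``"observation"`` (default: redraw the pooled
    signed values, matching the original subsample size) or ``"hour"``
    (redraw whole hours, keeping each hour's up/down pair together).
    Rank-deficient resamples — e.g. a segmented form drawn with no
    observations on one branch — are rejected and redrawn; their count is
    recorded, and the bootstrap aborts if they exceed
    ``max_degenerate_frac`` of all draws.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fit = fit_model(sample, form)
    s = _season_basis_totals(form, season)
    point = float(fit.coefficients @ s)

    x = np.asarray(sample["photo_signed"], dtype=float)
    y = np.asarray(sample["video_signed"], dtype=float)
    X = form.basis(x)
    m = len(x)

    rng = np.random.default_rng(seed)
    if resample_unit == "hour":
        hours = pd.Index(sample["hour"])
        codes = hours.factorize()[0]
        groups = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
        n_groups = len(groups)

        def draw() -> np.ndarray:
            picks = rng.integers(0, n_groups, n_groups)
            return np.concatenate([groups[g] for g in picks])

    elif resample_unit == "observation":

        def draw() -> np.ndarray:
            return rng.integers(0, m, m)

    else:
        raise ValueError(f"unknown resample_unit {resample_unit!r}")

    totals = np.empty(n_boot)
    degenerate = 0
    attempts = 0
    for b in range(n_boot):
        while True:
            attempts += 1
            idx = draw()
            coef = _solve_ls(X[idx], y[idx])
            if coef is not None:
                break
            degenerate += 1
            if attempts >= 20 and degenerate > max_degenerate_frac * attempts:
                raise FitError(
                    f"bootstrap aborted: {degenerate}/{attempts} resamples were "
                    "rank-deficient; the subsample cannot support this model form"
                )
        totals[b] = coef @ s

    lo, hi = np.percentile(totals, [2.5, 97.5])
    return EscapementEstimate(
        total=point,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_half_width=float((hi - lo) / 2.0),
        ci_max_dev=float(max(point - lo, hi - point)),
        n_boot=n_boot,
        seed=seed,
        form_name=form.name,
        coefficients=fit.coefficients,
        n_degenerate=degenerate,
        boot_totals=totals,
    )
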
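"""Candidate photo-count → passage regression models.

The double-sampling estimator rests on a regression of video-enumerated
passage (the accurate but expensive count) on time-lapse photo counts (the
cheap auxiliary count), fitted to a subsample of hours and then applied to
every hour of the season.  Four candidate forms are compared, all forced
through the origin (no fish in the photos, no passage):

``first_order``
    pass = b·x — a single detection-rate slope.
``polynomial``
    pass = b₁·x + b₂·x² — detection changing with run intensity.
``segmented_first``
    pass = b⁺·x⁺ + b⁻·x⁻ with x⁺ = max(x, 0), x⁻ = min(x, 0) — separate
    slopes for upstream and downstream movement (fish swim slower against
    the current, so their per-burst detection probability can differ by
    direction).  The split point is fixed at zero.
``segmented_poly``
    the segmented slopes plus a quadratic term.  By default the quadratic
    is a single shared x² coefficient; a sign-antisymmetric alternative
    (x·|x|) is selectable, which keeps the curvature an odd function of
    signed passage.

Model comparison uses small-sample AICc under the usual Gaussian
least-squares likelihood, with the residual variance counted as a
parameter (K = slopes + 1).  Only AICc *differences* matter for ranking,
so the additive normal constant does not affect selection; it is included
so the numbers are honest log-likelihoods.  Leave-one-out cross-validation
supplies an accuracy (signed percent error of the summed predictions) and
a precision (mean squared error) diagnostic for each form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class ModelSpecError(ValueError):
    """A model form or metric was requested with invalid inputs."""


class FitError(RuntimeError):
    """A least-squares fit could not be computed on the given sample."""


def _positive(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _negative(x: np.ndarray) -> np.ndarray:
    return np.minimum(x, 0.0)


@dataclass(frozen=True)
class ModelForm:
    """A through-origin regression basis over signed photo counts."""

    name: str
    k_slopes: int
    terms: tuple[str, ...]
    builder: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def basis(self, x) -> np.ndarray:
        """Design matrix, one row per signed photo count. basis(0) = 0."""
        arr = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(arr)):
            raise ModelSpecError(f"photo counts must be finite for form {self.name!r}")
        X = self.builder(arr)
        return X

    def formula(self, coefficients: Sequence[float]) -> str:
        """Human-readable model equation, e.g. ``pass = (x>0)*15.242 + ...``."""
        pretty = {"x": "x", "x^2": "x^2", "x+": "(x>0)", "x-": "(x<0)", "x|x|": "x|x|"}
        parts = [f"{pretty[t]}*{c:.4g}" for t, c in zip(self.terms, coefficients)]
        return "pass = " + " + ".join(parts)


FIRST_ORDER = ModelForm("first_order", 1, ("x",), lambda x: x[:, None])
POLYNOMIAL = ModelForm("polynomial", 2, ("x", "x^2"), lambda x: np.column_stack((x, x * x)))
SEGMENTED_FIRST = ModelForm(
    "segmented_first",
    2,
    ("x+", "x-"),
    lambda x: np.column_stack((_positive(x), _negative(x))),
)
SEGMENTED_POLY_SHARED = ModelForm(
    "segmented_poly",
    3,
    ("x+", "x-", "x^2"),
    lambda x: np.column_stack((_positive(x), _negative(x), x * x)),
)
SEGMENTED_POLY_ANTISYM = ModelForm(
    "segmented_poly",
    3,
    ("x+", "x-", "x|x|"),
    lambda x: np.column_stack((_positive(x), _negative(x), x * np.abs(x))),
)

FORM_NAMES = ("first_order", "polynomial", "segmented_first", "segmented_poly")


def get_form(name: str, seg_poly_basis: str = "shared_quadratic") -> ModelForm:
    """Look up a model form by name.

    ``seg_poly_basis`` selects the quadratic convention for the segmented
    polynomial: ``"shared_quadratic"`` (one x² coefficient) or
    ``"antisymmetric"`` (x·|x|, odd in x).
    """
    if name == "first_order":
        return FIRST_ORDER
    if name == "polynomial":
        return POLYNOMIAL
    if name == "segmented_first":
        return SEGMENTED_FIRST
    if name == "segmented_poly":
        if seg_poly_basis == "shared_quadratic":
            return SEGMENTED_POLY_SHARED
        if seg_poly_basis == "antisymmetric":
            return SEGMENTED_POLY_ANTISYM
        raise ModelSpecError(f"unknown seg_poly_basis {seg_poly_basis!r}")
    raise ModelSpecError(f"unknown model form {name!r}; expected one of {FORM_NAMES}")


def default_forms(seg_poly_basis: str = "shared_quadratic") -> list[ModelForm]:
    """The standard candidate set, in canonical order."""
    return [get_form(n, seg_poly_basis) for n in FORM_NAMES]


def gaussian_aicc(
    rss: float, n: int, n_params: int, include_constant: bool = True
) -> float:
    """Small-sample AIC for a Gaussian least-squares fit.

    ``n_params`` is the total parameter count K (slopes plus the residual
    variance).  With the constant included this is
    ``n·ln(rss/n) + n·ln(2π) + n + 2K + 2K(K+1)/(n−K−1)``.
    A zero RSS (perfect fit) returns −inf.
    """
    if n - n_params - 1 <= 0:
        raise ModelSpecError(
            f"AICc undefined: need n > K + 1 (n={n}, K={n_params})"
        )
    if rss < 0:
        raise ModelSpecError("rss must be non-negative")
    if rss == 0:
        return -math.inf
    ll = n * math.log(rss / n)
    if include_constant:
        ll += n * math.log(2.0 * math.pi) + n
    return ll + 2 * n_params + (2 * n_params * (n_params + 1)) / (n - n_params - 1)


@dataclass
class PassageModelFit:
    """A fitted through-origin passage model and its diagnostics.

    ``n_params`` counts the residual variance (K = k_slopes + 1), the
    convention used for AICc; ``k_slopes`` is the slope-only count reported
    alongside for reference.  LOOCV fields are populated by
    :func:`select_model` (or :func:`loocv` directly).
    """

    form: ModelForm
    coefficients: np.ndarray
    n: int
    rss: float
    aicc: float
    k_slopes: int
    n_params: int
    loocv_accuracy_pct: float | None = None
    loocv_mse: float | None = None

    def predict(self, x) -> np.ndarray:
        """Predicted signed passage for signed photo count(s) ``x``."""
        return self.form.basis(x) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "form": self.form.name,
            "terms": list(self.form.terms),
            "formula": self.form.formula(self.coefficients),
            "coefficients": [float(c) for c in self.coefficients],
            "n": int(self.n),
            "k_slopes": int(self.k_slopes),
            "n_params": int(self.n_params),
            "rss": float(self.rss),
            "aicc": float(self.aicc),
            "loocv_accuracy_pct": None
            if self.loocv_accuracy_pct is None
            else float(self.loocv_accuracy_pct),
            "loocv_mse": None if self.loocv_mse is None else float(self.loocv_mse),
        }


def _design(sample: pd.DataFrame, form: ModelForm) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(sample["photo_signed"], dtype=float)
    y = np.asarray(sample["video_signed"], dtype=float)
    X = form.basis(x)
    empty = [t for j, t in enumerate(form.terms) if not np.any(X[:, j] != 0.0)]
    if empty:
        raise FitError(
            f"form {form.name!r}: design column(s) {empty} are identically zero "
            "(no observations on that branch)"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(f"form {form.name!r}: rank-deficient design matrix")
    return X, y


def fit_model(sample: pd.DataFrame, form: ModelForm) -> PassageModelFit:
    """Through-origin ordinary least squares of video on photo counts.

    ``sample`` is a signed observation frame (columns ``photo_signed``,
    ``video_signed``).  Raises :class:`FitError` for rank-deficient designs,
    naming an empty segmented branch when that is the cause.
    """
    X, y = _design(sample, form)
    n, k = X.shape
    if n < k + 3:
        raise FitError(
            f"form {form.name!r}: need at least {k + 3} observations, got {n}"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    n_params = k + 1
    return PassageModelFit(
        form=form,
        coefficients=coef,
        n=n,
        rss=rss,
        aicc=gaussian_aicc(rss, n, n_params),
        k_slopes=k,
        n_params=n_params,
    )


@dataclass
class LOOCVResult:
    """Leave-one-out predictions and the derived accuracy/precision."""

    predictions: np.ndarray
    accuracy_pct: float
    mse: float


def loocv(sample: pd.DataFrame, form: ModelForm) -> LOOCVResult:
    """Exact leave-one-out cross-validation for a linear least-squares fit.

    Uses the hat-matrix identity ŷ₍₋ᵢ₎ = yᵢ − eᵢ/(1 − hᵢᵢ), which equals an
    explicit refit with observation i deleted.  Accuracy is the signed
    percent difference between the summed LOO predictions and the summed
    observed (signed) passage; MSE is the mean squared LOO residual.
    """
    fit = fit_model(sample, form)
    X, y = _design(sample, form)
    Q, _ = np.linalg.qr(X)
    h = np.einsum("ij,ij->i", Q, Q)
    blown = np.flatnonzero(h > 1.0 - 1e-10)
    if blown.size:
        raise FitError(
            f"form {form.name!r}: deleting observation {int(blown[0])} leaves a "
            "rank-deficient design (leverage 1)"
        )
    resid = y - X @ fit.coefficients
    preds = y - resid / (1.0 - h)
    total = float(y.sum())
    if total == 0.0:
        raise ModelSpecError(
            "net signed passage of the subsample is zero; LOOCV accuracy undefined"
        )
    accuracy = 100.0 * (float(preds.sum()) - total) / total
    mse = float(np.mean((preds - y) ** 2))
    return LOOCVResult(predictions=preds, accuracy_pct=accuracy, mse=mse)


def select_model(
    sample: pd.DataFrame,
    forms: Sequence[ModelForm] | None = None,
    seg_poly_basis: str = "shared_quadratic",
    tie_tol: float = 1e-9,
    override: str | None = None,
) -> list[PassageModelFit]:
    """Fit the candidate set and rank it by AICc (ascending).

    LOOCV accuracy and MSE are attached to every fit and reported alongside;
    ranking is by AICc, with near-exact ties (within ``tie_tol``) broken in
    favour of fewer parameters.  ``override`` forces a named form to the top
    (a manual selection) without changing the computed metrics.  Forms that
    fail to fit are dropped; if none fit, a :class:`FitError` aggregates the
    individual failures.
    """
    if forms is None:
        forms = default_forms(seg_poly_basis)
    fits: list[PassageModelFit] = []
    failures: list[str] = []
    for form in forms:
        try:
            fit = fit_model(sample, form)
            cv = loocv(sample, form)
        except (FitError, ModelSpecError) as exc:
            failures.append(str(exc))
            continue
        fit.loocv_accuracy_pct = cv.accuracy_pct
        fit.loocv_mse = cv.mse
        fits.append(fit)
    if not fits:
        raise FitError("no candidate model could be fitted: " + "; ".join(failures))
    fits.sort(key=lambda f: (f.aicc, f.n_params))
    # parsimony tie-break for AICc ties below tie_tol
    for i in range(len(fits) - 1):
        a, b = fits[i], fits[i + 1]
        if abs(a.aicc - b.aicc) < tie_tol and b.n_params < a.n_params:
            fits[i], fits[i + 1] = b, a
    if override is not None:
        idx = [i for i, f in enumerate(fits) if f.form.name == override]
        if not idx:
            raise ModelSpecError(
                f"override form {override!r} is not among the fitted candidates"
            )
        fits.insert(0, fits.pop(idx[0]))
    return fits


def model_report(fits: Sequence[PassageModelFit]) -> pd.DataFrame:
    """Tabular summary of a ranked candidate set (one row per model)."""
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "model": f.form.name,
                "formula": f.form.formula(f.coefficients),
                "k": f.k_slopes,
                "K": f.n_params,
                "aicc": f.aicc,
                "accuracy_pct": f.loocv_accuracy_pct,
                "mse": f.loocv_mse,
            }
            for i, f in enumerate(fits)
        ]
    )
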
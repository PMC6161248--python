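"""External calibration: serial dilutions, weighted/transformed regression,
quantification limits, and carryover checks.

Calibration series for targeted LC-MS/MS are strongly heteroscedastic: the
response scatter grows roughly in proportion to concentration over the
1000-fold dynamic range of an 11-point serial dilution.  Two standard
remedies are supported and are mutually exclusive:

* ``weighting="inv_x"`` — weighted least squares with weight 1/x on the
  untransformed scale, down-weighting the high end;
* ``transform="loglog"`` — ordinary least squares of ln(response) on
  ln(concentration), which stabilises proportional variance directly (so a
  further 1/x weighting would double-correct and is forced off).

The fitted curve is summarised by its coefficients, the coefficient of
determination on the fitted scale, per-level back-calculated accuracies
(measured/nominal x 100), and the quantification limits LLOQ/ULOQ derived
from the standard bioanalytical acceptance bands: +/-15% accuracy, relaxed
to +/-20% at the lowest calibration level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CalibrationError

ACCURACY_BAND_PCT = 15.0
ACCURACY_BAND_LLOQ_PCT = 20.0
CARRYOVER_THRESHOLD_PCT = 20.0

#: Candidate (model, transform, weighting) triples tried by default, in
#: increasing complexity order (the tie-break order of select_model).
DEFAULT_CANDIDATES: list[tuple[str, str | None, str | None]] = [
    ("linear", None, "inv_x"),
    ("linear", "loglog", None),
    ("quadratic", None, "inv_x"),
]


def make_serial_dilution(
    top_conc: float, n_levels: int = 11, factor: float = 2.0
) -> np.ndarray:
    """Nominal concentrations of a serial dilution, ascending.

    Level ``i`` (1-based) is ``top_conc / factor**(n_levels - i)``; the
    dynamic range is ``factor**(n_levels - 1)`` (1024-fold for the default
    11 levels at factor 2, i.e. over 1000-fold).
    """
    if top_conc <= 0:
        raise CalibrationError(f"top concentration must be positive, got {top_conc}")
    if n_levels < 2:
        raise CalibrationError("need at least 2 levels")
    if factor <= 1:
        raise CalibrationError("dilution factor must exceed 1")
    exponents = np.arange(n_levels - 1, -1, -1, dtype=float)
    return top_conc / factor ** exponents


@dataclass
class CalibrationSeries:
    """Response-ratio series versus nominal concentration (ascending)."""

    hmdb_id: str
    nominal: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.nominal = np.asarray(self.nominal, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.nominal.shape != self.response.shape:
            raise CalibrationError("nominal and response lengths differ")
        if np.any(np.diff(self.nominal) <= 0):
            raise CalibrationError("nominal concentrations must strictly increase")

    def __len__(self) -> int:
        return len(self.nominal)


@dataclass
class CurveFit:
    """Fitted calibration curve (the results object of CalibrationModel).

    ``coefficients`` are in ascending powers on the fitted scale (intercept
    first).  ``backcalc_accuracy`` holds the per-level measured/nominal
    percentage; levels whose response cannot be inverted are NaN.
    ``lloq``/``uloq`` are None when no calibration level meets the accuracy
    bands (the curve is then ``rejected``).
    """

    hmdb_id: str
    model: str
    transform: str | None
    weighting: str | None
    coefficients: np.ndarray
    r_squared: float
    nominal: np.ndarray
    response: np.ndarray
    lloq: float | None = None
    uloq: float | None = None
    backcalc_accuracy: np.ndarray | None = None
    rejected: bool = False

    # -- prediction / inversion -------------------------------------------

    def _to_fitted_x(self, conc: np.ndarray) -> np.ndarray:
        return np.log(conc) if self.transform == "loglog" else conc

    def predict(self, conc):
        """Predicted response at concentration(s), on the original scale."""
        conc = np.asarray(conc, dtype=float)
        x = self._to_fitted_x(conc)
        y = np.polyval(self.coefficients[::-1], x)
        return np.exp(y) if self.transform == "loglog" else y

    def back_calculate(self, response):
        """Inverse-predicted concentration(s) on the original scale.

        Responses outside the invertible region give NaN (flagged
        non-quantifiable downstream), never an exception.
        """
        response = np.asarray(response, dtype=float)
        scalar = response.ndim == 0
        resp = np.atleast_1d(response).astype(float)
        out = np.full(resp.shape, np.nan)
        xlo, xhi = self._to_fitted_x(self.nominal[[0, -1]])
        for i, r in enumerate(resp):
            if np.isnan(r):
                continue
            if self.transform == "loglog":
                if r <= 0:
                    continue
                y = np.log(r)
            else:
                y = r
            x = self._invert_fitted(y, xlo, xhi)
            if x is None:
                continue
            out[i] = np.exp(x) if self.transform == "loglog" else x
        return float(out[0]) if scalar else out

    def _invert_fitted(self, y: float, xlo: float, xhi: float) -> float | None:
        c = self.coefficients
        if self.model == "linear":
            if c[1] == 0:
                return None
            return (y - c[0]) / c[1]
        a, b, q = c[2], c[1], c[0] - y
        if a == 0:
            return None if b == 0 else -q / b
        disc = b * b - 4 * a * q
        if disc < 0:
            return None
        root = np.sqrt(disc)
        roots = [(-b - root) / (2 * a), (-b + root) / (2 * a)]
        inside = [r for r in roots if xlo <= r <= xhi]
        if len(inside) == 1:
            return inside[0]
        # both or neither inside the calibrated range: nearest to midpoint
        mid = 0.5 * (xlo + xhi)
        return min(roots, key=lambda r: abs(r - mid))

    def accuracy_at(self, nominal: np.ndarray, response: np.ndarray) -> np.ndarray:
        """Back-calculated accuracy (%) per level."""
        back = self.back_calculate(response)
        return 100.0 * np.asarray(back) / np.asarray(nominal, dtype=float)

    def summary(self) -> str:
        coef = ", ".join(f"b{i}={c:.6g}" for i, c in enumerate(self.coefficients))
        loq = (
            f"LLOQ={self.lloq:.6g}, ULOQ={self.uloq:.6g}"
            if self.lloq is not None
            else "rejected (no passing level)"
        )
        return (
            f"CurveFit[{self.hmdb_id}] {self.model}"
            f"/{self.transform or 'none'}/{self.weighting or 'none'}: "
            f"{coef}; R2={self.r_squared:.4f}; {loq}"
        )


class CalibrationModel:
    """Weighted/transformed polynomial regression of response on concentration.

    Parameters
    ----------
    series : CalibrationSeries
    model : {"linear", "quadratic"}
    transform : {None, "loglog"}
        ``loglog`` fits ln(response) on ln(concentration); requires strictly
        positive concentrations and responses and forces ``weighting=None``.
    weighting : {None, "inv_x"}
        ``inv_x`` applies weight 1/nominal on the untransformed scale.
    """

    _ORDER = {"linear": 1, "quadratic": 2}

    def __init__(
        self,
        series: CalibrationSeries,
        model: str = "linear",
        transform: str | None = None,
        weighting: str | None = None,
    ) -> None:
        if model not in self._ORDER:
            raise CalibrationError(f"unknown model {model!r}")
        if transform not in (None, "none", "loglog"):
            raise CalibrationError(f"unknown transform {transform!r}")
        if weighting not in (None, "none", "inv_x"):
            raise CalibrationError(f"unknown weighting {weighting!r}")
        transform = None if transform == "none" else transform
        weighting = None if weighting == "none" else weighting
        if transform == "loglog" and weighting is not None:
            warnings.warn(
                "loglog transform already stabilises proportional variance; "
                "forcing weighting to none",
                stacklevel=2,
            )
            weighting = None
        self.series = series
        self.model = model
        self.transform = transform
        self.weighting = weighting

    def fit(self) -> CurveFit:
        s = self.series
        mask = ~(np.isnan(s.nominal) | np.isnan(s.response))
        nominal, response = s.nominal[mask], s.response[mask]
        order = self._ORDER[self.model]
        if len(nominal) < order + 2:
            raise CalibrationError(
                f"{s.hmdb_id}: need at least {order + 2} non-missing levels, "
                f"got {len(nominal)}"
            )
        if self.transform == "loglog":
            if np.any(nominal <= 0) or np.any(response <= 0):
                raise CalibrationError(
                    f"{s.hmdb_id}: loglog requires positive concentrations "
                    "and responses"
                )
            x, y = np.log(nominal), np.log(response)
            w = np.ones_like(x)
        else:
            x, y = nominal, response
            if self.weighting == "inv_x":
                if np.any(nominal <= 0):
                    raise CalibrationError(
                        f"{s.hmdb_id}: 1/x weighting requires positive "
                        "concentrations"
                    )
                w = 1.0 / nominal
            else:
                w = np.ones_like(x)

        design = np.vander(x, order + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)

        fitted = design @ coef
        ss_res = float(np.sum(w * (y - fitted) ** 2))
        ybar = float(np.sum(w * y) / np.sum(w))
        ss_tot = float(np.sum(w * (y - ybar) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

        fit = CurveFit(
            hmdb_id=s.hmdb_id,
            model=self.model,
            transform=self.transform,
            weighting=self.weighting,
            coefficients=coef,
            r_squared=r2,
            nominal=nominal,
            response=response,
        )
        fit.backcalc_accuracy = fit.accuracy_at(nominal, response)
        lloq, uloq = determine_loq(fit)
        fit.lloq, fit.uloq = lloq, uloq
        fit.rejected = lloq is None
        return fit


def fit_curve(
    series: CalibrationSeries,
    model: str = "linear",
    transform: str | None = None,
    weighting: str | None = None,
) -> CurveFit:
    """Functional shorthand for ``CalibrationModel(series, ...).fit()``."""
    return CalibrationModel(series, model, transform, weighting).fit()


def back_calculate(fit: CurveFit, response) -> float | np.ndarray:
    return fit.back_calculate(response)


def _passing_levels(accuracy: np.ndarray) -> np.ndarray:
    """Boolean pass mask: +/-15% everywhere, +/-20% at the lowest level."""
    dev = np.abs(accuracy - 100.0)
    band = np.full(dev.shape, ACCURACY_BAND_PCT)
    band[0] = ACCURACY_BAND_LLOQ_PCT
    with np.errstate(invalid="ignore"):
        return (dev <= band) & ~np.isnan(dev)


def determine_loq(fit: CurveFit) -> tuple[float | None, float | None]:
    """LLOQ/ULOQ from the longest contiguous run of accuracy-passing levels.

    Returns (None, None) when no level passes; the curve is then rejected
    for that metabolite (flagged, not fatal).
    """
    acc = fit.backcalc_accuracy
    if acc is None:
        acc = fit.accuracy_at(fit.nominal, fit.response)
    ok = _passing_levels(np.asarray(acc))
    best: tuple[int, int] | None = None
    start = None
    for i, flag in enumerate(list(ok) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    if best is None:
        return None, None
    lo, hi = best
    return float(fit.nominal[lo]), float(fit.nominal[hi])


def select_model(
    series: CalibrationSeries,
    candidates: Sequence[tuple[str, str | None, str | None]] | None = None,
) -> CurveFit:
    """Fit every candidate and keep the best.

    Ranking: most accuracy-passing levels; ties broken by higher R-squared,
    then by simplicity (linear before quadratic, no transform before
    loglog, no weighting before 1/x).
    """
    cands = list(candidates) if candidates is not None else list(DEFAULT_CANDIDATES)
    if not cands:
        raise CalibrationError("need at least one candidate")
    scored = []
    for rank, (model, transform, weighting) in enumerate(cands):
        try:
            fit = fit_curve(series, model, transform, weighting)
        except CalibrationError:
            continue
        n_pass = int(_passing_levels(np.asarray(fit.backcalc_accuracy)).sum())
        complexity = (
            0 if fit.model == "linear" else 1,
            0 if fit.transform is None else 1,
            0 if fit.weighting is None else 1,
            rank,
        )
        scored.append((-n_pass, -fit.r_squared, complexity, fit))
    if not scored:
        raise CalibrationError(f"{series.hmdb_id}: no candidate could be fitted")
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]


@dataclass
class CarryoverResult:
    carryover_pct: float
    passed: bool
    threshold_pct: float = CARRYOVER_THRESHOLD_PCT

    def __iter__(self):
        return iter((self.carryover_pct, self.passed))


def check_carryover(
    blank_area: float,
    lloq_area: float,
    threshold_pct: float = CARRYOVER_THRESHOLD_PCT,
) -> CarryoverResult:
    """Blank-after-ULOQ signal as a percentage of the LLOQ peak area.

    Passes when the blank signal is at most ``threshold_pct`` (default 20%)
    of the LLOQ-level area.
    """
    if lloq_area <= 0:
        raise CalibrationError("LLOQ peak area must be positive")
    if blank_area < 0:
        raise CalibrationError("blank peak area cannot be negative")
    pct = 100.0 * blank_area / lloq_area
    return CarryoverResult(pct, pct <= threshold_pct, threshold_pct)
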
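"""Dose-response (4PL) fitting, IC50/AUC summaries and drug-synergy models.

Viability is normalised to the untreated control; the four-parameter
logistic curve is

    v(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

on concentration ``x``.  Synergy works on inhibition fractions
``y = clip(1 - v, 0, 1)``: expected combination effects under the Bliss,
HSA, Loewe and ZIP reference models are compared with the observed grid;
the synergy score is 100 times the mean excess inhibition over all
combination cells (positive = synergy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "DoseMatrix",
    "normalize_viability",
    "fit_4pl",
    "auc_dose_response",
    "expected_inhibition",
    "synergy_score",
    "fourpl",
]

SYNERGY_MODELS = ("bliss", "hsa", "loewe", "zip")


def fourpl(x, bottom: float, top: float, ic50: float, hill: float):
    """Four-parameter logistic viability curve."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def normalize_viability(raw, untreated_controls) -> np.ndarray:
    """Divide readings by the untreated-control mean (control mean -> 1)."""
    controls = np.asarray(untreated_controls, dtype=float)
    if controls.size == 0:
        raise ValueError("need at least one control well")
    mean = controls.mean()
    if mean <= 0:
        raise ValueError("non-positive control mean")
    return np.asarray(raw, dtype=float) / mean


@dataclass
class DoseResponseCurve:
    drug: str
    doses: np.ndarray
    viability: np.ndarray
    bottom: float
    top: float
    ic50: float
    hill: float
    residual: float
    converged: bool
    _fallback: Callable | None = field(default=None, repr=False)

    def predict(self, x) -> np.ndarray:
        """Fitted viability; a flagged curve uses its monotone-spline fallback."""
        if self.converged:
            return fourpl(x, self.bottom, self.top, self.ic50, self.hill)
        if self._fallback is None:
            raise ValueError(f"no usable fit for drug {self.drug!r}")
        x = np.asarray(x, dtype=float)
        lo, hi = self.doses.min(), self.doses.max()
        return self._fallback(np.log10(np.clip(x, lo, hi)))

    def inhibition(self, x) -> np.ndarray:
        return np.clip(1.0 - self.predict(x), 0.0, 1.0)

    def inverse_inhibition(self, effect: float) -> float:
        """Dose producing the given inhibition fraction (bisection, 1e-6).

        NaN when the effect is outside the curve's achievable range.
        """
        lo = self.ic50 * 1e-9 if self.converged else self.doses.min()
        hi = self.ic50 * 1e9 if self.converged else self.doses.max()
        ylo, yhi = float(self.inhibition(lo)), float(self.inhibition(hi))
        if ylo > yhi:
            lo, hi, ylo, yhi = hi, lo, yhi, ylo
        if not (ylo - 1e-9 <= effect <= yhi + 1e-9):
            return float("nan")
        llo, lhi = np.log10(lo), np.log10(hi)
        while lhi - llo > 1e-6:
            mid = 0.5 * (llo + lhi)
            if float(self.inhibition(10**mid)) < effect:
                llo = mid
            else:
                lhi = mid
        return float(10 ** (0.5 * (llo + lhi)))


def fit_4pl(doses, responses, drug: str = "drug") -> DoseResponseCurve:
    """Least-squares 4PL fit with a fixed multi-start grid.

    Starts span hill in {+/-0.5, +/-1, +/-2} and ic50 over the observed
    dose range; bounds: bottom in [-0.2, 1], top in [0.5, 1.5].  A curve
    with no dose effect (response range < 0.05) or no converging start is
    flagged non-convergent and falls back to a monotone spline in
    log10(dose) for synergy use.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    keep = x > 0
    x, y = x[keep], y[keep]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct positive doses")
    spline = PchipInterpolator(*_mean_by_dose(np.log10(x), y))
    flat = DoseResponseCurve(
        drug, x, y, float(np.mean(y)), float(np.mean(y)),
        float(np.median(x)), 1.0, float(np.std(y)), False, spline,
    )
    if y.max() - y.min() < 0.05:
        return flat  # no dose effect
    bounds = ([-0.2, 0.5, x.min() / 100.0, -6.0],
              [1.0, 1.5, x.max() * 100.0, 6.0])
    ic50_grid = np.geomspace(x.min(), x.max(), 4)
    best = None
    for hill0 in (0.5, 1.0, 2.0, -0.5, -1.0, -2.0):
        for ic0 in ic50_grid:
            p0 = np.clip(
                [max(y.min(), -0.2), min(max(y.max(), 0.5), 1.5), ic0, hill0],
                bounds[0], bounds[1],
            )
            try:
                res = least_squares(
                    lambda p: fourpl(x, *p) - y, p0, bounds=bounds,
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-15:
                best = res
    if best is None or not best.success:
        return flat
    bottom, top, ic50, hill = best.x
    return DoseResponseCurve(
        drug, x, y, float(bottom), float(top), float(ic50), float(hill),
        float(np.sqrt(2 * best.cost / x.size)), True, spline,
    )


def _mean_by_dose(logx: np.ndarray, y: np.ndarray):
    ux = np.unique(logx)
    return ux, np.array([y[logx == v].mean() for v in ux])


def auc_dose_response(doses, viability) -> float:
    """Mean viability over log10(dose): trapezoid integral / log-dose span."""
    x = np.asarray(doses, dtype=float)
    y = np.asarray(viability, dtype=float)
    keep = x > 0
    x, y = x[keep], y[keep]
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct positive doses")
    lx, my = _mean_by_dose(np.log10(x), y)
    return float(np.trapezoid(my, lx) / (lx[-1] - lx[0]))


@dataclass
class DoseMatrix:
    """Two-drug viability grid; row/column at dose 0 are the monotherapies."""

    drug1: str
    drug2: str
    doses1: np.ndarray  # includes 0 at index 0
    doses2: np.ndarray
    viability: np.ndarray  # shape (len(doses1), len(doses2))

    def __post_init__(self) -> None:
        self.doses1 = np.asarray(self.doses1, dtype=float)
        self.doses2 = np.asarray(self.doses2, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (self.doses1.size, self.doses2.size):
            raise ValueError("viability grid does not match dose vectors")
        if self.doses1[0] != 0 or self.doses2[0] != 0:
            raise ValueError("dose vectors must start at 0 (monotherapy axes)")
        if not (np.all(np.diff(self.doses1) > 0) and np.all(np.diff(self.doses2) > 0)):
            raise ValueError("doses must be strictly increasing")

    @property
    def inhibition(self) -> np.ndarray:
        return np.clip(1.0 - self.viability, 0.0, 1.0)

    def monotherapy_curve(self, which: int) -> DoseResponseCurve:
        if which == 1:
            return fit_4pl(self.doses1[1:], self.viability[1:, 0], self.drug1)
        return fit_4pl(self.doses2[1:], self.viability[0, 1:], self.drug2)


def _zip_directional(doses, effects, baseline: float):
    """Fit the ZIP potency-shift curve E(x)=b+(1-b)(x/m)^h/(1+(x/m)^h)."""
    x = np.asarray(doses, dtype=float)
    y = np.asarray(effects, dtype=float)
    if x.size < 2 or baseline >= 1.0:
        return None

    def resid(p):
        m, h = p
        t = (x / m) ** h
        return baseline + (1.0 - baseline) * t / (1.0 + t) - y

    best = None
    for h0 in (0.5, 1.0, 2.0):
        for m0 in np.geomspace(x.min(), x.max(), 3):
            try:
                res = least_squares(
                    resid, [m0, h0],
                    bounds=([x.min() / 1e4, 0.05], [x.max() * 1e4, 10.0]),
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not best.success:
        return None
    m, h = best.x

    def curve(xq):
        t = (np.asarray(xq, dtype=float) / m) ** h
        return baseline + (1.0 - baseline) * t / (1.0 + t)

    return curve


def expected_inhibition(model: str, matrix: DoseMatrix) -> np.ndarray:
    """Expected-inhibition grid under a reference model.

    Returns the full grid shape with NaN on the monotherapy row/column and
    in cells where the model is undefined (e.g. a non-invertible
    monotherapy curve under Loewe).
    """
    if model not in SYNERGY_MODELS:
        raise ValueError(f"unknown synergy model {model!r}")
    inh = matrix.inhibition
    n1, n2 = inh.shape
    y1 = inh[:, 0]  # monotherapy effect of drug1 at doses1
    y2 = inh[0, :]
    exp = np.full((n1, n2), np.nan)
    if model == "bliss":
        exp[1:, 1:] = (
            y1[1:, None] + y2[None, 1:] - y1[1:, None] * y2[None, 1:]
        )
    elif model == "hsa":
        exp[1:, 1:] = np.maximum(y1[1:, None], y2[None, 1:])
    elif model == "loewe":
        c1 = matrix.monotherapy_curve(1)
        c2 = matrix.monotherapy_curve(2)
        for i in range(1, n1):
            for j in range(1, n2):
                exp[i, j] = _loewe_cell(
                    matrix.doses1[i], matrix.doses2[j], c1, c2
                )
    else:  # zip: potency-shift refit of observed rows/columns
        bliss = expected_inhibition("bliss", matrix)
        row_fit = np.full((n1, n2), np.nan)
        col_fit = np.full((n1, n2), np.nan)
        for i in range(1, n1):
            f = _zip_directional(matrix.doses2[1:], inh[i, 1:], float(y1[i]))
            if f is not None:
                row_fit[i, 1:] = f(matrix.doses2[1:])
        for j in range(1, n2):
            f = _zip_directional(matrix.doses1[1:], inh[1:, j], float(y2[j]))
            if f is not None:
                col_fit[1:, j] = f(matrix.doses1[1:])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            both = np.nanmean(np.stack([row_fit, col_fit]), axis=0)
        exp[1:, 1:] = np.where(
            np.isnan(both[1:, 1:]), bliss[1:, 1:], both[1:, 1:]
        )
    return exp


def _loewe_cell(
    d1: float, d2: float, c1: DoseResponseCurve, c2: DoseResponseCurve
) -> float:
    """Solve d1/D1(E) + d2/D2(E) = 1 for the Loewe-additive effect E."""
    lo = max(float(c1.inhibition(c1.doses.min() * 1e-6)),
             float(c2.inhibition(c2.doses.min() * 1e-6)))
    hi = min(float(c1.inhibition(c1.doses.max() * 1e6)),
             float(c2.inhibition(c2.doses.max() * 1e6)))
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        return float("nan")

    def g(E):
        D1 = c1.inverse_inhibition(E)
        D2 = c2.inverse_inhibition(E)
        if not (np.isfinite(D1) and np.isfinite(D2)) or D1 <= 0 or D2 <= 0:
            return float("nan")
        return d1 / D1 + d2 / D2 - 1.0

    eps = (hi - lo) * 1e-6
    a, b = lo + eps, hi - eps
    ga, gb = g(a), g(b)
    if not (np.isfinite(ga) and np.isfinite(gb)):
        return float("nan")
    if ga < 0:  # even the weakest effect needs less dose than given: clamp
        return a
    if gb > 0:  # asked effect beyond achievable range: clamp
        return b
    while b - a > 1e-6:
        mid = 0.5 * (a + b)
        gm = g(mid)
        if not np.isfinite(gm):
            return float("nan")
        if gm > 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def synergy_score(matrix: DoseMatrix, model: str) -> float:
    """100 x mean excess of observed over expected inhibition (combo cells)."""
    exp = expected_inhibition(model, matrix)
    obs = matrix.inhibition
    diff = (obs - exp)[1:, 1:]
    valid = np.isfinite(diff)
    if not valid.any():
        raise ValueError("all combination cells undefined")
    return float(100.0 * diff[valid].mean())
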
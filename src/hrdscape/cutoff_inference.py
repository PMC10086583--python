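"""Bimodality-based cut-point inference.

A two-component Gaussian mixture is fitted to a bimodal biomarker (here the
HRR-CIN score); the cut-off separating the two peaks is the point between
the component means where the weighted component densities cross (posterior
probability 0.5), with a parametric-bootstrap confidence interval.  A
second biomarker is then dichotomised against the inferred status with a
ROC curve and the Youden index J = sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "MixtureFit",
    "ROCResult",
    "fit_two_component_mixture",
    "mixture_cutoff",
    "bootstrap_cutoff_ci",
    "classify_by_cutoff",
    "roc_youden",
]


@dataclass
class MixtureFit:
    means: tuple[float, float]  # ordered, mean1 < mean2
    sds: tuple[float, float]
    weights: tuple[float, float]
    loglik: float
    converged: bool
    cutoff: float | None = None
    cutoff_is_fallback: bool = False
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    optimal_cutpoint: float
    auc: float


def fit_two_component_mixture(
    values, seed: int = 0, max_iter: int = 500, tol: float = 1e-8
) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture.

    Deterministic: means initialise at the 25th/75th percentiles, weights
    at 0.5, both standard deviations at half the sample SD.  A component
    collapsing below sd 1e-6 is reported as non-converged.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite values")
    if np.std(x) == 0:
        raise ValueError("degenerate fit: zero-variance input")
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:
        mu = np.array([x.min(), x.max()], dtype=float)
    sd = np.full(2, np.std(x) / 2.0)
    w = np.array([0.5, 0.5])
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step
        dens = w * norm.pdf(x[:, None], mu[None, :], sd[None, :])
        total = dens.sum(axis=1)
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        resp = dens / total[:, None]
        new_loglik = float(np.log(total).sum())
        # M step
        nk = resp.sum(axis=0)
        if (nk <= 0).any():
            break
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if (sd < 1e-6).any():
            return MixtureFit(
                tuple(np.sort(mu)), tuple(sd), tuple(w), new_loglik, False
            )
        if new_loglik - loglik < tol and np.isfinite(loglik):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    order = np.argsort(mu)
    fit = MixtureFit(
        means=(float(mu[order[0]]), float(mu[order[1]])),
        sds=(float(sd[order[0]]), float(sd[order[1]])),
        weights=(float(w[order[0]]), float(w[order[1]])),
        loglik=float(loglik),
        converged=converged,
    )
    if converged:
        fit.cutoff, fit.cutoff_is_fallback = mixture_cutoff(fit, with_flag=True)
    return fit


def mixture_cutoff(fit: MixtureFit, with_flag: bool = False):
    """Weighted-density crossing between the component means.

    Root of ``w1 phi(x; m1, s1) = w2 phi(x; m2, s2)`` on (m1, m2), i.e. the
    point of posterior probability 0.5, by bisection to 1e-6.  Falls back
    to the midpoint (flagged) when the densities do not cross in the
    interval.
    """
    if not fit.converged:
        raise ValueError("cutoff requires a converged fit")
    (m1, m2), (s1, s2), (w1, w2) = fit.means, fit.sds, fit.weights

    def f(x):
        return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

    lo, hi = m1, m2
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return (float(lo), False) if with_flag else float(lo)
    if fhi == 0.0:
        return (float(hi), False) if with_flag else float(hi)
    if np.sign(flo) == np.sign(fhi):
        mid = 0.5 * (m1 + m2)
        return (float(mid), True) if with_flag else float(mid)
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            lo = hi = mid
            break
        if np.sign(fm) == np.sign(flo):
            lo, flo = mid, fm
        else:
            hi = mid
    root = 0.5 * (lo + hi)
    return (float(root), False) if with_flag else float(root)


def bootstrap_cutoff_ci(
    values, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Parametric-bootstrap 95% interval for the mixture cut-off.

    Simulates samples from the fitted mixture, refits, and takes the
    2.5/97.5 percentiles of the refitted cut-offs.  Warns when more than
    20% of replicates fail to converge.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    x = np.asarray(values, dtype=float)
    base = fit_two_component_mixture(x, seed=seed)
    if not base.converged:
        raise ValueError("base fit did not converge")
    rng = np.random.default_rng(seed)
    cutoffs = []
    failures = 0
    for _ in range(n_boot):
        comp = rng.choice(2, size=x.size, p=base.weights)
        sim = rng.normal(
            np.asarray(base.means)[comp], np.asarray(base.sds)[comp]
        )
        try:
            fit = fit_two_component_mixture(sim, seed=seed)
        except ValueError:
            failures += 1
            continue
        if not fit.converged or fit.cutoff is None:
            failures += 1
            continue
        cutoffs.append(fit.cutoff)
    if failures > 0.2 * n_boot:
        import warnings

        warnings.warn(
            f"degenerate bootstrap fits: {failures}/{n_boot}", stacklevel=2
        )
    if not cutoffs:
        raise ValueError("all bootstrap refits failed")
    lo, hi = np.percentile(cutoffs, [2.5, 97.5])
    return float(lo), float(hi)


def classify_by_cutoff(values, cutoff: float) -> np.ndarray:
    """Label each value 'high' (value >= cutoff, boundary inclusive) or 'low'."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    x = np.asarray(values, dtype=float)
    return np.where(x >= cutoff, "high", "low")


def roc_youden(labels, scores) -> ROCResult:
    """ROC curve and Youden-optimal cut-point of a score against labels.

    Candidate thresholds are the midpoints between adjacent distinct score
    values plus the two infinities; a sample is called positive when its
    score is at or above the threshold.  Ties on J resolve to the higher
    sensitivity, then the lower threshold.  AUC by the trapezoid rule.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValueError("labels and scores differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    # adjacent floats can swallow their midpoint: fall back to the upper
    # value so every distinct score still yields its own operating point
    mids = np.where(mids > distinct[:-1], mids, distinct[1:])
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = s >= t
        sens[i] = (pred & y).sum() / n_pos
        spec[i] = (~pred & ~y).sum() / n_neg
    youden = sens + spec - 1.0
    # maximise J; ties -> higher sensitivity, then lower threshold
    order = np.lexsort((thresholds, -sens, -youden))
    best = order[0]
    fpr = 1.0 - spec
    idx = np.lexsort((sens, fpr))  # staircase corners in drawing order
    auc = float(np.trapezoid(sens[idx], fpr[idx]))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        youden=youden,
        optimal_cutpoint=float(thresholds[best]),
        auc=auc,
    )
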
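"""Binarization of cell-type composition fractions.

Each cell type's fraction vector across samples is modelled as a
two-component univariate Gaussian mixture fitted by EM; samples assigned to
the higher-mean component get abundance state 1, the rest 0.  Because the
downstream network model treats the states as "low vs high abundance", the
labelling is forced to be monotone in the fraction value: a single cutoff
separates the two states even when unequal component variances would make the
raw posterior rule non-monotone.  A distribution-free midpoint split is
available as an alternative strategy and as the automatic fallback for
degenerate (constant) columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError
from .io import FractionTable

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8  # keeps a component from collapsing onto a single point


@dataclass(frozen=True)
class Gmm2Params:
    """Parameters of a fitted two-component univariate Gaussian mixture,
    with components ordered by increasing mean."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if min(self.sds) <= 0:
            raise ValueError("component standard deviations must be positive")
        if not math.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")


def _log_normal_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def _mixture_loglik(x, weights, means, sds) -> tuple[float, np.ndarray]:
    """Total log-likelihood and responsibilities of component 1."""
    comp = np.stack(
        [np.log(weights[k]) + _log_normal_pdf(x, means[k], sds[k]) for k in (0, 1)]
    )
    top = comp.max(axis=0)
    lse = top + np.log(np.exp(comp - top).sum(axis=0))
    resp1 = np.exp(comp[1] - lse)
    return float(lse.sum()), resp1


def _init_centers(x: np.ndarray, rng: np.random.Generator) -> tuple[float, float]:
    """k-means++-style pick of two distinct 1-D centers."""
    c0 = float(rng.choice(x))
    d2 = (x - c0) ** 2
    if d2.sum() == 0:
        raise DegenerateDataError("all values identical")
    c1 = float(rng.choice(x, p=d2 / d2.sum()))
    return (c0, c1) if c0 <= c1 else (c1, c0)


def _lloyd_1d(x: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Deterministic 2-means on a 1-D sample, started from the quartiles."""
    c0, c1 = np.quantile(x, 0.25), np.quantile(x, 0.75)
    if c0 == c1:
        c0, c1 = x.min(), x.max()
    for _ in range(max_iter):
        hi = np.abs(x - c1) < np.abs(x - c0)
        if hi.all() or (~hi).all():
            break
        n0, n1 = float(x[~hi].mean()), float(x[hi].mean())
        if (n0, n1) == (c0, c1):
            break
        c0, c1 = n0, n1
    return float(c0), float(c1)


def fit_gmm2(
    values,
    max_iter: int = 500,
    tol: float = 1e-4,
    seed: int = 0,
    n_init: int = 1,
) -> Gmm2Params:
    """EM fit of a two-component Gaussian mixture to a 1-D sample.

    Initialization is a deterministic 1-D 2-means from the quartiles (the
    same recipe generic mixture libraries default to); with ``n_init > 1``
    additional seeded k-means++-style restarts are run and the
    highest-likelihood solution wins.  EM on 1-D mixtures happily collapses
    a component onto a pair of outliers, so the balanced deterministic start
    is the default.  The EM log-likelihood trace is checked to be
    non-decreasing at every step.  Raises :class:`DegenerateDataError` when
    all values are identical (callers should fall back to the midpoint
    split).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values to fit a mixture")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise DegenerateDataError(
            "all values identical; use the midpoint strategy instead"
        )
    rng = np.random.default_rng(seed)
    best = _em_run(x, _lloyd_1d(x), max_iter=max_iter, tol=tol)
    for _ in range(n_init - 1):
        fit = _em_run(x, _init_centers(x, rng), max_iter=max_iter, tol=tol)
        if fit.loglik > best.loglik:
            best = fit
    return best


def _em_run(
    x: np.ndarray, centers: tuple[float, float], max_iter: int, tol: float
) -> Gmm2Params:
    m0, m1 = min(centers), max(centers)
    # hard 1-D k-means-style init for weights/variances
    assign = np.abs(x - m1) < np.abs(x - m0)
    weights = np.array([max(1 - assign.mean(), 1e-3), max(assign.mean(), 1e-3)])
    weights = weights / weights.sum()
    var_all = max(x.var(), _VAR_FLOOR)
    sds = np.sqrt(
        [
            max(x[~assign].var() if (~assign).sum() > 1 else var_all, _VAR_FLOOR),
            max(x[assign].var() if assign.sum() > 1 else var_all, _VAR_FLOOR),
        ]
    )
    means = np.array([m0, m1])

    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, r1 = _mixture_loglik(x, weights, means, sds)
        if ll < prev_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        if ll - prev_ll < tol and prev_ll > -np.inf:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        r = np.stack([1 - r1, r1])
        nk = r.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / x.size
        means = (r @ x) / nk
        var = (r * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk
        sds = np.sqrt(np.maximum(var, _VAR_FLOOR))

    order = np.argsort(means, kind="stable")
    return Gmm2Params(
        weights=tuple(weights[order]),
        means=tuple(means[order]),
        sds=tuple(sds[order]),
        loglik=prev_ll,
        converged=converged,
    )


def decision_threshold(params: Gmm2Params) -> float:
    """Posterior decision boundary between the two component means.

    Solves pi0*N(x; mu0, sd0) = pi1*N(x; mu1, sd1) for x in [mu0, mu1];
    when no root lies between the means (extreme weight/variance imbalance)
    the midpoint of the means is used.
    """
    (w0, w1), (m0, m1), (s0, s1) = params.weights, params.means, params.sds
    a = 0.5 / s0**2 - 0.5 / s1**2
    b = m1 / s1**2 - m0 / s0**2
    c = (
        0.5 * m0**2 / s0**2
        - 0.5 * m1**2 / s1**2
        + math.log(w1 / s1)
        - math.log(w0 / s0)
    )
    if abs(a) < 1e-300:
        if b == 0:
            return 0.5 * (m0 + m1)
        root = -c / b
        return root if m0 <= root <= m1 else 0.5 * (m0 + m1)
    disc = b * b - 4 * a * c
    if disc < 0:
        return 0.5 * (m0 + m1)
    roots = [(-b + s * math.sqrt(disc)) / (2 * a) for s in (1, -1)]
    inside = [r for r in roots if m0 <= r <= m1]
    return inside[0] if inside else 0.5 * (m0 + m1)


def assign_labels(params: Gmm2Params, values) -> np.ndarray:
    """Binary abundance labels: 1 for the higher-mean component.

    Uses the posterior argmax where that rule is monotone in the value;
    otherwise (possible with unequal variances) labels by a single cutoff at
    the posterior decision boundary between the means, so that
    x <= y implies label(x) <= label(y).
    """
    x = np.asarray(values, dtype=float).ravel()
    _, r1 = _mixture_loglik(x, params.weights, params.means, params.sds)
    raw = (r1 >= 0.5).astype(int)
    order = np.argsort(x, kind="stable")
    if np.all(np.diff(raw[order]) >= 0):
        return raw
    thr = decision_threshold(params)
    return (x >= thr).astype(int)


def midpoint_labels(values) -> np.ndarray:
    """Distribution-free split at (min+max)/2; 1 above the midpoint."""
    x = np.asarray(values, dtype=float).ravel()
    return (x > (x.min() + x.max()) / 2).astype(int)


def discretize_fractions(
    ft: FractionTable,
    strategy: str = "gmm",
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Binarize every cell-type column of a fraction table independently.

    Returns a samples x cell-types DataFrame of {0,1} abundance states.  The
    per-column 0/1 balance is whatever the mixture finds — it may be highly
    skewed.  Degenerate columns under ``"gmm"`` fall back to the midpoint
    split (logged) rather than aborting the run.
    """
    if strategy not in {"gmm", "midpoint"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    states = {}
    seeds = np.random.SeedSequence(seed).generate_state(ft.values.shape[1])
    for j, ct in enumerate(ft.values.columns):
        col = ft.values[ct].to_numpy(dtype=float)
        if strategy == "midpoint":
            states[ct] = midpoint_labels(col)
            continue
        try:
            params = fit_gmm2(col, max_iter=max_iter, tol=tol, seed=int(seeds[j] % 2**31))
            states[ct] = assign_labels(params, col)
        except DegenerateDataError:
            logger.info("cell type %s: degenerate column, midpoint fallback", ct)
            states[ct] = midpoint_labels(col)
    return pd.DataFrame(states, index=ft.values.index, columns=ft.values.columns)


def loo_stability(ft: FractionTable, seed: int = 0) -> pd.Series:
    """Leave-one-out agreement of the binarization, per cell type.

    For each cell type, the mixture is refitted with each sample held out and
    the held-out sample is labelled by the refitted model; the returned value
    is the fraction of samples whose held-out label matches the all-sample
    labelling.  High agreement means the cutoffs are not driven by single
    samples.
    """
    n = len(ft.values)
    if n < 3:
        raise ValueError("leave-one-out stability needs at least 3 samples")
    full = discretize_fractions(ft, strategy="gmm", seed=seed)
    seeds = np.random.SeedSequence(seed).generate_state(ft.values.shape[1])
    agreement = {}
    for j, ct in enumerate(ft.values.columns):
        col = ft.values[ct].to_numpy(dtype=float)
        col_seed = int(seeds[j] % 2**31)
        hits = 0
        for i in range(n):
            rest = np.delete(col, i)
            try:
                params = fit_gmm2(rest, seed=col_seed)
                label = int(assign_labels(params, col[i : i + 1])[0])
            except DegenerateDataError:
                x = rest
                label = int(col[i] > (x.min() + x.max()) / 2)
            hits += label == full[ct].iloc[i]
        agreement[ct] = hits / n
    return pd.Series(agreement, name="loo_agreement")
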
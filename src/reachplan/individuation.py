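"""Individuation models: predicting inter-participant differences.

The performance-optimization account of the obstacle experiments extends to
individuals by blending each participant's own inputs with the group
averages.  With away-from-obstacle margins ``m_i``, 2-target direction SDs
``s2_i`` and obstructed 1-target SDs ``s1_i``, the three-parameter-plus-
offset model predicts each participant's deviation from the group-mean
2-target direction::

    mu2_i - mean(mu2) ~ 1/2 * (km*m_i + (1-km)*mean(m))
                            * (k2*s2_i + (1-k2)*mean(s2))
                            * (k1/s1_i + (1-k1)/mean(s1))  - K0

The one-parameter form ties ``km = k2 = k1 = k``.  ``k = 1`` is full
individuation; ``k = 0`` reduces every factor to its group average (no
individuation, the model collapses to a constant).  Indices are constrained
to [0, 1]; ``K0`` is a free offset that centers the prediction.

Partial R^2 of an input variable is computed against the nested model with
that variable's index fixed at zero, with F degrees of freedom counting the
offset as a parameter: ``F(1, n-2)`` for the one-parameter model against
offset-only and ``F(1, n-4)`` for each partial of the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .obstacle_models import ObstacleSummary

VARIABLES = ("mu1A", "sigma2", "sigma1A")


@dataclass
class IndividuationData:
    """Per-participant model inputs (margin frame) and observed directions."""

    margin: np.ndarray  # away-from-obstacle 1-target deflection (deg)
    sigma2: np.ndarray
    sigma1A: np.ndarray
    mu2: np.ndarray

    @classmethod
    def from_summaries(cls, cohort: Sequence[ObstacleSummary]) -> "IndividuationData":
        return cls(
            margin=np.array([s.margin_1a for s in cohort]),
            sigma2=np.array([s.sigma2 for s in cohort]),
            sigma1A=np.array([s.sigma1A for s in cohort]),
            mu2=np.array([s.mu2 for s in cohort]),
        )

    @property
    def n(self) -> int:
        return len(self.mu2)

    @property
    def y(self) -> np.ndarray:
        """Observed deviations from the group-mean 2-target direction."""
        return self.mu2 - self.mu2.mean()

    def product_term(self, km: float, k2: float, k1: float) -> np.ndarray:
        """The half-product of blended inputs (before the K0 offset)."""
        f1 = km * self.margin + (1.0 - km) * self.margin.mean()
        f2 = k2 * self.sigma2 + (1.0 - k2) * self.sigma2.mean()
        f3 = k1 / self.sigma1A + (1.0 - k1) / self.sigma1A.mean()
        return 0.5 * f1 * f2 * f3

    def sse_profiled(self, km: float, k2: float, k1: float) -> tuple[float, float]:
        """SSE with the offset K0 profiled out analytically; returns (SSE, K0)."""
        c = self.product_term(km, k2, k1)
        k0 = float(np.mean(c) - np.mean(self.y))
        r = self.y - (c - k0)
        return float(r @ r), k0


@dataclass
class IndividuationFit:
    model: str  # "one_param" or "three_param"
    indices: dict[str, float]  # km/k2/k1 (or a single "k")
    K0: float
    sse: float
    r2: float
    predictions: np.ndarray = field(repr=False)
    n: int = 0
    F: float | None = None  # model vs offset-only (one-param form)
    p: float | None = None
    identifiable: bool = True


def _r2(data: IndividuationData, sse: float) -> float:
    sst = float(data.y @ data.y)
    return 1.0 - sse / sst if sst > 0 else 0.0


def _grid_polish_1d(f, x0: float, halfwidth: float = 0.05, step: float = 1e-4) -> float:
    grid = np.clip(np.arange(x0 - halfwidth, x0 + halfwidth + step / 2, step), 0.0, 1.0)
    vals = [f(x) for x in grid]
    return float(grid[int(np.argmin(vals))])


def fit_one_param(data_or_cohort) -> IndividuationFit:
    """Fit the one-parameter-plus-offset model by multi-start bounded least
    squares with a dense 1-D grid polish of the individuation index."""
    data = _as_data(data_or_cohort)
    if data.n < 4:
        raise ValueError("need at least 4 participants for the one-parameter model")
    identifiable = float(np.std(data.y)) > 1e-12

    def sse_k(k: float) -> float:
        return data.sse_profiled(k, k, k)[0]

    res = optimize.minimize_scalar(sse_k, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    cands = [float(res.x), 0.0, 1.0]
    for k0 in np.linspace(0.05, 0.95, 7):
        res2 = optimize.minimize(lambda v: sse_k(float(np.clip(v[0], 0, 1))),
                                 x0=[k0], method="Nelder-Mead",
                                 options={"xatol": 1e-6, "fatol": 1e-12})
        cands.append(float(np.clip(res2.x[0], 0.0, 1.0)))
    best_k = min(cands, key=sse_k)
    best_k = _grid_polish_1d(sse_k, best_k)
    sse, k0 = data.sse_profiled(best_k, best_k, best_k)
    preds = data.product_term(best_k, best_k, best_k) - k0
    r2 = _r2(data, sse)
    sst = float(data.y @ data.y)
    dof = data.n - 2  # index + offset
    F = ((sst - sse) / 1.0) / (sse / dof) if sse > 0 else np.inf
    p = float(stats.f.sf(F, 1, dof)) if np.isfinite(F) else 0.0
    return IndividuationFit("one_param", {"k": best_k}, k0, sse, r2, preds,
                            n=data.n, F=float(F), p=p, identifiable=identifiable)


def fit_three_param(data_or_cohort,
                    fixed: dict[str, float] | None = None) -> IndividuationFit:
    """Fit the three-parameter-plus-offset model (optionally with some
    indices held fixed, for nested comparisons).

    Multi-start bounded least squares over the free indices followed by
    cyclic coordinate-wise dense grid polish; the one-parameter solution is
    included among the starts so the nesting inequality
    ``SSE(three) <= SSE(one)`` holds by construction.
    """
    data = _as_data(data_or_cohort)
    if data.n < 6:
        raise ValueError("need at least 6 participants for the three-parameter model")
    fixed = dict(fixed or {})
    names = ["km", "k2", "k1"]
    free = [nm for nm in names if nm not in fixed]

    def full_vec(free_vals: np.ndarray) -> dict[str, float]:
        d = dict(fixed)
        for nm, v in zip(free, free_vals):
            d[nm] = float(np.clip(v, 0.0, 1.0))
        return d

    def sse_of(free_vals: np.ndarray) -> float:
        d = full_vec(free_vals)
        return data.sse_profiled(d["km"], d["k2"], d["k1"])[0]

    starts = [np.full(len(free), v) for v in (0.15, 0.5, 0.85)]
    from itertools import product as _product
    if len(free) > 1:
        starts += [np.array(c) for c in _product((0.1, 0.9), repeat=len(free))]
    if not fixed:
        k1p = fit_one_param(data).indices["k"]
        starts.append(np.full(3, k1p))
    best_vals, best = None, np.inf
    for s0 in starts:
        res = optimize.minimize(lambda v: sse_of(v), x0=s0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
        v = np.clip(res.x, 0.0, 1.0)
        if sse_of(v) < best:
            best, best_vals = sse_of(v), v
    # cyclic coordinate-wise grid polish
    vals = np.array(best_vals, dtype=float)
    for _ in range(3):
        for j in range(len(free)):
            def f1(x, j=j):
                w = vals.copy()
                w[j] = x
                return sse_of(w)
            vals[j] = _grid_polish_1d(f1, float(vals[j]))
    d = full_vec(vals)
    sse, k0 = data.sse_profiled(d["km"], d["k2"], d["k1"])
    preds = data.product_term(d["km"], d["k2"], d["k1"]) - k0
    label = "three_param" if not fixed else f"three_param[fixed {sorted(fixed)}]"
    return IndividuationFit(label, d, k0, sse, _r2(data, sse), preds, n=data.n,
                            identifiable=float(np.std(data.y)) > 1e-12)


def _as_data(x) -> IndividuationData:
    if isinstance(x, IndividuationData):
        return x
    return IndividuationData.from_summaries(list(x))


_INDEX_OF = {"mu1A": "km", "sigma2": "k2", "sigma1A": "k1"}


def partial_r2(data_or_cohort, variable: str,
               full: IndividuationFit | None = None) -> dict:
    """Partial R^2 of one input variable via the nested model with that
    variable's individuation index fixed at 0.

    ``partial R^2 = (SSE_reduced - SSE_full) / SSE_reduced`` with
    ``F(1, n - 4)``; returns a dict with the partial R^2, F, p and both SSEs.
    """
    if variable not in _INDEX_OF:
        raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    data = _as_data(data_or_cohort)
    full = full or fit_three_param(data)
    reduced = fit_three_param(data, fixed={_INDEX_OF[variable]: 0.0})
    sse_f, sse_r = full.sse, max(reduced.sse, full.sse)
    if sse_r == 0.0:
        raise ValueError("partial R^2 undefined: reduced model has zero residual")
    pr2 = (sse_r - sse_f) / sse_r
    dof = data.n - 4  # three indices + offset
    F = ((sse_r - sse_f) / 1.0) / (sse_f / dof) if sse_f > 0 else np.inf
    p = float(stats.f.sf(F, 1, dof)) if np.isfinite(F) else 0.0
    return {"variable": variable, "partial_r2": float(pr2), "F": float(F), "p": p,
            "sse_full": sse_f, "sse_reduced": sse_r}


def partial_residual_data(data_or_cohort, variable: str,
                          full: IndividuationFit | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Partial-residual scatter for one input variable.

    Predictions of the nested model that zeroes the *other* two indices
    (keeping the full fit's index for ``variable`` and its offset), plus the
    full-model residuals, mean-subtracted; paired with the variable's
    per-participant values.  Returns ``(x, y)`` arrays of cohort length.
    """
    if variable not in _INDEX_OF:
        raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    data = _as_data(data_or_cohort)
    full = full or fit_three_param(data)
    ks = {"km": 0.0, "k2": 0.0, "k1": 0.0}
    ks[_INDEX_OF[variable]] = full.indices[_INDEX_OF[variable]]
    pred = data.product_term(ks["km"], ks["k2"], ks["k1"]) - full.K0
    resid = data.y - full.predictions
    y = pred + resid
    y = y - y.mean()
    x = {"mu1A": data.margin, "sigma2": data.sigma2, "sigma1A": data.sigma1A}[variable]
    return x, y
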
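"""Three-way mixed-model variance components and the intraclass correlation.

The model for one organ's volumes is

    y[p, o, t] = mu + tau[t] + P[p] + O[o] + PO[p,o] + PT[p,t] + OT[o,t] + e

with patients (P) and observers (O) random, scan time (t, two levels) fixed,
and all random interactions included.  With one observation per cell the
three-way interaction is absorbed by the residual.  Components are estimated
by REML (bounded at zero), which also handles unbalanced designs where an
organ of some patient is excluded.

The ICC is the patient-attributable share of the total variance,

    icc = (s2_patient + s2_patient_time) / (sum of all six components),

the correlation between two arbitrary observers measuring the same patient
on the same scan.  The fixed time effect enters neither numerator nor
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .descriptives import DesignError, VolumeRecord, records_to_frame

logger = logging.getLogger(__name__)

COMPONENT_NAMES = (
    "sigma2_patient",
    "sigma2_observer",
    "sigma2_patient_observer",
    "sigma2_patient_time",
    "sigma2_observer_time",
    "sigma2_residual",
)

#: ICC thresholds for the verbal agreement bands; an interval (lo, hi]
#: (printed values on both endpoints are honoured by the printed labels).
ICC_BANDS = (
    (0.10, "virtually none"),
    (0.40, "slight"),
    (0.60, "fair"),
    (0.80, "moderate"),
    (1.00, "substantial"),
)


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge."""


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_patient: float
    sigma2_observer: float
    sigma2_patient_observer: float
    sigma2_patient_time: float
    sigma2_observer_time: float
    sigma2_residual: float
    time_effect: float  # mean volume difference rep - plan, cm^3

    def __post_init__(self) -> None:
        for name in COMPONENT_NAMES:
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.asarray([getattr(self, n) for n in COMPONENT_NAMES])

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


@dataclass(frozen=True)
class ICCResult:
    organ: str
    icc: float
    components: VarianceComponents
    band: str


def _design(records: Sequence[VolumeRecord], organ: str):
    df = records_to_frame(records)
    df = df[df["organ"] == organ].reset_index(drop=True)
    if df.empty:
        raise DesignError(f"no records for organ {organ!r}")
    for col, minimum in (("patient_id", 2), ("observer_id", 2), ("scan_time", 2)):
        if df[col].nunique() < minimum:
            raise DesignError(
                f"organ {organ!r}: need >= {minimum} levels of {col}, "
                f"got {df[col].nunique()}"
            )
    y = df["volume"].to_numpy(dtype=float)
    p = pd.factorize(df["patient_id"])[0]
    o = pd.factorize(df["observer_id"])[0]
    t = pd.factorize(df["scan_time"], sort=True)[0]  # plan=0, rep=1
    return df, y, p, o, t


def _grouping_matrices(p, o, t) -> list[np.ndarray]:
    """Same-group indicator matrices G_k = Z_k Z_k' for the five random terms."""
    def same(codes):
        return (codes[:, None] == codes[None, :]).astype(float)

    po = p * (o.max() + 1) + o
    pt = p * 2 + t
    ot = o * 2 + t
    return [same(p), same(o), same(po), same(pt), same(ot)]


def _neg2_reml(theta, G, X, y):
    """-2 * restricted log-likelihood (up to a constant) and its gradient."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for s2, Gk in zip(theta[:-1], G):
        V += s2 * Gk
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, np.zeros_like(theta)
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    Py = P @ y
    f = logdet_v + logdet_x + float(y @ Py)
    grads = np.empty_like(theta)
    terms = list(G) + [np.eye(n)]
    for k, Gk in enumerate(terms):
        grads[k] = np.trace(P @ Gk) - float(Py @ Gk @ Py)
    return f, grads


def _fisher_polish(theta, G, X, y, max_iter: int = 40, tol: float = 1e-12):
    """Fisher-scoring refinement of the REML solution on the free components.

    Components pinned at (near) zero with a non-descending score stay fixed;
    the rest are updated with the expected-information step.  Tightens the
    L-BFGS-B solution to ~1e-9 relative, needed to match the closed-form
    balanced-design estimators.
    """
    n = y.size
    theta = theta.copy()
    terms = list(G) + [np.eye(n)]
    for _ in range(max_iter):
        V = theta[-1] * np.eye(n)
        for s2, Gk in zip(theta[:-1], G):
            V += s2 * Gk
        try:
            Vi = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            return theta
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
        Py = P @ y
        PG = [P @ Gk for Gk in terms]
        score = np.array(
            [-0.5 * (np.trace(PGk) - float(Py @ Gk @ Py)) for PGk, Gk in zip(PG, terms)]
        )
        free = (theta > 1e-7) | (score > 0)
        if not free.any():
            break
        idx = np.flatnonzero(free)
        info = np.array(
            [[0.5 * np.trace(PG[i] @ PG[j]) for j in idx] for i in idx]
        )
        try:
            step = np.linalg.solve(info, score[idx])
        except np.linalg.LinAlgError:
            break
        new = theta.copy()
        new[idx] = np.maximum(theta[idx] + step, 1e-10)
        if np.max(np.abs(new - theta)) < tol * max(1.0, np.max(theta)):
            theta = new
            break
        theta = new
    return theta


def fit_components(records: Sequence[VolumeRecord], organ: str) -> VarianceComponents:
    """REML estimates of the six variance components for one organ.

    Raises :class:`DesignError` for fewer than two levels of any factor and
    :class:`ConvergenceError` if the bounded optimisation fails.
    """
    df, y, p, o, t = _design(records, organ)

    X = np.column_stack([np.ones_like(y), t.astype(float)])
    var_y = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
    if var_y < 1e-14 * max(1.0, float(np.mean(y)) ** 2):
        # all volumes (essentially) identical: every component is zero
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, time_effect=0.0)

    # work on a unit-variance scale for conditioning
    scale = np.sqrt(var_y)
    ys = y / scale
    G = _grouping_matrices(p, o, t)

    x0 = np.full(6, 1.0 / 6.0)
    bounds = [(1e-8, 50.0)] * 6
    res = optimize.minimize(
        _neg2_reml,
        x0,
        args=(G, X, ys),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.status != 2:  # status 2: precision-loss stop, inspect
        raise ConvergenceError(
            f"REML did not converge for organ {organ!r}: {res.message} "
            f"(nit={res.nit}, grad_inf_norm={np.abs(res.jac).max():.3g})"
        )
    theta_s = _fisher_polish(res.x, G, X, ys)
    theta = np.where(theta_s < 1e-7, 0.0, theta_s) * var_y

    # GLS estimate of the fixed time effect at the fitted components
    V = theta[-1] * np.eye(y.size)
    for s2, Gk in zip(theta[:-1], G):
        V += s2 * Gk
    V += 1e-12 * var_y * np.eye(y.size)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    time_effect = float(beta[1])

    return VarianceComponents(*theta, time_effect=time_effect)


def compute_icc(c: VarianceComponents) -> float:
    """Patient-attributable variance share; 0 by convention if all components are 0."""
    total = c.total
    if total <= 0:
        return 0.0
    return (c.sigma2_patient + c.sigma2_patient_time) / total


def classify_icc(icc: float) -> str:
    """Verbal agreement band for an ICC in [0, 1]."""
    if not (np.isfinite(icc) and 0.0 <= icc <= 1.0):
        raise ValueError(f"icc must be in [0, 1], got {icc}")
    for upper, label in ICC_BANDS:
        if icc <= upper + 1e-12:
            return label
    raise AssertionError("unreachable")


def icc_for_organ(records: Sequence[VolumeRecord], organ: str) -> ICCResult:
    """Convenience wrapper: fit, ratio, classify."""
    comps = fit_components(records, organ)
    icc = compute_icc(comps)
    return ICCResult(organ=organ, icc=icc, components=comps, band=classify_icc(icc))


def icc_results_to_frame(results: Sequence[ICCResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"organ": r.organ, "icc": r.icc, "band": r.band,
               "time_effect_cm3": r.components.time_effect}
        row.update({n: getattr(r.components, n) for n in COMPONENT_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
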
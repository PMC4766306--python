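"""Enzyme kinetics: Michaelis-Menten and substrate-inhibition fitting.

The velocity law is the standard uncompetitive substrate-inhibition form

    v(S) = kcat * [E] * S / (Km + S + S^2/Ki)

which reduces to Michaelis-Menten as Ki -> infinity.  Units follow the
assay bookkeeping used throughout: S and Km in uM, kcat in 1/min, [E] in
nM, so v is in nM/min and the catalytic efficiency kcat/Km is in
1/(uM*min).  The velocity peaks at S* = sqrt(Km*Ki) and declines beyond.

Fitting is damped least squares (scipy trust-region reflective with
positivity bounds) with an analytic Jacobian, relative tolerance 1e-10.
Standard errors are asymptotic, from the Jacobian at the optimum.  Model
choice ("auto") reports a finite Ki only when the substrate-inhibition
model reduces the residual sum of squares by at least 5% relative to the
Michaelis-Menten fit; otherwise no substrate inhibition is declared.

Small assay computations live here too: the -2 m/z mass bookkeeping for
C-C phenol-coupled products (oxidative coupling of two phenol rings loses
two hydrogens) and molar ratios from tissue contents in mg/g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "KineticFit",
    "FitError",
    "rate",
    "fit",
    "efficiency",
    "coupled_product_mz",
    "molar_ratio",
    "MOLAR_MASSES",
]

#: Monoisotopic-agnostic average molecular masses (g/mol) of the two
#: alkaloids quantified in bulb tissue.
MOLAR_MASSES: Mapping[str, float] = {
    "haemanthamine": 301.34,
    "galanthamine": 287.35,
}


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or produced a degenerate optimum."""


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants: Km (uM), kcat (1/min), Ki (uM; inf = no substrate
    inhibition) and enzyme concentration (nM)."""

    km: float
    kcat: float
    ki: float = math.inf
    enzyme_conc: float = 1.0

    def __post_init__(self) -> None:
        if self.km <= 0 or self.kcat <= 0 or self.ki <= 0 or self.enzyme_conc <= 0:
            raise ValueError("all kinetic parameters must be positive")


@dataclass(frozen=True)
class KineticFit:
    """Least-squares estimates with asymptotic standard errors."""

    params: KineticParams
    std_errors: Mapping[str, float]
    efficiency: float
    model: str  # "mm" or "substrate_inhibition"
    residual_ss: float
    n_points: int


def rate(S, params: KineticParams) -> np.ndarray | float:
    """Velocity at substrate concentration(s) S (uM); nM/min scale."""
    S_arr = np.asarray(S, dtype=float)
    if (S_arr < 0).any():
        raise ValueError("substrate concentrations must be non-negative")
    denom = params.km + S_arr + S_arr * S_arr / params.ki
    v = params.kcat * params.enzyme_conc * S_arr / denom
    return float(v) if np.isscalar(S) else v


def efficiency(params: KineticParams) -> float:
    """Catalytic efficiency kcat/Km, in 1/(uM*min)."""
    return params.kcat / params.km


def _model_and_jac(theta: np.ndarray, S: np.ndarray, E: float, si: bool):
    if si:
        kcat, km, ki = theta
        denom = km + S + S * S / ki
    else:
        kcat, km = theta
        ki = math.inf
        denom = km + S
    v = kcat * E * S / denom
    d_kcat = E * S / denom
    d_km = -kcat * E * S / denom**2
    cols = [d_kcat, d_km]
    if si:
        cols.append(kcat * E * S * (S * S / ki**2) / denom**2)
    return v, np.column_stack(cols)


def _initial_guess(S: np.ndarray, v: np.ndarray, E: float, si: bool) -> np.ndarray:
    vmax = v.max()
    kcat0 = max(vmax / E, 1e-12)
    s_peak = S[np.argmax(v)]
    rising = S <= s_peak
    half_idx = np.argmin(np.abs(v[rising] - vmax / 2.0))
    km0 = max(float(S[rising][half_idx]), float(S.min()) / 2.0, 1e-6)
    if si:
        return np.array([kcat0, km0, 10.0 * float(S.max())])
    return np.array([kcat0, km0])


def fit(
    S: Sequence[float],
    v: Sequence[float],
    model: str = "substrate_inhibition",
    enzyme_conc: float = 1.0,
    init: Sequence[float] | None = None,
) -> KineticFit:
    """Fit the rate law to (S, v) observations by least squares.

    Parameters
    ----------
    model
        ``"mm"`` (Km, kcat), ``"substrate_inhibition"`` (Km, kcat, Ki), or
        ``"auto"``: fit both and keep Ki only when substrate inhibition
        improves the residual SS by >= 5%.
    enzyme_conc
        Known enzyme concentration on the same scale as ``v`` (nM here).
    init
        Optional starting values (kcat, km[, ki]); by default Km starts at
        the substrate level of half-maximal observed velocity, kcat at
        max(v)/[E] and Ki at 10x the largest S.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.shape != v.shape or S.ndim != 1:
        raise ValueError("S and v must be equal-length vectors")
    if model == "auto":
        mm = fit(S, v, model="mm", enzyme_conc=enzyme_conc)
        si = fit(S, v, model="substrate_inhibition", enzyme_conc=enzyme_conc)
        if mm.residual_ss > 0 and (mm.residual_ss - si.residual_ss) / mm.residual_ss >= 0.05:
            return si
        return mm
    if model not in ("mm", "substrate_inhibition"):
        raise ValueError(f"unknown model {model!r}")
    si = model == "substrate_inhibition"
    n_params = 3 if si else 2
    if np.unique(S).size < n_params + 1:
        raise ValueError(
            f"{model} needs at least {n_params + 1} distinct substrate levels"
        )
    x0 = np.asarray(init, dtype=float) if init is not None else _initial_guess(S, v, enzyme_conc, si)
    if x0.size != n_params:
        raise ValueError(f"init must provide {n_params} values for model {model!r}")

    def residuals(theta):
        return _model_and_jac(theta, S, enzyme_conc, si)[0] - v

    def jac(theta):
        return _model_and_jac(theta, S, enzyme_conc, si)[1]

    result = least_squares(
        residuals,
        x0,
        jac=jac,
        bounds=(np.full(n_params, 1e-12), np.full(n_params, np.inf)),
        method="trf",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=500,
    )
    if not result.success:
        raise FitError(
            f"fit did not converge (status {result.status}, {result.nfev} evaluations): "
            f"{result.message}"
        )
    theta = result.x
    rss = float(2.0 * result.cost)
    n = S.size
    dof = n - n_params
    J = result.jac
    if not np.all(np.isfinite(J)):
        raise FitError("singular Jacobian at the optimum")
    jtj = J.T @ J
    s2 = rss / dof if dof > 0 else 0.0
    try:
        cov = np.linalg.pinv(jtj) * s2
    except np.linalg.LinAlgError as exc:
        raise FitError("singular Jacobian at the optimum") from exc
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    if si:
        params = KineticParams(km=theta[1], kcat=theta[0], ki=theta[2], enzyme_conc=enzyme_conc)
        std_errors = {"kcat": ses[0], "km": ses[1], "ki": ses[2]}
    else:
        params = KineticParams(km=theta[1], kcat=theta[0], enzyme_conc=enzyme_conc)
        std_errors = {"kcat": ses[0], "km": ses[1]}
    return KineticFit(
        params=params,
        std_errors=std_errors,
        efficiency=efficiency(params),
        model=model,
        residual_ss=rss,
        n_points=int(n),
    )


def coupled_product_mz(substrate_mz: float) -> float:
    """First-quadrupole m/z of the C-C phenol-coupled product.

    Oxidative C-C phenol coupling removes two hydrogens, so the product
    precursor ion sits 2 m/z below the substrate precursor.
    """
    if substrate_mz <= 2:
        raise ValueError("substrate precursor m/z must exceed 2")
    return substrate_mz - 2.0


def molar_ratio(content_a: float, mw_a: float, content_b: float, mw_b: float) -> float:
    """Molar ratio a:b from tissue contents (mg/g) and molar masses (g/mol)."""
    if min(content_a, mw_a, content_b, mw_b) <= 0:
        raise ValueError("contents and molar masses must be positive")
    return (content_a / mw_a) / (content_b / mw_b)
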
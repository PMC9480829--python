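"""Steady states, existence, and eigenvalue stability classification.

For the unregulated feed-forward cascade the steady state is solved in
closed form: at stationarity every net reaction flux equals the influx k0,
so each substrate follows from inverting its Michaelis-Menten law,
``S = KM * f / (Vmax - f)``, walking down the cascade (the D27 reverse flux
is known once CISB is, since CISB is fixed by the CCD7 step).  In model AC
the split of CLA consumption between MAX1 and ABA8HD is a scalar root find.

A steady state exists only while the demanded flux stays below every
consuming step's capacity; beyond that bound the upstream substrate
accumulates without limit (how a too-large influx k0 "destabilizes" this
feed-forward cascade).

With feedback the system is solved by a damped Newton iteration on
log-concentrations seeded from the unregulated solution, with a long-time
stiff integration as fallback, and the residual is always verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .kinetics import odes, rate_jacobian, rates, rates_named, stoichiometry
from .parameters import FeedbackExponents, ParameterSet

__all__ = [
    "SteadyStateResult",
    "SteadyStateError",
    "integrate",
    "solve_steady_state",
    "steady_state_exists",
    "jacobian",
    "classify_stability",
    "RESIDUAL_TOL",
    "STABILITY_RTOL",
]

#: Max allowed |dx/dt| (mM/s) for a state to count as stationary
#: (about 1e-10 times the nominal influx).
RESIDUAL_TOL = 1e-18

#: Relative threshold on the leading eigenvalue real part: eigenvalues within
#: STABILITY_RTOL * spectral scale of zero are marginal.
STABILITY_RTOL = 1e-12


class SteadyStateError(RuntimeError):
    """The steady-state solver could not produce a verified stationary state."""


@dataclass
class SteadyStateResult:
    """Solved steady state with fluxes, spectrum, and classification."""

    model_id: str
    species: tuple[str, ...]
    state: np.ndarray | None
    fluxes: dict[str, float] | None
    jacobian: np.ndarray | None
    eigenvalues: np.ndarray | None
    max_real_eig: float | None
    status: str  # "stable" | "unstable" | "marginal" | "no_steady_state"
    limiting_step: str | None = None

    @property
    def exists(self) -> bool:
        return self.status != "no_steady_state"

    @property
    def stable(self) -> bool:
        return self.status == "stable"

    def concentrations(self) -> dict[str, float]:
        if self.state is None:
            return {}
        return dict(zip(self.species, map(float, self.state)))

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "status": self.status,
            "limiting_step": self.limiting_step,
            "state": self.concentrations(),
            "fluxes": self.fluxes,
            "eigenvalues_real": None
            if self.eigenvalues is None
            else [float(v) for v in self.eigenvalues.real],
            "eigenvalues_imag": None
            if self.eigenvalues is None
            else [float(v) for v in self.eigenvalues.imag],
            "max_real_eig": self.max_real_eig,
        }


# ---------------------------------------------------------------------------
# Existence (capacity) test
# ---------------------------------------------------------------------------


def steady_state_exists(params: ParameterSet) -> tuple[bool, str | None]:
    """Capacity pre-check for the unregulated cascade.

    A finite steady state requires the influx k0 to be strictly below the
    maximal rate of every consuming step.  Returns ``(exists,
    limiting_step)`` where the limiting step is the tightest violated
    capacity (None when the steady state exists).
    """
    caps = {
        "d27_forward": params.Vmax_D27A,
        "ccd7": params.Vmax_CCD7,
        "ccd8": params.Vmax_CCD8,
    }
    if params.model_id == "AB":
        caps["max1"] = params.Vmax_MAX1
    else:
        caps["max1_cl_cla"] = params.Vmax_MAX1
        caps["cla_consumption"] = params.Vmax_MAX1 + params.Vmax_ABA8HD
        caps["max1_do_oro"] = params.Vmax_MAX1
    violated = {name: c for name, c in caps.items() if params.k0 >= c}
    if not violated:
        return True, None
    return False, min(violated, key=violated.get)


# ---------------------------------------------------------------------------
# Closed-form cascade inversion (unregulated)
# ---------------------------------------------------------------------------


def _invert_mm(vmax: float, km: float, flux: float) -> float:
    """Substrate level carrying ``flux`` through a Michaelis-Menten step."""
    if flux <= 0:
        return 0.0
    if flux >= vmax:
        raise SteadyStateError(f"flux {flux} exceeds capacity {vmax}")
    return km * flux / (vmax - flux)


def _unregulated_state(params: ParameterSet) -> np.ndarray:
    """Sequential closed-form steady state (feedback all zero)."""
    p = params
    k0 = p.k0
    if k0 == 0.0:
        return np.zeros(p.n_species)
    # CCD7 carries the net D27 flux = k0 at stationarity.
    cisb = _invert_mm(p.Vmax_CCD7, p.KM_CCD7, k0)
    # D27 forward must supply k0 plus the reverse flux out of CISB.
    reverse = p.Vmax_D27B * cisb / (p.KM_D27 + cisb)
    bcar = _invert_mm(p.Vmax_D27A, p.KM_D27, k0 + reverse)
    ctnl = _invert_mm(p.Vmax_CCD8, p.KM_CCD8, k0)
    cl = _invert_mm(p.Vmax_MAX1, p.KM_MAX1, k0)
    if p.model_id == "AB":
        oro = p.omega * k0 / p.k
        strig = (1.0 - p.omega) * k0 / p.k
        return np.array([bcar, cisb, ctnl, cl, oro, strig])
    # AC: CLA is consumed by MAX1 (-> DO -> ORO) and ABA8HD in parallel.
    vm, km = p.Vmax_MAX1, p.KM_MAX1
    va, ka = p.Vmax_ABA8HD, p.KM_ABA8HD

    def demand(a: float) -> float:
        return vm * a / (km + a) + va * a / (ka + a) - k0

    hi = max(km, ka)
    while demand(hi) < 0:  # expand until bracketing (capacity check guarantees a root)
        hi *= 10.0
        if hi > 1e30:
            raise SteadyStateError("CLA consumption cannot match the influx")
    cla = brentq(demand, 0.0, hi, xtol=1e-300, rtol=1e-15)
    f_max1 = vm * cla / (km + cla)
    f_aba = k0 - f_max1
    do = _invert_mm(vm, km, f_max1)
    oro = (p.phi * f_aba + f_max1) / p.k
    strig = (1.0 - p.phi) * f_aba / p.k
    return np.array([bcar, cisb, ctnl, cl, cla, do, oro, strig])


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def integrate(
    params: ParameterSet,
    fb: FeedbackExponents | None = None,
    init: Sequence[float] | None = None,
    t_end: float = 1e7,
    n_out: int = 50,
    rtol: float = 1e-10,
    atol: float = 1e-16,
    scales: dict[str, float] | None = None,
):
    """Integrate the ODEs with a stiff-capable method (LSODA, analytic Jacobian).

    Returns ``(t, Y)`` with ``Y[i]`` the state at ``t[i]``; ``Y[-1]`` is the
    final state.  ``init`` defaults to the all-zero state (only valid without
    negative feedback exponents).
    """
    fb = fb or FeedbackExponents()
    x0 = np.zeros(params.n_species) if init is None else np.asarray(init, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    N = stoichiometry(params.model_id)

    def f(_t, x):
        return N @ rates(np.maximum(x, 0.0), params, fb, scales)

    def jac(_t, x):
        return N @ rate_jacobian(np.maximum(x, 0.0), params, fb, scales)

    sol = solve_ivp(
        f,
        (0.0, t_end),
        x0,
        method="LSODA",
        jac=jac,
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(0.0, t_end, n_out),
        dense_output=False,
    )
    if not sol.success:
        raise SteadyStateError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0.0}: {sol.message}"
        )
    return sol.t, sol.y.T


# ---------------------------------------------------------------------------
# Jacobian and stability
# ---------------------------------------------------------------------------


def jacobian(
    state: Sequence[float],
    params: ParameterSet,
    fb: FeedbackExponents | None = None,
    method: str = "analytic",
    scales: dict[str, float] | None = None,
) -> np.ndarray:
    """d(odes)/d(state) at ``state``, analytic or central finite difference."""
    if method == "analytic":
        return stoichiometry(params.model_id) @ rate_jacobian(state, params, fb, scales)
    if method != "finite_difference":
        raise ValueError("method must be 'analytic' or 'finite_difference'")
    x = np.asarray(state, dtype=float)
    n = x.size
    J = np.zeros((n, n))
    for i in range(n):
        h = 1e-5 * max(abs(x[i]), 1e-12)  # central diff: round-off limited below this
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0)
        J[:, i] = (odes(xp, params, fb, scales) - odes(xm, params, fb, scales)) / (
            xp[i] - xm[i]
        )
    return J


def classify_stability(
    state: Sequence[float],
    params: ParameterSet,
    fb: FeedbackExponents | None = None,
    scales: dict[str, float] | None = None,
) -> SteadyStateResult:
    """Assemble a SteadyStateResult (fluxes, spectrum, verdict) at ``state``.

    Stable iff every eigenvalue real part is below ``-STABILITY_RTOL`` times
    the spectral scale; leading eigenvalues within tolerance of zero are
    reported as marginal (not stable).
    """
    x = np.asarray(state, dtype=float)
    J = jacobian(x, params, fb, scales=scales)
    eig = np.linalg.eigvals(J)
    max_re = float(eig.real.max())
    scale = float(np.abs(eig.real).max()) or 1.0
    if max_re < -STABILITY_RTOL * scale:
        status = "stable"
    elif max_re <= STABILITY_RTOL * scale:
        status = "marginal"
    else:
        status = "unstable"
    return SteadyStateResult(
        model_id=params.model_id,
        species=params.species,
        state=x,
        fluxes=rates_named(x, params, fb, scales),
        jacobian=J,
        eigenvalues=eig,
        max_real_eig=max_re,
        status=status,
    )


# ---------------------------------------------------------------------------
# Newton refinement (regulated models)
# ---------------------------------------------------------------------------


def _log_newton(
    x0: np.ndarray,
    params: ParameterSet,
    fb: FeedbackExponents,
    scales: dict[str, float] | None,
    max_iter: int = 200,
) -> np.ndarray | None:
    """Damped Newton on z = log(x); returns the root or None."""
    N = stoichiometry(params.model_id)
    z = np.log(x0)
    r = N @ rates(np.exp(z), params, fb, scales)
    norm = np.abs(r).max()
    for _ in range(max_iter):
        if norm <= RESIDUAL_TOL:
            return np.exp(z)
        x = np.exp(z)
        J = (N @ rate_jacobian(x, params, fb, scales)) * x[None, :]  # d r / d z
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            return None
        step = np.clip(step, -5.0, 5.0)  # never move a species > e^5 per step
        lam = 1.0
        for _half in range(50):
            z_new = z + lam * step
            r_new = N @ rates(np.exp(z_new), params, fb, scales)
            if np.abs(r_new).max() < norm:
                z, r, norm = z_new, r_new, np.abs(r_new).max()
                break
            lam *= 0.5
        else:
            return None
    return np.exp(z) if norm <= RESIDUAL_TOL else None


def solve_steady_state(
    params: ParameterSet,
    fb: FeedbackExponents | None = None,
    init: Sequence[float] | None = None,
    scales: dict[str, float] | None = None,
) -> SteadyStateResult:
    """Solve and classify the steady state of the model.

    Without feedback this is the closed-form cascade inversion; with feedback
    (or ``scales``) a damped log-space Newton seeded from the unregulated
    solution (or ``init``), with a long-time integration fallback.  Returns a
    ``no_steady_state`` result when the capacity pre-check fails; raises
    :class:`SteadyStateError` when both solvers fail on a regulated system.
    """
    fb = fb or FeedbackExponents()
    fb.validate_for(params.model_id)
    exists, limiting = steady_state_exists(params)
    if not exists:
        return SteadyStateResult(
            model_id=params.model_id,
            species=params.species,
            state=None,
            fluxes=None,
            jacobian=None,
            eigenvalues=None,
            max_real_eig=None,
            status="no_steady_state",
            limiting_step=limiting,
        )
    base = _unregulated_state(params)
    if fb.is_zero() and not scales:
        return classify_stability(base, params, fb)
    seed = base if init is None else np.asarray(init, dtype=float)
    if np.any(seed <= 0):
        raise SteadyStateError(
            "regulated models need a strictly positive seed state "
            "(default: the unregulated steady state)"
        )
    x = _log_newton(seed, params, fb, scales)
    if x is None:
        # fallback: relax by stiff integration, then polish with Newton
        try:
            _, traj = integrate(params, fb, init=seed, t_end=1e9, n_out=5, scales=scales)
            x = _log_newton(np.maximum(traj[-1], 1e-300), params, fb, scales)
        except SteadyStateError:
            x = None
    if x is None:
        raise SteadyStateError(
            f"no stationary state found for model {params.model_id} "
            f"with exponents {fb.active()}"
        )
    res = classify_stability(x, params, fb, scales=scales)
    resid = float(np.abs(odes(x, params, fb, scales)).max())
    if resid > RESIDUAL_TOL:
        raise SteadyStateError(f"candidate state residual {resid} exceeds tolerance")
    return res
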
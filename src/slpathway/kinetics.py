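"""Rate laws and ODE right-hand sides for Models AB and AC.

Every enzymatic step is an irreversible Michaelis-Menten flux
``v = Vmax * S / (KM + S)``; regulation, when present, multiplies a flux by
power-law factors ``[X]^f`` with exponents f in [-1, 0] (biochemical-systems
-theory style, no mechanistic inhibition form).  The network is encoded as a
reaction table (stoichiometry matrix x rate vector), which gives the ODEs
and an analytic Jacobian from one description.

All-zero exponents reduce every rate law exactly to the unregulated model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parameters import FeedbackExponents, ParameterSet

__all__ = [
    "michaelis_menten",
    "feedback_multiplier",
    "rates",
    "rates_named",
    "odes",
    "rate_jacobian",
    "reaction_names",
    "stoichiometry",
    "SingularMultiplierError",
    "CONC_FLOOR",
]

#: Below this concentration (mM) a negative-exponent multiplier is treated as
#: singular; integrations with feedback must start from positive states.
CONC_FLOOR = 1e-30


class SingularMultiplierError(ZeroDivisionError):
    """A power-law factor [X]^f with f < 0 was evaluated at [X] ~ 0."""


def michaelis_menten(vmax: float, km: float, s) -> float:
    """Michaelis-Menten flux vmax*s/(km+s), mM/s.

    Monotone nondecreasing in ``s`` and bounded above by ``vmax``.
    """
    if vmax < 0 or km <= 0 or np.any(np.asarray(s) < 0):
        raise ValueError("michaelis_menten requires vmax >= 0, km > 0, s >= 0")
    return vmax * s / (km + s)


def _mm_deriv(vmax: float, km: float, s: float) -> float:
    """d/ds of the Michaelis-Menten flux: vmax*km/(km+s)^2."""
    return vmax * km / (km + s) ** 2


def feedback_multiplier(conc: float, exponent: float) -> float:
    """Power-law regulation factor conc**exponent.

    Exactly 1 when ``exponent`` is 0, regardless of ``conc`` (including 0).
    Raises :class:`SingularMultiplierError` for conc below the documented
    floor with a negative exponent.
    """
    if not -1.0 <= exponent <= 0.0:
        raise ValueError(f"exponent must lie in [-1, 0], got {exponent}")
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if exponent == 0.0:
        return 1.0
    if conc < CONC_FLOOR:
        raise SingularMultiplierError(
            f"[X]^{exponent} is singular at [X]={conc!r} (< {CONC_FLOOR} mM)"
        )
    return conc**exponent


# ---------------------------------------------------------------------------
# Reaction tables
# ---------------------------------------------------------------------------

_CONST, _MM, _LINEAR = 0, 1, 2


@dataclass(frozen=True)
class _Reaction:
    name: str
    kind: int
    substrate: int  # state index, -1 for the constant influx
    # feedback attachments: ((state index, exponent attribute name), ...)
    regulators: tuple[tuple[int, str], ...] = ()


# Model AB: species (BCAR, CISB, CTNL, CL, ORO, STR)
_AB_REACTIONS = (
    _Reaction("influx", _CONST, -1),
    _Reaction("d27_forward", _MM, 0, ((3, "fcl"), (4, "foro1"), (5, "fstr1"))),
    _Reaction("d27_reverse", _MM, 1),
    _Reaction("ccd7", _MM, 1),
    _Reaction("ccd8", _MM, 2),
    _Reaction("max1_oro", _MM, 3, ((4, "foro2"),)),
    _Reaction("max1_str", _MM, 3, ((5, "fstr2"),)),
    _Reaction("removal_oro", _LINEAR, 4),
    _Reaction("removal_str", _LINEAR, 5),
)

_AB_STOICH = np.array(
    #  in  d27f d27r ccd7 ccd8 m1o  m1s  remO remS
    [
        [1, -1, 1, 0, 0, 0, 0, 0, 0],  # BCAR
        [0, 1, -1, -1, 0, 0, 0, 0, 0],  # CISB
        [0, 0, 0, 1, -1, 0, 0, 0, 0],  # CTNL
        [0, 0, 0, 0, 1, -1, -1, 0, 0],  # CL
        [0, 0, 0, 0, 0, 1, 0, -1, 0],  # ORO
        [0, 0, 0, 0, 0, 0, 1, 0, -1],  # STR
    ],
    dtype=float,
)

# Model AC: species (BCAR, CISB, CTNL, CL, CLA, DO, ORO, STR)
_AC_REACTIONS = (
    _Reaction("influx", _CONST, -1),
    _Reaction("d27_forward", _MM, 0, ((4, "fcla"), (6, "foro1"), (7, "fstr1"))),
    _Reaction("d27_reverse", _MM, 1),
    _Reaction("ccd7", _MM, 1),
    _Reaction("ccd8", _MM, 2),
    _Reaction("max1_cl_cla", _MM, 3),
    _Reaction("max1_cla_do", _MM, 4, ((6, "foro4"),)),
    _Reaction("max1_do_oro", _MM, 5),
    _Reaction("aba8hd_oro", _MM, 4, ((6, "foro3"),)),
    _Reaction("aba8hd_str", _MM, 4, ((7, "fstr3"),)),
    _Reaction("removal_oro", _LINEAR, 6),
    _Reaction("removal_str", _LINEAR, 7),
)

_AC_STOICH = np.array(
    #  in  d27f d27r ccd7 ccd8 m1a  m1b  m1c  abaO abaS remO remS
    [
        [1, -1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # BCAR
        [0, 1, -1, -1, 0, 0, 0, 0, 0, 0, 0, 0],  # CISB
        [0, 0, 0, 1, -1, 0, 0, 0, 0, 0, 0, 0],  # CTNL
        [0, 0, 0, 0, 1, -1, 0, 0, 0, 0, 0, 0],  # CL
        [0, 0, 0, 0, 0, 1, -1, 0, -1, -1, 0, 0],  # CLA
        [0, 0, 0, 0, 0, 0, 1, -1, 0, 0, 0, 0],  # DO
        [0, 0, 0, 0, 0, 0, 0, 1, 1, 0, -1, 0],  # ORO
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, -1],  # STR
    ],
    dtype=float,
)


def _tables(model_id: str):
    if model_id == "AB":
        return _AB_REACTIONS, _AB_STOICH
    if model_id == "AC":
        return _AC_REACTIONS, _AC_STOICH
    raise ValueError(f"unknown model_id {model_id!r}")


def reaction_names(model_id: str) -> tuple[str, ...]:
    """Ordered reaction (flux) names of the model."""
    return tuple(r.name for r in _tables(model_id)[0])


def stoichiometry(model_id: str) -> np.ndarray:
    """Stoichiometry matrix N (species x reactions); dx/dt = N @ v."""
    return _tables(model_id)[1].copy()


_MM_PARAM_EXPRS = {
    "d27_forward": lambda p: (p.Vmax_D27A, p.KM_D27),
    "d27_reverse": lambda p: (p.Vmax_D27B, p.KM_D27),
    "ccd7": lambda p: (p.Vmax_CCD7, p.KM_CCD7),
    "ccd8": lambda p: (p.Vmax_CCD8, p.KM_CCD8),
    "max1_oro": lambda p: (p.omega * p.Vmax_MAX1, p.KM_MAX1),
    "max1_str": lambda p: ((1.0 - p.omega) * p.Vmax_MAX1, p.KM_MAX1),
    "max1_cl_cla": lambda p: (p.Vmax_MAX1, p.KM_MAX1),
    "max1_cla_do": lambda p: (p.Vmax_MAX1, p.KM_MAX1),
    "max1_do_oro": lambda p: (p.Vmax_MAX1, p.KM_MAX1),
    "aba8hd_oro": lambda p: (p.phi * p.Vmax_ABA8HD, p.KM_ABA8HD),
    "aba8hd_str": lambda p: ((1.0 - p.phi) * p.Vmax_ABA8HD, p.KM_ABA8HD),
}


def _mm_params(rxn: _Reaction, p: ParameterSet) -> tuple[float, float]:
    """(vmax, km) of an enzymatic reaction."""
    return _MM_PARAM_EXPRS[rxn.name](p)


def _check_state(state: Sequence[float], p: ParameterSet) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (p.n_species,):
        raise ValueError(
            f"model {p.model_id} expects a state of length {p.n_species}, got shape {x.shape}"
        )
    if np.any(x < 0):
        raise ValueError("state concentrations must be nonnegative")
    return x


def rates(
    state: Sequence[float],
    params: ParameterSet,
    fb: FeedbackExponents | None = None,
    scales: dict[str, float] | None = None,
) -> np.ndarray:
    """Reaction flux vector (mM/s), ordered as :func:`reaction_names`.

    ``scales`` optionally multiplies named reactions by a constant factor
    (used by the flux-constrained feedback screen to rescale rate constants).
    """
    fb = fb or FeedbackExponents()
    fb.validate_for(params.model_id)
    x = _check_state(state, params)
    rxns, _ = _tables(params.model_id)
    v = np.empty(len(rxns))
    for j, rxn in enumerate(rxns):
        if rxn.kind == _CONST:
            vj = params.k0
        elif rxn.kind == _LINEAR:
            vj = params.k * x[rxn.substrate]
        else:
            vmax, km = _mm_params(rxn, params)
            vj = vmax * x[rxn.substrate] / (km + x[rxn.substrate])
        for idx, attr in rxn.regulators:
            vj *= feedback_multiplier(x[idx], getattr(fb, attr))
        if scales and rxn.name in scales:
            vj *= scales[rxn.name]
        v[j] = vj
    return v


def rates_named(
    state: Sequence[float],
    params: ParameterSet,
    fb: FeedbackExponents | None = None,
    scales: dict[str, float] | None = None,
) -> dict[str, float]:
    """Like :func:`rates` but keyed by reaction name."""
    return dict(zip(reaction_names(params.model_id), rates(state, params, fb, scales)))


def odes(
    state: Sequence[float],
    params: ParameterSet,
    fb: FeedbackExponents | None = None,
    scales: dict[str, float] | None = None,
) -> np.ndarray:
    """Time derivatives d[state]/dt = N @ v, mM/s.

    Internal fluxes telescope, so the entries always sum to
    ``k0 - k*([ORO] + [STR])`` exactly.
    """
    _, N = _tables(params.model_id)
    return N @ rates(state, params, fb, scales)


def rate_jacobian(
    state: Sequence[float],
    params: ParameterSet,
    fb: FeedbackExponents | None = None,
    scales: dict[str, float] | None = None,
) -> np.ndarray:
    """Analytic derivative of the flux vector: Dv[j, i] = dv_j / dx_i."""
    fb = fb or FeedbackExponents()
    fb.validate_for(params.model_id)
    x = _check_state(state, params)
    rxns, _ = _tables(params.model_id)
    v = rates(x, params, fb, scales)
    Dv = np.zeros((len(rxns), len(x)))
    for j, rxn in enumerate(rxns):
        if rxn.kind == _CONST:
            continue
        # substrate part: v_j = scale * base(s) * prod(multipliers)
        s = x[rxn.substrate]
        if rxn.kind == _LINEAR:  # removal steps carry no regulators
            Dv[j, rxn.substrate] = params.k * (
                scales.get(rxn.name, 1.0) if scales else 1.0
            )
        else:
            vmax, km = _mm_params(rxn, params)
            base = vmax * s / (km + s)
            if base > 0:
                Dv[j, rxn.substrate] += v[j] * (km / (s * (km + s)))
            else:
                # v_j = 0: derivative is mult * dbase/ds
                mult = 1.0
                for idx, attr in rxn.regulators:
                    mult *= feedback_multiplier(x[idx], getattr(fb, attr))
                if scales and rxn.name in scales:
                    mult *= scales[rxn.name]
                Dv[j, rxn.substrate] += mult * _mm_deriv(vmax, km, s)
        # regulator parts: d(X^f)/dX = f * X^(f-1) -> v_j * f / X
        for idx, attr in rxn.regulators:
            f = getattr(fb, attr)
            if f != 0.0:
                Dv[j, idx] += v[j] * f / x[idx]
    return Dv
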
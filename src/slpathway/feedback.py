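"""In-silico screen of hypothetical inhibitory feedback regulation.

Candidate feedback loops (end products and the branch-point metabolite
inhibiting the first reaction; branch products inhibiting their own branch
reactions) are scanned over strengths f = -1.00 ... 0.00 in steps of 0.01.
At each strength the steady state is solved and two physiological checks
are applied: eigenvalue stability, and the substrate BCAR staying inside
the experimentally reported window [1e-4, 1e-1] mM.

The flux-constrained variant rescales the regulated reaction's rate
constant so the unregulated reference state stays an exact steady state,
then asks how the leading Jacobian eigenvalue moves with feedback strength
(evolutionary compensation: could the pathway keep its operating point and
still afford feedback?).

The label-to-exponent mapping for the scheme names (AB1..AB5, AC1..AC6) is
a single configuration table (`SCHEME_EXPONENTS`) so it can be permuted
without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import feedback_multiplier
from .parameters import FeedbackExponents, ParameterSet
from .sensitivity import BCAR_WINDOW
from .steady_state import (
    SteadyStateError,
    classify_stability,
    solve_steady_state,
)

__all__ = [
    "FeedbackScheme",
    "ScreenRecord",
    "ScreenVerdict",
    "SCHEME_EXPONENTS",
    "enumerate_schemes",
    "default_strength_grid",
    "screen",
    "constrained_screen",
    "summarize",
]

#: Elementary feedback labels -> regulating exponent field.
SCHEME_EXPONENTS: dict[str, str] = {
    # model AB: ORO / STR / CL inhibit the first (D27) reaction ...
    "AB1": "foro1",
    "AB2": "fstr1",
    "AB3": "fcl",
    # ... and each end product its own MAX1 branch share
    "AB4": "foro2",
    "AB5": "fstr2",
    # model AC: ORO / STR / CLA inhibit the first reaction ...
    "AC1": "foro1",
    "AC2": "fstr1",
    "AC3": "fcla",
    # ... the end products their own ABA8HD shares, and ORO the CLA->DO step
    "AC4": "foro3",
    "AC5": "fstr3",
    "AC6": "foro4",
}

#: Tested combinations per model (single loops and pairs).
_AB_COMBINATIONS = (
    ("AB1",),
    ("AB2",),
    ("AB3",),
    ("AB1", "AB4"),
    ("AB2", "AB5"),
    ("AB1", "AB2"),
    ("AB1", "AB3"),
    ("AB2", "AB3"),
)
_AC_COMBINATIONS = (
    ("AC3",),
    ("AC1",),
    ("AC2",),
    ("AC2", "AC3"),
    ("AC1", "AC4"),
    ("AC2", "AC5"),
    ("AC2", "AC6"),
    ("AC1", "AC2"),
    ("AC1", "AC3"),
)

#: Exponent fields acting on the pathway's first reaction.
FIRST_REACTION_EXPONENTS = ("fcl", "fcla", "foro1", "fstr1")

#: Exponent field -> reaction it regulates (for the constrained rescaling).
_EXPONENT_REACTION = {
    "fcl": "d27_forward",
    "fcla": "d27_forward",
    "foro1": "d27_forward",
    "fstr1": "d27_forward",
    "foro2": "max1_oro",
    "fstr2": "max1_str",
    "foro3": "aba8hd_oro",
    "fstr3": "aba8hd_str",
    "foro4": "max1_cla_do",
}

#: Exponent field -> regulating species name.
_EXPONENT_SPECIES = {
    "fcl": "CL",
    "fcla": "CLA",
    "foro1": "ORO",
    "fstr1": "STR",
    "foro2": "ORO",
    "fstr2": "STR",
    "foro3": "ORO",
    "fstr3": "STR",
    "foro4": "ORO",
}


@dataclass(frozen=True)
class FeedbackScheme:
    """One tested feedback combination (all exponents share one strength)."""

    scheme_id: str
    model_id: str
    exponents: tuple[str, ...]

    def exponents_at(self, strength: float) -> FeedbackExponents:
        fb = FeedbackExponents.for_scheme(self.exponents, strength)
        fb.validate_for(self.model_id)
        return fb

    @property
    def touches_first_reaction(self) -> bool:
        return any(e in FIRST_REACTION_EXPONENTS for e in self.exponents)


def enumerate_schemes(model_id: str) -> list[FeedbackScheme]:
    """The tested feedback combinations: 8 for model AB, 9 for model AC."""
    combos = _AB_COMBINATIONS if model_id == "AB" else _AC_COMBINATIONS
    return [
        FeedbackScheme(
            scheme_id=" + ".join(labels),
            model_id=model_id,
            exponents=tuple(SCHEME_EXPONENTS[l] for l in labels),
        )
        for labels in combos
    ]


def default_strength_grid() -> np.ndarray:
    """Strengths -1.00, -0.99, ..., 0.00 (101 points)."""
    return np.round(np.arange(-100, 1) / 100.0, 2)


@dataclass(frozen=True)
class ScreenRecord:
    strength: float
    status: str
    bcar: float | None
    max_real_eig: float | None
    bcar_in_window: bool

    @property
    def viable(self) -> bool:
        return self.status == "stable" and self.bcar_in_window


@dataclass
class ScreenVerdict:
    """Per-strength records of one scheme plus a summary verdict."""

    scheme: FeedbackScheme
    records: list[ScreenRecord]
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        neg = [r for r in self.records if r.strength < 0]
        if neg and all(r.viable for r in neg):
            self.verdict = "viable"
        elif any(r.status != "no_steady_state" and not r.bcar_in_window for r in neg):
            self.verdict = "breaks_BCAR_window"
        elif any(r.status in ("unstable", "marginal") for r in neg):
            self.verdict = "destabilizes"
        else:
            self.verdict = "no_steady_state"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scheme": self.scheme.scheme_id,
                    "strength": r.strength,
                    "status": r.status,
                    "BCAR": r.bcar,
                    "max_real_eig": r.max_real_eig,
                    "bcar_in_window": r.bcar_in_window,
                }
                for r in self.records
            ]
        )


def screen(
    params: ParameterSet,
    scheme: FeedbackScheme,
    strengths: np.ndarray | None = None,
) -> ScreenVerdict:
    """Scan one feedback scheme over the strength grid.

    Strengths are visited from 0 downward so each solve can be seeded from
    the previous grid point (continuation); solver failures are recorded as
    ``no_steady_state`` for that strength, never aborting the screen.
    """
    if scheme.model_id != params.model_id:
        raise ValueError("scheme and parameter set belong to different models")
    strengths = default_strength_grid() if strengths is None else np.asarray(strengths)
    records: dict[float, ScreenRecord] = {}
    seed = None
    for s in sorted(strengths, reverse=True):  # 0 -> -1 continuation
        fb = scheme.exponents_at(float(s))
        try:
            res = solve_steady_state(params, fb, init=seed)
            seed = res.state
            bcar = res.concentrations().get("BCAR")
            rec = ScreenRecord(
                strength=float(s),
                status=res.status,
                bcar=bcar,
                max_real_eig=res.max_real_eig,
                bcar_in_window=(
                    bcar is not None and BCAR_WINDOW[0] <= bcar <= BCAR_WINDOW[1]
                ),
            )
        except SteadyStateError:
            rec = ScreenRecord(float(s), "no_steady_state", None, None, False)
        records[float(s)] = rec
    ordered = [records[float(s)] for s in strengths]
    return ScreenVerdict(scheme=scheme, records=ordered)


def constrained_screen(
    params: ParameterSet,
    scheme: FeedbackScheme,
    strengths: np.ndarray | None = None,
) -> ScreenVerdict:
    """Flux-constrained variant: keep the reference state stationary.

    For each strength f the regulated reaction's rate constant is multiplied
    by ``prod_r [X_r*]^(-f)`` evaluated at the unregulated reference
    concentrations, cancelling the feedback factor there, and the Jacobian
    eigenvalues are recomputed at the (unchanged) reference state.
    """
    if scheme.model_id != params.model_id:
        raise ValueError("scheme and parameter set belong to different models")
    ref = solve_steady_state(params)
    if not ref.exists:
        raise SteadyStateError("the unregulated reference steady state does not exist")
    conc = ref.concentrations()
    strengths = default_strength_grid() if strengths is None else np.asarray(strengths)
    records = []
    for s in strengths:
        fb = scheme.exponents_at(float(s))
        scales: dict[str, float] = {}
        for exp_name in scheme.exponents:
            rxn = _EXPONENT_REACTION[exp_name]
            x_ref = conc[_EXPONENT_SPECIES[exp_name]]
            scales[rxn] = scales.get(rxn, 1.0) / feedback_multiplier(x_ref, float(s))
        res = classify_stability(ref.state, params, fb, scales=scales)
        bcar = conc["BCAR"]
        records.append(
            ScreenRecord(
                strength=float(s),
                status=res.status,
                bcar=bcar,
                max_real_eig=res.max_real_eig,
                bcar_in_window=BCAR_WINDOW[0] <= bcar <= BCAR_WINDOW[1],
            )
        )
    return ScreenVerdict(scheme=scheme, records=records)


def summarize(verdicts: list[ScreenVerdict]) -> dict:
    """Screening report across schemes.

    The headline boolean asks whether any scheme is viable, i.e. keeps a
    stable steady state with BCAR inside the experimental window across its
    entire negative-strength grid.  ``weak_feedback_points`` counts the
    strengths at which an individual point is stable and in-window (weak
    feedback typically is), for transparency.
    """
    if not verdicts:
        return {"schemes": {}, "any_scheme_viable": None, "note": "empty verdict list"}
    table = {}
    weak_points = {}
    for v in verdicts:
        table[v.scheme.scheme_id] = v.verdict
        weak_points[v.scheme.scheme_id] = sum(
            1 for r in v.records if r.strength < 0 and r.viable
        )
    return {
        "schemes": table,
        "any_scheme_viable": any(v == "viable" for v in table.values()),
        "weak_feedback_points": weak_points,
    }
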
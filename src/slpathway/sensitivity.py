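"""Local logarithmic sensitivities and global parameter scans.

The local measure is the relative (logarithmic) sensitivity

    S(X, p) = d ln X / d ln p,

the percent response of a steady-state concentration X to a percent change
in parameter p, computed by a central difference with step h = 0.01 in
natural-log space (one-sided with h = 0.001 next to an existence boundary).
Global behaviour is probed by one-at-a-time log-spaced scans over several
decades, and by two-dimensional branch-fraction x removal-rate scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import FeedbackExponents, ParameterSet
from .steady_state import SteadyStateError, SteadyStateResult, solve_steady_state

__all__ = [
    "SensitivityUndefinedError",
    "relative_sensitivity",
    "sensitivity_matrix",
    "parameter_scan",
    "scan_table",
    "branch_fraction_scan",
    "ScanRecord",
    "BCAR_WINDOW",
]

#: Experimentally reported window for BCAR in maize, mM (inclusive).
BCAR_WINDOW = (1e-4, 1e-1)


class SensitivityUndefinedError(RuntimeError):
    """The steady state is lost at the perturbed point; S(X,p) undefined."""


@dataclass(frozen=True)
class ScanRecord:
    """One grid point of a parameter scan."""

    parameter: str
    value: float
    result: SteadyStateResult

    @property
    def bcar_in_window(self) -> bool | None:
        if not self.result.exists:
            return None
        b = self.result.concentrations()["BCAR"]
        return BCAR_WINDOW[0] <= b <= BCAR_WINDOW[1]


def _solve_at(params: ParameterSet, fb: FeedbackExponents | None) -> SteadyStateResult:
    res = solve_steady_state(params, fb)
    if not res.exists:
        raise SensitivityUndefinedError(
            f"no steady state at the requested point (limiting step {res.limiting_step})"
        )
    return res


def _species_log(params: ParameterSet, fb, species: str) -> float:
    conc = _solve_at(params, fb).concentrations()[species]
    if conc <= 0:
        raise SensitivityUndefinedError(f"{species} is zero at this point; log undefined")
    return math.log(conc)


def relative_sensitivity(
    params: ParameterSet,
    species: str,
    parameter: str,
    fb: FeedbackExponents | None = None,
    rel_step: float = 0.01,
) -> float:
    """S(species, parameter) = d ln X / d ln p at the model's steady state."""
    if parameter not in params.scannable_parameters():
        raise ValueError(f"unknown parameter {parameter!r} for model {params.model_id}")
    p0 = getattr(params, parameter)
    if p0 <= 0:
        raise ValueError(f"sensitivity needs {parameter} > 0, got {p0}")
    _solve_at(params, fb)  # fail early if the nominal point has no steady state
    h = rel_step

    def at(mult: float) -> float:
        return _species_log(params.replace(**{parameter: p0 * mult}), fb, species)

    try:
        return (at(math.exp(h)) - at(math.exp(-h))) / (2 * h)
    except (SensitivityUndefinedError, SteadyStateError):
        pass
    # near an existence boundary: one-sided with a smaller step, trying both sides
    h = 0.001
    mid = _species_log(params, fb, species)
    for sign in (-1.0, 1.0):
        try:
            return sign * (at(math.exp(sign * h)) - mid) / h
        except (SensitivityUndefinedError, SteadyStateError):
            continue
    raise SensitivityUndefinedError(
        f"steady state lost on both sides of {parameter} at {p0}"
    )


def sensitivity_matrix(
    params: ParameterSet,
    fb: FeedbackExponents | None = None,
    rel_step: float = 0.01,
) -> pd.DataFrame:
    """Full species x parameter matrix of relative sensitivities.

    Rows are steady-state species, columns every scannable parameter
    (including the branch fraction and the removal constant k).
    """
    cols = {}
    for par in params.scannable_parameters():
        p0 = getattr(params, par)
        if p0 == 0:
            cols[par] = [float("nan")] * params.n_species
            continue
        cols[par] = [
            relative_sensitivity(params, sp, par, fb, rel_step) for sp in params.species
        ]
    return pd.DataFrame(cols, index=list(params.species))


def parameter_scan(
    params: ParameterSet,
    parameter: str,
    decades: float = 4.0,
    points_per_decade: int = 10,
    fb: FeedbackExponents | None = None,
) -> list[ScanRecord]:
    """One-at-a-time log-spaced scan centred on the nominal parameter value.

    The grid spans ``decades`` total (half below, half above the nominal
    value) with ``decades * points_per_decade + 1`` points.  Points without a
    steady state are recorded, not skipped.
    """
    if decades < 1:
        raise ValueError("decades must be >= 1")
    if parameter in ("omega", "phi"):
        raise ValueError(
            "branch fractions live on [0,1]; use branch_fraction_scan, not a log scan"
        )
    p0 = getattr(params, parameter)
    if p0 is None or p0 <= 0:
        raise ValueError(f"cannot log-scan {parameter} around {p0!r}")
    n = int(round(decades * points_per_decade)) + 1
    grid = p0 * np.logspace(-decades / 2, decades / 2, n)
    records = []
    for value in grid:
        try:
            res = solve_steady_state(params.replace(**{parameter: value}), fb)
        except SteadyStateError:
            res = SteadyStateResult(
                model_id=params.model_id,
                species=params.species,
                state=None,
                fluxes=None,
                jacobian=None,
                eigenvalues=None,
                max_real_eig=None,
                status="no_steady_state",
                limiting_step=None,
            )
        records.append(ScanRecord(parameter, float(value), res))
    return records


def scan_table(records: list[ScanRecord]) -> pd.DataFrame:
    """Long-format table (parameter, value, species, concentration, status)."""
    rows = []
    for rec in records:
        conc = rec.result.concentrations()
        base = {
            "parameter": rec.parameter,
            "value": rec.value,
            "status": rec.result.status,
            "max_real_eig": rec.result.max_real_eig,
            "bcar_in_window": rec.bcar_in_window,
        }
        if conc:
            for sp, c in conc.items():
                rows.append({**base, "species": sp, "concentration": c})
        else:
            rows.append({**base, "species": None, "concentration": None})
    return pd.DataFrame(rows)


def branch_fraction_scan(
    params: ParameterSet,
    fraction_grid,
    k_grid,
    fb: FeedbackExponents | None = None,
) -> pd.DataFrame:
    """Steady-state ORO and STR over a branch-fraction x removal-rate grid.

    In model AB the closed forms ORO = omega*k0/k and STR = (1-omega)*k0/k
    hold exactly; in model AC the branch fraction phi only redistributes the
    small ABA8HD share, so ORO is confined to [phi*k0/k, k0/k].
    """
    frac_name = "omega" if params.model_id == "AB" else "phi"
    rows = []
    for frac in np.asarray(fraction_grid, dtype=float):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"branch fraction must lie in [0,1], got {frac}")
        for kv in np.asarray(k_grid, dtype=float):
            res = solve_steady_state(params.replace(**{frac_name: frac, "k": kv}), fb)
            conc = res.concentrations()
            rows.append(
                {
                    frac_name: float(frac),
                    "k": float(kv),
                    "ORO": conc.get("ORO"),
                    "STR": conc.get("STR"),
                    "status": res.status,
                }
            )
    return pd.DataFrame(rows)
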
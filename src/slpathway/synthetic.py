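"""Synthetic parameter ensembles, noisy observations, and parameter recovery.

No measured concentration series exist for this pathway beyond single
literature values, so test inputs are generated from the models themselves:
log-uniform parameter ensembles around a base set (robustness exploration),
and steady-state / time-course concentration observations with multiplicative
log-normal noise (concentrations span many decades, so noise is naturally
relative).  A bounded least-squares harness closes the loop by recovering
known parameters from such observations.

All randomness flows from one seed; each operation derives an independent
substream via ``numpy.random.SeedSequence.spawn``-style child seeding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .parameters import FeedbackExponents, ParameterSet
from .steady_state import (
    SteadyStateError,
    integrate,
    solve_steady_state,
    steady_state_exists,
)

__all__ = [
    "ParameterEnsemble",
    "ObservationDesign",
    "ObservationSet",
    "RecoveryReport",
    "sample_ensemble",
    "simulate_observations",
    "recover_parameters",
]

# Parameters drawn log-uniformly when sampling an ensemble (the branch
# fraction is drawn uniformly on [0,1]; k stays fixed unless requested).
_LOGUNIFORM_FIELDS = (
    "k0",
    "kcat_D27A",
    "kcat_D27B",
    "E_D27",
    "E_CCD7",
    "E_CCD8",
    "kcat_CCD7",
    "kcat_CCD8",
    "KM_D27",
    "KM_CCD7",
    "KM_CCD8",
    "KM_MAX1",
    "Vmax_MAX1",
    "Vmax_ABA8HD",
    "KM_ABA8HD",
)


@dataclass
class ParameterEnsemble:
    base: ParameterSet
    half_width_decades: float
    seed: int
    members: list[ParameterSet]

    def existence_fraction(self) -> float:
        """Fraction of members whose unregulated steady state exists."""
        ok = sum(1 for m in self.members if steady_state_exists(m)[0])
        return ok / len(self.members)


def sample_ensemble(
    base: ParameterSet,
    half_width_decades: float,
    n: int,
    seed: int,
    vary_k: bool = False,
    vary_branch_fraction: bool = True,
) -> ParameterEnsemble:
    """Draw ``n`` parameter sets log-uniform within +/- ``half_width_decades``.

    Each kinetic parameter p is drawn from [p*10^-w, p*10^w]; the branch
    fraction is uniform on [0,1]; the removal constant k is fixed unless
    ``vary_k``.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if half_width_decades < 0:
        raise ValueError("half_width_decades must be >= 0")
    rng = np.random.default_rng(seed)
    frac_name = "omega" if base.model_id == "AB" else "phi"
    members = []
    for _ in range(n):
        changes: dict[str, float] = {}
        for name in _LOGUNIFORM_FIELDS:
            p0 = getattr(base, name)
            if p0 is None:
                continue
            w = rng.uniform(-half_width_decades, half_width_decades)
            changes[name] = p0 * 10.0**w
        if vary_branch_fraction and half_width_decades > 0:
            changes[frac_name] = rng.uniform(0.0, 1.0)
        if vary_k:
            changes["k"] = base.k * 10.0 ** rng.uniform(
                -half_width_decades, half_width_decades
            )
        members.append(base.replace(**changes))
    return ParameterEnsemble(base, half_width_decades, seed, members)


@dataclass(frozen=True)
class ObservationDesign:
    """What is observed: which species, when, how many replicates.

    ``timepoints=None`` means steady-state observations (predicted by the
    steady-state solver rather than by integration).
    """

    species: tuple[str, ...]
    timepoints: tuple[float, ...] | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.timepoints is not None and any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be >= 0")


@dataclass
class ObservationSet:
    model_id: str
    truth: ParameterSet
    design: ObservationDesign
    sigma_log: float
    seed: int
    #: long-format table: species, time (NaN for steady state), replicate, value
    data: pd.DataFrame

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _predict(
    params: ParameterSet, design: ObservationDesign, fb: FeedbackExponents | None
) -> pd.DataFrame:
    """Noise-free predictions in the design's long format."""
    rows = []
    if design.timepoints is None:
        res = solve_steady_state(params, fb)
        if not res.exists:
            raise SteadyStateError(
                f"no steady state under these parameters ({res.limiting_step})"
            )
        conc = res.concentrations()
        for sp in design.species:
            rows.append({"species": sp, "time": np.nan, "value": conc[sp]})
    else:
        t_eval, traj = integrate(
            params, fb, t_end=max(design.timepoints), n_out=200
        )
        idx = {sp: i for i, sp in enumerate(params.species)}
        for t in design.timepoints:
            x = traj[np.argmin(np.abs(t_eval - t))]
            for sp in design.species:
                rows.append({"species": sp, "time": t, "value": x[idx[sp]]})
    return pd.DataFrame(rows)


def simulate_observations(
    params: ParameterSet,
    design: ObservationDesign,
    sigma_log: float,
    seed: int,
    fb: FeedbackExponents | None = None,
) -> ObservationSet:
    """Model predictions times exp(eps), eps ~ N(0, sigma_log^2) iid per datum."""
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    pred = _predict(params, design, fb)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for rep in range(design.replicates):
        for _, row in pred.iterrows():
            eps = rng.normal(0.0, sigma_log) if sigma_log > 0 else 0.0
            rows.append(
                {
                    "species": row["species"],
                    "time": row["time"],
                    "replicate": rep,
                    "value": float(row["value"]) * float(np.exp(eps)),
                }
            )
    return ObservationSet(
        model_id=params.model_id,
        truth=params,
        design=design,
        sigma_log=sigma_log,
        seed=seed,
        data=pd.DataFrame(rows),
    )


@dataclass
class RecoveryReport:
    estimates: dict[str, float]
    residual: float
    converged: bool
    relative_errors: dict[str, float]
    n_starts: int

    def within(self, tol: float) -> bool:
        return all(abs(e) <= tol for e in self.relative_errors.values())


def recover_parameters(
    obs: ObservationSet,
    free: list[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> RecoveryReport:
    """Bounded multi-start least squares on log-concentrations.

    ``free`` names the ParameterSet fields to estimate; all others are fixed
    at their true values.  Bounds default to two decades around the truth
    (branch fractions to [1e-6, 1-1e-6]).  Reports per-parameter relative
    error against the known truth.
    """
    truth = obs.truth
    if len(obs.data) < len(free):
        raise ValueError("need at least as many observations as free parameters")
    frac_fields = {"omega", "phi"}
    bounds = dict(bounds or {})
    for name in free:
        if name not in bounds:
            p0 = getattr(truth, name)
            if name in frac_fields:
                bounds[name] = (1e-6, 1.0 - 1e-6)
            else:
                bounds[name] = (p0 / 100.0, p0 * 100.0)

    y_obs = np.log(obs.data["value"].to_numpy(dtype=float))
    design = obs.design

    def unpack(theta: np.ndarray) -> ParameterSet:
        changes = {}
        for name, v in zip(free, theta):
            changes[name] = float(v) if name in frac_fields else float(np.exp(v))
        return truth.replace(**changes)

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            pred = _predict(unpack(theta), design, None)
        except (SteadyStateError, ValueError):
            return np.full_like(y_obs, 1e3)
        mu = np.log(
            np.tile(pred["value"].to_numpy(dtype=float), design.replicates)
        )
        return mu - y_obs

    # parametrize positive parameters in log space, fractions linearly
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    lo = np.array(
        [bounds[n][0] if n in frac_fields else np.log(bounds[n][0]) for n in free]
    )
    hi = np.array(
        [bounds[n][1] if n in frac_fields else np.log(bounds[n][1]) for n in free]
    )
    starts = [lo + (hi - lo) * rng.uniform(0.2, 0.8, size=len(free)) for _ in range(n_starts)]
    best = None
    for x0 in starts:
        fit = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or fit.cost < best.cost:
            best = fit
    est_params = unpack(best.x)
    estimates = {n: float(getattr(est_params, n)) for n in free}
    rel_err = {
        n: (estimates[n] - getattr(truth, n)) / getattr(truth, n) for n in free
    }
    return RecoveryReport(
        estimates=estimates,
        residual=float(np.sqrt(2.0 * best.cost / len(y_obs))),
        converged=bool(best.success),
        relative_errors=rel_err,
        n_starts=n_starts,
    )
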
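"""Parameter sets and feedback exponents for the two pathway models.

Model AB branches the flux at carlactone (CL): the P450 MAX1 converts CL
directly into orobanchol-type (ORO) and strigol-type (STR) strigolactones,
split by the branch fraction ``omega``.  Model AC routes CL through
carlactonic acid (CLA): MAX1 carries CLA to 4-deoxyorobanchol (DO) and on to
ORO, while ABA8HD converts CLA into ORO or STR, split by ``phi``.  Both
models share the upstream core (BCAR -> CISB -> CTNL -> CL, enzymes D27,
CCD7, CCD8) fed at the constant rate ``k0``, with first-order removal of the
end products at rate ``k``.

Units: concentrations mM, time s, rates mM/s.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "ParameterSet",
    "FeedbackExponents",
    "ParameterValidationError",
    "load_parameters",
    "bundled_parameters",
    "BUNDLED_FIXTURES",
    "AB_SPECIES",
    "AC_SPECIES",
    "species_names",
]

#: Ordered state-vector species per model.
AB_SPECIES = ("BCAR", "CISB", "CTNL", "CL", "ORO", "STR")
AC_SPECIES = ("BCAR", "CISB", "CTNL", "CL", "CLA", "DO", "ORO", "STR")

#: Bundled parameter fixtures shipped with the package.
BUNDLED_FIXTURES = ("ab_adjusted", "ab_literature", "ac_adjusted", "ac_literature")


class ParameterValidationError(ValueError):
    """A parameter file or parameter set violates a model constraint."""


def species_names(model_id: str) -> tuple[str, ...]:
    if model_id == "AB":
        return AB_SPECIES
    if model_id == "AC":
        return AC_SPECIES
    raise ParameterValidationError(f"unknown model_id {model_id!r}; expected 'AB' or 'AC'")


# Fields shared by both models; all must be nonnegative.
_COMMON_FIELDS = (
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
    "k",
)
_AB_ONLY = ("omega",)
_AC_ONLY = ("phi", "Vmax_ABA8HD", "KM_ABA8HD")


@dataclass(frozen=True)
class ParameterSet:
    """All kinetic constants of one model variant.

    ``omega`` is required for model AB, ``phi``/``Vmax_ABA8HD``/``KM_ABA8HD``
    for model AC.  Validation happens on construction.
    """

    model_id: str
    k0: float
    kcat_D27A: float
    kcat_D27B: float
    E_D27: float
    E_CCD7: float
    E_CCD8: float
    kcat_CCD7: float
    kcat_CCD8: float
    KM_D27: float
    KM_CCD7: float
    KM_CCD8: float
    KM_MAX1: float
    Vmax_MAX1: float
    k: float
    omega: float | None = None
    phi: float | None = None
    Vmax_ABA8HD: float | None = None
    KM_ABA8HD: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in ("AB", "AC"):
            raise ParameterValidationError(
                f"model_id must be 'AB' or 'AC', got {self.model_id!r}"
            )
        for name in _COMMON_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ParameterValidationError(f"{name} must be a finite number, got {v!r}")
            if v < 0:
                raise ParameterValidationError(f"{name} must be >= 0, got {v}")
        if self.k <= 0:
            raise ParameterValidationError(f"k must be > 0, got {self.k}")
        if self.model_id == "AB":
            if self.omega is None:
                raise ParameterValidationError("model AB requires omega")
            if not 0.0 <= self.omega <= 1.0:
                raise ParameterValidationError(f"omega must lie in [0,1], got {self.omega}")
            for name in _AC_ONLY:
                if getattr(self, name) is not None:
                    raise ParameterValidationError(f"{name} is not a model AB parameter")
        else:
            for name in _AC_ONLY:
                if getattr(self, name) is None:
                    raise ParameterValidationError(f"model AC requires {name}")
            if not 0.0 <= self.phi <= 1.0:
                raise ParameterValidationError(f"phi must lie in [0,1], got {self.phi}")
            if self.Vmax_ABA8HD < 0 or self.KM_ABA8HD < 0:
                raise ParameterValidationError("Vmax_ABA8HD and KM_ABA8HD must be >= 0")
            if self.omega is not None:
                raise ParameterValidationError("omega is not a model AC parameter")

    # -- derived quantities -------------------------------------------------

    @property
    def species(self) -> tuple[str, ...]:
        return species_names(self.model_id)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def Vmax_D27A(self) -> float:
        """Maximal forward isomerase rate kcat_D27A * [D27], mM/s."""
        return self.kcat_D27A * self.E_D27

    @property
    def Vmax_D27B(self) -> float:
        return self.kcat_D27B * self.E_D27

    @property
    def Vmax_CCD7(self) -> float:
        return self.kcat_CCD7 * self.E_CCD7

    @property
    def Vmax_CCD8(self) -> float:
        return self.kcat_CCD8 * self.E_CCD8

    @property
    def branch_fraction(self) -> float:
        """omega (AB) or phi (AC)."""
        return self.omega if self.model_id == "AB" else self.phi  # type: ignore[return-value]

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def scannable_parameters(self) -> tuple[str, ...]:
        """Parameter names that sensitivity and scan tools may vary."""
        names = list(_COMMON_FIELDS)
        names += list(_AB_ONLY if self.model_id == "AB" else _AC_ONLY)
        return tuple(names)

    def to_dict(self) -> dict:
        d = {"model_id": self.model_id}
        for name in self.scannable_parameters():
            d[name] = float(getattr(self, name))
        return d


# Exponent fields valid per model.  All exponents are dimensionless and must
# lie in [-1, 0]: -1 is strong inhibition, 0 switches the regulation off.
AB_EXPONENTS = ("fcl", "foro1", "fstr1", "foro2", "fstr2")
AC_EXPONENTS = ("fcla", "foro1", "fstr1", "foro3", "fstr3", "foro4")


@dataclass(frozen=True)
class FeedbackExponents:
    """Power-law feedback exponents attached to specific reactions.

    First reaction (D27 forward): ``fcl`` (AB, by CL), ``fcla`` (AC, by CLA),
    ``foro1`` and ``fstr1`` (both models, by the end products).  Branch
    reactions: ``foro2``/``fstr2`` (AB, each MAX1 share inhibited by its own
    product), ``foro3``/``fstr3`` (AC, ABA8HD shares), ``foro4`` (AC, the
    MAX1 CLA->DO step inhibited by ORO).
    """

    fcl: float = 0.0
    fcla: float = 0.0
    foro1: float = 0.0
    fstr1: float = 0.0
    foro2: float = 0.0
    fstr2: float = 0.0
    foro3: float = 0.0
    fstr3: float = 0.0
    foro4: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not -1.0 <= v <= 0.0:
                raise ParameterValidationError(
                    f"feedback exponent {f.name} must lie in [-1, 0], got {v}"
                )

    def is_zero(self) -> bool:
        return all(getattr(self, f.name) == 0.0 for f in dataclasses.fields(self))

    def active(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != 0.0
        }

    def validate_for(self, model_id: str) -> None:
        allowed = set(AB_EXPONENTS if model_id == "AB" else AC_EXPONENTS)
        bad = [n for n in self.active() if n not in allowed]
        if bad:
            raise ParameterValidationError(
                f"exponents {bad} are not defined for model {model_id}"
            )

    @classmethod
    def for_scheme(cls, exponents: Iterable[str], strength: float) -> "FeedbackExponents":
        """All named exponents set to ``strength``, the rest zero."""
        return cls(**{name: strength for name in exponents})


def _coerce_number(key: str, value) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ParameterValidationError(f"value for {key!r} is not a number: {value!r}")
    return float(value)


def load_parameters(source: str | Path) -> ParameterSet:
    """Read a flat key-value (YAML mapping) parameter file into a ParameterSet.

    ``source`` may be a path or the name of a bundled fixture
    (one of ``BUNDLED_FIXTURES``).  Unknown keys are rejected.
    """
    if isinstance(source, str) and source in BUNDLED_FIXTURES:
        text = (resources.files("slpathway") / "data" / f"{source}.yaml").read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ParameterValidationError("parameter file must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ParameterValidationError(f"unknown parameter keys: {unknown}")
    if "model_id" not in raw:
        raise ParameterValidationError("missing required key: model_id")
    kwargs = {"model_id": str(raw.pop("model_id"))}
    for key, value in raw.items():
        kwargs[key] = _coerce_number(key, value)
    try:
        return ParameterSet(**kwargs)
    except TypeError as exc:  # missing required dataclass field
        raise ParameterValidationError(str(exc)) from exc


def bundled_parameters(name: str) -> ParameterSet:
    """Load one of the bundled fixtures, e.g. ``'ab_adjusted'``."""
    if name not in BUNDLED_FIXTURES:
        raise ParameterValidationError(
            f"unknown fixture {name!r}; available: {BUNDLED_FIXTURES}"
        )
    return load_parameters(name)
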
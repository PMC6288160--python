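"""Kinetic and protocol parameters for the two-strain cross-protection model.

Two *Escherichia coli* strains protect each other from antibiotics: an
ampicillin-resistant strain (AmpR, density ``N1``) secretes beta-lactamase
that deactivates ampicillin (``A1``), while a chloramphenicol-resistant
strain (ChlR, density ``N2``) deactivates chloramphenicol (``A2``)
intracellularly.  Growth is logistic with a shared carrying capacity;
chloramphenicol is bacteriostatic for AmpR (growth slows to zero but never
turns negative) whereas ampicillin is bactericidal for ChlR (growth turns
negative at high concentration).  Ampicillin degradation follows
Michaelis-Menten kinetics driven by the AmpR density at the *start* of the
daily cycle, which encodes carry-over of free enzyme from the previous day.

The shipped default parameter set was calibrated once so that the daily
growth-migration-dilution protocol reproduces the qualitative dynamical
repertoire of the experimental system: asynchronous period-3 oscillations
of the strain ratio in isolated benign co-cultures, a period-4 window at
intermediate migration rates, synchronized period-3 oscillations at high
migration rates, and deterministic extinction of isolated populations in
the harsh condition.  Any value can be overridden from a YAML mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "ModelParams",
    "ProtocolParams",
    "default_model_params",
    "benign_protocol",
    "harsh_protocol",
    "default_parameters",
    "load_params_file",
]


@dataclass(frozen=True)
class ModelParams:
    """Within-cycle kinetic constants.

    Parameters
    ----------
    gamma1R : float
        Maximum growth rate of the AmpR strain (1/h).
    gamma2R : float
        Maximum growth rate of the ChlR strain (1/h).
    gamma2D : float
        Maximum death rate of the ChlR strain under ampicillin (1/h).
    I12 : float
        Chloramphenicol concentration at which AmpR growth is halved (ug/ml).
    I21 : float
        Ampicillin concentration at which ChlR growth interpolates halfway
        between +gamma2R and -gamma2D (ug/ml).
    K : float
        Shared carrying capacity (cells/ul).
    Vmax : float
        Maximum ampicillin deactivation rate per unit initial AmpR density
        (ug/ml/h per cells/ul).
    Km : float
        Michaelis constant of ampicillin degradation (ug/ml).
    c2 : float
        Chloramphenicol deactivation rate constant per unit ChlR density
        (1/h per cells/ul).
    t_lag : float
        Lag time before growth/death starts each cycle (h).  Antibiotic
        degradation is *not* lagged.
    T_cycle : float
        Duration of one growth cycle (h).
    """

    gamma1R: float
    gamma2R: float
    gamma2D: float
    I12: float
    I21: float
    K: float
    Vmax: float
    Km: float
    c2: float
    t_lag: float
    T_cycle: float = 24.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v == v):  # rejects NaN
                raise ValueError(f"{f.name} must be a finite number, got {v!r}")
            if f.name != "t_lag" and v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v}")
        if self.t_lag < 0:
            raise ValueError(f"t_lag must be non-negative, got {self.t_lag}")
        if self.t_lag >= self.T_cycle:
            raise ValueError(
                f"t_lag ({self.t_lag} h) must be shorter than the growth "
                f"cycle ({self.T_cycle} h)"
            )

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class ProtocolParams:
    """Daily growth-migration-dilution protocol settings.

    Parameters
    ----------
    m : float
        Migration rate: fraction of each culture transferred into the
        partner culture after growth, before dilution.  Restricted to
        [0, 0.5]; at 0.5 the two patches are fully mixed.
    D : float
        Daily dilution factor into fresh medium.
    A1_fresh, A2_fresh : float
        Ampicillin / chloramphenicol concentrations of the fresh medium
        (ug/ml).
    noise_cv : float
        Coefficient of variation of the multiplicative protocol noise
        applied to dilution factors and transferred migration fractions
        (lognormal, mean 1).  0 gives a fully deterministic protocol.
    extinction_threshold : float
        Density below which a subpopulation is set to zero after dilution
        (cells/ul).  The default corresponds to one cell in a 200 ul
        culture.
    antibiotic_carryover : bool
        If True, residual antibiotic is carried into the next cycle at a
        factor 1/(D*f) on top of the fresh concentration.
    """

    m: float = 0.0
    D: float = 100.0
    A1_fresh: float = 10.0
    A2_fresh: float = 8.0
    noise_cv: float = 0.0
    extinction_threshold: float = 0.005
    antibiotic_carryover: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 0.5:
            raise ValueError(f"migration rate m must lie in [0, 0.5], got {self.m}")
        if self.D <= 1:
            raise ValueError(f"dilution factor D must exceed 1, got {self.D}")
        if self.A1_fresh < 0 or self.A2_fresh < 0:
            raise ValueError("fresh antibiotic concentrations must be >= 0")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction_threshold must be > 0")

    def replace(self, **changes) -> "ProtocolParams":
        return replace(self, **changes)


#: Calibrated default kinetic constants (see module docstring).
_DEFAULT_MODEL = dict(
    gamma1R=0.593473,
    gamma2R=0.735524,
    gamma2D=1.37376,
    I12=4.01287,
    I21=2.18275,
    K=1.0e5,
    Vmax=0.0856983,
    Km=0.676303,
    c2=2.44382e-4,
    t_lag=2.49458,
    T_cycle=24.0,
)

#: Benign / harsh environments used throughout: ampicillin is held at
#: 10 ug/ml while chloramphenicol is 8 (benign) or 16 (harsh) ug/ml.
BENIGN_ANTIBIOTICS = (10.0, 8.0)
HARSH_ANTIBIOTICS = (10.0, 16.0)


def default_model_params() -> ModelParams:
    """The shipped calibrated kinetic parameter set."""
    return ModelParams(**_DEFAULT_MODEL)


def benign_protocol(**overrides) -> ProtocolParams:
    """Deterministic benign protocol (10 ug/ml amp, 8 ug/ml chl)."""
    kw = dict(A1_fresh=BENIGN_ANTIBIOTICS[0], A2_fresh=BENIGN_ANTIBIOTICS[1])
    kw.update(overrides)
    return ProtocolParams(**kw)


def harsh_protocol(**overrides) -> ProtocolParams:
    """Harsh protocol (10 ug/ml amp, 16 ug/ml chl); deterministic unless
    ``noise_cv`` is overridden."""
    kw = dict(A1_fresh=HARSH_ANTIBIOTICS[0], A2_fresh=HARSH_ANTIBIOTICS[1])
    kw.update(overrides)
    return ProtocolParams(**kw)


def default_parameters() -> tuple[ModelParams, ProtocolParams, ProtocolParams]:
    """Return ``(model, benign, harsh)`` default parameter objects."""
    return default_model_params(), benign_protocol(), harsh_protocol()


def load_params_file(
    path: Union[str, Path],
) -> tuple[ModelParams, ProtocolParams]:
    """Load model/protocol parameters from a flat YAML mapping.

    Keys are exactly the field names of :class:`ModelParams` and
    :class:`ProtocolParams`; omitted keys keep their defaults and unknown
    keys raise ``ValueError``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    model_fields = {f.name for f in fields(ModelParams)}
    proto_fields = {f.name for f in fields(ProtocolParams)}
    unknown = set(raw) - model_fields - proto_fields
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    mkw = dict(_DEFAULT_MODEL)
    mkw.update({k: v for k, v in raw.items() if k in model_fields})
    pkw = {k: v for k, v in raw.items() if k in proto_fields}
    return ModelParams(**mkw), ProtocolParams(**pkw)
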
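"""Two-population "island" demographic models and their epoch schedules.

Every model describes a split of an ancestral population (relative size
``nuA``, in units of an implicit reference size ``N_ref``) into two daughter
populations.  A founding fraction ``s`` divides the ancestor at the split:
population 2 (the derived "island") starts at size ``nuA*s`` and population 1
(the ancestral "mainland") at ``nuA*(1-s)``; ``s`` is capped at 0.5 so the
derived population is never the larger founding fraction.  Times are measured
in units of ``2*N_ref`` generations and migration rates in units of
``2*N_ref*m`` (``m`` = per-generation migrant fraction), the conventions used
by diffusion-based SFS software.

A model is rendered for simulation as an :class:`EpochSchedule`: a
backward-in-time list of epochs (most recent first), each with per-deme size
trajectories and a backward lineage-migration matrix, terminated by a merge of
both demes into the ancestral deme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

__all__ = [
    "ParamSet",
    "DemographicModel",
    "Epoch",
    "EpochSchedule",
    "model_registry",
    "get_model",
    "to_epochs",
    "validate_params",
    "ParamValidationError",
]

#: default box bounds for free parameters (configurable per model)
SIZE_BOUNDS = (1e-3, 100.0)
TIME_BOUNDS = (1e-3, 15.0)
RECENT_TIME_BOUNDS = (1e-3, 0.05)  # "recent founder" split times
MIG_BOUNDS = (0.0, 20.0)
S_BOUNDS = (0.0, 0.5)

PARAM_ORDER = ("nuA", "nu1", "nu2", "T", "T1", "T2", "s", "m12", "m21")


@dataclass
class ParamSet:
    """Free-parameter values of a demographic model.

    ``theta`` (``4*N_ref*mu*L``) is never part of the set: it is profiled
    analytically during fitting.  Unused parameters are ``None``.
    """

    nuA: Optional[float] = None
    nu1: Optional[float] = None
    nu2: Optional[float] = None
    T: Optional[float] = None
    T1: Optional[float] = None
    T2: Optional[float] = None
    s: Optional[float] = None
    m12: Optional[float] = None
    m21: Optional[float] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if getattr(self, f.name) is not None}

    def __getitem__(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise KeyError(f"parameter {name!r} not set")
        return v


@dataclass(frozen=True)
class DemographicModel:
    """A named epoch-structured two-population history.

    ``free_params`` is an ordered tuple of ``(name, low, high)`` bounds; ``k``
    (the AIC parameter count) is its length and excludes theta.
    """

    name: str
    scenario: str            # vicariance | founder_old | founder_recent
    growth: str              # constant | two_epoch | exp_growth
    migration: str           # none | ancestral_then_isolation | secondary_contact | continuous
    free_params: tuple       # ((name, lo, hi), ...)
    description: str = ""

    @property
    def k(self) -> int:
        return len(self.free_params)

    @property
    def param_names(self) -> tuple:
        return tuple(p[0] for p in self.free_params)

    def paramset(self, values) -> ParamSet:
        """Build a ParamSet from a vector ordered like ``free_params``."""
        values = list(values)
        if len(values) != self.k:
            raise ValueError(
                f"{self.name}: expected {self.k} values, got {len(values)}")
        return ParamSet(**dict(zip(self.param_names, values)))


@dataclass
class Epoch:
    """One backward-time epoch.

    ``size_start`` is the per-deme size at the *recent* edge of the epoch and
    ``size_end`` at the old edge; sizes interpolate exponentially between the
    two (equal endpoints = constant).  ``mig[d]`` is the backward per-lineage
    rate at which a lineage currently in deme ``d`` jumps to the other deme.
    """

    duration: float
    size_start: np.ndarray   # shape (2,)
    size_end: np.ndarray     # shape (2,)
    mig: np.ndarray          # shape (2,), mig[0] = rate 1->2 (= m12), mig[1] = m21


@dataclass
class EpochSchedule:
    """Backward-time rendering of a model: post-split epochs then the merge."""

    epochs: list             # recent-first post-split epochs
    nuA: float               # ancestral deme size after the merge

    @property
    def split_time(self) -> float:
        return float(sum(e.duration for e in self.epochs))

    def validate(self) -> None:
        for e in self.epochs:
            if e.duration < 0:
                raise ParamValidationError(["epoch duration < 0"])
            if np.any(e.size_start <= 0) or np.any(e.size_end <= 0):
                raise ParamValidationError(["non-positive deme size in epoch"])
        if self.nuA <= 0:
            raise ParamValidationError(["non-positive ancestral size"])


class ParamValidationError(ValueError):
    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


def _sz(name):
    return (name, *SIZE_BOUNDS)


def _tm(name, recent=False):
    return (name, *(RECENT_TIME_BOUNDS if recent else TIME_BOUNDS))


def _mg(name):
    return (name, *MIG_BOUNDS)


_S = ("s", *S_BOUNDS)


def _registry_full() -> list:
    """The eight-model candidate set.

    The four models named in the study's results table are reproduced exactly
    (names, free parameters, epoch/migration structure).  The remaining four
    complete the scenario (vicariance / old founder / recent founder) ×
    size-trajectory (constant / two-epoch / continuous growth) grid with the
    migration variants needed to cover ancestral and recent gene flow.
    """
    return [
        DemographicModel(
            "vic_no_mig", "vicariance", "constant", "none",
            (_sz("nuA"), _sz("nu1"), _sz("nu2"), _tm("T"), _S),
            "Old vicariance; constant daughter sizes; no gene flow.",
        ),
        DemographicModel(
            "vic_sec_contact_asym_mig", "vicariance", "constant", "secondary_contact",
            (_sz("nuA"), _sz("nu1"), _sz("nu2"), _tm("T1"), _tm("T2"),
             _S, _mg("m12"), _mg("m21")),
            "Old vicariance; isolation for T1 then asymmetric secondary "
            "contact for T2.",
        ),
        DemographicModel(
            "vic_anc_asym_mig", "vicariance", "constant", "ancestral_then_isolation",
            (_sz("nuA"), _sz("nu1"), _sz("nu2"), _tm("T1"), _tm("T2"),
             _S, _mg("m12"), _mg("m21")),
            "Old vicariance; asymmetric gene flow for T1 after the split, "
            "then isolation for T2.",
        ),
        DemographicModel(
            "founder_no_mig", "founder_old", "exp_growth", "none",
            (_sz("nuA"), _sz("nu1"), _sz("nu2"), _tm("T"), _S),
            "Old founder event; continuous exponential growth from the "
            "founding sizes; no gene flow.",
        ),
        DemographicModel(
            "founder_sec_contact_asym_two_epoch", "founder_old", "two_epoch",
            "secondary_contact",
            (_sz("nuA"), _sz("nu1"), _sz("nu2"), _tm("T1"), _tm("T2"),
             _S, _mg("m12"), _mg("m21")),
            "Old founder event; founding sizes for T1 in isolation, then "
            "nu1/nu2 with asymmetric secondary contact for T2.",
        ),
        DemographicModel(
            "founder_anc_asym_two_epoch", "founder_old", "two_epoch",
            "ancestral_then_isolation",
            (_sz("nuA"), _sz("nu1"), _sz("nu2"), _tm("T1"), _tm("T2"),
             _S, _mg("m12"), _mg("m21")),
            "Old founder event; founding sizes with asymmetric gene flow for "
            "T1, then nu1/nu2 in isolation for T2.",
        ),
        DemographicModel(
            "founder_continuous_asym_mig", "founder_old", "exp_growth", "continuous",
            (_sz("nuA"), _sz("nu1"), _sz("nu2"), _tm("T"), _S,
             _mg("m12"), _mg("m21")),
            "Old founder event; exponential growth with continuous "
            "asymmetric gene flow.",
        ),
        DemographicModel(
            "founder_recent_no_mig", "founder_recent", "exp_growth", "none",
            (_sz("nuA"), _sz("nu1"), _sz("nu2"), _tm("T", recent=True), _S),
            "Recent (postglacial) founder event: same topology as "
            "founder_no_mig with the split bounded to very recent times.",
        ),
    ]


def model_registry(comparison: str = "full") -> list:
    """Return the candidate model set.

    ``full`` is the eight-model set used for each pairwise population
    comparison; ``vicariance_family`` / ``founder_family`` are the obvious
    subsets.
    """
    full = _registry_full()
    if comparison == "full":
        return full
    if comparison == "vicariance_family":
        return [m for m in full if m.scenario == "vicariance"]
    if comparison == "founder_family":
        return [m for m in full if m.scenario.startswith("founder")]
    raise ValueError(f"unknown comparison {comparison!r}")


def get_model(name: str) -> DemographicModel:
    for m in _registry_full():
        if m.name == name:
            return m
    raise KeyError(f"no model named {name!r}")


def validate_params(model: DemographicModel, p: ParamSet) -> list:
    """Check ``p`` against the model's bounds; return a list of violations.

    An empty list means OK.  ``s`` additionally must lie in (0, 0.5].
    """
    violations = []
    for name, lo, hi in model.free_params:
        v = getattr(p, name)
        if v is None:
            violations.append(f"{name}: missing")
            continue
        if not np.isfinite(v):
            violations.append(f"{name}: non-finite")
            continue
        if name == "s" and v <= 0:
            violations.append(f"s: must be > 0, got {v}")
            continue
        if v < lo or v > hi:
            violations.append(f"{name}: {v} outside [{lo}, {hi}]")
    return violations


def to_epochs(model: DemographicModel, p: ParamSet) -> EpochSchedule:
    """Render (model, parameters) as an explicit backward-time epoch schedule.

    Forward semantics: at the split the ancestor of size ``nuA`` divides into
    founding sizes ``nuA*(1-s)`` (pop 1) and ``nuA*s`` (pop 2).  Then

    * ``constant`` – sizes jump immediately to ``nu1``/``nu2`` and stay;
    * ``two_epoch`` – founding sizes for the older interval ``T1``, then
      ``nu1``/``nu2`` for the recent interval ``T2``;
    * ``exp_growth`` – sizes interpolate exponentially from the founding
      sizes at the split to ``nu1``/``nu2`` at the present.

    Migration is placed per the model's variant: ``secondary_contact`` only
    in the most recent epoch, ``ancestral_then_isolation`` only in the oldest
    post-split epoch, ``continuous`` everywhere after the split.
    """
    violations = validate_params(model, p)
    if violations:
        raise ParamValidationError(violations)

    nuA = p["nuA"]
    s = p["s"]
    found = np.array([nuA * (1.0 - s), nuA * s])
    present = np.array([p["nu1"], p["nu2"]])
    mig = np.array([p.m12 or 0.0, p.m21 or 0.0])
    zero = np.zeros(2)

    two_times = "T1" in model.param_names
    if two_times:
        t_old, t_recent = p["T1"], p["T2"]
    else:
        t_old, t_recent = p["T"], None

    epochs = []
    if model.growth == "constant":
        if two_times:
            m_recent = mig if model.migration in ("secondary_contact", "continuous") else zero
            m_old = mig if model.migration in ("ancestral_then_isolation", "continuous") else zero
            epochs = [Epoch(t_recent, present.copy(), present.copy(), m_recent),
                      Epoch(t_old, present.copy(), present.copy(), m_old)]
        else:
            m = mig if model.migration == "continuous" else zero
            epochs = [Epoch(t_old, present.copy(), present.copy(), m)]
    elif model.growth == "two_epoch":
        m_recent = mig if model.migration in ("secondary_contact", "continuous") else zero
        m_old = mig if model.migration in ("ancestral_then_isolation", "continuous") else zero
        epochs = [Epoch(t_recent, present.copy(), present.copy(), m_recent),
                  Epoch(t_old, found.copy(), found.copy(), m_old)]
    elif model.growth == "exp_growth":
        m = mig if model.migration == "continuous" else zero
        # backward: present sizes at the recent edge, founding sizes at the split
        epochs = [Epoch(t_old, present.copy(), found.copy(), m)]
    else:  # pragma: no cover - registry guards this
        raise ValueError(f"unknown growth {model.growth!r}")

    sched = EpochSchedule(epochs=epochs, nuA=nuA)
    sched.validate()
    return sched
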
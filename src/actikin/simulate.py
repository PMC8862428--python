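"""Seeded synthetic ATPase assay generator.

Emulates the colorimetric phosphate-release assay: for each (MgATP, GSSG,
replicate) cell of a concentration design, released phosphate accumulates
linearly in time at the steady-state velocity of the nonessential activator
model, and each timed reading is perturbed by independent Gaussian noise with
standard deviation ``cv * reading + additive_floor``.  Rates are then
recovered from the noisy time courses exactly as from real data, by
ordinary-least-squares slopes normalized to transporter molarity.

The default design mirrors the published assay: 8 MgATP concentrations
(0–10 mM) x 6 GSSG concentrations (0–20 mM), aliquots every 5 min for
15 min, sextuplicate (detergent, proteoliposomes) or triplicate (nanodiscs)
replicates, 0.05 mg/ml transporter.

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import conditions as cond
from .errors import (
    DoubleCorrectionError,
    InvalidContextError,
    InvalidNoiseError,
)
from .models import ActivatorParams, specific_rate

__all__ = [
    "DesignGrid",
    "ReconstitutionContext",
    "NoiseSpec",
    "TimeCourse",
    "RateObservation",
    "standard_design",
    "standard_context",
    "transporter_molarity",
    "simulate_timecourse",
    "simulate_dataset",
    "apply_orientation_correction",
]


@dataclass(frozen=True)
class DesignGrid:
    """Concentration design of an assay: MgATP x GSSG grid, replicates, times."""

    atp_concentrations: tuple[float, ...]
    gssg_concentrations: tuple[float, ...]
    n_replicates: int
    time_points: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("atp_concentrations", "gssg_concentrations"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) == 0 or any(v < 0 for v in vals) or any(
                b <= a for a, b in zip(vals, vals[1:])
            ):
                raise InvalidContextError(
                    f"{name} must be non-negative and strictly increasing"
                )
            object.__setattr__(self, name, vals)
        if self.n_replicates < 1:
            raise InvalidContextError("n_replicates must be >= 1")
        times = tuple(float(t) for t in self.time_points)
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidContextError("need >= 2 strictly increasing time points")
        object.__setattr__(self, "time_points", times)

    @property
    def n_cells(self) -> int:
        return len(self.atp_concentrations) * len(self.gssg_concentrations)


@dataclass(frozen=True)
class ReconstitutionContext:
    """Converts mass-based protein loading to molar transporter concentration.

    For scaffold-containing preparations (nanodiscs) the transporter is only a
    mass fraction of total protein: MW_t / (MW_t + n_scaffold * MW_scaffold).
    For vesicular preparations with mixed transporter orientation, measured
    rates understate true activity by ``orientation_factor`` (about 2 for
    proteoliposomes; 1 for detergent and nanodiscs).
    """

    condition_name: str = "custom"
    protein_mass_conc: float = cond.ASSAY_PROTEIN_MASS_MG_PER_ML  # mg/ml
    transporter_mw: float = cond.TRANSPORTER_MW_KDA  # kDa
    scaffold_mw: float | None = None  # kDa
    scaffold_per_transporter: int | None = None
    transporter_mass_fraction: float = 1.0
    orientation_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.protein_mass_conc <= 0 or self.transporter_mw <= 0:
            raise InvalidContextError("protein mass and MW must be positive")
        if (self.scaffold_mw is None) != (self.scaffold_per_transporter is None):
            raise InvalidContextError(
                "scaffold_mw and scaffold_per_transporter must be set together"
            )
        if self.scaffold_mw is not None:
            frac = self.transporter_mw / (
                self.transporter_mw + self.scaffold_per_transporter * self.scaffold_mw
            )
            object.__setattr__(self, "transporter_mass_fraction", frac)
        if not (0.0 < self.transporter_mass_fraction <= 1.0):
            raise InvalidContextError("transporter_mass_fraction must be in (0, 1]")
        if self.orientation_factor < 1.0:
            raise InvalidContextError("orientation_factor must be >= 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Per-reading noise: sd = cv * reading + additive_floor (uM phosphate)."""

    cv: float = 0.05
    additive_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.cv < 0 or self.additive_floor < 0:
            raise InvalidNoiseError("noise parameters must be non-negative")


@dataclass(frozen=True)
class TimeCourse:
    """Timed phosphate-release readings for one reaction."""

    condition_name: str
    atp: float  # mM
    gssg: float  # mM
    replicate: int
    times: tuple[float, ...]  # min
    pi_conc: tuple[float, ...]  # uM released phosphate


@dataclass(frozen=True)
class RateObservation:
    """One steady-state ATPase rate (min^-1 per transporter) at a grid point."""

    condition_name: str
    atp: float  # mM
    gssg: float  # mM
    replicate: int
    rate: float  # min^-1
    orientation_corrected: bool = False


def standard_design(condition_name: str) -> DesignGrid:
    """The published 8 MgATP x 6 GSSG design for a named condition.

    Sextuplicate for detergent and proteoliposomes, triplicate for nanodiscs;
    four samples taken every 5 min.
    """
    cond.require_condition(condition_name)
    return DesignGrid(
        atp_concentrations=cond.ATP_CONCENTRATIONS_MM,
        gssg_concentrations=cond.GSSG_CONCENTRATIONS_MM,
        n_replicates=cond.N_REPLICATES[condition_name],
        time_points=cond.TIME_POINTS_MIN,
    )


def standard_context(condition_name: str) -> ReconstitutionContext:
    """The published reconstitution context for a named condition."""
    cond.require_condition(condition_name)
    if condition_name == "nanodiscs":
        return ReconstitutionContext(
            condition_name="nanodiscs",
            scaffold_mw=cond.SCAFFOLD_MW_KDA,
            scaffold_per_transporter=cond.SCAFFOLDS_PER_TRANSPORTER,
        )
    if condition_name == "proteoliposomes":
        return ReconstitutionContext(
            condition_name="proteoliposomes", orientation_factor=2.0
        )
    return ReconstitutionContext(condition_name="detergent")


def transporter_molarity(ctx: ReconstitutionContext) -> float:
    """Molar transporter concentration (mol/L) from mass-based loading.

    mass_conc [mg/ml = g/L] * mass_fraction / (MW [kDa] * 1000 [g/mol per kDa]).
    """
    return ctx.protein_mass_conc * ctx.transporter_mass_fraction / (
        ctx.transporter_mw * 1000.0
    )


def transporter_molarity_uM(ctx: ReconstitutionContext) -> float:
    """Transporter concentration in uM, the unit of the phosphate readings."""
    return transporter_molarity(ctx) * 1e6


def simulate_timecourse(
    p: ActivatorParams,
    ctx: ReconstitutionContext,
    atp: float,
    gssg: float,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | np.random.Generator = 0,
    replicate: int = 0,
    times: tuple[float, ...] = cond.TIME_POINTS_MIN,
    t0_measured: bool = True,
) -> TimeCourse:
    """Simulate one phosphate-release time course.

    Phosphate accumulates linearly, pi(t) = v * E_T * t (steady state over the
    15-min window), with independent Gaussian noise per reading.  With
    ``t0_measured=False`` the zero-time blank is taken as exactly zero rather
    than carrying reading noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e_uM = transporter_molarity_uM(ctx)
    v = specific_rate(p, atp, gssg)  # min^-1
    t = np.asarray(times, dtype=float)
    clean = v * e_uM * t  # uM
    sd = noise.cv * clean + noise.additive_floor
    pi = clean + sd * rng.standard_normal(t.size)
    if not t0_measured:
        pi[t == 0.0] = 0.0
    return TimeCourse(
        condition_name=ctx.condition_name,
        atp=float(atp),
        gssg=float(gssg),
        replicate=int(replicate),
        times=tuple(t),
        pi_conc=tuple(pi),
    )


def simulate_dataset(
    p: ActivatorParams,
    ctx: ReconstitutionContext,
    grid: DesignGrid,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    t0_measured: bool = True,
    return_timecourses: bool = False,
):
    """Simulate a full assay dataset: one rate per (MgATP, GSSG, replicate).

    Each rate is extracted from its simulated time course by the same
    ordinary-least-squares slope estimator used on real data, so rate-level
    noise is induced by, not assumed alongside, the reading-level noise model.
    Iteration order (GSSG outer, MgATP, replicate inner) is fixed so a given
    seed yields a bitwise-identical dataset.

    Returns a list of RateObservation, or ``(observations, timecourses)`` when
    ``return_timecourses`` is set.
    """
    from .fit import extract_rate  # local import; fit depends on our types

    if seed < 0:
        raise InvalidNoiseError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    observations: list[RateObservation] = []
    courses: list[TimeCourse] = []
    for gssg in grid.gssg_concentrations:
        for atp in grid.atp_concentrations:
            for rep in range(grid.n_replicates):
                tc = simulate_timecourse(
                    p, ctx, atp, gssg, noise, rng,
                    replicate=rep, times=grid.time_points, t0_measured=t0_measured,
                )
                observations.append(extract_rate(tc, ctx))
                if return_timecourses:
                    courses.append(tc)
    if return_timecourses:
        return observations, courses
    return observations


def apply_orientation_correction(
    obs: RateObservation, ctx: ReconstitutionContext
) -> RateObservation:
    """Scale a measured rate by the context's orientation factor.

    In proteoliposomes roughly half the transporters face away from the
    accessible side, so true turnover is about twice the measured rate.
    Correcting an already-corrected observation raises DoubleCorrectionError.
    """
    if obs.orientation_corrected:
        raise DoubleCorrectionError(
            "rate observation is already orientation-corrected"
        )
    return replace(
        obs, rate=obs.rate * ctx.orientation_factor, orientation_corrected=True
    )
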
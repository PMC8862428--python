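"""Closed-form steady-state rate laws for substrate-stimulated ATPase activity.

Implements the Michaelis–Menten equation and the nonessential activator model
for an ABC exporter whose basal ATP hydrolysis is stimulated by its transported
substrate.  In the activator scheme the enzyme E turns over with MgATP (T)
alone at rate constant ``k``; binding of the activator/substrate S (here,
oxidized glutathione) rescales the MgATP binding constant by the interaction
factor ``alpha`` and the hydrolysis rate constant by the acceleration factor
``beta``:

    v / E_T = k * (T/K_T + beta*S*T/(alpha*K_S*K_T))
              / (1 + T/K_T + S/K_S + S*T/(alpha*K_S*K_T))

which factorizes exactly into an apparent Michaelis–Menten form

    v / E_T = k_obs(S) * T / (K_T_app(S) + T)

with

    k_obs(S)   = k   * (1 + beta*S/(alpha*K_S)) / (1 + S/(alpha*K_S))
    K_T_app(S) = K_T * (1 +      S/K_S)         / (1 + S/(alpha*K_S)).

``alpha > 1`` encodes negative cooperativity between MgATP and the activator
(K_T_app rises with S), ``alpha < 1`` positive cooperativity; ``beta = 1``
means no rate acceleration.  All concentrations are in mM; rate constants in
min^-1 per transporter homodimer (135 kDa).  The total transporter
concentration E_T is carried separately so velocities can be reported either
specific (min^-1, the default) or absolute (concentration/min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "ActivatorParams",
    "MichaelisParams",
    "LigandState",
    "mm_rate",
    "activator_velocity",
    "specific_rate",
    "kobs",
    "kt_app",
    "fold_stimulation",
]

#: positive floor below which a rate or binding constant is rejected; the
#: activator expressions divide by alpha*K_S.
_PARAM_FLOOR = 1e-12


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value < _PARAM_FLOOR:
        raise InvalidParameterError(
            f"{name} must be finite and > {_PARAM_FLOOR:g}, got {value!r}"
        )
    return value


def _require_nonnegative(name: str, value) -> np.ndarray | float:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidParameterError(f"{name} must be finite and >= 0, got {value!r}")
    return arr if arr.ndim else float(arr)


@dataclass(frozen=True)
class ActivatorParams:
    """Five parameters of the nonessential activator rate law.

    Attributes
    ----------
    k : float
        Basal MgATP hydrolysis rate constant, min^-1 per transporter.
    K_T : float
        Michaelis binding constant for MgATP, mM.
    K_S : float
        Michaelis binding constant for the activator (GSSG), mM.
    alpha : float
        Dimensionless MgATP–activator interaction factor; 1 = no
        cooperativity, >1 negative, <1 positive.
    beta : float
        Dimensionless acceleration factor for hydrolysis with activator
        bound; 1 = no activation.
    """

    k: float
    K_T: float
    K_S: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("k", "K_T", "K_S", "alpha", "beta"):
            object.__setattr__(self, name, _require_positive(name, getattr(self, name)))

    def as_array(self) -> np.ndarray:
        return np.array([self.k, self.K_T, self.K_S, self.alpha, self.beta])

    @staticmethod
    def names() -> tuple[str, ...]:
        return ("k", "K_T", "K_S", "alpha", "beta")

    @classmethod
    def from_array(cls, values) -> "ActivatorParams":
        k, kt, ks, a, b = (float(v) for v in values)
        return cls(k=k, K_T=kt, K_S=ks, alpha=a, beta=b)


@dataclass(frozen=True)
class MichaelisParams:
    """Turnover number (min^-1) and Michaelis constant (mM) of a hyperbolic fit."""

    kcat: float
    Km: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kcat", _require_positive("kcat", self.kcat))
        object.__setattr__(self, "Km", _require_positive("Km", self.Km))


@dataclass(frozen=True)
class LigandState:
    """Ligand concentrations (mM) and, optionally, transporter concentration.

    ``e_total`` (molar units, e.g. uM) is only needed when an absolute
    velocity is requested; with ``e_total=None`` velocities are specific
    rates in min^-1 per transporter.
    """

    T: float
    S: float = 0.0
    e_total: float | None = None

    def __post_init__(self) -> None:
        _require_nonnegative("T", self.T)
        _require_nonnegative("S", self.S)
        if self.e_total is not None:
            _require_positive("e_total", self.e_total)


def mm_rate(p: MichaelisParams, T) -> np.ndarray | float:
    """Michaelis–Menten rate kcat*T/(Km+T) at MgATP concentration ``T`` (mM).

    Vectorized over ``T``; returns 0 at T=0 and approaches ``kcat`` as T grows.
    """
    T = _require_nonnegative("T", T)
    return p.kcat * T / (p.Km + T)


def kobs(p: ActivatorParams, S) -> np.ndarray | float:
    """Apparent catalytic rate constant at activator concentration ``S`` (mM).

    Equals ``k`` at S=0 and approaches ``beta*k`` at saturating S; monotone
    increasing in S whenever beta > 1.
    """
    S = _require_nonnegative("S", S)
    x = S / (p.alpha * p.K_S)
    return p.k * (1.0 + p.beta * x) / (1.0 + x)


def kt_app(p: ActivatorParams, S) -> np.ndarray | float:
    """Apparent MgATP Michaelis constant (mM) at activator concentration ``S``.

    Equals ``K_T`` at S=0; increasing in S iff alpha > 1 (negative
    cooperativity), constant at alpha = 1, and tending to ``alpha*K_T`` at
    saturating S.
    """
    S = _require_nonnegative("S", S)
    return p.K_T * (1.0 + S / p.K_S) / (1.0 + S / (p.alpha * p.K_S))


def activator_velocity(p: ActivatorParams, state: LigandState) -> float:
    """Steady-state velocity of the nonessential activator model.

    Returns the specific rate (min^-1) when ``state.e_total`` is unset,
    otherwise the absolute velocity ``e_total * rate``.  Zero whenever T=0:
    the activator alone drives no turnover.
    """
    v = specific_rate(p, state.T, state.S)
    return v if state.e_total is None else state.e_total * v


def specific_rate(p: ActivatorParams, T, S) -> np.ndarray | float:
    """Vectorized specific rate v/E_T (min^-1) of the activator model."""
    T = _require_nonnegative("T", T)
    S = _require_nonnegative("S", S)
    c = p.alpha * p.K_S * p.K_T
    num = p.k * (T / p.K_T + p.beta * S * T / c)
    den = 1.0 + T / p.K_T + S / p.K_S + S * T / c
    return num / den


def fold_stimulation(p: ActivatorParams, S) -> np.ndarray | float:
    """Ratio kobs(S)/kobs(0): fold stimulation of turnover by the activator.

    Equals 1 at S=0 and is bounded above by ``beta``.
    """
    return kobs(p, S) / p.k
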
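"""Pharmacokinetic ODE systems used as hard kinetic constraints.

Two phenomenological rate models ship built in:

``uptake``
    A single saturating state, the amount of drug bound inside a cellular
    compartment::

        dNb/dt = (Nrecp - Nb) * Kup * D

    where ``Kup`` is the uptake rate (h^-1 per unit dose), ``Nrecp`` the
    binding capacity and ``D`` the (constant, dimensionless) dose.  Only the
    product ``Kup * D`` drives the dynamics, so ``Kup`` and ``D`` are jointly
    identifiable; ``D`` is held fixed at 1.0 by default.

``uptake_response``
    Adds a second, slower state, the cellular response driven by the amount
    of bound drug::

        dNr/dt = (Nresp - Nr) * Kresp * Nb

Arbitrary user-declared systems are accepted through the same
:class:`KineticModel` interface (see :func:`model_from_expressions`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._exceptions import IntegrationError, InvalidParameterError

__all__ = [
    "KineticParams",
    "KineticModel",
    "ConcentrationProfiles",
    "solve_kinetics",
    "closed_form_uptake",
    "closed_form_uptake_response",
    "get_model",
    "register_model",
    "model_from_expressions",
    "MODEL_REGISTRY",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and capacities of the uptake/response system.

    Parameters
    ----------
    Kup : float
        Drug uptake rate, h^-1 per unit dose.
    Kresp : float
        Cellular response rate, h^-1 per unit bound drug.
    Nrecp : float
        Binding (receptor) capacity, arbitrary concentration units.
    Nresp : float
        Response capacity, arbitrary concentration units.
    D : float
        Drug dose, dimensionless and constant over time.  Only the product
        ``Kup * D`` is identifiable from uptake data.
    """

    Kup: float = 0.0
    Kresp: float = 0.0
    Nrecp: float = 0.0
    Nresp: float = 0.0
    D: float = 1.0

    def validate(self) -> "KineticParams":
        for name in ("Kup", "Kresp", "Nrecp", "Nresp", "D"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name}={v!r} is not finite")
            if v < 0:
                raise InvalidParameterError(f"{name}={v!r} must be >= 0")
        return self

    def as_dict(self) -> dict[str, float]:
        return {
            "Kup": self.Kup,
            "Kresp": self.Kresp,
            "Nrecp": self.Nrecp,
            "Nresp": self.Nresp,
            "D": self.D,
        }


def _as_param_dict(params: "KineticParams | Mapping[str, float]") -> dict[str, float]:
    if isinstance(params, KineticParams):
        return params.validate().as_dict()
    out = dict(params)
    for name, v in out.items():
        if not math.isfinite(v):
            raise InvalidParameterError(f"{name}={v!r} is not finite")
        if v < 0:
            raise InvalidParameterError(f"{name}={v!r} must be >= 0")
    return out


@dataclass(frozen=True)
class KineticModel:
    """A declared ODE system usable as a hard constraint.

    ``rhs(t, y, p)`` receives the state vector ``y`` and the parameter vector
    ``p`` ordered as ``param_names``.  ``component_map`` lists which resolved
    component index each state constrains (state order).  ``fixed_params``
    are excluded from the embedded nonlinear refit (the dose by default).
    ``state_caps``, when given, maps the parameter vector to per-state upper
    bounds used to clip solver round-off (the capacities for the built-ins).
    """

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    initial_state: tuple[float, ...] = ()
    component_map: tuple[int, ...] = ()
    fixed_params: frozenset[str] = frozenset({"D"})
    state_caps: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        init = self.initial_state or tuple(0.0 for _ in self.state_names)
        object.__setattr__(self, "initial_state", tuple(float(v) for v in init))
        cmap = self.component_map or tuple(range(len(self.state_names)))
        object.__setattr__(self, "component_map", tuple(int(i) for i in cmap))
        if len(self.initial_state) != self.n_states:
            raise ValueError("initial_state length must equal number of states")
        if len(self.component_map) != self.n_states:
            raise ValueError("component_map length must equal number of states")
        if len(set(self.component_map)) != self.n_states:
            raise ValueError("component_map indices must be distinct")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def free_param_names(self) -> tuple[str, ...]:
        return tuple(p for p in self.param_names if p not in self.fixed_params)

    def param_vector(self, params: "KineticParams | Mapping[str, float]") -> np.ndarray:
        d = _as_param_dict(params)
        try:
            return np.array([d[p] for p in self.param_names], dtype=float)
        except KeyError as e:  # pragma: no cover - defensive
            raise InvalidParameterError(f"missing parameter {e.args[0]!r}") from e


@dataclass(frozen=True)
class ConcentrationProfiles:
    """State trajectories on a time grid (hours by rows, states by columns)."""

    times: np.ndarray
    values: np.ndarray
    state_names: tuple[str, ...] = ()

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.shape[0] != times.shape[0]:
            values = values.T
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if np.any(np.isnan(values)):
            raise ValueError("concentration profiles contain NaN")


def _validate_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if t[0] < 0:
        raise ValueError("times must start at t >= 0")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t


def solve_kinetics(
    model: KineticModel,
    params: "KineticParams | Mapping[str, float]",
    times: Sequence[float],
) -> ConcentrationProfiles:
    """Integrate ``model`` at ``params`` and return states at ``times``.

    Adaptive explicit Runge-Kutta (RK45) with rtol=1e-8 / atol=1e-10; the
    built-in systems are non-stiff over the parameter ranges of interest.
    States are clipped to [0, capacity] to remove solver round-off, so the
    saturation invariants (Nb <= Nrecp, Nr <= Nresp) hold exactly.
    """
    t = _validate_times(times)
    p = model.param_vector(params)
    y0 = np.array(model.initial_state, dtype=float)

    # integrate from t=0 (where the initial state is defined) out to times[-1]
    if t[-1] == 0.0:
        values = np.tile(y0, (t.size, 1))
    else:
        sol = solve_ivp(
            model.rhs,
            (0.0, float(t[-1])),
            y0,
            t_eval=t,
            method="RK45",
            rtol=1e-8,
            atol=1e-10,
            args=(p,),
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed for model {model.name!r} with "
                f"parameters {dict(zip(model.param_names, p))}: {sol.message}"
            )
        values = sol.y.T
    values = np.clip(values, 0.0, None)
    if model.state_caps is not None:
        caps = np.asarray(model.state_caps(p), dtype=float)
        values = np.minimum(values, caps[np.newaxis, :])
    return ConcentrationProfiles(t, values, model.state_names)


def closed_form_uptake(
    params: "KineticParams | Mapping[str, float]",
    times: Sequence[float],
) -> ConcentrationProfiles:
    """Analytic solution of the uptake ODE for constant dose and Nb(0)=0.

    ``Nb(t) = Nrecp * (1 - exp(-Kup * D * t))`` — the closed form of the
    saturating first-order uptake; used as the independent oracle for the
    numerical integrator.
    """
    t = _validate_times(times)
    d = _as_param_dict(params)
    nb = d["Nrecp"] * (1.0 - np.exp(-d["Kup"] * d["D"] * t))
    return ConcentrationProfiles(t, nb[:, np.newaxis], ("Nb",))


def closed_form_uptake_response(
    params: "KineticParams | Mapping[str, float]",
    times: Sequence[float],
) -> ConcentrationProfiles:
    """Analytic solution of the two-state system for zero initial state.

    With Nb(t) as above, the response ODE is linear in Nr with integrating
    factor exp(Kresp * Int_0^t Nb), giving

        Nr(t) = Nresp * (1 - exp(-Kresp * Nrecp * (t - (1-exp(-a t))/a)))

    where a = Kup * D (the a -> 0 limit gives Nr = 0).
    """
    t = _validate_times(times)
    d = _as_param_dict(params)
    a = d["Kup"] * d["D"]
    nb = d["Nrecp"] * (1.0 - np.exp(-a * t))
    if a == 0.0:
        integral_nb = np.zeros_like(t)
    else:
        integral_nb = d["Nrecp"] * (t - (1.0 - np.exp(-a * t)) / a)
    nr = d["Nresp"] * (1.0 - np.exp(-d["Kresp"] * integral_nb))
    return ConcentrationProfiles(t, np.column_stack([nb, nr]), ("Nb", "Nr"))


def _uptake_rhs(t, y, p):
    kup, nrecp, dose = p
    return [(nrecp - y[0]) * kup * dose]


def _uptake_response_rhs(t, y, p):
    kup, kresp, nrecp, nresp, dose = p
    return [(nrecp - y[0]) * kup * dose, (nresp - y[1]) * kresp * y[0]]


MODEL_REGISTRY: dict[str, KineticModel] = {}


def register_model(model: KineticModel) -> KineticModel:
    MODEL_REGISTRY[model.name] = model
    return model


def get_model(name: str) -> KineticModel:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(MODEL_REGISTRY))
        raise KeyError(f"unknown kinetic model {name!r}; available: {known}") from None


register_model(
    KineticModel(
        name="uptake",
        state_names=("Nb",),
        param_names=("Kup", "Nrecp", "D"),
        rhs=_uptake_rhs,
        state_caps=lambda p: np.array([p[1]]),
    )
)

register_model(
    KineticModel(
        name="uptake_response",
        state_names=("Nb", "Nr"),
        param_names=("Kup", "Kresp", "Nrecp", "Nresp", "D"),
        rhs=_uptake_response_rhs,
        state_caps=lambda p: np.array([p[2], p[3]]),
    )
)


def model_from_expressions(
    name: str,
    state_names: Sequence[str],
    param_names: Sequence[str],
    rate_expressions: Sequence[str],
    initial_state: Sequence[float] | None = None,
    component_map: Sequence[int] | None = None,
    fixed_params: Sequence[str] = ("D",),
) -> KineticModel:
    """Build a :class:`KineticModel` from declarative rate expressions.

    Each expression gives d(state)/dt in terms of the declared state and
    parameter names (and optionally ``t``).  Expressions are parsed
    symbolically with sympy — only the declared symbols are admitted — and
    compiled to a numpy right-hand side; arbitrary code is rejected.
    """
    import sympy
    from sympy.parsing.sympy_parser import parse_expr

    if len(rate_expressions) != len(state_names):
        raise ValueError("one rate expression required per state")
    syms = {n: sympy.Symbol(n) for n in (*state_names, *param_names, "t")}
    exprs = []
    allowed = set(syms.values())
    for raw in rate_expressions:
        try:
            expr = parse_expr(raw, local_dict=syms, evaluate=True)
        except Exception as e:
            raise ValueError(f"could not parse rate expression {raw!r}: {e}") from e
        extra = expr.free_symbols - allowed
        if extra:
            names = ", ".join(sorted(str(s) for s in extra))
            raise ValueError(f"expression {raw!r} uses undeclared symbols: {names}")
        exprs.append(expr)
    state_vec = sympy.Matrix([syms[n] for n in state_names])
    param_vec = sympy.Matrix([syms[n] for n in param_names])
    func = sympy.lambdify((syms["t"], state_vec, param_vec), exprs, "numpy")

    def rhs(t, y, p):
        return np.asarray(func(t, y, p), dtype=float)

    return KineticModel(
        name=name,
        state_names=tuple(state_names),
        param_names=tuple(param_names),
        rhs=rhs,
        initial_state=tuple(initial_state) if initial_state is not None else (),
        component_map=tuple(component_map) if component_map is not None else (),
        fixed_params=frozenset(fixed_params) & set(param_names),
    )
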
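"""Normalized-Hill logic-ODE engine.

Each species' activity relaxes toward a gated steady target:

    dy_i/dt = (F_i * ymax_i - y_i) / tau_i

where ``F_i`` OR-combines the contributions of all reactions producing
species ``i``.  A reaction contributes ``w * AND(term_1, ..., term_k)``;
each term is the normalized Hill transform of the reactant's activity,
``f(x) = B x^n / (K^n + x^n)`` with ``B = (ec50^n - 1)/(2 ec50^n - 1)`` and
``K^n = B - 1``, so that ``f(0)=0``, ``f(ec50)=1/2``, ``f(1)=1``; a negated
term contributes ``1 - f(x)``.  A source reaction (no reactants)
contributes the constant ``w`` — its weight is the input stimulus level.

The gates are the standard continuous logic operators:
``NOT(a) = 1 - a``, ``AND(a, b) = a*b``, ``OR(a, b) = a + b - a*b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError, ParameterError
from .network_io import NetworkModel

__all__ = [
    "hill",
    "hill_constants",
    "gate_not",
    "gate_and",
    "gate_or",
    "SimulationSettings",
    "StateVector",
    "CompiledModel",
    "compile_model",
    "build_rhs",
    "simulate",
    "steady_state",
]

_GATE_TOL = 1e-9
#: Slack allowed between solver output and the [0, ymax] box before the
#: excursion is treated as an integration failure rather than roundoff.
_BOUND_TOL = 1e-4


def hill_constants(n: float, ec50: float) -> tuple[float, float]:
    """Return ``(B, K^n)`` for the normalized Hill function.

    Raises :class:`ParameterError` when ``ec50`` is outside (0, 1) or the
    normalization degenerates (``2*ec50^n`` too close to 1).
    """
    if not np.all((0 < np.asarray(ec50)) & (np.asarray(ec50) < 1)):
        raise ParameterError(f"ec50={ec50} outside open interval (0, 1)")
    if not np.all(np.asarray(n) > 0):
        raise ParameterError(f"Hill coefficient n={n} must be > 0")
    e = float(ec50) ** float(n)
    denom = 2.0 * e - 1.0
    if abs(denom) < 1e-9:
        raise ParameterError(
            f"degenerate Hill normalization at n={n}, ec50={ec50}: ec50^n == 1/2"
        )
    b = (e - 1.0) / denom
    return b, b - 1.0


def hill(x, n: float, ec50: float):
    """Normalized Hill activation of ``x`` in [0, 1].

    ``f(0)=0``, ``f(ec50)=1/2``, ``f(1)=1``; monotone nondecreasing on
    [0, 1].  Vectorized over ``x``.
    """
    b, kn = hill_constants(n, ec50)
    xn = np.power(np.asarray(x, dtype=float), n)
    out = b * xn / (kn + xn)
    return float(out) if np.isscalar(x) else out


def _check_unit(*vals) -> None:
    for v in vals:
        a = np.asarray(v, dtype=float)
        if np.any(a < -_GATE_TOL) or np.any(a > 1 + _GATE_TOL):
            raise ParameterError(f"gate input {v} outside [0, 1]")


def gate_not(f):
    """NOT gate: ``1 - f``."""
    _check_unit(f)
    return 1.0 - f


def gate_and(f1, f2, *rest):
    """AND gate: product; n-ary by left fold (associative)."""
    _check_unit(f1, f2, *rest)
    out = f1 * f2
    for f in rest:
        out = out * f
    return out


def gate_or(f1, f2, *rest):
    """OR gate: inclusion-exclusion ``a + b - a*b``; n-ary by left fold."""
    _check_unit(f1, f2, *rest)
    out = f1 + f2 - f1 * f2
    for f in rest:
        out = out + f - out * f
    return out


@dataclass(frozen=True)
class SimulationSettings:
    """Integrator controls: horizon (hours), tolerances, optional full
    trajectory recording."""

    t_end: float = 80.0
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = np.inf
    record: bool = False
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ParameterError(f"t_end must be > 0, got {self.t_end}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ParameterError("solver tolerances must be > 0")


@dataclass
class StateVector:
    """Per-species activities aligned with the model's species order."""

    activities: np.ndarray
    species: list[str]
    t: float = 0.0
    trajectory_t: np.ndarray | None = None
    trajectory_y: np.ndarray | None = None  # shape (n_times, n_species)
    converged: bool | None = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.species, map(float, self.activities)))

    def __getitem__(self, species_id: str) -> float:
        return float(self.activities[self.species.index(species_id)])


@dataclass
class CompiledModel:
    """Array form of a :class:`NetworkModel` for fast RHS evaluation."""

    model: NetworkModel
    species: list[str]
    ymax: np.ndarray
    y0: np.ndarray
    tau: np.ndarray
    # per reaction: product index, weight, Hill constants, term arrays
    rx_product: list[int]
    rx_w: np.ndarray
    rx_b: np.ndarray
    rx_kn: np.ndarray
    rx_n: np.ndarray
    rx_terms: list[np.ndarray]      # reactant indices
    rx_negated: list[np.ndarray]    # bool flags aligned with rx_terms

    @property
    def n_species(self) -> int:
        return len(self.species)

    def source_weights(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for j, terms in enumerate(self.rx_terms):
            if terms.size == 0:
                out[self.species[self.rx_product[j]]] = float(self.rx_w[j])
        return out

    def with_input_weights(self, input_weights: Mapping[str, float]) -> "CompiledModel":
        """Copy with the named source-reaction weights overridden."""
        unknown = [k for k in input_weights if k not in self.species]
        if unknown:
            raise IntegrationError(f"unknown input id(s): {', '.join(sorted(unknown))}")
        w = self.rx_w.copy()
        remaining = dict(input_weights)
        for j, terms in enumerate(self.rx_terms):
            if terms.size == 0:
                sid = self.species[self.rx_product[j]]
                if sid in remaining:
                    w[j] = float(input_weights[sid])
                    remaining.pop(sid, None)
        if remaining:
            raise IntegrationError(
                "input id(s) without a source reaction: "
                + ", ".join(sorted(remaining))
            )
        out = CompiledModel(**{**self.__dict__})
        out.rx_w = w
        return out

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        x = np.clip(y, 0.0, 1.0)
        not_acc = np.ones(self.n_species)  # running product of (1 - contribution)
        for j in range(len(self.rx_product)):
            terms = self.rx_terms[j]
            if terms.size == 0:
                c = self.rx_w[j]
            else:
                xn = np.power(x[terms], self.rx_n[j])
                f = self.rx_b[j] * xn / (self.rx_kn[j] + xn)
                f = np.where(self.rx_negated[j], 1.0 - f, f)
                c = self.rx_w[j] * np.prod(f)
            not_acc[self.rx_product[j]] *= 1.0 - c
        f_total = 1.0 - not_acc
        return (f_total * self.ymax - y) / self.tau


def compile_model(model: NetworkModel) -> CompiledModel:
    species = model.species_ids
    index = {sid: i for i, sid in enumerate(species)}
    rx_product, rx_w, rx_b, rx_kn, rx_n = [], [], [], [], []
    rx_terms, rx_negated = [], []
    for r in model.reactions:
        p = r.parsed()
        b, kn = hill_constants(r.n, r.ec50)
        rx_product.append(index[p.product])
        rx_w.append(r.w)
        rx_b.append(b)
        rx_kn.append(kn)
        rx_n.append(r.n)
        rx_terms.append(np.array([index[t] for t, _ in p.terms], dtype=int))
        rx_negated.append(np.array([neg for _, neg in p.terms], dtype=bool))
    return CompiledModel(
        model=model,
        species=species,
        ymax=np.array([s.ymax for s in model.species], dtype=float),
        y0=np.array([s.y0 for s in model.species], dtype=float),
        tau=np.array([s.resolved_tau(model.tau_by_class) for s in model.species],
                     dtype=float),
        rx_product=rx_product,
        rx_w=np.array(rx_w, dtype=float),
        rx_b=np.array(rx_b, dtype=float),
        rx_kn=np.array(rx_kn, dtype=float),
        rx_n=np.array(rx_n, dtype=float),
        rx_terms=rx_terms,
        rx_negated=rx_negated,
    )


def build_rhs(model: NetworkModel) -> Callable[[float, np.ndarray], np.ndarray]:
    """Derivative function ``(t, y) -> dy/dt`` for the compiled model.

    A species with no producing reaction has ``F = 0`` and decays to zero.
    """
    return compile_model(model).rhs


def _as_compiled(model) -> CompiledModel:
    return model if isinstance(model, CompiledModel) else compile_model(model)


def _start_vector(cm: CompiledModel, y_start) -> np.ndarray:
    if y_start is None:
        return cm.y0.copy()
    if isinstance(y_start, StateVector):
        if y_start.species != cm.species:
            raise IntegrationError("y_start species order does not match model")
        return np.asarray(y_start.activities, dtype=float).copy()
    y = np.asarray(y_start, dtype=float)
    if y.shape != (cm.n_species,):
        raise IntegrationError(
            f"y_start has shape {y.shape}, expected ({cm.n_species},)"
        )
    return y.copy()


def simulate(model, input_weights: Mapping[str, float] | None = None,
             settings: SimulationSettings | None = None,
             y_start=None) -> StateVector:
    """Integrate the network ODEs to ``settings.t_end``.

    ``input_weights`` override the weights of the named source reactions for
    this run; ``y_start`` defaults to each species' ``y0``.  Endpoint
    activities are clipped into ``[0, ymax]`` only within solver tolerance;
    a larger excursion raises :class:`IntegrationError`.
    """
    cm = _as_compiled(model)
    if input_weights:
        cm = cm.with_input_weights(input_weights)
    settings = settings or SimulationSettings()
    y_init = _start_vector(cm, y_start)

    sol = solve_ivp(
        cm.rhs, (0.0, settings.t_end), y_init,
        method=settings.method, rtol=settings.rtol, atol=settings.atol,
        max_step=settings.max_step, dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")

    y_end = sol.y[:, -1]
    # knockdowns may legally start above the (clamped) ymax and decay toward it
    upper = np.maximum(cm.ymax, y_init) + _BOUND_TOL
    if np.any(y_end < -_BOUND_TOL) or np.any(y_end > upper):
        worst = cm.species[int(np.argmax(np.maximum(-y_end, y_end - upper)))]
        raise IntegrationError(
            f"endpoint activity out of [0, ymax] beyond tolerance (worst: {worst})"
        )
    y_end = np.clip(y_end, 0.0, np.maximum(cm.ymax, y_init))
    return StateVector(
        activities=y_end,
        species=cm.species,
        t=settings.t_end,
        trajectory_t=sol.t if settings.record else None,
        trajectory_y=sol.y.T if settings.record else None,
    )


def steady_state(model, input_weights: Mapping[str, float] | None = None,
                 settings: SimulationSettings | None = None,
                 y_start=None, deriv_tol: float | None = None) -> StateVector:
    """Integrate until ``max|dy/dt| < deriv_tol`` or ``t_end`` is reached.

    Non-convergence within the horizon is flagged on the returned state
    (``converged=False``), not raised.
    """
    cm = _as_compiled(model)
    if input_weights:
        cm = cm.with_input_weights(input_weights)
    settings = settings or SimulationSettings(t_end=400.0)
    tol = settings.atol if deriv_tol is None else deriv_tol

    chunk = SimulationSettings(
        t_end=settings.t_end / 8.0, rtol=settings.rtol, atol=settings.atol,
        max_step=settings.max_step, method=settings.method,
    )
    state = StateVector(activities=_start_vector(cm, y_start), species=cm.species)
    elapsed = 0.0
    converged = bool(np.max(np.abs(cm.rhs(0.0, state.activities))) < tol)
    while not converged and elapsed < settings.t_end - 1e-12:
        state = simulate(cm, None, chunk, y_start=state)
        elapsed += chunk.t_end
        converged = bool(np.max(np.abs(cm.rhs(elapsed, state.activities))) < tol)
    state.t = elapsed
    state.converged = converged
    return state
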
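"""Kinetic model core: datasets, edges, Hill regulatory functions.

The model class is single-regulator Hill kinetics: each gene ``X`` evolves as

    dX/dt = alpha * f(Y) - beta * X + gamma

where ``Y`` is the regulator, ``f`` is the activating Hill function
``Y^n / (K^n + Y^n)`` or the repressing form ``K^n / (K^n + Y^n)``,
``alpha > 0`` is the regulation strength, ``beta >= 0`` the first-order
degradation rate, and ``gamma >= 0`` the basal production rate.

These primitives are shared by the benchmark simulator and the inference
engine; everything here is pure computation with no I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Sign",
    "Gate",
    "ExpressionDataset",
    "EdgeModel",
    "ParamVector",
    "NodeRule",
    "NetworkSpec",
    "ParameterDomainError",
    "hill",
    "edge_rhs",
    "count_topologies",
]


class ParameterDomainError(ValueError):
    """A kinetic parameter lies outside its admissible domain."""


class Sign(str, Enum):
    """Regulation sign: activation or repression."""

    ACTIVATION = "a"
    REPRESSION = "r"

    @classmethod
    def parse(cls, value: "Sign | str") -> "Sign":
        if isinstance(value, Sign):
            return value
        v = str(value).strip().lower()
        if v in ("a", "act", "activation", "activator", "+"):
            return cls.ACTIVATION
        if v in ("r", "rep", "repression", "repressor", "-"):
            return cls.REPRESSION
        raise ValueError(f"unknown regulation sign: {value!r}")


class Gate(str, Enum):
    """Combinatorial logic joining several Hill inputs (simulator only)."""

    AND = "AND"
    OR = "OR"


@dataclass(frozen=True)
class EdgeModel:
    """A signed, directed candidate regulation: ``target`` regulated by
    ``regulator`` with the given sign. Self-edges are permitted."""

    target: str
    regulator: str
    sign: Sign

    def __post_init__(self) -> None:
        object.__setattr__(self, "sign", Sign.parse(self.sign))

    def __str__(self) -> str:
        return f"({self.target}, {self.regulator}, {self.sign.value})"


@dataclass(frozen=True)
class ParamVector:
    """Kinetic parameters theta = (alpha, beta, gamma, n, K) of one edge.

    alpha : regulation strength, expression units / time, > 0 for a genuine
            regulation (alpha = 0 is accepted as the degenerate
            no-regulation limit, useful for linear test nodes)
    beta  : degradation rate, 1/time, >= 0
    gamma : basal production, expression units / time, >= 0
    n     : Hill coefficient, dimensionless, >= 1
    K     : half-saturation constant, expression units, > 0
    """

    alpha: float
    beta: float
    gamma: float
    n: float
    K: float

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta, self.gamma, self.n, self.K)
        if not all(np.isfinite(vals)):
            raise ParameterDomainError(f"non-finite parameter in {vals}")
        if self.alpha < 0:
            raise ParameterDomainError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < 0:
            raise ParameterDomainError(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            raise ParameterDomainError(f"gamma must be >= 0, got {self.gamma}")
        if self.n < 1:
            raise ParameterDomainError(f"n must be >= 1, got {self.n}")
        if self.K <= 0:
            raise ParameterDomainError(f"K must be > 0, got {self.K}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.n, self.K])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ParamVector":
        a, b, g, n, k = (float(v) for v in arr)
        return cls(alpha=a, beta=b, gamma=g, n=n, K=k)


PARAM_NAMES = ("alpha", "beta", "gamma", "n", "K")


@dataclass
class ExpressionDataset:
    """Observed trajectories of N genes on a common, strictly increasing
    time grid: ``values[i, j]`` is gene i's level at ``times[j]``.

    Expression values are non-negative in the model; inputs with small
    negative values (e.g., after noise) are clipped to 0 with a warning by
    the inference entry points, not here.
    """

    gene_names: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_names = list(self.gene_names)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 3:
            raise ValueError("need a 1-D time vector with at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x timepoints matrix")
        n, t = self.values.shape
        if n < 1:
            raise ValueError("need at least one gene")
        if len(self.gene_names) != n:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {n} value rows"
            )
        if t != self.times.size:
            raise ValueError(
                f"{t} value columns for {self.times.size} timepoints"
            )
        if len(set(self.gene_names)) != n:
            raise ValueError("gene names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def gene(self, name: str) -> np.ndarray:
        """Trajectory of one gene by name."""
        try:
            idx = self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"gene {name!r} not in dataset") from None
        return self.values[idx]

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            list(self.gene_names), self.times.copy(), self.values.copy()
        )


@dataclass
class NodeRule:
    """Generative regulation of one node in a benchmark network.

    ``inputs`` is a list of (regulator, sign); ``gate`` joins multiple
    inputs (AND/OR) and must be None for 0 or 1 input. Hill parameters are
    per input; alpha/beta/gamma are shared by the node. Zero-input nodes
    evolve as gamma - beta*X.
    """

    inputs: list[tuple[str, Sign]] = field(default_factory=list)
    gate: Gate | None = None
    hill_params: list[tuple[float, float]] = field(default_factory=list)  # (n, K) per input
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        self.inputs = [(r, Sign.parse(s)) for r, s in self.inputs]
        if self.gate is not None:
            self.gate = Gate(self.gate)
        if len(self.inputs) != len(self.hill_params):
            raise ValueError("one (n, K) pair required per input")
        if len(self.inputs) >= 2 and self.gate is None:
            raise ValueError("multi-input nodes require a gate")
        if len(self.inputs) < 2 and self.gate is not None:
            raise ValueError("gates require at least 2 inputs")


@dataclass
class NetworkSpec:
    """A generative network: node list plus one NodeRule per node.

    Serves both as the simulator's input and (via its input lists) as the
    gold-standard edge set for evaluation.
    """

    nodes: list[str]
    rules: dict[str, NodeRule]
    initial_state: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("node names must be unique")
        for node in self.nodes:
            if node not in self.rules:
                raise ValueError(f"no rule for node {node!r}")
        for node, rule in self.rules.items():
            if node not in node_set:
                raise ValueError(f"rule for unknown node {node!r}")
            for reg, _ in rule.inputs:
                if reg not in node_set:
                    raise ValueError(
                        f"rule for {node!r} names unknown regulator {reg!r}"
                    )

    def edges(self) -> list[EdgeModel]:
        """All generative regulations as signed directed edges."""
        out = []
        for node in self.nodes:
            for reg, sign in self.rules[node].inputs:
                out.append(EdgeModel(target=node, regulator=reg, sign=sign))
        return out


def hill(
    x: "float | np.ndarray", K: float, n: float, sign: Sign | str
) -> "float | np.ndarray":
    """Hill regulatory function, in [0, 1].

    Activation returns ``x^n / (K^n + x^n)``; repression returns the
    complement ``K^n / (K^n + x^n)``. ``x`` may be a scalar or array of
    non-negative regulator levels.

    Computed via ``(x/K)^n`` so that simultaneous rescaling of x and K
    leaves the value exactly invariant and large levels do not overflow.
    """
    sign = Sign.parse(sign)
    if not np.isfinite(K) or K <= 0:
        raise ParameterDomainError(f"K must be positive and finite, got {K}")
    if not np.isfinite(n) or n < 1:
        raise ParameterDomainError(f"n must be >= 1 and finite, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterDomainError("regulator level must be >= 0")
    r = np.power(x / K, n)
    with np.errstate(invalid="ignore"):
        act = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    out = act if sign is Sign.ACTIVATION else 1.0 - act
    return float(out) if out.ndim == 0 else out


def edge_rhs(
    x_target: "float | np.ndarray",
    x_regulator: "float | np.ndarray",
    theta: ParamVector,
    sign: Sign | str,
) -> "float | np.ndarray":
    """Right-hand side of the single-edge ODE:
    ``alpha * hill(x_regulator) - beta * x_target + gamma``."""
    h = hill(x_regulator, theta.K, theta.n, sign)
    out = theta.alpha * h - theta.beta * np.asarray(x_target, float) + theta.gamma
    return float(out) if np.ndim(out) == 0 else out


def count_topologies(n_nodes: int) -> int:
    """Number of signed directed topologies on ``n_nodes`` genes.

    Each ordered pair (including self-pairs) is independently absent,
    activating, or repressing: 3**(N^2). For N=3 this is 19,683.
    """
    if not isinstance(n_nodes, (int, np.integer)) or n_nodes < 1:
        raise ValueError(f"node count must be a positive integer, got {n_nodes}")
    return 3 ** (int(n_nodes) ** 2)
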
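"""Parameter vectors, the network Hamiltonian, and size offsets.

The probability of observing a graph g under a network Hamiltonian model is

    P(g) = h(g) exp(-H(g) / kB T) / Z,      H(g) = sum_X phi_X t_X(g),

with t_X(g) the sufficient statistics and h(g) a reference measure, here
fixed to the uniform counting measure.  phi is the physically motivated
form (negative coefficients are exothermic, i.e. favor motif formation);
simulation uses the statistically motivated theta form,
theta = -phi / (kB T), under which P(g) is proportional to exp(theta^T t(g)).

Transferring a model between system sizes uses a Krivitsky-style offset on
the edge coefficient: the baseline log-odds of a bond is attenuated by
log(N) so that mean degree, rather than density, is preserved as the number
of molecules N grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .netstats import Graph, StatSpec, compute_stats

__all__ = [
    "PhiVector",
    "ThetaVector",
    "ModelSpec",
    "energy",
    "phi_to_theta",
    "rescale_edge_phi",
]


class _ParamVector:
    """Real coefficients aligned with a StatSpec, one per statistic."""

    __slots__ = ("spec", "values")

    def __init__(self, spec: StatSpec, coefficients: Mapping[str, float] | Sequence[float]) -> None:
        self.spec = spec
        if isinstance(coefficients, Mapping):
            missing = [n for n in spec.names if n not in coefficients]
            if missing:
                raise ValueError(f"missing coefficients for {missing}")
            extra = [n for n in coefficients if n not in spec.names]
            if extra:
                raise ValueError(f"coefficients {extra} not in the statistic set")
            vals = [float(coefficients[n]) for n in spec.names]
        else:
            vals = [float(x) for x in coefficients]
            if len(vals) != len(spec):
                raise ValueError(
                    f"got {len(vals)} coefficients for {len(spec)} statistics"
                )
        if not all(math.isfinite(x) for x in vals):
            raise ValueError("coefficients must be finite")
        self.values = np.asarray(vals, dtype=np.float64)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.spec.index(name)])

    def as_array(self) -> np.ndarray:
        return self.values.copy()

    def as_dict(self) -> dict[str, float]:
        return {n: float(x) for n, x in zip(self.spec.names, self.values)}

    def __len__(self) -> int:
        return len(self.spec)

    def __repr__(self) -> str:
        body = ", ".join(f"{n}={x:g}" for n, x in self.as_dict().items())
        return f"{type(self).__name__}({body})"


class PhiVector(_ParamVector):
    """Physical-form coefficients, in units of kB*T."""


class ThetaVector(_ParamVector):
    """Simulation-form (dimensionless) coefficients, theta = -phi/(kB T)."""


@dataclass(frozen=True)
class ModelSpec:
    """A network Hamiltonian model: statistic set, phi coefficients, kB*T.

    The reference measure h(g) is the uniform counting measure.
    """

    spec: StatSpec
    phi: PhiVector
    kBT: float = 1.0
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        if self.phi.spec is not self.spec and self.phi.spec != self.spec:
            raise ValueError("phi is not aligned with the model's StatSpec")


def energy(g: Graph, model: ModelSpec) -> float:
    """Network Hamiltonian H(g) = sum_X phi_X t_X(g), in units of kB*T."""
    t = np.asarray(compute_stats(g, model.spec), dtype=np.float64)
    return float(model.phi.values @ t)


def phi_to_theta(
    model: ModelSpec,
    n_nodes: int,
    *,
    edge_offset: bool = True,
    offset_constant: float = 1.0,
) -> ThetaVector:
    """Convert phi to the theta form used for sampling, at system size N.

    theta_X = -phi_X for every statistic except edges; the edge coefficient
    absorbs a size offset, theta_e = -(phi_e + c - ln N) with c the
    ``offset_constant`` (default 1, as used with these models).  Pass
    ``edge_offset=False`` for the plain theta = -phi conversion.  The
    conversion assumes kB*T = 1.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    theta = {n: -p for n, p in model.phi.as_dict().items()}
    if edge_offset and "edges" in model.spec.names:
        phi_e = model.phi["edges"]
        theta["edges"] = -(phi_e + offset_constant - math.log(n_nodes))
    return ThetaVector(model.spec, theta)


def rescale_edge_phi(phi_e: float, n_from: int, n_to: int) -> float:
    """Krivitsky offset: move an edge coefficient fit at ``n_from`` nodes to
    a system of ``n_to`` nodes, phi_e + ln(n_from) - ln(n_to)."""
    if n_from < 2 or n_to < 2:
        raise ValueError("system sizes must be at least 2")
    return phi_e + math.log(n_from) - math.log(n_to)
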
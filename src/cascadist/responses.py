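"""Per-node cascade response functions.

A node of degree *d* carries a response function R(a), a = 0..d+1:
R(a) is the probability it activates exactly when *a* neighbors are
active (a-1 would not have sufficed); R(0) is the spontaneous seeding
probability and R(d+1) the probability of never activating. The
cumulative Rc(a) = sum_{l<=a} R(l) is the probability of being active
whenever *a* neighbors are active. Only monotone cumulative responses
are supported (each additional active neighbor can only help).

Two concrete models are provided:

* threshold model (TM): fractional threshold theta_i ~ F_i; the node
  activates once the active-neighbor fraction reaches theta_i, so
  R(a) = F(a/d) - F((a-1)/d) with R(0) = F(0), R(d+1) = 1 - F(1).
* independent cascade model (ICM): SIR-like transmission with a single
  probability p for seeding and per-edge transmission:
  R(a) = p(1-p)^a, R(d+1) = (1-p)^{d+1}, Rc(a) = 1-(1-p)^{a+1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.stats import norm

from ._pbinom import poisson_binomial_pmf

__all__ = [
    "ResponseFunction",
    "ModelConfig",
    "build_response",
    "ghost_update",
    "load_model_config",
]

_ATOL = 1e-12


@dataclass(frozen=True)
class ResponseFunction:
    """Validated response vectors for one node of a given degree."""

    degree: int
    R: np.ndarray  # length degree + 2, a = 0..d+1
    Rc: np.ndarray  # length degree + 1, a = 0..d

    def __post_init__(self):
        R, Rc, d = np.asarray(self.R, float), np.asarray(self.Rc, float), self.degree
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "Rc", Rc)
        if R.shape != (d + 2,) or Rc.shape != (d + 1,):
            raise ValueError(
                f"degree {d} requires R of length {d + 2} and Rc of length {d + 1}"
            )
        if np.any((R < -_ATOL) | (R > 1 + _ATOL)) or np.any(
            (Rc < -_ATOL) | (Rc > 1 + _ATOL)
        ):
            raise ValueError("response entries must lie in [0, 1]")
        total = R.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"response does not normalize: sum R = {total!r}")
        if np.max(np.abs(np.cumsum(R[:-1]) - Rc)) > 1e-9:
            raise ValueError("Rc is not the cumulative sum of R")
        if np.any(np.diff(Rc) < -_ATOL):
            raise ValueError("Rc must be nondecreasing")

    @classmethod
    def from_R(cls, degree: int, R) -> "ResponseFunction":
        R = np.asarray(R, float)
        return cls(degree=degree, R=R, Rc=np.cumsum(R[:-1]))


@dataclass
class ModelConfig:
    """Cascade-model configuration, optionally with per-node overrides.

    ``model`` is one of ``threshold_normal`` (parameters ``mu``, ``sigma``),
    ``threshold_custom_cdf`` (``cdf``: tabulated [(x, F(x)), ...] evaluated
    as a right-continuous step function), or ``icm`` (``p``).
    """

    model: str
    parameters: dict = field(default_factory=dict)
    per_node: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in ("threshold_normal", "threshold_custom_cdf", "icm"):
            raise ValueError(f"unknown model {self.model!r}")
        self._check(self.parameters)
        for params in self.per_node.values():
            self._check({**self.parameters, **params})

    def _check(self, params: Mapping) -> None:
        if self.model == "icm":
            p = float(params["p"])
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p must be in [0, 1], got {p}")
        elif self.model == "threshold_normal":
            if float(params["sigma"]) <= 0:
                raise ValueError("sigma must be positive")
        else:
            tab = np.asarray(params["cdf"], float)
            if tab.ndim != 2 or tab.shape[1] != 2:
                raise ValueError("cdf must be a table of (x, F(x)) pairs")
            if np.any(np.diff(tab[:, 1]) < 0) or np.any(
                (tab[:, 1] < 0) | (tab[:, 1] > 1)
            ):
                raise ValueError("cdf values must be nondecreasing in [0, 1]")

    def params_for(self, node: str | None) -> dict:
        merged = dict(self.parameters)
        if node is not None and str(node) in self.per_node:
            merged.update(self.per_node[str(node)])
        return merged

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        raw = json.loads(text)
        model = raw.pop("model")
        per_node = raw.pop("per_node", {})
        return cls(model=model, parameters=raw, per_node=per_node)

    def to_json(self) -> str:
        raw = {"model": self.model, **self.parameters}
        if self.per_node:
            raw["per_node"] = self.per_node
        return json.dumps(raw)


def load_model_config(source) -> ModelConfig:
    """Load a ModelConfig from a JSON file path, file object or string."""
    if hasattr(source, "read"):
        return ModelConfig.from_json(source.read())
    s = str(source)
    if s.lstrip().startswith("{"):
        return ModelConfig.from_json(s)
    with open(s) as fh:
        return ModelConfig.from_json(fh.read())


def _step_cdf(table: np.ndarray) -> Callable[[float], float]:
    xs, ys = table[:, 0], table[:, 1]

    def F(x: float) -> float:
        k = np.searchsorted(xs, x, side="right") - 1
        if k < 0:
            return 0.0
        return float(ys[k])

    return F


def build_response(config: ModelConfig, node: str | None, degree: int) -> ResponseFunction:
    """Response function for ``node`` at the given degree under ``config``."""
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    params = config.params_for(node)
    if config.model == "icm":
        p = float(params["p"])
        a = np.arange(degree + 1)
        R = np.empty(degree + 2)
        R[:-1] = p * (1.0 - p) ** a
        R[-1] = (1.0 - p) ** (degree + 1)
        return ResponseFunction(degree=degree, R=R, Rc=1.0 - (1.0 - p) ** (a + 1))
    if config.model == "threshold_normal":
        mu, sigma = float(params["mu"]), float(params["sigma"])
        F = lambda x: norm.cdf((x - mu) / sigma)  # noqa: E731
    else:
        F = _step_cdf(np.asarray(params["cdf"], float))
    if degree == 0:
        f0 = float(F(0.0))
        return ResponseFunction.from_R(0, [f0, 1.0 - f0])
    grid = np.array([float(F(a / degree)) for a in range(degree + 1)])
    R = np.empty(degree + 2)
    R[0] = grid[0]
    R[1 : degree + 1] = np.diff(grid)
    R[degree + 1] = 1.0 - grid[degree]
    return ResponseFunction(degree=degree, R=R, Rc=grid)


def ghost_update(r: ResponseFunction, ghost_probs) -> ResponseFunction:
    """Average a response over independently pre-activated ghost neighbors.

    Used by the tree distribution approximation: a node that lost m
    neighbors to loop-cutting keeps their influence as "ghosts" that are
    initially active with the given probabilities. With S the
    Poisson-binomial count of active ghosts, the reduced-degree response
    is Rt_c(a) = E[Rc(a + S)] and Rt(a) = E[R(a + S)] for a >= 1; the
    seeding mass Rt(0) = E[Rc(S)] absorbs ghost-triggered activation so
    the result normalizes and keeps integer-threshold semantics.
    """
    ghost_probs = np.asarray(ghost_probs, float)
    m = ghost_probs.size
    d_new = r.degree - m
    if d_new < 0:
        raise ValueError(
            f"cannot remove {m} ghosts from a degree-{r.degree} response"
        )
    if m == 0:
        return r
    w = poisson_binomial_pmf(ghost_probs)  # over S = 0..m
    Rc_new = np.array(
        [float(w @ r.Rc[a : a + m + 1]) for a in range(d_new + 1)]
    )
    R_new = np.empty(d_new + 2)
    R_new[0] = Rc_new[0]
    R_new[1 : d_new + 1] = np.diff(Rc_new)
    R_new[d_new + 1] = 1.0 - Rc_new[d_new]
    return ResponseFunction(degree=d_new, R=R_new, Rc=Rc_new)


def build_all_responses(
    config: ModelConfig, net, degrees: Mapping[str, int] | None = None
) -> dict[str, ResponseFunction]:
    """Responses for every node of a Network (or given degree map)."""
    if degrees is None:
        degrees = {n: net.degree(n) for n in net.nodes}
    return {n: build_response(config, n, d) for n, d in degrees.items()}
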
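"""Chaotic maps used to modulate the optimizer's exploration rate.

Five classic one-dimensional maps on the unit interval are provided:
logistic, sinusoidal, tent, singer and piecewise.  Each is a deterministic
recurrence x_{k+1} = G(x_k) whose orbit is bounded in [0, 1] but sensitive
to the initial condition, which is what makes it usable as a pseudo-random
— yet fully reproducible — schedule signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

MAP_NAMES = ("logistic", "sinusoidal", "tent", "singer", "piecewise")

# Operating values; the literature states admissible ranges, these are the
# concrete defaults this package runs with (configurable per map).
DEFAULT_PARAMS = {
    "logistic": {"a": 4.0},
    "sinusoidal": {"a": 2.3},
    "singer": {"mu": 1.07},
    "piecewise": {"p": 0.4},
    "tent": {},
}

# Initial conditions whose orbit provably collapses to a fixed point or a
# short absorbing cycle; rejected at construction.
_DEGENERATE_X0 = {
    "logistic": (0.25, 0.5, 0.75),  # 0.5 -> 1 -> 0; 0.75 fixed; 0.25 -> 0.75
    "tent": (0.7,),                 # fixed point of the second branch
}

_DEFAULT_X0 = {"tent": 0.6}


@dataclass(frozen=True)
class ChaoticMap:
    """A named chaotic map with its parameters and initial state.

    Parameters
    ----------
    name:
        One of ``logistic``, ``sinusoidal``, ``tent``, ``singer``,
        ``piecewise``.
    params:
        Map-specific constants: logistic/sinusoidal ``a``, singer ``mu``,
        piecewise ``p``.  Unset keys fall back to the package defaults.
    x0:
        Initial state, strictly inside (0, 1) and outside the map's known
        degenerate orbits.
    """

    name: str
    params: dict = field(default_factory=dict)
    x0: float | None = None

    def __post_init__(self):
        if self.name not in MAP_NAMES:
            raise ValueError(
                f"unknown chaotic map {self.name!r}; expected one of {MAP_NAMES}"
            )
        merged = {**DEFAULT_PARAMS[self.name], **self.params}
        object.__setattr__(self, "params", merged)
        x0 = self.x0 if self.x0 is not None else _DEFAULT_X0.get(self.name, 0.7)
        object.__setattr__(self, "x0", float(x0))
        self._validate()

    def _validate(self):
        if not 0.0 < self.x0 < 1.0:
            raise ValueError(f"x0 must lie strictly in (0, 1), got {self.x0}")
        for bad in _DEGENERATE_X0.get(self.name, ()):
            if math.isclose(self.x0, bad, abs_tol=1e-12):
                raise ValueError(
                    f"x0={self.x0} yields a degenerate (collapsing) orbit "
                    f"for the {self.name} map"
                )
        p = self.params
        if self.name == "logistic" and not 0.0 < p["a"] <= 4.0:
            raise ValueError(f"logistic parameter a must be in (0, 4], got {p['a']}")
        if self.name == "singer" and not 0.9 <= p["mu"] <= 1.08:
            raise ValueError(f"singer parameter mu must be in [0.9, 1.08], got {p['mu']}")
        if self.name == "piecewise":
            if not 0.0 < p["p"] < 1.0 or math.isclose(p["p"], 0.5):
                raise ValueError(
                    f"piecewise parameter p must be in (0, 1) and != 0.5, got {p['p']}"
                )


def map_step(spec: ChaoticMap, x: float) -> float:
    """Apply one iteration of the map: return ``x_{k+1} = G(x_k)``.

    Raises ``ValueError`` if ``x`` falls outside [0, 1].
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"chaotic state must lie in [0, 1], got {x}")
    p = spec.params
    if spec.name == "logistic":
        return p["a"] * x * (1.0 - x)
    if spec.name == "sinusoidal":
        return p["a"] * x * x * math.sin(math.pi * x)
    if spec.name == "tent":
        # boundary x = 0.7 belongs to the second branch (condition is x < 0.7)
        if x < 0.7:
            return x / 0.7
        return (10.0 / 3.0) * x * (1.0 - x)
    if spec.name == "singer":
        mu = p["mu"]
        return mu * (7.86 * x - 23.31 * x**2 + 28.75 * x**3 - 13.3 * x**4)
    # piecewise
    pp = p["p"]
    if x < pp:
        return x / pp
    if x < 0.5:
        return (x - pp) / (0.5 - pp)
    if x < 1.0 - pp:
        return (1.0 - pp - x) / (0.5 - pp)
    return (1.0 - x) / pp


def iterate_map(spec: ChaoticMap, n: int) -> list[float]:
    """Return the first ``n`` iterates ``[G(x0), G(G(x0)), ...]``.

    The sequence is fully determined by ``spec``; no randomness enters.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out = []
    x = spec.x0
    for _ in range(n):
        x = map_step(spec, x)
        out.append(x)
    return out


class ChaosState:
    """Mutable iterator over a map's orbit, one value per call."""

    def __init__(self, spec: ChaoticMap):
        self.spec = spec
        self.x = spec.x0

    def step(self) -> float:
        self.x = map_step(self.spec, self.x)
        return self.x
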
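"""Analytic benchmark objectives (all minimized, global optimum 0)."""

from __future__ import annotations

import numpy as np


def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.square(x)))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def ackley(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


REGISTRY = {
    "sphere": (sphere, (-5.0, 5.0)),
    "rastrigin": (rastrigin, (-5.12, 5.12)),
    "rosenbrock": (rosenbrock, (-5.0, 10.0)),
    "ackley": (ackley, (-32.0, 32.0)),
}


def get(name: str):
    """Return (callable, default bounds) for a named objective."""
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown objective {name!r}; choose from {sorted(REGISTRY)}"
        ) from None
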
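"""Minimal composable linear-map framework with exact adjoints.

Every discrete operator in the forward model is expressed as a
:class:`LinearMap` acting on flattened vectors, so that arbitrary
compositions automatically provide an adjoint and can be verified with
randomized dot tests.  Maps are linear over the complex field (real
kernels applied to complex vectors act componentwise), which lets the
reconstruction iterate complex images against complex harmonic data.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LinearMap",
    "Compose",
    "DenseMap",
    "DiagonalMap",
    "SparseMap",
    "IdentityMap",
    "VStack",
    "dot_test",
]


class LinearMap:
    """A linear operator C^dom_size -> C^ran_size with an exact adjoint."""

    dom_size: int
    ran_size: int

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def adjoint(self, y: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __matmul__(self, other: "LinearMap") -> "Compose":
        return Compose([self, other])

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def normal(self, x: np.ndarray) -> np.ndarray:
        """Apply the normal-equations map A^H A."""
        return self.adjoint(self.forward(x))


class Compose(LinearMap):
    """Composition ``maps[0] @ maps[1] @ ... @ maps[-1]`` (rightmost first)."""

    def __init__(self, maps: list[LinearMap]):
        if not maps:
            raise ValueError("empty composition")
        for left, right in zip(maps[:-1], maps[1:]):
            if left.dom_size != right.ran_size:
                raise ValueError(
                    f"incompatible composition: {type(right).__name__} produces "
                    f"{right.ran_size}, {type(left).__name__} expects {left.dom_size}"
                )
        flat: list[LinearMap] = []
        for m in maps:
            flat.extend(m.maps if isinstance(m, Compose) else [m])
        self.maps = flat
        self.dom_size = flat[-1].dom_size
        self.ran_size = flat[0].ran_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in reversed(self.maps):
            x = m.forward(x)
        return x

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        for m in self.maps:
            y = m.adjoint(y)
        return y


class DenseMap(LinearMap):
    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix)
        self.ran_size, self.dom_size = self.matrix.shape

    def forward(self, x):
        return self.matrix @ x

    def adjoint(self, y):
        return self.matrix.conj().T @ y


class DiagonalMap(LinearMap):
    def __init__(self, diag: np.ndarray):
        self.diag = np.asarray(diag)
        self.dom_size = self.ran_size = self.diag.size

    def forward(self, x):
        return self.diag * x

    def adjoint(self, y):
        return self.diag.conj() * y


class SparseMap(LinearMap):
    """Wrapper around a scipy sparse matrix; adjoint is the conjugate transpose."""

    def __init__(self, matrix):
        self.matrix = matrix.tocsr()
        self._adj = self.matrix.conj().T.tocsr()
        self.ran_size, self.dom_size = self.matrix.shape

    def forward(self, x):
        return self.matrix @ x

    def adjoint(self, y):
        return self._adj @ y


class IdentityMap(LinearMap):
    def __init__(self, n: int):
        self.dom_size = self.ran_size = n

    def forward(self, x):
        return np.asarray(x)

    def adjoint(self, y):
        return np.asarray(y)


class VStack(LinearMap):
    """Vertical stack of maps sharing a common domain."""

    def __init__(self, maps: list[LinearMap]):
        if not maps:
            raise ValueError("empty stack")
        dom = maps[0].dom_size
        if any(m.dom_size != dom for m in maps):
            raise ValueError("stacked maps must share a domain")
        self.maps = maps
        self.dom_size = dom
        self.ran_size = sum(m.ran_size for m in maps)
        self._offsets = np.cumsum([0] + [m.ran_size for m in maps])

    def forward(self, x):
        return np.concatenate([m.forward(x) for m in self.maps])

    def adjoint(self, y):
        out = None
        for m, lo, hi in zip(self.maps, self._offsets[:-1], self._offsets[1:]):
            part = m.adjoint(y[lo:hi])
            out = part if out is None else out + part
        return out


def dot_test(op: LinearMap, rng: np.random.Generator, n_draws: int = 20,
             complex_domain: bool = True) -> float:
    """Largest normalized adjoint discrepancy over random vector pairs.

    Returns ``max |<Ax, y> - <x, A^H y>| / (||Ax|| ||y||)``, which is at
    machine precision for an exactly implemented adjoint pair.
    """

    def draw(size: int) -> np.ndarray:
        v = rng.standard_normal(size)
        if complex_domain:
            v = v + 1j * rng.standard_normal(size)
        return v

    worst = 0.0
    for _ in range(n_draws):
        x = draw(op.dom_size)
        y = draw(op.ran_size)
        ax = op.forward(x)
        aty = op.adjoint(y)
        lhs = np.vdot(y, ax)
        rhs = np.vdot(aty, x)
        denom = np.linalg.norm(ax) * np.linalg.norm(y)
        if denom == 0:
            continue
        worst = max(worst, abs(lhs - rhs) / denom)
    return worst
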
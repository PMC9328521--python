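"""Domain-mixing transforms for the ⋆_M tensor algebra.

The M-product family of tensor-tensor products is parameterized by an
invertible n×n matrix ``M`` that mixes the time (third) axis of an
order-3 tensor.  Applying ``M`` to every tube fiber carries the tensor
into the "hat" domain, where the algebra becomes face-wise matrix
algebra.  Only real orthogonal transforms are supported: they make the
mode-3 product an exact isometry, so Frobenius errors measured in either
domain coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.fft import dct

__all__ = [
    "MTransform",
    "make_m_transform",
    "mode3_product",
    "mode3_inverse",
]

_KINDS = ("dct2", "haar_random", "custom")


@dataclass(frozen=True)
class MTransform:
    """An invertible mixing matrix defining a ⋆_M algebra.

    Parameters
    ----------
    matrix
        The n×n mixing matrix. For kinds ``dct2`` and ``haar_random``
        this is orthonormal, so the inverse is the transpose.
    kind
        One of ``dct2``, ``haar_random`` or ``custom``.
    seed
        The seed used to draw a Haar-random matrix; ``None`` otherwise.
    """

    matrix: np.ndarray
    kind: str = "custom"
    seed: int | None = None
    _inverse: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError(f"M must be square, got shape {mat.shape}")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown M kind {self.kind!r}; expected one of {_KINDS}")
        object.__setattr__(self, "matrix", mat)
        if self.kind in ("dct2", "haar_random"):
            inv = mat.T
        else:
            inv = np.linalg.inv(mat)
        object.__setattr__(self, "_inverse", inv)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def inverse(self) -> np.ndarray:
        return self._inverse

    # -- plain-text serialization ------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the matrix as whitespace-delimited text plus a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.matrix)
        sidecar = {"kind": self.kind, "n": self.n, "seed": self.seed}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "MTransform":
        path = Path(path)
        matrix = np.loadtxt(path, ndmin=2)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(matrix=matrix, kind=meta["kind"], seed=meta["seed"])


def make_m_transform(
    n: int, kind: str = "dct2", seed: int | None = None
) -> MTransform:
    """Construct the mixing matrix M for the ⋆_M product.

    ``dct2`` gives the orthonormal DCT-II (the default transform for
    TCAM); ``haar_random`` draws an orthogonal matrix uniformly from
    O(n) via the QR decomposition of a Gaussian matrix, reproducibly
    from ``seed``.
    """
    if n < 1:
        raise ValueError(f"M size must be >= 1, got {n}")
    if kind == "dct2":
        matrix = dct(np.eye(n), type=2, norm="ortho", axis=0)
        return MTransform(matrix=matrix, kind="dct2")
    if kind == "haar_random":
        if seed is None:
            raise ValueError("haar_random requires a seed for reproducibility")
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, n))
        q, r = np.linalg.qr(z)
        # fix the QR gauge so the distribution is Haar, not QR-biased
        q = q * np.sign(np.diag(r))
        return MTransform(matrix=q, kind="haar_random", seed=seed)
    raise ValueError(f"unknown M kind {kind!r}; expected one of {_KINDS}")


def _check_tube_match(a: np.ndarray, m: MTransform) -> None:
    if a.ndim != 3:
        raise ValueError(f"expected an order-3 tensor, got ndim={a.ndim}")
    if a.shape[2] != m.n:
        raise ValueError(
            f"third dimension {a.shape[2]} does not match M side length {m.n}"
        )


def mode3_product(a: np.ndarray, m: MTransform) -> np.ndarray:
    """Apply M to every tube fiber: Â_{i,j,:} = M A_{i,j,:}.

    Carries ``a`` into the hat domain. With orthonormal M this is an
    isometry in the Frobenius norm.
    """
    a = np.asarray(a, dtype=float)
    _check_tube_match(a, m)
    return a @ m.matrix.T


def mode3_inverse(a_hat: np.ndarray, m: MTransform) -> np.ndarray:
    """Undo :func:`mode3_product`: Â ×₃ M⁻¹ = A."""
    a_hat = np.asarray(a_hat, dtype=float)
    _check_tube_match(a_hat, m)
    return a_hat @ m.inverse.T
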
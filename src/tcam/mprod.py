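"""The ⋆_M tensor-tensor algebra and the tubal SVD (tsvdm).

Order-3 tensors are plain ``numpy`` arrays of shape ``(m, p, n)`` with
the convention axis 0 = subjects, axis 1 = features, axis 2 = timepoints.
The ⋆_M product of two tensors is the face-wise (frontal-slice-wise)
matrix product taken in the hat domain — after mixing the time axis with
an invertible matrix M — and mapped back with M⁻¹.  Under this product
every real tensor admits a tubal SVD, A = U ⋆_M S ⋆_M Vᵀ, with
⋆_M-orthogonal U, V and f-diagonal S, computed face-by-face in the hat
domain.

The decomposition here is the economy form with k = min(m, p) tubal
components: 'omics tensors have p in the thousands and m in the tens, and
the trailing p − m hat-domain singular values are identically zero, so
the full p×p×n V is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .transforms import MTransform, mode3_inverse, mode3_product

__all__ = [
    "TsvdmFactors",
    "facewise_product",
    "m_product",
    "m_transpose",
    "identity_tensor",
    "is_m_orthogonal",
    "tsvdm",
    "truncate_explicit_rank",
    "frobenius_norm",
    "validate_tensor3",
]


def validate_tensor3(a: np.ndarray, name: str = "tensor") -> np.ndarray:
    """Coerce to float ndarray and check the order-3, finite contract."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 3:
        raise ValueError(f"{name} must be order-3, got ndim={a.ndim}")
    if min(a.shape) < 1:
        raise ValueError(f"{name} has an empty axis: shape={a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def frobenius_norm(a: np.ndarray) -> float:
    """Square root of the sum of squared entries."""
    return float(np.linalg.norm(np.asarray(a, dtype=float)))


def facewise_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Slice-by-slice matrix product: C_{:,:,i} = A_{:,:,i} B_{:,:,i}."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 3 or b.ndim != 3:
        raise ValueError("facewise product requires two order-3 tensors")
    if a.shape[1] != b.shape[0] or a.shape[2] != b.shape[2]:
        raise ValueError(
            f"face-wise shape mismatch: {a.shape} incompatible with {b.shape}"
        )
    # einsum over faces: (m,p,n),(p,r,n)->(m,r,n)
    return np.einsum("ipn,prn->irn", a, b, optimize=True)


def m_product(a: np.ndarray, b: np.ndarray, m: MTransform) -> np.ndarray:
    """The ⋆_M tensor-tensor product: (Â △ B̂) ×₃ M⁻¹."""
    a_hat = mode3_product(a, m)
    b_hat = mode3_product(b, m)
    return mode3_inverse(facewise_product(a_hat, b_hat), m)


def m_transpose(a: np.ndarray) -> np.ndarray:
    """Face-wise transpose: slice i of the result is A_{:,:,i}ᵀ."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 3:
        raise ValueError("m_transpose requires an order-3 tensor")
    return np.transpose(a, (1, 0, 2))


def identity_tensor(m: int, n: int, mt: MTransform) -> np.ndarray:
    """The neutral element of ⋆_M: hat-domain faces are all the m×m identity."""
    if m < 1 or n < 1:
        raise ValueError("identity tensor dimensions must be >= 1")
    eye_hat = np.repeat(np.eye(m)[:, :, None], n, axis=2)
    return mode3_inverse(eye_hat, mt)


def is_m_orthogonal(q: np.ndarray, mt: MTransform, tol: float = 1e-8) -> bool:
    """True iff every hat-domain face of ``q`` has orthonormal columns."""
    q_hat = mode3_product(q, mt)
    k = q_hat.shape[1]
    eye = np.eye(k)
    for i in range(q_hat.shape[2]):
        face = q_hat[:, :, i]
        if np.max(np.abs(face.T @ face - eye)) > tol:
            return False
    return True


@dataclass
class TsvdmFactors:
    """Economy tubal SVD factors of a tensor, A = U ⋆_M S ⋆_M Vᵀ.

    ``u`` (m×k×n) and ``v`` (p×k×n) are stored in the original domain;
    ``s_hat`` is the k×n matrix of hat-domain diagonal singular values
    (column i holds the per-face singular values of face i, non-negative
    and non-increasing down each column). The f-diagonal S tensor is
    materialized only on demand.
    """

    u: np.ndarray
    v: np.ndarray
    s_hat: np.ndarray
    m_transform: MTransform

    @property
    def k(self) -> int:
        return self.s_hat.shape[0]

    @property
    def n(self) -> int:
        return self.s_hat.shape[1]

    def s_tensor(self) -> np.ndarray:
        """Materialize the f-diagonal S as a k×k×n tensor (original domain)."""
        k, n = self.s_hat.shape
        s_hat_t = np.zeros((k, k, n))
        idx = np.arange(k)
        s_hat_t[idx, idx, :] = self.s_hat
        return mode3_inverse(s_hat_t, self.m_transform)

    def reconstruct(self, keep_mask: np.ndarray | None = None) -> np.ndarray:
        """Rebuild the tensor, optionally keeping only a subset of diagonals.

        ``keep_mask`` is a boolean k×n array over hat-domain diagonal
        entries; ``None`` keeps all of them.
        """
        u_hat = mode3_product(self.u, self.m_transform)
        v_hat = mode3_product(self.v, self.m_transform)
        s = self.s_hat if keep_mask is None else self.s_hat * keep_mask
        # faces: U_hat_i diag(s_i) V_hat_iᵀ
        out_hat = np.einsum(
            "ikn,kn,jkn->ijn", u_hat, s, v_hat, optimize=True
        )
        return mode3_inverse(out_hat, self.m_transform)


def _sign_convention(u_face: np.ndarray, v_face: np.ndarray) -> None:
    """Deterministic sign fix, in place.

    For each singular-vector pair, the entry of largest magnitude in the
    V̂ column is made positive (ties resolved to the lowest feature
    index); the matching Û column flips with it.
    """
    for c in range(v_face.shape[1]):
        col = v_face[:, c]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            v_face[:, c] = -col
            u_face[:, c] = -u_face[:, c]


def tsvdm(a: np.ndarray, mt: MTransform) -> TsvdmFactors:
    """Tubal SVD of ``a`` under the ⋆_M product.

    Computes the economy matrix SVD of every hat-domain face and maps the
    stacked factors back to the original domain. Deterministic under the
    largest-|V̂|-entry-positive sign convention.
    """
    a = validate_tensor3(a)
    m_dim, p, n = a.shape
    if mt.n != n:
        raise ValueError(f"M side {mt.n} does not match tensor tube length {n}")
    k = min(m_dim, p)
    a_hat = mode3_product(a, mt)
    u_hat = np.empty((m_dim, k, n))
    v_hat = np.empty((p, k, n))
    s_hat = np.empty((k, n))
    for i in range(n):
        uf, sf, vtf = np.linalg.svd(a_hat[:, :, i], full_matrices=False)
        vf = vtf.T
        _sign_convention(uf, vf)
        u_hat[:, :, i] = uf
        v_hat[:, :, i] = vf
        s_hat[:, i] = sf
    return TsvdmFactors(
        u=mode3_inverse(u_hat, mt),
        v=mode3_inverse(v_hat, mt),
        s_hat=s_hat,
        m_transform=mt,
    )


def truncate_explicit_rank(
    factors: TsvdmFactors,
    q: int,
    ranking: Sequence[tuple[int, int]] | Iterable[tuple[int, int]],
) -> TsvdmFactors:
    """Explicit rank-q truncation of a tubal SVD.

    Zeroes every hat-domain diagonal entry except the ``q`` globally
    largest, as ordered by ``ranking`` — a sequence of 0-based
    ``(diagonal index, face index)`` pairs covering all k·n entries. For
    orthonormal M the resulting approximation error satisfies
    ‖A − A_q‖_F² = Σ_{h>q} σ̂_h².
    """
    ranking = list(ranking)
    k, n = factors.s_hat.shape
    if not 0 <= q <= k * n:
        raise ValueError(f"q must be in [0, {k * n}], got {q}")
    if len(ranking) != k * n:
        raise ValueError("ranking must cover every (diagonal, face) pair")
    mask = np.zeros((k, n), dtype=bool)
    for d, f in ranking[:q]:
        mask[d, f] = True
    return TsvdmFactors(
        u=factors.u,
        v=factors.v,
        s_hat=factors.s_hat * mask,
        m_transform=factors.m_transform,
    )
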
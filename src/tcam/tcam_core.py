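"""The TCAM estimator: fit, out-of-sample transform, scores and loadings.

TCAM (tensor component analysis via the M-product) generalizes PCA to
order-3 longitudinal tensors.  The data tensor (subjects × features ×
timepoints) is centered to mean-deviation form, decomposed with the
tubal SVD under a chosen ⋆_M algebra, and the hat-domain singular values
from all faces are pooled into a single global ranking.  Component h of
the embedding reads one entry of the hat domain of (A − Ā) ⋆_M V, so a
new subject's trajectory can be projected without refitting.  At n = 1
with M = [[1]] the whole construction degenerates to classical PCA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .mprod import TsvdmFactors, tsvdm, validate_tensor3
from .transforms import MTransform, make_m_transform, mode3_product

__all__ = [
    "RankingVector",
    "TcamModel",
    "TCAM",
    "mean_sample",
    "center_mdf",
    "ranking_vector",
    "fit",
    "scores",
    "transform",
    "loadings_matrix",
    "truncate_model",
    "choose_q_by_variance",
]


def mean_sample(a: np.ndarray) -> np.ndarray:
    """The mean horizontal slice Ā = (Σᵢ A_{i,:,:})/m, shape 1×p×n."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 3:
        raise ValueError("mean_sample requires an order-3 tensor")
    return a.mean(axis=0, keepdims=True)


def center_mdf(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center to mean-deviation form; returns (centered tensor, Ā)."""
    a_bar = mean_sample(a)
    return a - a_bar, a_bar


@dataclass(frozen=True)
class RankingVector:
    """Global ordering of the hat-domain singular values.

    ``diag`` and ``face`` are aligned 0-based index arrays: component h
    reads diagonal entry ``diag[h]`` of hat face ``face[h]``, whose
    singular value is ``sigma[h]``.  Sigmas are non-increasing; ties are
    broken by ascending diagonal index, then ascending face index.
    """

    diag: np.ndarray
    face: np.ndarray
    sigma: np.ndarray

    def __len__(self) -> int:
        return len(self.sigma)

    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.diag.tolist(), self.face.tolist()))


def ranking_vector(s_hat: np.ndarray) -> RankingVector:
    """Rank all (diagonal, face) singular values of Ŝ in descending order."""
    s_hat = np.asarray(s_hat, dtype=float)
    if s_hat.ndim != 2:
        raise ValueError("s_hat must be a k×n matrix of diagonal values")
    if np.any(s_hat < 0):
        raise ValueError("singular values must be non-negative")
    k, n = s_hat.shape
    flat = s_hat.ravel()  # row-major: index = diag*n + face
    order = np.argsort(-flat, kind="stable")  # stable => (diag, face) tie order
    return RankingVector(
        diag=order // n, face=order % n, sigma=flat[order]
    )


@dataclass
class TcamModel:
    """Fitted TCAM transform state.

    Holds everything needed to project new trajectories: the training
    mean sample Ā, the right factor tensor V, the mixing transform M,
    the global ranking of hat-domain singular values, and the explained
    variance fraction σ̂_h² / Σ σ̂² of each component.
    """

    mean_sample_: np.ndarray
    ranking: RankingVector
    v: np.ndarray
    m_transform: MTransform
    explained_variance: np.ndarray
    q: int
    feature_labels: list[str] | None = None
    timepoint_labels: list[str] | None = None
    subject_labels: list[str] | None = None
    training_scores_: np.ndarray | None = field(default=None, repr=False)
    _v_hat: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.ranking)

    @property
    def v_hat(self) -> np.ndarray:
        if self._v_hat is None:
            self._v_hat = mode3_product(self.v, self.m_transform)
        return self._v_hat

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize to an .npz archive plus a JSON label sidecar."""
        path = Path(path)
        np.savez(
            path,
            mean_sample=self.mean_sample_,
            v=self.v,
            m_matrix=self.m_transform.matrix,
            diag=self.ranking.diag,
            face=self.ranking.face,
            sigma=self.ranking.sigma,
            explained_variance=self.explained_variance,
            q=np.array([self.q]),
        )
        meta = {
            "m_kind": self.m_transform.kind,
            "m_seed": self.m_transform.seed,
            "feature_labels": self.feature_labels,
            "timepoint_labels": self.timepoint_labels,
            "subject_labels": self.subject_labels,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "TcamModel":
        path = Path(path)
        with np.load(path) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        mt = MTransform(
            matrix=arrays["m_matrix"], kind=meta["m_kind"], seed=meta["m_seed"]
        )
        return cls(
            mean_sample_=arrays["mean_sample"],
            ranking=RankingVector(
                diag=arrays["diag"], face=arrays["face"], sigma=arrays["sigma"]
            ),
            v=arrays["v"],
            m_transform=mt,
            explained_variance=arrays["explained_variance"],
            q=int(arrays["q"][0]),
            feature_labels=meta["feature_labels"],
            timepoint_labels=meta["timepoint_labels"],
            subject_labels=meta["subject_labels"],
        )


def fit(
    a: np.ndarray,
    m_transform: MTransform | None = None,
    *,
    feature_labels: Sequence[str] | None = None,
    timepoint_labels: Sequence[str] | None = None,
    subject_labels: Sequence[str] | None = None,
) -> TcamModel:
    """Fit TCAM to a subjects × features × timepoints tensor.

    Centers to mean-deviation form, computes the tubal SVD, ranks all
    hat-domain singular values globally, and stores the transform
    parameters (Ā, r, V).  The default M is the orthonormal DCT-II of
    size n.
    """
    a = validate_tensor3(a)
    m_dim, p, n = a.shape
    if m_dim < 2:
        raise ValueError("TCAM requires at least 2 subjects")
    if m_transform is None:
        m_transform = make_m_transform(n, "dct2")
    if m_transform.n != n:
        raise ValueError(
            f"M side {m_transform.n} does not match {n} timepoints"
        )
    centered, a_bar = center_mdf(a)
    factors = tsvdm(centered, m_transform)
    total = float(np.sum(factors.s_hat**2))
    # relative floor: centering m identical slices leaves ~eps-sized residue
    if total <= (1e-12 * max(np.linalg.norm(a), 1.0)) ** 2:
        raise ValueError(
            "degenerate input: the centered tensor has zero total variance "
            "(all horizontal slices are identical)"
        )
    rank = ranking_vector(factors.s_hat)
    explained = rank.sigma**2 / total
    u_hat = mode3_product(factors.u, m_transform)
    train_scores = u_hat[:, rank.diag, rank.face] * rank.sigma[None, :]
    return TcamModel(
        mean_sample_=a_bar,
        ranking=rank,
        v=factors.v,
        m_transform=m_transform,
        explained_variance=explained,
        q=len(rank),
        feature_labels=list(feature_labels) if feature_labels is not None else None,
        timepoint_labels=list(timepoint_labels) if timepoint_labels is not None else None,
        subject_labels=list(subject_labels) if subject_labels is not None else None,
        training_scores_=train_scores,
    )


def _project(model: TcamModel, a: np.ndarray) -> np.ndarray:
    """All-component scores of ``a`` via the normative hat-domain read-out.

    Z_{ℓ,h} = [((A − Ā) ⋆_M V) ×₃ M]_{ℓ, r_{h,1}, r_{h,2}}, which in the
    hat domain is simply (Â △ V̂) indexed at the ranked positions.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 3 or a.shape[1:] != model.mean_sample_.shape[1:]:
        raise ValueError(
            f"data shape {a.shape} does not match the model's "
            f"(features, timepoints) = {model.mean_sample_.shape[1:]}"
        )
    centered_hat = mode3_product(a - model.mean_sample_, model.m_transform)
    z_hat = np.einsum(
        "ipn,pkn->ikn", centered_hat, model.v_hat, optimize=True
    )
    rank = model.ranking
    return z_hat[:, rank.diag, rank.face]


def scores(model: TcamModel, a: np.ndarray) -> np.ndarray:
    """Scores matrix Z (m × q) of the subjects in ``a`` under the model."""
    return _project(model, a)[:, : model.q]


def transform(model: TcamModel, x: np.ndarray) -> np.ndarray:
    """Out-of-sample projection of a single 1×p×n trajectory to a q-vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None, :, :]
    if x.shape[0] != 1:
        raise ValueError("transform expects a single 1×p×n trajectory")
    return _project(model, x)[0, : model.q]


def loadings_matrix(model: TcamModel) -> np.ndarray:
    """The q×p loadings matrix.

    Row h is the (r_{h,1})-th hat-domain right singular vector of face
    r_{h,2}; each row has unit Euclidean norm, and rows drawn from the
    same face are mutually orthogonal.
    """
    rank = model.ranking
    # v_hat is p×k×n; component h reads column diag[h] of face face[h]
    return model.v_hat[:, rank.diag[: model.q], rank.face[: model.q]].T


def truncate_model(model: TcamModel, q: int) -> TcamModel:
    """Keep the first q components; scores/loadings nest exactly."""
    if not 1 <= q <= model.n_components:
        raise ValueError(f"q must be in [1, {model.n_components}], got {q}")
    return replace(model, q=q)


def choose_q_by_variance(model: TcamModel, threshold: float) -> int:
    """Smallest q whose cumulative explained variance reaches ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cumulative = np.cumsum(model.explained_variance)
    # tolerate roundoff at the top of the cumulative curve
    idx = np.searchsorted(cumulative, threshold - 1e-12)
    return int(min(idx, len(cumulative) - 1)) + 1


class TCAM:
    """Scikit-learn-style front end over the functional API.

    Parameters
    ----------
    m_transform
        The mixing transform; ``None`` selects the orthonormal DCT-II of
        the right size at fit time.
    q
        Number of components to retain; ``None`` keeps all k·n.
    """

    def __init__(self, m_transform: MTransform | None = None, q: int | None = None):
        self.m_transform = m_transform
        self.q = q
        self.model_: TcamModel | None = None

    def fit(self, a: np.ndarray, **labels) -> "TCAM":
        model = fit(a, self.m_transform, **labels)
        if self.q is not None:
            model = truncate_model(model, self.q)
        self.model_ = model
        return self

    def fit_transform(self, a: np.ndarray, **labels) -> np.ndarray:
        self.fit(a, **labels)
        return scores(self.model_, a)

    def transform(self, a: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("TCAM instance is not fitted")
        a = np.asarray(a, dtype=float)
        if a.ndim == 2:
            return transform(self.model_, a)[None, :]
        return scores(self.model_, a)

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("TCAM instance is not fitted")
        return self.model_.explained_variance[: self.model_.q]

    @property
    def loadings_(self) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("TCAM instance is not fitted")
        return loadings_matrix(self.model_)
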
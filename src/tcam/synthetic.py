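"""Synthetic longitudinal 'omics cohorts with known planted structure.

Real longitudinal microbiome and proteomics cohorts combine two sources
of variation that frustrate flat-matrix ordination: large, stable
inter-individual offsets (everyone's personal baseline) and the much
smaller intra-individual temporal responses that the study actually
cares about.  :func:`generate_longitudinal_tensor` emulates exactly
that: per-feature population baselines, per-(subject, feature) random
offsets, group-specific temporal effect profiles on a designated set of
signal features, and additive noise.  All randomness flows from a single
seed through ``numpy``'s generator-spawning scheme, so every draw is
bitwise reproducible.

:func:`planted_rank_tensor` builds tensors with an exactly known
explicit tubal rank for exercising truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mprod import TsvdmFactors
from .preprocessing import TensorDataset
from .transforms import MTransform, mode3_inverse

__all__ = ["SyntheticSpec", "generate_longitudinal_tensor", "planted_rank_tensor"]


def _default_effect_profile(groups: int, n: int) -> np.ndarray:
    """Group-specific temporal responses: group 0 is flat (control), each
    further group ramps up from 0 with a distinct slope."""
    t = np.linspace(0.0, 1.0, n)
    return np.stack([g * t for g in range(groups)])


@dataclass
class SyntheticSpec:
    """Parameters of a fully sampled synthetic cohort.

    ``effect_profile`` is a (groups × timepoints) array of additive
    effect sizes applied to the ``signal_features`` first features;
    ``subject_offset_sd`` scales the per-(subject, feature) random
    intercepts that model stable inter-individual differences, and
    ``noise_sd`` the i.i.d. Gaussian measurement noise.
    """

    groups: int = 2
    subjects_per_group: int = 10
    p: int = 50
    n: int = 6
    signal_features: int = 1
    effect_profile: np.ndarray | None = None
    subject_offset_sd: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0
    mode: str = "continuous"  # or "counts" (log-normal–Poisson chain)

    def __post_init__(self) -> None:
        if min(self.groups, self.subjects_per_group, self.p, self.n) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.signal_features <= self.p:
            raise ValueError("signal_features must be in [0, p]")
        if self.subject_offset_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.mode not in ("continuous", "counts"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.effect_profile is None:
            self.effect_profile = _default_effect_profile(self.groups, self.n)
        self.effect_profile = np.asarray(self.effect_profile, dtype=float)
        if self.effect_profile.shape != (self.groups, self.n):
            raise ValueError(
                f"effect_profile must be {self.groups}×{self.n}, "
                f"got {self.effect_profile.shape}"
            )


def generate_longitudinal_tensor(
    spec: SyntheticSpec,
) -> tuple[TensorDataset, np.ndarray]:
    """Draw one cohort; returns (dataset, per-subject group labels).

    Entry (i, j, t) = baseline_j + offset_{i,j}
                      + effect_{group(i), t} · 1[j < signal_features]
                      + noise_{i,j,t}.
    In ``counts`` mode the continuous value is treated as a log-intensity
    and pushed through a Poisson observation layer, giving sparse
    non-negative integers suitable for rclr testing.
    """
    m = spec.groups * spec.subjects_per_group
    rng_baseline, rng_offset, rng_noise, rng_counts = np.random.default_rng(
        spec.seed
    ).spawn(4)

    baseline = rng_baseline.normal(0.0, 1.0, size=spec.p)
    offsets = rng_offset.normal(0.0, spec.subject_offset_sd, size=(m, spec.p))
    noise = rng_noise.normal(0.0, spec.noise_sd, size=(m, spec.p, spec.n))

    group = np.repeat(np.arange(spec.groups), spec.subjects_per_group)
    tensor = baseline[None, :, None] + offsets[:, :, None] + noise
    if spec.signal_features:
        effect = spec.effect_profile[group]  # m×n
        tensor[:, : spec.signal_features, :] += effect[:, None, :]

    if spec.mode == "counts":
        lam = np.exp(tensor)  # log-normal intensities
        tensor = rng_counts.poisson(lam).astype(float)

    ds = TensorDataset(
        tensor=tensor,
        subject_labels=[f"S{i:03d}" for i in range(m)],
        feature_labels=[f"F{j:04d}" for j in range(spec.p)],
        timepoint_labels=[f"T{t}" for t in range(spec.n)],
        normalization_log=[],
    )
    return ds, group


def planted_rank_tensor(
    m: int, p: int, n: int, q: int, mt: MTransform, seed: int
) -> np.ndarray:
    """A tensor whose explicit tubal rank is exactly ``q``.

    Constructs ⋆_M-orthogonal U, V with exactly ``q`` nonzero hat-domain
    diagonal singular values (distinct, well separated) and returns
    U ⋆_M S ⋆_M Vᵀ.
    """
    k = min(m, p)
    if not 0 <= q <= k * n:
        raise ValueError(f"q must be in [0, {k * n}], got {q}")
    rng = np.random.default_rng(seed)
    u_hat = np.empty((m, k, n))
    v_hat = np.empty((p, k, n))
    for i in range(n):
        u_hat[:, :, i] = np.linalg.qr(rng.standard_normal((m, k)))[0]
        v_hat[:, :, i] = np.linalg.qr(rng.standard_normal((p, k)))[0]
    s_hat = np.zeros((k, n))
    positions = rng.choice(k * n, size=q, replace=False)
    s_hat[positions // n, positions % n] = np.linspace(2.0, 1.0, num=max(q, 1))[:q]
    factors = TsvdmFactors(
        u=mode3_inverse(u_hat, mt),
        v=mode3_inverse(v_hat, mt),
        s_hat=s_hat,
        m_transform=mt,
    )
    return factors.reconstruct()
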
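"""Cell subsampling and the donor-by-donor inner-product (Gram) matrix.

Each donor's distribution is represented by its kernel mean embedding; the
inner product between two donors is estimated as the mean of all pairwise RBF
kernel values between equal-size cell subsamples drawn without replacement:

    <p_i, p_j> = (1/n^2) sum_k sum_l exp(-gamma * ||x_ik - x_jl||^2)

The default bandwidth is ``gamma = 1/p`` where ``p`` is the number of
features entering the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io_preprocess import DonorProfile

__all__ = [
    "CellSample",
    "KernelConfig",
    "GramMatrix",
    "subsample_cells",
    "subsampling_seed",
    "default_gamma",
    "rbf_kernel_matrix",
    "profile_inner_product",
    "build_gram_matrix",
]


@dataclass(frozen=True)
class CellSample:
    """A without-replacement subsample of one donor's cells."""

    donor_id: str
    cells: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.cells.shape[0]

    @property
    def p(self) -> int:
        return self.cells.shape[1]


@dataclass(frozen=True)
class KernelConfig:
    """RBF bandwidth and subsample size for one embedding run.

    ``gamma=None`` means "use 1/p", resolved when p is known.
    """

    gamma: float | None = None
    n_cells: int = 1000

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")

    def resolve_gamma(self, p: int) -> float:
        return self.gamma if self.gamma is not None else default_gamma(p)


@dataclass
class GramMatrix:
    """N x N symmetric matrix of estimated distribution inner products."""

    values: np.ndarray
    donor_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.donor_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} donor ids"
            )

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)


def subsampling_seed(master_seed: int, donor_index: int, rep: int = 0) -> np.random.SeedSequence:
    """Deterministic expansion of one master seed into per-donor streams.

    The rule is ``SeedSequence([master_seed, rep, donor_index])``: independent
    across donors and across resampling repetitions, reproducible from the
    single master integer.
    """
    return np.random.SeedSequence([int(master_seed), int(rep), int(donor_index)])


def subsample_cells(profile: DonorProfile, n: int, seed) -> CellSample:
    """Uniform without-replacement draw of ``n`` cells; deterministic per seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n > profile.num_cells:
        raise ValueError(
            f"donor {profile.donor_id!r}: requested n={n} cells but profile has "
            f"only {profile.num_cells}; choose n <= the cohort minimum"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(profile.num_cells, size=n, replace=False)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return CellSample(
        donor_id=profile.donor_id,
        cells=profile.expression[idx].copy(),
        seed=int(seed_int),
    )


def default_gamma(p: int) -> float:
    """Bandwidth rule gamma = 1/p for p kernel features."""
    if p < 1:
        raise ValueError(f"p must be a positive integer, got {p}")
    return 1.0 / p


def rbf_kernel_matrix(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """Pairwise ``exp(-gamma * ||a - b||^2)`` between the rows of A and B."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature mismatch: A has p={A.shape[1]}, B has p={B.shape[1]}")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-gamma * sq)


def profile_inner_product(
    si: CellSample, sj: CellSample, gamma: float, block: int = 2048
) -> float:
    """Mean of all n^2 pairwise kernel values between two equal-n samples.

    Computed in blocks of ``block`` rows so peak memory is O(block^2) rather
    than O(n^2); the result is identical to the naive double loop.
    """
    if si.n != sj.n:
        raise ValueError(
            f"samples must share n: {si.donor_id!r} has {si.n}, "
            f"{sj.donor_id!r} has {sj.n}"
        )
    if si.p != sj.p:
        raise ValueError(f"feature mismatch: p={si.p} vs p={sj.p}")
    # Canonical argument order makes the summation order — and hence the
    # float result — identical for (si, sj) and (sj, si).
    if sj.donor_id < si.donor_id:
        si, sj = sj, si
    total = 0.0
    A, B = si.cells, sj.cells
    for a0 in range(0, si.n, block):
        Ab = A[a0 : a0 + block]
        for b0 in range(0, sj.n, block):
            total += rbf_kernel_matrix(Ab, B[b0 : b0 + block], gamma).sum()
    return total / (si.n * sj.n)


def build_gram_matrix(
    samples: Sequence[CellSample], gamma: float, block: int = 2048
) -> GramMatrix:
    """Inner-product matrix over a cohort; each unordered pair computed once
    and mirrored, so the result is exactly symmetric."""
    if len(samples) < 2:
        raise ValueError("a Gram matrix needs at least two donors")
    ids = [s.donor_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = next(d for d in ids if ids.count(d) > 1)
        raise ValueError(f"duplicate donor_id {dup!r} in cohort")
    n_set = {s.n for s in samples}
    if len(n_set) != 1:
        raise ValueError(f"all samples must share n; got sizes {sorted(n_set)}")
    p_set = {s.p for s in samples}
    if len(p_set) != 1:
        raise ValueError(f"all samples must share p; got dims {sorted(p_set)}")
    N = len(samples)
    G = np.empty((N, N))
    for i in range(N):
        for j in range(i, N):
            v = profile_inner_product(samples[i], samples[j], gamma, block=block)
            G[i, j] = v
            G[j, i] = v
    return GramMatrix(values=G, donor_ids=ids)
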
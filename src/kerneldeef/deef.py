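"""Theta coordinates from the eigendecomposition of the half-log Gram matrix.

``P = 0.5 * log(G)`` (elementwise natural log) is symmetric but generally
indefinite; its signed eigendecomposition yields per-donor coordinates
``theta_i = v_i * sqrt(|lambda_i|)``, ordered by signed eigenvalue from the
largest positive to the largest negative.  The signed reconstruction
``sum_i sign(lambda_i) theta_i theta_i^T == P`` is the module's core
invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .io_preprocess import DonorProfile
from .kernel_embedding import (
    GramMatrix,
    KernelConfig,
    build_gram_matrix,
    subsample_cells,
    subsampling_seed,
)

__all__ = [
    "ThetaDecomposition",
    "deef_decompose",
    "positive_axes",
    "top_theta",
    "embed_profiles",
    "resampling_stability",
]


@dataclass
class ThetaDecomposition:
    """Donor coordinates and signed eigenvalues of one decomposition.

    ``theta[:, i]`` is the i-th coordinate axis; ``eigenvalues[i]`` carries
    its sign.  ``tied_axes`` flags axes involved in (near-)degenerate
    eigenvalues, whose span rather than individual directions is identifiable.
    """

    theta: np.ndarray
    eigenvalues: np.ndarray
    donor_ids: list[str]
    tied_axes: list[int] = field(default_factory=list)

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.eigenvalues > 0))


def deef_decompose(
    gram: GramMatrix, zero_tol_factor: float = 1e-10
) -> ThetaDecomposition:
    """Eigendecompose ``0.5 * log(Gram)`` into signed theta coordinates.

    Eigenvector signs are fixed so each axis's largest-magnitude entry is
    positive, making runs bit-reproducible.  Eigenvalues within
    ``zero_tol_factor * max|lambda|`` of zero are kept (flagged zero) but
    never counted as positive.
    """
    G = gram.values
    if G.shape[0] < 2:
        raise ValueError("decomposition needs at least two donors")
    if np.any(G <= 0):
        i, j = np.argwhere(G <= 0)[0]
        raise ValueError(
            f"Gram entry ({i},{j}) = {G[i, j]} is not strictly positive; "
            "kernel-mean inner products with an RBF kernel are always > 0, "
            "so the elementwise log is undefined here"
        )
    P = 0.5 * np.log(G)
    P = (P + P.T) / 2.0
    lam, vec = np.linalg.eigh(P)

    zero_tol = zero_tol_factor * max(np.abs(lam).max(), 1e-300)
    lam = np.where(np.abs(lam) < zero_tol, 0.0, lam)

    # Signed descending order; eigh returns ascending. Stable sort keeps the
    # solver order within exact ties.
    order = np.argsort(-lam, kind="stable")
    lam = lam[order]
    vec = vec[:, order]

    theta = vec * np.sqrt(np.abs(lam))[np.newaxis, :]
    # Sign convention: largest-|entry| coordinate of each axis is positive.
    for i in range(theta.shape[1]):
        col = theta[:, i]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            theta[:, i] = -col

    tied: list[int] = []
    for i in range(len(lam) - 1):
        if abs(lam[i] - lam[i + 1]) <= zero_tol:
            tied.extend([i, i + 1])
    return ThetaDecomposition(
        theta=theta,
        eigenvalues=lam,
        donor_ids=list(gram.donor_ids),
        tied_axes=sorted(set(tied)),
    )


def positive_axes(dec: ThetaDecomposition) -> np.ndarray:
    """Theta columns with strictly positive eigenvalue, order preserved."""
    mask = dec.eigenvalues > 0
    if not mask.any():
        raise ValueError(
            "no positive eigenvalues; inspect the Gram matrix (all donors may "
            "be numerically identical or the kernel degenerate)"
        )
    return dec.theta[:, mask]


def top_theta(dec: ThetaDecomposition, k: int) -> np.ndarray:
    """First ``k`` theta columns in signed-eigenvalue order."""
    if not 1 <= k <= dec.theta.shape[1]:
        raise ValueError(f"k must be in [1, {dec.theta.shape[1]}], got {k}")
    return dec.theta[:, :k]


def embed_profiles(
    profiles: Sequence[DonorProfile],
    config: KernelConfig,
    master_seed: int,
    rep: int = 0,
) -> ThetaDecomposition:
    """Full subsample -> Gram -> decompose pipeline for one repetition."""
    samples = [
        subsample_cells(prof, config.n_cells, subsampling_seed(master_seed, i, rep))
        for i, prof in enumerate(profiles)
    ]
    gamma = config.resolve_gamma(samples[0].p)
    gram = build_gram_matrix(samples, gamma)
    return deef_decompose(gram)


def resampling_stability(
    profiles: Sequence[DonorProfile],
    n: int,
    config: KernelConfig | None = None,
    n_reps: int = 2,
    master_seed: int = 0,
) -> dict:
    """Repeat the embedding with fresh cell subsamples and correlate axes.

    Returns a dict with the per-repetition decompositions and, for every pair
    of repetitions and every axis, absolute Pearson and Spearman correlations
    of coordinate values (absolute because the eigenvector sign is arbitrary
    across runs).
    """
    if n_reps < 2:
        raise ValueError("stability analysis needs n_reps >= 2")
    config = config or KernelConfig()
    config = KernelConfig(gamma=config.gamma, n_cells=n)
    decs = [
        embed_profiles(profiles, config, master_seed, rep=r) for r in range(n_reps)
    ]
    n_axes = min(d.theta.shape[1] for d in decs)
    correlations = []
    for a in range(n_reps):
        for b in range(a + 1, n_reps):
            for ax in range(n_axes):
                x = decs[a].theta[:, ax]
                y = decs[b].theta[:, ax]
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    pr = sp = np.nan
                else:
                    pr = abs(pearsonr(x, y).statistic)
                    sp = abs(spearmanr(x, y).statistic)
                correlations.append(
                    {
                        "rep_a": a,
                        "rep_b": b,
                        "axis": ax + 1,
                        "abs_pearson": pr,
                        "abs_spearman": sp,
                    }
                )
    return {"decompositions": decs, "correlations": correlations}
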
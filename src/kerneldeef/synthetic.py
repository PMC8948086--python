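"""Synthetic cohort generators.

Cytometry-like cohorts are Gaussian mixtures per donor (components standing
in for cell subsets) with group-level differences in component means, weights
or covariances plus a random per-donor shift.  scRNA-seq-like cohorts are
negative-binomial count matrices with a ground-truth set of signal genes
whose distribution — mean, variance or modality — differs in one group.
Generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._fcs import write_fcs
from .io_preprocess import DonorProfile

__all__ = [
    "MixtureComponent",
    "CohortSpec",
    "two_group_cohort_spec",
    "simulate_cytometry_cohort",
    "simulate_scrnaseq_cohort",
    "write_fcs",
]


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=np.float64))
        if self.weight <= 0:
            raise ValueError("component weight must be positive")
        cov = self.cov
        if cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape must match mean dimension")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive definite")


@dataclass(frozen=True)
class CohortSpec:
    """Generative spec for a multi-donor, multi-group mixture cohort."""

    n_donors_per_group: int
    groups: tuple[str, ...]
    n_cells_per_donor: int
    p: int
    mixture: dict[str, tuple[MixtureComponent, ...]]
    donor_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for grp in self.groups:
            if grp not in self.mixture:
                raise ValueError(f"no mixture defined for group {grp!r}")
            comps = self.mixture[grp]
            total = sum(c.weight for c in comps)
            if not np.isclose(total, 1.0):
                raise ValueError(f"group {grp!r}: weights sum to {total}, not 1")
            for c in comps:
                if c.mean.size != self.p:
                    raise ValueError(f"group {grp!r}: component dimension != p")


def two_group_cohort_spec(
    n_donors_per_group: int = 10,
    n_cells_per_donor: int = 500,
    p: int = 5,
    shift: float = 3.0,
    donor_effect_sd: float = 0.2,
    seed: int = 0,
) -> CohortSpec:
    """Convenience spec: two equal-weight unit-covariance components per
    group, with the first component's mean shifted by ``shift`` standard
    deviations along every feature in group B."""
    eye = np.eye(p)
    base = (
        MixtureComponent(0.5, np.zeros(p), eye),
        MixtureComponent(0.5, np.full(p, 4.0), eye),
    )
    shifted = (
        MixtureComponent(0.5, np.full(p, shift), eye),
        MixtureComponent(0.5, np.full(p, 4.0), eye),
    )
    return CohortSpec(
        n_donors_per_group=n_donors_per_group,
        groups=("A", "B"),
        n_cells_per_donor=n_cells_per_donor,
        p=p,
        mixture={"A": base, "B": shifted},
        donor_effect_sd=donor_effect_sd,
        seed=seed,
    )


def simulate_cytometry_cohort(
    spec: CohortSpec,
) -> tuple[list[DonorProfile], list[str]]:
    """Draw one profile per donor from its group's perturbed mixture.

    Per donor, every component mean receives an independent
    ``Normal(0, donor_effect_sd^2)`` perturbation before ``n`` cells are
    drawn from the resulting Gaussian mixture.  Deterministic given the
    spec's seed.
    """
    profiles: list[DonorProfile] = []
    labels: list[str] = []
    feature_names = [f"marker{j + 1}" for j in range(spec.p)]
    for g_idx, grp in enumerate(spec.groups):
        comps = spec.mixture[grp]
        for d_idx in range(spec.n_donors_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, g_idx, d_idx])
            )
            means = [
                c.mean + rng.normal(0.0, spec.donor_effect_sd, size=spec.p)
                for c in comps
            ]
            weights = np.array([c.weight for c in comps])
            counts = rng.multinomial(spec.n_cells_per_donor, weights)
            blocks = [
                rng.multivariate_normal(mu, c.cov, size=k)
                for mu, c, k in zip(means, comps, counts)
                if k > 0
            ]
            cells = np.vstack(blocks)
            rng.shuffle(cells, axis=0)
            profiles.append(
                DonorProfile(
                    donor_id=f"{grp}{d_idx + 1:02d}",
                    expression=cells,
                    feature_names=list(feature_names),
                    group_label=grp,
                )
            )
            labels.append(grp)
    return profiles, labels


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_r: np.ndarray, n: int) -> np.ndarray:
    """Negative-binomial counts, shape (n, len(mean)); var = mu + mu^2 / r."""
    p = size_r / (size_r + mean)
    return rng.negative_binomial(size_r, p, size=(n, mean.size)).astype(np.float64)


def simulate_scrnaseq_cohort(
    n_donors_per_group: int,
    n_cells: int,
    n_genes: int,
    n_signal_genes: int,
    effect: Literal["mean_shift", "variance_shift", "bimodality_shift"] = "mean_shift",
    effect_size: float = 1.5,
    seed: int = 0,
    base_mean_log_mu: float = 0.5,
    base_mean_log_sd: float = 1.0,
    dispersion_log_mu: float = 0.7,
    dispersion_log_sd: float = 0.5,
    donor_effect_sd: float = 0.05,
) -> tuple[list[DonorProfile], list[str], pd.DataFrame]:
    """Negative-binomial count cohort with ground-truth signal genes.

    Per gene, a base mean and dispersion are drawn from log-normals; in group
    "case" the signal genes are altered per ``effect``:

    - ``mean_shift``: gene mean multiplied by ``effect_size``;
    - ``variance_shift``: dispersion parameter r divided by ``effect_size``
      (variance up, mean unchanged);
    - ``bimodality_shift``: a 50/50 mixture of means ``mu * (1 - d)`` and
      ``mu * (1 + d)`` with ``d = min(effect_size, 0.95)`` (overall mean
      unchanged, shape bimodal).

    Returns ``(profiles, labels, truth)`` where ``truth`` marks signal genes.
    """
    if n_signal_genes > n_genes:
        raise ValueError("n_signal_genes must be <= n_genes")
    if effect not in {"mean_shift", "variance_shift", "bimodality_shift"}:
        raise ValueError(f"unknown effect {effect!r}")
    if effect == "mean_shift" and effect_size < 0:
        raise ValueError("mean_shift effect_size must be non-negative")
    if effect == "bimodality_shift" and not 0 <= effect_size:
        raise ValueError("bimodality_shift effect_size must be non-negative")

    root = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    gene_names = [f"gene{j + 1:04d}" for j in range(n_genes)]
    base_mean = np.exp(root.normal(base_mean_log_mu, base_mean_log_sd, size=n_genes))
    dispersion = np.exp(
        root.normal(dispersion_log_mu, dispersion_log_sd, size=n_genes)
    )
    signal_idx = root.choice(n_genes, size=n_signal_genes, replace=False)
    is_signal = np.zeros(n_genes, dtype=bool)
    is_signal[signal_idx] = True

    profiles: list[DonorProfile] = []
    labels: list[str] = []
    for g_idx, grp in enumerate(("control", "case")):
        for d_idx in range(n_donors_per_group):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 1 + g_idx, d_idx]))
            mu = base_mean * np.exp(rng.normal(0.0, donor_effect_sd, size=n_genes))
            r = dispersion.copy()
            if grp == "case":
                if effect == "mean_shift":
                    mu = np.where(is_signal, mu * effect_size, mu)
                elif effect == "variance_shift":
                    r = np.where(is_signal, r / max(effect_size, 1e-12), r)
            if np.any(mu < 0):
                raise ValueError("parameter combination yields negative means")
            counts = _nb_draw(rng, mu, r, n_cells)
            if grp == "case" and effect == "bimodality_shift":
                d = min(effect_size, 0.95)
                lo = _nb_draw(rng, mu * (1 - d), r, n_cells)
                hi = _nb_draw(rng, mu * (1 + d), r, n_cells)
                pick_hi = rng.random((n_cells, n_genes)) < 0.5
                bimodal = np.where(pick_hi, hi, lo)
                counts = np.where(is_signal[None, :], bimodal, counts)
            profiles.append(
                DonorProfile(
                    donor_id=f"{grp}{d_idx + 1:02d}",
                    expression=counts,
                    feature_names=list(gene_names),
                    group_label=grp,
                    metadata={
                        "simulator": "negative_binomial",
                        "effect": effect,
                        "effect_size": effect_size,
                    },
                )
            )
            labels.append(grp)
    truth = pd.DataFrame(
        {"gene": gene_names, "is_signal": is_signal, "effect": effect}
    )
    return profiles, labels, truth
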
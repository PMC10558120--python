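"""Net biodiversity effects: additive partitioning, ΔSSCI, Hedges' g.

The net biodiversity effect (NBE, overyielding) of a mixture is its
observed yield minus the yield expected from monoculture performance at
the planted proportions. It decomposes additively into a complementarity
effect (CE) — all species deviating together from expected relative yields
— and a selection effect (SE) — the covariance between relative-yield
deviation and monoculture yield:

    dRY_i = Y_O,i / M_i - RY_E,i
    CE    = N * mean(dRY) * mean(M)
    SE    = N * cov_pop(dRY, M)        (population, divide-by-N covariance)
    NBE   = sum(Y_O,i) - sum(RY_E,i * M_i) = CE + SE

The same observed-minus-expected logic applied to stand structural
complexity gives ΔSSCI: the mixture's measured SSCI minus the mean
monoculture SSCI of its species weighted by their realized (mortality-
corrected) relative abundances. Hedges' g is the standardized mean
difference with pooled SD and the small-sample correction
J = 1 - 3 / (4(n1 + n2) - 9).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PartitionResult",
    "DeltaSSCI",
    "EffectSize",
    "additive_partitioning",
    "delta_ssci",
    "hedges_g",
]


@dataclass
class PartitionResult:
    """Additive partition of the net biodiversity effect of one mixture."""

    nbe: float
    ce: float
    se: float
    n_species: int
    species: tuple[str, ...]
    observed: np.ndarray  # Y_O,i
    mono_means: np.ndarray  # M_i
    expected_ry: np.ndarray  # RY_E,i
    delta_ry: np.ndarray
    plot_id: str | None = None


@dataclass
class DeltaSSCI:
    """Net biodiversity effect on stand structural complexity for one plot."""

    ssci_obs: float
    ssci_pred: float
    delta: float
    abundances: dict[str, float]  # realized relative abundances p_ij
    mono_means: dict[str, float]
    plot_id: str | None = None


@dataclass
class EffectSize:
    """Hedges' g standardized mean difference between two groups."""

    g: float
    mean_diff: float
    pooled_sd: float
    correction: float
    n1: int
    n2: int


def additive_partitioning(
    observed: Mapping[str, float],
    mono_means: Mapping[str, float],
    proportions: Mapping[str, float] | None = None,
    plot_id: str | None = None,
) -> PartitionResult:
    """Partition a mixture's NBE into complementarity and selection effects.

    Parameters
    ----------
    observed
        Per-species observed yields Y_O,i in the mixture (e.g. per-species
        AWP of the plot).
    mono_means
        Monoculture mean yields M_i of the same species; all must be > 0.
    proportions
        Expected (planted) relative yields RY_E,i; defaults to equal
        proportions 1/N, the design expectation when species are planted in
        equal numbers.
    """
    species = tuple(sorted(observed))
    missing = [s for s in species if s not in mono_means]
    if missing:
        raise KeyError(f"no monoculture mean for species: {', '.join(missing)}")
    n = len(species)
    y_o = np.array([observed[s] for s in species], dtype=float)
    m = np.array([mono_means[s] for s in species], dtype=float)
    if np.any(m <= 0):
        bad = [s for s, v in zip(species, m) if v <= 0]
        raise ValueError(f"monoculture mean must be > 0 for relative yields ({', '.join(bad)})")
    if proportions is None:
        ry_e = np.full(n, 1.0 / n)
    else:
        ry_e = np.array([proportions[s] for s in species], dtype=float)
        if abs(ry_e.sum() - 1.0) > 1e-9:
            raise ValueError("expected relative yields must sum to 1")

    d_ry = y_o / m - ry_e
    ce = n * d_ry.mean() * m.mean()
    se = n * float(np.mean((d_ry - d_ry.mean()) * (m - m.mean())))  # population cov
    nbe = float(y_o.sum() - (ry_e * m).sum())
    return PartitionResult(
        nbe=nbe, ce=float(ce), se=float(se), n_species=n, species=species,
        observed=y_o, mono_means=m, expected_ry=ry_e, delta_ry=d_ry, plot_id=plot_id,
    )


def delta_ssci(
    ssci_obs: float,
    mono_means: Mapping[str, float],
    abundances: Mapping[str, float],
    plot_id: str | None = None,
) -> DeltaSSCI:
    """Observed SSCI minus the abundance-weighted monoculture expectation.

    ``abundances`` are the realized relative abundances p_ij of the plot's
    species at the second census (living trees, i.e. corrected for
    mortality); they must be non-negative and sum to 1.
    """
    p = np.array([abundances[s] for s in sorted(abundances)], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must be non-negative and sum to 1")
    missing = [s for s in abundances if s not in mono_means]
    if missing:
        raise KeyError(f"no monoculture SSCI mean for species: {', '.join(missing)}")
    pred = float(sum(abundances[s] * mono_means[s] for s in abundances))
    return DeltaSSCI(
        ssci_obs=float(ssci_obs),
        ssci_pred=pred,
        delta=float(ssci_obs) - pred,
        abundances=dict(abundances),
        mono_means={s: float(mono_means[s]) for s in abundances},
        plot_id=plot_id,
    )


def hedges_g(
    group1: Sequence[float], group2: Sequence[float], small_sample_correction: bool = True
) -> EffectSize:
    """Hedges' g between two groups (positive when group1's mean is larger)."""
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    s_pooled = np.sqrt(
        ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0) if small_sample_correction else 1.0
    diff = float(x1.mean() - x2.mean())
    return EffectSize(
        g=diff / float(s_pooled) * j,
        mean_diff=diff,
        pooled_sd=float(s_pooled),
        correction=j,
        n1=n1,
        n2=n2,
    )
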
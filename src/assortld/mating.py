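"""Mating-type frequency distributions for the four mating systems.

Each model maps a :class:`~assortld.core.PopulationState` to a distribution
over the 55 unordered genotype x genotype mating types:

* ``wright_assortative`` — a proportion ``A`` of the population splits into
  the five phenotype groups and mates at random within its group (group
  weight = phenotype-class frequency); the remaining ``1 - A`` mates at
  random.  Allele frequencies are conserved.
* ``wright_disassortative`` — the disassortative counterpart with three
  isolated groups (phenotype 0 x 4 crosses, 1 x 3 crosses, random mating
  within phenotype 2).  This model is selective: it changes allele
  frequencies.
* ``selective_I`` — matings occur at random but only the 18 same-phenotype
  matings are successful; their frequencies are renormalised and mixed with
  random mating in proportion ``A`` : ``1 - A``.
* ``selective_II`` — every mating is weighted by ``m = 1 - s*d/4``
  (assortative) or ``m_D = 1 - s*(4 - d)/4`` (disassortative), where ``d`` is
  the phenotypic difference between the mates, then renormalised.

Internally a distribution is stored as a symmetric 10x10 matrix of *ordered*
pair frequencies; the unordered frequency of a pair (i, j), i != j, is the
sum over both orderings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .core import PHENOTYPE_CLASSES, PHENOTYPES, PopulationState

__all__ = [
    "MatingDistribution",
    "ModelSpec",
    "MODEL_NAMES",
    "random_mating",
    "wright_assortative",
    "wright_disassortative",
    "selective_model_I",
    "selective_model_II",
    "mating_distribution",
    "mate_correlation",
]

MODEL_NAMES = (
    "wright_assortative",
    "wright_disassortative",
    "selective_I",
    "selective_II",
)

# |phenotype(i) - phenotype(j)| for every ordered genotype pair.
_PHEN_DIFF = np.abs(PHENOTYPES[:, None] - PHENOTYPES[None, :])
_SAME_PHEN = _PHEN_DIFF == 0

#: Number of unordered same-phenotype mating types (1+3+10+3+1).
N_ASSORTATIVE_MATINGS = sum(
    len(c) * (len(c) + 1) // 2 for c in PHENOTYPE_CLASSES
)


@dataclass(frozen=True)
class MatingDistribution:
    """Distribution over the 55 unordered mating types.

    ``M`` is the symmetric matrix of ordered pair frequencies (sums to 1);
    ``pair_frequency(i, j)`` gives the unordered frequency, which for i != j
    covers both reciprocal orderings.
    """

    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        if M.shape != (10, 10):
            raise ValueError("MatingDistribution requires a 10x10 matrix")
        if np.any(M < -1e-12) or abs(M.sum() - 1.0) > 1e-6:
            raise ValueError("mating frequencies must be >=0 and sum to 1")
        if not np.allclose(M, M.T, atol=1e-12):
            raise ValueError("ordered mating matrix must be symmetric")

    def pair_frequency(self, i: int, j: int) -> float:
        """Unordered frequency of mating type (i, j)."""
        if i == j:
            return float(self.M[i, i])
        return float(self.M[i, j] + self.M[j, i])

    def unordered(self) -> dict[tuple[int, int], float]:
        """All 55 unordered mating-type frequencies keyed by (i, j), i <= j."""
        return {
            (i, j): self.pair_frequency(i, j)
            for i in range(10)
            for j in range(i, 10)
        }

    def phenotype_pair_share(self, a: int, b: int) -> float:
        """Total frequency of matings pairing phenotype classes a and b."""
        mask = np.zeros((10, 10), dtype=bool)
        ia = np.array(PHENOTYPE_CLASSES[a])
        ib = np.array(PHENOTYPE_CLASSES[b])
        mask[np.ix_(ia, ib)] = True
        mask[np.ix_(ib, ia)] = True
        return float(self.M[mask].sum())


@dataclass(frozen=True)
class ModelSpec:
    """A mating system and its parameters.

    Parameters
    ----------
    model : str
        One of :data:`MODEL_NAMES`.
    A : float, optional
        Proportion mating assortatively (Wright models, model I), in [0, 1].
    s : float, optional
        Strength of mating selection (model II), in [0, 1].
    mode : {"assortative", "disassortative"}, optional
        Direction of the model II weighting (default assortative).
    c : float
        Recombination fraction between the loci, in [0, 0.5].
    """

    model: str
    c: float = 0.5
    A: Optional[float] = None
    s: Optional[float] = None
    mode: Literal["assortative", "disassortative"] = "assortative"

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODEL_NAMES}")
        if not 0.0 <= self.c <= 0.5:
            raise ValueError("recombination fraction c must lie in [0, 0.5]")
        if self.model == "selective_II":
            if self.s is None or not 0.0 <= self.s <= 1.0:
                raise ValueError("selective_II requires s in [0, 1]")
            if self.mode not in ("assortative", "disassortative"):
                raise ValueError("mode must be 'assortative' or 'disassortative'")
        else:
            if self.A is None or not 0.0 <= self.A <= 1.0:
                raise ValueError(f"{self.model} requires A in [0, 1]")


def _random_matrix(g: np.ndarray) -> np.ndarray:
    return np.outer(g, g)


def random_mating(state: PopulationState) -> MatingDistribution:
    """Random union: unordered freq 2*gi*gj for i != j, gi^2 for i = j."""
    return MatingDistribution(_random_matrix(state.g))


def _wright_assortative_matrix(g: np.ndarray, A: float) -> np.ndarray:
    R = _random_matrix(g)
    if A == 0.0:
        return R
    MA = np.zeros((10, 10))
    for members in PHENOTYPE_CLASSES:
        idx = np.array(members)
        f = g[idx].sum()
        if f > 0.0:
            # random mating within the group, group weighted by its frequency
            MA[np.ix_(idx, idx)] += np.outer(g[idx], g[idx]) / f
    return A * MA + (1.0 - A) * R


def wright_assortative(state: PopulationState, A: float) -> MatingDistribution:
    """Phenotype-group assortative mating: a proportion ``A`` mates at random
    within its own phenotype class, the rest at random in the whole
    population.  Conserves allele frequencies for every ``A`` and state."""
    if not 0.0 <= A <= 1.0:
        raise ValueError("A must lie in [0, 1]")
    return MatingDistribution(_wright_assortative_matrix(state.g, A))


# Disassortative groups: (left class, right class) crosses, phenotype 2 within.
_DIS_CROSS = ((0, 4), (1, 3))


def _wright_disassortative_matrix(g: np.ndarray, A: float) -> np.ndarray:
    R = _random_matrix(g)
    if A == 0.0:
        return R
    contributions: list[tuple[float, np.ndarray]] = []
    for a, b in _DIS_CROSS:
        ia = np.array(PHENOTYPE_CLASSES[a])
        ib = np.array(PHENOTYPE_CLASSES[b])
        fa, fb = g[ia].sum(), g[ib].sum()
        if fa > 0.0 and fb > 0.0:
            # mates drawn independently from each side's within-class
            # distribution; group weight = total frequency of both sides
            ua, ub = g[ia] / fa, g[ib] / fb
            cross = np.zeros((10, 10))
            cross[np.ix_(ia, ib)] = 0.5 * np.outer(ua, ub)
            cross[np.ix_(ib, ia)] = 0.5 * np.outer(ub, ua)
            contributions.append((fa + fb, cross))
    i2 = np.array(PHENOTYPE_CLASSES[2])
    f2 = g[i2].sum()
    if f2 > 0.0:
        within = np.zeros((10, 10))
        within[np.ix_(i2, i2)] = np.outer(g[i2], g[i2]) / f2 ** 2
        contributions.append((f2, within))
    total = sum(w for w, _ in contributions)
    if total <= 0.0:
        raise ValueError("degenerate state: no disassortative mating group is viable")
    # empty-side cross groups contribute nothing; their weight is
    # redistributed proportionally over the viable groups
    MD = sum((w / total) * m for w, m in contributions)
    return A * MD + (1.0 - A) * R


def wright_disassortative(state: PopulationState, A: float) -> MatingDistribution:
    """Phenotype-group disassortative mating: three isolated groups (0 x 4
    crosses, 1 x 3 crosses, phenotype 2 random within), mixed with random
    mating in proportion ``A`` : ``1 - A``.  Selective — changes allele
    frequencies."""
    if not 0.0 <= A <= 1.0:
        raise ValueError("A must lie in [0, 1]")
    return MatingDistribution(_wright_disassortative_matrix(state.g, A))


def _selective_I_matrix(g: np.ndarray, A: float) -> np.ndarray:
    R = _random_matrix(g)
    if A == 0.0:
        return R
    masked = np.where(_SAME_PHEN, R, 0.0)
    total = masked.sum()
    if total <= 0.0:
        raise ValueError("degenerate population: no same-phenotype mating has positive frequency")
    return A * (masked / total) + (1.0 - A) * R


def selective_model_I(state: PopulationState, A: float) -> MatingDistribution:
    """Random pairing followed by failure of all cross-phenotype matings: the
    18 same-phenotype mating frequencies are renormalised and mixed with
    random mating in proportion ``A`` : ``1 - A``."""
    if not 0.0 <= A <= 1.0:
        raise ValueError("A must lie in [0, 1]")
    return MatingDistribution(_selective_I_matrix(state.g, A))


def _selective_II_matrix(g: np.ndarray, s: float, mode: str) -> np.ndarray:
    if mode == "assortative":
        W = 1.0 - s * _PHEN_DIFF / 4.0
    elif mode == "disassortative":
        W = 1.0 - s * (4.0 - _PHEN_DIFF) / 4.0
    else:
        raise ValueError("mode must be 'assortative' or 'disassortative'")
    weighted = _random_matrix(g) * W
    total = weighted.sum()
    if total <= 0.0:
        raise ValueError("degenerate population: all mating weights are zero")
    return weighted / total


def selective_model_II(
    state: PopulationState, s: float, mode: str = "assortative"
) -> MatingDistribution:
    """Graduated mate preference: each mating is weighted by its phenotypic
    similarity, ``m = 1 - s*d/4`` (assortative) or ``m_D = 1 - s*(4 - d)/4``
    (disassortative), and the weighted frequencies renormalised."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    return MatingDistribution(_selective_II_matrix(state.g, s, mode))


def _mating_matrix(g: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Ordered mating matrix for raw genotype frequencies (dynamics hot path)."""
    if spec.model == "wright_assortative":
        return _wright_assortative_matrix(g, spec.A)
    if spec.model == "wright_disassortative":
        return _wright_disassortative_matrix(g, spec.A)
    if spec.model == "selective_I":
        return _selective_I_matrix(g, spec.A)
    return _selective_II_matrix(g, spec.s, spec.mode)


def mating_distribution(state: PopulationState, spec: ModelSpec) -> MatingDistribution:
    """Dispatch to the mating model named in ``spec``."""
    return MatingDistribution(_mating_matrix(state.g, spec))


def mate_correlation(md: MatingDistribution) -> float:
    """Pearson correlation of the mate phenotype pair, weighted by mating
    frequencies over the symmetrised (ordered) distribution.

    Returns ``nan`` when the phenotypic variance among mating individuals is
    zero (degenerate distribution).
    """
    M = md.M
    ph = PHENOTYPES.astype(float)
    marg = M.sum(axis=1)  # symmetric, so both marginals are equal
    mu = float(marg @ ph)
    dev = ph - mu
    var = float(marg @ dev ** 2)
    if var <= 1e-14:
        return math.nan
    cov = float(dev @ M @ dev)
    return cov / var
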
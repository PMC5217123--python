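"""State space, phenotype map, summary measures, and closed-form equilibria.

The model tracks two diallelic loci (alleles ``A0/A1`` and ``B0/B1``) in an
infinite, deterministic population.  The fundamental objects are the four
gamete frequencies and the ten two-locus genotype frequencies, where the two
double heterozygotes are kept distinct: the *coupling* heterozygote carries
gametes ``A0B0`` and ``A1B1``, the *repulsion* heterozygote carries ``A0B1``
and ``A1B0``.  The phenotype of a genotype is the number of subscript-1
alleles it carries (0-4), which defines the five phenotype classes used by
all mating models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAMETE_LABELS",
    "GENOTYPE_GAMETES",
    "GENOTYPE_LABELS",
    "PHENOTYPES",
    "PHENOTYPE_CLASSES",
    "COUPLING_HET",
    "REPULSION_HET",
    "GameteVector",
    "PopulationState",
    "MeasureSet",
    "phenotype",
    "hardy_weinberg_state",
    "linkage_D",
    "r_squared",
    "fixation_index",
    "dH",
    "closed_form_F_assortative",
    "closed_form_F_selfing",
    "wright_A1_equilibrium",
]

#: Gamete order used everywhere: index 0..3 = A0B0, A0B1, A1B0, A1B1.
GAMETE_LABELS = ("A0B0", "A0B1", "A1B0", "A1B1")

#: Number of subscript-1 alleles carried by each gamete.
_GAMETE_ONES = np.array([0, 1, 1, 2])

#: The ten genotypes as unordered gamete pairs (i <= j).  Maternal/paternal
#: origin is never tracked.
GENOTYPE_GAMETES = (
    (0, 0), (0, 1), (0, 2), (0, 3), (1, 1),
    (1, 2), (1, 3), (2, 2), (2, 3), (3, 3),
)

GENOTYPE_LABELS = tuple(
    f"{GAMETE_LABELS[i]}/{GAMETE_LABELS[j]}" for i, j in GENOTYPE_GAMETES
)

#: Index of the coupling (A0B0/A1B1) and repulsion (A0B1/A1B0) double
#: heterozygotes in the genotype order above.
COUPLING_HET = 3
REPULSION_HET = 5

#: Phenotypic value (count of A1/B1 alleles) per genotype: 0,1,1,2,2,2,3,2,3,4.
PHENOTYPES = np.array([_GAMETE_ONES[i] + _GAMETE_ONES[j] for i, j in GENOTYPE_GAMETES])

#: Genotype indices belonging to each phenotype class 0..4 (sizes 1,2,4,2,1).
PHENOTYPE_CLASSES = tuple(
    tuple(int(k) for k in np.flatnonzero(PHENOTYPES == p)) for p in range(5)
)

# Genotypes heterozygous at the A locus (one gamete in {A0B*}, one in {A1B*})
# and at the B locus, used for observed heterozygosities.
_HET_A = np.array([(i < 2) != (j < 2) for i, j in GENOTYPE_GAMETES])
_HET_B = np.array([(i % 2) != (j % 2) for i, j in GENOTYPE_GAMETES])

_TOL = 1e-9


def phenotype(genotype_id: int) -> int:
    """Phenotypic value (0-4) of a genotype: its count of A1/B1 alleles."""
    if not 0 <= int(genotype_id) < 10:
        raise ValueError(f"unknown genotype id {genotype_id!r}; expected 0..9")
    return int(PHENOTYPES[genotype_id])


@dataclass(frozen=True)
class GameteVector:
    """Frequencies of the four gametes A0B0, A0B1, A1B0, A1B1."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.shape != (4,):
            raise ValueError("GameteVector requires 4 frequencies")
        if np.any(x < -_TOL) or abs(x.sum() - 1.0) > 1e-6:
            raise ValueError(f"invalid gamete frequencies {x}: must be >=0 and sum to 1")

    @property
    def x00(self) -> float:
        return float(self.x[0])

    @property
    def x01(self) -> float:
        return float(self.x[1])

    @property
    def x10(self) -> float:
        return float(self.x[2])

    @property
    def x11(self) -> float:
        return float(self.x[3])

    # Allele frequencies are derived, never stored.
    @property
    def p0(self) -> float:
        """Frequency of allele A0."""
        return float(self.x[0] + self.x[1])

    @property
    def p1(self) -> float:
        return float(self.x[2] + self.x[3])

    @property
    def q0(self) -> float:
        """Frequency of allele B0."""
        return float(self.x[0] + self.x[2])

    @property
    def q1(self) -> float:
        return float(self.x[1] + self.x[3])


@dataclass(frozen=True)
class PopulationState:
    """Frequencies of the ten two-locus genotypes (coupling and repulsion
    double heterozygotes distinct), in the order of :data:`GENOTYPE_GAMETES`."""

    g: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "g", g)
        if g.shape != (10,):
            raise ValueError("PopulationState requires 10 genotype frequencies")
        if np.any(g < -_TOL) or abs(g.sum() - 1.0) > 1e-6:
            raise ValueError(f"invalid genotype frequencies: must be >=0 and sum to 1 (got sum {g.sum()})")

    def gametes(self) -> GameteVector:
        """Gamete pool obtained by splitting each genotype into its two
        constituent gametes (no recombination is applied here)."""
        x = np.zeros(4)
        for k, (i, j) in enumerate(GENOTYPE_GAMETES):
            x[i] += 0.5 * self.g[k]
            x[j] += 0.5 * self.g[k]
        return GameteVector(x)

    @property
    def p0(self) -> float:
        return self.gametes().p0

    @property
    def q0(self) -> float:
        return self.gametes().q0

    def observed_het_A(self) -> float:
        return float(self.g[_HET_A].sum())

    def observed_het_B(self) -> float:
        return float(self.g[_HET_B].sum())

    def observed_het_AB(self) -> float:
        """Frequency of double heterozygotes (coupling + repulsion)."""
        return float(self.g[COUPLING_HET] + self.g[REPULSION_HET])

    def swap_loci(self) -> "PopulationState":
        """The same population with the A and B locus labels exchanged."""
        # gamete relabelling: A0B0->A0B0, A0B1->A1B0, A1B0->A0B1, A1B1->A1B1
        perm = (0, 2, 1, 3)
        g = np.zeros(10)
        index = {pair: k for k, pair in enumerate(GENOTYPE_GAMETES)}
        for k, (i, j) in enumerate(GENOTYPE_GAMETES):
            a, b = sorted((perm[i], perm[j]))
            g[index[(a, b)]] += self.g[k]
        return PopulationState(g)


def gametes_of_state(state: PopulationState) -> GameteVector:
    """Functional alias for :meth:`PopulationState.gametes`."""
    return state.gametes()


def hardy_weinberg_state(p0: float, q0: float, D0: float = 0.0) -> PopulationState:
    """Population in random-union-of-gametes proportions.

    Gamete frequencies are ``(p0*q0 + D0, p0*q1 - D0, p1*q0 - D0, p1*q1 + D0)``
    and genotypes are formed by random union: ``x_i**2`` for homozygotes and
    ``2*x_i*x_j`` for unordered heterozygotes.

    Raises
    ------
    ValueError
        If ``D0`` pushes any gamete frequency outside ``[0, 1]`` (the message
        names the first violated gamete).
    """
    if not (0.0 <= p0 <= 1.0 and 0.0 <= q0 <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    p1, q1 = 1.0 - p0, 1.0 - q0
    x = np.array([p0 * q0 + D0, p0 * q1 - D0, p1 * q0 - D0, p1 * q1 + D0])
    for label, xi in zip(GAMETE_LABELS, x):
        if xi < -_TOL or xi > 1.0 + _TOL:
            raise ValueError(
                f"D0={D0} is infeasible: gamete {label} frequency {xi:.6g} outside [0, 1]"
            )
    x = np.clip(x, 0.0, 1.0)
    return state_from_gametes(GameteVector(x))


def state_from_gametes(gv: GameteVector) -> PopulationState:
    """Random union of gametes: ``x_i**2`` homozygotes, ``2*x_i*x_j`` heterozygotes."""
    g = np.empty(10)
    for k, (i, j) in enumerate(GENOTYPE_GAMETES):
        g[k] = gv.x[i] ** 2 if i == j else 2.0 * gv.x[i] * gv.x[j]
    return PopulationState(g)


def linkage_D(gv: GameteVector) -> float:
    """Linkage disequilibrium D = x00*x11 - x01*x10 (= x00 - p0*q0)."""
    d_prod = gv.x00 * gv.x11 - gv.x01 * gv.x10
    d_dev = gv.x00 - gv.p0 * gv.q0
    assert abs(d_prod - d_dev) < 1e-9, "the two D formulas disagree"
    return d_prod


def r_squared(gv: GameteVector) -> float:
    """Squared allelic correlation r^2 = D^2 / (p0*p1*q0*q1).

    Returns ``nan`` (undefined) when either locus is fixed; never silently 0.
    """
    denom = gv.p0 * gv.p1 * gv.q0 * gv.q1
    if denom <= 0.0:
        return math.nan
    return linkage_D(gv) ** 2 / denom


def fixation_index(state: PopulationState) -> float:
    """Fixation index F = (H_E - H_O) / H_E, averaged over the two loci.

    H_E is the Hardy-Weinberg expected heterozygosity from the current allele
    frequencies; F is computed per locus and the mean returned (the two are
    equal by construction in symmetric settings).  ``nan`` when a locus is
    monomorphic.
    """
    gv = state.gametes()
    he_a = 2.0 * gv.p0 * gv.p1
    he_b = 2.0 * gv.q0 * gv.q1
    if he_a <= 0.0 or he_b <= 0.0:
        return math.nan
    f_a = (he_a - state.observed_het_A()) / he_a
    f_b = (he_b - state.observed_het_B()) / he_b
    return 0.5 * (f_a + f_b)


def dH(state: PopulationState) -> float:
    """Two-locus identity disequilibrium d_H = H_O(AB) - H_O(A) * H_O(B).

    The excess of the double-heterozygote frequency over the product of the
    single-locus observed heterozygosities.
    """
    return state.observed_het_AB() - state.observed_het_A() * state.observed_het_B()


def closed_form_F_assortative(A: float) -> float:
    """Equilibrium fixation index F = A / (4 - 3A) for the Wright phenotype-
    group assortative model at equal allele frequencies 1/2."""
    if not 0.0 <= A <= 1.0:
        raise ValueError("A must lie in [0, 1]")
    return A / (4.0 - 3.0 * A)


def closed_form_F_selfing(S: float) -> float:
    """Equilibrium fixation index F = S / (2 - S) under partial selfing."""
    if not 0.0 <= S <= 1.0:
        raise ValueError("S must lie in [0, 1]")
    return S / (2.0 - S)


def wright_A1_equilibrium(p0: float, q0: float) -> tuple[GameteVector, float, float]:
    """Closed-form equilibrium gametes, D and r^2 for complete phenotype-group
    assortative mating (A = 1), independent of recombination.

    Three branches by sign of ``p0 - q0``; at ``p0 = q0`` only the coupling
    gametes survive and r^2 = 1.
    """
    if not (0.0 <= p0 <= 1.0 and 0.0 <= q0 <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    p1, q1 = 1.0 - p0, 1.0 - q0
    if p0 < q0:
        gv = GameteVector(np.array([p0, 0.0, q0 - p0, q1]))
        D = p0 * q1
        r2 = p0 * q1 / (p1 * q0) if p1 * q0 > 0 else math.nan
    elif p0 > q0:
        gv = GameteVector(np.array([q0, p0 - q0, 0.0, p1]))
        D = q0 * p1
        r2 = p1 * q0 / (p0 * q1) if p0 * q1 > 0 else math.nan
    else:
        gv = GameteVector(np.array([p0, 0.0, 0.0, p1]))
        D = p0 * p1
        r2 = 1.0 if 0.0 < p0 < 1.0 else math.nan
    return gv, D, r2


@dataclass(frozen=True)
class MeasureSet:
    """Summary measures of a population (optionally with its mating pattern).

    ``nan`` fields mean the measure is undefined for this state (a fixed locus
    or a degenerate mating distribution), never zero-by-convention.
    """

    D: float
    r2: float
    F: float
    dH: float
    mate_corr: float = field(default=math.nan)

    @classmethod
    def from_state(cls, state: PopulationState, mate_corr: float = math.nan) -> "MeasureSet":
        gv = state.gametes()
        return cls(
            D=linkage_D(gv),
            r2=r_squared(gv),
            F=fixation_index(state),
            dH=dH(state),
            mate_corr=mate_corr,
        )

    def rounded(self, ndigits: int = 4) -> dict[str, float | None]:
        """Presentation form: values rounded, undefined measures as None."""
        out: dict[str, float | None] = {}
        for name in ("D", "r2", "F", "dH", "mate_corr"):
            v = getattr(self, name)
            out[name] = None if math.isnan(v) else round(v, ndigits)
        return out
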
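"""Meiosis and offspring genotype frequencies.

Each parent genotype produces gametes Mendelianly; only the two double
heterozygotes are sensitive to the recombination fraction ``c``: the coupling
heterozygote A0B0/A1B1 emits its parental gametes with probability
``(1 - c)/2`` each and the recombinant (repulsion) gametes with ``c/2`` each,
and vice versa for the repulsion heterozygote A0B1/A1B0.  Offspring of a
mating are the random union of the two parents' gamete outputs, and the next
generation is the mating-frequency-weighted sum over all 55 mating types.
"""

from __future__ import annotations

import numpy as np

from .core import (
    COUPLING_HET,
    GENOTYPE_GAMETES,
    REPULSION_HET,
    GameteVector,
    PopulationState,
)
from .mating import MatingDistribution

__all__ = [
    "gamete_output",
    "gamete_output_table",
    "offspring_distribution",
    "offspring_tensor",
    "next_generation",
]

_PAIR_INDEX = {pair: k for k, pair in enumerate(GENOTYPE_GAMETES)}


def gamete_output_table(c: float) -> np.ndarray:
    """10 x 4 matrix of gamete production probabilities per genotype."""
    if not 0.0 <= c <= 0.5:
        raise ValueError("recombination fraction c must lie in [0, 0.5]")
    G = np.zeros((10, 4))
    for k, (i, j) in enumerate(GENOTYPE_GAMETES):
        G[k, i] += 0.5
        G[k, j] += 0.5
    # recombination reshuffles only the double heterozygotes
    G[COUPLING_HET] = [(1 - c) / 2, c / 2, c / 2, (1 - c) / 2]
    G[REPULSION_HET] = [c / 2, (1 - c) / 2, (1 - c) / 2, c / 2]
    return G


def gamete_output(genotype_id: int, c: float) -> GameteVector:
    """Gamete production probabilities of one genotype at recombination ``c``."""
    if not 0 <= int(genotype_id) < 10:
        raise ValueError(f"unknown genotype id {genotype_id!r}")
    return GameteVector(gamete_output_table(c)[genotype_id])


def offspring_tensor(c: float) -> np.ndarray:
    """10 x 10 x 10 tensor: O[i, j] is the offspring genotype distribution of
    the mating i x j (symmetric in the parents)."""
    G = gamete_output_table(c)
    # random union of one gamete from each parent, folded to unordered pairs
    O = np.zeros((10, 10, 10))
    for a in range(4):
        for b in range(4):
            k = _PAIR_INDEX[(min(a, b), max(a, b))]
            O[:, :, k] += np.outer(G[:, a], G[:, b])
    return O


def offspring_distribution(i: int, j: int, c: float) -> np.ndarray:
    """Offspring genotype distribution (10-vector) of mating type (i, j)."""
    return offspring_tensor(c)[i, j]


def next_generation(md: MatingDistribution, c: float) -> PopulationState:
    """Next generation's genotype frequencies: the offspring distributions of
    all 55 mating types weighted by their mating frequencies."""
    O = offspring_tensor(c)
    g = np.einsum("ij,ijk->k", md.M, O)
    return PopulationState(g)
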
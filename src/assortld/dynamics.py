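"""Fixed-point iteration of the mating -> reproduction map.

Every model here is a deterministic recursion on the ten genotype
frequencies — "simulation" means iterating that map, no randomness is
involved anywhere.  ``iterate`` runs one model to its equilibrium (or to
fixation), ``sweep`` tabulates equilibrium measures over a parameter grid,
and ``basin_scan`` maps initial allele frequencies to outcomes, locating the
boundaries of the polymorphic basin on the equal-frequency diagonal by
bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import MeasureSet, PopulationState, hardy_weinberg_state
from .mating import MatingDistribution, ModelSpec, _mating_matrix, mate_correlation
from .reproduction import offspring_tensor

__all__ = [
    "EquilibriumResult",
    "iterate",
    "sweep",
    "basin_scan",
    "diagonal_basin_boundaries",
]

#: Default convergence tolerance (L-infinity on genotype frequencies).  The
#: published equilibria are quoted to 3-4 significant digits and low-c runs
#: approach equilibrium slowly, so convergence is pushed deep.
DEFAULT_TOL = 1e-12
DEFAULT_MAX_GENS = 2_000_000

#: A population is called fixed when a single genotype exceeds this frequency.
FIXED_THRESHOLD = 1.0 - 1e-9

CLASSIFICATIONS = (
    "polymorphic_equilibrium",
    "fixed_A0B0",
    "fixed_A1B1",
    "fixed_other",
    "not_converged",
)


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of iterating one model from one starting state."""

    final_state: PopulationState
    measures: MeasureSet
    iterations: int
    converged: bool
    classification: str
    spec: ModelSpec
    trajectory: Optional[pd.DataFrame] = field(default=None, repr=False)

    def summary(self) -> dict:
        """Flat presentation record (measures rounded to 4 decimals)."""
        out = {
            "model": self.spec.model,
            "A": self.spec.A,
            "s": self.spec.s,
            "mode": self.spec.mode if self.spec.model == "selective_II" else None,
            "c": self.spec.c,
            "iterations": self.iterations,
            "converged": self.converged,
            "classification": self.classification,
        }
        out.update(self.measures.rounded())
        return out


def _classify(g: np.ndarray, converged: bool) -> str:
    top = int(np.argmax(g))
    if g[top] > FIXED_THRESHOLD:
        return {0: "fixed_A0B0", 9: "fixed_A1B1"}.get(top, "fixed_other")
    return "polymorphic_equilibrium" if converged else "not_converged"


def iterate(
    state0: PopulationState,
    spec: ModelSpec,
    max_gens: int = DEFAULT_MAX_GENS,
    tol: float = DEFAULT_TOL,
    record_trajectory: bool = False,
) -> EquilibriumResult:
    """Iterate mating -> reproduction until the genotype frequencies stop
    moving (L-infinity change < ``tol``) or ``max_gens`` is reached.

    Measures (D, r^2, F, d_H and the mate correlation of the final mating
    distribution) are evaluated at the final state.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    O = offspring_tensor(spec.c)
    g = state0.g.copy()
    records = [] if record_trajectory else None
    converged = False
    gens = 0
    for gens in range(1, max_gens + 1):
        M = _mating_matrix(g, spec)
        g_next = np.einsum("ij,ijk->k", M, O)
        if not np.all(np.isfinite(g_next)):
            raise ArithmeticError("non-finite genotype frequencies during iteration")
        # guard against float drift in the total: the renormalising models
        # amplify any deficit in sum(g) exponentially across generations
        g_next /= g_next.sum()
        delta = float(np.max(np.abs(g_next - g)))
        g = g_next
        if records is not None:
            records.append(_trajectory_row(gens, g))
        if delta < tol:
            converged = True
            break
    final = PopulationState(g)
    measures = MeasureSet.from_state(
        final, mate_corr=mate_correlation(MatingDistribution(_mating_matrix(g, spec)))
    )
    trajectory = pd.DataFrame(records) if records is not None else None
    return EquilibriumResult(
        final_state=final,
        measures=measures,
        iterations=gens,
        converged=converged,
        classification=_classify(g, converged),
        spec=spec,
        trajectory=trajectory,
    )


def _trajectory_row(gen: int, g: np.ndarray) -> dict:
    state = PopulationState(g)
    gv = state.gametes()
    m = MeasureSet.from_state(state)
    return {
        "generation": gen,
        "p0": gv.p0,
        "q0": gv.q0,
        "D": m.D,
        "r2": m.r2,
        "F": m.F,
        "dH": m.dH,
    }


def sweep(
    spec_template: ModelSpec,
    param_name: str,
    grid,
    initial: PopulationState,
    max_gens: int = DEFAULT_MAX_GENS,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Equilibrium measures over a parameter grid.

    One row per grid point with columns (param value, D, r2, F, dH,
    mate_corr, iterations, classification); a failing point is flagged in an
    ``error`` column rather than aborting the sweep.
    """
    rows = []
    for value in grid:
        row: dict = {param_name: float(value), "error": None}
        try:
            spec = replace(spec_template, **{param_name: float(value)})
            res = iterate(initial, spec, max_gens=max_gens, tol=tol)
            row.update(
                D=res.measures.D,
                r2=res.measures.r2,
                F=res.measures.F,
                dH=res.measures.dH,
                mate_corr=res.measures.mate_corr,
                iterations=res.iterations,
                classification=res.classification,
            )
        except (ValueError, ArithmeticError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    columns = [
        param_name, "error", "D", "r2", "F", "dH",
        "mate_corr", "iterations", "classification",
    ]
    return pd.DataFrame(rows, columns=columns)


def _classify_start(
    p0: float,
    q0: float,
    D0: float,
    spec: ModelSpec,
    max_gens: int,
    tol: float,
) -> str:
    res = iterate(hardy_weinberg_state(p0, q0, D0), spec, max_gens=max_gens, tol=tol)
    if res.classification == "not_converged":
        # near-boundary slow dynamics: decide by where the allele frequencies
        # ended up rather than guessing from the unconverged state
        gv = res.final_state.gametes()
        if min(gv.p0, gv.p1, gv.q0, gv.q1) < 1e-3:
            return "fixed_other"
    return res.classification


def basin_scan(
    spec: ModelSpec,
    freq_grid,
    D0: float = 0.0,
    max_gens: int = 200_000,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Classify the outcome for every (p0_init, q0_init) on a grid.

    Returns a long-format table with columns p0_init, q0_init,
    classification.  Infeasible (p0, q0, D0) combinations are flagged.
    """
    rows = []
    for p0 in freq_grid:
        for q0 in freq_grid:
            row = {"p0_init": float(p0), "q0_init": float(q0)}
            try:
                row["classification"] = _classify_start(
                    float(p0), float(q0), D0, spec, max_gens, tol
                )
            except ValueError as exc:
                row["classification"] = f"error: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def diagonal_basin_boundaries(
    spec: ModelSpec,
    D0: float = 0.0,
    resolution: float = 1e-3,
    max_gens: int = 200_000,
    tol: float = DEFAULT_TOL,
) -> tuple[float, float]:
    """Boundaries of the polymorphic basin on the equal-initial-frequency
    diagonal, located by bisection to ``resolution``.

    Assumes 1/2 is inside the basin (it is for every model here when a
    polymorphic equilibrium exists); returns (lower, upper).  Raises if the
    centre itself is not polymorphic.
    """

    def polymorphic(p: float) -> bool:
        return (
            _classify_start(p, p, D0, spec, max_gens, tol)
            == "polymorphic_equilibrium"
        )

    if not polymorphic(0.5):
        raise ValueError("no polymorphic equilibrium at equal frequencies 1/2")

    def bisect(outside: float, inside: float) -> float:
        # invariant: polymorphic(inside) and not polymorphic(outside)
        while abs(inside - outside) > resolution:
            mid = 0.5 * (inside + outside)
            if polymorphic(mid):
                inside = mid
            else:
                outside = mid
        return 0.5 * (inside + outside)

    eps = 1e-3
    lower = bisect(eps, 0.5) if not polymorphic(eps) else 0.0
    upper = bisect(1.0 - eps, 0.5) if not polymorphic(1.0 - eps) else 1.0
    return lower, upper
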
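"""Deterministic serial-propagation model for a compartmentalized consortium.

One propagation round: the pooled population (described only by its cell-type
fractions) is diluted into a fresh emulsion with Poisson(lam) founders per
droplet, every droplet grows to endpoint, and all droplets are pooled again.
Treating the emulsion as infinitely many droplets, the pooled update is exact
in expectation and needs only the *expected per-cell growth factor* of each
type,

    G_i = sum over compositions c containing a type-i cell of
          P(cell of type i lands in c) * g_i(c),

followed by the fraction update f_i' = f_i G_i / sum_j f_j G_j. The
cell-centric probability is the size-biased Poisson/multinomial law from
:mod:`dropcoop.founder_stats`; g_i(c) is the per-cell growth factor of type i
in composition c from :mod:`dropcoop.growth_rules`. Sums are truncated at the
occupancy model's ``n_max`` companions and renormalized over the retained
support.

This captures the group-selection effect (a Simpson's paradox): cheaters
out-reproduce cooperators inside every shared droplet, yet cooperators can
increase in the pool because droplet compositions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founder_stats import (
    OccupancyModel,
    compositions_up_to,
    multinomial_pmf,
    poisson_pmf,
)
from .growth_rules import ConsortiumSpec, GrowthParams, grow_compositions

__all__ = [
    "PopulationState",
    "GrowthFactors",
    "Trajectory",
    "expected_growth_factors",
    "expected_growth_factors_compartment_centric",
    "update_fractions",
    "propagate",
    "cooperator_advantage",
]


@dataclass(frozen=True)
class PopulationState:
    """Cell-type fractions of the pooled population at one propagation."""

    fractions: np.ndarray
    propagation_index: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if np.any(f < 0):
            raise ValueError(f"fractions must be >= 0, got {f}")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got sum {f.sum()}")


@dataclass(frozen=True)
class GrowthFactors:
    """Expected per-cell growth factor per type for one propagation round."""

    per_type: np.ndarray
    cooperator_advantage: float


@dataclass
class Trajectory:
    """States and growth factors over serial propagations, round 0..R."""

    states: list[PopulationState]
    growth_factors: list[GrowthFactors]
    type_names: tuple[str, ...] = field(default_factory=tuple)

    def fractions_matrix(self) -> np.ndarray:
        return np.vstack([s.fractions for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        """One row per propagation: round, fractions, growth factors, advantage.

        Growth factors on row r are those applied going from round r to
        round r+1 (NaN on the final row).
        """
        names = self.type_names or tuple(
            f"type_{i}" for i in range(len(self.states[0].fractions))
        )
        rows = []
        for r, s in enumerate(self.states):
            row: dict[str, float] = {"round": r}
            for name, f in zip(names, s.fractions):
                row[f"fraction_{name}"] = f
            if r < len(self.growth_factors):
                gf = self.growth_factors[r]
                for name, g in zip(names, gf.per_type):
                    row[f"G_{name}"] = g
                row["cooperator_advantage"] = gf.cooperator_advantage
            else:
                for name in names:
                    row[f"G_{name}"] = np.nan
                row["cooperator_advantage"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)


class _GrowthTable:
    """Precomputed compositions, growth factors and Poisson weights.

    Everything here depends only on (occupancy, consortium, params), not on
    the population fractions, so a serial propagation builds it once.
    """

    def __init__(
        self, occ: OccupancyModel, consortium: ConsortiumSpec, params: GrowthParams
    ):
        self.occ = occ
        self.consortium = consortium
        k = consortium.n_types
        # A focal cell plus up to n_max companions.
        comps = compositions_up_to(occ.n_max + 1, k)
        comps = comps[comps.sum(axis=1) >= 1]
        self.comps = comps
        finals = grow_compositions(comps, consortium, params)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.g = np.where(comps > 0, finals / np.where(comps > 0, comps, 1), np.nan)
        self.totals = comps.sum(axis=1)
        self.pois_companions = poisson_pmf(occ.lam, self.totals - 1)

    def expected_growth_factors(self, fractions: np.ndarray) -> np.ndarray:
        """G_i for every type via the cell-centric (size-biased) sum."""
        k = self.consortium.n_types
        G = np.empty(k)
        for i in range(k):
            mask = self.comps[:, i] >= 1
            companions = self.comps[mask].copy()
            companions[:, i] -= 1
            w = self.pois_companions[mask] * multinomial_pmf(companions, fractions)
            norm = w.sum()  # retained cell-centric mass, ~1 - tail_tol
            G[i] = float(w @ self.g[mask, i] / norm)
        return G


def cooperator_advantage(gf: GrowthFactors | np.ndarray, consortium: ConsortiumSpec) -> float:
    """Mean cooperator growth factor minus the cheater's.

    Positive values predict cooperator enrichment over propagations.
    """
    per_type = gf.per_type if isinstance(gf, GrowthFactors) else np.asarray(gf)
    coop = consortium.cooperator_indices
    cheat = consortium.cheater_indices
    if len(cheat) != 1:
        raise ValueError(f"expected exactly one cheater type, found {len(cheat)}")
    return float(np.mean(per_type[list(coop)]) - per_type[cheat[0]])


def expected_growth_factors(
    state: PopulationState,
    occ: OccupancyModel,
    consortium: ConsortiumSpec,
    params: GrowthParams,
) -> GrowthFactors:
    """Expected per-cell growth factors for one round at the current fractions.

    Types at fraction 0 get their hypothetical per-cell factor (what a single
    invading cell of that type would experience), which supports invasion
    analyses without special-casing.
    """
    f = state.fractions
    if not np.any(f > 0):
        raise ValueError("all fractions are zero")
    if occ.lam <= 0:
        raise ValueError("occupancy lam must be > 0 for a propagation round")
    table = _GrowthTable(occ, consortium, params)
    G = table.expected_growth_factors(f)
    return GrowthFactors(per_type=G, cooperator_advantage=cooperator_advantage(G, consortium))


def expected_growth_factors_compartment_centric(
    state: PopulationState,
    occ: OccupancyModel,
    consortium: ConsortiumSpec,
    params: GrowthParams,
) -> GrowthFactors:
    """The same G_i by the compartment-centric route E[n_i g_i] / E[n_i].

    Weights each composition by its droplet probability pmf(total) *
    multinomial(comp) and by the focal-type count n_i. Mathematically
    identical (term by term, via Poisson size-biasing) to the cell-centric
    sum; kept as an independent computation path for cross-checking.
    """
    f = state.fractions
    k = consortium.n_types
    comps = compositions_up_to(occ.n_max + 1, k)
    comps = comps[comps.sum(axis=1) >= 1]
    finals = grow_compositions(comps, consortium, params)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(comps > 0, finals / np.where(comps > 0, comps, 1), 0.0)
    totals = comps.sum(axis=1)
    p_comp = poisson_pmf(occ.lam, totals) * multinomial_pmf(comps, f)
    G = np.empty(k)
    for i in range(k):
        num = float((comps[:, i] * p_comp) @ g[:, i])
        den = float((comps[:, i] * p_comp).sum())
        if den == 0.0:
            # fraction-zero type: fall back to the invasion (cell-centric) value
            mask = comps[:, i] >= 1
            companions = comps[mask].copy()
            companions[:, i] -= 1
            w = poisson_pmf(occ.lam, companions.sum(axis=1)) * multinomial_pmf(
                companions, f
            )
            G[i] = float(w @ g[mask, i] / w.sum())
        else:
            G[i] = num / den
    return GrowthFactors(per_type=G, cooperator_advantage=cooperator_advantage(G, consortium))


def update_fractions(state: PopulationState, gf: GrowthFactors) -> PopulationState:
    """Multiplicative fraction update f_i' = f_i G_i / sum_j f_j G_j."""
    f = state.fractions
    # Absent types stay absent regardless of their (possibly hypothetical,
    # possibly NaN) growth factor.
    weighted = np.where(f > 0, f * gf.per_type, 0.0)
    total = weighted.sum()
    if total <= 0:
        raise ValueError("population extinct: sum of fraction-weighted growth is 0")
    return PopulationState(
        fractions=weighted / total, propagation_index=state.propagation_index + 1
    )


def propagate(
    state0: PopulationState,
    rounds: int,
    occ: OccupancyModel,
    consortium: ConsortiumSpec,
    params: GrowthParams,
) -> Trajectory:
    """Iterate the expected-growth-factor update for ``rounds`` propagations."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    table = _GrowthTable(occ, consortium, params)
    states = [state0]
    gfs: list[GrowthFactors] = []
    state = state0
    for _ in range(rounds):
        G = table.expected_growth_factors(state.fractions)
        gf = GrowthFactors(
            per_type=G, cooperator_advantage=cooperator_advantage(G, consortium)
        )
        gfs.append(gf)
        state = update_fractions(state, gf)
        states.append(state)
    return Trajectory(states=states, growth_factors=gfs, type_names=consortium.names)
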
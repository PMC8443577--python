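"""Stochastic finite-droplet Monte-Carlo simulator.

The brute-force counterpart of the expectation model in
:mod:`dropcoop.propagation`: a finite number of droplets is inoculated
(founder count per droplet ~ Poisson(lam), types i.i.d. from the pooled
fractions), each droplet grows to endpoint, and final cells are pooled. With
many droplets the realized one-round update converges to the deterministic
model (law of large numbers); with few droplets it exhibits genetic drift,
including stochastic cheater fixation that the expectation model cannot show.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_rules import (
    ConsortiumSpec,
    GrowthParams,
    ROLE_COOPERATOR_A,
    ROLE_COOPERATOR_B,
    grow_compositions,
)
from .propagation import GrowthFactors, PopulationState, cooperator_advantage

__all__ = ["EmulsionRun", "simulate_emulsion", "serial_simulate", "suspension_limit"]


@dataclass
class EmulsionRun:
    """One stochastic emulsion round: sampled founders and pooled endpoint."""

    n_droplets: int
    seed: int | None
    per_droplet_founders: np.ndarray  # (n_droplets, n_types) int
    pooled_counts: np.ndarray  # (n_types,) float, summed endpoint cells
    realized_fractions: np.ndarray  # pooled proportions (NaN if nothing grew)
    status: str = "ok"  # "ok" | "extinct"

    def founders_frame(self) -> pd.DataFrame:
        """Per-droplet founder table for debugging/inspection."""
        n = self.per_droplet_founders.shape[1]
        df = pd.DataFrame(
            self.per_droplet_founders, columns=[f"founders_{i}" for i in range(n)]
        )
        df.insert(0, "droplet", np.arange(self.n_droplets))
        return df


def _sample_founders(
    rng: np.random.Generator, fractions: np.ndarray, lam: float, n_droplets: int
) -> np.ndarray:
    totals = rng.poisson(lam, size=n_droplets)
    founders = np.zeros((n_droplets, fractions.shape[0]), dtype=np.int64)
    # Group droplets by total so each unique total is one multinomial batch.
    for t in np.unique(totals):
        if t == 0:
            continue
        idx = np.nonzero(totals == t)[0]
        founders[idx] = rng.multinomial(int(t), fractions, size=idx.size)
    return founders


def simulate_emulsion(
    state: PopulationState,
    lam: float,
    n_droplets: int,
    consortium: ConsortiumSpec,
    params: GrowthParams,
    seed: int | np.random.Generator | None = None,
) -> EmulsionRun:
    """Sample one emulsion round and pool the endpoint cells.

    ``seed`` may be an integer, a ``numpy.random.Generator`` (for chaining),
    or None. Identical inputs and integer seed give bit-identical results.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    founders = _sample_founders(rng, state.fractions, lam, n_droplets)

    occupied = founders.sum(axis=1) > 0
    if not np.any(occupied):
        k = consortium.n_types
        return EmulsionRun(
            n_droplets=n_droplets,
            seed=seed if isinstance(seed, int) else None,
            per_droplet_founders=founders,
            pooled_counts=np.zeros(k),
            realized_fractions=np.full(k, np.nan),
            status="extinct",
        )

    # Grow each unique composition once and weight by its droplet count.
    uniq, counts = np.unique(founders[occupied], axis=0, return_counts=True)
    finals = grow_compositions(uniq, consortium, params)
    pooled = (counts[:, None] * finals).sum(axis=0)
    total = pooled.sum()
    return EmulsionRun(
        n_droplets=n_droplets,
        seed=seed if isinstance(seed, int) else None,
        per_droplet_founders=founders,
        pooled_counts=pooled,
        realized_fractions=pooled / total,
        status="ok",
    )


def serial_simulate(
    state0: PopulationState,
    rounds: int,
    lam: float,
    n_droplets: int,
    consortium: ConsortiumSpec,
    params: GrowthParams,
    seed: int | None = None,
) -> list[EmulsionRun]:
    """Serial propagation with a fresh finite emulsion each round.

    Each round pools the previous round's realized fractions and
    re-inoculates at the same lam, mimicking the experimental re-dilution.
    If a round leaves no cells, the run is truncated with the final run's
    status set to ``"extinct"``.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    runs: list[EmulsionRun] = []
    state = state0
    for _ in range(rounds):
        run = simulate_emulsion(state, lam, n_droplets, consortium, params, seed=rng)
        runs.append(run)
        if run.status == "extinct":
            break
        state = PopulationState(
            fractions=run.realized_fractions,
            propagation_index=state.propagation_index + 1,
        )
    return runs


def suspension_limit(
    state: PopulationState,
    consortium: ConsortiumSpec,
    params: GrowthParams,
    inoculum_fraction: float = 1.5e-3,
) -> GrowthFactors:
    """Growth factors for well-mixed suspension propagation (no droplets).

    The suspension is one compartment seeded with the whole population at its
    own fractions — the limit of a single droplet with a very large founder
    population. ``inoculum_fraction`` is the inoculum density relative to the
    carrying capacity (default 1.5e-3, i.e. 3e6 cells/mL into a medium
    supporting 2e9 cells/mL). All types with fraction > 0 are co-resident, so
    whenever both cooperators are present the compartment fills to capacity
    and the cheater's per-cell growth exceeds the cooperators' by its pool
    weight — in suspension the cheater always wins.
    """
    f = state.fractions
    if not np.any(f > 0):
        raise ValueError("all fractions are zero")
    K = params.carrying_capacity
    n0 = inoculum_fraction * K
    founders = f * n0
    founded = founders > 0
    B = consortium.backgrounds
    w = consortium.weights

    a_idx = list(consortium.role_indices(ROLE_COOPERATOR_A))
    b_idx = list(consortium.role_indices(ROLE_COOPERATOR_B))
    pair = founded[a_idx].any() and founded[b_idx].any()

    base = np.where(founded, B, 0.0)
    wcounts = founders * w
    if pair:
        pool = max(0.0, K - base.sum())
        alloc = base + pool * wcounts / wcounts.sum()
    else:
        alloc = base
    final = np.where(founded, np.maximum(founders, alloc), 0.0)
    tot = final.sum()
    if tot > K and founders.sum() < K:
        factor = (K - founders.sum()) / (tot - founders.sum())
        final = founders + (final - founders) * max(0.0, min(1.0, factor))
    G = np.where(founded, final / np.where(founded, founders, 1.0), np.nan)
    # Absent types: hypothetical factor for an infinitesimal invader sharing
    # the same pool (background ceiling dominates at zero abundance).
    return GrowthFactors(
        per_type=G, cooperator_advantage=cooperator_advantage(np.nan_to_num(G, nan=0.0), consortium)
    )
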
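"""Endpoint growth of one droplet compartment given its founder composition.

The consortium is a bidirectional cross-feeding pair (cooperator A secretes
the carbon source cooperator B needs; B liberates the nitrogen source A
needs) plus a cheater that consumes both public goods and produces neither.
Growth over one incubation is modelled at endpoint only:

* each cell type founded in the compartment can reach its
  cooperation-independent *background capacity* ``B_i`` (a per-compartment
  ceiling for that type, regardless of how many founders of the type are
  present);
* if at least one cooperator A *and* one cooperator B cell are present (a
  cooperator pair), the compartment additionally fills up to the carrying
  capacity ``K``: the cooperative pool ``K - sum(B_i over founded types)`` is
  shared among all founded cells in proportion to ``founder_count * weight``,
  where the cheater's weight ``1 + s_c`` expresses its per-cell growth
  advantage over cooperators when consuming shared public goods;
* founder cells persist through the incubation, so a type's final count is
  never below its founder count (growth factors are >= 1).

If the summed targets would exceed ``K`` (possible only for extreme
cost/benefit parameterizations where several background capacities sum past
the carrying capacity), above-founder growth is scaled down proportionally so
the compartment total never exceeds ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founder_stats import Composition


__all__ = [
    "ROLE_COOPERATOR_A",
    "ROLE_COOPERATOR_B",
    "ROLE_CHEATER",
    "CellTypeSpec",
    "ConsortiumSpec",
    "GrowthParams",
    "CompartmentOutcome",
    "has_cooperator_pair",
    "grow_compartment",
    "grow_compositions",
    "scenario_preset",
    "from_cost_benefit",
    "SCENARIO_NAMES",
    "DEFAULT_CHEATER_ADVANTAGE",
]

ROLE_COOPERATOR_A = "cooperator_A"
ROLE_COOPERATOR_B = "cooperator_B"
ROLE_CHEATER = "cheater"
_ROLES = (ROLE_COOPERATOR_A, ROLE_COOPERATOR_B, ROLE_CHEATER)

#: Cheater growth advantage s_c used throughout unless overridden.
DEFAULT_CHEATER_ADVANTAGE = 0.40

SCENARIO_NAMES = ("dependent", "costless_background", "costly_background")


@dataclass(frozen=True)
class CellTypeSpec:
    """One cell type: its role, background capacity B_i and pool weight w_i."""

    name: str
    role: str
    background_capacity: float
    coop_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {_ROLES}")
        if self.background_capacity < 0:
            raise ValueError("background_capacity must be >= 0")
        if self.coop_weight <= 0:
            raise ValueError("coop_weight must be > 0")


@dataclass(frozen=True)
class ConsortiumSpec:
    """The cell types of the consortium, in a fixed order."""

    types: tuple[CellTypeSpec, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ValueError("a consortium needs at least 2 cell types")

    @property
    def n_types(self) -> int:
        return len(self.types)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.types)

    @property
    def backgrounds(self) -> np.ndarray:
        return np.array([t.background_capacity for t in self.types], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([t.coop_weight for t in self.types], dtype=float)

    def role_indices(self, role: str) -> tuple[int, ...]:
        return tuple(i for i, t in enumerate(self.types) if t.role == role)

    @property
    def cooperator_indices(self) -> tuple[int, ...]:
        return self.role_indices(ROLE_COOPERATOR_A) + self.role_indices(
            ROLE_COOPERATOR_B
        )

    @property
    def cheater_indices(self) -> tuple[int, ...]:
        return self.role_indices(ROLE_CHEATER)


@dataclass(frozen=True)
class GrowthParams:
    """Compartment-level growth parameters.

    ``carrying_capacity`` (K) is the maximum total cells one droplet
    supports. ``benefit_fraction`` and ``cost_percent`` record the
    cost/benefit axes a consortium was derived from (see
    :func:`from_cost_benefit`); growth itself only uses K together with the
    per-type background capacities stored on the consortium.
    """

    carrying_capacity: float
    benefit_fraction: float = 1.0
    cost_percent: float = 0.0

    def __post_init__(self) -> None:
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be > 0")
        if not 0.0 <= self.benefit_fraction <= 1.0:
            raise ValueError("benefit_fraction must be in [0, 1]")
        if not 0.0 <= self.cost_percent <= 100.0:
            raise ValueError("cost_percent must be in [0, 100]")


@dataclass(frozen=True)
class CompartmentOutcome:
    """Endpoint cell counts and per-cell growth factors for one compartment."""

    final_counts: np.ndarray
    growth_factors: np.ndarray  # NaN for types not founded


def has_cooperator_pair(comp: Composition, consortium: ConsortiumSpec) -> bool:
    """True iff at least one cooperator A and one cooperator B cell are present."""
    counts = comp.counts
    if len(counts) != consortium.n_types:
        raise ValueError("composition length does not match consortium")
    has_a = any(counts[i] >= 1 for i in consortium.role_indices(ROLE_COOPERATOR_A))
    has_b = any(counts[i] >= 1 for i in consortium.role_indices(ROLE_COOPERATOR_B))
    return has_a and has_b


def grow_compositions(
    comps: np.ndarray, consortium: ConsortiumSpec, params: GrowthParams
) -> np.ndarray:
    """Vectorized endpoint growth: final counts for each composition row.

    ``comps`` has shape (N, n_types); rows may include the empty compartment
    (final counts all zero). Returns an (N, n_types) float array.
    """
    comps = np.atleast_2d(np.asarray(comps, dtype=float))
    if comps.shape[1] != consortium.n_types:
        raise ValueError("composition width does not match consortium")
    K = params.carrying_capacity
    B = consortium.backgrounds
    w = consortium.weights

    founded = comps > 0
    base = np.where(founded, B[None, :], 0.0)

    a_idx = list(consortium.role_indices(ROLE_COOPERATOR_A))
    b_idx = list(consortium.role_indices(ROLE_COOPERATOR_B))
    pair = founded[:, a_idx].any(axis=1) & founded[:, b_idx].any(axis=1)

    wcounts = comps * w[None, :]
    denom = wcounts.sum(axis=1)
    pool = np.where(pair, np.clip(K - base.sum(axis=1), 0.0, None), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(denom[:, None] > 0, wcounts / denom[:, None], 0.0)
    alloc = base + pool[:, None] * share

    final = np.maximum(comps, alloc)  # persistence floor; zero where not founded
    final[~founded] = 0.0

    # Cap at K: scale the above-founder part down where the total overshoots.
    tot = final.sum(axis=1)
    over = tot > K
    if np.any(over):
        ftot = comps.sum(axis=1)
        excess = final - comps
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(
                tot - ftot > 0, np.clip((K - ftot) / (tot - ftot), 0.0, 1.0), 0.0
            )
        final = np.where(over[:, None], comps + excess * factor[:, None], final)
    return final


def grow_compartment(
    comp: Composition, consortium: ConsortiumSpec, params: GrowthParams
) -> CompartmentOutcome:
    """Endpoint growth of a single compartment; errors on an empty one."""
    if comp.total < 1:
        raise ValueError("cannot grow an empty compartment")
    counts = comp.as_array().astype(float)
    final = grow_compositions(counts[None, :], consortium, params)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        gf = np.where(counts > 0, final / np.where(counts > 0, counts, 1.0), np.nan)
    return CompartmentOutcome(final_counts=final, growth_factors=gf)


def _standard_consortium(
    backgrounds: tuple[float, float, float], s_c: float
) -> ConsortiumSpec:
    b_a, b_b, b_c = backgrounds
    return ConsortiumSpec(
        types=(
            CellTypeSpec("cooperator_A", ROLE_COOPERATOR_A, b_a, 1.0),
            CellTypeSpec("cooperator_B", ROLE_COOPERATOR_B, b_b, 1.0),
            CellTypeSpec("cheater", ROLE_CHEATER, b_c, 1.0 + s_c),
        )
    )


def scenario_preset(
    name: str,
    K: float = 750.0,
    s_c: float = DEFAULT_CHEATER_ADVANTAGE,
) -> tuple[ConsortiumSpec, GrowthParams]:
    """The three named growth scenarios.

    ``dependent``: no background growth at all — cheaters (and lone
    cooperators) need a cooperator pair to grow. ``costless_background``: all
    three types independently reach 20% of K. ``costly_background``:
    cooperation is costly — cooperators independently reach only 10% of K
    while cheaters still reach 20%.
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    if name == "dependent":
        backgrounds = (0.0, 0.0, 0.0)
        benefit, cost = 1.0, 0.0
    elif name == "costless_background":
        backgrounds = (0.2 * K, 0.2 * K, 0.2 * K)
        benefit, cost = 0.8, 0.0
    elif name == "costly_background":
        backgrounds = (0.1 * K, 0.1 * K, 0.2 * K)
        benefit, cost = 0.8, 50.0
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    return (
        _standard_consortium(backgrounds, s_c),
        GrowthParams(K, benefit_fraction=benefit, cost_percent=cost),
    )


def from_cost_benefit(
    benefit_fraction: float,
    cost_percent: float,
    K: float = 750.0,
    s_c: float = DEFAULT_CHEATER_ADVANTAGE,
) -> tuple[ConsortiumSpec, GrowthParams]:
    """Map cost/benefit phase-diagram axes to concrete background capacities.

    The benefit of cooperation is the fraction of K that can only be filled
    in the presence of a cooperator pair, so the cheater independently
    reaches ``B_cheater = (1 - benefit) * K``. The cost of cooperation is the
    percentage difference between cheater and cooperator independent growth:
    ``B_coop = (1 - cost/100) * B_cheater`` for both cooperators.
    """
    params = GrowthParams(
        K, benefit_fraction=benefit_fraction, cost_percent=cost_percent
    )  # validates ranges
    b_cheater = (1.0 - benefit_fraction) * K
    b_coop = (1.0 - cost_percent / 100.0) * b_cheater
    return _standard_consortium((b_coop, b_coop, b_cheater), s_c), params
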
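"""Experiment pipelines over the propagation model.

Each pipeline is a pure function of its configuration (and seed, where
randomness is involved) returning tidy :class:`pandas.DataFrame` tables:

* :func:`optimal_lambda` — which average founder population size enriches
  cooperators fastest for given starting fractions;
* :func:`run_scenario_grid` — serial-propagation trajectories for the three
  named growth scenarios over a grid of starting fractions;
* :func:`run_lambda_sweep` — cooperator advantage vs lambda over randomly
  sampled cost/benefit parameter sets (the three-regime picture: too few
  cells, cooperators never meet; too many, cheaters always share; an
  intermediate lambda maximizes the cooperator advantage);
* :func:`run_phase_diagram` — final cheater fraction over the cooperation
  cost/benefit plane after many propagations;
* :func:`lambda_from_protocol` — emulsion arithmetic mapping the wet-lab
  protocol (droplet diameter, cell concentration) to lambda and the
  carrying capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founder_stats import OccupancyModel
from .growth_rules import (
    ConsortiumSpec,
    DEFAULT_CHEATER_ADVANTAGE,
    GrowthParams,
    from_cost_benefit,
    scenario_preset,
)
from .propagation import (
    PopulationState,
    cooperator_advantage,
    expected_growth_factors,
    propagate,
    update_fractions,
)

__all__ = [
    "SweepSpec",
    "PhaseDiagramSpec",
    "EmulsionPhysics",
    "optimal_lambda",
    "run_scenario_grid",
    "run_lambda_sweep",
    "run_phase_diagram",
    "lambda_from_protocol",
]


def _default_lam_grid() -> np.ndarray:
    return np.geomspace(0.05, 10.0, 40)


@dataclass(frozen=True)
class SweepSpec:
    """Randomized lambda-sweep configuration.

    Defaults follow the published sampling scheme: 4000 parameter sets;
    cheater background uniform on [20, 120] cells; each cooperator background
    uniform on [0, cheater background], independently; cheater advantage s_c
    normal around 0.40 with a relative standard deviation of 8% (sd 0.032),
    truncated at 0; initial fractions uniform on the simplex.
    """

    lam_grid: np.ndarray = field(default_factory=_default_lam_grid)
    n_parameter_sets: int = 4000
    cheater_background_range: tuple[float, float] = (20.0, 120.0)
    s_c_mean: float = DEFAULT_CHEATER_ADVANTAGE
    s_c_sd: float = 0.08 * DEFAULT_CHEATER_ADVANTAGE
    carrying_capacity: float = 750.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.lam_grid, dtype=float)
        object.__setattr__(self, "lam_grid", grid)
        if np.any(grid <= 0):
            raise ValueError("lam_grid values must be > 0")
        if self.n_parameter_sets < 1:
            raise ValueError("n_parameter_sets must be >= 1")


@dataclass(frozen=True)
class PhaseDiagramSpec:
    """Cost/benefit phase-diagram configuration.

    Defaults reproduce the published setting: start with 50% cooperator A,
    1% cooperator B, 49% cheater; lambda = 2; 40 serial propagations; 21x21
    grid over benefit in [0, 1] and cost in [0, 100]%.
    """

    benefit_grid: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 21))
    cost_grid: np.ndarray = field(default_factory=lambda: np.linspace(0, 100, 21))
    rounds: int = 40
    lam: float = 2.0
    initial_fractions: tuple[float, float, float] = (0.50, 0.01, 0.49)
    carrying_capacity: float = 750.0
    s_c: float = DEFAULT_CHEATER_ADVANTAGE

    def __post_init__(self) -> None:
        b = np.asarray(self.benefit_grid, dtype=float)
        c = np.asarray(self.cost_grid, dtype=float)
        object.__setattr__(self, "benefit_grid", b)
        object.__setattr__(self, "cost_grid", c)
        if np.any((b < 0) | (b > 1)):
            raise ValueError("benefit_grid must lie in [0, 1]")
        if np.any((c < 0) | (c > 100)):
            raise ValueError("cost_grid must lie in [0, 100]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass(frozen=True)
class EmulsionPhysics:
    """Emulsion arithmetic: droplet geometry and cell concentrations.

    Lengths in micrometres, volumes in picolitres, concentrations in
    cells/mL. The droplet volume may be given directly or derived from the
    diameter as (pi/6) d^3.
    """

    droplet_diameter_um: float | None = None
    droplet_volume_pl: float | None = None
    cell_concentration_per_ml: float | None = None
    max_cell_concentration_per_ml: float | None = None

    def __post_init__(self) -> None:
        if self.droplet_diameter_um is None and self.droplet_volume_pl is None:
            raise ValueError("need droplet_diameter_um or droplet_volume_pl")
        if self.droplet_diameter_um is not None and self.droplet_diameter_um <= 0:
            raise ValueError("droplet_diameter_um must be > 0")
        if self.droplet_volume_pl is not None and self.droplet_volume_pl <= 0:
            raise ValueError("droplet_volume_pl must be > 0")

    @property
    def volume_pl(self) -> float:
        """Droplet volume in pL: (pi/6) d^3 with d in um (1 um^3 = 1e-3 pL)."""
        if self.droplet_volume_pl is not None:
            return self.droplet_volume_pl
        return (np.pi / 6.0) * self.droplet_diameter_um**3 * 1e-3

    @property
    def volume_ml(self) -> float:
        return self.volume_pl * 1e-9

    @property
    def carrying_capacity_cells(self) -> float:
        """Cells per droplet at the medium's maximal final concentration."""
        if self.max_cell_concentration_per_ml is None:
            raise ValueError("max_cell_concentration_per_ml not set")
        return self.max_cell_concentration_per_ml * self.volume_ml


def lambda_from_protocol(physics: EmulsionPhysics) -> float:
    """Expected founders per droplet: concentration (cells/mL) x volume (mL)."""
    if physics.cell_concentration_per_ml is None:
        raise ValueError("cell_concentration_per_ml not set")
    if physics.cell_concentration_per_ml < 0:
        raise ValueError("cell_concentration_per_ml must be >= 0")
    return physics.cell_concentration_per_ml * physics.volume_ml


def optimal_lambda(
    initial_fractions,
    consortium: ConsortiumSpec,
    params: GrowthParams,
    lam_grid,
    tail_tol: float = 1e-12,
) -> tuple[float, pd.DataFrame]:
    """Grid lambda maximizing the one-round gain in total cooperator fraction.

    Returns ``(lam_opt, profile)`` where ``profile`` has one row per grid
    lambda with the one-round cooperator-fraction gain and the cooperator
    advantage.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("lam_grid must be non-empty")
    state = PopulationState(np.asarray(initial_fractions, dtype=float))
    coop_idx = list(consortium.cooperator_indices)
    coop0 = state.fractions[coop_idx].sum()
    rows = []
    for lam in lam_grid:
        occ = OccupancyModel(lam=lam, tail_tol=tail_tol)
        gf = expected_growth_factors(state, occ, consortium, params)
        new = update_fractions(state, gf)
        rows.append(
            {
                "lam": lam,
                "cooperator_gain": new.fractions[coop_idx].sum() - coop0,
                "cooperator_advantage": gf.cooperator_advantage,
            }
        )
    profile = pd.DataFrame(rows)
    lam_opt = float(profile.loc[profile["cooperator_gain"].idxmax(), "lam"])
    return lam_opt, profile


def _default_fraction_sets() -> dict[str, tuple[float, float, float]]:
    # Cheater starting fractions 0.1/0.5/0.9, cooperators split equally.
    out = {}
    for ch in (0.1, 0.5, 0.9):
        co = (1.0 - ch) / 2.0
        out[f"cheater_{ch:g}"] = (co, co, ch)
    return out


def run_scenario_grid(
    scenarios=("dependent", "costless_background", "costly_background"),
    initial_fraction_sets: dict[str, tuple[float, float, float]] | None = None,
    lam: float = 0.15,
    rounds: int = 10,
    K: float = 750.0,
    s_c: float = DEFAULT_CHEATER_ADVANTAGE,
) -> pd.DataFrame:
    """Serial-propagation trajectories for each (scenario, start) cell.

    Long-format table: scenario, start label, round, per-type fractions and
    growth factors, cooperator advantage.
    """
    if initial_fraction_sets is None:
        initial_fraction_sets = _default_fraction_sets()
    occ = OccupancyModel(lam=lam)
    frames = []
    for scenario in scenarios:
        consortium, params = scenario_preset(scenario, K=K, s_c=s_c)
        for label, fracs in initial_fraction_sets.items():
            traj = propagate(
                PopulationState(np.asarray(fracs, dtype=float)),
                rounds,
                occ,
                consortium,
                params,
            )
            df = traj.to_frame()
            df.insert(0, "scenario", scenario)
            df.insert(1, "start", label)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_lambda_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Cooperator advantage for each sampled parameter set at each lambda.

    One row per (parameter set, lambda); sampled parameters are echoed on
    every row. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.cheater_background_range
    K = spec.carrying_capacity
    rows = []
    occs = [OccupancyModel(lam=lam) for lam in spec.lam_grid]
    for set_id in range(spec.n_parameter_sets):
        b_cheater = rng.uniform(lo, hi)
        b_a = rng.uniform(0.0, b_cheater)
        b_b = rng.uniform(0.0, b_cheater)
        s_c = rng.normal(spec.s_c_mean, spec.s_c_sd)
        s_c = max(s_c, 0.0)  # a negative draw would invert the cheater role
        fracs = rng.dirichlet(np.ones(3))
        from .growth_rules import CellTypeSpec, ROLE_CHEATER, ROLE_COOPERATOR_A, ROLE_COOPERATOR_B

        consortium = ConsortiumSpec(
            types=(
                CellTypeSpec("cooperator_A", ROLE_COOPERATOR_A, b_a, 1.0),
                CellTypeSpec("cooperator_B", ROLE_COOPERATOR_B, b_b, 1.0),
                CellTypeSpec("cheater", ROLE_CHEATER, b_cheater, 1.0 + s_c),
            )
        )
        params = GrowthParams(carrying_capacity=K)
        state = PopulationState(fracs)
        for occ in occs:
            gf = expected_growth_factors(state, occ, consortium, params)
            rows.append(
                {
                    "set_id": set_id,
                    "lam": occ.lam,
                    "cooperator_advantage": gf.cooperator_advantage,
                    "b_coopA": b_a,
                    "b_coopB": b_b,
                    "b_cheater": b_cheater,
                    "s_c": s_c,
                    "f_coopA": fracs[0],
                    "f_coopB": fracs[1],
                    "f_cheater": fracs[2],
                }
            )
    return pd.DataFrame(rows)


def run_phase_diagram(spec: PhaseDiagramSpec) -> pd.DataFrame:
    """Final cheater fraction for every (benefit, cost) grid cell.

    One row per cell: benefit_fraction, cost_percent, cheater fraction after
    ``spec.rounds`` propagations, plus the cheater fraction 10 rounds earlier
    (for convergence diagnostics). Deterministic.
    """
    occ = OccupancyModel(lam=spec.lam)
    state0 = PopulationState(np.asarray(spec.initial_fractions, dtype=float))
    rows = []
    for benefit in spec.benefit_grid:
        for cost in spec.cost_grid:
            consortium, params = from_cost_benefit(
                benefit, cost, K=spec.carrying_capacity, s_c=spec.s_c
            )
            traj = propagate(state0, spec.rounds, occ, consortium, params)
            cheat_idx = consortium.cheater_indices[0]
            fracs = traj.fractions_matrix()[:, cheat_idx]
            rows.append(
                {
                    "benefit_fraction": float(benefit),
                    "cost_percent": float(cost),
                    "final_cheater_fraction": float(fracs[-1]),
                    "cheater_fraction_minus10": float(
                        fracs[max(len(fracs) - 11, 0)]
                    ),
                }
            )
    return pd.DataFrame(rows)
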
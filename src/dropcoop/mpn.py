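"""Most-probable-number (MPN) estimation and assay simulation.

MPN is the classic dilution-to-extinction readout for viable-cell
concentrations: replicate wells are inoculated from a dilution series, scored
positive/negative for growth, and the concentration is estimated by maximum
likelihood under the Poisson-inoculum model — a well at effective volume ``v``
is positive with probability ``1 - exp(-c v)``. The experimental design
emulated here scores 8 replicates of a tenfold dilution series per selective
medium; per-type concentrations follow from assays that are selective for
subsets of the cell types, with fractions recovered by subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .propagation import Trajectory

__all__ = [
    "MpnDesign",
    "MpnObservation",
    "MpnResult",
    "mpn_estimate",
    "simulate_mpn_assay",
    "observe_trajectory",
    "DEFAULT_SELECTIVITY",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class MpnDesign:
    """Dilution-series layout: factors, inoculated volume, replication.

    ``dilution_factors`` are the multiplicative dilutions applied to the
    sample at each level (strictly increasing, e.g. 10, 100, ...);
    ``inoculum_volume`` (mL) is the volume assayed per well; each level has
    ``replicates_per_level`` wells.
    """

    dilution_factors: tuple[float, ...]
    inoculum_volume: float = 1.0
    replicates_per_level: int = 8

    def __post_init__(self) -> None:
        d = np.asarray(self.dilution_factors, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("dilution_factors must be a non-empty sequence")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dilution_factors must be strictly increasing")
        if np.any(d < 1):
            raise ValueError("dilution factors must be >= 1")
        if self.inoculum_volume <= 0:
            raise ValueError("inoculum_volume must be > 0")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")

    @property
    def n_levels(self) -> int:
        return len(self.dilution_factors)

    @property
    def well_volumes(self) -> np.ndarray:
        """Effective undiluted-sample volume per well at each level (mL)."""
        return self.inoculum_volume / np.asarray(self.dilution_factors, dtype=float)

    @classmethod
    def tenfold(
        cls,
        n_levels: int,
        first_dilution: float = 10.0,
        inoculum_volume: float = 1.0,
        replicates_per_level: int = 8,
    ) -> "MpnDesign":
        """Tenfold series of ``n_levels`` levels starting at ``first_dilution``."""
        factors = tuple(first_dilution * 10.0**i for i in range(n_levels))
        return cls(factors, inoculum_volume, replicates_per_level)


@dataclass(frozen=True)
class MpnObservation:
    """Positive-well counts per dilution level."""

    positives_per_level: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.positives_per_level):
            raise ValueError("positive counts must be >= 0")


@dataclass(frozen=True)
class MpnResult:
    """ML concentration estimate (cells/mL) with 95% log-normal CI."""

    mpn: float
    ci_low: float
    ci_high: float
    status: str  # "ok" | "all_negative" | "all_positive"


def _check(design: MpnDesign, obs: MpnObservation) -> np.ndarray:
    pos = np.asarray(obs.positives_per_level, dtype=np.int64)
    if pos.size != design.n_levels:
        raise ValueError(
            f"observation has {pos.size} levels but design has {design.n_levels}"
        )
    if np.any(pos > design.replicates_per_level):
        raise ValueError("more positives than replicates at some level")
    return pos


def _loglik(logc: float, pos: np.ndarray, n: int, vol: np.ndarray) -> float:
    c = np.exp(logc)
    p = -np.expm1(-c * vol)  # 1 - exp(-c v), accurate for small c v
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    ll = np.where(pos > 0, pos * logp, 0.0) - (n - pos) * c * vol
    return float(ll.sum())


def _fisher_info_logc(c: float, n: int, vol: np.ndarray) -> float:
    """Expected information for ln(c): sum n (cv)^2 e^{-cv} / (1 - e^{-cv})."""
    cv = c * vol
    with np.errstate(over="ignore"):
        denom = -np.expm1(-cv)
    terms = np.where(denom > 0, cv**2 * np.exp(-cv) / np.where(denom > 0, denom, 1), 0.0)
    return float(n * terms.sum())


def mpn_estimate(design: MpnDesign, obs: MpnObservation) -> MpnResult:
    """Maximum-likelihood MPN with a log-normal 95% confidence interval.

    The likelihood is maximized over ln(c) — a coarse log grid bracket
    followed by scalar refinement; the likelihood is unimodal in ln(c). The
    CI is ``exp(ln c_hat ± 1.96 / sqrt(I))`` with ``I`` the expected Fisher
    information for ln(c) at the estimate.

    Degenerate score patterns carry no point estimate: all-negative returns
    ``mpn = 0`` with a one-sided 95% upper bound, all-positive returns
    ``mpn = inf`` with a one-sided 95% lower bound.
    """
    pos = _check(design, obs)
    n = design.replicates_per_level
    vol = design.well_volumes

    if np.all(pos == 0):
        # P(all negative | c) = exp(-c * n * sum(v)) = 0.05 at the bound
        upper = -np.log(0.05) / (n * vol.sum())
        return MpnResult(0.0, 0.0, float(upper), "all_negative")
    if np.all(pos == n):
        # P(all positive | c) = prod (1 - e^{-c v})^n = 0.05 at the bound
        def log_p_allpos(logc: float) -> float:
            p = -np.expm1(-np.exp(logc) * vol)
            return float(n * np.log(p).sum()) - np.log(0.05)

        lo, hi = -40.0, np.log(1.0 / vol.min())
        while log_p_allpos(hi) < 0:
            hi += 5.0
        lower = float(np.exp(brentq(log_p_allpos, lo, hi, xtol=1e-12)))
        return MpnResult(np.inf, lower, np.inf, "all_positive")

    # Coarse log grid spanning far past the design's dynamic range.
    grid = np.log(10.0) * np.arange(-9.0, 15.01, 0.25) - np.log(vol.max())
    lls = np.array([_loglik(x, pos, n, vol) for x in grid])
    j = int(np.argmax(lls))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda x: -_loglik(x, pos, n, vol),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    c_hat = float(np.exp(res.x))
    info = _fisher_info_logc(c_hat, n, vol)
    half = _Z95 / np.sqrt(info) if info > 0 else np.inf
    return MpnResult(c_hat, c_hat * np.exp(-half), c_hat * np.exp(half), "ok")


def simulate_mpn_assay(
    true_concentration: float,
    design: MpnDesign,
    seed: int | np.random.Generator | None = None,
) -> MpnObservation:
    """Simulate well scores: each well positive with prob 1 - exp(-c v)."""
    if true_concentration < 0:
        raise ValueError("true_concentration must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = -np.expm1(-true_concentration * design.well_volumes)
    pos = rng.binomial(design.replicates_per_level, p)
    return MpnObservation(tuple(int(x) for x in pos))


#: The three selective media of the consortium readout: one grows the cheater
#: only, one grows cooperator B only, one grows cheater and cooperator A.
#: Cooperator A's concentration follows by subtraction.
DEFAULT_SELECTIVITY: dict[str, tuple[str, ...]] = {
    "cheater_only": ("cheater",),
    "coopB_only": ("cooperator_B",),
    "cheater_plus_coopA": ("cheater", "cooperator_A"),
}


def observe_trajectory(
    traj: Trajectory,
    total_concentration: float,
    design: MpnDesign,
    selectivity: dict[str, tuple[str, ...]] | None = None,
    seed: int | None = None,
    return_assays: bool = False,
):
    """Simulate the MPN readout of a model trajectory and recover fractions.

    For every propagation and every selective medium, the summed
    concentration of the types that medium scores is measured by a simulated
    MPN assay; per-type concentrations are then recovered by solving the
    selectivity system (least squares), mirroring the experimental
    subtraction logic (cooperator A = (cheater + cooperator A assay) -
    cheater assay). Noisy subtraction can produce small negative observed
    fractions; they are reported as-is with ``negative_observed`` flagged,
    never clamped.

    If the selectivity matrix leaves exactly one linear combination of types
    unresolved (rank n-1), the types involved are marked ``confounded`` and
    their observed fractions are NaN; a larger deficiency is an error.

    Returns a table with one row per (round, type): true fraction, observed
    fraction, and flags. With ``return_assays=True`` also returns the raw
    per-(round, medium) assay table (true concentration, MPN estimate and
    95% CI bounds).
    """
    selectivity = DEFAULT_SELECTIVITY if selectivity is None else selectivity
    names = list(traj.type_names)
    media = list(selectivity)
    S = np.zeros((len(media), len(names)))
    for r_i, m in enumerate(media):
        for t in selectivity[m]:
            if t not in names:
                raise ValueError(f"selectivity refers to unknown type {t!r}")
            S[r_i, names.index(t)] = 1.0

    rank = np.linalg.matrix_rank(S)
    confounded = np.zeros(len(names), dtype=bool)
    if rank < len(names) - 1:
        raise ValueError(
            "selectivity map leaves more than one linear combination of types unresolved"
        )
    if rank == len(names) - 1:
        # Null-space direction identifies the confounded types.
        _, s, vt = np.linalg.svd(S)
        null = vt[-1]
        confounded = np.abs(null) > 1e-9

    rng = np.random.default_rng(seed)
    rows = []
    assay_rows = []
    for r, state in enumerate(traj.states):
        true_f = np.asarray(state.fractions, dtype=float)
        est = np.empty(len(media))
        for m_i, m in enumerate(media):
            c_true = total_concentration * float(S[m_i] @ true_f)
            obs = simulate_mpn_assay(c_true, design, seed=rng)
            res = mpn_estimate(design, obs)
            est[m_i] = res.mpn if np.isfinite(res.mpn) else np.nan
            assay_rows.append(
                {
                    "round": r,
                    "medium": m,
                    "true_concentration": c_true,
                    "mpn": res.mpn,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "status": res.status,
                }
            )
        if np.any(np.isnan(est)):
            conc = np.full(len(names), np.nan)
        else:
            conc, *_ = np.linalg.lstsq(S, est, rcond=None)
        # Total observed concentration: sum of per-type estimates. With a
        # rank-deficient selectivity, individual confounded types are NaN.
        denom = conc.sum() if not confounded.any() else np.nan
        for t_i, name in enumerate(names):
            obs_frac = (
                np.nan
                if (confounded[t_i] or not np.isfinite(denom) or denom == 0)
                else conc[t_i] / denom
            )
            rows.append(
                {
                    "round": r,
                    "type": name,
                    "true_fraction": true_f[t_i],
                    "observed_fraction": obs_frac,
                    "confounded": bool(confounded[t_i]),
                    "negative_observed": bool(
                        np.isfinite(obs_frac) and obs_frac < 0
                    ),
                }
            )
    types_df = pd.DataFrame(rows)
    if return_assays:
        return types_df, pd.DataFrame(assay_rows)
    return types_df
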
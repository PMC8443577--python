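"""Probability machinery for founder cells distributed over droplet compartments.

When a dilute cell suspension is emulsified, the number of founder cells per
droplet is Poisson distributed with mean ``lam`` (the average founder
population size), and — given a droplet's total — the cell-type identities are
an i.i.d. multinomial draw from the pooled population's cell-type fractions.
This module provides the occupancy distribution, enumeration of cell-type
compositions, and the two complementary probability views used by the growth
model:

* compartment-centric: the probability that a droplet contains a given
  composition;
* cell-centric: the probability that a randomly chosen *founder cell* of a
  given type finds itself in a droplet with a given full composition. By
  Poisson size-biasing this equals the probability that the focal cell's
  companions (a Poisson(``lam``) number of them) realize the remaining counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import comb, ceil

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson as _poisson


__all__ = [
    "OccupancyModel",
    "Composition",
    "poisson_pmf",
    "truncation_bound",
    "enumerate_compositions",
    "compositions_up_to",
    "composition_probability",
    "multinomial_pmf",
    "cell_centric_probability",
]


def poisson_pmf(lam: float, k):
    """Poisson probability mass e^(-lam) * lam^k / k!.

    Accepts scalar or array ``k``. Numerically stable for large ``lam`` and
    ``k`` (evaluated in log space by scipy).
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValueError("k must be >= 0")
    out = _poisson.pmf(k_arr, lam)
    return float(out) if np.isscalar(k) else out


def truncation_bound(lam: float, tail_tol: float) -> int:
    """Smallest n such that P(K > n) < tail_tol for K ~ Poisson(lam)."""
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if not 0.0 < tail_tol < 1.0:
        raise ValueError(f"tail_tol must be in (0, 1), got {tail_tol}")
    if lam == 0:
        return 0
    n = int(_poisson.ppf(1.0 - tail_tol, lam))
    # ppf guarantees cdf(n) >= 1 - tol; bump in the rare boundary case where
    # the survival mass is still not strictly below tol.
    while _poisson.sf(n, lam) >= tail_tol:
        n += 1
    return max(n, ceil(lam))


@dataclass(frozen=True)
class OccupancyModel:
    """Poisson droplet-occupancy model truncated at a negligible tail.

    Parameters
    ----------
    lam
        Mean founder cells per droplet (the emulsion-wide average founder
        population size).
    tail_tol
        Probability mass allowed to be truncated from the upper tail when
        enumerating occupancies. Expectations computed under the model are
        renormalized over the retained support ``0..n_max``.
    """

    lam: float
    tail_tol: float = 1e-12
    n_max: int = field(init=False)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        object.__setattr__(self, "n_max", truncation_bound(self.lam, self.tail_tol))

    def pmf(self, k):
        return poisson_pmf(self.lam, k)

    @property
    def retained_mass(self) -> float:
        """Total probability of occupancies 0..n_max (>= 1 - tail_tol)."""
        return float(_poisson.cdf(self.n_max, self.lam))


@dataclass(frozen=True)
class Composition:
    """Integer founder counts per cell type in one compartment."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError(f"counts must be >= 0, got {self.counts}")

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def enumerate_compositions(total: int, n_types: int) -> list[Composition]:
    """All compositions of ``total`` founder cells over ``n_types`` types.

    Returned in lexicographically decreasing order of the count vector, which
    is fixed so that iteration-order-sensitive floating point sums are
    reproducible. The number of compositions is C(total + n_types - 1,
    n_types - 1).
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    out = []
    # combinations_with_replacement over "bar positions" yields the standard
    # stars-and-bars enumeration.
    for bars in combinations_with_replacement(range(total + 1), n_types - 1):
        counts = []
        prev = 0
        for b in bars:
            counts.append(b - prev)
            prev = b
        counts.append(total - prev)
        out.append(Composition(tuple(counts)))
    out.sort(key=lambda c: c.counts, reverse=True)
    assert len(out) == comb(total + n_types - 1, n_types - 1)
    return out


def compositions_up_to(total_max: int, n_types: int) -> np.ndarray:
    """Array of all compositions with 0 <= total <= total_max, shape (N, n_types).

    Ordered by total, then lexicographically decreasing within a total
    (matching :func:`enumerate_compositions`).
    """
    rows: list[tuple[int, ...]] = []
    for t in range(total_max + 1):
        rows.extend(c.counts for c in enumerate_compositions(t, n_types))
    return np.asarray(rows, dtype=np.int64)


def multinomial_pmf(counts, fractions) -> np.ndarray:
    """Vectorized multinomial pmf for count rows given per-type fractions.

    ``counts`` may be one vector or a 2-D array of rows. Zero fractions are
    handled exactly: a row with a positive count in a zero-probability type
    has probability 0, and 0^0 = 1.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    p = np.asarray(fractions, dtype=float)
    if counts.shape[1] != p.shape[0]:
        raise ValueError(
            f"composition length {counts.shape[1]} != number of fractions {p.shape[0]}"
        )
    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
        terms = counts * logp[None, :]
    terms[counts == 0] = 0.0  # 0 * (-inf) -> 0^0 = 1
    loglik = (
        gammaln(totals + 1.0)
        - gammaln(counts + 1.0).sum(axis=1)
        + terms.sum(axis=1)
    )
    return np.exp(loglik)


def composition_probability(comp: Composition, fractions) -> float:
    """Multinomial probability of ``comp`` given ``comp.total`` i.i.d. draws."""
    p = np.asarray(fractions, dtype=float)
    if len(comp.counts) != p.shape[0]:
        raise ValueError("composition length does not match fractions")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {p.sum()}")
    return float(multinomial_pmf(comp.as_array(), p)[0])


def cell_centric_probability(
    focal_type: int,
    comp: Composition,
    occ: OccupancyModel,
    fractions,
) -> float:
    """Probability that a founder cell of ``focal_type`` lands in composition ``comp``.

    ``comp`` is the full droplet composition including the focal cell itself.
    By Poisson size-biasing, the focal cell's number of companions is again
    Poisson(``lam``) and their types are i.i.d. from ``fractions``, so this is
    ``pmf(total - 1) * multinomial(comp - e_focal)``. Equivalently it equals
    the compartment-centric ``comp[focal] * P(comp) * pmf(total) /
    (lam * fractions[focal])``.
    """
    if comp.counts[focal_type] < 1:
        raise ValueError(
            f"focal type {focal_type} absent from composition {comp.counts}"
        )
    companions = comp.as_array().copy()
    companions[focal_type] -= 1
    m = int(companions.sum())
    return float(poisson_pmf(occ.lam, m) * multinomial_pmf(companions, fractions)[0])
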
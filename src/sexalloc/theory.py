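"""Closed-form sex-allocation theory under local mate competition.

Hamilton's classic result gives the evolutionarily stable (ES) allocation to
female function (seeds) as ``(n + 1) / (2n)`` for a local mating population of
``n`` individuals.  When a species is rare, some pollen-dispersal areas contain
no conspecifics at all; sex allocation is then shaped only by the occupied
areas, so ``n`` must be replaced by the mean of a zero-truncated Poisson
distribution with parameter ``lam`` (the expected conspecific density per
area).  Substituting gives the ES female allocation as a function of density:

    s(lam) = (lam + 1 - exp(-lam)) / (2 lam)

which decreases from 1 (an isolated founder selfs and puts everything into
seeds) to 1/2 (equal allocation in a large, well-mixed mating population).

The module also provides the equal-growth-rate allocation threshold used to
compare species that receive different resource amounts, and a brute-force
Shaw-Mohler-type invasion-fitness oracle used to verify the ESS formulas
numerically.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hamilton_ess",
    "ztp_mean",
    "ess_allocation",
    "equal_growth_allocation",
    "invasion_fitness",
    "ess_table",
]

# Below this density the direct formulas are evaluated by second-order series
# to avoid catastrophic cancellation in 1 - exp(-lam).
_SERIES_THRESHOLD = 1e-8


def hamilton_ess(n):
    """ES female allocation ``(n + 1) / (2n)`` for local mating number ``n``.

    Parameters
    ----------
    n : float or array-like
        Number of individuals in the local mating population (the pollen
        dispersal area). Must be >= 1.

    Returns
    -------
    float or ndarray
        Stable allocation to seeds, in ``[0.5, 1]``.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("local mating number n must be >= 1")
    out = (n + 1.0) / (2.0 * n)
    return out if out.ndim else float(out)


def ztp_mean(lam):
    """Mean of a zero-truncated Poisson distribution, ``lam / (1 - exp(-lam))``.

    This is the expected number of conspecifics in a pollen-dispersal area,
    conditional on the area containing at least one. Tends to 1 as ``lam -> 0``
    and to ``lam`` as ``lam -> inf``.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("density lam must be > 0")
    small = lam < _SERIES_THRESHOLD
    # -expm1(-lam) = 1 - exp(-lam), computed without cancellation
    denom = -np.expm1(-np.where(small, 1.0, lam))
    out = np.where(small, 1.0 + lam / 2.0 + lam**2 / 12.0, lam / denom)
    return out if out.ndim else float(out)


def ess_allocation(lam):
    """ES female allocation at conspecific density ``lam`` per dispersal area.

    Evaluates ``(lam + 1 - exp(-lam)) / (2 lam)``, which is identically
    ``hamilton_ess(ztp_mean(lam))``. Strictly decreasing in ``lam`` with
    limits 1 at zero density and 1/2 at high density.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("density lam must be > 0")
    small = lam < _SERIES_THRESHOLD
    # lam + 1 - exp(-lam) = lam - expm1(-lam)
    direct = (lam - np.expm1(-np.where(small, 1.0, lam))) / (2.0 * lam)
    out = np.where(small, 1.0 - lam / 4.0 + lam**2 / 12.0, direct)
    return out if out.ndim else float(out)


def equal_growth_allocation(r_i, r_ref, s_ref):
    """Female allocation at which species ``i`` matches a reference growth rate.

    Under the global seed lottery, per-capita population growth is proportional
    to seed output ``R * s``.  A species with resources ``r_i`` grows exactly as
    fast as a reference species (resources ``r_ref``, allocation ``s_ref``)
    when its own allocation equals ``r_ref * s_ref / r_i``.  Values above 1
    mean no feasible allocation lets the species keep up.
    """
    r_i = np.asarray(r_i, dtype=float)
    if np.any(r_i <= 0) or r_ref <= 0 or s_ref <= 0:
        raise ValueError("resources and allocation must be positive")
    out = r_ref * s_ref / r_i
    return out if out.ndim else float(out)


def invasion_fitness(x, s, n, r=1.0):
    """Expected gene copies of a rare mutant with female allocation ``x``.

    Brute-force Shaw-Mohler-type bookkeeping for one haploid mutant in a local
    mating population of ``n`` individuals whose ``n - 1`` residents allocate
    ``s``: the mutant transmits ``R*x`` copies through its own seeds plus a
    share of the local seed pool through pollen, where its pollen competes
    with resident pollen in proportion to ``(1 - allocation) * R``.  Selfed
    seeds credit the mutant with both the maternal and the paternal copy.

    The maximiser over ``x`` at the resident ESS ``s = (n+1)/(2n)`` is the
    resident value itself (first-order ESS condition), which is how this
    function serves as an independent check on :func:`hamilton_ess`.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)) or not (0 < s < 1):
        raise ValueError("allocations must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("local mating number n must be >= 1")
    if r <= 0:
        raise ValueError("resource amount must be positive")
    pollen_share = (1.0 - x) / ((1.0 - x) + (n - 1.0) * (1.0 - s))
    local_seeds = x + (n - 1.0) * s
    out = r * x + pollen_share * r * local_seeds
    return out if out.ndim else float(out)


def ess_table(lam_grid):
    """Tabulate (lam, n, s) along a density grid, for overlaying theory curves.

    Returns a pandas DataFrame with columns ``lam`` (conspecific density per
    pollen-dispersal area), ``n`` (zero-truncated Poisson mean) and ``s``
    (ES female allocation).
    """
    import pandas as pd

    lam = np.asarray(lam_grid, dtype=float)
    return pd.DataFrame(
        {"lam": lam, "n": ztp_mean(lam), "s": ess_allocation(lam)}
    )
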
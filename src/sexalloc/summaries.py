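"""Census statistics: rank-abundance diagrams, densities, richness, and the
allocation-density trajectories that the simulator's figures are built from."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import theory

__all__ = [
    "rank_abundance",
    "density_lambda",
    "richness_over_time",
    "aggregate_rads",
    "allocation_density_trajectory",
]


def rank_abundance(census) -> pd.DataFrame:
    """Rank-abundance table from a per-species abundance vector.

    Species are sorted by descending abundance (ties broken by ascending
    species id); zero-abundance species are dropped. Columns: ``rank``
    (1-based), ``species_id``, ``abundance``, ``log10_abundance``.
    """
    counts = np.asarray(census)
    if counts.size and np.any(counts < 0):
        raise ValueError("abundances must be non-negative")
    species = np.arange(counts.size)
    keep = counts > 0
    counts, species = counts[keep], species[keep]
    order = np.argsort(-counts, kind="stable")  # stable: ties keep id order
    counts, species = counts[order], species[order]
    return pd.DataFrame(
        {
            "rank": np.arange(1, counts.size + 1),
            "species_id": species,
            "abundance": counts,
            "log10_abundance": np.log10(counts) if counts.size else np.array([]),
        }
    )


def density_lambda(abundance, n_demes: int):
    """Conspecific density per pollen-dispersal area: abundance / D."""
    if n_demes < 1:
        raise ValueError("n_demes must be >= 1")
    out = np.asarray(abundance, dtype=float) / n_demes
    return out if out.ndim else float(out)


def richness_over_time(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Number of extant species (abundance > 0) at each recorded generation."""
    out = (
        trajectory.groupby("generation", sort=True)["abundance"]
        .apply(lambda a: int((a > 0).sum()))
        .rename("richness")
        .reset_index()
    )
    return out


def aggregate_rads(rads: list[pd.DataFrame], scale: str = "log") -> pd.DataFrame:
    """Average rank-abundance tables across replicate runs, rank by rank.

    With ``scale="log"`` (default) the mean is taken on log10 abundance,
    matching plots of mean log abundance; ``scale="linear"`` averages raw
    abundances and reports their log.  Ranks present in only some replicates
    are averaged over the replicates that have them (``n_replicates`` column
    records how many).
    """
    if not rads:
        raise ValueError("need at least one rank-abundance table")
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")
    stacked = pd.concat(rads, keys=range(len(rads)), names=["replicate"])
    grp = stacked.groupby("rank")
    if scale == "log":
        mean_log = grp["log10_abundance"].mean()
    else:
        mean_log = np.log10(grp["abundance"].mean())
    return pd.DataFrame(
        {
            "rank": mean_log.index.to_numpy(),
            "mean_log10_abundance": mean_log.to_numpy(),
            "n_replicates": grp.size().to_numpy(),
        }
    )


def allocation_density_trajectory(
    trajectory: pd.DataFrame,
    n_demes: int,
    resources,
) -> pd.DataFrame:
    """Tidy per-species path of mean allocation vs abundance with theory
    overlays.

    For every recorded (generation, species) with abundance > 0, emits the
    mean allocation gene, abundance, log10 abundance, density ``lam``, the
    ES allocation prediction ``ess_allocation(lam)`` (the dashed theory
    curve), and the equal-growth allocation threshold relative to the
    dominant species' final state (the grey reference lines):
    ``R_dom * s_dom / R_i``, flagged infeasible when it exceeds 1.

    ``resources`` is the per-species resource vector of the reference
    environment type.
    """
    resources = np.asarray(resources, dtype=float)
    final_gen = trajectory["generation"].max()
    final = trajectory[trajectory["generation"] == final_gen]
    alive = final[final["abundance"] > 0]
    if alive.empty:
        raise ValueError("no species extant at the final recorded generation")
    # dominant: max abundance, ties broken by lower species id
    top = alive.sort_values(
        ["abundance", "species_id"], ascending=[False, True]
    ).iloc[0]
    dom_id = int(top["species_id"])
    r_ref, s_ref = float(resources[dom_id]), float(top["mean_g"])

    rows = trajectory[trajectory["abundance"] > 0].copy()
    lam = density_lambda(rows["abundance"].to_numpy(), n_demes)
    rows["log10_abundance"] = np.log10(rows["abundance"].to_numpy())
    rows["lam"] = lam
    rows["ess_prediction"] = theory.ess_allocation(lam)
    thr = theory.equal_growth_allocation(
        resources[rows["species_id"].to_numpy()], r_ref, s_ref
    )
    rows["equal_growth_threshold"] = thr
    rows["growth_match_feasible"] = thr <= 1.0
    rows["dominant_species_id"] = dom_id
    return rows.reset_index(drop=True)
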
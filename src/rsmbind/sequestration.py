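"""Equilibrium partitioning of protein binding sites among competing RNA motifs.

A CsrA/RsmE homodimer carries two identical RNA-binding sites; every GGA
motif (on mRNA ribosome-binding sites or on decoy sRNAs) is treated as an
independent ligand pool with its own per-site dissociation constant.  At
equilibrium the free-site concentration S solves the site conservation

    S + sum_j M_j * S / (kd_j + S) = S_tot,    S_tot = 2 * [dimer],

a strictly increasing function of S, so the root is unique and found by
bracketed bisection/Brent iteration.  Per-pool occupancy is the standard
isotherm theta_j = S / (kd_j + S).  Translation activity of an mRNA is read
out as 1 - theta_RBS: the fraction of ribosome-binding sites not occluded by
the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .motifs import kd_from_tier

DEFAULT_DIMER_CONC = 100e-9  # M, cell-free assay preset
CELLULAR_DIMER_RANGE = (6e-6, 17e-6)  # M, estimated cellular protein range

__all__ = [
    "LigandPool",
    "SequestrationModel",
    "SequestrationSystem",
    "SequestrationResult",
    "solve_free_sites",
    "occupancy",
    "derepression_curve",
    "rank_mutants",
    "sequential_occupancy",
]


@dataclass(frozen=True)
class LigandPool:
    """One motif site pool: total site concentration (M) and per-site K_d (M).

    ``tier`` may be given instead of ``kd``; the pool then uses the geometric
    mean of that affinity tier's K_d bounds.
    """

    name: str
    site_conc: float
    kd: Optional[float] = None
    tier: Optional[str] = None
    role: str = "decoy"  # rbs | decoy | other

    def __post_init__(self) -> None:
        if self.site_conc < 0:
            raise ValueError(f"pool {self.name!r}: site_conc must be >= 0")
        if self.kd is None and self.tier is None:
            raise ValueError(f"pool {self.name!r}: needs kd or tier")
        if self.kd is not None and self.kd <= 0:
            raise ValueError(f"pool {self.name!r}: kd must be positive")

    @property
    def kd_value(self) -> float:
        return self.kd if self.kd is not None else kd_from_tier(self.tier)


def occupancy(kd: float, free_site: float) -> float:
    """Single-site isotherm theta = S/(kd + S)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if free_site < 0:
        raise ValueError("free site concentration must be >= 0")
    return free_site / (kd + free_site)


class SequestrationModel:
    """Competition of ligand pools for a fixed total of protein sites."""

    def __init__(self, protein_dimer_conc: float, pools: Sequence[LigandPool]):
        if protein_dimer_conc <= 0:
            raise ValueError("protein_dimer_conc must be positive")
        if not pools:
            raise ValueError("need at least one ligand pool")
        names = [p.name for p in pools]
        if len(set(names)) != len(names):
            raise ValueError("pool names must be unique")
        self.protein_dimer_conc = protein_dimer_conc
        self.pools = list(pools)

    @property
    def site_total(self) -> float:
        """Two identical sites per homodimer."""
        return 2.0 * self.protein_dimer_conc

    def _site_balance(self, s: float) -> float:
        bound = sum(p.site_conc * s / (p.kd_value + s) for p in self.pools)
        return s + bound - self.site_total

    def solve(self) -> "SequestrationResult":
        s_tot = self.site_total
        if all(p.site_conc == 0 for p in self.pools):
            free = s_tot
        else:
            free = brentq(self._site_balance, 0.0, s_tot, xtol=1e-30, rtol=1e-15, maxiter=300)
        occ = {p.name: occupancy(p.kd_value, free) for p in self.pools}
        return SequestrationResult(self, float(free), occ)


# spec-style alias: the system *is* the model
SequestrationSystem = SequestrationModel


@dataclass
class SequestrationResult:
    """Solved equilibrium: free sites and per-pool occupancies."""

    model: SequestrationModel
    free_site_conc: float
    occupancies: dict[str, float]

    @property
    def bound(self) -> dict[str, float]:
        return {
            p.name: p.site_conc * self.occupancies[p.name] for p in self.model.pools
        }

    @property
    def mass_balance_residual(self) -> float:
        total = self.free_site_conc + sum(self.bound.values())
        return abs(total - self.model.site_total) / self.model.site_total

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "pool": p.name,
                "role": p.role,
                "site_conc_M": p.site_conc,
                "kd_M": p.kd_value,
                "theta": self.occupancies[p.name],
                "bound_M": self.bound[p.name],
            }
            for p in self.model.pools
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Sequestration equilibrium: dimer {self.model.protein_dimer_conc:.3g} M "
            f"({self.model.site_total:.3g} M sites)",
            f"  free sites: {self.free_site_conc:.4g} M "
            f"(mass-balance residual {self.mass_balance_residual:.1e})",
        ]
        for p in self.model.pools:
            lines.append(
                f"  {p.name:>16s} [{p.role}]: kd {p.kd_value:.3g} M, "
                f"sites {p.site_conc:.3g} M, theta {self.occupancies[p.name]:.4f}"
            )
        return "\n".join(lines)


def solve_free_sites(system: SequestrationModel) -> float:
    """Free protein-site concentration of a system (functional surface)."""
    return system.solve().free_site_conc


def derepression_curve(
    mrna_rbs: LigandPool,
    srna_pools: Sequence[LigandPool],
    protein_dimer_conc: float,
    srna_conc_grid: Sequence[float],
) -> pd.DataFrame:
    """Translation activity versus decoy sRNA concentration.

    ``srna_pools`` carry sites per sRNA molecule in ``site_conc`` (copies);
    at each grid concentration c the decoy pool contributes copies*c sites.
    Activity is 1 − theta_RBS normalised to the maximum over the grid,
    mirroring reporter assays normalised to full de-repression.
    """
    if mrna_rbs.role != "rbs":
        raise ValueError("mrna_rbs pool must have role='rbs'")
    grid = list(srna_conc_grid)
    if not grid:
        raise ValueError("empty sRNA concentration grid")
    raw = []
    for conc in grid:
        pools = [mrna_rbs] + [
            replace(p, site_conc=p.site_conc * conc) for p in srna_pools
        ]
        res = SequestrationModel(protein_dimer_conc, pools).solve()
        raw.append(1.0 - res.occupancies[mrna_rbs.name])
    raw_arr = np.asarray(raw)
    peak = raw_arr.max()
    return pd.DataFrame(
        {
            "srna_conc_M": grid,
            "free_rbs_fraction": raw_arr,
            "activity": raw_arr / peak if peak > 0 else raw_arr,
        }
    )


def rank_mutants(
    base_pools: Sequence[LigandPool],
    mutations: Sequence[str],
    mrna_rbs: LigandPool,
    srna_conc: float,
    protein_dimer_conc: float,
) -> pd.DataFrame:
    """Activity of wild type and single-site knockout variants, ranked.

    Each mutation names one decoy pool to remove (a GGA→AGA point mutation
    abolishing binding, equivalent to kd → infinity).  Returns a frame
    ordered by descending activity; exact ties share their order of first
    appearance and are flagged.
    """
    names = {p.name for p in base_pools}
    for mut in mutations:
        if mut not in names:
            raise KeyError(f"unknown site {mut!r}; pools: {sorted(names)}")

    def activity(pools: Sequence[LigandPool]) -> float:
        scaled = [mrna_rbs] + [replace(p, site_conc=p.site_conc * srna_conc) for p in pools]
        res = SequestrationModel(protein_dimer_conc, scaled).solve()
        return 1.0 - res.occupancies[mrna_rbs.name]

    rows = [{"variant": "wild_type", "activity": activity(base_pools)}]
    for mut in mutations:
        kept = [p for p in base_pools if p.name != mut]
        rows.append({"variant": f"delta_{mut}", "activity": activity(kept)})
    df = pd.DataFrame(rows).sort_values("activity", ascending=False, kind="stable")
    df["tied_with_next"] = df["activity"].diff(-1).abs() < 1e-15
    return df.reset_index(drop=True)


def sequential_occupancy(
    site_pools: Sequence[LigandPool],
    equivalents_grid: Sequence[float],
    rna_conc: float = 10e-6,
) -> pd.DataFrame:
    """Per-site occupancy along a protein titration of one multi-site RNA.

    ``site_pools`` are the GGA motifs of a single RNA in positional order,
    each at concentration ``rna_conc``; the grid gives protein dimer
    equivalents relative to the RNA.  Returns theta per site per titration
    point plus, per site, the first equivalence point where theta exceeds
    one half (NaN if never reached).
    """
    if not site_pools:
        raise ValueError("need at least one site pool")
    grid = list(equivalents_grid)
    pools = [replace(p, site_conc=rna_conc) for p in site_pools]
    records = []
    for eq in grid:
        dimer = eq * rna_conc
        if dimer <= 0:
            records.append({"equivalents": eq, **{p.name: 0.0 for p in pools}})
            continue
        res = SequestrationModel(dimer, pools).solve()
        records.append({"equivalents": eq, **res.occupancies})
    df = pd.DataFrame(records)
    half: dict[str, float] = {}
    for p in pools:
        above = df[df[p.name] > 0.5]
        half[p.name] = float(above["equivalents"].iloc[0]) if len(above) else float("nan")
    df.attrs["half_occupancy_equivalents"] = half
    return df
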
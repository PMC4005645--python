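"""Binding thermodynamics: ITC isotherm models and the slow-exchange NMR estimator.

Two forward models are provided for isothermal titration calorimetry of an
RNA ligand titrated into a protein (dimer) cell:

* ``one_site`` — P + L <-> PL with macroscopic dissociation constant kd1;
* ``two_site`` — sequential P + L <-> PL (kd1), PL + L <-> PL2 (kd2), the
  macroscopic constants a two-site homodimer fit reports.

Fitting follows the statsmodels idiom: :class:`ItcModel` is built from an
:class:`ItcExperiment` carrying measured heats and ``fit()`` returns an
:class:`ItcResults` with estimates, standard errors and a ``summary()``.

For complexes in slow exchange on the NMR chemical-shift timescale, free and
bound species give separate resonances whose integrals report the bound
fraction directly; :func:`kd_from_integrals` turns free/bound integral pairs
plus the known totals into a dissociation constant via the exact mass-balance
quadratic, and :func:`bound_fraction_forward` is its inverse for simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

R_GAS = 8.314  # J / (mol K)
DEFAULT_TEMPERATURE = 298.0  # K
DEFAULT_CELL_VOLUME = 1.4e-3  # L, VP-ITC working volume

__all__ = [
    "BindingParameters",
    "ItcExperiment",
    "ItcModel",
    "ItcResults",
    "NmrIntegralPair",
    "KdEstimate",
    "free_ligand",
    "itc_isotherm",
    "fit_itc",
    "kd_from_integrals",
    "bound_fraction_forward",
    "SlowExchangeError",
]


@dataclass(frozen=True)
class BindingParameters:
    """Parameters of a one- or two-site binding model.

    kd1/kd2 are macroscopic dissociation constants (M) of the first and
    second binding event; dh1/dh2 molar enthalpies of those events (J/mol);
    n the stoichiometry (active-fraction) correction multiplying the cell
    protein concentration; q_dil a constant per-injection dilution heat (J).
    """

    model: str  # "one_site" | "two_site"
    kd1: float
    dh1: float
    kd2: Optional[float] = None
    dh2: Optional[float] = None
    n: float = 1.0
    q_dil: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("one_site", "two_site"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.kd1 <= 0:
            raise ValueError("kd1 must be positive")
        if self.model == "two_site":
            if self.kd2 is None or self.dh2 is None:
                raise ValueError("two_site model requires kd2 and dh2")
            if self.kd2 <= 0:
                raise ValueError("kd2 must be positive")


@dataclass
class ItcExperiment:
    """An ITC titration design, optionally carrying measured heats.

    The ligand (RNA) sits in the syringe, the protein in the cell;
    concentrations are molar, volumes litres, heats joules.
    """

    cell_conc: float  # protein (dimer) concentration in the cell, M
    syringe_conc: float  # ligand concentration in the syringe, M
    injection_volumes: Sequence[float]  # L
    cell_volume: float = DEFAULT_CELL_VOLUME
    temperature: float = DEFAULT_TEMPERATURE
    heats: Optional[Sequence[float]] = None  # J, one per injection

    def __post_init__(self) -> None:
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.cell_volume <= 0:
            raise ValueError("concentrations and cell volume must be positive")
        if self.heats is not None and len(self.heats) != len(self.injection_volumes):
            raise ValueError("heats and injection_volumes length mismatch")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


def _bound_ligand(l_free: float, p_tot: float, params: BindingParameters) -> float:
    """Ligand sequestered into complexes at free ligand l_free."""
    if params.model == "one_site":
        return p_tot * l_free / (params.kd1 + l_free)
    k1, k2 = params.kd1, params.kd2
    # sequential: PL/P = L/k1, PL2/PL = L/k2
    a1 = l_free / k1
    a2 = a1 * l_free / k2
    denom = 1.0 + a1 + a2
    return p_tot * (a1 + 2.0 * a2) / denom


def free_ligand(l_tot: float, p_tot: float, params: BindingParameters) -> float:
    """Free ligand concentration from total ligand/protein by mass balance.

    Solves l + bound(l) = l_tot for the unique root in [0, l_tot] by
    bracketed root finding; the residual is below 1e-12 relative.
    """
    if l_tot < 0 or p_tot < 0:
        raise ValueError("totals must be non-negative")
    if l_tot == 0.0:
        return 0.0
    if p_tot == 0.0:
        return l_tot

    def resid(l: float) -> float:
        return l + _bound_ligand(l, p_tot, params) - l_tot

    if resid(l_tot) <= 0:  # numerically saturated: everything free
        return l_tot
    lo = 0.0
    hi = l_tot
    root = brentq(resid, lo, hi, xtol=1e-18, rtol=1e-15, maxiter=200)
    return float(root)


def _complex_concentrations(
    l_free: float, p_tot: float, params: BindingParameters
) -> tuple[float, float]:
    """([PL], [PL2]) at given free ligand."""
    if params.model == "one_site":
        pl = p_tot * l_free / (params.kd1 + l_free)
        return pl, 0.0
    a1 = l_free / params.kd1
    a2 = a1 * l_free / params.kd2
    denom = 1.0 + a1 + a2
    return p_tot * a1 / denom, p_tot * a2 / denom


def _enthalpy_content(l_tot: float, p_tot: float, params: BindingParameters) -> float:
    """Volumetric enthalpy of complexes (J/L) at equilibrium for given totals."""
    lf = free_ligand(l_tot, p_tot, params)
    pl, pl2 = _complex_concentrations(lf, p_tot, params)
    dh2 = params.dh2 or 0.0
    return pl * params.dh1 + pl2 * (params.dh1 + dh2)


def itc_isotherm(params: BindingParameters, exp: ItcExperiment) -> np.ndarray:
    """Predicted injection heats (J) for a titration.

    Displaced-volume convention: injecting volume v dilutes existing cell
    totals by d = V0/(V0+v) and adds syringe ligand at c_syr*(1-d);
    concentrations are always referenced to the active cell volume V0.  The
    heat of injection i is V0 times the change in complex enthalpy relative
    to the diluted pre-injection state, plus the constant dilution offset.
    """
    v0 = exp.cell_volume
    p_tot = params.n * exp.cell_conc
    l_tot = 0.0
    h_prev = 0.0  # J/L
    heats = np.empty(exp.n_injections)
    for i, v in enumerate(exp.injection_volumes):
        d = v0 / (v0 + v)
        p_tot *= d
        l_tot = l_tot * d + exp.syringe_conc * (1.0 - d)
        h_now = _enthalpy_content(l_tot, p_tot, params)
        heats[i] = v0 * (h_now - d * h_prev) + params.q_dil
        h_prev = h_now
    return heats


class ItcModel:
    """Nonlinear least-squares model for an ITC thermogram.

    Parameters are optimised as [log10 kd1, (log10 kd2), dh1, (dh2), q_dil]
    with optional stoichiometry n; multi-start over a log-spaced kd grid
    guards against local minima of the biphasic two-site surface.
    """

    def __init__(self, experiment: ItcExperiment, model: str = "one_site", fit_n: bool = False):
        if experiment.heats is None:
            raise ValueError("experiment carries no measured heats")
        if experiment.n_injections < 10:
            raise ValueError("need at least 10 injections to fit")
        if model not in ("one_site", "two_site"):
            raise ValueError(f"unknown model {model!r}")
        self.experiment = experiment
        self.model = model
        self.fit_n = fit_n
        self.heats = np.asarray(experiment.heats, dtype=float)

    # -- parameter vector plumbing -------------------------------------
    def _unpack(self, theta: np.ndarray) -> BindingParameters:
        if self.model == "one_site":
            lk1, dh1, qd = theta[0], theta[1], theta[2]
            n = theta[3] if self.fit_n else 1.0
            return BindingParameters("one_site", kd1=10.0 ** lk1, dh1=dh1, n=n, q_dil=qd)
        lk1, lk2, dh1, dh2, qd = theta[:5]
        n = theta[5] if self.fit_n else 1.0
        return BindingParameters(
            "two_site", kd1=10.0 ** lk1, kd2=10.0 ** lk2, dh1=dh1, dh2=dh2, n=n, q_dil=qd
        )

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return itc_isotherm(self._unpack(theta), self.experiment) - self.heats

    def _starts(self, seed: int) -> list[np.ndarray]:
        rng = np.random.default_rng(seed)
        scale = float(np.max(np.abs(self.heats))) or 1.0
        # enthalpy scale guess from the early plateau heats
        dh_guess = -abs(self.heats[0]) / (
            self.experiment.cell_volume * self.experiment.syringe_conc * 6e-3
        )
        dh_guess = float(np.clip(dh_guess, -2e5, -1e3))
        starts = []
        for lk in np.linspace(-9.0, -4.5, 8):
            jitter = rng.normal(0.0, 0.05, size=2)
            if self.model == "one_site":
                t = [lk + jitter[0], dh_guess, 0.0]
            else:
                t = [lk + jitter[0], lk + 1.0 + jitter[1], dh_guess, 0.7 * dh_guess, 0.0]
            if self.fit_n:
                t.append(1.0)
            starts.append(np.array(t))
        return starts

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        # log10 kd in [-12, 0] (pM..1 M), dh in +/-1 MJ/mol, q_dil in +/-0.1 J
        if self.model == "one_site":
            lo, hi = [-12.0, -1e6, -0.1], [0.0, 1e6, 0.1]
        else:
            lo, hi = [-12.0, -12.0, -1e6, -1e6, -0.1], [0.0, 0.0, 1e6, 1e6, 0.1]
        if self.fit_n:
            lo, hi = lo + [0.1], hi + [10.0]
        return np.array(lo), np.array(hi)

    def fit(self, seed: int = 0) -> "ItcResults":
        best = None
        for theta0 in self._starts(seed):
            try:
                sol = least_squares(
                    self._residuals,
                    theta0,
                    method="trf",
                    bounds=self._bounds(),
                    gtol=1e-10,
                    xtol=1e-12,
                    ftol=1e-12,
                    max_nfev=4000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimisation starts failed")
        params = self._unpack(best.x)
        rss = float(2.0 * best.cost)
        bse = self._standard_errors(best, params)
        converged = bool(best.status > 0)
        return ItcResults(self, params, bse, rss, converged)

    def _standard_errors(self, sol, params: BindingParameters) -> dict[str, float]:
        m, p = len(self.heats), len(sol.x)
        dof = max(m - p, 1)
        s2 = 2.0 * sol.cost / dof
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj) * s2
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except Exception:
            se = np.full(p, np.nan)
        ln10 = math.log(10.0)
        out: dict[str, float] = {}
        if self.model == "one_site":
            out["kd1"] = params.kd1 * ln10 * se[0]
            out["dh1"] = se[1]
            out["q_dil"] = se[2]
        else:
            out["kd1"] = params.kd1 * ln10 * se[0]
            out["kd2"] = params.kd2 * ln10 * se[1]
            out["dh1"] = se[2]
            out["dh2"] = se[3]
            out["q_dil"] = se[4]
        if self.fit_n:
            out["n"] = se[-1]
        return out


class ItcResults:
    """Fit results: parameters, standard errors, RSS and the ΔG/ΔH/TΔS split.

    ΔG = RT ln(K_d) (negative for K_d < 1 M) and TΔS = ΔH − ΔG at the
    experiment temperature; an exothermic event with TΔS < ΔH is
    enthalpy-driven with entropic compensation.
    """

    def __init__(
        self,
        model: ItcModel,
        params: BindingParameters,
        bse: dict[str, float],
        rss: float,
        converged: bool,
    ):
        self.model = model
        self.params = params
        self.bse = bse
        self.rss = rss
        self.converged = converged
        T = model.experiment.temperature
        self.dg1 = R_GAS * T * math.log(params.kd1)
        self.tds1 = params.dh1 - self.dg1
        if params.model == "two_site":
            self.dg2 = R_GAS * T * math.log(params.kd2)
            self.tds2 = params.dh2 - self.dg2
        else:
            self.dg2 = None
            self.tds2 = None

    @property
    def fittedvalues(self) -> np.ndarray:
        return itc_isotherm(self.params, self.model.experiment)

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self.model.heats

    def to_dict(self) -> dict:
        p = self.params
        out = {
            "model": p.model,
            "kd1_M": p.kd1,
            "kd1_se_M": self.bse.get("kd1"),
            "dh1_J_mol": p.dh1,
            "dh1_se_J_mol": self.bse.get("dh1"),
            "dg1_J_mol": self.dg1,
            "tds1_J_mol": self.tds1,
            "n": p.n,
            "q_dil_J": p.q_dil,
            "rss_J2": self.rss,
            "converged": self.converged,
            "temperature_K": self.model.experiment.temperature,
        }
        if p.model == "two_site":
            out.update(
                {
                    "kd2_M": p.kd2,
                    "kd2_se_M": self.bse.get("kd2"),
                    "dh2_J_mol": p.dh2,
                    "dh2_se_J_mol": self.bse.get("dh2"),
                    "dg2_J_mol": self.dg2,
                    "tds2_J_mol": self.tds2,
                }
            )
        return out

    def summary(self) -> str:
        p = self.params
        lines = [
            f"ITC {p.model} fit ({'converged' if self.converged else 'NOT converged'})",
            f"  T = {self.model.experiment.temperature:.1f} K, "
            f"{self.model.experiment.n_injections} injections, RSS = {self.rss:.3e} J^2",
            f"  Kd1 = {p.kd1:.4g} M (se {self.bse.get('kd1', float('nan')):.2g})",
            f"  dH1 = {p.dh1 / 1000:.2f} kJ/mol, dG1 = {self.dg1 / 1000:.2f} kJ/mol, "
            f"TdS1 = {self.tds1 / 1000:.2f} kJ/mol",
        ]
        if p.model == "two_site":
            lines += [
                f"  Kd2 = {p.kd2:.4g} M (se {self.bse.get('kd2', float('nan')):.2g})",
                f"  dH2 = {p.dh2 / 1000:.2f} kJ/mol, dG2 = {self.dg2 / 1000:.2f} kJ/mol, "
                f"TdS2 = {self.tds2 / 1000:.2f} kJ/mol",
            ]
        lines.append(f"  n = {p.n:.3f}, q_dil = {p.q_dil:.3e} J")
        return "\n".join(lines)


def fit_itc(exp: ItcExperiment, model: str = "one_site", seed: int = 0, fit_n: bool = False) -> ItcResults:
    """Fit a thermogram with the chosen model (thin wrapper over ItcModel)."""
    return ItcModel(exp, model=model, fit_n=fit_n).fit(seed=seed)


# ---------------------------------------------------------------------------
# slow-exchange NMR estimator


class SlowExchangeError(ValueError):
    """Bound fraction of exactly 0 or 1: outside the quantifiable range."""


@dataclass(frozen=True)
class NmrIntegralPair:
    """Free/bound peak integrals of one resonance (arbitrary, shared units)."""

    resonance_id: str
    i_free: float
    i_bound: float

    def __post_init__(self) -> None:
        if self.i_free < 0 or self.i_bound < 0:
            raise ValueError("integrals must be non-negative")
        if self.i_free == 0 and self.i_bound == 0:
            raise ValueError("integrals cannot both be zero")

    @property
    def f_bound(self) -> float:
        return self.i_bound / (self.i_free + self.i_bound)


@dataclass(frozen=True)
class KdEstimate:
    kd_mean: float  # M
    kd_sd: float  # M, sample sd across resonance pairs (0 with flag if n=1)
    n_pairs: int
    p_tot: float
    r_tot: float
    per_pair: tuple[float, ...] = ()
    single_pair: bool = False


def kd_from_integrals(
    pairs: Sequence[NmrIntegralPair], p_tot: float, r_tot: float
) -> KdEstimate:
    """Dissociation constant from slow-exchange free/bound integral pairs.

    Per pair, f_bound = I_bound/(I_free + I_bound) gives the complex
    concentration c = f_bound * min(p_tot, r_tot), and mass balance yields
    K_d = (p_tot − c)(r_tot − c)/c exactly.  Pairs are aggregated as an
    unweighted mean ± sample standard deviation.
    """
    if p_tot <= 0 or r_tot <= 0:
        raise ValueError("totals must be positive")
    if not pairs:
        raise ValueError("need at least one integral pair")
    limiting = min(p_tot, r_tot)
    kds = []
    for pair in pairs:
        f = pair.f_bound
        if f <= 0.0 or f >= 1.0:
            raise SlowExchangeError(
                f"resonance {pair.resonance_id!r}: bound fraction {f} is outside "
                "the slow-exchange quantifiable range (0, 1)"
            )
        c = f * limiting
        kds.append((p_tot - c) * (r_tot - c) / c)
    arr = np.asarray(kds)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return KdEstimate(
        kd_mean=float(arr.mean()),
        kd_sd=sd,
        n_pairs=len(arr),
        p_tot=p_tot,
        r_tot=r_tot,
        per_pair=tuple(float(k) for k in arr),
        single_pair=len(arr) == 1,
    )


def bound_fraction_forward(kd: float, p_tot: float, r_tot: float) -> float:
    """Bound fraction of the limiting species at equilibrium (inverse of
    :func:`kd_from_integrals` for a single ideal pair).

    Solves kd*c = (p_tot − c)(r_tot − c) for the physical root 0 < c <
    min(p_tot, r_tot).
    """
    if kd <= 0 or p_tot <= 0 or r_tot <= 0:
        raise ValueError("kd and totals must be positive")
    b = p_tot + r_tot + kd
    c = (b - math.sqrt(b * b - 4.0 * p_tot * r_tot)) / 2.0
    return c / min(p_tot, r_tot)
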
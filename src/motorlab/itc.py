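"""Single-site isothermal titration calorimetry (ITC) model and fitting.

A titration injects ligand from a syringe into a fixed-volume reaction cell
containing the macromolecule; each injection releases (or absorbs) heat
proportional to the increment of bound ligand.  With a single class of
independent sites, the bound concentration after each injection follows the
quadratic mass balance

    [MX] = ((M_t + X_t + K_d) - sqrt((M_t + X_t + K_d)^2 - 4 M_t X_t)) / 2,

where M_t = n * [macromolecule] is the total site concentration, X_t the
total ligand concentration and K_d the dissociation constant.  The heat of
injection i is

    q_i = dH * V_cell * ([MX]_i - [MX]_{i-1} * (1 - dV_i / V_cell)) + q_0,

the (1 - dV/V) factor accounting for the complex displaced out of the
constant-volume cell by the injection (perfusion convention of MicroCal
instruments).  Concentrations are in mM, volumes in uL, dH in kcal/mol, so
heats come out in ucal (mM * uL * kcal/mol = nmol * kcal/mol = ucal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "TitrationSchedule",
    "BindingParams",
    "SingleSiteFit",
    "simulate_titration",
    "injection_heats",
    "fit_single_site",
    "paper_schedule",
]


@dataclass(frozen=True)
class TitrationSchedule:
    """Injection schedule and concentrations.

    cell_volume          : reaction-cell volume, uL
    cell_concentration   : macromolecule in the cell (binding-site basis), mM
    syringe_concentration: ligand in the syringe, mM
    injection_volumes    : per-injection volumes, uL
    temperature          : deg C (bookkeeping only; the model is isothermal)
    """

    cell_volume: float
    cell_concentration: float
    syringe_concentration: float
    injection_volumes: tuple
    temperature: float = 20.0

    def __post_init__(self) -> None:
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be > 0")
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("concentrations must be > 0")
        vols = tuple(float(v) for v in self.injection_volumes)
        if not vols or any(v <= 0 for v in vols):
            raise ValueError("injection volumes must be positive")
        object.__setattr__(self, "injection_volumes", vols)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


def paper_schedule(
    cell_volume: float = 200.0,
    cell_concentration: float = 0.03,
    syringe_concentration: float = 200.0,
    temperature: float = 20.0,
) -> TitrationSchedule:
    """The salicylate-titration schedule: 0.4 uL first, then 19 x 2 uL, 20 C."""
    return TitrationSchedule(
        cell_volume=cell_volume,
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        injection_volumes=(0.4,) + (2.0,) * 19,
        temperature=temperature,
    )


@dataclass(frozen=True)
class BindingParams:
    """Single-site parameters: K_d (mM), dH (kcal/mol), n sites, baseline (ucal)."""

    K_d: float
    dH: float
    n_sites: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.K_d > 0):
            raise ValueError("K_d must be > 0")
        if not (self.n_sites > 0):
            raise ValueError("n_sites must be > 0")


def _bound_concentration(m_tot: float, x_tot: float, k_d: float) -> float:
    """Exact single-site quadratic mass balance; returns [bound] in mM."""
    b = m_tot + x_tot + k_d
    disc = b * b - 4.0 * m_tot * x_tot
    root = (b - math.sqrt(max(disc, 0.0))) / 2.0
    return min(root, m_tot, x_tot)


def injection_heats(schedule: TitrationSchedule, params: BindingParams) -> np.ndarray:
    """Noise-free per-injection heats (ucal) under displacement bookkeeping.

    Each injection of dV displaces dV of cell contents: existing total
    concentrations are scaled by (1 - dV/V) and the ligand gains
    X_syr * dV/V.  The heat reflects the change in moles of complex in the
    cell, crediting the complex expelled during the injection.
    """
    v0 = schedule.cell_volume
    m_tot = schedule.cell_concentration * params.n_sites  # site concentration
    x_tot = 0.0
    bound_prev = 0.0
    heats = np.empty(schedule.n_injections)
    for i, dv in enumerate(schedule.injection_volumes):
        f = 1.0 - dv / v0
        m_tot *= f
        x_tot = x_tot * f + schedule.syringe_concentration * dv / v0
        bound = _bound_concentration(m_tot, x_tot, params.K_d)
        heats[i] = params.dH * v0 * (bound - bound_prev * f) + params.baseline
        bound_prev = bound
    return heats


def simulate_titration(
    schedule: TitrationSchedule,
    params: BindingParams,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Per-injection heats (ucal) with additive Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    q = injection_heats(schedule, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd, size=q.shape)
    return q


@dataclass
class SingleSiteFit:
    params: BindingParams
    stderr: dict = field(default_factory=dict)
    residual_sd: float = float("nan")
    converged: bool = False
    identifiable: bool = True
    skipped_first: bool = True


def fit_single_site(
    heats: Sequence[float],
    schedule: TitrationSchedule,
    init: Optional[BindingParams] = None,
    fit_n: bool = False,
    fit_baseline: bool = True,
    skip_first: bool = True,
) -> SingleSiteFit:
    """Least-squares fit of the single-site isotherm to per-injection heats.

    The first injection is excluded by default (small pre-injection, diluted
    during equilibration — the customary treatment).  ``n_sites`` is fixed at
    1 unless ``fit_n``; the baseline is fitted unless ``fit_baseline`` is
    false, in which case it is the mean of the last two injections.

    A fit is flagged non-identifiable when the data carry no curvature
    (heats statistically flat), in which case K_d is meaningless.
    """
    q = np.asarray(heats, dtype=float)
    if q.shape != (schedule.n_injections,):
        raise ValueError("heats length does not match the schedule")
    mask = np.ones_like(q, dtype=bool)
    if skip_first:
        mask[0] = False
    if mask.sum() < 5:
        raise ValueError("need at least 5 informative injections")

    baseline0 = float(np.mean(q[-2:]))
    scale = max(float(np.max(np.abs(q - baseline0))), 1e-12)
    identifiable = float(np.std(q[mask])) > 1e-9 * max(abs(baseline0), 1.0)

    if init is None:
        # K_d guess: half the final total ligand concentration (mid-titration);
        # dH guess from the cumulative excess heat over the cell's site content
        x_final = schedule.syringe_concentration * sum(schedule.injection_volumes) / schedule.cell_volume
        sites_nmol = schedule.cell_volume * schedule.cell_concentration
        dh0 = float(np.sum(q[mask] - baseline0)) / max(sites_nmol, 1e-9)
        if abs(dh0) < 1e-6:
            dh0 = -1.0
        init = BindingParams(K_d=max(x_final / 2.0, 1e-6), dH=dh0, n_sites=1.0, baseline=baseline0)

    def unpack(theta):
        log_kd, dh = theta[0], theta[1]
        j = 2
        n = math.exp(theta[j]) if fit_n else 1.0
        if fit_n:
            j += 1
        base = theta[j] if fit_baseline else baseline0
        return BindingParams(K_d=math.exp(log_kd), dH=dh, n_sites=n, baseline=base)

    def resid(theta):
        p = unpack(theta)
        return (injection_heats(schedule, p) - q)[mask] / scale

    theta0 = [math.log(init.K_d), init.dH]
    if fit_n:
        theta0.append(math.log(init.n_sites))
    if fit_baseline:
        theta0.append(init.baseline)
    sol = optimize.least_squares(resid, np.asarray(theta0), method="lm", xtol=1e-14, ftol=1e-14)
    best = unpack(sol.x)

    dof = max(int(mask.sum()) - sol.x.size, 1)
    rss = float(2.0 * sol.cost) * scale * scale
    res_sd = math.sqrt(rss / dof)
    names = ["log_K_d", "dH"] + (["log_n"] if fit_n else []) + (["baseline"] if fit_baseline else [])
    stderr = {}
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * (2.0 * sol.cost / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr = dict(zip(names, map(float, se)))
        if "log_K_d" in stderr:
            stderr["K_d"] = stderr["log_K_d"] * best.K_d  # delta method
    except np.linalg.LinAlgError:
        pass
    if stderr.get("log_K_d", 0.0) > 5.0:  # K_d uncertain over >2 decades
        identifiable = False

    return SingleSiteFit(
        params=best,
        stderr=stderr,
        residual_sd=res_sd,
        converged=bool(sol.success),
        identifiable=identifiable,
        skipped_first=skip_first,
    )
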
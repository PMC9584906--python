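"""Two-state Boltzmann nonlinear capacitance (NLC) model.

Prestin's voltage-sensor charge movement appears in whole-cell recordings as a
bell-shaped, voltage-dependent component of the membrane capacitance.  The
model evaluated and fitted here is the derivative of a two-state Boltzmann
charge-voltage relation,

    C_m(V) = alpha * Q_max * exp[alpha (V - V_pk)]
             / (1 + exp[alpha (V - V_pk)])**2  +  C_lin,

where ``alpha`` is the slope factor (mV^-1), ``Q_max`` the maximum mobile
sensor charge (fC), ``V_pk`` the voltage of peak charge movement (mV) and
``C_lin`` the voltage-independent (linear) membrane capacitance (pF).  The
peak NLC magnitude is alpha*Q_max/4, attained at V = V_pk.

Because expression level scales with cell size, NLC magnitude is corrected by
the linear capacitance: charge density = Q_max/C_lin (fC/pF) and
C_sp = (C_m - C_lin)/C_lin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "NLCParams",
    "CapacitanceSweep",
    "NLCFit",
    "eval_nlc",
    "fit_nlc",
    "detect_nlc",
    "compare_groups",
    "compare_to_control",
]

# fit bounds: alpha in (0, 1] mV^-1, |V_pk| <= 500 mV, Q_max >= 0, C_lin > 0
_ALPHA_MAX = 1.0
_VPK_LIM = 500.0
_DETECT_CSP_FLOOR = 0.005  # minimum peak C_sp for NLC to count as detectable
_DETECT_QMAX_K = 3.0       # Q_max must exceed this multiple of its SE


@dataclass(frozen=True)
class NLCParams:
    """Parameters of the two-state Boltzmann NLC function.

    alpha : slope factor, mV^-1 (> 0)
    V_pk  : voltage of maximal charge movement, mV
    Q_max : maximum charge transfer, fC (>= 0)
    C_lin : linear capacitance, pF (> 0)
    """

    alpha: float
    V_pk: float
    Q_max: float
    C_lin: float

    def __post_init__(self) -> None:
        for name in ("alpha", "V_pk", "Q_max", "C_lin"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"NLCParams.{name} must be finite, got {v!r}")
        if self.alpha <= 0:
            raise ValueError(f"NLCParams.alpha must be > 0, got {self.alpha}")
        if self.Q_max < 0:
            raise ValueError(f"NLCParams.Q_max must be >= 0, got {self.Q_max}")
        if self.C_lin <= 0:
            raise ValueError(f"NLCParams.C_lin must be > 0, got {self.C_lin}")

    @property
    def charge_density(self) -> float:
        """Q_max / C_lin in fC/pF (cell-size-corrected total charge)."""
        return self.Q_max / self.C_lin

    @property
    def peak_Csp(self) -> float:
        """Peak of (C_m - C_lin)/C_lin, i.e. alpha * Q_max / (4 C_lin)."""
        return self.alpha * self.Q_max / (4.0 * self.C_lin)


@dataclass
class CapacitanceSweep:
    """One capacitance-voltage sweep: V in mV, C_m in pF."""

    V: np.ndarray
    C_m: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.C_m = np.asarray(self.C_m, dtype=float)
        if self.V.shape != self.C_m.shape or self.V.ndim != 1:
            raise ValueError("V and C_m must be 1-D arrays of equal length")
        if self.V.size < 8:
            raise ValueError("sweep needs at least 8 points")
        dv = np.diff(self.V)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValueError("V must be strictly monotone")
        if not np.all(np.isfinite(self.C_m)):
            raise ValueError("C_m contains non-finite values")


@dataclass
class NLCFit:
    """Result of fitting Eq.-style two-state Boltzmann NLC to one sweep."""

    params: NLCParams
    stderr: dict = field(default_factory=dict)
    residual_sd: float = float("nan")
    converged: bool = False
    n_iter: int = 0
    detectable: bool = False
    cell_id: str = ""

    @property
    def charge_density(self) -> float:
        return self.params.charge_density

    @property
    def peak_Csp(self) -> float:
        return self.params.peak_Csp


def eval_nlc(params: NLCParams, V: Sequence[float]) -> np.ndarray:
    """Evaluate the two-state Boltzmann NLC function on a voltage grid.

    Uses the algebraically equivalent sech^2 form,
    alpha*Q_max / (4 cosh^2(alpha (V-V_pk)/2)) + C_lin, which cannot overflow
    for large |alpha (V - V_pk)|.
    """
    V = np.asarray(V, dtype=float)
    x = 0.5 * params.alpha * (V - params.V_pk)
    # cosh overflows near 710; beyond that the NLC term is < 1e-300 pF
    out = np.full_like(x, params.C_lin)
    ok = np.abs(x) < 350.0
    out[ok] += params.alpha * params.Q_max / (4.0 * np.cosh(x[ok]) ** 2)
    return out


def _auto_init(V: np.ndarray, C: np.ndarray) -> NLCParams:
    # C_lin from the 10% most extreme-voltage points (tails of the bell)
    n_tail = max(1, int(round(0.05 * V.size)))
    order = np.argsort(np.abs(V - np.median(V)))[::-1]
    c_lin = float(np.mean(C[order[: 2 * n_tail]]))
    c_lin = max(c_lin, 1e-6)
    v_pk = float(V[int(np.argmax(C - c_lin))])
    peak = max(float(np.max(C) - c_lin), 1e-9)
    alpha0 = 0.03
    q_max = 4.0 * peak / alpha0
    return NLCParams(alpha=alpha0, V_pk=v_pk, Q_max=q_max, C_lin=c_lin)


def fit_nlc(
    sweep: CapacitanceSweep,
    init: Optional[NLCParams] = None,
    window: float = 200.0,
) -> NLCFit:
    """Least-squares fit of the two-state Boltzmann NLC model to a sweep.

    All four parameters (alpha, V_pk, Q_max, C_lin) are free.  Standard
    errors come from the Jacobian-based covariance at the solution.  The
    ``detectable`` flag applies :func:`detect_nlc` with the given voltage
    window (mV, symmetric about 0).
    """
    V, C = sweep.V, sweep.C_m
    if V.size < 4:
        raise ValueError("fewer points than parameters")
    p0 = init if init is not None else _auto_init(V, C)

    def resid(theta: np.ndarray) -> np.ndarray:
        a, vpk, q, cl = theta
        pars = NLCParams(max(a, 1e-9), vpk, max(q, 0.0), max(cl, 1e-9))
        return eval_nlc(pars, V) - C

    x0 = np.array([p0.alpha, p0.V_pk, p0.Q_max, p0.C_lin])
    lo = np.array([1e-6, -_VPK_LIM, 0.0, 1e-6])
    hi = np.array([_ALPHA_MAX, _VPK_LIM, np.inf, np.inf])
    x0 = np.clip(x0, lo, hi)
    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)

    a, vpk, q, cl = sol.x
    params = NLCParams(alpha=float(a), V_pk=float(vpk), Q_max=float(q), C_lin=float(cl))
    dof = max(V.size - 4, 1)
    rss = float(2.0 * sol.cost)
    res_sd = math.sqrt(rss / dof)
    # covariance from J^T J pseudo-inverse, scaled by residual variance
    stderr = {}
    try:
        JTJ = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(JTJ) * (rss / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr = dict(zip(("alpha", "V_pk", "Q_max", "C_lin"), map(float, se)))
    except np.linalg.LinAlgError:
        pass

    fit = NLCFit(
        params=params,
        stderr=stderr,
        residual_sd=res_sd,
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        cell_id=sweep.cell_id,
    )
    fit.detectable = detect_nlc(fit, window=window)
    return fit


def detect_nlc(fit: NLCFit, window: float = 200.0) -> bool:
    """Decide whether a fitted NLC is detectable inside a voltage window.

    True iff the fit converged, V_pk lies within +/- window mV, Q_max exceeds
    3x its standard error, and the peak C_sp clears a small floor (0.005).
    Mirrors the experimental notion of NLC being lost when its peak moves
    outside the measurable range or its magnitude sinks into noise.
    """
    if not fit.converged:
        return False
    p = fit.params
    if not (-window <= p.V_pk <= window):
        return False
    se_q = fit.stderr.get("Q_max", float("inf"))
    if not (p.Q_max > _DETECT_QMAX_K * se_q):
        return False
    return p.peak_Csp >= _DETECT_CSP_FLOOR


_PARAM_NAMES = ("alpha", "V_pk", "Q_max", "C_lin", "charge_density")


def _param_matrix(fits: Sequence[NLCFit]) -> dict:
    out = {}
    for name in _PARAM_NAMES:
        if name == "charge_density":
            vals = [f.charge_density for f in fits]
        else:
            vals = [getattr(f.params, name) for f in fits]
        out[name] = np.asarray(vals, dtype=float)
    return out


def compare_groups(fits_a: Sequence[NLCFit], fits_b: Sequence[NLCFit]) -> dict:
    """Two-group comparison of fitted NLC parameters (Welch's t per parameter).

    Returns, per parameter: group means and SDs, the mean difference, and the
    Welch t-test p-value.  Groups of size < 2 get SD/p flagged as NaN.
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("each group needs at least 2 fits")
    A, B = _param_matrix(fits_a), _param_matrix(fits_b)
    table = {}
    for name in _PARAM_NAMES:
        a, b = A[name], B[name]
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            p = 1.0  # identical degenerate groups
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        table[name] = {
            "mean_a": float(a.mean()),
            "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()),
            "sd_b": float(b.std(ddof=1)),
            "diff": float(a.mean() - b.mean()),
            "p": p,
        }
    return table


def compare_to_control(control: Sequence[NLCFit], *groups: Sequence[NLCFit]) -> dict:
    """Dunnett's many-to-one comparison of each group against a control.

    Per parameter, returns the control mean and, for each treatment group,
    its mean and the Dunnett-adjusted p-value (scipy implementation).
    """
    if len(control) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 fits")
    C = _param_matrix(control)
    Gs = [_param_matrix(g) for g in groups]
    table = {}
    for name in _PARAM_NAMES:
        res = stats.dunnett(*[g[name] for g in Gs], control=C[name])
        table[name] = {
            "control_mean": float(C[name].mean()),
            "group_means": [float(g[name].mean()) for g in Gs],
            "p_adjusted": [float(p) for p in res.pvalue],
        }
    return table
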
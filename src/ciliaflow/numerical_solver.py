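"""Independent numerical solution of the reduced boundary-value problem.

Serves as the validation oracle for the closed-form perturbation
expressions.  The momentum equation integrates exactly (using the
centreline symmetry psi_yy(0) = 0) to the cubic first integral

    psi_yy - zeta * psi_yy**3 = A * y,

where A is the constant axial pressure gradient.  The solver inverts the
cubic on its Newtonian-continuous branch pointwise and reduces the
remaining boundary conditions to a single bracketed root find in A, with
a direct collocation solve of the fourth-order form as a cross-check.
All tolerances are fixed; there is no randomness anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, simpson, solve_bvp
from scipy.optimize import brentq

from .model_core import FlowParameters, wall_state
from . import perturbation_solution as ps

__all__ = [
    "BranchLossError",
    "SolverError",
    "cubic_branch_root",
    "MomentumSolution",
    "solve_momentum_bvp",
    "solve_momentum_collocation",
    "ThermalBVP",
    "solve_thermal_bvp",
    "compare_tables",
    "scan_conventions",
]

log = logging.getLogger("ciliaflow")


class SolverError(RuntimeError):
    """Numerical solver failed to converge; carries final residuals."""


class BranchLossError(SolverError):
    """|rhs| exceeds the constitutive fold 2/(3*sqrt(3*zeta))."""


def cubic_branch_root(zeta: float, rhs):
    """Real root w of  w - zeta*w**3 = rhs  continuous in zeta at zeta=0.

    For zeta > 0 the constitutive law w -> w - zeta*w^3 is monotone only
    for |w| < 1/sqrt(3*zeta); the Newtonian branch is returned via the
    trigonometric root  w = (2/sqrt(3*zeta)) * sin(arcsin(r)/3)  with
    r = (3*sqrt(3*zeta)/2)*rhs.  Beyond the fold (|r| > 1) no root exists
    on the branch and BranchLossError is raised rather than silently
    switching branches.
    """
    rhs = np.asarray(rhs, dtype=float)
    if zeta < 0:
        raise ValueError("zeta must be >= 0")
    if zeta == 0:
        return rhs if rhs.ndim else float(rhs)
    s = math.sqrt(3.0 * zeta)
    r = 1.5 * s * rhs
    if np.any(np.abs(r) > 1.0):
        raise BranchLossError(
            f"rhs magnitude {np.max(np.abs(rhs)):.6g} beyond the fold "
            f"{2.0 / (3.0 * s):.6g} (constitutive non-monotonicity)"
        )
    w = (2.0 / s) * np.sin(np.arcsin(r) / 3.0)
    return w if w.ndim else float(w)


@dataclass
class MomentumSolution:
    """Momentum BVP solution on [0, h] with the implied dp/dx = A."""

    y: np.ndarray
    psi: np.ndarray
    psi_y: np.ndarray
    psi_yy: np.ndarray
    A: float
    h: float
    u_h: float
    q: float
    zeta: float
    bc_residual: float = field(default=0.0)

    def first_integral_residual(self) -> float:
        return float(np.max(np.abs(
            self.psi_yy - self.zeta * self.psi_yy**3 - self.A * self.y)))

    def u(self, y):
        from scipy.interpolate import CubicSpline
        return CubicSpline(self.y, self.psi_y)(y)

    def psi_at(self, y):
        from scipy.interpolate import CubicSpline
        return CubicSpline(self.y, self.psi)(y)


def solve_momentum_bvp(p: FlowParameters, x: float = 1.0, n: int = 2001) -> MomentumSolution:
    """Solve the momentum BVP at station x on an n-point grid.

    The two-parameter shoot (A, psi_y(0)) reduces exactly: psi_yy depends
    on y alone through the first integral, so psi_y(0) enters linearly and
    is eliminated, leaving one scalar equation in A solved by bracketed
    Brent iteration (xtol 1e-14).  At zeta = 0 the result reproduces the
    Newtonian cubic closed form to quadrature accuracy (~1e-12 at n=2001).
    """
    w = wall_state(x, p)
    h, uh, q, zeta = w.h, w.u_h, p.flux(), p.zeta
    y = np.linspace(0.0, h, n)

    def phi(A):
        g = cubic_branch_root(zeta, A * y)
        G1 = simpson(g, x=y)
        G2 = simpson((h - y) * g, x=y)
        return (uh - G1) * h + G2 - q

    A0 = 3.0 * (h * uh - q) / h**3
    fold = math.inf if zeta == 0 else 2.0 / (3.0 * math.sqrt(3.0 * zeta) * h)
    lo = hi = A0
    step = max(abs(A0), 1.0)
    for _ in range(80):
        lo = max(lo - step, -fold * (1 - 1e-12))
        hi = min(hi + step, fold * (1 - 1e-12))
        try:
            flo, fhi = phi(lo), phi(hi)
        except BranchLossError:
            raise
        if flo * fhi <= 0:
            break
    else:
        raise SolverError(f"could not bracket pressure gradient near A0={A0:.6g}")
    A = brentq(phi, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    g = cubic_branch_root(zeta, A * y)
    Cg = cumulative_simpson(g, x=y, initial=0.0)
    Ctg = cumulative_simpson(y * g, x=y, initial=0.0)
    s0 = uh - Cg[-1]
    psi_y = s0 + Cg
    psi = s0 * y + y * Cg - Ctg
    sol = MomentumSolution(y=y, psi=psi, psi_y=psi_y, psi_yy=g, A=float(A),
                           h=h, u_h=uh, q=q, zeta=zeta)
    sol.bc_residual = float(max(abs(psi[0]), abs(g[0]), abs(psi[-1] - q),
                                abs(psi_y[-1] - uh)))
    log.info("momentum shoot x=%g zeta=%g n=%d A=%.12g bc_res=%.3e fint_res=%.3e",
             x, zeta, n, A, sol.bc_residual, sol.first_integral_residual())
    if sol.bc_residual > 1e-10:
        raise SolverError(f"momentum BC residual {sol.bc_residual:.3e}")
    return sol


def solve_momentum_collocation(p: FlowParameters, x: float = 1.0, n: int = 201) -> MomentumSolution:
    """Cross-check: collocation on the fourth-order form.

    psi'''' * (1 - 3*zeta*psi''^2) = 6*zeta*psi''*psi'''^2 with
    psi(0)=psi''(0)=0, psi(h)=q, psi'(h)=u_h, solved by scipy's
    collocation method seeded with the Newtonian closed form.
    """
    w = wall_state(x, p)
    h, uh, q, zeta = w.h, w.u_h, p.flux(), p.zeta

    def rhs(y, z):
        denom = 1.0 - 3.0 * zeta * z[2] ** 2
        return np.vstack([z[1], z[2], z[3], 6.0 * zeta * z[2] * z[3] ** 2 / denom])

    def bc(za, zb):
        return np.array([za[0], za[2], zb[0] - q, zb[1] - uh])

    y = np.linspace(0.0, h, n)
    psis, As = ps.momentum_series(h, uh, q, order=0)
    z0 = np.vstack([
        np.polynomial.polynomial.polyval(y, psis[0]),
        np.polynomial.polynomial.polyval(y, np.polynomial.polynomial.polyder(psis[0])),
        As[0] * y,
        np.full_like(y, As[0]),
    ])
    res = solve_bvp(rhs, bc, y, z0, tol=1e-10, max_nodes=200000)
    if not res.success:
        raise SolverError(f"collocation failed: {res.message}")
    yy = np.linspace(0.0, h, n)
    z = res.sol(yy)
    # first integral: A = (w - zeta*w^3)/y evaluated at the wall
    wh = float(res.sol(h)[2])
    A = (wh - zeta * wh**3) / h
    sol = MomentumSolution(y=yy, psi=z[0], psi_y=z[1], psi_yy=z[2], A=A,
                           h=h, u_h=uh, q=q, zeta=zeta)
    sol.bc_residual = float(max(abs(z[0, 0]), abs(z[2, 0]),
                                abs(z[0, -1] - q), abs(z[1, -1] - uh)))
    return sol


# ---------------------------------------------------------------------------
# thermal BVP
# ---------------------------------------------------------------------------

@dataclass
class ThermalBVP:
    """theta/sigma profiles of the coupled heat/mass BVP."""

    y: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray
    c_sigma: float          # constant of the integrated concentration equation
    k: float                # decay rate Pr*Nb*c_sigma
    bc_residual: float


def solve_thermal_bvp(p: FlowParameters, x: float = 1.0,
                      m: MomentumSolution | None = None) -> ThermalBVP:
    """Solve the coupled theta/sigma system against a momentum solution.

    Uses the exact reduction sigma' = -(Nt/Nb)*theta' + c from integrating
    the concentration equation, and a damped-Newton two-condition shoot on
    (theta'(0), c) with residuals (theta(h)-1, sigma(h)-1), conduction
    initial guess, tolerance 1e-10, at most 100 iterations.
    """
    if m is None:
        m = solve_momentum_bvp(p, x)
    y, h = m.y, m.h
    f = -p.Pr * p.Ec * m.psi_yy**2

    def profiles(t1, c):
        k = p.Pr * p.Nb * c
        # theta'(y) = t1*e^{-ky} + int_0^y e^{-k(y-s)} f(s) ds; the kernel is
        # written with exponents shifted by h so nothing overflows for k*h >> 1
        I = cumulative_simpson(np.exp(k * (y - h)) * f, x=y, initial=0.0)
        tp = t1 * np.exp(-k * y) + np.exp(-k * (y - h)) * I
        theta = cumulative_simpson(tp, x=y, initial=0.0)
        sigma = -(p.Nt / p.Nb) * theta + c * y
        return theta, sigma

    t1 = 1.0 / h
    c = (1.0 + p.Nt / p.Nb) / h
    for it in range(100):
        theta, sigma = profiles(t1, c)
        r = np.array([theta[-1] - 1.0, sigma[-1] - 1.0])
        if np.max(np.abs(r)) < 1e-10:
            break
        eps_fd = 1e-7
        J = np.empty((2, 2))
        for j, (dt, dc) in enumerate([(eps_fd, 0.0), (0.0, eps_fd)]):
            th2, sg2 = profiles(t1 + dt, c + dc)
            J[:, j] = ([th2[-1] - 1.0, sg2[-1] - 1.0] - r) / eps_fd
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as e:
            raise SolverError(f"thermal Jacobian singular: {e}") from e
        lam = 1.0
        base = np.max(np.abs(r))
        for _ in range(30):
            th2, sg2 = profiles(t1 + lam * step[0], c + lam * step[1])
            if max(abs(th2[-1] - 1.0), abs(sg2[-1] - 1.0)) < base:
                break
            lam *= 0.5
        t1 += lam * step[0]
        c += lam * step[1]
    else:
        raise SolverError(
            f"thermal shoot did not converge: residuals {r.tolist()}")
    theta, sigma = profiles(t1, c)
    res = float(max(abs(theta[0]), abs(sigma[0]),
                    abs(theta[-1] - 1.0), abs(sigma[-1] - 1.0)))
    log.info("thermal shoot x=%g zeta=%g c=%.9g bc_res=%.3e", x, p.zeta, c, res)
    return ThermalBVP(y=y, theta=theta, sigma=sigma, c_sigma=float(c),
                      k=float(p.Pr * p.Nb * c), bc_residual=res)


# ---------------------------------------------------------------------------
# table comparison
# ---------------------------------------------------------------------------

def compare_tables(p: FlowParameters, x: float, ygrid, n: int = 2001) -> pd.DataFrame:
    """Perturbation vs numerical u and psi on a y-grid (table layout).

    Returns one row per y with (perturb, numerical, difference) for the
    axial velocity and the stream function, mirroring the published
    comparison tables.
    """
    ygrid = np.asarray(ygrid, dtype=float)
    m = solve_momentum_bvp(p, x, n=n)
    up = np.asarray(ps.u_perturb(ygrid, x, p))
    pp = np.asarray(ps.psi_perturb(ygrid, x, p))
    un = m.u(ygrid)
    pn = m.psi_at(ygrid)
    return pd.DataFrame({
        "y": ygrid,
        "u_perturb": up, "u_numerical": un, "u_difference": up - un,
        "psi_perturb": pp, "psi_numerical": pn, "psi_difference": pp - pn,
    })


def scan_conventions(base: FlowParameters, x: float | None = None) -> pd.DataFrame:
    """Deviation of each convention combination from the printed tables.

    Evaluates the perturbation and numerical columns under every
    (wall, tip, series, flux) toggle combination at the published table
    parameters and reports the maximum absolute deviation from the printed
    Table-1/Table-2 columns, plus the internal perturbation-vs-numerical
    gap.  Sorted so the best-matching convention comes first.
    """
    from . import reference_tables as rt
    from .model_core import Conventions

    x = rt.TABLE_X if x is None else x
    rows = []
    for wall in ("scaled", "verbatim"):
        for tip in ("printed", "two_pi"):
            for series in ("derived", "printed"):
                for flux in ("half", "full"):
                    conv = Conventions(wall=wall, tip=tip, series=series, flux=flux)
                    p = base.with_(conventions=conv)
                    df = compare_tables(p, x, rt.Y_GRID)
                    rows.append({
                        "wall": wall, "tip": tip, "series": series, "flux": flux,
                        "table1_dev": float(np.max(np.abs(df.u_perturb - rt.TABLE1_U_PERTURB))),
                        "table1_num_dev": float(np.max(np.abs(df.u_numerical - rt.TABLE1_U_NUMERICAL))),
                        "table2_dev": float(np.max(np.abs(df.psi_perturb - rt.TABLE2_PSI_PERTURB))),
                        "table2_num_dev": float(np.max(np.abs(df.psi_numerical - rt.TABLE2_PSI_NUMERICAL))),
                        "internal_u_gap": float(np.max(np.abs(df.u_difference))),
                        "internal_psi_gap": float(np.max(np.abs(df.psi_difference))),
                    })
    out = pd.DataFrame(rows)
    out["total_dev"] = out.table1_dev + out.table2_dev
    return out.sort_values("total_dev", ignore_index=True)
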
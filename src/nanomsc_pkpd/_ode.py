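"""Numerical integration backends.

Two paths are provided:

* an exact matrix-exponential propagator for the static-geometry PK system,
  which is linear time-invariant between dose events;
* an LSODA path (numba-compiled right-hand side) for the coupled PK-PD
  system, whose dynamic geometry (VT = a*TV**b) makes it nonlinear.  The
  system is stiff: the free-PTX tumor compartment equilibrates on a ~2e-3 h
  timescale while tumor growth evolves over hundreds of hours.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from numba import njit
from scipy.integrate import ODEintWarning, odeint
from scipy.linalg import expm

from .model import LAYER_CENTRAL_INDEX, NSTATE, TV_FLOOR, linear_system_matrix
from .params import ModelParams

__all__ = [
    "pack_theta",
    "coupled_rhs",
    "coupled_jac",
    "integrate_coupled",
    "integrate_coupled_fast",
    "integrate_linear",
]

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


def pack_theta(params: ModelParams, arm: str = "nano_msc",
               Kg0: float = None, tv_floor: float = TV_FLOOR) -> np.ndarray:
    """Pack a ModelParams (+ arm growth rate) into the flat float vector
    consumed by the compiled right-hand side."""
    p, n, m, tr, g = params.ptx, params.np_, params.msc, params.transfer, params.geometry
    pdp = params.pd
    if Kg0 is None:
        Kg0 = pdp.Kg0[arm] if (pdp is not None and arm in pdp.Kg0) else 0.0
    cal = params.calibration
    a = cal.a if cal is not None else 1.0
    b = cal.b if cal is not None else 1.0
    kill = (pdp.Kmax_PTX, pdp.IC50_PTX, pdp.Kmax_NP, pdp.IC50_NP, pdp.K_MSC) \
        if pdp is not None else (0.0, 1.0, 0.0, 1.0, 0.0)
    return np.array([
        p.CL, p.CLD, p.Vc, p.Vp, p.E, p.P, p.D,
        n.CL, n.CLD, n.Vc, n.Vp, n.E, n.P, n.D,
        m.Kct, m.Kcp, tr.Krel, tr.Kexo,
        g.Rcap, g.RKrogh, a, b,
        Kg0, *kill,
        tv_floor, 0.0 if g.dynamic else 1.0, g.VT,
    ])


@njit(cache=True)
def coupled_rhs(y, t, v):
    """dy/dt for [9 PK amounts, log TV]; ``v`` is the packed parameter
    vector.  The tumor burden is integrated on log scale, which keeps the
    right-hand side smooth through near-remission trajectories (the burden
    can decay arbitrarily close to zero without sign changes or floors in
    the state itself; only the geometry map applies the burden floor)."""
    z = y[9] if y[9] < 700.0 else 700.0
    TV = np.exp(z)
    TVf = TV if TV > v[28] else v[28]  # floored burden for the geometry map
    if v[29] > 0.5:  # static geometry
        VT = v[30]
    else:
        VT = v[20] * TVf ** v[21]
    Rt = (VT / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    rk2 = v[19] * v[19]
    kexP = (2.0 * v[5] * v[18] / rk2 + 6.0 * v[6] / (Rt * Rt)) * VT
    kexN = (2.0 * v[12] * v[18] / rk2 + 6.0 * v[13] / (Rt * Rt)) * VT

    CcP = y[0] / v[2]
    CtP = y[1] / VT
    CpP = y[2] / v[3]
    fluxP = kexP * (CcP * v[4] - CtP)
    distP = v[1] * (CpP - CcP)
    elimP = v[0] * CcP

    CcN = y[3] / v[9]
    CtN = y[4] / VT
    CpN = y[5] / v[10]
    fluxN = kexN * (CcN * v[11] - CtN)
    distN = v[8] * (CpN - CcN)
    elimN = v[7] * CcN

    krel = v[16]
    kexo = v[17]
    d = np.empty(10)
    d[6] = -(v[14] + v[15] + krel + kexo) * y[6]
    d[7] = v[14] * y[6] - (krel + kexo) * y[7]
    d[8] = v[15] * y[6] - (krel + kexo) * y[8]
    d[3] = distN - elimN - fluxN - krel * y[3] + kexo * y[6]
    d[4] = fluxN - krel * y[4] + kexo * y[7]
    d[5] = -distN - krel * y[5] + kexo * y[8]
    d[0] = distP - elimP - fluxP + krel * (y[3] + y[6])
    d[1] = fluxP + krel * (y[4] + y[7])
    d[2] = -distP + krel * (y[5] + y[8])

    kkP = v[23] * CtP / (v[24] + CtP)
    kkN = v[25] * CtN / (v[26] + CtN)
    kkM = v[27] * (y[7] / VT)
    d[9] = v[22] - kkP - kkN - kkM  # d(log TV)/dt
    return d


def integrate_coupled(theta_vec: np.ndarray, dose_times, dose_amounts,
                      dose_layers, tv0: float, t_out,
                      rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
    """Integrate the coupled PK-PD system through a bolus schedule.

    ``dose_layers`` are central-compartment state indices (0 free, 3 NP,
    6 MSC).  Returns states of shape (len(t_out), 10); ``t_out`` must be
    nondecreasing and start at >= 0.  Doses at t=0 are applied before the
    first output.
    """
    t_req = np.asarray(t_out, dtype=float)
    if t_req.size and np.any(np.diff(t_req) < 0):
        raise ValueError("output times must be nondecreasing")
    t_out, inv = np.unique(t_req, return_inverse=True)
    dose_times = np.asarray(dose_times, dtype=float)
    order = np.argsort(dose_times, kind="stable")
    dose_times = dose_times[order]
    dose_amounts = np.asarray(dose_amounts, dtype=float)[order]
    dose_layers = np.asarray(dose_layers, dtype=np.int64)[order]

    if not (tv0 > 0):
        raise ValueError(f"initial tumor burden must be > 0, got {tv0!r}")
    y = np.zeros(NSTATE + 1)
    y[9] = math.log(tv0)  # burden integrated on log scale
    out = np.empty((t_out.size, NSTATE + 1))
    t_now = 0.0
    i_out = 0
    i_dose = 0
    horizon = max(t_out[-1] if t_out.size else 0.0,
                  dose_times[-1] if dose_times.size else 0.0)
    # apply any t=0 doses before emitting t=0 outputs
    while i_dose < dose_times.size and dose_times[i_dose] <= 0.0:
        y[dose_layers[i_dose]] += dose_amounts[i_dose]
        i_dose += 1
    while True:
        # emit outputs at the current time (post-dose values)
        while i_out < t_out.size and t_out[i_out] <= t_now:
            out[i_out] = y
            i_out += 1
        t_next = dose_times[i_dose] if i_dose < dose_times.size else horizon
        if t_next <= t_now:
            if i_dose < dose_times.size:
                y[dose_layers[i_dose]] += dose_amounts[i_dose]
                i_dose += 1
                continue
            break
        # outputs strictly inside (t_now, t_next)
        seg = []
        j = i_out
        while j < t_out.size and t_out[j] < t_next:
            seg.append(j)
            j += 1
        ts = np.concatenate(([t_now], t_out[seg], [t_next]))
        with warnings.catch_warnings():
            # trial parameter vectors during optimization can be absurd;
            # failures surface through the non-finite-state guards upstream
            warnings.simplefilter("ignore", ODEintWarning)
            ys = odeint(coupled_rhs, y, ts, args=(theta_vec,),
                        rtol=rtol, atol=atol, mxstep=100000)
        for k, jj in enumerate(seg):
            out[jj] = ys[1 + k]
        i_out = j
        y = ys[-1].copy()
        t_now = t_next
        if i_dose < dose_times.size and dose_times[i_dose] <= t_now:
            y[dose_layers[i_dose]] += dose_amounts[i_dose]
            i_dose += 1
        elif t_now >= horizon:
            while i_out < t_out.size:
                out[i_out] = y
                i_out += 1
            break
    out = out[inv]
    out[:, 9] = np.exp(np.minimum(out[:, 9], 700.0))
    return out


def integrate_linear(params: ModelParams, arm: str, dose_times, dose_amounts,
                     dose_layers, t_out,
                     with_elimination_accumulator: bool = False) -> np.ndarray:
    """Exact propagation of the static-geometry (linear) PK system through a
    bolus schedule using matrix exponentials.

    ``dose_layers`` may be layer names or central-compartment indices.
    Returns states of shape (len(t_out), 9) (10 with the accumulator).
    """
    A = linear_system_matrix(params, arm,
                             with_elimination_accumulator=with_elimination_accumulator)
    n = A.shape[0]
    t_out = np.asarray(t_out, dtype=float)
    dose_times = np.asarray(dose_times, dtype=float)
    idx = np.array([LAYER_CENTRAL_INDEX[l] if isinstance(l, str) else int(l)
                    for l in dose_layers], dtype=np.int64)
    order = np.argsort(dose_times, kind="stable")
    dose_times, idx = dose_times[order], idx[order]
    dose_amounts = np.asarray(dose_amounts, dtype=float)[order]

    # event-sorted sweep over the union of dose and output times
    events = sorted(
        [(t, 0, k) for k, t in enumerate(dose_times)]
        + [(t, 1, k) for k, t in enumerate(t_out)],
        key=lambda e: (e[0], e[1])
    )
    y = np.zeros(n)
    out = np.empty((t_out.size, n))
    t_now = 0.0
    cache = {}
    for t, kind, k in events:
        dt = t - t_now
        if dt < 0:
            raise ValueError("times must be >= 0")
        if dt > 0:
            key = round(dt, 12)
            if key not in cache:
                with np.errstate(over="ignore", invalid="ignore"):
                    cache[key] = expm(A * dt)
            y = cache[key] @ y
            t_now = t
        if kind == 0:
            y = y.copy()
            y[idx[k]] += dose_amounts[k]
        else:
            out[k] = y
    return out


# --- compiled TR-BDF2 path ---------------------------------------------------
#
# The estimation stack evaluates thousands of trajectories; LSODA through the
# odeint callback interface spends most of its time crossing the Python/numba
# boundary and finite-differencing the Jacobian.  The one-step, L-stable
# TR-BDF2 scheme with gamma = 2 - sqrt(2) shares a single iteration matrix
# between its trapezoidal and BDF2 stages, so each step costs one LU
# factorization of the analytic 10x10 Jacobian plus a few back-solves, and
# the whole trajectory runs inside compiled code.

_GAMMA = 2.0 - math.sqrt(2.0)


@njit(cache=True)
def coupled_jac(y, t, v):
    """Analytic Jacobian of :func:`coupled_rhs` (10x10)."""
    J = np.zeros((10, 10))
    z = y[9] if y[9] < 700.0 else 700.0
    TV = np.exp(z)
    floored = TV <= v[28]
    TVf = TV if not floored else v[28]
    static = v[29] > 0.5
    if static:
        VT = v[30]
        dVT_dz = 0.0
    else:
        VT = v[20] * TVf ** v[21]
        dVT_dz = 0.0 if floored else v[21] * VT
    K23 = _FOUR_THIRDS_PI ** (2.0 / 3.0)
    rk2 = v[19] * v[19]
    c1P = 2.0 * v[5] * v[18] / rk2
    c2P = 6.0 * v[6] * K23
    c1N = 2.0 * v[12] * v[18] / rk2
    c2N = 6.0 * v[13] * K23
    kexP = c1P * VT + c2P * VT ** (1.0 / 3.0)
    kexN = c1N * VT + c2N * VT ** (1.0 / 3.0)
    dkexP = c1P + c2P / 3.0 * VT ** (-2.0 / 3.0)
    dkexN = c1N + c2N / 3.0 * VT ** (-2.0 / 3.0)

    CcP = y[0] / v[2]
    CtP = y[1] / VT
    CcN = y[3] / v[9]
    CtN = y[4] / VT
    krel = v[16]
    kexo = v[17]

    # free-PTX layer
    dfP_d0 = kexP * v[4] / v[2]
    dfP_d1 = -kexP / VT
    dfP_dz = (dkexP * (CcP * v[4] - CtP) + kexP * y[1] / (VT * VT)) * dVT_dz
    J[0, 0] = -(v[1] + v[0]) / v[2] - dfP_d0
    J[0, 1] = -dfP_d1
    J[0, 2] = v[1] / v[3]
    J[0, 3] = krel
    J[0, 6] = krel
    J[0, 9] = -dfP_dz
    J[1, 0] = dfP_d0
    J[1, 1] = dfP_d1
    J[1, 4] = krel
    J[1, 7] = krel
    J[1, 9] = dfP_dz
    J[2, 0] = v[1] / v[2]
    J[2, 2] = -v[1] / v[3]
    J[2, 5] = krel
    J[2, 8] = krel

    # NP layer
    dfN_d3 = kexN * v[11] / v[9]
    dfN_d4 = -kexN / VT
    dfN_dz = (dkexN * (CcN * v[11] - CtN) + kexN * y[4] / (VT * VT)) * dVT_dz
    J[3, 3] = -(v[8] + v[7]) / v[9] - dfN_d3 - krel
    J[3, 4] = -dfN_d4
    J[3, 5] = v[8] / v[10]
    J[3, 6] = kexo
    J[3, 9] = -dfN_dz
    J[4, 3] = dfN_d3
    J[4, 4] = dfN_d4 - krel
    J[4, 7] = kexo
    J[4, 9] = dfN_dz
    J[5, 3] = v[8] / v[9]
    J[5, 5] = -v[8] / v[10] - krel
    J[5, 8] = kexo

    # MSC layer
    J[6, 6] = -(v[14] + v[15] + krel + kexo)
    J[7, 6] = v[14]
    J[7, 7] = -(krel + kexo)
    J[8, 6] = v[15]
    J[8, 8] = -(krel + kexo)

    # log-burden row: d9 = Kg0 - kkP - kkN - kkM
    denP = v[24] + CtP
    denN = v[26] + CtN
    dkkP_d1 = v[23] * v[24] / (denP * denP) / VT
    dkkN_d4 = v[25] * v[26] / (denN * denN) / VT
    dkkM_d7 = v[27] / VT
    J[9, 1] = -dkkP_d1
    J[9, 4] = -dkkN_d4
    J[9, 7] = -dkkM_d7
    if dVT_dz != 0.0:
        dkkP_dz = v[23] * v[24] / (denP * denP) * (-y[1] / (VT * VT)) * dVT_dz
        dkkN_dz = v[25] * v[26] / (denN * denN) * (-y[4] / (VT * VT)) * dVT_dz
        dkkM_dz = v[27] * (-y[7] / (VT * VT)) * dVT_dz
        J[9, 9] = -(dkkP_dz + dkkN_dz + dkkM_dz)
    return J


@njit(cache=True)
def _newton_stage(M_lu_a, M_lu_b, rhs_const, coef, y_guess, t, v, tol_vec):
    """Solve Y = rhs_const + coef*f(Y) by Newton iteration with the
    prefactored matrix (I - coef*J) given as (a, b) LU pair via np.linalg.

    numba has no LU factor reuse helper, so the factored matrix is passed as
    the matrix itself and np.linalg.solve is called per iteration (10x10 —
    the solve cost is negligible next to everything else).
    """
    Y = y_guess.copy()
    for _ in range(8):
        G = Y - rhs_const - coef * coupled_rhs(Y, t, v)
        dY = np.linalg.solve(M_lu_a, G)
        Y -= dY
        ok = True
        for i in range(Y.size):
            if np.abs(dY[i]) > tol_vec[i]:
                ok = False
                break
        if ok:
            return Y, True
    return Y, False


@njit(cache=True)
def _trbdf2_segment(v, y0, t0, t1, t_eval, out, rtol, atol):
    """Integrate from t0 to t1, writing states at t_eval (sorted, within
    (t0, t1]) into ``out`` rows.  Returns (y_end, status) with status 0 on
    success."""
    g = _GAMMA
    w = (1.0 - g) / (2.0 - g)
    c_yg = 1.0 / (g * (2.0 - g))
    c_yn = (1.0 - g) * (1.0 - g) / (g * (2.0 - g))
    y = y0.copy()
    t = t0
    h = min(1.0, t1 - t0)
    n = y.size
    I = np.eye(n)
    k_out = 0
    n_out = t_eval.size
    f_n = coupled_rhs(y, t, v)
    while t < t1 - 1e-12 * max(1.0, abs(t1)):
        # do not step over the next requested output
        t_stop = t1 if k_out >= n_out else t_eval[k_out]
        if t + h > t_stop:
            h = t_stop - t
        if h <= 0.0:
            h = 1e-10
        J = coupled_jac(y, t, v)
        M = I - (g * h / 2.0) * J
        tol_vec = atol + rtol * np.abs(y)
        # trapezoidal stage to t + g*h
        rhs1 = y + (g * h / 2.0) * f_n
        Yg, ok1 = _newton_stage(M, M, rhs1, g * h / 2.0,
                                y + g * h * f_n, t + g * h, v, tol_vec)
        if not ok1:
            h *= 0.3
            continue
        # BDF2 stage to t + h
        rhs2 = c_yg * Yg - c_yn * y
        Y1, ok2 = _newton_stage(M, M, rhs2, w * h,
                                Yg + (1.0 - g) * h * (Yg - y) / (g * h), t + h,
                                v, tol_vec)
        if not ok2:
            h *= 0.3
            continue
        f_g = coupled_rhs(Yg, t + g * h, v)
        f_1 = coupled_rhs(Y1, t + h, v)
        # local error: divided-difference estimate filtered through the
        # stage matrix for stiff robustness
        est = 0.0808 * h * ((f_1 - f_g) / (1.0 - g) - (f_g - f_n) / g)
        est = np.linalg.solve(M, est)
        errn = 0.0
        for i in range(n):
            e = est[i] / (atol + rtol * max(np.abs(y[i]), np.abs(Y1[i])))
            errn += e * e
        errn = math.sqrt(errn / n)
        if errn > 1.0:
            fac = 0.9 * errn ** (-1.0 / 3.0)
            h *= min(max(fac, 0.2), 0.9)
            if h < 1e-10:
                return y, 1
            continue
        # accept
        t_new = t + h
        y = Y1
        f_n = f_1
        while k_out < n_out and t_eval[k_out] <= t_new + 1e-12 * max(1.0, abs(t_new)):
            for i in range(n):
                out[k_out, i] = y[i]
            k_out += 1
        t = t_new
        fac = 0.9 * errn ** (-1.0 / 3.0) if errn > 0 else 5.0
        h *= min(max(fac, 0.2), 5.0)
        if h > t1 - t0:
            h = t1 - t0
    while k_out < n_out:
        for i in range(n):
            out[k_out, i] = y[i]
        k_out += 1
    return y, 0


def integrate_coupled_fast(theta_vec: np.ndarray, dose_times, dose_amounts,
                           dose_layers, tv0: float, t_out,
                           rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
    """Compiled TR-BDF2 counterpart of :func:`integrate_coupled`; same
    contract, written for the many-trajectory workloads of estimation and
    population simulation."""
    t_req = np.asarray(t_out, dtype=float)
    if t_req.size and np.any(np.diff(t_req) < 0):
        raise ValueError("output times must be nondecreasing")
    t_uni, inv = np.unique(t_req, return_inverse=True)
    dose_times = np.asarray(dose_times, dtype=float)
    order = np.argsort(dose_times, kind="stable")
    dose_times = dose_times[order]
    dose_amounts = np.asarray(dose_amounts, dtype=float)[order]
    dose_layers = np.asarray(dose_layers, dtype=np.int64)[order]
    if not (tv0 > 0):
        raise ValueError(f"initial tumor burden must be > 0, got {tv0!r}")

    y = np.zeros(NSTATE + 1)
    y[9] = math.log(tv0)
    out = np.empty((t_uni.size, NSTATE + 1))
    horizon = max(t_uni[-1] if t_uni.size else 0.0,
                  dose_times[-1] if dose_times.size else 0.0)
    i_dose = 0
    i_out = 0
    t_now = 0.0
    while i_dose < dose_times.size and dose_times[i_dose] <= 0.0:
        y[dose_layers[i_dose]] += dose_amounts[i_dose]
        i_dose += 1
    while True:
        while i_out < t_uni.size and t_uni[i_out] <= t_now:
            out[i_out] = y
            i_out += 1
        t_next = dose_times[i_dose] if i_dose < dose_times.size else horizon
        if t_next <= t_now:
            if i_dose < dose_times.size:
                y[dose_layers[i_dose]] += dose_amounts[i_dose]
                i_dose += 1
                continue
            break
        j = i_out
        while j < t_uni.size and t_uni[j] < t_next:
            j += 1
        seg_eval = t_uni[i_out:j]
        y, status = _trbdf2_segment(theta_vec, y, t_now, t_next, seg_eval,
                                    out[i_out:j], rtol, atol)
        if status != 0:
            raise ArithmeticError(
                f"TR-BDF2 step size underflow near t={t_now:.3f} h")
        i_out = j
        t_now = t_next
        if i_dose < dose_times.size and dose_times[i_dose] <= t_now:
            y[dose_layers[i_dose]] += dose_amounts[i_dose]
            i_dose += 1
        elif t_now >= horizon:
            while i_out < t_uni.size:
                out[i_out] = y
                i_out += 1
            break
    out = out[inv]
    out[:, 9] = np.exp(np.minimum(out[:, 9], 700.0))
    return out
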
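"""Model core: right-hand sides of the three-layer tumor-disposition PK
models, the coupled PK-PD system, and the observation/geometry maps.

The drug exists in three physical forms (free PTX, PLGA-NP-bound PTX,
MSC-associated PTX), each modeled as a parallel three-compartment layer
(central / tumor / peripheral).  The small-molecule layers exchange with the
tumor through two parallel routes: vascular exchange across the capillary
endothelium, 2*P*Rcap/RKrogh^2, and surface exchange by diffusion across the
tumor surface, 6*D/Rtumor^2 (Krogh-cylinder scaling).  The cell layer moves
by unidirectional extravasation (Kct, Kcp).  The layers are connected by
first-order release (Krel: NP->free and MSC->free) and exocytosis (Kexo:
MSC->NP).

State vector layout (amounts, ng PTX-equivalent)::

    0 A_PTXcentral   1 A_PTXtumor   2 A_PTXperipheral
    3 A_NPcentral    4 A_NPtumor    5 A_NPperipheral
    6 A_MSCcentral   7 A_MSCtumor   8 A_MSCperipheral

The coupled PK-PD state appends the tumor burden TV (1e6 photon/s) at
index 9.  The linear-system matrix builder appends instead a cumulative
eliminated-mass accumulator at index 9 (used in conservation audits).
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    ARMS,
    BioluminescenceCalibration,
    MSCLayerParams,
    ModelParams,
    PDParams,
    SmallMoleculeLayerParams,
    TumorGeometry,
    radius_from_volume,
)

__all__ = [
    "NSTATE",
    "IDX",
    "LAYER_CENTRAL_INDEX",
    "tumor_exchange_flux",
    "rhs_ptx_solution",
    "rhs_ptx_plga",
    "rhs_nanomsc",
    "kill_rates",
    "rhs_pkpd",
    "volume_from_bioluminescence",
    "radius_from_volume",
    "observed_plasma_concentration",
    "observed_lung_concentration",
    "linear_system_matrix",
    "arm_layers",
    "TV_FLOOR",
]

NSTATE = 9
IDX = {
    "PTXc": 0, "PTXt": 1, "PTXp": 2,
    "NPc": 3, "NPt": 4, "NPp": 5,
    "MSCc": 6, "MSCt": 7, "MSCp": 8,
}
#: dose target layer -> central-compartment state index
LAYER_CENTRAL_INDEX = {"free": 0, "np": 3, "msc": 6}

#: floor on tumor burden (1e6 photon/s) guarding the power map near zero
TV_FLOOR = 1e-6


def arm_layers(arm: str) -> tuple:
    """Which drug-form layers exist for a treatment arm."""
    if arm == "ptx_solution":
        return ("free",)
    if arm == "ptx_plga_np":
        return ("free", "np")
    if arm == "nano_msc":
        return ("free", "np", "msc")
    if arm == "control":
        return ()
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


def _exchange_coefficient(layer: SmallMoleculeLayerParams,
                          geom: TumorGeometry) -> float:
    """Total tumor exchange conductance (mL/h): [2 P Rcap / RKrogh^2 +
    6 D / Rtumor^2] * VT, the sum of the vascular and surface routes."""
    if geom.RKrogh <= 0 or geom.Rtumor <= 0:
        raise ValueError("RKrogh and Rtumor must be > 0")
    ve = 2.0 * layer.P * geom.Rcap / geom.RKrogh**2
    se = 6.0 * layer.D / geom.Rtumor**2
    return (ve + se) * geom.VT


def tumor_exchange_flux(Cc: float, Ct: float,
                        layer: SmallMoleculeLayerParams,
                        geom: TumorGeometry) -> float:
    """Net drug flux (ng/h) from the central compartment into the tumor.

    flux = [2 P Rcap/RKrogh^2 + 6 D/Rtumor^2] * VT * (Cc*E - Ct), positive
    into the tumor.  Cc and Ct are the source (central) and tumor
    concentrations in ng/mL.
    """
    if not (math.isfinite(Cc) and math.isfinite(Ct)):
        raise ValueError("concentrations must be finite")
    return _exchange_coefficient(layer, geom) * (Cc * layer.E - Ct)


def _layer_rhs(A_c, A_t, A_p, layer, geom, eliminate=True):
    """Central/tumor/peripheral balance of one small-molecule layer, before
    cross-layer transfer terms.  Returns (dc, dt_, dp)."""
    Cc = A_c / layer.Vc
    Cp = A_p / layer.Vp
    Ct = A_t / geom.VT
    dist = layer.CLD * (Cp - Cc)
    elim = layer.CL * Cc if eliminate else 0.0
    flux = _exchange_coefficient(layer, geom) * (Cc * layer.E - Ct)
    return dist - elim - flux, flux, -dist


def rhs_ptx_solution(state, p: SmallMoleculeLayerParams,
                     geom: TumorGeometry) -> np.ndarray:
    """Free-PTX three-compartment model (bottom layer): distribution
    CLD*(Cp-Cc), elimination CL*Cc from central, tumor exchange."""
    state = np.asarray(state, dtype=float)
    if state.shape != (3,):
        raise ValueError(f"expected 3 free-PTX amounts, got shape {state.shape}")
    dc, dt_, dp = _layer_rhs(state[0], state[1], state[2], p, geom)
    return np.array([dc, dt_, dp])


def rhs_ptx_plga(state, pNP: SmallMoleculeLayerParams,
                 pPTX: SmallMoleculeLayerParams, tr, geom) -> np.ndarray:
    """NP + free-PTX layers (middle model).  The NP layer loses Krel*A from
    every compartment; the free layer gains the matching +Krel*A."""
    state = np.asarray(state, dtype=float)
    if state.shape != (6,):
        raise ValueError(f"expected 6 amounts (free then NP), got shape {state.shape}")
    Pc, Pt, Pp, Nc, Nt, Np_ = state
    dPc, dPt, dPp = _layer_rhs(Pc, Pt, Pp, pPTX, geom)
    dNc, dNt, dNp = _layer_rhs(Nc, Nt, Np_, pNP, geom)
    k = tr.Krel
    return np.array([
        dPc + k * Nc, dPt + k * Nt, dPp + k * Np_,
        dNc - k * Nc, dNt - k * Nt, dNp - k * Np_,
    ])


def rhs_nanomsc(state, pNP, pPTX, m: MSCLayerParams, tr, geom) -> np.ndarray:
    """Full three-layer model.  MSC compartments lose Krel+Kexo everywhere
    plus Kct/Kcp extravasation from central; NP compartments gain +Kexo from
    the matching MSC compartment; free compartments gain +Krel from both."""
    state = np.asarray(state, dtype=float)
    if state.shape != (NSTATE,):
        raise ValueError(f"expected {NSTATE} amounts, got shape {state.shape}")
    Pc, Pt, Pp, Nc, Nt, Np_, Mc, Mt, Mp = state
    dPc, dPt, dPp = _layer_rhs(Pc, Pt, Pp, pPTX, geom)
    dNc, dNt, dNp = _layer_rhs(Nc, Nt, Np_, pNP, geom)
    krel, kexo = tr.Krel, tr.Kexo
    dMc = -(m.Kct + m.Kcp + krel + kexo) * Mc
    dMt = m.Kct * Mc - (krel + kexo) * Mt
    dMp = m.Kcp * Mc - (krel + kexo) * Mp
    return np.array([
        dPc + krel * (Nc + Mc), dPt + krel * (Nt + Mt), dPp + krel * (Np_ + Mp),
        dNc - krel * Nc + kexo * Mc, dNt - krel * Nt + kexo * Mt,
        dNp - krel * Np_ + kexo * Mp,
        dMc, dMt, dMp,
    ])


def kill_rates(C_PTXtumor: float, C_NPtumor: float, C_MSCtumor: float,
               pd: PDParams) -> tuple:
    """Tumor kill rates (1/h) from the tumor-site concentrations of each
    form: Emax for free and NP-bound PTX, linear for the MSC form."""
    for c in (C_PTXtumor, C_NPtumor, C_MSCtumor):
        if c < 0 or not math.isfinite(c):
            raise ValueError(f"tumor concentrations must be finite and >= 0, got {c}")
    k_ptx = pd.Kmax_PTX * C_PTXtumor / (pd.IC50_PTX + C_PTXtumor)
    k_np = pd.Kmax_NP * C_NPtumor / (pd.IC50_NP + C_NPtumor)
    k_msc = pd.K_MSC * C_MSCtumor
    return k_ptx, k_np, k_msc


def volume_from_bioluminescence(TV: float,
                                cal: BioluminescenceCalibration) -> float:
    """Tumor volume VT (mL) from bioluminescence TV (1e6 photon/s):
    VT = a * TV**b."""
    if not (TV > 0):
        raise ValueError(f"TV must be > 0, got {TV!r}")
    return cal.volume(TV)


def rhs_pkpd(t: float, state, params: ModelParams, arm: str = "nano_msc",
             Kg0: float = None, tv_floor: float = TV_FLOOR) -> np.ndarray:
    """Coupled PK-PD right-hand side: nine PK amounts plus tumor burden TV.

    dTV/dt = Kg0*TV - (Kkill_PTX + Kkill_NP + Kkill_MSC)*TV.  With dynamic
    geometry, VT = a*TV**b and Rtumor = (3 VT/4 pi)^(1/3) are recomputed at
    every evaluation and drive all tumor exchange terms and tumor
    concentrations; with static geometry the configured VT is used.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (NSTATE + 1,):
        raise ValueError(f"expected {NSTATE + 1} states (PK + TV)")
    TV = state[9]
    if TV <= -tv_floor:
        raise ValueError(f"TV must be > 0 at evaluation, got {TV}")
    TV = max(TV, tv_floor)  # floor guards the power map near zero burden
    pdp = params.pd
    if pdp is None:
        raise ValueError("params.pd is required for the coupled system")
    geom = params.geometry
    if geom.dynamic:
        VT = params.calibration.volume(max(TV, tv_floor))
        geom = geom.with_volume(VT)
    dpk = rhs_nanomsc(state[:9], params.np_, params.ptx, params.msc,
                      params.transfer, geom)
    kP, kN, kM = kill_rates(state[1] / geom.VT, state[4] / geom.VT,
                            state[7] / geom.VT, pdp)
    g = pdp.Kg0[arm] if Kg0 is None else Kg0
    net = g - kP - kN - kM
    if state[9] <= tv_floor and net < 0.0:
        dTV = 0.0  # burden pinned at the floor; cannot shrink further
    else:
        dTV = net * TV
    return np.append(dpk, dTV)


# --- observation model ------------------------------------------------------

def observed_plasma_concentration(state, pPTX: SmallMoleculeLayerParams,
                                  pNP: SmallMoleculeLayerParams,
                                  m: MSCLayerParams,
                                  arm: str = "nano_msc") -> float:
    """Total measured plasma PTX (ng/mL).

    The free and NP layers contribute their central concentration scaled by
    the plasma-to-blood ratio f_u; the cell layer (which has no f_u) is read
    as raw amount over its central volume.  Only the layers present in the
    given arm contribute.
    """
    state = np.asarray(state, dtype=float)
    layers = arm_layers(arm)
    total = 0.0
    if "free" in layers:
        total += pPTX.fu * state[0] / pPTX.Vc
    if "np" in layers:
        total += pNP.fu * state[3] / pNP.Vc
    if "msc" in layers:
        total += state[6] / m.Vc
    return total


def observed_lung_concentration(state, geom: TumorGeometry) -> float:
    """Total PTX concentration in the tumor-bearing lung (ng/mL):
    (A_PTXtumor + A_NPtumor + A_MSCtumor) / VT."""
    if geom.VT <= 0:
        raise ValueError("VT must be > 0")
    state = np.asarray(state, dtype=float)
    return (state[1] + state[4] + state[7]) / geom.VT


# --- linear system (static geometry) ----------------------------------------

def linear_system_matrix(params: ModelParams, arm: str = "nano_msc",
                         with_elimination_accumulator: bool = False) -> np.ndarray:
    """Constant coefficient matrix A with dA/dt = A @ amounts for the
    static-geometry PK system of an arm (absent layers stay zero rows).

    With ``with_elimination_accumulator`` a tenth row accumulates the mass
    eliminated through both clearances, so that the augmented system is
    mass-conserving exactly (used in conservation audits).
    """
    geom = params.geometry
    if geom.dynamic:
        raise ValueError("linear system requires static geometry")
    n = NSTATE + 1 if with_elimination_accumulator else NSTATE
    A = np.zeros((n, n))
    layers = arm_layers(arm)
    krel, kexo = params.transfer.Krel, params.transfer.Kexo

    def fill_sm_layer(base, lp):
        kex = _exchange_coefficient(lp, geom)
        c, t_, p = base, base + 1, base + 2
        A[c, c] += -(lp.CLD + lp.CL + kex * lp.E) / lp.Vc
        A[c, p] += lp.CLD / lp.Vp
        A[c, t_] += kex / geom.VT
        A[t_, c] += kex * lp.E / lp.Vc
        A[t_, t_] += -kex / geom.VT
        A[p, c] += lp.CLD / lp.Vc
        A[p, p] += -lp.CLD / lp.Vp
        if with_elimination_accumulator:
            A[NSTATE, c] += lp.CL / lp.Vc

    if "free" in layers:
        fill_sm_layer(0, params.ptx)
    if "np" in layers:
        fill_sm_layer(3, params.np_)
        for j in range(3):  # NP -> free release
            A[3 + j, 3 + j] += -krel
            A[j, 3 + j] += krel
    if "msc" in layers:
        m = params.msc
        A[6, 6] += -(m.Kct + m.Kcp + krel + kexo)
        A[7, 6] += m.Kct
        A[7, 7] += -(krel + kexo)
        A[8, 6] += m.Kcp
        A[8, 8] += -(krel + kexo)
        for j in range(3):  # MSC -> NP exocytosis and MSC -> free release
            A[3 + j, 6 + j] += kexo
            A[j, 6 + j] += krel
    return A
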
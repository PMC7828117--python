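"""Parameter containers for the three-layer tumor-disposition PK model and the
tumor-growth PD model.

Units follow the conventions used throughout the package: amounts in ng
PTX-equivalent, volumes in mL, time in h, concentrations in ng/mL, tumor
burden (bioluminescence) in 1e6 photon/s.  All unit conversions happen at the
I/O boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = [
    "SmallMoleculeLayerParams",
    "MSCLayerParams",
    "TransferParams",
    "TumorGeometry",
    "PDParams",
    "BioluminescenceCalibration",
    "ModelParams",
    "ARMS",
    "BODY_WEIGHT_KG",
    "paper_2021",
    "params_to_flat",
    "flat_to_params",
    "save_params",
    "load_params",
]

#: treatment arms, in the order used for parameter vectors and reports
ARMS = ("control", "ptx_solution", "ptx_plga_np", "nano_msc")

#: default mouse body weight (kg) implied by the 5 ug == 0.25 mg/kg dose
#: equivalence; overridable through run configuration
BODY_WEIGHT_KG = 0.02


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _all_positive(obj, names) -> None:
    for n in names:
        v = getattr(obj, n)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            raise ValueError(f"{type(obj).__name__}.{n} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class SmallMoleculeLayerParams:
    """Disposition parameters for one small-molecule-like layer (free PTX or
    PLGA-NP-bound PTX).

    CL/CLD in mL/h, volumes in mL, permeability P in cm/h, surface diffusivity
    D in cm^2/h; fu (plasma-to-blood ratio) and E (tumor accessible fraction)
    are unitless fractions in (0, 1].
    """

    CL: float
    CLD: float
    Vc: float
    Vp: float
    fu: float
    P: float
    D: float
    E: float

    def __post_init__(self):
        _all_positive(self, [f.name for f in fields(self)])
        _require(self.E <= 1.0, f"E must be in (0, 1], got {self.E}")
        _require(self.fu <= 1.0, f"fu must be in (0, 1], got {self.fu}")


@dataclass(frozen=True)
class MSCLayerParams:
    """Cell-layer parameters: unidirectional extravasation rate constants (1/h)
    out of the central compartment, and the central/peripheral volumes (mL).

    The layer dynamics are written on amounts only; ``Vc`` enters solely the
    plasma observation model and ``Vp`` enters no equation (it is carried for
    completeness and flagged in reports).
    """

    Kct: float
    Kcp: float
    Vc: float
    Vp: float

    def __post_init__(self):
        _all_positive(self, [f.name for f in fields(self)])


@dataclass(frozen=True)
class TransferParams:
    """Cross-layer first-order transfer constants.

    Krel: drug release rate (1/h), identical for NP->free and MSC->free.
    Kexo: exocytosis rate on a PTX-mass basis (1/h), MSC->NP.
    loading: drug loading, mg PTX per mg NP, in (0, 1).
    """

    Krel: float
    Kexo: float
    loading: float

    def __post_init__(self):
        _all_positive(self, ["Krel", "Kexo", "loading"])
        _require(self.loading < 1.0, f"loading must be in (0, 1), got {self.loading}")


@dataclass(frozen=True)
class TumorGeometry:
    """Tumor geometry driving the vascular/surface exchange fluxes.

    VT tumor volume (mL), Rtumor tumor radius (cm), Rcap capillary radius
    (cm), RKrogh inter-capillary (Krogh) half-distance (cm).  When ``dynamic``
    is set, VT and Rtumor are recomputed from the tumor burden at every RHS
    evaluation during PD integration (sphere assumption).
    """

    VT: float = 0.3
    Rtumor: float = None  # type: ignore[assignment]
    Rcap: float = 0.0075
    RKrogh: float = 0.0008
    dynamic: bool = False

    def __post_init__(self):
        if self.Rtumor is None:
            object.__setattr__(self, "Rtumor", radius_from_volume(self.VT))
        _all_positive(self, ["VT", "Rtumor", "Rcap", "RKrogh"])

    def with_volume(self, VT: float) -> "TumorGeometry":
        """Return a copy with VT and the consistent sphere radius."""
        return replace(self, VT=VT, Rtumor=radius_from_volume(VT))


def radius_from_volume(VT: float) -> float:
    """Radius (cm) of a sphere of volume ``VT`` (mL): (3 VT / 4 pi)^(1/3)."""
    if not (math.isfinite(VT) and VT > 0):
        raise ValueError(f"tumor volume must be finite and > 0, got {VT!r}")
    return (3.0 * VT / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class BioluminescenceCalibration:
    """Power-law map from tumor bioluminescence TV (1e6 photon/s) to tumor
    volume VT (mL): VT = a * TV**b.  Strictly positive for positive TV by
    construction, which is the reason a power function is used."""

    a: float
    b: float

    def __post_init__(self):
        _require(math.isfinite(self.a) and self.a > 0, f"a must be > 0, got {self.a}")
        _require(math.isfinite(self.b), f"b must be finite, got {self.b}")

    def volume(self, TV: float) -> float:
        if not (TV > 0):
            raise ValueError(f"TV must be > 0, got {TV!r}")
        return self.a * TV**self.b

    def bioluminescence(self, VT: float) -> float:
        """Inverse map TV = (VT/a)^(1/b)."""
        if not (VT > 0):
            raise ValueError(f"VT must be > 0, got {VT!r}")
        if self.b == 0:
            raise ValueError("calibration with b=0 is not invertible")
        return (VT / self.a) ** (1.0 / self.b)


@dataclass(frozen=True)
class PDParams:
    """Tumor-growth PD parameters.

    Per-arm exponential growth rates Kg0 (1/h) and baselines TVBL (1e6
    photon/s); Emax kill parameters for free and NP-bound PTX; a linear
    (unsaturable) kill coefficient for the MSC-associated form; one log-normal
    between-subject SD on baseline (omega, log scale) and per-arm proportional
    residual-error CVs (sigma).
    """

    Kg0: dict = field(default_factory=dict)  # arm -> 1/h
    TVBL: dict = field(default_factory=dict)  # arm -> 1e6 photon/s
    Kmax_PTX: float = 0.0
    Kmax_NP: float = 0.0
    K_MSC: float = 0.0
    IC50_PTX: float = 1.0
    IC50_NP: float = 1.0
    omega_TVBL: float = 0.0
    sigma: dict = field(default_factory=dict)  # arm -> proportional CV

    def __post_init__(self):
        for arm in ARMS:
            _require(arm in self.Kg0, f"Kg0 missing arm {arm!r}")
            _require(arm in self.TVBL, f"TVBL missing arm {arm!r}")
            _require(arm in self.sigma, f"sigma missing arm {arm!r}")
            _require(self.Kg0[arm] > 0, f"Kg0[{arm!r}] must be > 0")
            _require(self.TVBL[arm] > 0, f"TVBL[{arm!r}] must be > 0")
            _require(self.sigma[arm] >= 0, f"sigma[{arm!r}] must be >= 0")
        _all_positive(self, ["Kmax_PTX", "Kmax_NP", "K_MSC", "IC50_PTX", "IC50_NP"])
        _require(self.omega_TVBL >= 0, "omega_TVBL must be >= 0")


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set for the three-layer PK model (and optionally
    the coupled PK-PD model)."""

    ptx: SmallMoleculeLayerParams
    np_: SmallMoleculeLayerParams
    msc: MSCLayerParams
    transfer: TransferParams
    geometry: TumorGeometry
    pd: PDParams = None  # type: ignore[assignment]
    calibration: BioluminescenceCalibration = None  # type: ignore[assignment]
    body_weight_kg: float = BODY_WEIGHT_KG

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def with_dynamic_geometry(self, dynamic: bool = True) -> "ModelParams":
        return replace(self, geometry=replace(self.geometry, dynamic=dynamic))


# --- canonical published parameter set -------------------------------------

_PAPER_PK = dict(
    # free-PTX layer
    P_PTX=0.0875, D_PTX=0.01, E_PTX=0.44,
    CL_PTX=0.909, CLD_PTX=0.336, V_PTXcentral=6.64, V_PTXperipheral=18.5,
    f_uPTX=0.0237,
    # NP layer
    P_NP=0.00035, D_NP=3.6e-6, E_NP=0.055,
    CL_NP=0.241, CLD_NP=0.0627, V_NPcentral=1.32, V_NPperipheral=43.2,
    f_uNP=0.00302,
    # MSC layer
    K_ct=1.45, K_cp=10.2, V_MSCcentral=7.15e-8, V_MSCperipheral=15021.0,
    # transfers
    K_rel=0.0085, K_exo=0.081, loading=0.148,
    # geometry
    R_cap=0.0075, R_krogh=0.0008, VT=0.3,
    # proportional RUV CVs (plasma/lung, per arm)
    eps_PTX_plasma=1.16, eps_PTX_tumor=0.649,
    eps_NP_plasma=0.812, eps_NP_tumor=0.545,
    eps_MSC_plasma=0.873, eps_MSC_tumor=0.581,
)

_PAPER_PD = dict(
    Kg0_CTR=0.00339, Kg0_PTX=0.00372, Kg0_PTXNP=0.00417, Kg0_MSC=0.00588,
    TVBL_CTR=0.360, TVBL_PTX=0.376, TVBL_PTXNP=0.539, TVBL_MSC=0.227,
    Kmax_PTX=0.00343, Kmax_NP=0.000427, K_MSC=4.35e-6,
    IC50_PTX=1.5, IC50_NP=5.7,
    eta_TVBL=0.964,
    eps_CTR=0.493, eps_PTXsol=0.668, eps_PTXNP=0.624, eps_nanoMSC=0.622,
)

#: the bioluminescence->volume calibration coefficients were never published.
#: These defaults place baseline tumors (TV ~ 0.2-0.5 in 1e6 photon/s) near
#: 0.2 mL and end-stage tumors (TV ~ 60-100) near 1 g, make the static PK
#: tumor volume of 0.3 mL correspond to an early-study burden (TV = 1), and
#: put the standard nano-MSC regimen in the reported qualitative regime:
#: net tumor growth under treatment, remission only at the highest simulated
#: maintenance dose.
_DEFAULT_CAL = BioluminescenceCalibration(a=0.3, b=0.3)

#: per-arm PK residual-error CVs keyed as (arm, tissue)
PK_SIGMAS = {
    ("ptx_solution", "plasma"): _PAPER_PK["eps_PTX_plasma"],
    ("ptx_solution", "lung"): _PAPER_PK["eps_PTX_tumor"],
    ("ptx_plga_np", "plasma"): _PAPER_PK["eps_NP_plasma"],
    ("ptx_plga_np", "lung"): _PAPER_PK["eps_NP_tumor"],
    ("nano_msc", "plasma"): _PAPER_PK["eps_MSC_plasma"],
    ("nano_msc", "lung"): _PAPER_PK["eps_MSC_tumor"],
}


def paper_2021(dynamic_geometry: bool = False) -> ModelParams:
    """The canonical published parameter set (built-in defaults).

    PK layer constants, transfer constants, geometry, PD growth/kill
    parameters and variability terms as reported for the orthotopic A549
    nano-MSC mouse study.
    """
    k = _PAPER_PK
    ptx = SmallMoleculeLayerParams(
        CL=k["CL_PTX"], CLD=k["CLD_PTX"], Vc=k["V_PTXcentral"],
        Vp=k["V_PTXperipheral"], fu=k["f_uPTX"], P=k["P_PTX"], D=k["D_PTX"],
        E=k["E_PTX"],
    )
    np_ = SmallMoleculeLayerParams(
        CL=k["CL_NP"], CLD=k["CLD_NP"], Vc=k["V_NPcentral"],
        Vp=k["V_NPperipheral"], fu=k["f_uNP"], P=k["P_NP"], D=k["D_NP"],
        E=k["E_NP"],
    )
    msc = MSCLayerParams(Kct=k["K_ct"], Kcp=k["K_cp"], Vc=k["V_MSCcentral"],
                         Vp=k["V_MSCperipheral"])
    transfer = TransferParams(Krel=k["K_rel"], Kexo=k["K_exo"],
                              loading=k["loading"])
    geometry = TumorGeometry(VT=k["VT"], Rcap=k["R_cap"], RKrogh=k["R_krogh"],
                             dynamic=dynamic_geometry)
    p = _PAPER_PD
    pdp = PDParams(
        Kg0={"control": p["Kg0_CTR"], "ptx_solution": p["Kg0_PTX"],
             "ptx_plga_np": p["Kg0_PTXNP"], "nano_msc": p["Kg0_MSC"]},
        TVBL={"control": p["TVBL_CTR"], "ptx_solution": p["TVBL_PTX"],
              "ptx_plga_np": p["TVBL_PTXNP"], "nano_msc": p["TVBL_MSC"]},
        Kmax_PTX=p["Kmax_PTX"], Kmax_NP=p["Kmax_NP"], K_MSC=p["K_MSC"],
        IC50_PTX=p["IC50_PTX"], IC50_NP=p["IC50_NP"],
        omega_TVBL=p["eta_TVBL"],
        sigma={"control": p["eps_CTR"], "ptx_solution": p["eps_PTXsol"],
               "ptx_plga_np": p["eps_PTXNP"], "nano_msc": p["eps_nanoMSC"]},
    )
    return ModelParams(ptx=ptx, np_=np_, msc=msc, transfer=transfer,
                       geometry=geometry, pd=pdp, calibration=_DEFAULT_CAL)


# --- flat key<->value serialization ----------------------------------------

def params_to_flat(p: ModelParams) -> dict:
    """Flatten a ModelParams into the canonical symbol->value table."""
    out = {
        "CL_PTX": p.ptx.CL, "CLD_PTX": p.ptx.CLD,
        "V_PTXcentral": p.ptx.Vc, "V_PTXperipheral": p.ptx.Vp,
        "f_uPTX": p.ptx.fu, "P_PTX": p.ptx.P, "D_PTX": p.ptx.D,
        "E_PTX": p.ptx.E,
        "CL_NP": p.np_.CL, "CLD_NP": p.np_.CLD,
        "V_NPcentral": p.np_.Vc, "V_NPperipheral": p.np_.Vp,
        "f_uNP": p.np_.fu, "P_NP": p.np_.P, "D_NP": p.np_.D, "E_NP": p.np_.E,
        "K_ct": p.msc.Kct, "K_cp": p.msc.Kcp,
        "V_MSCcentral": p.msc.Vc, "V_MSCperipheral": p.msc.Vp,
        "K_rel": p.transfer.Krel, "K_exo": p.transfer.Kexo,
        "loading": p.transfer.loading,
        "VT": p.geometry.VT, "R_tumor": p.geometry.Rtumor,
        "R_cap": p.geometry.Rcap, "R_krogh": p.geometry.RKrogh,
        "body_weight_kg": p.body_weight_kg,
    }
    if p.calibration is not None:
        out["cal_a"] = p.calibration.a
        out["cal_b"] = p.calibration.b
    if p.pd is not None:
        d = p.pd
        out.update({
            "Kg0_CTR": d.Kg0["control"], "Kg0_PTX": d.Kg0["ptx_solution"],
            "Kg0_PTXNP": d.Kg0["ptx_plga_np"], "Kg0_MSC": d.Kg0["nano_msc"],
            "TVBL_CTR": d.TVBL["control"], "TVBL_PTX": d.TVBL["ptx_solution"],
            "TVBL_PTXNP": d.TVBL["ptx_plga_np"], "TVBL_MSC": d.TVBL["nano_msc"],
            "Kmax_PTX": d.Kmax_PTX, "Kmax_NP": d.Kmax_NP, "K_MSC": d.K_MSC,
            "IC50_PTX": d.IC50_PTX, "IC50_NP": d.IC50_NP,
            "eta_TVBL": d.omega_TVBL,
            "eps_CTR": d.sigma["control"], "eps_PTXsol": d.sigma["ptx_solution"],
            "eps_PTXNP": d.sigma["ptx_plga_np"], "eps_nanoMSC": d.sigma["nano_msc"],
        })
    return out


def flat_to_params(flat: dict, dynamic_geometry: bool = False) -> ModelParams:
    """Build ModelParams from a flat symbol->value table; unlisted symbols
    fall back to the built-in published defaults."""
    base = params_to_flat(paper_2021())
    unknown = set(flat) - set(base)
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    merged = {**base, **flat}
    k = merged
    ptx = SmallMoleculeLayerParams(CL=k["CL_PTX"], CLD=k["CLD_PTX"],
                                   Vc=k["V_PTXcentral"], Vp=k["V_PTXperipheral"],
                                   fu=k["f_uPTX"], P=k["P_PTX"], D=k["D_PTX"],
                                   E=k["E_PTX"])
    np_ = SmallMoleculeLayerParams(CL=k["CL_NP"], CLD=k["CLD_NP"],
                                   Vc=k["V_NPcentral"], Vp=k["V_NPperipheral"],
                                   fu=k["f_uNP"], P=k["P_NP"], D=k["D_NP"],
                                   E=k["E_NP"])
    msc = MSCLayerParams(Kct=k["K_ct"], Kcp=k["K_cp"], Vc=k["V_MSCcentral"],
                         Vp=k["V_MSCperipheral"])
    transfer = TransferParams(Krel=k["K_rel"], Kexo=k["K_exo"],
                              loading=k["loading"])
    geometry = TumorGeometry(VT=k["VT"], Rcap=k["R_cap"], RKrogh=k["R_krogh"],
                             dynamic=dynamic_geometry)
    cal = BioluminescenceCalibration(a=k["cal_a"], b=k["cal_b"])
    pdp = PDParams(
        Kg0={"control": k["Kg0_CTR"], "ptx_solution": k["Kg0_PTX"],
             "ptx_plga_np": k["Kg0_PTXNP"], "nano_msc": k["Kg0_MSC"]},
        TVBL={"control": k["TVBL_CTR"], "ptx_solution": k["TVBL_PTX"],
              "ptx_plga_np": k["TVBL_PTXNP"], "nano_msc": k["TVBL_MSC"]},
        Kmax_PTX=k["Kmax_PTX"], Kmax_NP=k["Kmax_NP"], K_MSC=k["K_MSC"],
        IC50_PTX=k["IC50_PTX"], IC50_NP=k["IC50_NP"],
        omega_TVBL=k["eta_TVBL"],
        sigma={"control": k["eps_CTR"], "ptx_solution": k["eps_PTXsol"],
               "ptx_plga_np": k["eps_PTXNP"], "nano_msc": k["eps_nanoMSC"]},
    )
    return ModelParams(ptx=ptx, np_=np_, msc=msc, transfer=transfer,
                       geometry=geometry, pd=pdp, calibration=cal,
                       body_weight_kg=k["body_weight_kg"])


def save_params(p: ModelParams, path) -> None:
    Path(path).write_text(json.dumps(params_to_flat(p), indent=1, sort_keys=True))


def load_params(path, dynamic_geometry: bool = False) -> ModelParams:
    return flat_to_params(json.loads(Path(path).read_text()),
                          dynamic_geometry=dynamic_geometry)
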
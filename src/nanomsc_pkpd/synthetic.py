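"""Synthetic study generators that emulate the original animal-study
designs, so the whole estimation stack is testable without any external
data.

Every generator is a pure function of (truth parameters, design, seed).
Observation tables use the NONMEM-style long format of :mod:`.io`:
ID, ARM, TIME, TYPE, DV, CENS, ULIM, AMT, EVID.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._ode import integrate_coupled, integrate_linear, pack_theta
from .dosing import msc_efficacy_regimen, solution_efficacy_regimen
from .model import LAYER_CENTRAL_INDEX, arm_layers
from .params import PK_SIGMAS, ModelParams

__all__ = [
    "PK_STUDY_TIMES",
    "PD_SCHEDULE",
    "default_pd_regimens",
    "generate_pk_study",
    "generate_pd_study",
    "generate_release_exocytosis_data",
    "generate_calibration_pairs",
]

#: destructive-sampling PK time points: 2 h and 1, 2, 5, 12 days post-dose
PK_STUDY_TIMES = (2.0, 24.0, 48.0, 120.0, 288.0)

#: twice-weekly tumor-imaging schedule over the 63-day study span (h)
PD_SCHEDULE = tuple(np.arange(0.0, 1512.0 + 1e-9, 84.0))

#: PK arms and the layer their 5 ug bolus targets
_PK_ARM_LAYER = {"ptx_solution": "free", "ptx_plga_np": "np", "nano_msc": "msc"}


def _obs_row(sid, arm, time, typ, dv, cens=0, ulim=np.nan, amt=np.nan, evid=0):
    return dict(ID=sid, ARM=arm, TIME=time, TYPE=typ, DV=dv, CENS=cens,
                ULIM=ulim, AMT=amt, EVID=evid)


def generate_pk_study(params: ModelParams, seed: int,
                      arms=tuple(_PK_ARM_LAYER), times=PK_STUDY_TIMES,
                      n_per_time: int = 3, dose_ng: float = 5000.0,
                      sigmas: dict = None, loq: float = 0.0) -> pd.DataFrame:
    """Destructive-sampling PK study: per arm, a single IV bolus and
    ``n_per_time`` mice sacrificed at each time point with plasma and lung
    PTX measured.

    Observations are y = f*(1+eps) with proportional, tissue- and
    arm-specific error; each record carries a distinct subject id
    (destructive sampling).  Records that fall at or below ``loq`` (default
    0, i.e. nonpositive values) are dropped, emulating the exclusion of
    concentrations measured as zero.
    """
    if n_per_time < 1 or not times or any(t < 0 for t in times):
        raise ValueError("invalid design")
    if sigmas is None:
        sigmas = PK_SIGMAS
    rng = np.random.default_rng(seed)
    times = np.asarray(sorted(times), dtype=float)
    rows = []
    sid = 0
    for arm in arms:
        layer = _PK_ARM_LAYER[arm]
        states = integrate_linear(params, arm, [0.0], [dose_ng], [layer], times)
        # observation model per tissue
        f_plasma = np.zeros(len(times))
        layers = arm_layers(arm)
        if "free" in layers:
            f_plasma += params.ptx.fu * states[:, 0] / params.ptx.Vc
        if "np" in layers:
            f_plasma += params.np_.fu * states[:, 3] / params.np_.Vc
        if "msc" in layers:
            f_plasma += states[:, 6] / params.msc.Vc
        f_lung = (states[:, 1] + states[:, 4] + states[:, 7]) / params.geometry.VT
        for k, t in enumerate(times):
            for _ in range(n_per_time):
                sid += 1
                for tissue, f in (("plasma", f_plasma[k]), ("lung", f_lung[k])):
                    eps = rng.normal(0.0, sigmas[(arm, tissue)])
                    y = f * (1.0 + eps)
                    rows.append(_obs_row(f"pk{sid:03d}", arm, t, tissue, y))
    df = pd.DataFrame(rows)
    return df[df.DV > loq].reset_index(drop=True)


def default_pd_regimens(params: ModelParams) -> dict:
    """The efficacy-study regimens per arm: none for control, 40 mg/kg on
    days 0/4/8 for the free-drug and nanoparticle arms, and the nano-MSC
    loading + q14d maintenance regimen."""
    bw = params.body_weight_kg
    return {
        "control": None,
        "ptx_solution": solution_efficacy_regimen("free", bw),
        "ptx_plga_np": solution_efficacy_regimen("np", bw),
        "nano_msc": msc_efficacy_regimen(),
    }


def generate_pd_study(params: ModelParams, seed: int, n_per_arm: int = 8,
                      schedule=PD_SCHEDULE, regimens: dict = None,
                      dropout_threshold: float = 100.0,
                      rtol: float = 1e-8, atol: float = 1e-10):
    """Four-arm tumor-bioluminescence efficacy study.

    Per animal: a log-normal baseline TVBL*exp(eta), the coupled PK-PD
    trajectory with the arm's regimen and dynamic geometry, proportional
    residual error on observations, and deterministic dropout — the animal
    is observed up to and including the first scheduled time at which its
    latent burden exceeds ``dropout_threshold`` and contributes nothing
    afterwards.

    Returns ``(observations, latent)``: the observable table (with
    post-dropout schedule gaps) and the latent noise-free trajectories for
    oracle checks.
    """
    pdp = params.pd
    if regimens is None:
        regimens = default_pd_regimens(params)
    schedule = np.asarray(schedule, dtype=float)
    if dropout_threshold <= max(pdp.TVBL.values()):
        raise ValueError("dropout threshold must exceed every baseline TVBL")
    if not params.geometry.dynamic:
        raise ValueError("PD generation requires dynamic tumor geometry")
    rng = np.random.default_rng(seed)
    obs_rows, latent_rows = [], []
    for arm, regimen in regimens.items():
        events = [] if regimen is None else list(regimen.events)
        vec = pack_theta(params, arm=arm)
        dt = [e.time for e in events]
        da = [e.amount for e in events]
        dl = [LAYER_CENTRAL_INDEX[e.layer] for e in events]
        sigma = pdp.sigma[arm]
        for i in range(n_per_arm):
            sid = f"{arm}_{i + 1:02d}"
            eta = rng.normal(0.0, pdp.omega_TVBL)
            tv0 = pdp.TVBL[arm] * np.exp(eta)
            tv = integrate_coupled(vec, dt, da, dl, tv0, schedule,
                                   rtol=rtol, atol=atol)[:, 9]
            eps = rng.normal(0.0, sigma, size=len(schedule))
            y = tv * (1.0 + np.maximum(eps, -0.999))
            crossed = tv > dropout_threshold
            drop_at = int(np.argmax(crossed)) if crossed.any() else len(schedule)
            for k, t in enumerate(schedule):
                latent_rows.append(dict(ID=sid, ARM=arm, TIME=t, TV=tv[k],
                                        eta=eta, dropped=k > drop_at))
                if k <= drop_at:
                    obs_rows.append(_obs_row(sid, arm, t, "bioluminescence", y[k]))
    return pd.DataFrame(obs_rows), pd.DataFrame(latent_rows)


def generate_release_exocytosis_data(Krel: float, Kexo: float, seed: int,
                                     release_times=(4.0, 24.0, 72.0, 168.0, 336.0),
                                     exocytosis_times=(0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0),
                                     noise_cv: float = 0.10):
    """In-vitro calibration inputs: cumulative drug release
    100*(1-exp(-Krel*t)) (% of load) and nanoparticle retention
    100*exp(-Kexo*t) (% of initial), both with proportional noise.

    Returns two (time, value) DataFrames: (release, retention).
    """
    for ts in (release_times, exocytosis_times):
        a = np.asarray(ts, dtype=float)
        if np.any(a <= 0) or np.any(np.diff(a) <= 0):
            raise ValueError("times must be positive and increasing")
    rng = np.random.default_rng(seed)
    rt = np.asarray(release_times, dtype=float)
    et = np.asarray(exocytosis_times, dtype=float)
    rel = 100.0 * (1.0 - np.exp(-Krel * rt))
    rel = rel * (1.0 + rng.normal(0.0, noise_cv, rt.size))
    ret = 100.0 * np.exp(-Kexo * et)
    ret = ret * (1.0 + rng.normal(0.0, noise_cv, et.size))
    return (pd.DataFrame({"time": rt, "release_pct": rel}),
            pd.DataFrame({"time": et, "retained_pct": ret}))


def generate_calibration_pairs(a: float, b: float, seed: int, n: int = 8,
                               noise_sd_log: float = 0.2,
                               tv_range=(0.5, 200.0)) -> pd.DataFrame:
    """Tumor bioluminescence / tumor weight calibration pairs: TV sampled
    log-uniformly, weight = a*TV**b * exp(noise) at 1 g/mL density."""
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    rng = np.random.default_rng(seed)
    lo, hi = tv_range
    tv = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    w = a * tv**b * np.exp(rng.normal(0.0, noise_sd_log, size=n))
    return pd.DataFrame({"TV": tv, "weight_g": w})
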
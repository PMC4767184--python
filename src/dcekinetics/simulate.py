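"""Synthetic dose-dependent DCE-MRI signal curves.

Generates cohorts of tumour time-signal curves with the generative
structure the downstream analysis assumes:

* a biexponential population arterial input function (AIF) whose
  amplitude scales linearly with the injected contrast-agent dose;
* single-compartment (Tofts) tissue kinetics with transfer constant
  Ktrans and efflux rate kep, in closed form for the biexponential AIF;
* a spoiled-gradient-echo (SPGR/FLASH) steady-state signal equation that
  converts tissue concentration to MR signal, which saturates at high
  relaxation rate — so dose linearity holds in concentration space but
  not in signal space;
* triplicate-ROI measurement noise with an optional per-ROI placement
  bias.

With the efflux rate well above the terminal AIF decay the simulated
curves peak within the first few post-contrast scans and wash out — the
type III shape.  Amplitude-like curve features then grow with dose while
timing features do not, which is the contrast the group statistics are
designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

from .schedule import ScanSchedule
from .tic import RoiSignalSeries

__all__ = [
    "AIFParams",
    "SubjectPK",
    "NoiseModel",
    "CohortSpec",
    "PoleError",
    "aif_concentration",
    "tissue_concentration",
    "spgr_signal",
    "simulate_subject",
    "simulate_cohort",
    "cohort_manifest",
]

#: Minimum allowed |kep - m_i| (1/min) before the closed form degenerates.
POLE_TOL = 1e-6


class PoleError(ValueError):
    """kep coincides with an AIF decay rate; the closed form has a pole."""


@dataclass(frozen=True)
class AIFParams:
    """Biexponential population AIF, Cp(t) = dose * (a1 e^-m1 t + a2 e^-m2 t).

    Defaults are the classical Gd-DTPA population values
    (a1 = 3.99, a2 = 4.78 kg/L; m1 = 0.144, m2 = 0.0111 /min): a fast
    distribution phase and a slow elimination phase.  Amplitudes are per
    unit dose (mmol/kg), so plasma concentration is linear in dose.
    """

    a1: float = 3.99
    a2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("AIF amplitudes a1, a2 must be positive")
        if not self.m1 > self.m2 > 0:
            raise ValueError("AIF decay rates must satisfy m1 > m2 > 0")


@dataclass(frozen=True)
class SubjectPK:
    """One subject's generative kinetic and signal parameters.

    ktrans, kep in 1/min; r10 (pre-contrast longitudinal relaxation
    rate) in 1/s; r1_relaxivity in L/(mmol*s); s_eq is the equilibrium
    signal scale in arbitrary units; dose in mmol/kg.
    """

    ktrans: float
    kep: float
    r10: float
    r1_relaxivity: float
    s_eq: float
    dose: float

    def __post_init__(self) -> None:
        bad = [
            name
            for name, v in (
                ("ktrans", self.ktrans),
                ("kep", self.kep),
                ("r10", self.r10),
                ("r1_relaxivity", self.r1_relaxivity),
                ("s_eq", self.s_eq),
            )
            if v <= 0
        ]
        if self.dose < 0:
            bad.append("dose")
        if bad:
            raise ValueError(f"non-positive SubjectPK fields: {', '.join(bad)}")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for triplicate-ROI signals.

    sigma_frac is the additive noise SD as a fraction of the noiseless
    pre-contrast (baseline) signal.  roi_bias_frac is the SD of a
    per-ROI multiplicative log-normal bias, constant across scans,
    modelling ROI placement variability between the three planes.
    """

    kind: Literal["gaussian", "rician", "none"] = "gaussian"
    sigma_frac: float = 0.02
    roi_bias_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "rician", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma_frac < 0 or self.roi_bias_frac < 0:
            raise ValueError("noise fractions must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Population description of a simulated multi-dose cohort.

    Subject-level PK parameters are drawn from log-normal distributions
    with the given means and coefficients of variation; dose is the only
    systematic difference between groups.  ``seed`` expands to one
    independent substream per subject keyed by (group index, subject
    index), so enlarging a group never reshuffles existing subjects.
    """

    doses: Sequence[float] = (0.2, 0.3, 0.5)
    n_per_group: int = 7
    ktrans_mean: float = 0.5
    kep_mean: float = 2.0
    r10_mean: float = 0.7
    s_eq_mean: float = 98000.0
    r1_relaxivity: float = 3.6
    cv_ktrans: float = 0.15
    cv_kep: float = 0.15
    cv_r10: float = 0.05
    cv_s_eq: float = 0.05
    noise: NoiseModel = field(default_factory=NoiseModel)
    aif: AIFParams = field(default_factory=AIFParams)
    schedule: ScanSchedule = field(default_factory=ScanSchedule)
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if len(self.doses) < 1 or any(d <= 0 for d in self.doses):
            bad.append("doses")
        if self.n_per_group < 1:
            bad.append("n_per_group")
        for name in ("ktrans_mean", "kep_mean", "r10_mean", "s_eq_mean",
                     "r1_relaxivity"):
            if getattr(self, name) <= 0:
                bad.append(name)
        for name in ("cv_ktrans", "cv_kep", "cv_r10", "cv_s_eq"):
            if getattr(self, name) < 0:
                bad.append(name)
        if bad:
            raise ValueError(f"invalid CohortSpec fields: {', '.join(bad)}")

    def __post_init__(self) -> None:
        self.validate()


def aif_concentration(t, dose: float, aif: AIFParams | None = None):
    """Plasma CA concentration (mmol/L) at ``t`` seconds after injection.

    Cp(t) = dose * (a1 e^(-m1 t') + a2 e^(-m2 t')) with t' in minutes.
    Strictly decreasing in t and linear in dose.
    """
    if aif is None:
        aif = AIFParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative (seconds since injection)")
    tm = t / 60.0
    cp = dose * (aif.a1 * np.exp(-aif.m1 * tm) + aif.a2 * np.exp(-aif.m2 * tm))
    return cp if cp.shape else float(cp)


def tissue_concentration(t, pk: SubjectPK, aif: AIFParams | None = None):
    """Tissue CA concentration (mmol/L): closed-form Tofts convolution.

    Ct(t) = Ktrans * int_0^t Cp(tau) e^(-kep (t - tau)) dtau evaluated
    in closed form for the biexponential AIF:

        Ct = dose * Ktrans * sum_i a_i (e^(-m_i t') - e^(-kep t')) / (kep - m_i)

    with t' in minutes.  Ct(0) = 0 and Ct >= 0 everywhere.
    """
    if aif is None:
        aif = AIFParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative (seconds since injection)")
    for m in (aif.m1, aif.m2):
        if abs(pk.kep - m) < POLE_TOL:
            raise PoleError(
                f"kep={pk.kep} coincides with AIF decay rate {m} "
                "(closed-form pole); jitter kep slightly to proceed"
            )
    tm = t / 60.0
    ek = np.exp(-pk.kep * tm)
    total = np.zeros_like(tm)
    for a, m in ((aif.a1, aif.m1), (aif.a2, aif.m2)):
        total = total + a * (np.exp(-m * tm) - ek) / (pk.kep - m)
    ct = pk.dose * pk.ktrans * total
    return ct if ct.shape else float(ct)


def spgr_signal(conc, pk: SubjectPK, tr: float = 0.029,
                flip_angle: float = 30.0):
    """Spoiled-gradient-echo steady-state signal for concentration ``conc``.

    S = s_eq sin(a) (1 - E1) / (1 - cos(a) E1),
    E1 = exp(-TR (r10 + r1 * conc)), TR in seconds.

    Strictly increasing in concentration, saturating at s_eq sin(a).
    T2*/TE decay is not modelled (appropriate for short echo times).
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    if not 0 < flip_angle < 90:
        raise ValueError("flip angle must be in (0, 90) degrees")
    alpha = np.deg2rad(flip_angle)
    e1 = np.exp(-tr * (pk.r10 + pk.r1_relaxivity * conc))
    s = pk.s_eq * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)
    return s if s.shape else float(s)


def _noiseless_scan_signals(pk: SubjectPK, schedule: ScanSchedule,
                            aif: AIFParams, tr: float, flip_angle: float):
    """(n_pre + n_post,) noiseless signals; post scans at mid-acquisition."""
    mid = np.array([schedule.mid_time(n) for n in range(1, schedule.n_post + 1)])
    post = spgr_signal(tissue_concentration(mid, pk, aif), pk, tr, flip_angle)
    pre = np.full(schedule.n_pre, spgr_signal(0.0, pk, tr, flip_angle))
    return np.concatenate([pre, post])


def simulate_subject(pk: SubjectPK, schedule: ScanSchedule | None = None,
                     noise: NoiseModel | None = None,
                     rng: np.random.Generator | None = None,
                     aif: AIFParams | None = None,
                     subject_id: str = "sim",
                     tr: float = 0.029, flip_angle: float = 30.0,
                     n_roi: int = 3) -> RoiSignalSeries:
    """Simulate one subject's triplicate-ROI signals over the full schedule.

    Each of the ``n_roi`` ROI replicates carries a fixed multiplicative
    placement bias (log-normal, SD ``roi_bias_frac``) and per-scan
    additive noise with SD ``sigma_frac`` times the noiseless baseline
    signal.  Deterministic given ``rng`` state.
    """
    schedule = schedule or ScanSchedule()
    noise = noise or NoiseModel()
    aif = aif or AIFParams()
    rng = rng or np.random.default_rng()

    clean = _noiseless_scan_signals(pk, schedule, aif, tr, flip_angle)
    s0_clean = clean[0]

    if noise.roi_bias_frac > 0:
        bias = np.exp(rng.normal(0.0, noise.roi_bias_frac, size=n_roi))
    else:
        bias = np.ones(n_roi)

    grid = clean[:, None] * bias[None, :]
    sigma = noise.sigma_frac * s0_clean
    if noise.kind == "gaussian" and sigma > 0:
        grid = grid + rng.normal(0.0, sigma, size=grid.shape)
    elif noise.kind == "rician" and sigma > 0:
        re = grid + rng.normal(0.0, sigma, size=grid.shape)
        im = rng.normal(0.0, sigma, size=grid.shape)
        grid = np.hypot(re, im)
    grid = np.maximum(grid, 1e-9)  # signals must stay positive

    return RoiSignalSeries(subject_id=subject_id, dose=pk.dose,
                           signals=grid, n_pre=schedule.n_pre)


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw from a log-normal with the given arithmetic mean and CV."""
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def _subject_rng(seed: int, group_idx: int, subj_idx: int) -> np.random.Generator:
    # counter-keyed substream: (seed; group, subject) -> independent stream
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group_idx, subj_idx))
    return np.random.default_rng(ss)


def simulate_cohort(spec: CohortSpec) -> list[RoiSignalSeries]:
    """Simulate a full multi-dose cohort.

    Subject PK values are drawn from a single log-normal population
    shared by all groups — dose is the only systematic group difference.
    If a drawn kep lands on an AIF decay-rate pole it is nudged upward
    by successive 0.1% steps until clear.
    """
    spec.validate()
    cohort: list[RoiSignalSeries] = []
    for gi, dose in enumerate(spec.doses):
        for si in range(spec.n_per_group):
            rng = _subject_rng(spec.seed, gi, si)
            ktrans = _lognormal(rng, spec.ktrans_mean, spec.cv_ktrans)
            kep = _lognormal(rng, spec.kep_mean, spec.cv_kep)
            while any(abs(kep - m) < POLE_TOL for m in (spec.aif.m1, spec.aif.m2)):
                kep *= 1.001
            r10 = _lognormal(rng, spec.r10_mean, spec.cv_r10)
            s_eq = _lognormal(rng, spec.s_eq_mean, spec.cv_s_eq)
            pk = SubjectPK(ktrans=ktrans, kep=kep, r10=r10,
                           r1_relaxivity=spec.r1_relaxivity,
                           s_eq=s_eq, dose=dose)
            cohort.append(simulate_subject(
                pk, spec.schedule, spec.noise, rng, spec.aif,
                subject_id=f"g{gi + 1}s{si + 1:02d}"))
    return cohort


def cohort_manifest(spec: CohortSpec) -> str:
    """JSON provenance record of a cohort specification (includes seed)."""
    d = asdict(spec)
    d["doses"] = list(spec.doses)
    return json.dumps({"generator": "dcekinetics.simulate_cohort",
                       "spec": d}, indent=2, sort_keys=True)
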
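"""Synthetic spinal-cord cohorts: geometry, tensors, signals, Rician noise.

The phantom draws a procedural cord cross-section on every axial slice:
an outer white-matter annulus split into ventral / dorsal / ventro-lateral
/ dorso-lateral sectors and an inner gray-matter ellipse split into
ventral and dorsal halves.  Each tissue carries an axially symmetric
ground-truth tensor ``D = RD*I + (AD-RD) * n nᵀ`` (µm²/ms) with the
principal axis ``n`` along the slice direction, optionally tilted.

Inter-subject biological variation is a multiplicative Gaussian factor
per tissue parameter per subject; disease effects are fractional shifts
applied on top for case-group subjects.  Magnitude noise follows the
scanner averaging structure: NA acquisitions are combined in the complex
domain (noise SD sigma/sqrt(NA) per channel), each of NR repetitions is
magnitude-reconstructed, and the NR magnitudes are averaged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dwi_io import (DWIStudy, RoiSet, LABELS, LABEL_NAMES, WM_LABELS,
                     GM_LABELS, ROI_NAMES)
from .schemes import AcquisitionProtocol, SLICE_AXIS

__all__ = [
    "TissueParams", "PhantomSpec", "SubjectPhantom", "Cohort",
    "default_tissue_params", "default_disease_effects",
    "make_label_map", "make_subject", "simulate_signal",
    "add_noise_and_average", "simulate_study", "make_cohort",
    "axisym_fa", "axisym_tensor", "rd_for_fa_target",
    "GROUPS", "TIMEPOINTS", "METRICS",
]

GROUPS = ("WT", "G93A")
TIMEPOINTS = ("week10", "week17")
METRICS = ("FA", "MD", "AD", "RD")

#: default voxel size (mm): (read, phase, slice)
DEFAULT_VOXEL_SIZE = (0.078, 0.109, 0.8)
#: default grid covering a 1.4 x 1 cm in-plane FOV over 8 slices
DEFAULT_GRID = (128, 180, 8)


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth parameters of one tissue class.

    ``f``/``fast_scale``/``slow_scale`` define the optional
    bi-exponential signal split: the fast (volume fraction ``f``) and
    slow compartments use the base tensor scaled by the two factors.
    """

    ad: float                 # axial diffusivity, µm²/ms
    rd: float                 # radial diffusivity, µm²/ms
    s0: float = 1000.0        # unweighted signal, arbitrary units
    tilt_deg: float = 0.0     # principal-axis tilt from the slice axis
    f: float = 0.7
    fast_scale: float = 1.5
    slow_scale: float = 0.25

    def __post_init__(self):
        if not (self.ad > 0 and self.rd > 0):
            raise ValueError("diffusivities must be positive")
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("bi-exponential fraction f must be in [0, 1]")

    @property
    def axis(self) -> np.ndarray:
        """Principal axis: slice axis tilted by ``tilt_deg`` about read."""
        t = np.deg2rad(self.tilt_deg)
        return np.array([0.0, np.sin(t), np.cos(t)])

    def tensor(self) -> np.ndarray:
        return axisym_tensor(self.ad, self.rd, self.axis)

    def metrics(self) -> dict:
        return {"FA": axisym_fa(self.ad, self.rd),
                "MD": (self.ad + 2 * self.rd) / 3.0,
                "AD": self.ad, "RD": self.rd}


def axisym_tensor(ad: float, rd: float, axis=SLICE_AXIS) -> np.ndarray:
    """Axially symmetric tensor ``RD*I + (AD-RD) n nᵀ`` (3x3)."""
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    return rd * np.eye(3) + (ad - rd) * np.outer(n, n)


def axisym_fa(ad: float, rd: float) -> float:
    """FA of an axially symmetric tensor: |AD-RD| / sqrt(AD² + 2 RD²)."""
    return abs(ad - rd) / np.sqrt(ad ** 2 + 2 * rd ** 2)


def rd_for_fa_target(ad: float, fa_target: float) -> float:
    """RD (< AD) such that the axisymmetric FA equals ``fa_target``."""
    if not 0.0 < fa_target < 1.0:
        raise ValueError("target FA must lie in (0, 1)")
    return brentq(lambda rd: axisym_fa(ad, rd) - fa_target, 1e-12, ad - 1e-12,
                  xtol=1e-14)


def default_tissue_params() -> dict:
    """Configurable defaults, typical of rodent cord at 7 T; WM darker
    than GM on b0 to provide contrast, dlWM tilted 10° for the
    angular-deviation analysis."""
    wm = dict(ad=1.5, rd=0.25, s0=800.0)
    gm = dict(ad=0.85, rd=0.65, s0=1000.0)
    params = {name: TissueParams(**wm) for name in WM_LABELS}
    params["dlWM"] = TissueParams(**wm, tilt_deg=10.0)
    params.update({name: TissueParams(**gm) for name in GM_LABELS})
    return params


def default_disease_effects() -> dict:
    """Fractional AD/RD shifts per timepoint producing the qualitative
    late-stage pattern: FA/MD/AD down everywhere, RD up in WM and down
    in GM; the early timepoint carries a quarter of the effect."""
    week17 = {}
    for name in WM_LABELS:
        week17[name] = {"AD": -0.20, "RD": +0.20}
    for name in GM_LABELS:
        week17[name] = {"AD": -0.20, "RD": -0.12}
    week10 = {roi: {k: v / 4.0 for k, v in eff.items()}
              for roi, eff in week17.items()}
    return {"week10": week10, "week17": week17}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the synthetic cohort's ground truth."""

    grid: tuple = DEFAULT_GRID
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    tissue_params: dict = field(default_factory=default_tissue_params)
    noise_sigma: float = 20.0   # per-channel Gaussian SD, S0 units
    subject_cv: float = 0.03    # fractional inter-subject SD on AD and RD
    disease_effects: dict = field(default_factory=default_disease_effects)
    signal_mode: str = "mono"   # "mono" or "biexp"

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.subject_cv < 0:
            raise ValueError("subject_cv must be >= 0")
        if self.signal_mode not in ("mono", "biexp"):
            raise ValueError("signal_mode must be 'mono' or 'biexp'")
        for name in ROI_NAMES:
            if name not in self.tissue_params:
                raise ValueError(f"tissue_params missing ROI {name!r}")
        for name in WM_LABELS:
            tp = self.tissue_params[name]
            if tp.ad < tp.rd:
                raise ValueError(f"WM tissue {name} must have AD >= RD")
        for eff in self._effects_table().values():
            for roi, shifts in eff.items():
                for metric in ("FA", "MD", "AD"):
                    if shifts.get(metric, 0.0) > 0:
                        raise ValueError(
                            f"disease effect on {metric} in {roi} must be <= 0")

    def _effects_table(self) -> dict:
        """Normalize ``disease_effects`` to {timepoint: {roi: shifts}}."""
        if not self.disease_effects:
            return {tp: {} for tp in TIMEPOINTS}
        if any(k in TIMEPOINTS for k in self.disease_effects):
            return {tp: self.disease_effects.get(tp, {}) for tp in TIMEPOINTS}
        return {tp: self.disease_effects for tp in TIMEPOINTS}

    def effects_for(self, timepoint: str) -> dict:
        return self._effects_table().get(timepoint, {})


def make_label_map(grid) -> np.ndarray:
    """Procedural cord cross-section, identical on every slice.

    Outer WM annulus split by in-plane angle (dorsal = +y half,
    ventral = -y half, laterals in between); inner GM ellipse split into
    ventral/dorsal halves.  Background fills >= 50% of the FOV.
    """
    nx, ny, nz = grid
    if nx < 12 or ny < 12 or nz < 1:
        raise ValueError(f"grid {grid} too small to contain all six ROIs")
    x = (np.arange(nx) - (nx - 1) / 2.0)
    y = (np.arange(ny) - (ny - 1) / 2.0)
    u = x[:, None] / (0.35 * nx)   # normalized read coordinate
    v = y[None, :] / (0.35 * ny)   # normalized phase coordinate
    r2 = u ** 2 + v ** 2
    in_cord = r2 <= 1.0
    in_gm = (u / 0.55) ** 2 + (v / 0.65) ** 2 <= 1.0

    phi = np.degrees(np.arctan2(np.broadcast_to(v, r2.shape),
                                np.broadcast_to(u, r2.shape)))
    section = np.zeros((nx, ny), dtype=np.int16)
    wm = in_cord & ~in_gm
    dorsal = (phi > 45) & (phi < 135)
    ventral = (phi < -45) & (phi > -135)
    lateral_d = ~dorsal & ~ventral & (v >= 0)
    lateral_v = ~dorsal & ~ventral & (v < 0)
    section[wm & ventral] = LABELS["vWM"]
    section[wm & dorsal] = LABELS["dWM"]
    section[wm & lateral_v] = LABELS["vlWM"]
    section[wm & lateral_d] = LABELS["dlWM"]
    gm = in_cord & in_gm
    section[gm & (v < 0)] = LABELS["vGM"]
    section[gm & (v >= 0)] = LABELS["dGM"]

    present = set(np.unique(section))
    missing = [n for n in ROI_NAMES if LABELS[n] not in present]
    if missing:
        raise ValueError(f"grid {grid} too small: ROIs {missing} are empty")
    return np.repeat(section[:, :, None], nz, axis=2)


@dataclass
class SubjectPhantom:
    """Realized ground truth for one subject (shared across protocols)."""

    subject_id: str
    group: str
    timepoint: str
    label_map: np.ndarray
    voxel_size: tuple
    params: dict                  # ROI name -> realized TissueParams

    def rois(self) -> RoiSet:
        return RoiSet(label_map=self.label_map)

    def s0_map(self) -> np.ndarray:
        out = np.zeros(self.label_map.shape)
        for name, tp in self.params.items():
            out[self.label_map == LABELS[name]] = tp.s0
        return out

    def tensor_field(self) -> np.ndarray:
        """Per-voxel tensor, shape grid + (3, 3); zero outside the cord."""
        out = np.zeros(self.label_map.shape + (3, 3))
        for name, tp in self.params.items():
            out[self.label_map == LABELS[name]] = tp.tensor()
        return out

    def ground_truth(self) -> pd.DataFrame:
        rows = [
            dict(subject=self.subject_id, group=self.group,
                 timepoint=self.timepoint, roi=name, metric=metric,
                 value=value)
            for name, tp in self.params.items()
            for metric, value in tp.metrics().items()
        ]
        return pd.DataFrame(rows)


def _apply_effects(tp: TissueParams, effects: dict) -> TissueParams:
    """Apply fractional metric shifts to one tissue's (AD, RD).

    Order: direct AD and RD shifts, then an FA shift (solved by moving
    RD at fixed AD), then an MD shift (uniform scaling, FA-preserving).
    """
    ad = tp.ad * (1.0 + effects.get("AD", 0.0))
    rd = tp.rd * (1.0 + effects.get("RD", 0.0))
    if "FA" in effects:
        target = axisym_fa(ad, rd) * (1.0 + effects["FA"])
        rd = rd_for_fa_target(ad, target)
    if "MD" in effects:
        scale = 1.0 + effects["MD"]
        ad *= scale
        rd *= scale
    return replace(tp, ad=ad, rd=rd)


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([int(seed),
                                  zlib.crc32(str(subject_id).encode())])


def make_subject(spec: PhantomSpec, subject_id: str, group: str = "WT",
                 timepoint: str = "week10", seed: int = 0) -> SubjectPhantom:
    """Realize one subject's ground truth.

    Biological variation: independent factors ``1 + eps``,
    ``eps ~ N(0, subject_cv)``, per tissue per parameter (AD, RD), drawn
    from an RNG keyed on ``(seed, subject_id)`` only — the same animal
    keeps its anatomy across timepoints and protocols.  Case-group
    subjects additionally receive the spec's disease effects for their
    timepoint.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
    label_map = make_label_map(spec.grid)
    rng = _subject_rng(seed, subject_id)
    effects = spec.effects_for(timepoint) if group == "G93A" else {}
    params = {}
    for name in ROI_NAMES:
        base = spec.tissue_params[name]
        eps_ad, eps_rd = rng.normal(0.0, 1.0, size=2) * spec.subject_cv
        factors = np.clip([1.0 + eps_ad, 1.0 + eps_rd], 0.05, None)
        tp = replace(base, ad=base.ad * factors[0], rd=base.rd * factors[1])
        if name in effects:
            tp = _apply_effects(tp, effects[name])
        params[name] = tp
    return SubjectPhantom(subject_id=subject_id, group=group,
                          timepoint=timepoint, label_map=label_map,
                          voxel_size=spec.voxel_size, params=params)


def simulate_signal(subject: SubjectPhantom, protocol: AcquisitionProtocol,
                    mode: str = "mono") -> np.ndarray:
    """Noiseless 4D signal under a protocol (b0 volumes first).

    mono:  ``S = S0 exp(-b gᵀ D g)``;
    biexp: ``S = S0 (f exp(-b gᵀ D_fast g) + (1-f) exp(-b gᵀ D_slow g))``
    with ``D_fast/slow = fast_scale/slow_scale * D``.  Background = 0.
    """
    if mode not in ("mono", "biexp"):
        raise ValueError("mode must be 'mono' or 'biexp'")
    scheme = protocol.scheme
    b = scheme.full_bvalues()
    g = scheme.full_directions()
    out = np.zeros(subject.label_map.shape + (scheme.n_volumes,))
    for name, tp in subject.params.items():
        mask = subject.label_map == LABELS[name]
        if not mask.any():
            continue
        q = np.einsum("vi,ij,vj->v", g, tp.tensor(), g)  # gᵀDg per volume
        if mode == "mono":
            att = np.exp(-b * q)
        else:
            att = (tp.f * np.exp(-b * q * tp.fast_scale)
                   + (1.0 - tp.f) * np.exp(-b * q * tp.slow_scale))
        out[mask] = tp.s0 * att
    return out


def add_noise_and_average(noiseless: np.ndarray,
                          protocol: AcquisitionProtocol,
                          sigma: float, seed,
                          voxel_size: tuple = DEFAULT_VOXEL_SIZE,
                          meta: dict | None = None) -> DWIStudy:
    """Rician magnitude noise with the protocol's averaging structure.

    Each of NR repetitions is the magnitude of ``(S + n_re, n_im)`` with
    per-channel SD ``sigma / sqrt(NA)`` (NA complex-domain averages);
    the NR magnitude repetitions are then arithmetically averaged.
    ``sigma = 0`` returns the noiseless input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    noiseless = np.asarray(noiseless, dtype=float)
    if sigma == 0:
        data = noiseless.copy()
    else:
        rng = np.random.default_rng(seed)
        sig_eff = sigma / np.sqrt(protocol.n_averages)
        acc = np.zeros_like(noiseless)
        for _ in range(protocol.n_repetitions):
            re = noiseless + rng.normal(0.0, sig_eff, size=noiseless.shape)
            im = rng.normal(0.0, sig_eff, size=noiseless.shape)
            acc += np.hypot(re, im)
        data = acc / protocol.n_repetitions
    return DWIStudy(data=data, voxel_size=voxel_size, scheme=protocol.scheme,
                    meta=dict(meta or {}, protocol=protocol.name))


def simulate_study(subject: SubjectPhantom, protocol: AcquisitionProtocol,
                   sigma: float, seed, mode: str = "mono") -> DWIStudy:
    """Convenience: noiseless signal + noise/averaging for one subject."""
    clean = simulate_signal(subject, protocol, mode=mode)
    meta = dict(subject=subject.subject_id, group=subject.group,
                timepoint=subject.timepoint)
    return add_noise_and_average(clean, protocol, sigma, seed,
                                 voxel_size=subject.voxel_size, meta=meta)


@dataclass
class Cohort:
    """All simulated studies plus the ground-truth registry."""

    studies: list
    phantoms: list
    rois: RoiSet
    truth: pd.DataFrame


def make_cohort(spec: PhantomSpec, n_per_group: int,
                timepoints=TIMEPOINTS, protocols=(), seed: int = 0,
                groups=GROUPS) -> Cohort:
    """Simulate a full cohort.

    Every subject is simulated under all requested protocols from the
    same :class:`SubjectPhantom` (within-session consistency); the noise
    seed differs per (subject, timepoint, protocol).  Deterministic for
    a fixed ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    protocols = list(protocols)
    if not protocols:
        raise ValueError("at least one protocol is required")
    studies, phantoms, truth_frames = [], [], []
    rois = None
    for gi, group in enumerate(groups):
        for si in range(n_per_group):
            subject_id = f"{group}{si + 1:02d}"
            for ti, timepoint in enumerate(timepoints):
                subj = make_subject(spec, subject_id, group=group,
                                    timepoint=timepoint, seed=seed)
                phantoms.append(subj)
                truth_frames.append(subj.ground_truth())
                if rois is None:
                    rois = subj.rois()
                for pi, protocol in enumerate(protocols):
                    noise_seed = [int(seed) + 1, gi, si, ti, pi]
                    study = simulate_study(subj, protocol, spec.noise_sigma,
                                           noise_seed, mode=spec.signal_mode)
                    studies.append(study)
    truth = pd.concat(truth_frames, ignore_index=True)
    return Cohort(studies=studies, phantoms=phantoms, rois=rois, truth=truth)
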
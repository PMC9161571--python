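"""Synthetic NSCLC immunotherapy cohorts with the statistical structure the
analysis assumes.

Three linked generators:

* **Clinical + blot cohort** (:func:`simulate_cohort`): each patient draws a
  durable-responder label, a latent ΔEV PD-L1 ratio (lognormal, class-
  dependent log-median), four positive densitometry bands that decompose
  that ratio, and PFS/OS times from an exponential proportional-hazards
  model in which the Δ<1 ("decrease") class has its hazard multiplied by
  the configured hazard ratios.
* **Lesion phantoms** (:func:`simulate_lesion_image`): a textured
  ellipsoidal lesion (Gaussian random field whose correlation length
  depends on responder class) over a noisy background, plus a cuboidal
  pectoralis-muscle reference VOI, on a 3D grid with CT-like spacing.

Survival construction. PFS is the composite time to first progression or
death, so ``pfs <= os`` must hold per patient. We draw a latent death time
``T_death ~ Exp(h_os * HR_os^dec)`` — OS is therefore *exactly*
exponential proportional hazards — and a latent progression time with
rate chosen so that ``T_pfs = min(T_prog, T_death)`` is *exactly*
``Exp(h_pfs * HR_pfs^dec)``: since minima of independent exponentials are
exponential with summed rates, it suffices that the progression rate be
the difference of the configured PFS and OS rates within each class.
Censoring is uniform ``C ~ U(0, c_max)`` with ``c_max`` calibrated
numerically so the expected censored fraction matches the configuration;
a single uniform draw per patient is shared by both endpoints so observed
times keep ``pfs <= os``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .config import SimulationConfig
from .errors import PlacementError, ValidationError

ARMS = ("ICI", "ICI_plus_chemo", "chemo")
TPS_LEVELS = ("<1%", "1-49%", ">=50%", "unknown")
RECIST = ("CR", "PR", "SD", "PD")

#: log-scale SD of the nuisance band draws (CD9 loading, baseline PD-L1)
_BAND_LOGSD = 0.3
#: slope/noise of the lesion-size-change map (percent per log-ratio unit)
_SIZE_SLOPE = 30.0
_SIZE_NOISE_SD = 12.0
#: log-scale SD of the per-patient texture correlation-length jitter
_CORR_LEN_JITTER = 0.25


@dataclass(frozen=True)
class PatientRecord:
    """One row of the clinical cohort table."""

    patient_id: str
    arm: str
    line: int
    tissue_tps: str
    durable_response: str
    early_response: str
    lesion_size_change: float
    pfs_months: float
    os_months: float
    pfs_event: bool
    os_event: bool

    @property
    def durable_responder(self) -> bool:
        """Durable responders are CR/PR/SD at the 21±3-week evaluation."""
        return self.durable_response in ("CR", "PR", "SD")


@dataclass(frozen=True)
class BlotPanel:
    """Paired T1/T2 PD-L1 and CD9 densitometry for one patient."""

    patient_id: str
    pdl1_t1: float
    cd9_t1: float
    pdl1_t2: float
    cd9_t2: float


@dataclass
class ImagingStudy:
    """A 3D scalar volume with lesion mask(s) and a muscle reference VOI."""

    patient_id: str
    volume: np.ndarray
    lesion_masks: list[np.ndarray] = field(default_factory=list)
    muscle_mask: np.ndarray | None = None
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        if self.volume.ndim != 3:
            raise ValidationError("volume must be 3D")
        if self.muscle_mask is None or not self.lesion_masks:
            raise ValidationError("study requires a muscle mask and >=1 lesion mask")
        for m in [self.muscle_mask, *self.lesion_masks]:
            if m.shape != self.volume.shape:
                raise ValidationError("mask shape differs from volume shape")
            if not m.any():
                raise ValidationError("empty mask")
        union = np.zeros(self.volume.shape, dtype=int)
        for m in self.lesion_masks:
            union += m.astype(int)
        if (union > 1).any() or (union.astype(bool) & self.muscle_mask.astype(bool)).any():
            raise ValidationError("lesion and muscle masks must be pairwise disjoint")


def _stable_id_seed(patient_id: str) -> int:
    return zlib.crc32(patient_id.encode("utf-8"))


def _uniform_censor_cmax(rates: np.ndarray, target_fraction: float) -> float:
    """Solve for c_max so that mean_i P(U(0,c_max) < Exp(rate_i)) = target.

    The per-subject censoring probability P(C < T) under C ~ U(0, c) and
    T ~ Exp(lam) is (1 - exp(-lam*c)) / (lam*c), which decreases from 1
    at c -> 0 to 0 as c -> inf.
    """

    def frac(c: float) -> float:
        x = rates * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while frac(hi) > target_fraction:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid configs
            raise ValidationError("censoring calibration failed")
    return brentq(lambda c: frac(c) - target_fraction, lo, hi, xtol=1e-10)


def _response_category(size_change: float, responder: bool) -> str:
    """Map a % lesion-size change and responder status to a RECIST label.

    Non-responders are PD by definition of durable response; responders
    split CR/PR/SD on the standard -30% / near-complete thresholds.
    """
    if not responder:
        return "PD"
    if size_change <= -90.0:
        return "CR"
    if size_change <= -30.0:
        return "PR"
    return "SD"


def simulate_cohort(config: SimulationConfig) -> tuple[list[PatientRecord], list[BlotPanel]]:
    """Draw a cohort of clinical records and paired blot panels.

    Fully reproducible for a fixed ``config.seed``. The latent ΔEV PD-L1
    is decomposed into four positive bands whose recomputed ratio equals
    the latent value exactly when ``band_noise_cv == 0``.
    """
    records, panels, _ = simulate_cohort_with_latent(config)
    return records, panels


def simulate_cohort_with_latent(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], list[BlotPanel], np.ndarray]:
    """As :func:`simulate_cohort`, also returning the latent (pre-band-noise)
    ΔEV PD-L1 draws, in patient order — useful for validating the band
    decomposition and the survival link."""
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_patients
    ids = [f"P{i + 1:04d}" for i in range(n)]

    responder = rng.random(n) < config.responder_fraction
    logmu = np.where(
        responder, config.delta_logmean_responder, config.delta_logmean_nonresponder
    )
    log_delta = rng.normal(logmu, config.delta_logsd)
    delta = np.exp(log_delta)
    decrease = delta < 1.0

    # band decomposition: three nuisance bands around 1, fourth carries Δ
    cd9_t1 = np.exp(rng.normal(0.0, _BAND_LOGSD, n))
    cd9_t2 = np.exp(rng.normal(0.0, _BAND_LOGSD, n))
    pdl1_t1 = np.exp(rng.normal(0.0, _BAND_LOGSD, n))
    pdl1_t2 = delta * (pdl1_t1 / cd9_t1) * cd9_t2
    bands = np.stack([pdl1_t1, cd9_t1, pdl1_t2, cd9_t2])
    if config.band_noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.band_noise_cv**2))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, bands.shape))
        bands = bands * noise
    pdl1_t1, cd9_t1, pdl1_t2, cd9_t2 = bands

    # survival: latent death + progression, both exponential PH (see module docs)
    lam_os = config.baseline_hazard_os * np.where(decrease, config.true_hr_os, 1.0)
    lam_pfs = config.baseline_hazard_pfs * np.where(decrease, config.true_hr_pfs, 1.0)
    lam_prog = lam_pfs - lam_os  # positive by config validation
    t_death = rng.exponential(1.0 / lam_os)
    t_prog = rng.exponential(1.0 / lam_prog)
    t_pfs = np.minimum(t_prog, t_death)

    if config.censor_fraction > 0:
        c_pfs = _uniform_censor_cmax(lam_pfs, config.censor_fraction)
        c_os = _uniform_censor_cmax(lam_os, config.censor_fraction)
        u = rng.random(n)
        censor_os = u * c_os
        censor_pfs = u * min(c_pfs, c_os)
        pfs_event = t_pfs <= censor_pfs
        os_event = t_death <= censor_os
        pfs_months = np.minimum(t_pfs, censor_pfs)
        os_months = np.minimum(t_death, censor_os)
    else:
        pfs_event = np.ones(n, dtype=bool)
        os_event = np.ones(n, dtype=bool)
        pfs_months = t_pfs
        os_months = t_death

    # lesion-size change: monotone noisy function of log Δ
    size_change = np.clip(
        _SIZE_SLOPE * log_delta + rng.normal(0.0, _SIZE_NOISE_SD, n), -100.0, 200.0
    )
    early_change = 0.6 * size_change + rng.normal(0.0, 8.0, n)

    tps = rng.choice(TPS_LEVELS, size=n, p=[0.30, 0.35, 0.25, 0.10])
    line = rng.choice([1, 2, 3], size=n, p=[0.6, 0.3, 0.1])

    records: list[PatientRecord] = []
    panels: list[BlotPanel] = []
    for i, pid in enumerate(ids):
        durable = _response_category(size_change[i], responder[i])
        if responder[i]:
            early = _response_category(early_change[i], True)
        else:
            early = "PD" if early_change[i] >= 20.0 else "SD"
        records.append(
            PatientRecord(
                patient_id=pid,
                arm="ICI",
                line=int(line[i]),
                tissue_tps=str(tps[i]),
                durable_response=durable,
                early_response=early,
                lesion_size_change=float(size_change[i]),
                pfs_months=float(pfs_months[i]),
                os_months=float(os_months[i]),
                pfs_event=bool(pfs_event[i]),
                os_event=bool(os_event[i]),
            )
        )
        panels.append(
            BlotPanel(
                patient_id=pid,
                pdl1_t1=float(pdl1_t1[i]),
                cd9_t1=float(cd9_t1[i]),
                pdl1_t2=float(pdl1_t2[i]),
                cd9_t2=float(cd9_t2[i]),
            )
        )
    return records, panels, delta


def simulate_lesion_image(
    config: SimulationConfig, responder_class: bool, patient_id: str
) -> ImagingStudy:
    """Generate a textured lesion phantom with a muscle reference VOI.

    The lesion is an ellipsoid filled with a Gaussian random field whose
    correlation length is ``texture_corr_len_responder`` (responders:
    smoother, coarser texture) or ``texture_corr_len_nonresponder``;
    shorter correlation length yields higher GLCM contrast. A cuboidal
    muscle VOI with fixed mean/SD sits in the low corner of the grid,
    disjoint from the lesion. Voxel-identical for a fixed config seed,
    class and patient id.
    """
    rng = np.random.default_rng(
        [config.seed, 2, _stable_id_seed(patient_id), int(responder_class)]
    )
    shape = np.asarray(config.image_shape)

    m = int(max(3, min(6, shape.min() // 6)))
    muscle_lo = np.array([1, 1, 1])
    muscle_hi = muscle_lo + m  # exclusive

    max_semi = (shape - 4) // 2
    max_semi[0] = (shape[0] - muscle_hi[0] - 4) // 2
    max_semi = np.minimum(max_semi, 8)
    if (max_semi < 2).any():
        raise PlacementError(
            f"image_shape {config.image_shape} too small to place a lesion "
            "disjoint from the muscle VOI"
        )
    semi = np.array([rng.integers(2, hi + 1) for hi in np.minimum(max_semi, 7)])

    lo = np.array([muscle_hi[0] + 1 + semi[0], 2 + semi[1], 2 + semi[2]])
    hi = shape - 2 - semi
    if (hi < lo).any():
        raise PlacementError("no feasible lesion center inside the grid")
    center = np.array([rng.integers(lo[a], hi[a] + 1) for a in range(3)])

    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    lesion = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0

    muscle = np.zeros(tuple(shape), dtype=bool)
    muscle[
        muscle_lo[0] : muscle_hi[0], muscle_lo[1] : muscle_hi[1], muscle_lo[2] : muscle_hi[2]
    ] = True

    corr_len = (
        config.texture_corr_len_responder
        if responder_class
        else config.texture_corr_len_nonresponder
    )
    # biological heterogeneity: per-patient jitter makes texture an
    # imperfect class marker, as in real exploratory radiomics cohorts
    corr_len = corr_len * float(np.exp(rng.normal(0.0, _CORR_LEN_JITTER)))
    field_ = gaussian_filter(rng.normal(size=tuple(shape)), sigma=corr_len)
    inside = field_[lesion]
    field_std = inside.std()
    if field_std == 0:  # pragma: no cover - smoothing never flattens noise exactly
        field_std = 1.0
    texture = (field_ - inside.mean()) / field_std

    volume = rng.normal(0.0, 5.0, tuple(shape))
    volume[lesion] = 60.0 + 20.0 * texture[lesion]
    volume[muscle] = 50.0 + rng.normal(0.0, 8.0, int(muscle.sum()))

    study = ImagingStudy(
        patient_id=patient_id,
        volume=volume,
        lesion_masks=[lesion],
        muscle_mask=muscle,
        voxel_spacing_mm=config.voxel_spacing_mm,
    )
    study.validate()
    return study


def simulate_imaging(
    config: SimulationConfig, records: list[PatientRecord]
) -> list[ImagingStudy]:
    """One phantom per patient, class-linked to the durable-response label."""
    return [
        simulate_lesion_image(config, r.durable_responder, r.patient_id) for r in records
    ]
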
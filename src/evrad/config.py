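"""Configuration objects for simulation and pipeline runs.

The :class:`SimulationConfig` defaults define the synthetic study
conditions: a 60-patient immune-checkpoint-inhibitor cohort in which
responders' EV PD-L1 falls during treatment (log-median −0.5) and
non-responders' rises (log-median +0.4), survival follows exponential
proportional hazards with the decrease class enjoying hazard ratios of
0.45 (PFS) and 0.35 (OS), and lesion texture correlation length differs
by responder class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

from .errors import ValidationError


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-cohort generator.

    Attributes
    ----------
    n_patients
        Cohort size.
    responder_fraction
        Probability a patient is a durable responder (CR/PR/SD at the
        21±3-week evaluation), in (0, 1).
    delta_logmean_responder, delta_logmean_nonresponder
        Natural-log-scale medians of the latent ΔEV PD-L1 ratio per class.
    delta_logsd
        Log-scale SD of ΔEV PD-L1 (shared across classes).
    band_noise_cv
        Multiplicative lognormal noise CV applied to each of the four
        densitometry bands (0 = noise-free decomposition).
    true_hr_pfs, true_hr_os
        Hazard ratios (decrease class vs increase class) for the PFS and
        OS endpoints.
    baseline_hazard_pfs, baseline_hazard_os
        Per-month exponential hazards of the increase class. PFS is the
        composite progression-or-death endpoint, so its baseline hazard
        must exceed the OS baseline hazard.
    censor_fraction
        Expected fraction of subjects censored (uniform, covariate
        independent), in [0, 1).
    image_shape, voxel_spacing_mm
        Phantom CT grid and spacing.
    texture_corr_len_responder, texture_corr_len_nonresponder
        Gaussian-random-field correlation length (voxels) of lesion
        texture per class.
    seed
        Base seed for all randomness.
    """

    n_patients: int = 60
    responder_fraction: float = 0.5
    delta_logmean_responder: float = -0.5
    delta_logmean_nonresponder: float = 0.4
    delta_logsd: float = 0.6
    band_noise_cv: float = 0.05
    true_hr_pfs: float = 0.45
    true_hr_os: float = 0.35
    baseline_hazard_pfs: float = 1.0 / 6.0
    baseline_hazard_os: float = 1.0 / 12.0
    censor_fraction: float = 0.15
    image_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (0.8, 0.8, 1.5)
    texture_corr_len_responder: float = 2.4
    texture_corr_len_nonresponder: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_patients) != self.n_patients or self.n_patients <= 0:
            raise ValidationError(f"n_patients must be a positive integer, got {self.n_patients}")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValidationError(
                f"responder_fraction must lie in (0, 1), got {self.responder_fraction}"
            )
        if self.delta_logsd <= 0:
            raise ValidationError("delta_logsd must be positive")
        if self.band_noise_cv < 0:
            raise ValidationError("band_noise_cv must be nonnegative")
        for name in ("true_hr_pfs", "true_hr_os", "baseline_hazard_pfs", "baseline_hazard_os"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValidationError("censor_fraction must lie in [0, 1)")
        self.image_shape = tuple(int(s) for s in self.image_shape)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(self.image_shape) != 3 or any(s < 9 for s in self.image_shape):
            raise ValidationError(
                "image_shape must be three axes each >= 9 voxels so a lesion "
                f"and a muscle VOI both fit, got {self.image_shape}"
            )
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValidationError("voxel_spacing_mm must be three positive reals")
        if self.texture_corr_len_responder <= 0 or self.texture_corr_len_nonresponder <= 0:
            raise ValidationError("texture correlation lengths must be positive")
        # PFS (progression-or-death) decomposes into latent progression and
        # death hazards; both must stay positive in both classes.
        if self.baseline_hazard_pfs <= self.baseline_hazard_os:
            raise ValidationError(
                "baseline_hazard_pfs must exceed baseline_hazard_os (PFS is the "
                "composite progression-or-death endpoint)"
            )
        if self.baseline_hazard_pfs * self.true_hr_pfs <= self.baseline_hazard_os * self.true_hr_os:
            raise ValidationError(
                "decrease-class PFS hazard must exceed decrease-class OS hazard"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        payload = json.loads(text)
        return cls(**payload)


@dataclass
class ModelConfig:
    """Hyperparameters of the response-prediction recipes.

    The LASSO penalty is chosen by cross-validated deviance over a log
    grid of ``n_penalties`` values with ``n_folds`` stratified folds; the
    boosted model uses shallow trees with a small learning rate.
    """

    n_penalties: int = 15
    n_folds: int = 5
    fixed_c: float | None = None  # overrides CV when set (inverse penalty)
    xgb_n_estimators: int = 100
    xgb_max_depth: int = 2
    xgb_learning_rate: float = 0.1
    selection_outside: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_penalties < 2 or self.n_folds < 2:
            raise ValidationError("n_penalties and n_folds must each be >= 2")
        if self.fixed_c is not None and self.fixed_c <= 0:
            raise ValidationError("fixed_c must be positive when set")


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration.

    Exactly one of ``input_dir`` (pre-existing cohort files) or
    ``simulation`` must be provided; ``seed`` fans out deterministically
    to every stochastic stage.
    """

    out_dir: str = "results"
    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    recipes: tuple[str, ...] = ("ev_only", "radiomics", "ev_plus_radiomics", "tissue_tps")
    endpoints: tuple[str, ...] = ("pfs", "os")
    with_imaging: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ValidationError(
                "provide exactly one of input_dir or simulation in PipelineConfig"
            )
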
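"""Configuration objects for the synthetic cohort generator and the pipeline.

The generator emulates a paired-acquisition study: every participant has
voxel-wise grey-matter (GM), white-matter (WM) and CSF volume maps from a
*standard* high-resolution T1-weighted acquisition and from a *rapid*
(EPI-based, reduced field-of-view) acquisition, plus a table of brain-age
predictions per sequence. All statistical targets of the emulation (age
distribution, cross-sequence agreement, retest reliability, systematic
brain-age offset of the rapid sequence) live here as explicit parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigurationError

#: The three segmented tissue classes, in canonical order.
TISSUES = ("GM", "WM", "CSF")

#: Sequence labels used throughout the package.
STANDARD = "standard"
RAPID = "rapid"
STANDARD_FOVREDUCED = "standard_fovreduced"


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Volumes are in mm^3, ages in years, distances in mm. Global-level
    standard deviations (``subject_sd``, ``standard_noise_sd``,
    ``retest_noise_sd``) refer to the standard deviation of the *global*
    (summed) tissue volume; the generator distributes them over voxels in
    proportion to the tissue template.
    """

    n_participants: int = 64
    n_retest: int = 10
    grid_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_dims: tuple[float, float, float] = (4.0, 4.0, 6.0)

    # Age distribution: truncated normal.
    age_mean: float = 28.2
    age_sd: float = 9.2
    age_min: float = 18.0
    age_max: float = 59.0

    # Linear age effects on global tissue volume (mm^3 per year). Grey matter
    # declines with age; CSF expands (ventricular growth); WM is kept flat.
    gm_age_slope: float = -800.0
    csf_age_slope: float = 250.0

    # Between-participant SD of global volume, per tissue (mm^3).
    subject_sd: Mapping[str, float] = field(
        default_factory=lambda: {"GM": 9000.0, "WM": 9000.0, "CSF": 7000.0}
    )

    # Between-participant coefficient of variation of *individual voxel*
    # volume (stable anatomy, shared between sequences and retest). This is
    # what gives voxel-wise agreement its signal; the global mode above is
    # what carries the age trend.
    voxel_effect_cv: Mapping[str, float] = field(
        default_factory=lambda: {"GM": 0.7, "WM": 0.75, "CSF": 0.55}
    )

    # Target cross-participant correlation of global volumes between the
    # standard and rapid sequences, per tissue.
    cross_sequence_corr_target: Mapping[str, float] = field(
        default_factory=lambda: {"GM": 0.84, "WM": 0.84, "CSF": 0.56}
    )

    # Measurement noise of one acquisition, at the global-volume level (mm^3).
    standard_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"GM": 3000.0, "WM": 2600.0, "CSF": 1500.0}
    )
    retest_noise_sd: float = 1000.0

    # Axial slices removed at each extreme of the rapid acquisition's grid.
    fov_drop_slices: int = 3

    # Brain-age prediction table. The standard sequence predicts age with
    # unbiased noise; the rapid and FoV-reduced predictions are compressed
    # toward a constant (slope < 1) which produces the systematic offset.
    brainage_noise_sd: float = 4.0
    brainage_offset_intercept: float = 31.6
    brainage_offset_slope: float = 0.42
    fovreduced_offset_intercept: float = 34.1
    fovreduced_offset_slope: float = 0.30
    fovreduced_noise_sd: float = 5.7

    # Gaussian smoothing applied to rapid-sequence maps (FWHM, mm; 0 = none).
    smoothing_fwhm: float = 4.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        self.subject_sd = dict(self.subject_sd)
        self.voxel_effect_cv = dict(self.voxel_effect_cv)
        self.cross_sequence_corr_target = dict(self.cross_sequence_corr_target)
        self.standard_noise_sd = dict(self.standard_noise_sd)
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if self.n_retest < 0:
            raise ConfigurationError("n_retest must be non-negative")
        if self.n_retest > self.n_participants:
            raise ConfigurationError(
                f"n_retest ({self.n_retest}) exceeds n_participants "
                f"({self.n_participants})"
            )
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ConfigurationError(f"invalid grid_shape {self.grid_shape}")
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ConfigurationError(f"invalid voxel_dims {self.voxel_dims}")
        if not (self.age_min < self.age_max):
            raise ConfigurationError("age_min must be below age_max")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")
        for tissue in TISSUES:
            rho = self.cross_sequence_corr_target.get(tissue)
            if rho is None or not (0.0 < rho <= 1.0):
                raise ConfigurationError(
                    f"cross_sequence_corr_target[{tissue!r}] must lie in (0, 1], "
                    f"got {rho!r}"
                )
            if self.subject_sd.get(tissue, -1.0) <= 0:
                raise ConfigurationError(f"subject_sd[{tissue!r}] must be positive")
            if self.standard_noise_sd.get(tissue, -1.0) < 0:
                raise ConfigurationError(
                    f"standard_noise_sd[{tissue!r}] must be non-negative"
                )
            if self.voxel_effect_cv.get(tissue, -1.0) < 0:
                raise ConfigurationError(
                    f"voxel_effect_cv[{tissue!r}] must be non-negative"
                )
        if self.retest_noise_sd < 0:
            raise ConfigurationError("retest_noise_sd must be non-negative")
        if self.brainage_noise_sd < 0 or self.fovreduced_noise_sd < 0:
            raise ConfigurationError("brain-age noise SDs must be non-negative")
        if self.fov_drop_slices < 0:
            raise ConfigurationError("fov_drop_slices must be non-negative")
        if 2 * self.fov_drop_slices >= self.grid_shape[2]:
            raise ConfigurationError(
                f"2 x fov_drop_slices ({2 * self.fov_drop_slices}) must be smaller "
                f"than the axial extent ({self.grid_shape[2]})"
            )
        if self.smoothing_fwhm < 0:
            raise ConfigurationError("smoothing_fwhm must be non-negative")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["grid_shape"] = list(self.grid_shape)
        out["voxel_dims"] = list(self.voxel_dims)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown generator keys: {sorted(unknown)}")
        return cls(**dict(data))


@dataclass
class RunConfig:
    """Full pipeline configuration: generator plus analysis choices."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    correlation_method: str = "spearman"
    icc_form: str = "icc3"
    n_boot: int = 10_000
    ci_level: float = 0.95
    reference_age: float = 40.6
    inclusion_threshold: float = 0.001
    inclusion_fraction: float = 0.95
    mae_kind: str = "median"

    def __post_init__(self) -> None:
        if isinstance(self.generator, Mapping):
            self.generator = GeneratorConfig.from_dict(self.generator)
        self.validate()

    def validate(self) -> None:
        if self.correlation_method not in ("spearman", "pearson"):
            raise ConfigurationError(
                f"unknown correlation_method {self.correlation_method!r}"
            )
        if self.icc_form not in ("icc3", "icc1"):
            raise ConfigurationError(f"unknown icc_form {self.icc_form!r}")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be at least 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigurationError("ci_level must lie in (0, 1)")
        if not (0.0 < self.inclusion_fraction <= 1.0):
            raise ConfigurationError("inclusion_fraction must lie in (0, 1]")
        if self.mae_kind not in ("median", "mean"):
            raise ConfigurationError(f"unknown mae_kind {self.mae_kind!r}")

    @property
    def seed(self) -> int:
        return self.generator.seed

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["generator"] = self.generator.to_dict()
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
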
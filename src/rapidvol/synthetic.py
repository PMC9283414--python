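"""Synthetic paired-acquisition cohort generator.

The generator emulates the data structure of a cross-sequence agreement
study: each participant has voxel-wise GM/WM/CSF volume maps from a
*standard* acquisition (full field of view, low noise) and from a *rapid*
acquisition (reduced axial field of view, smoothed, noisier), a subset of
participants has a within-session *retest* rapid acquisition, and every
participant has brain-age predictions per sequence.

Generative model (per tissue ``t``, participant ``i``, voxel ``v``)::

    latent_iv   = T_v * (1 + e_i / G)          e_i = u_i + slope_t * (age_i - mu)
    standard_iv = latent_iv + T_v * eps^std_iv
    rapid_iv    = mask_v * smooth(latent_iv + T_v * d_i / G + T_v * eps^acq_iv)
    retest_iv   = mask_v * smooth(latent_iv + T_v * d_i / G + T_v * eps'^acq_iv)

where ``T`` is the tissue template (mm^3 per voxel), ``G = sum(T)``, ``u_i``
is a participant random effect, ``d_i`` a *stable* sequence-specific
deviation (it is what limits cross-sequence agreement while leaving retest
reliability near unity), and the ``eps`` terms are independent per-voxel
acquisition noise. Noise is a template-proportional, mean-zero lognormal
perturbation so every voxel value stays positive while the *global-volume*
noise variance is exact; the variance of ``d_i`` is solved in closed form so
the expected cross-participant correlation of global volumes between the two
sequences equals the configured per-tissue target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy import stats as sps

from .config import RAPID, STANDARD, TISSUES, GeneratorConfig
from .errors import ConfigurationError, DataError, SchemaError
from .volumetrics import TissueMapSet

# Independent RNG streams (combined with the tissue index and the seed).
(
    _AGES,
    _SUBJECT,
    _SEQDEV,
    _STD_NOISE,
    _ACQ_NOISE,
    _RETEST_NOISE,
    _BRAINAGE,
    _VOXEL_EFFECT,
) = range(11, 19)

#: Target total tissue volumes of the templates (mm^3).
TEMPLATE_TOTALS = {"GM": 190_000.0, "WM": 110_000.0, "CSF": 60_000.0}

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _rng(seed: int, stream: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng([stream, sub, seed])


# ---------------------------------------------------------------------------
# Templates and masks


def tissue_templates(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Smooth head-phantom templates of voxel tissue volume (mm^3).

    The phantom is an ellipsoid: a white-matter core, a grey-matter shell
    around it, and CSF in a central ventricle-like blob plus a thin outer
    rim. Shapes are schematic; only their statistical role matters (distinct
    spatial supports, axial taper so a field-of-view cut removes tissue).
    """
    nx, ny, nz = config.grid_shape
    dx, dy, dz = config.voxel_dims
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
    # Ellipsoid semi-axes: ~85% of the half-extent per axis.
    ax = 0.42 * nx * dx
    ay = 0.44 * ny * dy
    az = 0.46 * nz * dz
    r = np.sqrt((gx / ax) ** 2 + (gy / ay) ** 2 + (gz / az) ** 2)

    shapes = {
        "GM": np.exp(-(((r - 0.82) / 0.14) ** 2)) * (r < 1.12),
        "WM": np.exp(-((r / 0.62) ** 4)),
        "CSF": np.exp(-(((r - 1.02) / 0.07) ** 2)) * (r < 1.2)
        + 1.5 * np.exp(-((r / 0.24) ** 2)),
    }
    voxel_volume = dx * dy * dz
    templates = {}
    for tissue, w in shapes.items():
        w = np.where(w < 0.02 * w.max(), 0.0, w)
        t = w * (TEMPLATE_TOTALS[tissue] / w.sum())
        # A voxel cannot hold more tissue than its own volume.
        templates[tissue] = np.minimum(t, voxel_volume)
    return templates


def make_fov_mask(config: GeneratorConfig) -> np.ndarray:
    """Validity mask of the rapid acquisition: the top and bottom
    ``fov_drop_slices`` axial slices are outside the field of view."""
    config.validate()
    nz = config.grid_shape[2]
    drop = config.fov_drop_slices
    mask = np.ones(config.grid_shape, dtype=bool)
    if drop > 0:
        mask[:, :, :drop] = False
        mask[:, :, nz - drop :] = False
    if not mask.any():
        raise ConfigurationError("field-of-view mask is empty")
    return mask


# ---------------------------------------------------------------------------
# Cohort


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Participant table: ``participant_id``, ``age``, ``has_retest``.

    Ages are drawn from a normal(age_mean, age_sd) truncated to
    [age_min, age_max] by rejection sampling; the first ``n_retest``
    participants carry the retest flag. Fully reproducible from the seed.
    """
    config.validate()
    rng = _rng(config.seed, _AGES)
    n = config.n_participants
    ages = np.empty(0)
    while ages.size < n:
        draw = rng.normal(config.age_mean, config.age_sd, size=2 * n)
        draw = draw[(draw >= config.age_min) & (draw <= config.age_max)]
        ages = np.concatenate([ages, draw])
    ages = ages[:n]
    return pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": ages,
            "has_retest": np.arange(n) < config.n_retest,
        }
    )


def age_moments(config: GeneratorConfig) -> tuple[float, float]:
    """Mean and variance of the truncated-normal age distribution."""
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    dist = sps.truncnorm(a, b, loc=config.age_mean, scale=config.age_sd)
    return float(dist.mean()), float(dist.var())


# ---------------------------------------------------------------------------
# Variance components


@dataclass
class VarianceComponents:
    """Closed-form variance decomposition of global volume for one tissue.

    All variances are at the global-volume (mm^3) level. ``var_subject`` is
    the global subject mode (random effect plus age trend), ``var_voxel_*``
    the summed contribution of the per-voxel anatomical field (over the full
    support and over the field-of-view mask respectively), ``var_seqdev``
    the solved stable sequence-deviation variance, and ``fov_fraction`` the
    share of (smoothed) template volume inside the rapid field of view.
    """

    tissue: str
    var_subject: float
    var_seqdev: float
    var_standard_noise: float
    var_acq: float
    var_voxel_full: float
    var_voxel_mask: float
    fov_fraction: float

    @property
    def implied_cross_corr(self) -> float:
        s = self.fov_fraction
        num = s * self.var_subject + self.var_voxel_mask
        den_standard = (
            self.var_subject + self.var_voxel_full + self.var_standard_noise
        )
        den_rapid = (
            s**2 * (self.var_subject + self.var_seqdev)
            + self.var_voxel_mask
            + self.var_acq
        )
        return num / np.sqrt(den_standard * den_rapid)

    @property
    def implied_retest_icc(self) -> float:
        shared = (
            self.fov_fraction**2 * (self.var_subject + self.var_seqdev)
            + self.var_voxel_mask
        )
        return shared / (shared + self.var_acq)


def _age_slope(config: GeneratorConfig, tissue: str) -> float:
    if tissue == "GM":
        return config.gm_age_slope
    if tissue == "CSF":
        return config.csf_age_slope
    return 0.0


def variance_components(config: GeneratorConfig) -> dict[str, VarianceComponents]:
    """Solve the sequence-deviation variance per tissue from the configured
    cross-sequence correlation target.

    At the global-volume level the standard acquisition is
    ``G + e_i + H_full + eps_std`` and the (masked) rapid acquisition
    ``s (G + e_i + d_i) + H_mask + eps_acq``, where ``e_i`` is the global
    subject mode, ``H`` the summed per-voxel anatomical field (independent
    across voxels, so only the in-mask part is shared between sequences) and
    ``s`` the in-mask template fraction. The deviation variance ``vd`` is
    solved in closed form so the expected cross-participant correlation of
    the two global volumes equals the configured target; a target
    unreachable given the noise levels raises a configuration error.
    """
    _, age_var = age_moments(config)
    templates = tissue_templates(config)
    mask = make_fov_mask(config)
    out = {}
    for tissue in TISSUES:
        t = templates[tissue]
        g = t.sum()
        support = t > 0
        t_sm = _smooth_volume(t, config) if config.smoothing_fwhm > 0 else t
        s = float(t_sm[mask].sum() / g)
        tau2 = config.voxel_effect_cv[tissue] ** 2
        v_eta_full = tau2 * float((t[support] ** 2).sum())
        v_eta_mask = tau2 * float((t[support & mask] ** 2).sum())
        slope = _age_slope(config, tissue)
        ve = config.subject_sd[tissue] ** 2 + slope**2 * age_var
        vs = config.standard_noise_sd[tissue] ** 2
        va = config.retest_noise_sd**2
        rho = config.cross_sequence_corr_target[tissue]
        num = s * ve + v_eta_mask
        den_standard = ve + v_eta_full + vs
        den_rapid_required = num**2 / (rho**2 * den_standard)
        vd = (den_rapid_required - v_eta_mask - va) / s**2 - ve
        if vd < 0:
            raise ConfigurationError(
                f"cross-sequence correlation target {rho} for {tissue} is "
                f"unreachable given the configured noise levels"
            )
        out[tissue] = VarianceComponents(
            tissue=tissue,
            var_subject=ve,
            var_seqdev=vd,
            var_standard_noise=vs,
            var_acq=va,
            var_voxel_full=v_eta_full,
            var_voxel_mask=v_eta_mask,
            fov_fraction=s,
        )
    return out


# ---------------------------------------------------------------------------
# Maps


def _smooth_volume(vol: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    sigma = tuple(
        config.smoothing_fwhm / _FWHM_TO_SIGMA / d for d in config.voxel_dims
    )
    return ndimage.gaussian_filter(vol, sigma=sigma, truncate=4.0, mode="constant")


def _smooth_stack(values: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    if config.smoothing_fwhm <= 0:
        return values
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        out[i] = _smooth_volume(values[i], config)
    return out


def _noise_field(
    rng: np.random.Generator, template: np.ndarray, support: np.ndarray,
    var_global: float, second_moment_factor: float, n: int,
) -> np.ndarray:
    """Unit-mean lognormal acquisition-noise factors on ``support`` voxels.

    Multiplying the latent map by the field leaves every voxel positive and
    adds mean-zero noise whose summed (global) variance equals
    ``var_global`` exactly: the per-voxel noise variance is
    ``E[latent^2] (e^{c^2} - 1)`` and ``E[latent_v^2] =
    second_moment_factor * T_v^2`` under the generative model.
    """
    nvox = int(support.sum())
    if var_global <= 0 or nvox == 0:
        return np.ones((n, nvox))
    s2 = second_moment_factor * float((template[support] ** 2).sum())
    c2 = np.log1p(var_global / s2)
    c = np.sqrt(c2)
    z = rng.standard_normal((n, nvox))
    return np.exp(c * z - c2 / 2.0)


def _latent_maps(
    cohort: pd.DataFrame, config: GeneratorConfig, tissue: str,
    template: np.ndarray,
) -> np.ndarray:
    """Noise-free per-participant maps (n, nx, ny, nz): template scaled by
    the global subject mode plus the stable per-voxel anatomical field."""
    tissue_idx = TISSUES.index(tissue)
    n = len(cohort)
    g = template.sum()
    mu_age, _ = age_moments(config)
    u = _rng(config.seed, _SUBJECT, tissue_idx).normal(
        0.0, config.subject_sd[tissue], size=n
    )
    e = u + _age_slope(config, tissue) * (cohort["age"].to_numpy() - mu_age)
    latent = template[None, :, :, :] * (1.0 + e / g)[:, None, None, None]
    tau = config.voxel_effect_cv[tissue]
    if tau > 0:
        support = template > 0
        c2 = np.log1p(tau**2)
        z = _rng(config.seed, _VOXEL_EFFECT, tissue_idx).standard_normal(
            (n, int(support.sum()))
        )
        latent[:, support] += template[support] * (
            np.exp(np.sqrt(c2) * z - c2 / 2.0) - 1.0
        )
    return latent


def _seqdev(cohort: pd.DataFrame, config: GeneratorConfig, tissue: str,
            var_seqdev: float) -> np.ndarray:
    tissue_idx = TISSUES.index(tissue)
    return _rng(config.seed, _SEQDEV, tissue_idx).normal(
        0.0, np.sqrt(var_seqdev), size=len(cohort)
    )


def generate_tissue_maps(
    cohort: pd.DataFrame, config: GeneratorConfig
) -> dict[str, dict[str, TissueMapSet]]:
    """Paired standard/rapid tissue-volume map sets for every tissue class.

    Returns ``{"standard": {tissue: TissueMapSet}, "rapid": {...}}``. The
    rapid maps carry the field-of-view mask and are Gaussian-smoothed at
    ``smoothing_fwhm``; voxels outside the mask hold volume 0.
    """
    if len(cohort) == 0:
        raise DataError("cohort is empty")
    config.validate()
    ids = list(cohort["participant_id"])
    n = len(cohort)
    templates = tissue_templates(config)
    mask = make_fov_mask(config)
    comps = variance_components(config)
    out: dict[str, dict[str, TissueMapSet]] = {STANDARD: {}, RAPID: {}}
    for tissue_idx, tissue in enumerate(TISSUES):
        t = templates[tissue]
        g = t.sum()
        support = t > 0
        c = comps[tissue]
        latent = _latent_maps(cohort, config, tissue, t)
        tau2 = config.voxel_effect_cv[tissue] ** 2

        std_vals = latent.copy()
        std_vals[:, support] *= _noise_field(
            _rng(config.seed, _STD_NOISE, tissue_idx), t, support,
            c.var_standard_noise, 1.0 + tau2 + c.var_subject / g**2, n,
        )
        out[STANDARD][tissue] = TissueMapSet(
            values=np.clip(std_vals, 0.0, None),
            participant_ids=ids,
            tissue_class=tissue,
            sequence_label=STANDARD,
            voxel_dims=config.voxel_dims,
        )

        d = _seqdev(cohort, config, tissue, c.var_seqdev)
        rapid_vals = latent + t[None] * (d / g)[:, None, None, None]
        acq_support = support & mask
        rapid_vals[:, acq_support] *= _noise_field(
            _rng(config.seed, _ACQ_NOISE, tissue_idx), t, acq_support,
            c.var_acq, 1.0 + tau2 + (c.var_subject + c.var_seqdev) / g**2, n,
        )
        rapid_vals = _smooth_stack(rapid_vals, config)
        rapid_vals *= mask[None, :, :, :]
        out[RAPID][tissue] = TissueMapSet(
            values=np.clip(rapid_vals, 0.0, None),
            participant_ids=ids,
            tissue_class=tissue,
            sequence_label=RAPID,
            voxel_dims=config.voxel_dims,
            fov_mask=mask.copy(),
        )
    return out


def generate_retest_maps(
    rapid_maps: TissueMapSet, cohort: pd.DataFrame, config: GeneratorConfig
) -> TissueMapSet:
    """Second within-session rapid acquisition for retest participants.

    The participant's latent map and sequence deviation are identical to the
    first rapid acquisition (they are stable participant properties); only
    the acquisition noise is redrawn, at ``retest_noise_sd``. With
    ``retest_noise_sd = 0`` the retest maps equal the first rapid maps
    exactly. The field-of-view mask is shared with the first acquisition.
    """
    flagged = cohort[cohort["has_retest"]]
    if len(flagged) == 0:
        raise DataError("no retest participants in cohort")
    tissue = rapid_maps.tissue_class
    tissue_idx = TISSUES.index(tissue)
    templates = tissue_templates(config)
    t = templates[tissue]
    g = t.sum()
    support = t > 0
    mask = (
        rapid_maps.fov_mask if rapid_maps.fov_mask is not None
        else make_fov_mask(config)
    )
    comps = variance_components(config)
    c = comps[tissue]
    latent = _latent_maps(cohort, config, tissue, t)
    d = _seqdev(cohort, config, tissue, c.var_seqdev)
    vals = latent + t[None] * (d / g)[:, None, None, None]
    rows = flagged.index.to_numpy()
    vals = vals[rows]
    acq_support = support & mask
    tau2 = config.voxel_effect_cv[tissue] ** 2
    vals[:, acq_support] *= _noise_field(
        _rng(config.seed, _RETEST_NOISE, tissue_idx), t, acq_support,
        c.var_acq, 1.0 + tau2 + (c.var_subject + c.var_seqdev) / g**2, len(rows),
    )
    vals = _smooth_stack(vals, config)
    vals *= mask[None, :, :, :]
    return TissueMapSet(
        values=np.clip(vals, 0.0, None),
        participant_ids=list(flagged["participant_id"]),
        tissue_class=tissue,
        sequence_label="retest",
        voxel_dims=config.voxel_dims,
        fov_mask=mask.copy(),
    )


# ---------------------------------------------------------------------------
# Brain-age predictions


def generate_age_predictions(
    cohort: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Brain-age prediction table per participant and sequence.

    The standard sequence predicts chronological age with unbiased noise;
    the rapid and FoV-reduced predictions are affinely compressed
    (``intercept + slope * age``, slope < 1) plus noise, emulating the
    systematic offset of a model applied outside its training domain.
    """
    if len(cohort) == 0:
        raise DataError("cohort is empty")
    rng = _rng(config.seed, _BRAINAGE)
    age = cohort["age"].to_numpy()
    n = len(cohort)
    noise_std = rng.standard_normal(n) * config.brainage_noise_sd
    noise_rapid = rng.standard_normal(n) * config.brainage_noise_sd
    noise_fov = rng.standard_normal(n) * config.fovreduced_noise_sd
    return pd.DataFrame(
        {
            "participant_id": list(cohort["participant_id"]),
            "age": age,
            "pred_standard": age + noise_std,
            "pred_rapid": config.brainage_offset_intercept
            + config.brainage_offset_slope * age
            + noise_rapid,
            "pred_standard_fovreduced": config.fovreduced_offset_intercept
            + config.fovreduced_offset_slope * age
            + noise_fov,
        }
    )


# ---------------------------------------------------------------------------
# Dataset container and round-trip I/O


@dataclass
class Dataset:
    """Everything one pipeline run consumes."""

    cohort: pd.DataFrame
    maps: dict[str, dict[str, TissueMapSet]]  # sequence -> tissue -> maps
    retest_maps: dict[str, TissueMapSet]  # tissue -> maps
    fov_mask: np.ndarray
    predictions: pd.DataFrame
    config: Optional[GeneratorConfig] = None


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Run the whole generator: cohort, paired maps, retest maps, mask,
    brain-age predictions."""
    cohort = generate_cohort(config)
    maps = generate_tissue_maps(cohort, config)
    retest = {
        tissue: generate_retest_maps(maps[RAPID][tissue], cohort, config)
        for tissue in TISSUES
    }
    return Dataset(
        cohort=cohort,
        maps=maps,
        retest_maps=retest,
        fov_mask=make_fov_mask(config),
        predictions=generate_age_predictions(cohort, config),
        config=config,
    )


def _nifti_from_mapset(maps: TissueMapSet) -> nib.Nifti1Image:
    data = np.moveaxis(maps.values, 0, -1)  # (x, y, z, participant)
    affine = np.diag(list(maps.voxel_dims) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(tuple(maps.voxel_dims) + (1.0,))
    return img


def write_dataset(dataset: Dataset, directory) -> None:
    """Write a dataset to disk: NIfTI-1 maps, TSV tables, YAML config.

    Layout::

        participants.tsv            participant_id, age, has_retest
        predictions.tsv             participant_id, age, pred_* per sequence
        fov_mask.nii.gz
        maps/<sequence>_<tissue>.nii.gz   4-D, participants on the 4th axis
        maps/retest_<tissue>.nii.gz
        generator.yaml              (when the dataset records its config)
    """
    directory = Path(directory)
    (directory / "maps").mkdir(parents=True, exist_ok=True)
    cohort = dataset.cohort.copy()
    cohort["has_retest"] = cohort["has_retest"].astype(int)
    cohort.to_csv(directory / "participants.tsv", sep="\t", index=False)
    dataset.predictions.to_csv(directory / "predictions.tsv", sep="\t", index=False)
    voxel_dims = next(iter(dataset.maps[STANDARD].values())).voxel_dims
    mask_img = nib.Nifti1Image(
        dataset.fov_mask.astype(np.uint8), np.diag(list(voxel_dims) + [1.0])
    )
    nib.save(mask_img, directory / "fov_mask.nii.gz")
    for sequence, per_tissue in dataset.maps.items():
        for tissue, maps in per_tissue.items():
            nib.save(
                _nifti_from_mapset(maps),
                directory / "maps" / f"{sequence}_{tissue}.nii.gz",
            )
    for tissue, maps in dataset.retest_maps.items():
        nib.save(
            _nifti_from_mapset(maps), directory / "maps" / f"retest_{tissue}.nii.gz"
        )
    if dataset.config is not None:
        with open(directory / "generator.yaml", "w") as fh:
            yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"missing file: {path}")
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for column in required:
        if column not in table.columns:
            raise SchemaError(f"{path.name}: missing column {column!r}")
    return table


def read_dataset(directory) -> Dataset:
    """Read back a directory produced by :func:`write_dataset` (or any
    external directory following the same layout)."""
    directory = Path(directory)
    cohort = _read_table(
        directory / "participants.tsv", ["participant_id", "age", "has_retest"]
    )
    cohort["has_retest"] = cohort["has_retest"].astype(bool)
    predictions = _read_table(
        directory / "predictions.tsv",
        ["participant_id", "age", "pred_standard", "pred_rapid",
         "pred_standard_fovreduced"],
    )
    mask_path = directory / "fov_mask.nii.gz"
    if not mask_path.exists():
        raise DataError(f"missing file: {mask_path}")
    fov_mask = np.asarray(nib.load(mask_path).dataobj).astype(bool)

    ids = list(cohort["participant_id"])
    retest_ids = list(cohort.loc[cohort["has_retest"], "participant_id"])
    maps: dict[str, dict[str, TissueMapSet]] = {STANDARD: {}, RAPID: {}}
    retest: dict[str, TissueMapSet] = {}
    for sequence in (STANDARD, RAPID, "retest"):
        for tissue in TISSUES:
            path = directory / "maps" / f"{sequence}_{tissue}.nii.gz"
            if not path.exists():
                raise DataError(f"missing file: {path}")
            img = nib.load(path)
            values = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
            voxel_dims = tuple(float(v) for v in img.header.get_zooms()[:3])
            expected_ids = retest_ids if sequence == "retest" else ids
            if values.shape[0] != len(expected_ids):
                raise SchemaError(
                    f"{path.name}: {values.shape[0]} volumes for "
                    f"{len(expected_ids)} participants"
                )
            mapset = TissueMapSet(
                values=values,
                participant_ids=expected_ids,
                tissue_class=tissue,
                sequence_label=sequence,
                voxel_dims=voxel_dims,
                fov_mask=fov_mask if sequence in (RAPID, "retest") else None,
            )
            if sequence == "retest":
                retest[tissue] = mapset
            else:
                maps[sequence][tissue] = mapset
    config = None
    cfg_path = directory / "generator.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = GeneratorConfig.from_dict(yaml.safe_load(fh))
    return Dataset(
        cohort=cohort,
        maps=maps,
        retest_maps=retest,
        fov_mask=fov_mask,
        predictions=predictions,
        config=config,
    )
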
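"""End-to-end pipeline: generate (or load) → volumetrics → associations →
brain-age evaluation → reliability, emitting one reproducible report.

The report aggregates the study's result surfaces: global-volume agreement
per tissue and contrast pair, voxel-wise correlation summaries, GM–age
associations with bootstrap pairwise difference CIs, a per-sequence
brain-age metrics table with the LOO-adjusted MAE, and global plus
voxel-wise test-retest reliability. Identical configuration and seed yield a
byte-identical JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brainage import evaluate_sequence, loo_adjust
from .config import RAPID, STANDARD, STANDARD_FOVREDUCED, TISSUES, RunConfig
from .errors import RapidvolError, SchemaError
from .stats import association, bootstrap_corr_difference, icc_3_1, icc_map
from .synthetic import Dataset, generate_dataset, read_dataset
from .volumetrics import (
    global_volumes,
    inclusion_mask,
    reduce_fov,
    summarize_distribution,
    voxelwise_correlation,
)

logger = logging.getLogger("rapidvol")

#: Contrast pairs reported for global-volume agreement.
GLOBAL_PAIRS = ((STANDARD, RAPID), (RAPID, STANDARD_FOVREDUCED))

#: Contrasts evaluated against age and in the brain-age table.
CONTRASTS = (STANDARD, RAPID, STANDARD_FOVREDUCED)


class PipelineStageError(RapidvolError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")


@contextmanager
def _stage(name: str):
    start = time.perf_counter()
    logger.info("stage=%s status=start", name)
    try:
        yield
    except RapidvolError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapping
        raise PipelineStageError(name, exc) from exc
    logger.info("stage=%s status=done wall_s=%.2f", name, time.perf_counter() - start)


@dataclass
class PipelineReport:
    """Structured result of one pipeline run."""

    provenance: dict
    global_volume_associations: dict
    voxelwise_correlation: dict
    gm_age: dict
    brain_age: dict
    reliability: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "global_volume_associations": self.global_volume_associations,
            "voxelwise_correlation": self.voxelwise_correlation,
            "gm_age": self.gm_age,
            "brain_age": self.brain_age,
            "reliability": self.reliability,
        }

    def to_json(self) -> str:
        return json.dumps(_jsonify(self.to_dict()), indent=2, sort_keys=True)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def _config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def load_external(directory) -> Dataset:
    """Load pipeline inputs from a directory in the documented layout and
    validate that tables and maps refer to the same participants."""
    dataset = read_dataset(directory)
    cohort_ids = list(dataset.cohort["participant_id"])
    if len(set(cohort_ids)) != len(cohort_ids):
        raise SchemaError("participants.tsv: duplicate participant_id values")
    pred_ids = set(dataset.predictions["participant_id"])
    missing = [p for p in cohort_ids if p not in pred_ids]
    if missing:
        raise SchemaError(
            f"predictions.tsv: missing participants {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    # Align prediction rows to cohort order.
    dataset.predictions = (
        dataset.predictions.set_index("participant_id")
        .loc[cohort_ids]
        .reset_index()
    )
    return dataset


def run_pipeline(
    config: RunConfig,
    out_dir=None,
    dataset: Dataset | None = None,
    figures: bool = False,
) -> PipelineReport:
    """Execute all analysis stages and assemble the report.

    When ``dataset`` is None the synthetic generator runs with
    ``config.generator``; a dataset loaded by :func:`load_external` can be
    supplied instead. ``out_dir`` (optional) receives ``report.json``, TSV
    tables, NIfTI correlation/ICC maps and, when ``figures`` is set,
    scatter/density figures.
    """
    seed = config.seed

    with _stage("generate"):
        if dataset is None:
            dataset = generate_dataset(config.generator)
    cohort = dataset.cohort
    age = cohort["age"].to_numpy(dtype=float)

    with _stage("volumetrics"):
        maps = {
            STANDARD: dataset.maps[STANDARD],
            RAPID: dataset.maps[RAPID],
            STANDARD_FOVREDUCED: {
                t: reduce_fov(dataset.maps[STANDARD][t], dataset.fov_mask)
                for t in TISSUES
            },
        }
        gvol = {
            seq: {
                t: global_volumes(maps[seq][t])["volume_mm3"].to_numpy()
                for t in TISSUES
            }
            for seq in maps
        }
        incl = {
            t: inclusion_mask(
                maps[RAPID][t],
                threshold=config.inclusion_threshold,
                fraction=config.inclusion_fraction,
            )
            for t in TISSUES
        }
        corr_maps = {
            t: voxelwise_correlation(
                maps[STANDARD][t], maps[RAPID][t], incl[t],
                method=config.correlation_method,
            )
            for t in TISSUES
        }
        voxelwise = {}
        for t in TISSUES:
            summary = summarize_distribution(corr_maps[t]).to_dict()
            summary["n_voxels_included"] = incl[t].n_voxels
            voxelwise[t] = summary

    with _stage("associations"):
        global_assoc = {
            t: {
                f"{a}_vs_{b}": association(gvol[a][t], gvol[b][t]).to_dict()
                for a, b in GLOBAL_PAIRS
            }
            for t in TISSUES
        }
        gm_contrast_assoc = {
            seq: association(age, gvol[seq]["GM"]).to_dict() for seq in CONTRASTS
        }
        gm_contrasts = {seq: gvol[seq]["GM"] for seq in CONTRASTS}
        bootstrap = {}
        for statistic in ("rs", "r2"):
            results = bootstrap_corr_difference(
                age,
                gm_contrasts,
                statistic=statistic,
                n_boot=config.n_boot,
                seed=seed + 3,
                ci_level=config.ci_level,
            )
            bootstrap[statistic] = {
                f"{a}_vs_{b}": res.to_dict() for (a, b), res in results.items()
            }

    with _stage("brainage"):
        table_rows = [
            evaluate_sequence(
                dataset.predictions, seq,
                reference_age=config.reference_age, mae_kind=config.mae_kind,
            ).to_dict()
            for seq in CONTRASTS
        ]
        adjustment = loo_adjust(
            dataset.predictions["pred_rapid"].to_numpy(),
            dataset.predictions["pred_standard"].to_numpy(),
            age,
            mae_kind=config.mae_kind,
        )
        brain_age = {
            "table": table_rows,
            "loo_adjusted_mae": adjustment.adjusted_mae,
            "reference_age": config.reference_age,
        }

    with _stage("reliability"):
        retest_ids = list(cohort.loc[cohort["has_retest"], "participant_id"])
        reliability = {}
        icc_maps = {}
        for t in TISSUES:
            test_maps = maps[RAPID][t].subset(retest_ids)
            retest_maps = dataset.retest_maps[t].subset(retest_ids)
            test_g = global_volumes(test_maps)["volume_mm3"].to_numpy()
            retest_g = global_volumes(retest_maps)["volume_mm3"].to_numpy()
            global_icc = icc_3_1(
                np.column_stack([test_g, retest_g]), form=config.icc_form
            )
            vox = icc_map(test_maps, retest_maps, incl[t], form=config.icc_form)
            icc_maps[t] = vox
            reliability[t] = {
                "global": global_icc.to_dict(),
                "voxelwise": summarize_distribution(vox).to_dict(),
            }

    provenance = {
        "package": "rapidvol",
        "version": __version__,
        "seed": seed,
        "n_participants": len(cohort),
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
    }
    report = PipelineReport(
        provenance=provenance,
        global_volume_associations=global_assoc,
        voxelwise_correlation=voxelwise,
        gm_age={"associations": gm_contrast_assoc, "bootstrap": bootstrap},
        brain_age=brain_age,
        reliability=reliability,
    )

    if out_dir is not None:
        with _stage("write"):
            _write_outputs(
                Path(out_dir), report, dataset, gvol, corr_maps, icc_maps,
                figures=figures,
            )
    return report


def _write_outputs(out_dir: Path, report, dataset, gvol, corr_maps, icc_maps,
                   figures: bool = False) -> None:
    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report.to_json())

    rows = []
    for seq, per_tissue in gvol.items():
        for t, values in per_tissue.items():
            for pid, v in zip(dataset.cohort["participant_id"], values):
                rows.append(
                    {"participant_id": pid, "sequence": seq, "tissue": t,
                     "volume_mm3": v}
                )
    pd.DataFrame(rows).to_csv(out_dir / "global_volumes.tsv", sep="\t", index=False)

    pd.DataFrame(report.brain_age["table"]).to_csv(
        out_dir / "brainage_table.tsv", sep="\t", index=False
    )

    voxel_dims = next(iter(dataset.maps[STANDARD].values())).voxel_dims
    affine = np.diag(list(voxel_dims) + [1.0])
    for t in TISSUES:
        nib.save(
            nib.Nifti1Image(np.asarray(corr_maps[t], dtype=np.float32), affine),
            out_dir / f"crossseq_corr_{t}.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(np.asarray(icc_maps[t], dtype=np.float32), affine),
            out_dir / f"retest_icc_{t}.nii.gz",
        )
    if figures:
        from .figures import write_figures

        write_figures(out_dir / "figures", dataset, gvol, corr_maps, icc_maps)
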
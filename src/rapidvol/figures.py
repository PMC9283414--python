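"""Optional figure outputs: scatter and density analogues of the study's
result panels. Numbers, not figures, are the tested surface; these exist for
visual inspection of a run."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import RAPID, STANDARD, STANDARD_FOVREDUCED, TISSUES


def _axes_grid(n):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.5))
    return fig, np.atleast_1d(axes)


def write_figures(out_dir, dataset, gvol, corr_maps, icc_maps) -> None:
    """Write global-volume scatters, voxel-wise correlation densities,
    GM-age scatters, brain-age scatters and ICC densities as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    age = dataset.cohort["age"].to_numpy()

    fig, axes = _axes_grid(len(TISSUES))
    for ax, t in zip(axes, TISSUES):
        ax.scatter(gvol[STANDARD][t] / 1e3, gvol[RAPID][t] / 1e3, s=12)
        ax.set_xlabel(f"standard {t} volume (cm$^3$)")
        ax.set_ylabel(f"rapid {t} volume (cm$^3$)")
    fig.tight_layout()
    fig.savefig(out_dir / "global_volume_agreement.png", dpi=120)
    plt.close(fig)

    fig, axes = _axes_grid(len(TISSUES))
    for ax, t in zip(axes, TISSUES):
        vals = corr_maps[t][np.isfinite(corr_maps[t])]
        ax.hist(vals, bins=40, density=True)
        ax.set_xlabel(f"{t} voxel-wise cross-sequence correlation")
    fig.tight_layout()
    fig.savefig(out_dir / "voxelwise_correlation_density.png", dpi=120)
    plt.close(fig)

    fig, axes = _axes_grid(3)
    for ax, seq in zip(axes, (STANDARD, RAPID, STANDARD_FOVREDUCED)):
        ax.scatter(age, gvol[seq]["GM"] / 1e3, s=12)
        ax.set_xlabel("age (y)")
        ax.set_ylabel(f"{seq} GM volume (cm$^3$)")
    fig.tight_layout()
    fig.savefig(out_dir / "gm_age.png", dpi=120)
    plt.close(fig)

    preds = dataset.predictions
    fig, axes = _axes_grid(3)
    for ax, col in zip(
        axes, ("pred_standard", "pred_rapid", "pred_standard_fovreduced")
    ):
        ax.scatter(age, preds[col], s=12)
        lims = [min(age.min(), preds[col].min()), max(age.max(), preds[col].max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("chronological age (y)")
        ax.set_ylabel(f"{col} (y)")
    fig.tight_layout()
    fig.savefig(out_dir / "brainage_scatter.png", dpi=120)
    plt.close(fig)

    fig, axes = _axes_grid(len(TISSUES))
    for ax, t in zip(axes, TISSUES):
        vals = icc_maps[t][np.isfinite(icc_maps[t])]
        ax.hist(vals, bins=40, density=True)
        ax.set_xlabel(f"{t} voxel-wise retest ICC")
    fig.tight_layout()
    fig.savefig(out_dir / "retest_icc_density.png", dpi=120)
    plt.close(fig)
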
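"""Association and reliability statistics.

Three families of statistics drive the cross-sequence comparison:

* Spearman rank correlation (with a t-approximation p-value) and the squared
  Pearson correlation, used for every pairwise agreement measure;
* a paired bootstrap for the *difference* in association strength between
  contrasts: the same participant resample is applied to every contrast
  within a replicate, so the difference distribution is that of paired
  statistics and its percentile interval is a valid test of equality;
* the intraclass correlation ICC(3,1) — two-way mixed model, consistency of
  single measurements — with an F-based 95% confidence interval, used for
  test-retest reliability (a one-way ICC(1,1) is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .errors import (
    AlignmentError,
    DataError,
    DegenerateDataError,
    ParameterError,
)
from .volumetrics import TissueMapSet, _as_mask_array


# ---------------------------------------------------------------------------
# Correlation coefficients


@dataclass
class AssociationResult:
    """Spearman coefficient with significance, plus Pearson r^2."""

    rs: float
    p: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {"rs": self.rs, "p": self.p, "r2": self.r2, "n": self.n}


def _validate_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DataError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < min_n:
        raise DataError(f"need at least {min_n} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("inputs contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    return x, y


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rank correlation and two-sided p-value.

    The coefficient is the Pearson correlation of average ranks; the p-value
    uses the t transform ``t = rs * sqrt((n-2) / (1 - rs^2))`` on ``n - 2``
    degrees of freedom, with ``p = 0`` in the limiting case ``|rs| = 1``.
    """
    x, y = _validate_pair(x, y)
    rs, _ = sps.spearmanr(x, y)
    rs = float(rs)
    if 1.0 - abs(rs) < 1e-12:  # numerically perfect monotone association
        rs = float(np.sign(rs))
    n = x.size
    if abs(rs) >= 1.0:
        return float(np.sign(rs)), 0.0
    t = rs * np.sqrt((n - 2) / (1.0 - rs**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rs, float(p)


def pearson_r2(x, y) -> float:
    """Square of the sample Pearson correlation coefficient."""
    x, y = _validate_pair(x, y)
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r**2, 1.0))


def association(x, y) -> AssociationResult:
    """Bundle Spearman rs/p and Pearson r^2 for one pair of vectors."""
    rs, p = spearman(x, y)
    return AssociationResult(rs=rs, p=p, r2=pearson_r2(x, y), n=np.size(x))


# ---------------------------------------------------------------------------
# Paired bootstrap for differences in association strength


@dataclass
class BootstrapDiffResult:
    """Percentile summary of a bootstrap difference in association strength."""

    contrast_a: str
    contrast_b: str
    statistic_name: str
    n_boot: int
    seed: int
    median: float
    ci_low: float
    ci_high: float
    ci_includes_zero: bool
    n_redrawn: int

    def to_dict(self) -> dict:
        return {
            "contrast_a": self.contrast_a,
            "contrast_b": self.contrast_b,
            "statistic": self.statistic_name,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "median": self.median,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_includes_zero": self.ci_includes_zero,
            "n_redrawn": self.n_redrawn,
        }


def _rowwise_stat(x: np.ndarray, y: np.ndarray, statistic: str) -> np.ndarray:
    """Statistic per row of two (B, n) matrices; NaN where undefined."""
    if statistic == "rs":
        x = sps.rankdata(x, axis=1)
        y = sps.rankdata(y, axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.einsum("ij,ij->i", xc, xc)
    sy = np.einsum("ij,ij->i", yc, yc)
    cov = np.einsum("ij,ij->i", xc, yc)
    denom = np.sqrt(sx * sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    if statistic == "r2":
        return r**2
    return r


def bootstrap_corr_difference(
    age,
    contrasts: Mapping[str, np.ndarray],
    statistic: str = "rs",
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict[tuple[str, str], BootstrapDiffResult]:
    """Bootstrap test for differences in association strength with age.

    For each replicate, one resample of participants (with replacement) is
    drawn and applied to *every* contrast; the statistic (Spearman ``rs`` or
    Pearson ``r2``) of (age, contrast) is computed per contrast on that same
    resample and all pairwise differences are formed. The CI bounds are the
    percentile quantiles of each difference distribution. Replicates where
    any contrast's statistic is undefined (zero-variance resample) are
    redrawn so exactly ``n_boot`` replicates remain; the redraw count is
    reported.
    """
    if statistic not in ("rs", "r2"):
        raise ParameterError(f"unknown statistic {statistic!r}")
    if n_boot < 1:
        raise ParameterError("n_boot must be at least 1")
    if not (0.0 < ci_level < 1.0):
        raise ParameterError("ci_level must lie in (0, 1)")
    age = np.asarray(age, dtype=float).ravel()
    names = list(contrasts)
    vectors = {}
    for name in names:
        v = np.asarray(contrasts[name], dtype=float).ravel()
        if v.size != age.size:
            raise DataError(f"contrast {name!r} has length {v.size}, age {age.size}")
        vectors[name] = v
    if age.size < 3:
        raise DataError("need at least 3 participants")

    rng = np.random.default_rng(seed)
    n = age.size
    idx = rng.integers(0, n, size=(n_boot, n))
    stats_by_contrast = {
        name: _rowwise_stat(age[idx], vectors[name][idx], statistic)
        for name in names
    }
    n_redrawn = 0
    for _ in range(100):
        bad = np.zeros(n_boot, dtype=bool)
        for name in names:
            bad |= ~np.isfinite(stats_by_contrast[name])
        if not bad.any():
            break
        n_bad = int(bad.sum())
        n_redrawn += n_bad
        idx_new = rng.integers(0, n, size=(n_bad, n))
        for name in names:
            stats_by_contrast[name][bad] = _rowwise_stat(
                age[idx_new], vectors[name][idx_new], statistic
            )
    else:
        raise DataError("could not draw non-degenerate bootstrap resamples")

    alpha = (1.0 - ci_level) / 2.0
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = stats_by_contrast[a] - stats_by_contrast[b]
            lo, md, hi = np.percentile(diff, [100 * alpha, 50.0, 100 * (1 - alpha)])
            out[(a, b)] = BootstrapDiffResult(
                contrast_a=a,
                contrast_b=b,
                statistic_name=statistic,
                n_boot=n_boot,
                seed=seed,
                median=float(md),
                ci_low=float(lo),
                ci_high=float(hi),
                ci_includes_zero=bool(lo <= 0.0 <= hi),
                n_redrawn=n_redrawn,
            )
    return out


# ---------------------------------------------------------------------------
# Intraclass correlation


@dataclass
class ICCResult:
    """ICC point estimate with F-based 95% confidence interval."""

    icc: float
    ci95: tuple[float, float]
    n: int
    k: int
    f_value: float
    df1: int
    df2: int
    p: float
    form: str = "icc3"

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "n": self.n,
            "k": self.k,
            "f": self.f_value,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "form": self.form,
        }


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters) mean squares: subjects, raters, error."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_sub = k * ((row_means - grand) ** 2).sum()
    ss_rater = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_sub - ss_rater
    ms_sub = ss_sub / (n - 1)
    ms_rater = ss_rater / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_sub, ms_rater, ms_err


def icc_3_1(ratings, form: str = "icc3") -> ICCResult:
    """Intraclass correlation of a subjects x measurements table.

    ``form="icc3"`` (default): two-way mixed model, consistency of single
    measurements — ``(MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)``
    with the rater effect removed from the error term, so a constant shift
    between measurements leaves the ICC at 1. ``form="icc1"``: one-way
    random-effects ICC(1,1). The 95% CI follows from F-distribution
    quantiles of ``F = MS_subjects / MS_error``.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise DataError(f"ratings must be 2-D (subjects x raters), got {x.shape}")
    n, k = x.shape
    if n < 2 or k < 2:
        raise DataError(f"need at least 2 subjects and 2 measurements, got {x.shape}")
    if not np.isfinite(x).all():
        raise DataError("ratings contain missing or non-finite cells")
    if form not in ("icc3", "icc1"):
        raise ParameterError(f"unknown ICC form {form!r}")

    if form == "icc3":
        ms_sub, _, ms_err = _anova_mean_squares(x)
        df1, df2 = n - 1, (n - 1) * (k - 1)
    else:
        grand = x.mean()
        row_means = x.mean(axis=1)
        ss_sub = k * ((row_means - grand) ** 2).sum()
        ss_within = ((x - row_means[:, None]) ** 2).sum()
        ms_sub = ss_sub / (n - 1)
        ms_err = ss_within / (n * (k - 1))
        df1, df2 = n - 1, n * (k - 1)

    if ms_sub == 0 and ms_err == 0:
        raise DegenerateDataError("no variance in ratings; ICC undefined")
    denom = ms_sub + (k - 1) * ms_err
    icc = (ms_sub - ms_err) / denom if denom > 0 else np.nan

    if ms_err == 0:
        f_value, p = np.inf, 0.0
        ci = (1.0, 1.0) if icc == 1.0 else (np.nan, np.nan)
    else:
        f_value = ms_sub / ms_err
        p = float(sps.f.sf(f_value, df1, df2))
        f_upper = sps.f.ppf(0.975, df1, df2)
        f_lower = sps.f.ppf(0.975, df2, df1)
        fl = f_value / f_upper
        fu = f_value * f_lower
        ci = (
            float((fl - 1.0) / (fl + k - 1.0)),
            float((fu - 1.0) / (fu + k - 1.0)),
        )
    return ICCResult(
        icc=float(icc), ci95=ci, n=n, k=k,
        f_value=float(f_value), df1=df1, df2=df2, p=p, form=form,
    )


def icc_map(
    maps_test: TissueMapSet,
    maps_retest: TissueMapSet,
    mask,
    form: str = "icc3",
) -> np.ndarray:
    """Voxel-wise ICC between test and retest map sets.

    Returns a 3-D array with the ICC at voxels inside ``mask`` and NaN
    elsewhere; voxels with degenerate tables (no variance) are NaN.
    """
    if maps_test.participant_ids != maps_retest.participant_ids:
        raise AlignmentError(
            "test and retest map sets must hold the same participants"
        )
    if maps_test.n_participants < 2:
        raise DataError("need at least 2 retest participants")
    if form not in ("icc3", "icc1"):
        raise ParameterError(f"unknown ICC form {form!r}")
    m = _as_mask_array(mask)
    a = maps_test.values[:, m]  # (n, V)
    b = maps_retest.values[:, m]
    n = a.shape[0]
    k = 2
    x = np.stack([a, b], axis=1)  # (n, 2, V)
    grand = x.mean(axis=(0, 1))
    row_means = x.mean(axis=1)  # (n, V)
    ss_sub = k * ((row_means - grand) ** 2).sum(axis=0)
    ss_tot = ((x - grand) ** 2).sum(axis=(0, 1))
    ms_sub = ss_sub / (n - 1)
    if form == "icc3":
        col_means = x.mean(axis=0)  # (2, V)
        ss_rater = n * ((col_means - grand) ** 2).sum(axis=0)
        ss_err = ss_tot - ss_sub - ss_rater
        ms_err = ss_err / ((n - 1) * (k - 1))
    else:
        ss_within = ((x - row_means[:, None, :]) ** 2).sum(axis=(0, 1))
        ms_err = ss_within / (n * (k - 1))
    denom = ms_sub + (k - 1) * ms_err
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (ms_sub - ms_err) / np.where(denom > 0, denom, 1.0),
                       np.nan)
    out = np.full(maps_test.grid_shape, np.nan)
    out[m] = icc
    return out
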
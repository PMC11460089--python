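"""Comparison statistics for predicted vs reference input functions and
influx-rate maps: Deming (orthogonal) regression, the signed mean relative
error, paired t-tests, quantile-quantile normality points, maximum-intensity
projections and a cohort-level report.

Orthogonal regression is used for method comparison because both the
predicted and the reference quantity carry measurement error; with an error
variance ratio λ = 1 it minimizes perpendicular distances to the line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .imaging_core import DynamicImage, TimeActivityCurve, ValidationError
from .kinetics import patlak_fit, patlak_voxelwise

__all__ = [
    "DemingFit",
    "ComparisonReport",
    "deming_fit",
    "average_error",
    "paired_t",
    "qq_points",
    "render_mip",
    "build_report",
]


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    correlation_r: float
    n: int


def deming_fit(x: np.ndarray, y: np.ndarray, lambda_ratio: float = 1.0) -> DemingFit:
    """Errors-in-both-variables line fit.

    With centered second moments S_xx, S_yy, S_xy and error-variance ratio
    λ = Var(err_y)/Var(err_x):

        slope = [S_yy − λ S_xx + sqrt((S_yy − λ S_xx)² + 4 λ S_xy²)] / (2 S_xy)

    and intercept = ȳ − slope·x̄.  λ = 1 is orthogonal regression.  The
    reported r is the Pearson correlation of the pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("x and y must be 1-D, equal length, n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x values are all equal")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    syy = np.sum((y - ym) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    if sxy == 0:
        if np.isclose(syy, lambda_ratio * sxx):
            raise DegenerateFitError("no preferred orientation (S_xy = 0)")
        # vertical/horizontal principal axis degenerates to slope 0 or inf
        raise DegenerateFitError("S_xy = 0; orthogonal slope undefined")
    d = syy - lambda_ratio * sxx
    slope = (d + np.sqrt(d**2 + 4 * lambda_ratio * sxy**2)) / (2 * sxy)
    intercept = ym - slope * xm
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    return DemingFit(float(slope), float(intercept), float(r), len(x))


def average_error(ref: np.ndarray, est: np.ndarray) -> float:
    """Signed mean relative error in percent: mean((ref − est) / ref) × 100.

    An estimate above the reference gives a negative error.
    """
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape:
        raise ValidationError("ref and est must have equal length")
    if np.any(ref == 0):
        raise ValidationError("reference values must be nonzero")
    return float(np.mean((ref - est) / ref) * 100.0)


def paired_t(
    ref: np.ndarray, est: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool, bool]:
    """Two-sided paired t-test on ref − est.

    Returns (t, P, reject, degenerate); zero-variance differences are
    flagged degenerate with P = 1 rather than raising.
    """
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if len(ref) < 2 or ref.shape != est.shape:
        raise ValidationError("need n >= 2 paired observations")
    diff = ref - est
    if np.allclose(diff.std(ddof=1), 0.0):
        return 0.0, 1.0, False, True
    t, p = stats.ttest_rel(ref, est)
    return float(t), float(p), bool(p < alpha), False


def qq_points(sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal quantile-quantile pairs at plotting positions (i−0.5)/n."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 3:
        raise ValidationError("need n >= 3 for a Q-Q plot")
    n = len(sample)
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theoretical, np.sort(sample)


def render_mip(
    ki_map: np.ndarray, axis: int = 2, path: str | Path | None = None
) -> np.ndarray:
    """NaN-ignoring maximum-intensity projection; optionally save a PNG."""
    ki_map = np.asarray(ki_map, dtype=float)
    if np.all(np.isnan(ki_map)):
        raise ValidationError("all-NaN volume")
    with warnings.catch_warnings():
        # rays with no in-mask voxel legitimately project to NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mip = np.nanmax(ki_map, axis=axis)
    if path is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(mip.T, cmap="gray", origin="lower")
        fig.colorbar(im, ax=ax, label="Ki [ml/g/min]")
        ax.set_axis_off()
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return mip


@dataclass
class ScanComparison:
    """Per-scan inputs to the cohort report."""

    scan_id: str
    predicted_if: TimeActivityCurve
    reference_if: TimeActivityCurve
    image: DynamicImage | None = None
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class ComparisonReport:
    curve_fit_pooled: DemingFit
    curve_fits: list[DemingFit]
    voxel_fits: list[DemingFit]
    voxel_fit_pooled: DemingFit | None
    outlier_scans: list[str]
    regional: pd.DataFrame

    @property
    def n_scans(self) -> int:
        return len(self.curve_fits)


def _ci_halfwidth(values: np.ndarray) -> float:
    """t-based 95% confidence half-width of the mean."""
    n = len(values)
    if n < 2:
        return float("nan")
    return float(stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n))


def build_report(
    scans: list[ScanComparison],
    t_star_min: float = 10.0,
    outlier_band: float = 0.4,
    outdir: str | Path | None = None,
    scatter_points: int = 1000,
    seed: int = 0,
) -> ComparisonReport:
    """Cohort comparison of predicted vs reference input functions.

    Per scan: an orthogonal fit of the curve points, and — when the image
    is present — voxelwise Patlak influx maps under both input functions
    compared by an orthogonal fit, flagging scans whose slope falls outside
    1 ± ``outlier_band``.  Per region (masks given per scan): Patlak Ki
    under both input functions across scans, reported as mean ± SD,
    mean ± 95% CI half-width, the signed average error, Pearson r and a
    paired t-test.  With ``outdir`` set, tables (CSV) and scatter plots
    (PNG, subsampled to ``scatter_points`` for display only) are written.
    """
    if not scans:
        raise ValidationError("no scans to compare")
    rng = np.random.default_rng(seed)

    curve_fits, voxel_fits, outliers = [], [], []
    all_pred, all_ref = [], []
    voxel_pred, voxel_ref = [], []
    regional_rows: dict[str, dict[str, list]] = {}

    for scan in scans:
        p = scan.predicted_if.value_suv
        r = scan.reference_if.value_suv
        curve_fits.append(deming_fit(r, p))
        all_pred.append(p)
        all_ref.append(r)
        if scan.image is not None:
            ki_pred, _ = patlak_voxelwise(scan.image, scan.predicted_if, t_star_min)
            ki_ref, _ = patlak_voxelwise(scan.image, scan.reference_if, t_star_min)
            ok = np.isfinite(ki_pred) & np.isfinite(ki_ref)
            fit = deming_fit(ki_ref[ok], ki_pred[ok])
            voxel_fits.append(fit)
            voxel_pred.append(ki_pred[ok])
            voxel_ref.append(ki_ref[ok])
            if abs(fit.slope - 1.0) > outlier_band:
                outliers.append(scan.scan_id)
            for name, mask in scan.region_masks.items():
                tac = TimeActivityCurve(
                    scan.image.schedule.midpoint_s,
                    scan.image.voxels[:, np.asarray(mask, dtype=bool)].mean(axis=1),
                )
                ki_p = patlak_fit(tac, scan.predicted_if, t_star_min).Ki
                ki_r = patlak_fit(tac, scan.reference_if, t_star_min).Ki
                row = regional_rows.setdefault(name, {"pred": [], "ref": []})
                row["pred"].append(ki_p)
                row["ref"].append(ki_r)

    pooled_curve = deming_fit(np.concatenate(all_ref), np.concatenate(all_pred))
    pooled_voxel = (
        deming_fit(np.concatenate(voxel_ref), np.concatenate(voxel_pred))
        if voxel_fits
        else None
    )

    reg_records = []
    for name, row in regional_rows.items():
        ref = np.asarray(row["ref"])
        pred = np.asarray(row["pred"])
        n = len(ref)
        if n >= 2:
            t, pval, reject, degen = paired_t(ref, pred)
            r_pear = float(stats.pearsonr(ref, pred)[0]) if np.ptp(ref) > 0 else np.nan
        else:
            t = pval = r_pear = np.nan
            reject = degen = False
        reg_records.append(
            {
                "region": name,
                "n": n,
                "ki_ref_mean": ref.mean(),
                "ki_ref_sd": ref.std(ddof=1) if n > 1 else np.nan,
                "ki_ref_ci95": _ci_halfwidth(ref),
                "ki_pred_mean": pred.mean(),
                "ki_pred_sd": pred.std(ddof=1) if n > 1 else np.nan,
                "ki_pred_ci95": _ci_halfwidth(pred),
                "average_error_pct": average_error(ref, pred),
                "pearson_r": r_pear,
                "t_stat": t,
                "p_value": pval,
                "significant": reject,
                "degenerate_t": degen,
            }
        )
    regional = pd.DataFrame(reg_records)

    report = ComparisonReport(
        curve_fit_pooled=pooled_curve,
        curve_fits=curve_fits,
        voxel_fits=voxel_fits,
        voxel_fit_pooled=pooled_voxel,
        outlier_scans=outliers,
        regional=regional,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_scan = pd.DataFrame(
            {
                "scan_id": [s.scan_id for s in scans],
                "curve_slope": [f.slope for f in curve_fits],
                "curve_r": [f.correlation_r for f in curve_fits],
                "voxel_slope": [f.slope for f in voxel_fits] or np.nan,
                "outlier": [s.scan_id in outliers for s in scans],
            }
        )
        per_scan.to_csv(outdir / "per_scan.csv", index=False)
        regional.to_csv(outdir / "regional.csv", index=False)
        _scatter(
            np.concatenate(all_ref),
            np.concatenate(all_pred),
            pooled_curve,
            outdir / "curves_scatter.png",
            "reference IF [SUV]",
            "predicted IF [SUV]",
            scatter_points,
            rng,
        )
        if pooled_voxel is not None:
            _scatter(
                np.concatenate(voxel_ref),
                np.concatenate(voxel_pred),
                pooled_voxel,
                outdir / "voxel_ki_scatter.png",
                "Ki (reference) [ml/g/min]",
                "Ki (predicted) [ml/g/min]",
                scatter_points,
                rng,
            )
    return report


def _scatter(x, y, fit: DemingFit, path, xlabel, ylabel, n_show, rng):
    idx = rng.choice(len(x), size=min(n_show, len(x)), replace=False)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x[idx], y[idx], s=4, alpha=0.4)
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lims, lims, "k--", lw=0.8, label="identity")
    xs = np.asarray(lims)
    ax.plot(xs, fit.slope * xs + fit.intercept, "r-", lw=1,
            label=f"slope {fit.slope:.2f}, r {fit.correlation_r:.2f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
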
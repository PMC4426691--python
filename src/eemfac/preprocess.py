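"""EEM correction chain.

Order contract (enforced by :func:`preprocess_pipeline`): inner-filter
correction -> Raman-area normalization -> scatter excision -> per-sample
total-signal normalization. All corrections are per-sample; only the blank
Raman area is shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import WavelengthGrid
from .parafac import ParafacModel, leverage, reconstruct
from .synth import EEMDataset, ScatterSpec, raman_emission_center

__all__ = [
    "PreprocessReport",
    "ife_correct",
    "ife_correct_eem",
    "raman_area",
    "raman_normalize",
    "excise_scatter",
    "normalize_total_signal",
    "reverse_normalization",
    "flag_outliers",
    "preprocess_pipeline",
]

RAMAN_EX = 350.0
RAMAN_BAND = (381.0, 426.0)

# Above this summed absorbance the ABA correction is considered unreliable.
IFE_ABS_LIMIT = 3.0


@dataclass
class PreprocessReport:
    """Per-sample audit trail of the correction chain."""

    sample_ids: list[str] = field(default_factory=list)
    raman_area: float | None = None
    norm_factors: np.ndarray | None = None
    ife_flags: list[str] = field(default_factory=list)
    outlier_flags: list[str] = field(default_factory=list)
    leverage: np.ndarray | None = None
    residual_sse: np.ndarray | None = None
    steps: list[str] = field(default_factory=list)


def _interp_covering(
    wl: np.ndarray, values: np.ndarray, targets: np.ndarray, what: str
) -> np.ndarray:
    if targets.min() < wl.min() - 1e-9 or targets.max() > wl.max() + 1e-9:
        raise ValueError(
            f"absorbance grid [{wl.min()}, {wl.max()}] does not cover the "
            f"EEM {what} axis [{targets.min()}, {targets.max()}]"
        )
    return np.interp(targets, wl, values)


def ife_correct_eem(
    eem: np.ndarray,
    grid: WavelengthGrid,
    abs_wavelengths: np.ndarray,
    absorbance: np.ndarray,
) -> tuple[np.ndarray, bool]:
    """Absorbance-based (ABA) inner-filter correction of one EEM.

    corrected(j, k) = raw(j, k) * 10^((A(ex_k) + A(em_j)) / 2). Returns the
    corrected matrix and a flag that is True where any pixel had
    A(ex) + A(em) above the reliability limit.
    """
    a_ex = _interp_covering(abs_wavelengths, absorbance, grid.ex, "excitation")
    a_em = _interp_covering(abs_wavelengths, absorbance, grid.em, "emission")
    total = a_ex[None, :] + a_em[:, None]
    flagged = bool(np.any(total > IFE_ABS_LIMIT))
    return eem * 10.0 ** (total / 2.0), flagged


def ife_correct(
    dataset: EEMDataset, report: PreprocessReport | None = None
) -> EEMDataset:
    """Apply inner-filter correction to every sample that has an absorbance
    spectrum attached. Samples without one raise, since the correction is
    part of the mandated chain."""
    out = dataset.copy()
    for i, meta in enumerate(out.samples):
        if meta.absorbance is None:
            raise ValueError(
                f"sample {meta.sample_id} has no absorbance spectrum for IFE"
            )
        corrected, flagged = ife_correct_eem(
            out.intensities[i], out.grid, meta.absorbance_wavelengths, meta.absorbance
        )
        out.intensities[i] = corrected
        if flagged:
            msg = f"A(ex)+A(em) > {IFE_ABS_LIMIT} for {meta.sample_id}"
            warnings.warn("inner-filter correction unreliable: " + msg, stacklevel=2)
            if report is not None:
                report.ife_flags.append(msg)
    if report is not None:
        report.steps.append("ife_correct")
    return out


def raman_area(
    blank_eem: np.ndarray,
    grid: WavelengthGrid,
    *,
    ex: float = RAMAN_EX,
    band: tuple[float, float] = RAMAN_BAND,
) -> float:
    """Area under the water Raman band of a blank EEM.

    Trapezoidal integral of the Ex = 350 nm emission scan over
    Em in [381, 426] nm, with the band endpoints included by linear
    interpolation when they fall between grid points. Units: intensity * nm.
    """
    k = np.nonzero(np.isclose(grid.ex, ex))[0]
    if k.size == 0:
        raise ValueError(f"excitation {ex} nm absent from grid")
    lo, hi = band
    if grid.em[0] > lo or grid.em[-1] < hi:
        raise ValueError(f"emission band [{lo}, {hi}] only partially covered")
    scan = blank_eem[:, k[0]]
    inside = (grid.em > lo) & (grid.em < hi)
    em_pts = np.concatenate(([lo], grid.em[inside], [hi]))
    vals = np.concatenate(
        (
            [np.interp(lo, grid.em, scan)],
            scan[inside],
            [np.interp(hi, grid.em, scan)],
        )
    )
    return float(np.trapezoid(vals, em_pts))


def raman_normalize(
    dataset: EEMDataset, blank_area: float, report: PreprocessReport | None = None
) -> EEMDataset:
    """Divide every intensity by the blank's Raman area -> Raman Units."""
    if blank_area <= 0:
        raise ValueError("blank Raman area must be > 0")
    out = dataset.copy()
    out.intensities /= blank_area
    if report is not None:
        report.raman_area = float(blank_area)
        report.steps.append("raman_normalize")
    return out


def excise_scatter(
    dataset: EEMDataset,
    spec: ScatterSpec | None = None,
    report: PreprocessReport | None = None,
) -> EEMDataset:
    """Mask physically meaningless and scatter-contaminated pixels.

    Pixels strictly within the half-width of em = ex (first-order Rayleigh),
    em = 2 ex (second-order Rayleigh) or the water-Raman line are marked
    missing; the em < ex triangle is always masked. Intensities are left
    untouched — imputation is the solver's concern.
    """
    spec = spec if spec is not None else ScatterSpec(
        rayleigh1_width=15.0, rayleigh2_width=15.0, raman_width=5.0
    )
    out = dataset.copy()
    em = out.grid.em[:, None]
    ex = out.grid.ex[None, :]
    excised = em < ex
    if spec.rayleigh1_width > 0:
        excised |= np.abs(em - ex) < spec.rayleigh1_width
    if spec.rayleigh2_width > 0:
        excised |= np.abs(em - 2.0 * ex) < spec.rayleigh2_width
    if spec.raman_width > 0:
        excised |= np.abs(em - raman_emission_center(ex)) < spec.raman_width
    out.mask |= excised[None, :, :]
    if report is not None:
        report.steps.append("excise_scatter")
    return out


def normalize_total_signal(
    dataset: EEMDataset, report: PreprocessReport | None = None
) -> tuple[EEMDataset, np.ndarray]:
    """Scale each sample to unit Frobenius norm over its unmasked pixels.

    The stored factor (the norm) multiplies the sample's running
    ``norm_factor`` so the scaling can be reversed on the scores later.
    """
    out = dataset.copy()
    factors = np.empty(out.n_samples)
    for i in range(out.n_samples):
        valid = ~out.mask[i]
        norm = float(np.sqrt(np.sum(out.intensities[i][valid] ** 2)))
        if norm <= 0:
            raise ValueError(
                f"sample {out.samples[i].sample_id} has no positive signal"
            )
        out.intensities[i] /= norm
        out.samples[i].norm_factor *= norm
        factors[i] = norm
    if report is not None:
        report.norm_factors = factors.copy()
        report.sample_ids = [m.sample_id for m in out.samples]
        report.steps.append("normalize_total_signal")
    return out, factors


def reverse_normalization(scores: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Undo total-signal normalization on the score matrix.

    Each sample's scores are multiplied by its stored norm so downstream
    F_max is on the original intensity scale.
    """
    scores = np.asarray(scores, dtype=float)
    factors = np.asarray(factors, dtype=float)
    if factors.ndim != 1 or factors.size != scores.shape[0]:
        raise ValueError("one factor per sample required")
    return scores * factors[:, None]


def flag_outliers(
    dataset: EEMDataset,
    model: ParafacModel,
    *,
    leverage_multiplier: float = 3.0,
    residual_multiplier: float = 3.0,
) -> PreprocessReport:
    """Advisory outlier flags from sample leverage and residual SSE.

    A sample is flagged when its leverage or residual SSE exceeds the given
    multiple of the respective mean. Removal is the caller's decision.
    """
    lev = leverage(model, "sample")
    resid = dataset.intensities - reconstruct(model)
    resid = np.where(dataset.mask, 0.0, resid)
    sse = np.sum(resid * resid, axis=(1, 2))
    lev_thr = leverage_multiplier * lev.mean()
    sse_thr = residual_multiplier * sse.mean() if sse.mean() > 0 else np.inf
    report = PreprocessReport(
        sample_ids=[m.sample_id for m in dataset.samples],
        leverage=lev,
        residual_sse=sse,
    )
    for i, meta in enumerate(dataset.samples):
        reasons = []
        if lev[i] > lev_thr:
            reasons.append(f"leverage {lev[i]:.3f} > {lev_thr:.3f}")
        if sse[i] > sse_thr:
            reasons.append(f"residual SSE {sse[i]:.3g} > {sse_thr:.3g}")
        report.outlier_flags.append("; ".join(reasons))
    report.steps.append("flag_outliers")
    return report


def preprocess_pipeline(
    dataset: EEMDataset,
    blank_eem: np.ndarray | None = None,
    *,
    scatter: ScatterSpec | None = None,
    do_ife: bool = True,
    do_raman: bool = True,
    do_excise: bool = True,
    do_normalize: bool = True,
) -> tuple[EEMDataset, PreprocessReport]:
    """Run the correction chain in the mandated order, recording each step."""
    report = PreprocessReport()
    out = dataset
    if do_ife:
        out = ife_correct(out, report)
    if do_raman:
        if blank_eem is None:
            raise ValueError("Raman normalization requires a blank EEM")
        area = raman_area(blank_eem, dataset.grid)
        out = raman_normalize(out, area, report)
    if do_excise:
        out = excise_scatter(out, scatter, report)
    if do_normalize:
        out, _ = normalize_total_signal(out, report)
    return out, report
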
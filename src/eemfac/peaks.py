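"""Peak-picking sensitivity analysis.

For each component, F_max across samples is regressed against the raw
intensity at every wavelength pair, giving R^2 and slope maps; peak
monitoring is reliable where R^2 stays near 1 around the component's peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import WavelengthGrid
from .parafac import FitConfig, ParafacModel, fit, fmax
from .synth import (
    ConcentrationDesign,
    EEMDataset,
    NoiseModel,
    SpectralLibrary,
    make_cocktail,
    shift_component,
    simulate_dataset,
)

__all__ = [
    "PeakLocation",
    "RegressionMap",
    "peak_location",
    "regression_map",
    "peak_monitor_report",
    "ContaminationConfig",
    "ContaminationResult",
    "contamination_experiment",
]


@dataclass(frozen=True)
class PeakLocation:
    """Primary peak of a component plus secondary excitation maxima
    (local maxima at >= 50 % of the global maximum)."""

    ex: float
    em: float
    secondary_ex: tuple[float, ...] = ()


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima plus maximal endpoints."""
    idx = []
    n = values.size
    for i in range(n):
        left = values[i - 1] if i > 0 else -np.inf
        right = values[i + 1] if i < n - 1 else -np.inf
        if values[i] > left and values[i] > right:
            idx.append(i)
    return np.array(idx, dtype=int)


def peak_location(model: ParafacModel, f: int) -> PeakLocation:
    """Excitation/emission wavelengths of component ``f``'s loading maxima.

    Ties break toward the shorter wavelength. Secondary excitation maxima
    (local maxima reaching half the global peak) are reported too.
    """
    c = model.ex_loadings[:, f]
    b = model.em_loadings[:, f]
    if np.ptp(c) == 0 or np.ptp(b) == 0:
        raise ValueError(f"component {f} has a flat loading")
    k = int(np.argmax(c))
    j = int(np.argmax(b))
    secondary = tuple(
        float(model.ex_wavelengths[i])
        for i in _local_maxima(c)
        if i != k and c[i] >= 0.5 * c[k]
    )
    return PeakLocation(
        ex=float(model.ex_wavelengths[k]),
        em=float(model.em_wavelengths[j]),
        secondary_ex=secondary,
    )


@dataclass
class RegressionMap:
    """Per-pixel OLS of intensity on F_max for one component.

    ``r2`` and ``slope`` are (n_em, n_ex); NaN where the pixel is masked in
    too many samples to regress.
    """

    r2: np.ndarray
    slope: np.ndarray
    grid: WavelengthGrid
    peak: PeakLocation | None = None
    r2_at_peak: float | None = None
    slope_at_peak: float | None = None

    def at(self, ex: float, em: float) -> tuple[float, float]:
        k = int(np.argmin(np.abs(self.grid.ex - ex)))
        j = int(np.argmin(np.abs(self.grid.em - em)))
        return float(self.r2[j, k]), float(self.slope[j, k])


def regression_map(
    dataset: EEMDataset,
    fmax_values: np.ndarray,
    *,
    peak: PeakLocation | None = None,
) -> RegressionMap:
    """R^2 and slope of x_ijk (across samples) on F_max at every pixel.

    OLS with intercept; slope is d(intensity)/d(F_max). Pixels with fewer
    than 3 unmasked samples are NaN.
    """
    y = np.asarray(fmax_values, dtype=float)
    if y.size != dataset.n_samples:
        raise ValueError("F_max vector must align with dataset samples")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance F_max")

    x = dataset.intensities
    valid = ~dataset.mask  # (n, J, K)
    n_valid = valid.sum(axis=0).astype(float)

    yb = y[:, None, None]
    w = valid.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sy = (w * yb).sum(axis=0)
        sx = (w * x).sum(axis=0)
        my = sy / n_valid
        mx = sx / n_valid
        cov = (w * (yb - my) * (x - mx)).sum(axis=0)
        var_y = (w * (yb - my) ** 2).sum(axis=0)
        var_x = (w * (x - mx) ** 2).sum(axis=0)
        slope = cov / var_y
        r2 = cov**2 / (var_y * var_x)
    bad = n_valid < 3
    r2 = np.where(bad | (var_y <= 0), np.nan, r2)
    # A pixel with zero intensity variance carries no signal: R^2 = 0 there.
    r2 = np.where(~bad & (var_x <= 0), 0.0, r2)
    slope = np.where(bad | (var_y <= 0), np.nan, slope)
    out = RegressionMap(r2=r2, slope=slope, grid=dataset.grid, peak=peak)
    if peak is not None:
        out.r2_at_peak, out.slope_at_peak = out.at(peak.ex, peak.em)
    return out


def peak_monitor_report(
    model: ParafacModel,
    dataset: EEMDataset,
    *,
    fmax_values: np.ndarray | None = None,
    r2_threshold: float = 0.9,
    window_nm: float = 25.0,
) -> tuple[pd.DataFrame, list[RegressionMap]]:
    """One row per component: peak position, R^2 and slope at the peak, and
    the fraction of unmasked pixels within +/- ``window_nm`` of the peak
    with R^2 >= ``r2_threshold``."""
    fm = fmax_values if fmax_values is not None else fmax(model)
    rows = []
    maps = []
    for f in range(model.n_components):
        peak = peak_location(model, f)
        rm = regression_map(dataset, fm[:, f], peak=peak)
        in_window = (
            (np.abs(dataset.grid.em[:, None] - peak.em) <= window_nm)
            & (np.abs(dataset.grid.ex[None, :] - peak.ex) <= window_nm)
            & ~np.all(dataset.mask, axis=0)
        )
        window_r2 = rm.r2[in_window]
        window_r2 = window_r2[~np.isnan(window_r2)]
        frac = float((window_r2 >= r2_threshold).mean()) if window_r2.size else np.nan
        rows.append(
            {
                "component": model.component_names[f],
                "peak_ex": peak.ex,
                "peak_em": peak.em,
                "r2_at_peak": rm.r2_at_peak,
                "slope_at_peak": rm.slope_at_peak,
                "high_r2_area_fraction": frac,
            }
        )
        maps.append(rm)
    return pd.DataFrame(rows), maps


@dataclass(frozen=True)
class ContaminationConfig:
    """Design of the clean-vs-cocktail comparison."""

    n_base: int = 76
    n_contaminated: int = 10
    target_component: str | None = None  # default: first in the base subset
    intruder_amplitude: float = 1.0
    noise_sigma: float = 0.002
    seed: int = 0
    fit: FitConfig = field(default_factory=lambda: FitConfig(n_starts=4))


@dataclass
class ContaminationResult:
    clean_report: pd.DataFrame
    cocktail_report: pd.DataFrame
    delta_r2: dict[str, float]
    clean_model: ParafacModel
    cocktail_model: ParafacModel


def contamination_experiment(
    base_library: SpectralLibrary,
    intruder_library: SpectralLibrary | None,
    delta_nm: float,
    n_contaminated: int,
    config: ContaminationConfig | None = None,
    *,
    grid: WavelengthGrid | None = None,
) -> ContaminationResult:
    """Run the peak-monitoring analysis on a clean and a contaminated dataset.

    The intruder is either taken from ``intruder_library`` (its first
    component) or, when that is None, constructed by shifting the target
    base component ``delta_nm`` in emission. Contaminated samples contain
    the base components plus the intruder. Both runs fit the base component
    count, evaluate the regression maps, and report the per-component R^2
    change at the clean model's peaks.
    """
    if delta_nm < 0:
        raise ValueError("delta_nm must be >= 0")
    config = config if config is not None else ContaminationConfig(
        n_contaminated=n_contaminated
    )
    base_names = base_library.names
    n_f = len(base_names)
    design = ConcentrationDesign(n_samples=config.n_base, seed=config.seed)
    noise = NoiseModel(additive_sigma=config.noise_sigma, seed=config.seed + 1)
    base_ds, _ = simulate_dataset(
        base_library, base_names, design, grid=grid, noise=noise, source_label="base"
    )

    fit_cfg = replace(config.fit, seed=config.seed)
    clean_model = fit(base_ds, n_f, fit_cfg)
    clean_report, clean_maps = peak_monitor_report(clean_model, base_ds)

    target = config.target_component or base_names[0]
    if intruder_library is not None:
        intruder = intruder_library.components[0]
    else:
        intruder = shift_component(
            base_library[target], 0.0, delta_nm, grid
        )
    intruder = replace(intruder, name="intruder")
    cocktail_lib = SpectralLibrary(tuple(base_library.components) + (intruder,))
    cocktail_design = ConcentrationDesign(
        n_samples=n_contaminated,
        median=config.intruder_amplitude,
        seed=config.seed + 2,
    )
    cocktail_ds = make_cocktail(
        base_ds,
        cocktail_lib,
        base_names + ["intruder"],
        n_contaminated,
        cocktail_design,
        noise=NoiseModel(additive_sigma=config.noise_sigma, seed=config.seed + 3),
    )
    cocktail_model = fit(cocktail_ds, n_f, fit_cfg)

    # Evaluate the cocktail maps at the CLEAN model's peaks so the delta is
    # measured at the wavelengths an online monitor would actually watch.
    from .compare import match_components

    matches = {
        m.index_a: m.index_b
        for m in match_components(clean_model, cocktail_model)
        if m.index_a is not None and m.index_b is not None
    }
    cocktail_fm = fmax(cocktail_model)
    cocktail_report, _ = peak_monitor_report(cocktail_model, cocktail_ds)
    delta_r2: dict[str, float] = {}
    for f_clean, f_cock in matches.items():
        peak = peak_location(clean_model, f_clean)
        rm_clean = clean_maps[f_clean]
        rm_cock = regression_map(cocktail_ds, cocktail_fm[:, f_cock], peak=peak)
        r2_clean, _ = rm_clean.at(peak.ex, peak.em)
        r2_cock, _ = rm_cock.at(peak.ex, peak.em)
        delta_r2[clean_model.component_names[f_clean]] = r2_clean - r2_cock
    return ContaminationResult(
        clean_report=clean_report,
        cocktail_report=cocktail_report,
        delta_r2=delta_r2,
        clean_model=clean_model,
        cocktail_model=cocktail_model,
    )
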
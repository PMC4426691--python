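"""Synthetic multi-source EEM generation.

Ground-truth datasets are built from a library of fluorophore components,
each described by Gaussian bands in excitation and emission. The generated
tensor is exactly trilinear (scores x emission loading x excitation loading)
plus optional scatter ridges and noise, so every downstream stage can be
tested against a known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import WavelengthGrid, default_grid

__all__ = [
    "GaussianBand",
    "FluorophoreComponent",
    "SpectralLibrary",
    "ConcentrationDesign",
    "NoiseModel",
    "ScatterSpec",
    "SampleMeta",
    "EEMDataset",
    "component_loadings",
    "shift_component",
    "simulate_dataset",
    "make_cocktail",
    "simulate_absorbance",
    "apply_inner_filter",
    "reference_library",
    "raman_emission_center",
    "WATER_RAMAN_SHIFT_CM",
]

# Water O-H stretch Raman shift; maps Ex 350 nm to Em ~397.6 nm.
WATER_RAMAN_SHIFT_CM = 3382.0


def raman_emission_center(ex_nm: float | np.ndarray) -> float | np.ndarray:
    """Emission wavelength (nm) of the water Raman line for a given excitation."""
    return 1.0 / (1.0 / np.asarray(ex_nm, dtype=float) - WATER_RAMAN_SHIFT_CM * 1e-7)


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian band: center (nm), width (Gaussian sigma, nm), relative height."""

    center: float
    width: float
    height: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.height <= 0:
            raise ValueError("band height must be > 0")


def _as_bands(bands) -> tuple[GaussianBand, ...]:
    out = []
    for b in bands:
        out.append(b if isinstance(b, GaussianBand) else GaussianBand(*b))
    return tuple(out)


@dataclass(frozen=True)
class FluorophoreComponent:
    """Generator spec for one fluorophore: Gaussian bands in each mode.

    The loading vector in each mode is the sum of the bands evaluated on the
    grid, rescaled to unit maximum.
    """

    name: str
    ex_bands: tuple[GaussianBand, ...]
    em_bands: tuple[GaussianBand, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ex_bands", _as_bands(self.ex_bands))
        object.__setattr__(self, "em_bands", _as_bands(self.em_bands))
        if not self.ex_bands or not self.em_bands:
            raise ValueError(f"component {self.name!r} needs >= 1 band per mode")


def _band_profile(bands: tuple[GaussianBand, ...], wl: np.ndarray) -> np.ndarray:
    y = np.zeros_like(wl, dtype=float)
    for b in bands:
        y += b.height * np.exp(-0.5 * ((wl - b.center) / b.width) ** 2)
    peak = y.max()
    if peak <= 0:
        raise ValueError("band profile vanished on the grid")
    return y / peak


def component_loadings(
    component: FluorophoreComponent, grid: WavelengthGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a component on a grid.

    Returns
    -------
    (em_loading, ex_loading)
        Non-negative vectors over the emission and excitation axes, each
        scaled to unit maximum.
    """
    em = _band_profile(component.em_bands, grid.em)
    ex = _band_profile(component.ex_bands, grid.ex)
    return em, ex


def shift_component(
    component: FluorophoreComponent,
    delta_ex: float,
    delta_em: float,
    grid: WavelengthGrid | None = None,
) -> FluorophoreComponent:
    """Translate every band center; widths and heights are unchanged.

    Raises ``ValueError`` if a shifted center leaves the grid range (the
    default grid's range when ``grid`` is None).
    """
    g = grid if grid is not None else default_grid()
    new_ex = tuple(replace(b, center=b.center + delta_ex) for b in component.ex_bands)
    new_em = tuple(replace(b, center=b.center + delta_em) for b in component.em_bands)
    for b in new_ex:
        if not (g.ex[0] <= b.center <= g.ex[-1]):
            raise ValueError(
                f"shifted excitation center {b.center} nm leaves grid "
                f"[{g.ex[0]}, {g.ex[-1]}]"
            )
    for b in new_em:
        if not (g.em[0] <= b.center <= g.em[-1]):
            raise ValueError(
                f"shifted emission center {b.center} nm leaves grid "
                f"[{g.em[0]}, {g.em[-1]}]"
            )
    return FluorophoreComponent(component.name, new_ex, new_em)


@dataclass(frozen=True)
class SpectralLibrary:
    """Named set of fluorophore components."""

    components: tuple[FluorophoreComponent, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def __getitem__(self, name: str) -> FluorophoreComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def subset(self, names) -> "SpectralLibrary":
        return SpectralLibrary(tuple(self[n] for n in names))


def reference_library() -> SpectralLibrary:
    """Seven-component library spanning humic-like and protein-like peaks.

    Peak positions follow the common DOM assignments: two humic-like
    components with dual excitation maxima and long emission (G1, G6), a
    humic-like triple-excitation component (G3), tryptophan-like (G2, G4),
    amino-acid-like (G5), and tyrosine-like (G7).
    """
    return SpectralLibrary(
        (
            FluorophoreComponent(
                "G1",
                ex_bands=((230, 14, 0.9), (305, 18, 1.0)),
                em_bands=((414, 28, 1.0),),
            ),
            FluorophoreComponent(
                "G2", ex_bands=((280, 14, 1.0),), em_bands=((332, 22, 1.0),)
            ),
            FluorophoreComponent(
                "G3",
                ex_bands=((245, 11, 0.7), (285, 13, 0.8), (335, 16, 1.0)),
                em_bands=((420, 30, 1.0),),
            ),
            FluorophoreComponent(
                "G4", ex_bands=((225, 12, 1.0),), em_bands=((332, 24, 1.0),)
            ),
            FluorophoreComponent(
                "G5",
                ex_bands=((245, 12, 0.8), (290, 14, 1.0)),
                em_bands=((364, 24, 1.0),),
            ),
            FluorophoreComponent(
                "G6",
                ex_bands=((265, 16, 0.8), (365, 18, 1.0)),
                em_bands=((472, 30, 1.0),),
            ),
            FluorophoreComponent(
                "G7", ex_bands=((265, 12, 1.0),), em_bands=((314, 18, 1.0),)
            ),
        )
    )


@dataclass(frozen=True)
class ConcentrationDesign:
    """Per-sample, per-component concentrations: log-normal by default.

    ``median`` and ``sigma_log`` parametrize the log-normal; the seed fully
    determines the draw.
    """

    n_samples: int
    median: float = 1.0
    sigma_log: float = 0.6
    seed: int = 0
    component_medians: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.median <= 0 or self.sigma_log < 0:
            raise ValueError("median must be > 0 and sigma_log >= 0")
        if self.component_medians is not None:
            object.__setattr__(
                self, "component_medians", tuple(self.component_medians)
            )
            if any(m <= 0 for m in self.component_medians):
                raise ValueError("component medians must be > 0")

    def draw(self, n_components: int) -> np.ndarray:
        if self.component_medians is not None and len(
            self.component_medians
        ) != n_components:
            raise ValueError("one median per component required")
        rng = np.random.default_rng(self.seed)
        medians = (
            np.asarray(self.component_medians)
            if self.component_medians is not None
            else self.median
        )
        return medians * np.exp(
            self.sigma_log * rng.standard_normal((self.n_samples, n_components))
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive + multiplicative Gaussian noise, fully seeded."""

    additive_sigma: float = 0.0
    multiplicative_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sigma < 0 or self.multiplicative_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.additive_sigma == 0 and self.multiplicative_sigma == 0:
            return x
        rng = np.random.default_rng(self.seed)
        out = x.copy()
        if self.multiplicative_sigma > 0:
            out *= 1.0 + self.multiplicative_sigma * rng.standard_normal(x.shape)
        if self.additive_sigma > 0:
            out += self.additive_sigma * rng.standard_normal(x.shape)
        return out


@dataclass(frozen=True)
class ScatterSpec:
    """Scatter ridge parameters: (half-width nm, peak amplitude) per type.

    The Raman ridge's emission center follows the water Raman shift, so the
    ridge passes through Em ~398 nm at Ex 350 nm.
    """

    rayleigh1_width: float = 10.0
    rayleigh1_amplitude: float = 0.0
    rayleigh2_width: float = 10.0
    rayleigh2_amplitude: float = 0.0
    raman_width: float = 4.0
    raman_amplitude: float = 0.0

    def __post_init__(self) -> None:
        for w in (self.rayleigh1_width, self.rayleigh2_width, self.raman_width):
            if w < 0:
                raise ValueError("scatter half-widths must be >= 0")

    def surface(self, grid: WavelengthGrid) -> np.ndarray:
        """Scatter intensity surface (n_em, n_ex) for one sample."""
        em = grid.em[:, None]
        ex = grid.ex[None, :]
        out = np.zeros(grid.shape)
        if self.rayleigh1_amplitude > 0 and self.rayleigh1_width > 0:
            out += self.rayleigh1_amplitude * np.exp(
                -0.5 * ((em - ex) / self.rayleigh1_width) ** 2
            )
        if self.rayleigh2_amplitude > 0 and self.rayleigh2_width > 0:
            out += self.rayleigh2_amplitude * np.exp(
                -0.5 * ((em - 2.0 * ex) / self.rayleigh2_width) ** 2
            )
        if self.raman_amplitude > 0 and self.raman_width > 0:
            center = raman_emission_center(ex)
            out += self.raman_amplitude * np.exp(
                -0.5 * ((em - center) / self.raman_width) ** 2
            )
        return out


@dataclass
class SampleMeta:
    """Per-sample bookkeeping carried through the pipeline."""

    sample_id: str
    source: str = "synthetic"
    norm_factor: float = 1.0
    absorbance_wavelengths: np.ndarray | None = None
    absorbance: np.ndarray | None = None


@dataclass
class EEMDataset:
    """Three-way EEM stack: samples x emission x excitation.

    ``mask`` is True where a pixel is missing/excised; masked pixels keep
    their last intensity value but must be ignored by consumers.
    """

    intensities: np.ndarray
    grid: WavelengthGrid
    mask: np.ndarray = None  # type: ignore[assignment]
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be 3-way (sample, em, ex)")
        if self.intensities.shape[1:] != self.grid.shape:
            raise ValueError(
                f"intensity shape {self.intensities.shape[1:]} does not match "
                f"grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.intensities.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.intensities.shape:
            raise ValueError("mask and intensities must have identical shape")
        if not self.samples:
            self.samples = [
                SampleMeta(sample_id=f"sample_{i:03d}")
                for i in range(self.intensities.shape[0])
            ]
        if len(self.samples) != self.intensities.shape[0]:
            raise ValueError("one SampleMeta per sample required")
        if not np.all(np.isfinite(self.intensities[~self.mask])):
            raise ValueError("non-missing intensities must be finite")
        for m in self.samples:
            if m.norm_factor <= 0:
                raise ValueError("normalization factors must be > 0")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "EEMDataset":
        return EEMDataset(
            intensities=self.intensities.copy(),
            grid=self.grid,
            mask=self.mask.copy(),
            samples=[replace(m) for m in self.samples],
        )


def simulate_absorbance(
    concentrations: np.ndarray,
    wavelengths: np.ndarray | None = None,
    *,
    scale: float = 0.05,
    decay: float = 0.008,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth exponentially decaying UV-Vis absorbance spectra.

    ``concentrations`` is (n_samples, n_components); the spectrum scales
    linearly with total concentration: A(wl) = total * scale * exp(-decay*(wl-200)).

    Returns (wavelengths, absorbance) with absorbance shaped
    (n_samples, n_wavelengths).
    """
    if wavelengths is None:
        wavelengths = np.arange(200.0, 801.0, 1.0)
    total = np.atleast_2d(np.asarray(concentrations, dtype=float)).sum(axis=1)
    shape = scale * np.exp(-decay * (wavelengths - 200.0))
    return wavelengths, total[:, None] * shape[None, :]


def _interp_absorbance(
    wl: np.ndarray, a: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    if targets.min() < wl.min() or targets.max() > wl.max():
        raise ValueError("absorbance spectrum does not cover the EEM grid")
    return np.interp(targets, wl, a)


def apply_inner_filter(dataset: EEMDataset) -> EEMDataset:
    """Attenuate each EEM by its sample's absorbance (forward inner-filter effect).

    Multiplies pixel (em j, ex k) by 10^(-(A(ex_k)+A(em_j))/2) — the exact
    inverse of the absorbance-based correction in :mod:`eemfac.preprocess`.
    """
    out = dataset.copy()
    for i, meta in enumerate(out.samples):
        if meta.absorbance is None:
            continue
        a_ex = _interp_absorbance(
            meta.absorbance_wavelengths, meta.absorbance, out.grid.ex
        )
        a_em = _interp_absorbance(
            meta.absorbance_wavelengths, meta.absorbance, out.grid.em
        )
        factor = 10.0 ** (-(a_ex[None, :] + a_em[:, None]) / 2.0)
        out.intensities[i] *= factor
    return out


def simulate_dataset(
    library: SpectralLibrary,
    subset,
    design: ConcentrationDesign,
    grid: WavelengthGrid | None = None,
    noise: NoiseModel | None = None,
    scatter: ScatterSpec | None = None,
    *,
    source_label: str = "synthetic",
    with_absorbance: bool = False,
    inner_filter: bool = False,
):
    """Generate a trilinear EEM dataset plus its exact ground truth.

    The clean signal is sum_f a_if * b_jf * c_kf with unit-maximum loadings
    (concentration scale lives entirely in the scores), then scatter ridges
    and noise are added. Identical inputs and seeds give bitwise-identical
    output.

    Returns
    -------
    (EEMDataset, ParafacModel)
        The dataset and a model object holding the exact scores/loadings used.
    """
    from .parafac import ParafacModel  # local import to avoid cycle

    subset = list(subset)
    if not subset:
        raise ValueError("component subset must be nonempty")
    grid = grid if grid is not None else default_grid()
    comps = [library[name] for name in subset]
    n_f = len(comps)

    b = np.empty((grid.n_em, n_f))
    c = np.empty((grid.n_ex, n_f))
    for f, comp in enumerate(comps):
        b[:, f], c[:, f] = component_loadings(comp, grid)

    a = design.draw(n_f)
    x = np.einsum("if,jf,kf->ijk", a, b, c)
    if scatter is not None:
        x = x + scatter.surface(grid)[None, :, :]
    if noise is not None:
        x = noise.apply(x)

    samples = [
        SampleMeta(sample_id=f"{source_label}_{i:03d}", source=source_label)
        for i in range(design.n_samples)
    ]
    if with_absorbance:
        wl, absorb = simulate_absorbance(a)
        for i, meta in enumerate(samples):
            meta.absorbance_wavelengths = wl
            meta.absorbance = absorb[i]

    dataset = EEMDataset(intensities=x, grid=grid, samples=samples)
    if inner_filter:
        if not with_absorbance:
            raise ValueError("inner_filter requires with_absorbance=True")
        dataset = apply_inner_filter(dataset)

    truth = ParafacModel(
        scores=a,
        em_loadings=b,
        ex_loadings=c,
        em_wavelengths=grid.em.copy(),
        ex_wavelengths=grid.ex.copy(),
        component_names=list(subset),
        sse=0.0,
        explained_variance=1.0,
        iterations=0,
        converged=True,
        config={"generator": True, "seed": design.seed},
    )
    return dataset, truth


def make_cocktail(
    base: EEMDataset,
    intruder_library: SpectralLibrary,
    intruder_subset,
    n_contaminated: int,
    design: ConcentrationDesign,
    noise: NoiseModel | None = None,
    *,
    intruder_label: str = "intruder",
) -> EEMDataset:
    """Append contaminated samples to a base dataset.

    The appended samples are generated from ``intruder_subset`` of
    ``intruder_library`` (which may mix base and foreign components) on the
    base grid; their source labels are set to ``intruder_label``.
    """
    if n_contaminated < 1:
        raise ValueError("n_contaminated must be >= 1")
    contaminated, _ = simulate_dataset(
        intruder_library,
        intruder_subset,
        replace(design, n_samples=n_contaminated),
        grid=base.grid,
        noise=noise,
        source_label=intruder_label,
    )
    if contaminated.grid != base.grid:
        raise ValueError("grid mismatch between base and contaminated samples")
    return EEMDataset(
        intensities=np.concatenate(
            [base.intensities, contaminated.intensities], axis=0
        ),
        grid=base.grid,
        mask=np.concatenate([base.mask, contaminated.mask], axis=0),
        samples=[replace(m) for m in base.samples] + contaminated.samples,
    )
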
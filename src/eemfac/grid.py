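"""Wavelength grids for excitation-emission matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavelengthGrid", "default_grid", "instrument_grid"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Excitation x emission wavelength axes of an EEM, in nm.

    Both axes must be strictly increasing. An EEM on this grid has shape
    ``(n_em, n_ex)`` (emission rows, excitation columns).
    """

    ex: np.ndarray
    em: np.ndarray

    def __post_init__(self) -> None:
        ex = np.asarray(self.ex, dtype=float)
        em = np.asarray(self.em, dtype=float)
        object.__setattr__(self, "ex", ex)
        object.__setattr__(self, "em", em)
        for name, wl in (("ex", ex), ("em", em)):
            if wl.ndim != 1 or wl.size < 2:
                raise ValueError(f"{name} axis must be 1-D with >= 2 points")
            if not np.all(np.diff(wl) > 0):
                raise ValueError(f"{name} wavelengths must be strictly increasing")
            if np.any(wl <= 0):
                raise ValueError(f"{name} wavelengths must be positive")

    @property
    def n_ex(self) -> int:
        return self.ex.size

    @property
    def n_em(self) -> int:
        return self.em.size

    @property
    def shape(self) -> tuple[int, int]:
        """EEM shape ``(n_em, n_ex)``."""
        return (self.em.size, self.ex.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.ex.shape == other.ex.shape
            and self.em.shape == other.em.shape
            and np.array_equal(self.ex, other.ex)
            and np.array_equal(self.em, other.em)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.ex.tobytes(), self.em.tobytes()))


def default_grid() -> WavelengthGrid:
    """Default synthetic grid: ex 220-450 nm step 5, em 250-550 nm step 2.

    The emission step is twice the instrument step to keep simulations and
    model fits fast; use :func:`instrument_grid` for the full-resolution axes.
    """
    return WavelengthGrid(
        ex=np.arange(220.0, 451.0, 5.0),
        em=np.arange(250.0, 551.0, 2.0),
    )


def instrument_grid() -> WavelengthGrid:
    """Full-resolution grid: ex 220-450 nm step 5, em 250-550 nm step 1."""
    return WavelengthGrid(
        ex=np.arange(220.0, 451.0, 5.0),
        em=np.arange(250.0, 551.0, 1.0),
    )
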
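"""Cross-model component matching via Tucker congruence."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .parafac import ParafacModel

__all__ = [
    "tucker_congruence",
    "classify_similarity",
    "ComponentMatch",
    "match_components",
    "cross_model_fmax_regression",
]


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Congruence coefficient r_c = <x, y> / (||x|| ||y||).

    Scale-invariant cosine of the angle between two loading vectors on the
    same wavelength grid (resampling is the caller's job).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("loading vectors must be 1-D")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("vectors must have length >= 2")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero vector has no direction")
    return float(np.dot(x, y) / (nx * ny))


def classify_similarity(rc: float) -> str:
    """Map r_c to a similarity class.

    < 0.85 -> "dissimilar"; [0.85, 0.95) -> "fair"; >= 0.95 -> "equal".
    The 0.95 boundary is right-closed.
    """
    if not -1.0 - 1e-12 <= rc <= 1.0 + 1e-12:
        raise ValueError(f"r_c out of [-1, 1]: {rc}")
    if rc >= 0.95:
        return "equal"
    if rc >= 0.85:
        return "fair"
    return "dissimilar"


@dataclass(frozen=True)
class ComponentMatch:
    """One pairing of components across two models.

    ``index_b`` is None for unmatched components of the larger model; then
    ``rc_ex``/``rc_em`` hold the component's best unilateral congruence.
    The similarity class is taken on min(rc_ex, rc_em) — both modes must
    agree for two components to be called equal.
    """

    index_a: int | None
    index_b: int | None
    rc_ex: float
    rc_em: float

    @property
    def combined(self) -> float:
        return self.rc_ex * self.rc_em

    @property
    def similarity(self) -> str:
        return classify_similarity(min(self.rc_ex, self.rc_em))


def _congruence_matrix(
    a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Pairwise congruence between columns of two loading matrices."""
    an = a / np.linalg.norm(a, axis=0, keepdims=True)
    bn = b / np.linalg.norm(b, axis=0, keepdims=True)
    return an.T @ bn


def match_components(
    model_a: ParafacModel, model_b: ParafacModel
) -> list[ComponentMatch]:
    """Optimal one-to-one component assignment between two models.

    Maximizes the summed product of excitation and emission congruence via
    the Hungarian algorithm. When component counts differ, the surplus
    components of the larger model are reported unmatched with their best
    unilateral scores. Requires identical wavelength grids.
    """
    if not (
        np.array_equal(model_a.em_wavelengths, model_b.em_wavelengths)
        and np.array_equal(model_a.ex_wavelengths, model_b.ex_wavelengths)
    ):
        raise ValueError("models were fitted on different wavelength grids")
    rc_ex = _congruence_matrix(model_a.ex_loadings, model_b.ex_loadings)
    rc_em = _congruence_matrix(model_a.em_loadings, model_b.em_loadings)
    score = rc_ex * rc_em
    row, col = linear_sum_assignment(-score)
    matches = [
        ComponentMatch(
            index_a=int(r),
            index_b=int(c),
            rc_ex=float(rc_ex[r, c]),
            rc_em=float(rc_em[r, c]),
        )
        for r, c in zip(row, col)
    ]
    matched_a = set(row.tolist())
    matched_b = set(col.tolist())
    for r in range(model_a.n_components):
        if r not in matched_a:
            c = int(np.argmax(score[r]))
            matches.append(
                ComponentMatch(
                    index_a=r,
                    index_b=None,
                    rc_ex=float(rc_ex[r, c]),
                    rc_em=float(rc_em[r, c]),
                )
            )
    for c in range(model_b.n_components):
        if c not in matched_b:
            r = int(np.argmax(score[:, c]))
            matches.append(
                ComponentMatch(
                    index_a=None,
                    index_b=c,
                    rc_ex=float(rc_ex[r, c]),
                    rc_em=float(rc_em[r, c]),
                )
            )
    matches.sort(
        key=lambda m: (
            m.index_a is None or m.index_b is None,
            -1 if m.index_a is None else m.index_a,
        )
    )
    return matches


def cross_model_fmax_regression(
    fmax_a: np.ndarray, fmax_b: np.ndarray
) -> tuple[float, float]:
    """OLS of model-B F_max on model-A F_max (with intercept) for one
    matched component over the same samples.

    Returns (R^2, slope).
    """
    a = np.asarray(fmax_a, dtype=float)
    b = np.asarray(fmax_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("F_max vectors must be 1-D and aligned")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(a) == 0:
        raise ValueError("zero variance in predictor F_max")
    slope, _intercept = np.polyfit(a, b, 1)
    if np.ptp(b) == 0:
        return 0.0, float(slope)
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r), float(slope)
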
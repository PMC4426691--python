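"""Non-negative trilinear (PARAFAC) decomposition with validation.

The model is x_ijk = sum_f a_if b_jf c_kf + e_ijk, fitted by alternating
least squares with column-wise non-negativity and EM-style imputation of
masked pixels. Loadings are reported unit-maximum with all scale absorbed
into the scores, so a component's F_max equals its score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import nnls

from .synth import EEMDataset

__all__ = [
    "FitConfig",
    "ParafacModel",
    "SplitHalfResult",
    "fit",
    "core_consistency",
    "split_half",
    "select_components",
    "fmax",
    "leverage",
    "reconstruct",
]


@dataclass(frozen=True)
class FitConfig:
    """ALS settings: multistart count, iteration/tolerance limits, seed."""

    n_starts: int = 10
    max_iter: int = 2500
    tol: float = 1e-8
    nonneg: bool = True
    missing: str = "em-impute"
    seed: int = 0
    debug_monotone: bool = False

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class ParafacModel:
    """Fitted (or ground-truth) trilinear model.

    scores: (n_samples, F), >= 0, proportional to component concentration.
    em_loadings: (n_em, F); ex_loadings: (n_ex, F) — unit maximum columns.
    """

    scores: np.ndarray
    em_loadings: np.ndarray
    ex_loadings: np.ndarray
    em_wavelengths: np.ndarray
    ex_wavelengths: np.ndarray
    sse: float
    explained_variance: float
    iterations: int
    converged: bool
    component_names: list[str] = field(default_factory=list)
    core_consistency: float | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.em_loadings = np.asarray(self.em_loadings, dtype=float)
        self.ex_loadings = np.asarray(self.ex_loadings, dtype=float)
        f = self.scores.shape[1]
        if self.em_loadings.shape[1] != f or self.ex_loadings.shape[1] != f:
            raise ValueError("factor matrices disagree on component count")
        if not self.component_names:
            self.component_names = [f"C{i + 1}" for i in range(f)]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def reconstruct(model: ParafacModel) -> np.ndarray:
    """Model tensor sum_f a_f (x) b_f (x) c_f, shape (n, J, K)."""
    return np.einsum(
        "if,jf,kf->ijk", model.scores, model.em_loadings, model.ex_loadings
    )


def _khatri_rao(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise expansion: rows indexed (i of u, i of v), columns = factors."""
    n_u, f = u.shape
    n_v = v.shape[0]
    return (u[:, None, :] * v[None, :, :]).reshape(n_u * n_v, f)


def _solve_rows(y: np.ndarray, z: np.ndarray, nonneg: bool) -> np.ndarray:
    """argmin_W ||Y - W Z^T||_F row-wise, optionally with W >= 0.

    Works from the F x F normal equations so the per-row problems stay tiny.
    """
    g = z.T @ z
    g = g + np.eye(g.shape[0]) * (1e-12 * max(np.trace(g), 1.0))
    ct = y @ z  # (rows, F)
    if not nonneg:
        c, low = cho_factor(g)
        return cho_solve((c, low), ct.T).T
    # ||Zw - y||^2 = w'Gw - 2 c'w + const = ||Rw - R^-T c||^2 + const
    r = cholesky(g, lower=False)
    rhs = solve_triangular(r, ct.T, trans="T", lower=False)  # (F, rows)
    out = np.empty_like(ct)
    for i in range(ct.shape[0]):
        out[i], _ = nnls(r, rhs[:, i])
    return out


def _initial_fill(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill masked pixels by per-sample linear interpolation along emission."""
    filled = x.copy()
    n, n_em, n_ex = x.shape
    idx = np.arange(n_em)
    for i in range(n):
        for k in range(n_ex):
            m = mask[i, :, k]
            if not m.any():
                continue
            if m.all():
                filled[i, :, k] = 0.0
                continue
            filled[i, m, k] = np.interp(idx[m], idx[~m], x[i, ~m, k])
    return filled


def _single_start(
    x: np.ndarray,
    mask: np.ndarray,
    n_f: int,
    config: FitConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    n, n_em, n_ex = x.shape
    has_missing = mask.any()
    a = rng.uniform(0.1, 1.1, (n, n_f))
    b = rng.uniform(0.1, 1.1, (n_em, n_f))
    c = rng.uniform(0.1, 1.1, (n_ex, n_f))
    return _als_loop(x, mask, a, b, c, config, rng, has_missing)


def _als_loop(
    x: np.ndarray,
    mask: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator,
    has_missing: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    n, n_em, n_ex = x.shape
    xw = x  # working copy: masked entries overwritten by the model each cycle
    total_ss = float(np.sum(np.where(mask, 0.0, x) ** 2))
    floor = max(total_ss, 1.0) * 1e-16  # machine-precision fit: stop iterating
    prev_sse = np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        a = _solve_rows(xw.reshape(n, -1), _khatri_rao(b, c), config.nonneg)
        _revive_dead_columns(a, rng)
        xb = xw.transpose(1, 0, 2).reshape(n_em, -1)
        b = _solve_rows(xb, _khatri_rao(a, c), config.nonneg)
        _revive_dead_columns(b, rng)
        xc = xw.transpose(2, 0, 1).reshape(n_ex, -1)
        c = _solve_rows(xc, _khatri_rao(a, b), config.nonneg)
        _revive_dead_columns(c, rng)

        model_x = np.einsum("if,jf,kf->ijk", a, b, c)
        resid = x - model_x
        if has_missing:
            resid = np.where(mask, 0.0, resid)
            xw = np.where(mask, model_x, x)
        sse = float(np.sum(resid * resid))
        if config.debug_monotone and sse > prev_sse * (1 + 1e-9) + 1e-12:
            raise AssertionError(
                f"ALS SSE increased at iteration {it}: {prev_sse} -> {sse}"
            )
        if sse < floor:
            converged = True
            prev_sse = sse
            break
        if prev_sse < np.inf:
            denom = max(prev_sse, 1e-300)
            if abs(prev_sse - sse) / denom < config.tol:
                converged = True
                prev_sse = sse
                break
        prev_sse = sse
    return a, b, c, prev_sse, it, converged


def _revive_dead_columns(m: np.ndarray, rng: np.random.Generator) -> None:
    norms = np.linalg.norm(m, axis=0)
    dead = norms < 1e-12
    if dead.any():
        m[:, dead] = rng.uniform(0.1, 1.1, (m.shape[0], int(dead.sum())))


def _finalize(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-maximum loadings, scale into scores, order by variance share."""
    bmax = np.maximum(b.max(axis=0), 1e-300)
    cmax = np.maximum(c.max(axis=0), 1e-300)
    a = a * bmax * cmax
    b = b / bmax
    c = c / cmax
    share = (
        (a**2).sum(axis=0) * (b**2).sum(axis=0) * (c**2).sum(axis=0)
    )
    order = np.argsort(-share, kind="stable")
    return a[:, order], b[:, order], c[:, order]


def _check_degeneracy(model: ParafacModel) -> None:
    from .compare import tucker_congruence

    f = model.n_components
    for p in range(f):
        for q in range(p + 1, f):
            score = tucker_congruence(
                model.ex_loadings[:, p], model.ex_loadings[:, q]
            ) * tucker_congruence(model.em_loadings[:, p], model.em_loadings[:, q])
            if score > 0.98:
                warnings.warn(
                    f"components {p} and {q} have combined congruence "
                    f"{score:.4f} > 0.98 — possible two-factor degeneracy",
                    stacklevel=3,
                )


def fit(
    dataset: EEMDataset,
    n_components: int,
    config: FitConfig | None = None,
    *,
    extra_inits: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
) -> ParafacModel:
    """Fit a trilinear model; best SSE over ``config.n_starts`` random starts.

    ``extra_inits`` allows warm starts (used by :func:`select_components` to
    guarantee nested-model behaviour); they run in addition to the random
    starts.
    """
    config = config if config is not None else FitConfig()
    f = int(n_components)
    if f < 1:
        raise ValueError("n_components must be >= 1")
    n, n_em, n_ex = dataset.intensities.shape
    if f > min(n, n_em, n_ex):
        raise ValueError(
            f"n_components={f} exceeds a mode dimension of {dataset.intensities.shape}"
        )
    if n < f:
        raise ValueError("need at least as many samples as components")
    mask = dataset.mask
    for i in range(n):
        if mask[i].all():
            raise ValueError(f"sample {i} is entirely masked")

    x = dataset.intensities
    if mask.any():
        x = _initial_fill(x, mask)

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_starts + 1)
    best = None
    for s in range(config.n_starts):
        rng = np.random.default_rng(child_seeds[s])
        result = _single_start(x, mask, f, config, rng)
        if best is None or result[3] < best[3]:
            best = result
    if extra_inits:
        rng = np.random.default_rng(child_seeds[-1])
        for a0, b0, c0 in extra_inits:
            result = _als_loop(
                x, mask, a0.copy(), b0.copy(), c0.copy(), config, rng, mask.any()
            )
            if result[3] < best[3]:
                best = result

    a, b, c, sse, iterations, converged = best
    a, b, c = _finalize(a, b, c)
    total_ss = float(np.sum(dataset.intensities[~mask] ** 2))
    model = ParafacModel(
        scores=a,
        em_loadings=b,
        ex_loadings=c,
        em_wavelengths=dataset.grid.em.copy(),
        ex_wavelengths=dataset.grid.ex.copy(),
        sse=sse,
        explained_variance=1.0 - sse / total_ss if total_ss > 0 else 0.0,
        iterations=iterations,
        converged=converged,
        config={
            "n_starts": config.n_starts,
            "max_iter": config.max_iter,
            "tol": config.tol,
            "nonneg": config.nonneg,
            "missing": config.missing,
            "seed": config.seed,
        },
    )
    if f >= 2:
        _check_degeneracy(model)
    return model


def core_consistency(model: ParafacModel, dataset: EEMDataset) -> float:
    """Core consistency diagnostic in percent.

    100 * (1 - ||G - T||^2 / ||T||^2) where G is the least-squares Tucker3
    core for the fitted loadings and T the superidentity; near 100 indicates
    an appropriate component count. Masked pixels are imputed from the model
    before computing the core.
    """
    f = model.n_components
    if f == 1:
        return 100.0
    x = dataset.intensities
    if dataset.mask.any():
        x = np.where(dataset.mask, reconstruct(model), x)
    pa = np.linalg.pinv(model.scores)
    pb = np.linalg.pinv(model.em_loadings)
    pc = np.linalg.pinv(model.ex_loadings)
    core = np.einsum("ai,bj,ck,ijk->abc", pa, pb, pc, x)
    t = np.zeros((f, f, f))
    for q in range(f):
        t[q, q, q] = 1.0
    return float(100.0 * (1.0 - np.sum((core - t) ** 2) / f))


def fmax(model: ParafacModel) -> np.ndarray:
    """Maximum fluorescence per sample and component: a_if * max(b_f) * max(c_f).

    Equals the score matrix under the unit-maximum loading convention.
    """
    return (
        model.scores
        * model.em_loadings.max(axis=0)[None, :]
        * model.ex_loadings.max(axis=0)[None, :]
    )


def leverage(model: ParafacModel, mode: str = "sample") -> np.ndarray:
    """Hat-matrix diagonal of a mode's factor matrix; values in [0, 1]."""
    m = {
        "sample": model.scores,
        "emission": model.em_loadings,
        "excitation": model.ex_loadings,
    }[mode]
    g = m.T @ m
    if np.linalg.matrix_rank(g) < g.shape[0]:
        raise np.linalg.LinAlgError("rank-deficient factor matrix")
    h = np.einsum("if,fg,ig->i", m, np.linalg.inv(g), m)
    return np.clip(h, 0.0, 1.0)


@dataclass
class SplitHalfResult:
    """Outcome of split-half validation at one component count."""

    model_a: ParafacModel
    model_b: ParafacModel
    rc_ex: np.ndarray  # per matched component
    rc_em: np.ndarray
    threshold: float
    passed: bool
    half_indices: tuple[np.ndarray, np.ndarray]

    @property
    def min_rc(self) -> float:
        if self.rc_ex.size == 0:
            return float("nan")
        return float(min(self.rc_ex.min(), self.rc_em.min()))


def split_half(
    dataset: EEMDataset,
    n_components: int,
    config: FitConfig | None = None,
    *,
    threshold: float = 0.95,
    scheme: str = "alternating",
) -> SplitHalfResult:
    """Fit two independent sample halves and compare matched loadings.

    Samples are shuffled with the config seed then assigned alternately;
    components are matched across halves by optimal assignment on the
    product of excitation and emission congruence. Passes when every matched
    component reaches ``threshold`` in both modes.
    """
    from .compare import match_components

    config = config if config is not None else FitConfig()
    n = dataset.n_samples
    if n < 2 * n_components:
        raise ValueError("need at least 2 * n_components samples to split")
    if scheme != "alternating":
        raise ValueError(f"unknown split scheme {scheme!r}")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    idx_a, idx_b = order[0::2], order[1::2]

    def _subset(idx: np.ndarray) -> EEMDataset:
        return EEMDataset(
            intensities=dataset.intensities[idx],
            grid=dataset.grid,
            mask=dataset.mask[idx],
            samples=[replace(dataset.samples[i]) for i in idx],
        )

    model_a = fit(_subset(idx_a), n_components, config)
    model_b = fit(_subset(idx_b), n_components, config)
    matches = [m for m in match_components(model_a, model_b) if m.index_b is not None]
    rc_ex = np.array([m.rc_ex for m in matches])
    rc_em = np.array([m.rc_em for m in matches])
    passed = (
        len(matches) == n_components
        and bool(np.all(rc_ex >= threshold))
        and bool(np.all(rc_em >= threshold))
    )
    return SplitHalfResult(
        model_a=model_a,
        model_b=model_b,
        rc_ex=rc_ex,
        rc_em=rc_em,
        threshold=threshold,
        passed=passed,
        half_indices=(idx_a, idx_b),
    )


def select_components(
    dataset: EEMDataset,
    f_range=range(3, 8),
    config: FitConfig | None = None,
    *,
    split_threshold: float = 0.95,
    cc_floor: float = 50.0,
):
    """Fit a series of component counts and recommend one.

    Returns ``(table, recommended_f, models)`` where ``table`` is a pandas
    DataFrame with one row per F (SSE, explained variance, core consistency,
    split-half outcome). The recommendation is the largest F that passes
    split-half validation with core consistency above ``cc_floor``; if none
    passes, the F with the highest core consistency is returned.

    Each F beyond the smallest also gets a warm start built from the
    previous model plus a small random extra component, which makes
    explained variance non-decreasing in F.
    """
    import pandas as pd

    config = config if config is not None else FitConfig()
    f_values = list(f_range)
    if not f_values:
        raise ValueError("empty component range")
    rows = []
    models: dict[int, ParafacModel] = {}
    prev: ParafacModel | None = None
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    for f in f_values:
        extra = None
        if prev is not None and f == prev.n_components + 1:
            n = dataset.n_samples
            a0 = np.column_stack([prev.scores, rng.uniform(0, 1e-3, n)])
            b0 = np.column_stack(
                [prev.em_loadings, rng.uniform(0, 1e-3, prev.em_loadings.shape[0])]
            )
            c0 = np.column_stack(
                [prev.ex_loadings, rng.uniform(0, 1e-3, prev.ex_loadings.shape[0])]
            )
            extra = [(a0, b0, c0)]
        try:
            model = fit(dataset, f, config, extra_inits=extra)
            cc = core_consistency(model, dataset)
            sh = split_half(dataset, f, config, threshold=split_threshold)
            rows.append(
                {
                    "n_components": f,
                    "sse": model.sse,
                    "explained_variance": model.explained_variance,
                    "core_consistency": cc,
                    "split_half_pass": sh.passed,
                    "split_half_min_rc": sh.min_rc,
                    "error": "",
                }
            )
            model.core_consistency = cc
            models[f] = model
            prev = model
        except (ValueError, np.linalg.LinAlgError) as exc:  # continue other F
            rows.append(
                {
                    "n_components": f,
                    "sse": np.nan,
                    "explained_variance": np.nan,
                    "core_consistency": np.nan,
                    "split_half_pass": False,
                    "split_half_min_rc": np.nan,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    ok = table[
        table["split_half_pass"] & (table["core_consistency"] >= cc_floor)
    ]
    if len(ok):
        recommended = int(ok["n_components"].max())
    else:
        valid = table.dropna(subset=["core_consistency"])
        recommended = (
            int(valid.loc[valid["core_consistency"].idxmax(), "n_components"])
            if len(valid)
            else f_values[0]
        )
    return table, recommended, models
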
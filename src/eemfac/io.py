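"""Plain-text readers/writers for datasets and models, plus the pipeline driver.

Dataset directory layout::

    manifest.csv            sample_id, source, eem_file, absorbance_file, norm_factor
    <sample_id>.csv         first row = excitation wavelengths, first column =
                            emission wavelengths, blank cell = missing pixel
    <sample_id>_abs.csv     two columns: wavelength_nm, absorbance
    truth.json              optional generator ground truth

Model directory layout: model.json, scores.csv, em_loadings.csv, ex_loadings.csv.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import WavelengthGrid, default_grid
from .parafac import FitConfig, ParafacModel, fmax, select_components
from .preprocess import preprocess_pipeline, reverse_normalization
from .synth import (
    ConcentrationDesign,
    EEMDataset,
    NoiseModel,
    SampleMeta,
    ScatterSpec,
    SpectralLibrary,
    reference_library,
    simulate_dataset,
)

__all__ = [
    "read_eem_csv",
    "write_eem_csv",
    "read_dataset",
    "write_dataset",
    "read_absorbance_csv",
    "write_absorbance_csv",
    "read_model",
    "write_model",
    "run_pipeline",
    "load_config",
]

_FLOAT_FMT = "%.17g"


def write_eem_csv(
    path, eem: np.ndarray, grid: WavelengthGrid, mask: np.ndarray | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("," + ",".join(_FLOAT_FMT % w for w in grid.ex) + "\n")
        for j, em in enumerate(grid.em):
            cells = [
                ""
                if mask is not None and mask[j, k]
                else _FLOAT_FMT % eem[j, k]
                for k in range(grid.n_ex)
            ]
            fh.write(_FLOAT_FMT % em + "," + ",".join(cells) + "\n")


def read_eem_csv(path) -> tuple[np.ndarray, WavelengthGrid, np.ndarray]:
    """Read one EEM; returns (matrix, grid, mask) with mask True at blanks."""
    path = Path(path)
    rows = [line.rstrip("\n").split(",") for line in path.open() if line.strip()]
    header, body = rows[0], rows[1:]
    try:
        ex = np.array([float(v) for v in header[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric excitation header: {exc}") from exc
    width = len(header)
    em = np.empty(len(body))
    values = np.zeros((len(body), ex.size))
    mask = np.zeros((len(body), ex.size), dtype=bool)
    for j, row in enumerate(body):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {j + 2}")
        em[j] = float(row[0])
        for k, cell in enumerate(row[1:]):
            if cell == "":
                mask[j, k] = True
            else:
                values[j, k] = float(cell)
    if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
        raise ValueError(f"{path}: wavelength axes must be strictly increasing")
    return values, WavelengthGrid(ex=ex, em=em), mask


def write_absorbance_csv(path, wavelengths: np.ndarray, absorbance: np.ndarray) -> None:
    pd.DataFrame(
        {"wavelength_nm": wavelengths, "absorbance": absorbance}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_absorbance_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    return df["wavelength_nm"].to_numpy(float), df["absorbance"].to_numpy(float)


def write_dataset(directory, dataset: EEMDataset, truth: ParafacModel | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, meta in enumerate(dataset.samples):
        eem_file = f"{meta.sample_id}.csv"
        write_eem_csv(
            directory / eem_file, dataset.intensities[i], dataset.grid, dataset.mask[i]
        )
        abs_file = ""
        if meta.absorbance is not None:
            abs_file = f"{meta.sample_id}_abs.csv"
            write_absorbance_csv(
                directory / abs_file, meta.absorbance_wavelengths, meta.absorbance
            )
        records.append(
            {
                "sample_id": meta.sample_id,
                "source": meta.source,
                "eem_file": eem_file,
                "absorbance_file": abs_file,
                "norm_factor": meta.norm_factor,
            }
        )
    pd.DataFrame(records).to_csv(
        directory / "manifest.csv", index=False, float_format=_FLOAT_FMT
    )
    if truth is not None:
        (directory / "truth.json").write_text(
            json.dumps(
                {
                    "component_names": truth.component_names,
                    "scores": truth.scores.tolist(),
                    "em_loadings": truth.em_loadings.tolist(),
                    "ex_loadings": truth.ex_loadings.tolist(),
                },
                indent=1,
            )
        )


def read_dataset(directory) -> EEMDataset:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv", keep_default_na=False)
    grid = None
    stack, masks, metas = [], [], []
    for rec in manifest.to_dict("records"):
        eem_path = directory / rec["eem_file"]
        if not eem_path.exists():
            raise FileNotFoundError(f"manifest references missing file {eem_path}")
        eem, g, mask = read_eem_csv(eem_path)
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"grid mismatch in {rec['eem_file']}")
        stack.append(eem)
        masks.append(mask)
        meta = SampleMeta(
            sample_id=str(rec["sample_id"]),
            source=str(rec["source"]),
            norm_factor=float(rec.get("norm_factor", 1.0) or 1.0),
        )
        if rec.get("absorbance_file"):
            wl, a = read_absorbance_csv(directory / rec["absorbance_file"])
            meta.absorbance_wavelengths = wl
            meta.absorbance = a
        metas.append(meta)
    return EEMDataset(
        intensities=np.stack(stack), grid=grid, mask=np.stack(masks), samples=metas
    )


def write_model(directory, model: ParafacModel) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_components": model.n_components,
        "component_names": model.component_names,
        "sse": model.sse,
        "explained_variance": model.explained_variance,
        "core_consistency": model.core_consistency,
        "iterations": model.iterations,
        "converged": model.converged,
        "config": model.config,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=1))
    names = model.component_names
    pd.DataFrame(model.scores, columns=names).to_csv(
        directory / "scores.csv", index_label="sample", float_format=_FLOAT_FMT
    )
    pd.DataFrame(
        model.em_loadings, columns=names, index=model.em_wavelengths
    ).to_csv(directory / "em_loadings.csv", index_label="em_nm", float_format=_FLOAT_FMT)
    pd.DataFrame(
        model.ex_loadings, columns=names, index=model.ex_wavelengths
    ).to_csv(directory / "ex_loadings.csv", index_label="ex_nm", float_format=_FLOAT_FMT)


def read_model(directory) -> ParafacModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    kw = {"index_col": 0, "float_precision": "round_trip"}
    scores = pd.read_csv(directory / "scores.csv", **kw)
    em = pd.read_csv(directory / "em_loadings.csv", **kw)
    ex = pd.read_csv(directory / "ex_loadings.csv", **kw)
    return ParafacModel(
        scores=scores.to_numpy(float),
        em_loadings=em.to_numpy(float),
        ex_loadings=ex.to_numpy(float),
        em_wavelengths=em.index.to_numpy(float),
        ex_wavelengths=ex.index.to_numpy(float),
        sse=meta["sse"],
        explained_variance=meta["explained_variance"],
        core_consistency=meta.get("core_consistency"),
        iterations=meta["iterations"],
        converged=meta["converged"],
        component_names=meta["component_names"],
        config=meta.get("config", {}),
    )


def load_config(path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _log(log_lines: list[str], stage: str, message: str) -> None:
    line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{stage}\t{message}"
    log_lines.append(line)


def run_pipeline(config: dict, out_dir) -> dict:
    """simulate/load -> preprocess -> select & fit -> report, all seeded.

    ``config`` keys (all optional unless noted): ``seed``; ``simulate``
    (n_samples, components, noise_sigma, scatter) or ``input_dir``;
    ``preprocess`` (blank handling, switches); ``fit`` (f_min, f_max,
    n_starts, max_iter, tol). Writes the dataset, model directory, summary
    JSON and a line-oriented log under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log_lines: list[str] = []
    _log(log_lines, "start", f"config_hash={_config_hash(config)} seed={seed}")

    sim_cfg = config.get("simulate")
    if sim_cfg is not None:
        library = reference_library()
        names = sim_cfg.get("components", ["G2", "G6", "G7"])
        design = ConcentrationDesign(
            n_samples=int(sim_cfg.get("n_samples", 30)), seed=seed
        )
        noise = NoiseModel(
            additive_sigma=float(sim_cfg.get("noise_sigma", 0.0)), seed=seed + 1
        )
        dataset, truth = simulate_dataset(
            library, names, design, noise=noise, with_absorbance=True,
            inner_filter=bool(sim_cfg.get("inner_filter", False)),
        )
        write_dataset(out_dir / "dataset", dataset, truth)
        _log(log_lines, "simulate", f"n={dataset.n_samples} components={names}")
    elif config.get("input_dir"):
        dataset = read_dataset(config["input_dir"])
        _log(log_lines, "load", f"n={dataset.n_samples} from {config['input_dir']}")
    else:
        raise ValueError("config needs either 'simulate' or 'input_dir'")

    pp_cfg = config.get("preprocess", {})
    blank = None
    if pp_cfg.get("blank_file"):
        blank, bgrid, _ = read_eem_csv(pp_cfg["blank_file"])
        if bgrid != dataset.grid:
            raise ValueError("preprocess: blank grid does not match dataset grid")
    elif pp_cfg.get("do_raman", False):
        raise ValueError("preprocess: Raman normalization enabled but no blank_file")
    processed, report = preprocess_pipeline(
        dataset,
        blank,
        do_ife=bool(pp_cfg.get("do_ife", sim_cfg is not None)),
        do_raman=blank is not None,
        do_excise=bool(pp_cfg.get("do_excise", False)),
        do_normalize=bool(pp_cfg.get("do_normalize", True)),
    )
    _log(log_lines, "preprocess", "steps=" + ">".join(report.steps))

    fit_cfg_in = config.get("fit", {})
    fit_config = FitConfig(
        n_starts=int(fit_cfg_in.get("n_starts", 5)),
        max_iter=int(fit_cfg_in.get("max_iter", 1000)),
        tol=float(fit_cfg_in.get("tol", 1e-8)),
        seed=seed,
    )
    f_min = int(fit_cfg_in.get("f_min", 3))
    f_max = int(fit_cfg_in.get("f_max", 7))
    table, recommended, models = select_components(
        processed, range(f_min, f_max + 1), fit_config
    )
    table.to_csv(out_dir / "selection.csv", index=False, float_format=_FLOAT_FMT)
    model = models[recommended]
    _log(log_lines, "fit", f"recommended_f={recommended} sse={model.sse:.6g}")

    if report.norm_factors is not None:
        model.scores = reverse_normalization(model.scores, report.norm_factors)
    write_model(out_dir / "model", model)

    summary = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "n_samples": int(dataset.n_samples),
        "recommended_f": int(recommended),
        "explained_variance": float(model.explained_variance),
        "core_consistency": model.core_consistency,
        "split_half_pass": bool(
            table.loc[table["n_components"] == recommended, "split_half_pass"].iloc[0]
        ),
        "fmax_mean": fmax(model).mean(axis=0).tolist(),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary
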
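"""CSV readers/writers, config handling, and the recovery benchmark.

Datasets travel as wide CSV: first column ``time_h``, remaining column
headers the wavenumbers in cm^-1.  Fit results are written as C.csv /
S.csv / k_history.csv plus a JSON run report carrying the configuration
hash and seed needed for a bit-exact re-run.  Values are printed with 12
significant digits, locale independent.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd

from ._exceptions import FormatError
from .core import ConstraintConfig, KineticLink, MCRResult, run_mcr_als
from .kinetics import KineticModel, get_model, model_from_expressions
from .preprocessing import NormalizationSpec, SpectraDataset, normalize_dataset
from .synthetic import SimulationConfig, simulate_dataset

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "write_results",
    "write_simulation",
    "load_config",
    "constraint_config_from_dict",
    "normalization_spec_from_dict",
    "kinetic_model_from_config",
    "config_hash",
    "recover_benchmark",
    "summarize_recovery",
]

_FLOAT_FMT = "%.12g"


def read_spectra_csv(path: str | Path) -> SpectraDataset:
    """Read a wide-format dataset CSV (time_h column + wavenumber headers).

    Wavenumber columns are sorted ascending if needed (with a warning).
    Malformed input raises :class:`FormatError` naming the offending column
    or row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise FormatError(f"{path}: ragged or malformed CSV ({e})") from e
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need a time column plus >= 2 wavenumber columns")
    wn = []
    for col in df.columns[1:]:
        try:
            wn.append(float(col))
        except ValueError:
            raise FormatError(
                f"{path}: column header {col!r} does not parse as a wavenumber"
            ) from None
    wn = np.array(wn)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    times = df.iloc[:, 0].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(values).all(axis=1))[0]
    if bad.size:
        raise FormatError(f"{path}: non-finite or missing values in row {bad[0]}")
    order = np.argsort(wn)
    if not np.array_equal(order, np.arange(wn.size)):
        warnings.warn(f"{path}: wavenumber columns were not sorted; reordering")
        wn = wn[order]
        values = values[:, order]
    return SpectraDataset(values, times, wn, meta={"source": str(path)})


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_spectra_csv(ds: SpectraDataset, path: str | Path) -> Path:
    """Write a dataset as wide CSV (inverse of :func:`read_spectra_csv`)."""
    path = Path(path)
    df = pd.DataFrame(ds.intensities, columns=[_fmt(w) for w in ds.wavenumbers])
    df.insert(0, "time_h", ds.times)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_simulation(sim, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset with its ground truth and config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"data": write_spectra_csv(sim.dataset, outdir / "data.csv")}
    comp_names = ["binding", "response", "cell"]
    c = pd.DataFrame(sim.C_true, columns=comp_names)
    c.insert(0, "time_h", sim.dataset.times)
    c.to_csv(outdir / "C_true.csv", index=False, float_format=_FLOAT_FMT)
    s = pd.DataFrame(sim.S_true.T, columns=comp_names)
    s.insert(0, "wavenumber", sim.dataset.wavenumbers)
    s.to_csv(outdir / "S_true.csv", index=False, float_format=_FLOAT_FMT)
    sidecar = {"simulation": sim.config.to_dict()}
    sidecar["config_hash"] = config_hash(sidecar["simulation"])
    (outdir / "config.json").write_text(json.dumps(sidecar, indent=2))
    paths.update(
        C_true=outdir / "C_true.csv",
        S_true=outdir / "S_true.csv",
        config=outdir / "config.json",
    )
    return paths


def write_results(
    result: MCRResult,
    outdir: str | Path,
    times: np.ndarray,
    wavenumbers: np.ndarray,
    config: Mapping[str, Any] | None = None,
) -> dict[str, Path]:
    """Write C.csv, S.csv, k_history.csv and report.json for one fit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ncomp = result.C.shape[1]
    comp_cols = [f"component_{i + 1}" for i in range(ncomp)]
    c = pd.DataFrame(result.C, columns=comp_cols)
    c.insert(0, "time_h", times)
    c.to_csv(outdir / "C.csv", index=False, float_format=_FLOAT_FMT)
    s = pd.DataFrame(result.S.T, columns=comp_cols)
    s.insert(0, "wavenumber", wavenumbers)
    s.to_csv(outdir / "S.csv", index=False, float_format=_FLOAT_FMT)
    kh = pd.DataFrame(result.k_history, columns=list(result.k_param_names))
    kh.insert(0, "iteration", np.arange(1, len(kh) + 1))
    kh["ssr"] = result.lof_history[: len(kh)]
    kh["pct_lof"] = result.pct_lof_history[: len(kh)]
    kh.to_csv(outdir / "k_history.csv", index=False, float_format=_FLOAT_FMT)
    report = {
        "stop_reason": result.stop_reason,
        "converged": result.converged,
        "n_iter": result.n_iter,
        "final_ssr": float(result.lof_history[-1]),
        "final_pct_lof": float(result.pct_lof_history[-1]),
        "k_final": result.k_final,
        "n_components": ncomp,
    }
    if config is not None:
        report["config"] = dict(config)
        report["config_hash"] = config_hash(report["config"])
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return {
        "C": outdir / "C.csv",
        "S": outdir / "S.csv",
        "k_history": outdir / "k_history.csv",
        "report": outdir / "report.json",
    }


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file (identical schema)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)


def kinetic_model_from_config(spec: str | Mapping[str, Any]) -> KineticModel:
    """Resolve a kinetic model from a config entry.

    Either the name of a registered model (``"uptake"``,
    ``"uptake_response"``) or a mapping declaring a custom system::

        {name, states, params, rates, initial_state?, components?, fixed?}

    with ``rates`` a list of d(state)/dt expressions parsed symbolically.
    """
    if isinstance(spec, str):
        return get_model(spec)
    return model_from_expressions(
        name=spec.get("name", "custom"),
        state_names=spec["states"],
        param_names=spec["params"],
        rate_expressions=spec["rates"],
        initial_state=spec.get("initial_state"),
        component_map=spec.get("components"),
        fixed_params=spec.get("fixed", ("D",)),
    )


def normalization_spec_from_dict(d: Mapping[str, Any] | None) -> NormalizationSpec:
    if not d:
        return NormalizationSpec()
    kwargs = {}
    if "band" in d:
        kwargs["band_lo"], kwargs["band_hi"] = (float(v) for v in d["band"])
    if "baseline" in d:
        lo, hi = d["baseline"]
        kwargs["base_lo_window"] = tuple(float(v) for v in lo)
        kwargs["base_hi_window"] = tuple(float(v) for v in hi)
    return NormalizationSpec(**kwargs)


def constraint_config_from_dict(d: Mapping[str, Any]) -> ConstraintConfig:
    """Build a :class:`ConstraintConfig` from the config-file schema."""
    kin = None
    if d.get("kinetic"):
        kd = d["kinetic"]
        model = kinetic_model_from_config(kd["model"])
        kin = KineticLink(
            model=model,
            k0={str(k): float(v) for k, v in kd["k0"].items()},
            component_indices=tuple(kd.get("components", ())),
        )
    conv = d.get("convergence", {})
    return ConstraintConfig(
        n_components=int(d["n_components"]),
        nonneg_conc=d.get("nonneg_conc", True),
        nonneg_spec=d.get("nonneg_spec", True),
        kinetic=kin,
        max_iter=int(conv.get("max_iter", 200)),
        patience=int(conv.get("patience", 20)),
        rel_tol=float(conv.get("rel_tol", 0.01)),
    )


def _sub_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def recover_benchmark(
    sim_config: SimulationConfig,
    fit_config: ConstraintConfig,
    n_replicates: int,
    seed: int,
    normalize: bool = True,
    progress: Callable[[int, dict], None] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte-Carlo rate-constant recovery on freshly simulated datasets.

    Each replicate simulates a dataset under ``sim_config`` with a sub-seed
    derived from the master ``seed``, fits it with ``fit_config`` and records
    the true and estimated kinetic constants, relative errors, iteration
    count and final %LOF.  Returns (per-replicate table, summary table with
    the median relative error per parameter).  Deterministic given the
    master seed; a replicate whose fit raises is recorded with NaNs, not
    fatal.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if fit_config.kinetic is None:
        raise ValueError("recovery benchmark needs a kinetic link in fit_config")
    free = fit_config.kinetic.model.free_param_names
    truth = sim_config.params.as_dict()
    rows = []
    for rep, sub in enumerate(_sub_seeds(seed, n_replicates)):
        cfg = SimulationConfig.from_dict({**sim_config.to_dict(), "seed": sub})
        sim = simulate_dataset(config=cfg)
        row: dict[str, Any] = {"replicate": rep, "seed": sub}
        try:
            ds = normalize_dataset(sim.dataset) if normalize else sim.dataset
            res = run_mcr_als(ds, fit_config)
            for p in free:
                row[f"{p}_true"] = truth.get(p, np.nan)
                row[f"{p}_est"] = res.k_final[p]
                t = truth.get(p, np.nan)
                row[f"{p}_rel_err"] = (
                    abs(res.k_final[p] - t) / t if t else np.nan
                )
            row["n_iter"] = res.n_iter
            row["final_pct_lof"] = float(res.pct_lof_history[-1])
            row["failed"] = False
        except Exception as e:  # noqa: BLE001 - record, continue
            warnings.warn(f"replicate {rep} failed: {e}")
            for p in free:
                row[f"{p}_true"] = truth.get(p, np.nan)
                row[f"{p}_est"] = np.nan
                row[f"{p}_rel_err"] = np.nan
            row["n_iter"] = 0
            row["final_pct_lof"] = np.nan
            row["failed"] = True
        rows.append(row)
        if progress is not None:
            progress(rep, row)
    table = pd.DataFrame(rows)
    return table, summarize_recovery(table, free)


def summarize_recovery(table: pd.DataFrame, param_names) -> pd.DataFrame:
    """Median relative recovery error per kinetic parameter."""
    recs = []
    for p in param_names:
        col = table[f"{p}_rel_err"]
        recs.append(
            {
                "parameter": p,
                "median_rel_err": float(col.median()),
                "max_rel_err": float(col.max()),
                "n_ok": int((~col.isna()).sum()),
            }
        )
    return pd.DataFrame(recs)
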
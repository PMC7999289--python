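"""Readers and writers: HDF5 datasets, delimited-text bundles, fit results, manifests.

The HDF5 layout stores one dataset per matrix (/M, /E, /X_M, /X_E, /H_M,
/H_E, /coords) with dimension attributes; trial-level files use /meg_trials
and /eeg_trials instead of /M and /E and are auto-detected on load.  The
text bundle (one CSV per matrix plus a JSON manifest) uses 17-significant-
digit decimal formatting, which round-trips IEEE doubles exactly.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np

from .bootstrap import TrialData
from .model import FitResult, InputError, MixtureState, SensorDataset, SourceField

_DATASET_FIELDS = ("M", "E", "X_M", "X_E", "H_M", "H_E", "coords")
_TRIAL_FIELDS = ("meg_trials", "eeg_trials", "X_M", "X_E", "H_M", "H_E", "coords")
_FMT = "%.17g"  # lossless for float64


def write_dataset(path: Union[str, Path], data: Union[SensorDataset, TrialData]) -> None:
    """Write an averaged or trial-level dataset to one HDF5 file."""
    path = Path(path)
    fields = _DATASET_FIELDS if isinstance(data, SensorDataset) else _TRIAL_FIELDS
    with h5py.File(path, "w") as f:
        for name in fields:
            arr = getattr(data, name)
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr, dtype=np.float64))
        if isinstance(data, SensorDataset):
            f.attrs.update({"n_M": data.n_M, "n_E": data.n_E, "P": data.P, "T": data.T})


def read_dataset(path: Union[str, Path]) -> Union[SensorDataset, TrialData]:
    """Load a dataset, auto-detecting averaged vs trial-level layout and text vs HDF5."""
    path = Path(path)
    if path.is_dir():
        return _read_text_bundle(path)
    with h5py.File(path, "r") as f:
        trial_level = "meg_trials" in f
        fields = _TRIAL_FIELDS if trial_level else _DATASET_FIELDS
        kwargs = {}
        for name in fields:
            if name in f:
                kwargs[name] = f[name][()]
            elif name in ("H_M", "H_E", "coords"):
                kwargs[name] = None
            else:
                raise InputError(f"dataset file {path} is missing required matrix '{name}'")
    cls = TrialData if trial_level else SensorDataset
    try:
        return cls(**kwargs)
    except InputError as exc:
        raise InputError(f"invalid dataset in {path}: {exc}") from exc


def write_dataset_text(directory: Union[str, Path], data: SensorDataset) -> None:
    """Write an averaged dataset as a bundle of CSV matrices plus manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    present = []
    for name in _DATASET_FIELDS:
        arr = getattr(data, name)
        if arr is not None:
            np.savetxt(directory / f"{name}.csv", np.asarray(arr), fmt=_FMT, delimiter=",")
            present.append(name)
    manifest = {
        "format": "acsicm-dataset-text-v1",
        "fields": present,
        "n_M": data.n_M,
        "n_E": data.n_E,
        "P": data.P,
        "T": data.T,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _read_text_bundle(directory: Path) -> SensorDataset:
    manifest = json.loads((directory / "manifest.json").read_text())
    kwargs = {}
    for name in _DATASET_FIELDS:
        if name in manifest["fields"]:
            kwargs[name] = np.loadtxt(directory / f"{name}.csv", delimiter=",", ndmin=2)
        else:
            kwargs[name] = None
    try:
        return SensorDataset(**kwargs)
    except InputError as exc:
        raise InputError(f"invalid dataset bundle in {directory}: {exc}") from exc


def write_fit(path: Union[str, Path], fit: FitResult, settings: dict | None = None) -> None:
    """Serialize a fit to HDF5 (arrays) plus a JSON sidecar (trace, metadata)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("S", data=fit.sources.S)
        f.create_dataset("Z", data=fit.state.Z)
        f.create_dataset("mu", data=fit.state.mu)
        f.create_dataset("alpha", data=fit.state.alpha)
        f.create_dataset("A", data=fit.state.A)
        f.attrs.update(
            {
                "sigma2_a": fit.state.sigma2_a,
                "sigma2_E": fit.state.sigma2_E,
                "sigma2_M": fit.state.sigma2_M,
                "k_hat": fit.k_hat,
                "converged": fit.converged,
                "iterations": fit.iterations,
            }
        )
    meta = {
        "objective_trace": [float(x) for x in fit.objective_trace],
        "k_hat": fit.k_hat,
        "converged": bool(fit.converged),
        "iterations": fit.iterations,
        "seed": fit.seed,
        "settings": settings or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_fit(path: Union[str, Path]) -> FitResult:
    path = Path(path)
    with h5py.File(path, "r") as f:
        state = MixtureState(
            Z=f["Z"][()],
            mu=f["mu"][()],
            alpha=f["alpha"][()],
            A=f["A"][()],
            sigma2_a=float(f.attrs["sigma2_a"]),
            sigma2_E=float(f.attrs["sigma2_E"]),
            sigma2_M=float(f.attrs["sigma2_M"]),
        )
        sources = SourceField(f["S"][()])
        attrs = dict(f.attrs)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FitResult(
        state=state,
        sources=sources,
        objective_trace=meta.get("objective_trace", []),
        k_hat=int(attrs["k_hat"]),
        converged=bool(attrs["converged"]),
        iterations=int(attrs["iterations"]),
        seed=meta.get("seed"),
    )


def write_manifest(path: Union[str, Path], config: dict) -> None:
    """Record everything needed to re-run a command bit-for-bit."""
    from . import __version__

    payload = {"acsicm_version": __version__, **config}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return {k: v for k, v in dataclasses.asdict(obj).items() if not isinstance(v, np.ndarray)}
    raise TypeError(f"cannot serialize {type(obj)}")
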
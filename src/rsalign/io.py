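"""Lossless round-trip I/O for the pipeline's core objects.

Numeric arrays (epochs, response matrices) go to chunked zarr stores with
named dimensions via xarray; tables (probe plans, mapping tables, results)
to delimited text; ground truth and metadata to JSON sidecars. Every file
carries a format version tag and, where applicable, the generator seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .types import (
    BandSpec,
    EpochSet,
    ProbeMapping,
    ProbePlan,
    RDM,
    ResponseMatrix,
    ROISpec,
    SyntheticTruth,
)

FORMAT_VERSION = "1"


class SchemaError(ValueError):
    """A file does not conform to the documented layout."""


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _roi_to_dict(roi: ROISpec | None) -> dict | None:
    if roi is None:
        return None
    return {
        "band": {"name": roi.band.name, "f_lo": roi.band.f_lo,
                 "f_hi": roi.band.f_hi, "cycles": roi.band.cycles},
        "window": list(roi.window),
        "baseline": list(roi.baseline),
    }


def _roi_from_dict(d: dict | None) -> ROISpec | None:
    if d is None:
        return None
    return ROISpec(
        band=BandSpec(**d["band"]),
        window=tuple(d["window"]),
        baseline=tuple(d["baseline"]),
    )


def save_epochs(epochs: EpochSet, path: str | Path, seed: int | None = None) -> None:
    ds = xr.Dataset(
        {
            "data": (("probe", "stimulus", "time"), epochs.data),
            "valid": (("probe", "stimulus"), epochs.valid_mask),
        },
        coords={
            "probe": list(epochs.probe_ids),
            "stimulus": list(epochs.stimulus_ids),
            "time": epochs.times,
        },
        attrs={
            "fs": epochs.fs,
            "t_start": epochs.t_start,
            "format_version": FORMAT_VERSION,
            "seed": -1 if seed is None else int(seed),
        },
    )
    ds.to_zarr(str(path), mode="w")


def load_epochs(path: str | Path) -> EpochSet:
    ds = xr.open_zarr(str(path))
    for field in ("fs", "t_start"):
        if field not in ds.attrs:
            raise SchemaError(f"epoch container missing attribute: {field}")
    return EpochSet(
        data=ds["data"].values,
        fs=float(ds.attrs["fs"]),
        t_start=float(ds.attrs["t_start"]),
        probe_ids=[str(p) for p in ds["probe"].values],
        stimulus_ids=[str(s) for s in ds["stimulus"].values],
        valid_mask=ds["valid"].values,
    )


def save_response_matrix(rm: ResponseMatrix, path: str | Path,
                         seed: int | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(rm.values, index=list(rm.probe_ids),
                      columns=list(rm.stimulus_ids))
    df.index.name = "probe_id"
    df.to_csv(path)
    meta = {
        "format_version": FORMAT_VERSION,
        "roi": _roi_to_dict(rm.roi),
        "seed": seed,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=2))


def load_response_matrix(path: str | Path) -> ResponseMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col="probe_id")
    roi = None
    mp = _meta_path(path)
    if mp.exists():
        roi = _roi_from_dict(json.loads(mp.read_text()).get("roi"))
    return ResponseMatrix(
        values=df.to_numpy(dtype=float),
        probe_ids=[str(i) for i in df.index],
        stimulus_ids=[str(c) for c in df.columns],
        roi=roi,
    )


def save_rdm(rdm: RDM, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(rdm.matrix).to_csv(path, index=False)
    _meta_path(path).write_text(json.dumps(
        {"format_version": FORMAT_VERSION, "metric": rdm.metric,
         "source": rdm.source}, indent=2))


def load_rdm(path: str | Path) -> RDM:
    path = Path(path)
    m = pd.read_csv(path).to_numpy(dtype=float)
    metric, source = "euclidean", ""
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
        metric = meta.get("metric", metric)
        source = meta.get("source", source)
    m = 0.5 * (m + m.T)  # absorb decimal round-trip asymmetry
    return RDM(matrix=m, metric=metric, source=source)


def save_probe_plan(plan: ProbePlan, path: str | Path) -> None:
    path = Path(path)
    plan.table.to_csv(path, index=False)
    _meta_path(path).write_text(json.dumps(
        {"format_version": FORMAT_VERSION, "area_order": list(plan.area_order)},
        indent=2))


def load_probe_plan(path: str | Path) -> ProbePlan:
    path = Path(path)
    table = pd.read_csv(path, dtype={"area": str, "probe_id": str, "shaft_id": str})
    missing = set(ProbePlan.REQUIRED) - set(table.columns)
    if missing:
        raise SchemaError(f"probe plan missing columns: {sorted(missing)}")
    area_order = None
    mp = _meta_path(path)
    if mp.exists():
        area_order = json.loads(mp.read_text()).get("area_order")
    kwargs = {} if area_order is None else {"area_order": area_order}
    return ProbePlan(table=table, **kwargs)


def save_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def load_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())


def save_mapping(mapping: ProbeMapping, path: str | Path) -> None:
    path = Path(path)
    mapping.table.to_csv(path, index=False)
    _meta_path(path).write_text(json.dumps(
        {
            "format_version": FORMAT_VERSION,
            "layer_names": list(mapping.layer_names),
            "area_order": list(mapping.area_order),
            "n_perm": mapping.n_perm,
            "alpha": mapping.alpha,
            "seed": mapping.seed,
            "degenerate_probes": list(mapping.degenerate_probes),
        }, indent=2))


def load_mapping(path: str | Path) -> ProbeMapping:
    path = Path(path)
    table = pd.read_csv(path, dtype={"area": str, "probe_id": str})
    missing = set(ProbeMapping.REQUIRED) - set(table.columns)
    if missing:
        raise SchemaError(f"mapping table missing columns: {sorted(missing)}")
    mp = _meta_path(path)
    if not mp.exists():
        raise SchemaError("mapping metadata sidecar missing")
    meta = json.loads(mp.read_text())
    return ProbeMapping(
        table=table,
        layer_names=meta["layer_names"],
        area_order=meta["area_order"],
        n_perm=meta["n_perm"],
        alpha=meta["alpha"],
        seed=meta["seed"],
        degenerate_probes=meta.get("degenerate_probes", []),
    )
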
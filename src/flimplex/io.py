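"""Readers and writers for the pipeline's on-disk formats.

HDF5 is the canonical container for FLIM images (dataset ``counts`` of
shape y * x * t with timing attributes); a multi-page TIFF (one page per
time bin) with a JSON timing sidecar is the interchange dialect.  Label
masks are 16-bit TIFFs with a JSON legend; scene configurations and
lifetime windows travel as YAML.  Timing metadata is mandatory on read —
no silent defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import DecayParams, FLIMImage, IRFModel, LabelMask, TimingConfig
from .fitting import LifetimeMap
from .simulate import RegionSpec, SceneConfig
from .unmix import LifetimeWindows


class MissingMetadataError(ValueError):
    """A FLIM container lacks required timing attributes."""


REQUIRED_ATTRS = ("bin_width_ns", "period_ns")


def _irf_to_attrs(irf: IRFModel | None) -> dict:
    if irf is None:
        return {}
    return {"irf_t0_ns": irf.center_t0, "irf_fwhm_ns": irf.fwhm, "irf_kind": irf.kind}


def _irf_from_attrs(attrs) -> IRFModel | None:
    if "irf_kind" not in attrs:
        return None
    return IRFModel(
        center_t0=float(attrs["irf_t0_ns"]),
        fwhm=float(attrs["irf_fwhm_ns"]),
        kind=str(attrs["irf_kind"]),
    )


def write_flim(path: str | Path, img: FLIMImage) -> Path:
    """Write a FLIMImage as HDF5 (.h5/.hdf5) or multi-page TIFF + sidecar."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("counts", data=img.counts.astype(np.uint32),
                                 compression="gzip")
            d.attrs["bin_width_ns"] = img.timing.bin_width_ns
            d.attrs["period_ns"] = img.timing.period_ns
            d.attrs["n_bins"] = img.timing.n_bins
            d.attrs["channel"] = img.channel
            for k, v in _irf_to_attrs(img.irf).items():
                d.attrs[k] = v
    elif path.suffix in (".tif", ".tiff"):
        # one page per time bin
        tifffile.imwrite(path, np.moveaxis(img.counts, 2, 0).astype(np.uint32))
        sidecar = {
            "bin_width_ns": img.timing.bin_width_ns,
            "period_ns": img.timing.period_ns,
            "n_bins": img.timing.n_bins,
            "channel": img.channel,
            **_irf_to_attrs(img.irf),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported FLIM container suffix {path.suffix!r}")
    return path


def read_flim(path: str | Path) -> FLIMImage:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            d = f["counts"]
            attrs = dict(d.attrs)
            counts = d[()]
    elif path.suffix in (".tif", ".tiff"):
        counts = np.moveaxis(tifffile.imread(path), 0, 2)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise MissingMetadataError(f"timing sidecar {sidecar} not found")
        attrs = json.loads(sidecar.read_text())
    else:
        raise ValueError(f"unsupported FLIM container suffix {path.suffix!r}")
    missing = [k for k in REQUIRED_ATTRS if k not in attrs]
    if missing:
        raise MissingMetadataError(f"{path} lacks timing attributes {missing}")
    n_bins = int(attrs.get("n_bins", counts.shape[2]))
    timing = TimingConfig(period_ns=float(attrs["period_ns"]), n_bins=n_bins)
    return FLIMImage(
        counts,
        timing,
        channel=str(attrs.get("channel", "green")),
        irf=_irf_from_attrs(attrs),
    )


def write_label_mask(path: str | Path, mask: LabelMask) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    legend = {str(k): v for k, v in mask.legend.items()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(legend, indent=1))
    return path


def read_label_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    legend_path = path.with_suffix(path.suffix + ".json")
    if not legend_path.exists():
        raise MissingMetadataError(f"legend sidecar {legend_path} not found")
    legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return LabelMask(labels, legend)


def write_lifetime_map(path: str | Path, lmap: LifetimeMap) -> Path:
    """32-bit float TIFF of T_i (NaN-filled) plus chi2 / order / photon pages."""
    path = Path(path)
    stack = np.stack(
        [lmap.ti, lmap.chi2, lmap.model_order.astype(float), lmap.photons]
    ).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


def read_lifetime_map(path: str | Path, min_photons: int = 0) -> LifetimeMap:
    stack = tifffile.imread(Path(path)).astype(float)
    return LifetimeMap(stack[0], stack[1], stack[2].astype(np.int8), stack[3],
                       min_photons)


def lifetime_map_summary(lmap: LifetimeMap, truth: LabelMask | None = None) -> pd.DataFrame:
    """Per-region (or global) mean T_i, SD, pixel count, model fractions."""
    rows = []
    regions = truth.legend.items() if truth is not None else [(0, "all")]
    for lab, name in regions:
        sel = (truth.labels == lab) if truth is not None else np.ones(lmap.ti.shape, bool)
        vals = lmap.ti[sel]
        vals = vals[np.isfinite(vals)]
        orders = lmap.model_order[sel]
        rows.append({
            "region": name,
            "n_pixels": int(vals.size),
            "mean_ti_ns": float(vals.mean()) if vals.size else np.nan,
            "sd_ti_ns": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            "frac_biexp": float(np.mean(orders == 2)) if orders.size else np.nan,
        })
    return pd.DataFrame(rows).set_index("region")


# --------------------------------------------------------------------------
# YAML config round-trips
# --------------------------------------------------------------------------

def _decay_to_dict(d: DecayParams) -> dict:
    return {"amplitudes": list(d.amplitudes), "lifetimes": list(d.lifetimes)}


def _decay_from_dict(d: dict) -> DecayParams:
    return DecayParams(tuple(d["amplitudes"]), tuple(d["lifetimes"]))


def scene_to_dict(scene: SceneConfig) -> dict:
    return {
        "shape": list(scene.shape),
        "seed": scene.seed,
        "timing": {"period_ns": scene.timing.period_ns, "n_bins": scene.timing.n_bins},
        "irf": {"center_t0": scene.irf.center_t0, "fwhm": scene.irf.fwhm,
                "kind": scene.irf.kind},
        "autofluorescence": _decay_to_dict(scene.autofluorescence),
        "background_rate": scene.background_rate,
        "regions": [
            {
                "kind": r.kind,
                "species": r.species,
                "decay": _decay_to_dict(r.decay),
                "photons_per_pixel": r.photons_per_pixel,
                "channel": r.channel,
                "n_objects": r.n_objects,
                "autofluorescence_fraction": r.autofluorescence_fraction,
                "geometry": {k: v for k, v in r.geometry.items() if k != "mask"},
            }
            for r in scene.regions
        ],
    }


def scene_from_dict(d: dict) -> SceneConfig:
    return SceneConfig(
        shape=tuple(d["shape"]),
        seed=int(d["seed"]),
        timing=TimingConfig(**d.get("timing", {})),
        irf=IRFModel(**d.get("irf", {})),
        autofluorescence=_decay_from_dict(d["autofluorescence"])
        if "autofluorescence" in d
        else SceneConfig.__dataclass_fields__["autofluorescence"].default,
        background_rate=float(d.get("background_rate", 0.0)),
        regions=tuple(
            RegionSpec(
                kind=r["kind"],
                species=r["species"],
                decay=_decay_from_dict(r["decay"]),
                photons_per_pixel=float(r["photons_per_pixel"]),
                channel=r.get("channel", "green"),
                n_objects=int(r.get("n_objects", 1)),
                autofluorescence_fraction=float(r.get("autofluorescence_fraction", 0.0)),
                geometry=r.get("geometry", {}),
            )
            for r in d["regions"]
        ),
    )


def write_scene_yaml(path: str | Path, scene: SceneConfig) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(scene_to_dict(scene), sort_keys=False))
    return path


def read_scene_yaml(path: str | Path) -> SceneConfig:
    return scene_from_dict(yaml.safe_load(Path(path).read_text()))


def write_windows_yaml(path: str | Path, windows: LifetimeWindows) -> Path:
    path = Path(path)
    payload = [
        {"label": label, "lower_ns": lo, "upper_ns": hi}
        for label, lo, hi in windows.windows
    ]
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_windows_yaml(path: str | Path) -> LifetimeWindows:
    payload = yaml.safe_load(Path(path).read_text())
    return LifetimeWindows(
        tuple((w["label"], float(w["lower_ns"]), float(w["upper_ns"])) for w in payload)
    )
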
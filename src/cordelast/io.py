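"""HDF5 acquisition container, YAML configs and CSV result tables.

One HDF5 file holds one acquisition: /phantom (modulus map + labels),
/truth (strain, displacement, true strain ratio), /rf/pre and /rf/post with
the probe parameters as attributes, /elasto (estimated strain, NCC, quality
mask), /masks (cord/reference ROIs) and /meta (JSON-encoded phantom spec).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .elasto import Elastogram, TrackingParams
from .phantom import GroundTruthField, ModulusMap, PhantomSpec, CohortConfig
from .quantify import ROIMasks, StrainRatioRecord
from .rf_sim import RFConfig, RFFrame


def _spec_to_json(spec: PhantomSpec) -> str:
    return json.dumps(dataclasses.asdict(spec))


def _spec_from_json(text: str) -> PhantomSpec:
    d = json.loads(text)
    for key in ("cord_center_mm", "window_x_mm"):
        d[key] = tuple(d[key])
    return PhantomSpec(**d)


def save_acquisition(
    path,
    spec: PhantomSpec | None = None,
    modulus_map: ModulusMap | None = None,
    truth: GroundTruthField | None = None,
    pre: RFFrame | None = None,
    post: RFFrame | None = None,
    elastogram: Elastogram | None = None,
    masks: ROIMasks | None = None,
    mode: str = "w",
) -> None:
    """Write any subset of the pipeline stages into one acquisition file."""
    with h5py.File(path, mode) as f:
        if spec is not None:
            meta = f.require_group("meta")
            meta.attrs["spec_json"] = _spec_to_json(spec)
        if modulus_map is not None:
            g = f.require_group("phantom")
            g.create_dataset("modulus_kpa", data=modulus_map.e_kpa)
            g.create_dataset("labels", data=modulus_map.labels)
            g.create_dataset("z_mm", data=modulus_map.z_mm)
            g.create_dataset("x_mm", data=modulus_map.x_mm)
        if truth is not None:
            g = f.require_group("truth")
            g.create_dataset("strain", data=truth.strain)
            g.create_dataset("displacement_mm", data=truth.displacement)
            g.create_dataset("z_mm", data=truth.z_mm)
            g.create_dataset("x_mm", data=truth.x_mm)
            g.attrs["true_strain_ratio"] = truth.true_strain_ratio
            g.attrs["applied_strain"] = truth.applied_strain
            g.attrs["sigma0_kpa"] = truth.sigma0_kpa
        for role, frame in (("pre", pre), ("post", post)):
            if frame is None:
                continue
            g = f.require_group("rf")
            ds = g.create_dataset(role, data=frame.samples)
            ds.attrs["x_mm"] = frame.x_mm
            cfg = g.require_group("config")
            for fld in dataclasses.fields(frame.config):
                val = getattr(frame.config, fld.name)
                cfg.attrs[fld.name] = np.nan if val is None else val
        if elastogram is not None:
            g = f.require_group("elasto")
            g.create_dataset("strain", data=elastogram.strain)
            g.create_dataset("ncc", data=elastogram.ncc)
            g.create_dataset("quality_mask", data=elastogram.quality_mask)
            g.create_dataset("grid_z_mm", data=elastogram.grid_z_mm)
            g.create_dataset("grid_x_mm", data=elastogram.grid_x_mm)
            for fld in dataclasses.fields(elastogram.params):
                g.attrs[fld.name] = getattr(elastogram.params, fld.name)
        if masks is not None:
            g = f.require_group("masks")
            g.create_dataset("cord", data=masks.cord_mask)
            g.create_dataset("reference", data=masks.reference_mask)
            g.attrs["provenance"] = masks.provenance


def load_acquisition(path) -> dict:
    """Read an acquisition file back into pipeline objects (missing → None)."""
    out: dict = {"spec": None, "modulus_map": None, "truth": None,
                 "pre": None, "post": None, "elastogram": None, "masks": None}
    with h5py.File(path, "r") as f:
        if "meta" in f and "spec_json" in f["meta"].attrs:
            out["spec"] = _spec_from_json(f["meta"].attrs["spec_json"])
        if "phantom" in f and out["spec"] is not None:
            g = f["phantom"]
            out["modulus_map"] = ModulusMap(
                e_kpa=g["modulus_kpa"][()], labels=g["labels"][()],
                z_mm=g["z_mm"][()], x_mm=g["x_mm"][()], spec=out["spec"],
            )
        if "truth" in f:
            g = f["truth"]
            out["truth"] = GroundTruthField(
                strain=g["strain"][()], displacement=g["displacement_mm"][()],
                true_strain_ratio=float(g.attrs["true_strain_ratio"]),
                z_mm=g["z_mm"][()], x_mm=g["x_mm"][()],
                applied_strain=float(g.attrs["applied_strain"]),
                sigma0_kpa=float(g.attrs["sigma0_kpa"]),
            )
        if "rf" in f:
            cfg_attrs = dict(f["rf/config"].attrs)
            snr = cfg_attrs.get("noise_snr_db", np.nan)
            cfg = RFConfig(
                f0_mhz=float(cfg_attrs["f0_mhz"]),
                fractional_bandwidth=float(cfg_attrs["fractional_bandwidth"]),
                fs_mhz=float(cfg_attrs["fs_mhz"]),
                c_m_s=float(cfg_attrs["c_m_s"]),
                lateral_beamwidth_mm=float(cfg_attrs["lateral_beamwidth_mm"]),
                line_pitch_mm=float(cfg_attrs["line_pitch_mm"]),
                noise_snr_db=None if np.isnan(snr) else float(snr),
            )
            for role in ("pre", "post"):
                if role in f["rf"]:
                    ds = f["rf"][role]
                    out[role] = RFFrame(samples=ds[()], config=cfg,
                                        x_mm=np.asarray(ds.attrs["x_mm"]),
                                        frame_role=role)
        if "elasto" in f:
            g = f["elasto"]
            pfields = {fld.name: fld.type for fld in dataclasses.fields(TrackingParams)}
            pkw = {}
            for name in pfields:
                if name in g.attrs:
                    val = g.attrs[name]
                    pkw[name] = val.item() if hasattr(val, "item") else val
            if "subsample" in pkw:
                pkw["subsample"] = str(pkw["subsample"])
            pkw = {k: (bool(v) if k in ("guided", "median_filter") else v) for k, v in pkw.items()}
            if "lsq_kernel" in pkw:
                pkw["lsq_kernel"] = int(pkw["lsq_kernel"])
            out["elastogram"] = Elastogram(
                strain=g["strain"][()], quality_mask=g["quality_mask"][()].astype(bool),
                ncc=g["ncc"][()], grid_z_mm=g["grid_z_mm"][()],
                grid_x_mm=g["grid_x_mm"][()], params=TrackingParams(**pkw),
            )
        if "masks" in f:
            g = f["masks"]
            out["masks"] = ROIMasks(cord_mask=g["cord"][()].astype(bool),
                                    reference_mask=g["reference"][()].astype(bool),
                                    provenance=str(g.attrs.get("provenance", "supplied")))
    return out


def load_cohort_config(path) -> CohortConfig:
    with open(path) as f:
        return CohortConfig(**yaml.safe_load(f))


def records_to_frame(records: list[StrainRatioRecord]) -> pd.DataFrame:
    """Per-animal results table (one row per animal)."""
    rows = []
    for rec in records:
        nb = rec.per_neighborhood
        rows.append({
            "animal_id": rec.animal_id,
            "group": rec.group,
            "n_acquisitions": int(sum(len(x) for x in rec.per_acquisition)),
            "n_neighborhoods": len(rec.per_acquisition),
            "sr_mean": rec.per_animal,
            "sr_sd": float(nb.std(ddof=1)) if nb.size > 1 else float("nan"),
        })
    return pd.DataFrame(rows)


def save_strain_overlay(path, elastogram: Elastogram, frame: RFFrame | None = None,
                        dpi: int = 120) -> None:
    """PNG of the strain elastogram, optionally over the B-mode envelope."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if frame is not None:
        env = frame.envelope()
        env_db = 20 * np.log10(env / (env.max() + 1e-30) + 1e-6)
        ax.imshow(env_db, cmap="gray", aspect="auto", vmin=-60, vmax=0,
                  extent=[frame.x_mm[0], frame.x_mm[-1], frame.z_mm[-1], frame.z_mm[0]])
    shown = np.where(elastogram.quality_mask, elastogram.strain, np.nan)
    im = ax.imshow(shown, cmap="jet", aspect="auto", alpha=0.7,
                   extent=[elastogram.grid_x_mm[0], elastogram.grid_x_mm[-1],
                           elastogram.grid_z_mm[-1], elastogram.grid_z_mm[0]])
    fig.colorbar(im, ax=ax, label="axial normal strain")
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    fig.savefig(Path(path), dpi=dpi, bbox_inches="tight")
    plt.close(fig)
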
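"""End-to-end pipeline orchestration.

Runs the stages in fixed order — phantom (or input load), optional
fringe synthesis + reconstruction, BM registration/averaging, axial
alignment, flattening, graph-cut segmentation with thickness summary,
and speckle-variance angiography with en face exports — writing every
intermediate artifact and a provenance manifest (stage parameters,
input hashes, seed) into a run directory.  Re-running with an identical
configuration and seed reproduces all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Dict

import numpy as np
import yaml

from . import __version__
from .angiography import (
    DEFAULT_SLABS,
    build_angio_volume,
    enface_project,
    enhance_contrast,
    oct_fundus,
)
from .flattening import FlattenParams, applied_shifts, flatten_volume
from .phantom import PhantomSpec, generate_structural, species_preset, synthesize_fringes
from .reconstruction import ReconParams, reconstruct_volume, to_log_grayscale
from .registration import average_bm_volume, axial_align_volume
from .segmentation import GraphCutParams, compute_thickness, segment_surfaces_graphcut
from .volume_model import AcquisitionMeta, export_image, read_volume, write_volume

__all__ = ["validate_config", "run_pipeline", "PipelineError", "DEFAULT_CONFIG"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure; partial outputs are retained."""


class ConfigError(ValueError):
    """Configuration does not validate; message lists every violation."""


_META_KEYS = {f.name for f in dataclasses.fields(AcquisitionMeta)}
_PHANTOM_KEYS = {
    "species",
    "curvature_sag_px",
    "thickness_ripple_um",
    "speckle_contrast",
    "static_frame_correlation",
    "n_vessels",
    "vessel_radius_px",
    "jitter_walk_sigma_px",
    "bm_jitter_px",
    "noise_floor",
    "ilm_center_depth_px",
}

DEFAULT_CONFIG: Dict[str, Any] = {
    "seed": 0,
    "input": None,  # path to a .oct.raw volume; overrides the phantom
    "phantom": {"species": "mouse"},
    "synthesize_fringes": False,
    "recon": {"c2": 0.0, "c3": 0.0, "floor_db": -30.0, "ceil_db": 5.0},
    "register": {"ref": "auto", "max_lag": 50, "upsample": 10},
    "flatten": {},
    "segment": {},
    "angio": {
        "enabled": True,
        "slabs": ["superficial", "deep", "choroid"],
        "bg_sigma": 20.0,
        "stretch": [1.0, 99.0],
    },
}


def _merge(defaults: Dict[str, Any], user: Dict[str, Any], path: str, errors) -> Dict:
    out = dict(defaults)
    for key, val in user.items():
        if key not in defaults and path in ("recon", "register", "angio", ""):
            errors.append(f"unknown key {path + '.' if path else ''}{key}")
            continue
        if isinstance(val, dict) and isinstance(defaults.get(key), dict):
            out[key] = _merge(defaults[key], val, f"{path}.{key}".strip("."), errors)
        else:
            out[key] = val
    return out


def validate_config(source) -> Dict[str, Any]:
    """Validate and normalise a pipeline configuration.

    ``source`` is a path to a YAML document or an already-parsed dict.
    Unknown keys are rejected, defaults filled in, and every parameter
    invariant checked (by constructing the stage parameter objects)
    before any execution; violations are reported as one itemised list.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source or {})
    if not isinstance(user, dict):
        raise ConfigError("configuration must be a mapping")

    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, user, "", errors)

    # per-stage structured checks
    ph = cfg.get("phantom") or {}
    unknown = set(ph) - _PHANTOM_KEYS - _META_KEYS
    for k in sorted(unknown):
        errors.append(f"unknown key phantom.{k}")
    for section, cls in (("flatten", FlattenParams), ("segment", GraphCutParams)):
        vals = cfg.get(section) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        for k in sorted(set(vals) - known):
            errors.append(f"unknown key {section}.{k}")
        try:
            cls(**{k: v for k, v in vals.items() if k in known})
        except (ValueError, TypeError) as exc:
            errors.append(f"{section}: {exc}")
    try:
        ReconParams(
            dispersion_c2=cfg["recon"]["c2"],
            dispersion_c3=cfg["recon"]["c3"],
            dynamic_range_db=(cfg["recon"]["floor_db"], cfg["recon"]["ceil_db"]),
        )
    except (ValueError, TypeError, KeyError) as exc:
        errors.append(f"recon: {exc}")
    if not errors and cfg["input"] is None:
        try:
            _phantom_spec(cfg)
        except (ValueError, TypeError) as exc:
            errors.append(f"phantom: {exc}")
    st = (cfg.get("angio") or {}).get("stretch", [1.0, 99.0])
    if not (isinstance(st, (list, tuple)) and len(st) == 2 and st[0] < st[1]):
        errors.append("angio.stretch must be an increasing (p_lo, p_hi) pair")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def _phantom_spec(cfg: Dict[str, Any]) -> PhantomSpec:
    ph = dict(cfg.get("phantom") or {})
    species = ph.pop("species", "mouse")
    meta_over = {k: ph.pop(k) for k in list(ph) if k in _META_KEYS}
    spec_over = {k: v for k, v in ph.items() if k in _PHANTOM_KEYS}
    meta = AcquisitionMeta(**meta_over) if meta_over else AcquisitionMeta()
    return species_preset(species, meta=meta, seed=int(cfg["seed"]), **spec_over)


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config, out_dir) -> Path:
    """Execute the full pipeline; returns the run directory.

    ``config`` is a path or dict accepted by :func:`validate_config`.
    Stage failures raise :class:`PipelineError` tagged with the stage
    name; artifacts of completed stages are retained.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Any] = {
        "version": __version__,
        "seed": int(cfg["seed"]),
        "config": cfg,
        "stages": [],
    }

    def _stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-tagged below
                _write_manifest(out, manifest)
                raise PipelineError(f"[{name}] {exc}") from exc
            return result

        return wrap

    # --- stage 1: phantom or input ------------------------------------
    truth = None
    if cfg["input"] is not None:

        @_stage("input")
        def vol():
            return read_volume(cfg["input"])

    else:

        @_stage("phantom")
        def vol():
            spec = _phantom_spec(cfg)
            structural, tr = generate_structural(spec)
            write_volume(structural, out / "phantom.oct.raw", out / "phantom.oct.yaml")
            np.savetxt(out / "truth_ilm.csv", tr.ilm_surface.z, delimiter=",")
            np.savetxt(out / "truth_rpe.csv", tr.rpe_surface.z, delimiter=",")
            np.savetxt(out / "truth_jitter.csv", tr.jitter_px, delimiter=",", fmt="%d")
            if cfg["synthesize_fringes"]:
                return synthesize_fringes(structural, spec)
            return structural

    manifest["stages"].append({"stage": "acquire", "hash": _hash(vol.data)})

    # --- stage 2: reconstruction or grayscale conversion ---------------
    @_stage("reconstruct")
    def bm_log():
        from .volume_model import FringeVolume

        rc = cfg["recon"]
        params = ReconParams(
            dispersion_c2=rc["c2"],
            dispersion_c3=rc["c3"],
            dynamic_range_db=(rc["floor_db"], rc["ceil_db"]),
        )
        if isinstance(vol, FringeVolume):
            return reconstruct_volume(vol, params)
        if vol.intensity_domain == "linear":
            return to_log_grayscale(vol)
        return vol

    manifest["stages"].append({"stage": "reconstruct", "hash": _hash(bm_log.data)})

    # --- stage 3: BM averaging + axial alignment -----------------------
    reg = cfg["register"]

    @_stage("register")
    def aligned_and_offsets():
        averaged = average_bm_volume(bm_log, upsample=int(reg["upsample"]))
        ref = reg["ref"]
        ref = ref if ref == "auto" else int(ref)
        aligned, offsets = axial_align_volume(
            averaged, ref_index=ref, max_lag=int(reg["max_lag"])
        )
        np.savetxt(out / "axial_offsets.csv", offsets, delimiter=",", fmt="%d")
        write_volume(aligned, out / "aligned.oct.raw", out / "aligned.oct.yaml")
        return aligned, offsets

    aligned, offsets = aligned_and_offsets
    manifest["stages"].append({"stage": "register", "hash": _hash(aligned.data)})

    # --- stage 4: flattening -------------------------------------------
    @_stage("flatten")
    def flat_and_surface():
        fp = FlattenParams(**(cfg["flatten"] or {}))
        flat, surface = flatten_volume(aligned, fp)
        np.savetxt(out / "flatten_surface.csv", surface.z, delimiter=",")
        write_volume(flat, out / "flattened.oct.raw", out / "flattened.oct.yaml")
        return flat, surface, fp

    flat, flatten_surface, fparams = flat_and_surface
    manifest["stages"].append({"stage": "flatten", "hash": _hash(flat.data)})

    # --- stage 5: segmentation + thickness -----------------------------
    @_stage("segment")
    def seg():
        seg_cfg = dict(cfg["segment"] or {})
        # after flattening the detected surface sits at the centre depth,
        # so narrow default search bands around it are well founded: the
        # ILM within +-40 px, the RPE within 800 um below the ILM
        nd = flat.meta.n_depth
        center = fparams.center_depth_px if fparams.center_depth_px is not None else nd // 3
        if seg_cfg.get("search_band_ilm") is None:
            seg_cfg["search_band_ilm"] = (max(0, center - 40), min(nd, center + 40))
        if seg_cfg.get("search_band_rpe") is None:
            depth_800um = int(round(800.0 / flat.meta.axial_um_per_px))
            seg_cfg["search_band_rpe"] = (center, min(nd, center + depth_800um))
        gp = GraphCutParams(**seg_cfg)
        ilm, rpe = segment_surfaces_graphcut(flat, gp)
        res = compute_thickness(ilm, rpe, flat.meta.axial_um_per_px)
        np.savetxt(out / "ilm.csv", ilm.z, delimiter=",")
        np.savetxt(out / "rpe.csv", rpe.z, delimiter=",")
        export_image(
            res.thickness_um / max(res.thickness_um.max(), 1e-9),
            out / "thickness.tiff",
            "tiff16",
        )
        label = (cfg.get("phantom") or {}).get("species", "input")
        with open(out / "thickness_summary.csv", "w") as fh:
            fh.write("label,n_columns,mean_um,sd_um\n")
            fh.write(f"{label},{res.n_columns},{res.mean_um:.3f},{res.sd_um:.3f}\n")
        return ilm, rpe, res

    ilm, rpe, thickness = seg
    manifest["stages"].append(
        {
            "stage": "segment",
            "mean_um": thickness.mean_um,
            "sd_um": thickness.sd_um,
            "n_columns": thickness.n_columns,
        }
    )

    # --- stage 6: angiography + en face --------------------------------
    if (cfg.get("angio") or {}).get("enabled", True):

        @_stage("angio")
        def _angio():
            an = cfg["angio"]
            sv = build_angio_volume(
                bm_log, upsample=int(reg["upsample"]), axial_offsets=offsets
            )
            # flatten the angiogram with the structural shift field so the
            # segmentation surfaces apply directly
            shifts = applied_shifts(
                flatten_surface.z,
                fparams.center_depth_px
                if fparams.center_depth_px is not None
                else flat.meta.n_depth // 3,
            )
            nz = sv.shape[1]
            zz = np.arange(nz)[:, None]
            xx = np.arange(sv.shape[2])[None, :]
            for y in range(sv.shape[0]):
                sv[y] = sv[y][(zz - shifts[y][None, :]) % nz, xx]
            fundus = oct_fundus(aligned)
            export_image(fundus, out / "fundus.png", "png8")
            for slab_name in an["slabs"]:
                slab = DEFAULT_SLABS[slab_name]
                mode = "mean" if slab_name == "choroid" else "max"
                img = enface_project(sv, ilm, rpe, slab, mode=mode)
                img = enhance_contrast(
                    img, an["bg_sigma"], tuple(an["stretch"])
                )
                export_image(img, out / f"angio_{slab_name}.png", "png8")
            return sv

        sv = _angio
        manifest["stages"].append({"stage": "angio", "hash": _hash(sv)})

    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: Dict[str, Any]) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
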
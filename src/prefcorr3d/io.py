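"""Readers and writers for on-disk artifacts.

Space bundle: a directory with ``manifest.json`` (dims, cells, seed, scales,
band edges), ``.npy`` arrays for bases/averages, a per-cell average mesh as
OBJ and average texture as PNG (L*a*b* converted to sRGB, D65, preview only
— the numeric arrays are authoritative).

Trial tables: CSV with header ``trial_id, viewpoint, rating, s0..s{k-1},
c{band}_{dim}``; the rating column may be empty before simulation.

Preference models: a directory with ``manifest.json`` plus ``.npy`` arrays.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import trimesh
from PIL import Image
from skimage import color

from .errors import InvalidInputError, TrialParseError
from .revcorr import PreferenceModel
from .space import (
    Cell,
    GenerativeSpaceSpec,
    SpaceConfig,
    TrialRecord,
)


def lab_texture_to_srgb(texture: np.ndarray) -> np.ndarray:
    """L*a*b* (D65) texture -> uint8 sRGB image array, for previews."""
    rgb = color.lab2rgb(texture)
    return (np.clip(rgb, 0.0, 1.0) * 255).round().astype(np.uint8)


# --- space bundle ----------------------------------------------------------

def write_space_bundle(space: GenerativeSpaceSpec, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = asdict(space.config)
    cfg["texture_shape"] = list(space.config.texture_shape)
    cfg["ethnicities"] = list(space.config.ethnicities)
    cfg["sexes"] = list(space.config.sexes)
    manifest = {
        "format": "prefcorr3d-space/1",
        "seed": space.seed,
        "config": cfg,
        "band_edges": [list(e) for e in space.band_edges],
        "cells": sorted(space.cells),
        "n_sf_bands": space.config.n_sf_bands,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    np.save(path / "shape_basis.npy", space.shape_basis)
    np.save(path / "faces.npy", space.faces)
    np.save(path / "shape_coeff_scale.npy", space.shape_coeff_scale)
    np.save(path / "complexion_coeff_scale.npy", space.complexion_coeff_scale)
    for b, basis in enumerate(space.complexion_bases):
        np.save(path / f"complexion_basis_band{b}.npy", basis)
    for label, cell in space.cells.items():
        np.save(path / f"cell_{label}_mesh.npy", cell.avg_mesh)
        np.save(path / f"cell_{label}_texture.npy", cell.avg_texture)
        mesh = trimesh.Trimesh(vertices=cell.avg_mesh, faces=space.faces, process=False)
        mesh.export(path / f"cell_{label}_mesh.obj")
        Image.fromarray(lab_texture_to_srgb(cell.avg_texture)).save(
            path / f"cell_{label}_texture.png")
    return path


def read_space_bundle(path: str | Path) -> GenerativeSpaceSpec:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["texture_shape"] = tuple(cfg_d["texture_shape"])
    cfg_d["ethnicities"] = tuple(cfg_d["ethnicities"])
    cfg_d["sexes"] = tuple(cfg_d["sexes"])
    cfg = SpaceConfig(**cfg_d)
    cells = {}
    for label in manifest["cells"]:
        eth, sex = label.rsplit("_", 1)
        cells[label] = Cell(
            ethnicity=eth, sex=sex,
            avg_mesh=np.load(path / f"cell_{label}_mesh.npy"),
            avg_texture=np.load(path / f"cell_{label}_texture.npy"),
        )
    bases = [np.load(path / f"complexion_basis_band{b}.npy")
             for b in range(manifest["n_sf_bands"])]
    return GenerativeSpaceSpec(
        config=cfg, seed=manifest["seed"], cells=cells,
        faces=np.load(path / "faces.npy"),
        shape_basis=np.load(path / "shape_basis.npy"),
        complexion_bases=bases,
        band_edges=[tuple(e) for e in manifest["band_edges"]],
        shape_coeff_scale=np.load(path / "shape_coeff_scale.npy"),
        complexion_coeff_scale=np.load(path / "complexion_coeff_scale.npy"),
    )


# --- trial tables ----------------------------------------------------------

def trial_columns(n_shape_dims: int, n_complexion_dims: int, n_sf_bands: int) -> list[str]:
    cols = ["trial_id", "viewpoint", "rating"]
    cols += [f"s{j}" for j in range(n_shape_dims)]
    cols += [f"c{b}_{j}" for b in range(n_sf_bands) for j in range(n_complexion_dims)]
    return cols


def write_trials(records: Sequence[TrialRecord], path: str | Path) -> Path:
    path = Path(path)
    if not records:
        raise InvalidInputError("no trial records to write")
    k = records[0].shape_coeffs.shape[0]
    kc, nb = records[0].complexion_coeffs.shape
    rows = []
    for t in records:
        row = [t.trial_id, t.viewpoint, "" if t.rating is None else int(t.rating)]
        row += list(np.asarray(t.shape_coeffs, float))
        row += [t.complexion_coeffs[j, b] for b in range(nb) for j in range(kc)]
        rows.append(row)
    df = pd.DataFrame(rows, columns=trial_columns(k, kc, nb))
    df.to_csv(path, index=False)
    return path


def read_trials(path: str | Path) -> list[TrialRecord]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise TrialParseError(f"malformed trial table {path}: {e}") from e
    required = {"trial_id", "viewpoint"}
    if not required.issubset(df.columns):
        raise TrialParseError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    scols = sorted((c for c in df.columns if c.startswith("s") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    ccols = [c for c in df.columns if c.startswith("c") and "_" in c]
    bands = sorted({int(c[1:].split("_")[0]) for c in ccols}) if ccols else []
    dims = sorted({int(c.split("_")[1]) for c in ccols}) if ccols else []
    has_rating = "rating" in df.columns

    records = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        rating = None
        if has_rating and not pd.isna(row["rating"]):
            r = float(row["rating"])
            if r != int(r) or not (1 <= r <= 9):
                raise TrialParseError(
                    f"{path} line {line_no}: rating {row['rating']!r} is not an integer in 1..9")
            rating = int(r)
        shape = row[scols].to_numpy(dtype=float)
        comp = np.empty((len(dims), len(bands)))
        for b in bands:
            for j in dims:
                comp[j, b] = row[f"c{b}_{j}"]
        if not (np.all(np.isfinite(shape)) and np.all(np.isfinite(comp))):
            raise TrialParseError(f"{path} line {line_no}: non-finite coefficient")
        records.append(TrialRecord(
            trial_id=int(row["trial_id"]), shape_coeffs=shape,
            complexion_coeffs=comp, viewpoint=int(row["viewpoint"]), rating=rating))
    return records


# --- preference models -----------------------------------------------------

def write_model(model: PreferenceModel, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "prefcorr3d-model/1",
        "participant_id": model.participant_id,
        "condition": model.condition,
        "method": model.method,
        "n_trials": model.n_trials,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    np.save(path / "shape_beta1.npy", model.shape_beta1)
    np.save(path / "shape_beta2.npy", model.shape_beta2)
    np.save(path / "complexion_beta1.npy", model.complexion_beta1)
    np.save(path / "complexion_beta2.npy", model.complexion_beta2)
    return path


def read_model(path: str | Path) -> PreferenceModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    return PreferenceModel(
        participant_id=manifest["participant_id"],
        condition=manifest["condition"],
        method=manifest["method"],
        shape_beta1=np.load(path / "shape_beta1.npy"),
        shape_beta2=np.load(path / "shape_beta2.npy"),
        complexion_beta1=np.load(path / "complexion_beta1.npy"),
        complexion_beta2=np.load(path / "complexion_beta2.npy"),
        n_trials=manifest["n_trials"],
    )
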
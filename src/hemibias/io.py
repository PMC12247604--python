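"""Reading and writing datasets, stat maps, meshes, and masks.

Datasets are stored as one tab-delimited file per subject (TR rows x node
columns, header ``region_hemisphere``) plus a JSON sidecar recording run
lengths, generator parameters and seed, so downstream stages are agnostic
to whether series came from the simulator or from real extractions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import node_label
from .roi import ROIMask, StatMap, SurfaceMesh
from .synthetic import HEMISPHERES, LatentSpec, ROITimecourseDataset

SIDECAR_NAME = "dataset.json"


def save_dataset(dataset: ROITimecourseDataset, directory) -> Path:
    """Write per-subject TSVs and the JSON sidecar; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    columns = [node_label(r, h) for r in dataset.regions for h in dataset.hemispheres]
    for s in range(dataset.n_subjects):
        frame = pd.DataFrame(dataset.node_matrix(s).T, columns=columns)
        frame.to_csv(directory / f"sub-{s:02d}.tsv", sep="\t", index=False,
                     float_format="%.10g")
    sidecar = {
        "n_subjects": dataset.n_subjects,
        "regions": list(dataset.regions),
        "hemispheres": list(dataset.hemispheres),
        "run_lengths": list(dataset.run_lengths),
        "network": dataset.network,
        "seed": dataset.seed,
        "spec": dataclasses.asdict(dataset.spec) if dataset.spec else None,
    }
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return directory


def load_dataset(directory) -> ROITimecourseDataset:
    """Load a dataset written by :func:`save_dataset`."""
    directory = Path(directory)
    sidecar = json.loads((directory / SIDECAR_NAME).read_text())
    regions = tuple(sidecar["regions"])
    hemis = tuple(sidecar.get("hemispheres", HEMISPHERES))
    columns = [node_label(r, h) for r in regions for h in hemis]
    data = []
    for s in range(sidecar["n_subjects"]):
        frame = pd.read_csv(directory / f"sub-{s:02d}.tsv", sep="\t")
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise ValueError(f"subject {s} file lacks columns {missing}")
        data.append(frame[columns].to_numpy().T.reshape(len(regions), len(hemis), -1))
    spec = LatentSpec(**{**sidecar["spec"], "regions": tuple(sidecar["spec"]["regions"])}) \
        if sidecar.get("spec") else None
    return ROITimecourseDataset(
        data=np.stack(data),
        regions=regions,
        run_lengths=tuple(sidecar["run_lengths"]),
        network=sidecar.get("network", "network"),
        spec=spec,
        seed=sidecar.get("seed"),
    )


# ---------------------------------------------------------------------------
# Volumes and surfaces


def save_statmap(statmap: StatMap, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(statmap.values, dtype=np.float32),
                          affine=statmap.affine)
    img.header.set_zooms(statmap.voxel_size)
    nib.save(img, path)
    return path


def load_statmap(path) -> StatMap:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return StatMap(values=np.asanyarray(img.dataobj, dtype=float),
                   voxel_size=tuple(float(z) for z in zooms),
                   affine=np.asarray(img.affine))


def save_mesh(mesh: SurfaceMesh, path) -> Path:
    """Write a mesh with per-vertex scalars as GIFTI."""
    path = Path(path)
    arrays = [
        nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
        nib.gifti.GiftiDataArray(mesh.scalars.astype(np.float32),
                                 intent="NIFTI_INTENT_SHAPE"),
    ]
    nib.save(nib.gifti.GiftiImage(darrays=arrays), path)
    return path


def load_mesh(path) -> SurfaceMesh:
    img = nib.load(str(path))
    vertices = faces = scalars = None
    for arr in img.darrays:
        intent = nib.nifti1.intent_codes.label[arr.intent]
        if intent == "pointset":
            vertices = arr.data
        elif intent == "triangle":
            faces = arr.data
        else:
            scalars = arr.data
    if vertices is None or faces is None:
        raise ValueError("GIFTI file lacks pointset/triangle arrays")
    if scalars is None:
        scalars = np.zeros(len(vertices))
    return SurfaceMesh(vertices=vertices, faces=faces, scalars=scalars)


def save_mask(mask: ROIMask, path, shape: tuple[int, int, int] | None = None,
              affine: np.ndarray | None = None) -> Path:
    """Write a volume mask as 0/1 NIfTI, or a surface mask as JSON."""
    path = Path(path)
    meta = {
        "kind": mask.kind,
        "seed": list(mask.seed) if mask.kind == "volume" else mask.seed,
        "region": mask.region,
        "hemisphere": mask.hemisphere,
        "network": mask.network,
        "achieved_size": mask.achieved_size,
        "final_threshold": mask.final_threshold,
        "connectivity": mask.connectivity,
    }
    if mask.kind == "volume":
        if shape is None:
            raise ValueError("volume masks need the grid shape")
        img = nib.Nifti1Image(mask.to_volume(shape),
                              affine=np.eye(4) if affine is None else affine)
        nib.save(img, path)
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True))
    else:
        meta["members"] = [int(m) for m in mask.members]
        path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path
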
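"""HDF5 and TSV persistence for pipeline artifacts.

Sensor epochs travel in a self-describing HDF5 container with datasets
``/data`` (trials × channels × samples, float64), ``/sfreq``, ``/times``,
``/chan_pos``, ``/chan_ori``, ``/events`` and a ``schema_version``
attribute. Synthetic subject datasets additionally embed the forward
model (grid, leadfield, source orientations, head sphere) so a run is
fully reproducible from one file; the parcel atlas is a sidecar TSV
(voxel_index, label, name, hemisphere, lobe).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .containers import SensorEpochs
from .synthetic import HeadModel, Leadfield, ParcelAtlas, SourceGrid

SCHEMA_VERSION = 1

__all__ = [
    "SubjectData",
    "save_epochs",
    "load_epochs",
    "save_dataset",
    "load_dataset",
    "save_atlas_tsv",
    "load_atlas_tsv",
    "save_adjacency",
    "load_adjacency",
    "save_source_estimate",
    "load_source_estimate",
]


@dataclass
class SubjectData:
    """A complete synthetic subject: epochs plus forward model and truth."""

    epochs: SensorEpochs
    head: HeadModel
    grid: SourceGrid
    leadfield: Leadfield
    source_orientations: np.ndarray
    atlas: Optional[ParcelAtlas] = None
    truth: Optional[dict] = None  # ground-truth scenario summary


def _write_epochs(g: h5py.Group, epochs: SensorEpochs) -> None:
    g.create_dataset("data", data=epochs.data, dtype="float64")
    g.create_dataset("sfreq", data=float(epochs.sfreq))
    g.create_dataset("times", data=epochs.times)
    if epochs.chan_pos is not None:
        g.create_dataset("chan_pos", data=epochs.chan_pos)
    if epochs.chan_ori is not None:
        g.create_dataset("chan_ori", data=epochs.chan_ori)
    if epochs.events is not None:
        g.create_dataset("events", data=epochs.events)
    g.create_dataset("trial_keep_mask", data=epochs.trial_keep_mask)
    g.attrs["schema_version"] = SCHEMA_VERSION


def _read_epochs(g: h5py.Group) -> SensorEpochs:
    def opt(name):
        return g[name][()] if name in g else None

    return SensorEpochs(
        data=g["data"][()],
        sfreq=float(g["sfreq"][()]),
        times=g["times"][()],
        chan_pos=opt("chan_pos"),
        chan_ori=opt("chan_ori"),
        events=opt("events"),
        trial_keep_mask=opt("trial_keep_mask"),
    )


def save_epochs(path: str, epochs: SensorEpochs) -> None:
    with h5py.File(path, "w") as f:
        _write_epochs(f, epochs)


def load_epochs(path: str) -> SensorEpochs:
    with h5py.File(path, "r") as f:
        return _read_epochs(f)


def save_dataset(path: str, data: SubjectData) -> None:
    with h5py.File(path, "w") as f:
        _write_epochs(f, data.epochs)
        fm = f.create_group("forward")
        fm.create_dataset("head_center", data=data.head.center)
        fm.create_dataset("head_radius", data=float(data.head.radius))
        fm.create_dataset("grid_points", data=data.grid.points)
        fm.create_dataset("grid_ijk", data=data.grid.ijk)
        fm.create_dataset("grid_spacing", data=float(data.grid.spacing))
        fm.create_dataset("leadfield", data=data.leadfield.gain)
        fm.create_dataset("source_orientations", data=data.source_orientations)
        if data.truth is not None:
            f.attrs["truth"] = json.dumps(data.truth)
        if data.atlas is not None:
            ag = f.create_group("atlas")
            ag.create_dataset("labels", data=data.atlas.labels)
            ag.attrs["names"] = json.dumps({str(k): v for k, v in data.atlas.names.items()})
            ag.attrs["hemisphere"] = json.dumps({str(k): v for k, v in data.atlas.hemisphere.items()})
            ag.attrs["lobe"] = json.dumps({str(k): v for k, v in data.atlas.lobe.items()})


def load_dataset(path: str) -> SubjectData:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"{path}: not a recognised subject dataset (schema mismatch)")
        epochs = _read_epochs(f)
        fm = f["forward"]
        head = HeadModel(center=fm["head_center"][()], radius=float(fm["head_radius"][()]))
        grid = SourceGrid(
            points=fm["grid_points"][()],
            spacing=float(fm["grid_spacing"][()]),
            ijk=fm["grid_ijk"][()],
        )
        lf = Leadfield(gain=fm["leadfield"][()])
        ori = fm["source_orientations"][()]
        atlas = None
        if "atlas" in f:
            ag = f["atlas"]
            atlas = ParcelAtlas(
                labels=ag["labels"][()],
                names={int(k): v for k, v in json.loads(ag.attrs["names"]).items()},
                hemisphere={int(k): v for k, v in json.loads(ag.attrs["hemisphere"]).items()},
                lobe={int(k): v for k, v in json.loads(ag.attrs["lobe"]).items()},
            )
        truth = json.loads(f.attrs["truth"]) if "truth" in f.attrs else None
    return SubjectData(
        epochs=epochs, head=head, grid=grid, leadfield=lf,
        source_orientations=ori, atlas=atlas, truth=truth,
    )


def save_atlas_tsv(path: str, atlas: ParcelAtlas) -> None:
    df = pd.DataFrame(
        {
            "voxel_index": np.arange(len(atlas.labels)),
            "label": atlas.labels,
            "name": [atlas.names[int(l)] for l in atlas.labels],
            "hemisphere": [atlas.hemisphere[int(l)] for l in atlas.labels],
            "lobe": [atlas.lobe[int(l)] for l in atlas.labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_atlas_tsv(path: str) -> ParcelAtlas:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("voxel_index")
    labels = df["label"].to_numpy()
    first = df.drop_duplicates("label").set_index("label")
    return ParcelAtlas(
        labels=labels,
        names=first["name"].to_dict(),
        hemisphere=first["hemisphere"].to_dict(),
        lobe=first["lobe"].to_dict(),
    )


def save_adjacency(path: str, values: np.ndarray, freqs: np.ndarray, provenance: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("adjacency", data=values)
        f.create_dataset("freqs", data=freqs)
        f.attrs["provenance"] = provenance
        f.attrs["schema_version"] = SCHEMA_VERSION


def load_adjacency(path: str):
    with h5py.File(path, "r") as f:
        return f["adjacency"][()], f["freqs"][()]


def save_source_estimate(path: str, data: np.ndarray, sfreq: float, times: np.ndarray,
                         grid_points: Optional[np.ndarray] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("source_data", data=data)
        f.create_dataset("sfreq", data=float(sfreq))
        f.create_dataset("times", data=times)
        if grid_points is not None:
            f.create_dataset("grid", data=grid_points)
        f.attrs["schema_version"] = SCHEMA_VERSION


def load_source_estimate(path: str):
    from .containers import SourceEstimate

    with h5py.File(path, "r") as f:
        return SourceEstimate(
            data=f["source_data"][()],
            sfreq=float(f["sfreq"][()]),
            times=f["times"][()],
            grid_points=f["grid"][()] if "grid" in f else None,
        )
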
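"""Persistence: HDF5 datasets, model checkpoints, VTK/STL/CSV export.

Datasets round-trip losslessly through a single HDF5 file with groups
``designs/``, ``shapes/``, ``stresses/`` and ``mesh/`` plus a JSON manifest
attribute carrying seed, config and a format version that is checked on load.

Fields are exported as legacy ASCII VTK unstructured grids (ParaView-loadable)
with named point-data arrays; coordinates are written with 17 significant
digits so an export/import round trip reproduces them exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .design_space import DesignParams, DesignSpace, designs_to_array
from .exceptions import ConfigError, FormatError
from .leaflet_geometry import Contour2D, LeafletMesh2D
from .nn import MLP, Dense, L2Normalize, Standardize
from .surrogate_models import SurrogateModel
from .synthetic_fea import DATASET_VERSION, FieldDataset, SyntheticConfig

MODEL_VERSION = 1


# ---------------------------------------------------------------------------
# designs as CSV


def save_designs_csv(designs, path) -> None:
    import pandas as pd

    arr = designs_to_array(designs)
    frame = pd.DataFrame(arr, columns=["a", "b", "ssl"])
    frame.insert(0, "design_id", np.arange(len(designs)))
    frame.to_csv(path, index=False)


def load_designs_csv(path) -> list[DesignParams]:
    import pandas as pd

    frame = pd.read_csv(path)
    for col in ("a", "b", "ssl"):
        if col not in frame.columns:
            raise FormatError(f"designs CSV is missing column {col!r}")
    return [DesignParams(r.a, r.b, r.ssl) for r in frame.itertuples()]


# ---------------------------------------------------------------------------
# dataset container


def save_dataset(dataset: FieldDataset, path) -> None:
    mesh = dataset.mesh
    with h5py.File(path, "w") as f:
        f.attrs["version"] = DATASET_VERSION
        f.attrs["manifest"] = json.dumps(dataset.manifest)
        f.create_dataset("designs/params", data=dataset.design_array)
        f.create_dataset("shapes/coords", data=dataset.coords)
        f.create_dataset("stresses/components", data=dataset.stress)
        g = f.create_group("mesh")
        g.create_dataset("nodes", data=mesh.nodes)
        g.create_dataset("triangles", data=mesh.triangles)
        g.create_dataset("attachment_node_ids", data=mesh.attachment_node_ids)
        g.create_dataset("free_edge_node_ids", data=mesh.free_edge_node_ids)
        g.create_dataset("commissure_node_ids", data=np.array(mesh.commissure_node_ids))
        g.create_dataset("node_u", data=mesh.node_u)
        g.create_dataset("node_v", data=mesh.node_v)
        g.attrs["n_rows"] = mesh.n_rows
        g.attrs["n_cols"] = mesh.n_cols


def load_dataset(path) -> FieldDataset:
    if not Path(path).exists():
        raise FormatError(f"dataset file {path} does not exist")
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("version", -1))
        if version != DATASET_VERSION:
            raise FormatError(
                f"unsupported dataset version {version} (supported: {DATASET_VERSION})"
            )
        try:
            manifest = json.loads(f.attrs["manifest"])
            design_array = f["designs/params"][...]
            coords = f["shapes/coords"][...]
            stress = f["stresses/components"][...]
            g = f["mesh"]
            mesh = LeafletMesh2D(
                nodes=g["nodes"][...],
                triangles=g["triangles"][...],
                attachment_node_ids=g["attachment_node_ids"][...],
                free_edge_node_ids=g["free_edge_node_ids"][...],
                commissure_node_ids=tuple(int(i) for i in g["commissure_node_ids"][...]),
                node_u=g["node_u"][...],
                node_v=g["node_v"][...],
                n_rows=int(g.attrs["n_rows"]),
                n_cols=int(g.attrs["n_cols"]),
                contour=None,
            )
        except KeyError as err:
            raise FormatError(f"dataset file {path} is missing {err}") from err
    cfg = SyntheticConfig(
        pressure=manifest.get("pressure_mmHg", 120.0),
        noise_sd=manifest.get("noise_sd", 0.0),
        seed=manifest.get("seed", 0),
        stress_scale=tuple(manifest.get("stress_scale_kPa", (500.0, 120.0, 180.0))),
        low_rank=manifest.get("low_rank", False),
    )
    designs = [DesignParams(*row) for row in design_array]
    return FieldDataset(
        designs=designs,
        design_array=design_array,
        coords=coords,
        stress=stress,
        mesh=mesh,
        config=cfg,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# VTK / STL export


def export_vtk(nodes: np.ndarray, triangles: np.ndarray, point_fields: dict, path) -> None:
    """Write a legacy ASCII VTK unstructured grid with named point-data arrays.

    ``point_fields`` maps names to length-N scalars or (N, 3) vectors.  2D node
    arrays are padded with z = 0.
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 2 or nodes.shape[1] not in (2, 3):
        raise ConfigError("nodes must be (N, 2) or (N, 3)")
    if nodes.shape[1] == 2:
        nodes = np.column_stack([nodes, np.zeros(len(nodes))])
    triangles = np.asarray(triangles, dtype=int)
    n = len(nodes)
    for name, arr in point_fields.items():
        if np.asarray(arr).shape[0] != n:
            raise ConfigError(f"point field {name!r} length does not match node count")

    def fmt(row):
        return " ".join(f"{v:.17g}" for v in row)

    lines = [
        "# vtk DataFile Version 3.0",
        "tavsurrogate leaflet fields",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [fmt(p) for p in nodes]
    lines.append(f"CELLS {len(triangles)} {4 * len(triangles)}")
    lines += [f"3 {t[0]} {t[1]} {t[2]}" for t in triangles]
    lines.append(f"CELL_TYPES {len(triangles)}")
    lines += ["5"] * len(triangles)
    if point_fields:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_fields.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.17g}" for v in arr]
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [fmt(row) for row in arr]
            else:
                raise ConfigError(f"point field {name!r} must be (N,) or (N, 3)")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Read back a legacy ASCII VTK unstructured grid written by export_vtk."""
    tokens = Path(path).read_text().splitlines()
    nodes = triangles = None
    fields: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            nodes = np.array(
                [[float(v) for v in tokens[i + 1 + k].split()] for k in range(n)]
            )
            i += n
        elif line.startswith("CELLS"):
            m = int(line.split()[1])
            triangles = np.array(
                [[int(v) for v in tokens[i + 1 + k].split()[1:]] for k in range(m)]
            )
            i += m
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            n = len(nodes)
            fields[name] = np.array(
                [float(tokens[i + 2 + k]) for k in range(n)]
            )
            i += n + 1
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            n = len(nodes)
            fields[name] = np.array(
                [[float(v) for v in tokens[i + 1 + k].split()] for k in range(n)]
            )
            i += n
        i += 1
    if nodes is None:
        raise FormatError(f"{path} does not look like a legacy VTK file")
    return nodes, triangles, fields


def export_stl(nodes: np.ndarray, triangles: np.ndarray, path) -> None:
    """ASCII STL of the (possibly 3D) triangulated leaflet surface."""
    nodes = np.asarray(nodes, dtype=float)
    if nodes.shape[1] == 2:
        nodes = np.column_stack([nodes, np.zeros(len(nodes))])
    lines = ["solid leaflet"]
    for t in np.asarray(triangles, dtype=int):
        p0, p1, p2 = nodes[t]
        nvec = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(nvec)
        nvec = nvec / norm if norm > 0 else nvec
        lines.append(f"  facet normal {nvec[0]:.9g} {nvec[1]:.9g} {nvec[2]:.9g}")
        lines.append("    outer loop")
        for p in (p0, p1, p2):
            lines.append(f"      vertex {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid leaflet")
    Path(path).write_text("\n".join(lines) + "\n")


def export_contour_csv(contour: Contour2D, path) -> None:
    import pandas as pd

    att, free = contour.attachment_points, contour.free_edge_points
    frame = pd.DataFrame(
        {
            "edge": ["attachment"] * len(att) + ["free"] * len(free),
            "x": np.concatenate([att[:, 0], free[:, 0]]),
            "y": np.concatenate([att[:, 1], free[:, 1]]),
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model checkpoints


def save_model(model: SurrogateModel, directory) -> None:
    """Checkpoint = architecture JSON + weight arrays + scalers + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arch = []
    weights = {}
    for i, layer in enumerate(model.net.layers):
        if isinstance(layer, Dense):
            arch.append({"type": "dense", "activation": layer.activation,
                         "n_in": layer.W.shape[0], "n_out": layer.W.shape[1]})
            weights[f"W{i}"] = layer.W
            weights[f"b{i}"] = layer.b
        elif isinstance(layer, L2Normalize):
            arch.append({"type": "l2norm"})
        elif isinstance(layer, Standardize):
            arch.append({"type": "standardize", "dim": len(layer.mean)})
            weights[f"mean{i}"] = layer.mean
            weights[f"sd{i}"] = layer.sd
        else:  # pragma: no cover - no other layer types exist
            raise ConfigError(f"cannot serialize layer {type(layer).__name__}")
    (directory / "architecture.json").write_text(json.dumps(arch, indent=1))
    np.savez(directory / "weights.npz", **weights)
    np.savez(
        directory / "scalers.npz",
        y_mean=model.y_mean,
        y_std=model.y_std,
        lows=model.space.lows(),
        highs=model.space.highs(),
    )
    manifest = {"version": MODEL_VERSION, "kind": model.kind, **model.manifest}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def load_model(directory) -> SurrogateModel:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no model checkpoint at {directory}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("version") != MODEL_VERSION:
        raise FormatError(f"unsupported model version {manifest.get('version')}")
    arch = json.loads((directory / "architecture.json").read_text())
    weights = np.load(directory / "weights.npz")
    scalers = np.load(directory / "scalers.npz")
    layers: list = []
    for i, spec in enumerate(arch):
        if spec["type"] == "dense":
            layer = Dense(spec["n_in"], spec["n_out"], spec["activation"])
            layer.W = weights[f"W{i}"]
            layer.b = weights[f"b{i}"]
        elif spec["type"] == "l2norm":
            layer = L2Normalize()
        else:
            layer = Standardize(spec["dim"])
            layer.mean = weights[f"mean{i}"]
            layer.sd = weights[f"sd{i}"]
        layers.append(layer)
    bounds = dict(zip(("a", "b", "ssl"), zip(scalers["lows"], scalers["highs"])))
    return SurrogateModel(
        kind=manifest["kind"],
        net=MLP(layers),
        space=DesignSpace({k: (float(lo), float(hi)) for k, (lo, hi) in bounds.items()}),
        y_mean=scalers["y_mean"],
        y_std=scalers["y_std"],
        manifest=manifest,
    )
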
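"""Readers/writers for the formats the pipeline touches.

The primary, fully round-tripped representation of every artifact is plain
text: TSV tables with JSON sidecars for metadata. Neuroimaging container
formats are supported through nibabel where a practitioner would expect them:
GIFTI surfaces and label maps (read and write), CIFTI-2 dense timeseries
(read). Round-trips are bit-exact for integer labels and within 1e-6 for
floats.

TSV column schemas
------------------
node space      : ``node_id  x  y  z  area  structure`` plus an ``.edges.tsv``
                  companion with columns ``node_a  node_b``
timeseries      : one row per node, one column per frame, no header; a
                  ``.json`` sidecar carries ``subject_id``, ``tr``,
                  ``run_boundaries``
label map       : ``node_id  label``; a ``.json`` sidecar carries the label
                  table ``{label: [name, color]}``
meta-analytic   : activations ``study_id  x  y  z``; features: ``study_id``
                  column followed by one column per term, weights in [0, 1]
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from subnets.spaces import STRUCTURE_TAGS, LabelMap, NodeSpace, Timeseries


class FormatError(ValueError):
    """Malformed input file; the message names the file and offending axis/row."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


# -- node spaces -------------------------------------------------------------

def write_nodespace_tsv(space: NodeSpace, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "node_id": np.arange(space.n_nodes),
            "x": space.coords[:, 0],
            "y": space.coords[:, 1],
            "z": space.coords[:, 2],
            "area": space.area,
            "structure": space.structure,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    edges = pd.DataFrame(space.edges, columns=["node_a", "node_b"])
    edges.to_csv(path.with_suffix(".edges.tsv"), sep="\t", index=False)
    _sidecar(path).write_text(json.dumps({"space": space.space}) + "\n")


def read_nodespace_tsv(path: str | Path) -> NodeSpace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"node_id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric coordinate in column {col!r} at row "
                f"{int(bad.index[0])}"
            )
    df = df.sort_values("node_id").reset_index(drop=True)
    if not np.array_equal(df["node_id"].to_numpy(), np.arange(len(df))):
        raise FormatError(f"{path}: node_id must be contiguous 0..N-1")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    area = df["area"].to_numpy(dtype=float) if "area" in df.columns else None
    structure = df["structure"].to_numpy(dtype=object) if "structure" in df.columns else None
    edge_path = path.with_suffix(".edges.tsv")
    if edge_path.exists():
        edf = pd.read_csv(edge_path, sep="\t")
        edges = edf[["node_a", "node_b"]].to_numpy(dtype=int)
    else:
        edges = np.empty((0, 2), dtype=int)
    space_name = "MNI152"
    if _sidecar(path).exists():
        space_name = json.loads(_sidecar(path).read_text()).get("space", space_name)
    return NodeSpace(coords=coords, edges=edges, area=area, structure=structure, space=space_name)


def read_nodespace_gifti(surf_path: str | Path, space: str = "MNI152") -> NodeSpace:
    """Node space from a GIFTI surface: vertices + triangle-derived edges.

    Per-vertex area is one third of the summed area of incident triangles.
    """
    import nibabel as nib

    img = nib.load(str(surf_path))
    coords = tris = None
    for da in img.darrays:
        intent = da.intent
        if intent == 1008:  # NIFTI_INTENT_POINTSET
            coords = np.asarray(da.data, dtype=float)
        elif intent == 1009:  # NIFTI_INTENT_TRIANGLE
            tris = np.asarray(da.data, dtype=int)
    if coords is None or tris is None:
        raise FormatError(f"{surf_path}: GIFTI surface needs POINTSET and TRIANGLE arrays")
    edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [0, 2]]])
    a, b, c = coords[tris[:, 0]], coords[tris[:, 1]], coords[tris[:, 2]]
    tri_area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    area = np.zeros(len(coords))
    for k in range(3):
        np.add.at(area, tris[:, k], tri_area / 3.0)
    return NodeSpace(coords=coords, edges=edges, area=area, space=space)


# -- timeseries --------------------------------------------------------------

def write_timeseries_tsv(ts: Timeseries, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.8g")
    _sidecar(path).write_text(
        json.dumps(
            {
                "subject_id": ts.subject_id,
                "tr": ts.tr,
                "run_boundaries": list(ts.run_boundaries),
            }
        )
        + "\n"
    )


def read_timeseries_tsv(path: str | Path, space: NodeSpace | None = None) -> Timeseries:
    path = Path(path)
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise FormatError(f"{path}: missing sidecar {meta_path.name} (subject_id, tr)")
    meta = json.loads(meta_path.read_text())
    ts = Timeseries(
        subject_id=meta["subject_id"],
        values=values,
        tr=float(meta["tr"]),
        run_boundaries=tuple(meta.get("run_boundaries", [0])),
    )
    if space is not None and ts.n_nodes != space.n_nodes:
        raise FormatError(
            f"{path}: node axis has {ts.n_nodes} rows but node space has "
            f"{space.n_nodes} nodes"
        )
    return ts


def read_timeseries_cifti(path: str | Path, subject_id: str | None = None) -> Timeseries:
    """Dense timeseries from a CIFTI-2 .dtseries.nii (greyordinates x time)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())  # time x greyordinate
    ax0 = img.header.get_axis(0)
    try:
        tr = float(ax0.step)
    except AttributeError as exc:
        raise FormatError(f"{path}: first CIFTI axis is not a series axis") from exc
    return Timeseries(
        subject_id=subject_id or Path(path).stem,
        values=data.T,
        tr=tr,
    )


# -- label maps --------------------------------------------------------------

def write_labelmap_tsv(lm: LabelMap, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"node_id": np.arange(lm.n_nodes), "label": lm.labels}
    ).to_csv(path, sep="\t", index=False)
    table = {str(k): list(v) for k, v in lm.label_table.items()}
    _sidecar(path).write_text(json.dumps({"label_table": table}, indent=0) + "\n")


def read_labelmap_tsv(path: str | Path, space: NodeSpace | None = None) -> LabelMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if not {"node_id", "label"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns node_id, label")
    df = df.sort_values("node_id")
    labels = df["label"].to_numpy(dtype=int)
    table: dict[int, tuple[str, str]] = {}
    meta_path = _sidecar(path)
    if meta_path.exists():
        raw = json.loads(meta_path.read_text()).get("label_table", {})
        table = {int(k): tuple(v) for k, v in raw.items()}
    lm = LabelMap(labels=labels, label_table=table)
    if space is not None and lm.n_nodes != space.n_nodes:
        raise FormatError(
            f"{path}: label axis has {lm.n_nodes} nodes but node space has "
            f"{space.n_nodes}"
        )
    return lm


def write_labelmap_gifti(lm: LabelMap, path: str | Path) -> None:
    import nibabel as nib
    from nibabel.gifti import GiftiDataArray, GiftiImage, GiftiLabel, GiftiLabelTable

    table = GiftiLabelTable()
    table.labels.append(GiftiLabel(key=0, red=1, green=1, blue=1, alpha=0))
    table.labels[-1].label = "???"
    for key, (name, _color) in sorted(lm.label_table.items()):
        gl = GiftiLabel(key=int(key), red=0.5, green=0.5, blue=0.5, alpha=1)
        gl.label = name
        table.labels.append(gl)
    da = GiftiDataArray(lm.labels.astype(np.int32), intent="NIFTI_INTENT_LABEL")
    img = GiftiImage(darrays=[da], labeltable=table)
    nib.save(img, str(path))


def read_labelmap_gifti(path: str | Path) -> LabelMap:
    import nibabel as nib

    img = nib.load(str(path))
    if not img.darrays:
        raise FormatError(f"{path}: GIFTI label file has no data arrays")
    labels = np.asarray(img.darrays[0].data, dtype=int)
    table: dict[int, tuple[str, str]] = {}
    if img.labeltable is not None:
        for gl in img.labeltable.labels:
            if gl.key != 0:
                table[int(gl.key)] = (gl.label or f"label_{gl.key}", "#808080")
    return LabelMap(labels=labels, label_table=table)


# -- meta-analytic tables ----------------------------------------------------

def write_meta_tables(
    activations: pd.DataFrame, features: pd.DataFrame, prefix: str | Path
) -> tuple[Path, Path]:
    prefix = Path(prefix)
    act_path = prefix.with_name(prefix.name + "_activations.tsv")
    feat_path = prefix.with_name(prefix.name + "_features.tsv")
    activations.to_csv(act_path, sep="\t", index=False, float_format="%.8g")
    features.to_csv(feat_path, sep="\t", index=False, float_format="%.8g")
    return act_path, feat_path


def read_meta_tables(
    activations_path: str | Path, features_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    act = pd.read_csv(activations_path, sep="\t")
    missing = {"study_id", "x", "y", "z"} - set(act.columns)
    if missing:
        raise FormatError(f"{activations_path}: missing columns {sorted(missing)}")
    feat = pd.read_csv(features_path, sep="\t")
    if "study_id" not in feat.columns:
        raise FormatError(f"{features_path}: missing study_id column")
    return act, feat


# -- generic helpers ---------------------------------------------------------

def write_density_map_tsv(counts: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"node_id": np.arange(len(counts)), "count": np.asarray(counts, dtype=int)}
    ).to_csv(path, sep="\t", index=False)


def read_density_map_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t").sort_values("node_id")
    return df["count"].to_numpy(dtype=int)
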
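"""Reading and writing the on-disk formats.

Features travel as HDF5 (datasets ``features`` and ``object_ids``), NPY with
a sidecar id list, or CSV with the id in the first column. Gold labels and
cluster assignments are two-column TSV tables; run traces are JSON lines.
Assignment files may carry ``#``-prefixed comment headers (the experiment
runner stamps the config hash and seed there).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import EmbeddingSet, FormatError


def _sidecar_ids_path(path: Path) -> Path:
    return path.with_suffix(".ids.txt")


def save_features(dataset: EmbeddingSet, path: str | Path) -> None:
    """Write features + ids in the format implied by the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    ids = np.asarray(dataset.object_ids).astype(str)
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=dataset.features)
            f.create_dataset(
                "object_ids", data=np.array(ids, dtype=h5py.string_dtype())
            )
    elif suffix == ".npy":
        np.save(path, dataset.features)
        _sidecar_ids_path(path).write_text("\n".join(ids) + "\n")
    elif suffix == ".csv":
        df = pd.DataFrame(dataset.features)
        df.insert(0, "object_id", ids)
        df.to_csv(path, index=False)
    else:
        raise FormatError(f"unsupported feature file suffix: {suffix}")


def load_features(path: str | Path, labels_path: str | Path | None = None) -> EmbeddingSet:
    """Load an :class:`EmbeddingSet`, optionally attaching a gold-label TSV.

    Row order is preserved and ids are checked unique. The label table must
    cover exactly the loaded ids; a mismatch is a format error naming both
    counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            features = np.asarray(f["features"])
            ids = np.array([x.decode() if isinstance(x, bytes) else str(x) for x in f["object_ids"][()]], dtype=object)
    elif suffix == ".npy":
        features = np.load(path)
        sidecar = _sidecar_ids_path(path)
        if not sidecar.exists():
            raise FormatError(f"missing sidecar id list {sidecar}")
        ids = np.array(sidecar.read_text().splitlines(), dtype=object)
    elif suffix == ".csv":
        df = pd.read_csv(path)
        ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
        features = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    else:
        raise FormatError(f"unsupported feature file suffix: {suffix}")

    gold = None
    if labels_path is not None:
        label_map = read_labels(labels_path)
        missing = [i for i in ids if i not in label_map]
        if missing:
            raise FormatError(
                f"label table covers {len(label_map)} ids but features have "
                f"{len(ids)}; first missing id: {missing[0]}"
            )
        gold = np.array([label_map[i] for i in ids], dtype=object)
    return EmbeddingSet(object_ids=ids, features=features, gold_labels=gold)


def write_labels(dataset: EmbeddingSet, path: str | Path) -> None:
    if dataset.gold_labels is None:
        raise FormatError("dataset has no gold labels to write")
    pd.DataFrame(
        {"object_id": dataset.object_ids.astype(str), "label": dataset.gold_labels}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"object_id", "label"}.issubset(df.columns):
        raise FormatError("label TSV needs columns object_id and label")
    return dict(zip(df["object_id"], df["label"]))


def write_assignment(
    object_ids: np.ndarray,
    labels: np.ndarray,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Object/cluster TSV; UNASSIGNED objects get an empty cluster field."""
    path = Path(path)
    with open(path, "w") as f:
        if header_comment:
            f.write(f"# {header_comment}\n")
        f.write("object_id\tcluster_id\n")
        for oid, lab in zip(object_ids, labels):
            f.write(f"{oid}\t{'' if lab < 0 else int(lab)}\n")


def read_assignment(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"object_id": str}, keep_default_na=False
    )
    df["cluster_id"] = [
        -1 if str(c) == "" else int(c) for c in df["cluster_id"]
    ]
    return df


def write_rejections(rejections, object_ids: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as f:
        f.write("object_id\tcluster_id\n")
        for obj, cid in rejections.pairs():
            f.write(f"{object_ids[obj]}\t{cid}\n")


def write_trace(trace: list[dict], path: str | Path) -> None:
    with open(path, "w") as f:
        for record in trace:
            f.write(json.dumps(record) + "\n")


def read_trace(path: str | Path) -> list[dict]:
    with open(path) as f:
        return [json.loads(line) for line in f if line.strip()]


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
        f.write("\n")
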
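"""Persistence of fitted retrieval indexes and PNG image/mask round-trips.

A model directory holds ``meta.json`` (configuration, code length, ids,
labels, bandwidths) plus ``arrays.npz`` with the numeric payload (anchors,
coefficients, biases, centers, assignments, packed codes, standardizer).
Images travel as 8-bit grayscale PNGs with a companion binary mask PNG and a
``labels.csv`` table (columns: id, label).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .clustering import ClusterModel
from .features import FeatureConfig, SignThresholds, Standardizer
from .hashing import HashModel
from .retrieval import HashDatabase
from .synthetic import NoduleImage

_META = "meta.json"
_ARRAYS = "arrays.npz"


# ---------------------------------------------------------------------------
# model directory


def save_results(results, directory) -> None:
    from .model import NoduleRetrievalResults  # noqa: F401  (type of `results`)

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    db = results.db
    fc = db.feature_config
    meta = {
        "format": "nodulehash-model-v1",
        "r": db.hash_model.r,
        "sigma": db.hash_model.sigma,
        "k": db.clusters.k,
        "delta": db.clusters.delta,
        "seed": results.seed,
        "ids": db.ids.tolist(),
        "labels": db.labels.tolist(),
        "feature_config": {
            "k_levels": fc.k_levels,
            "distance": fc.distance,
            "tau_cal": fc.thresholds.tau_cal,
            "tau_cav": fc.thresholds.tau_cav,
        },
    }
    (d / _META).write_text(json.dumps(meta, indent=2))
    arrays = {
        "anchors": db.hash_model.anchors,
        "A": db.hash_model.A,
        "bias": db.hash_model.bias,
        "kernel_mean": db.hash_model.kernel_mean,
        "centers": db.clusters.centers,
        "assignments": db.clusters.assignments,
        "cluster_ids": db.cluster_ids,
        "codes": db.codes,
        "std_mean": db.standardizer.mean,
        "std_scale": db.standardizer.scale,
    }
    np.savez_compressed(d / _ARRAYS, **arrays)


def load_results(directory):
    from .model import NoduleRetrievalResults

    d = Path(directory)
    meta = json.loads((d / _META).read_text())
    if meta.get("format") != "nodulehash-model-v1":
        raise ValueError(f"unrecognized model directory format in {d}")
    with np.load(d / _ARRAYS) as z:
        arrays = {k: z[k] for k in z.files}
    fc = meta["feature_config"]
    feature_config = FeatureConfig(
        k_levels=int(fc["k_levels"]),
        distance=int(fc["distance"]),
        thresholds=SignThresholds(tau_cal=fc["tau_cal"], tau_cav=fc["tau_cav"]),
    )
    hash_model = HashModel(
        anchors=arrays["anchors"],
        A=arrays["A"],
        sigma=float(meta["sigma"]),
        bias=arrays["bias"],
        r=int(meta["r"]),
        kernel_mean=arrays["kernel_mean"],
    )
    clusters = ClusterModel(
        centers=arrays["centers"],
        assignments=arrays["assignments"].astype(int),
        delta=float(meta["delta"]),
        k=int(meta["k"]),
    )
    db = HashDatabase(
        ids=np.asarray(meta["ids"], dtype=str),
        codes=arrays["codes"],
        labels=np.asarray(meta["labels"], dtype=int),
        cluster_ids=arrays["cluster_ids"].astype(int),
        clusters=clusters,
        hash_model=hash_model,
        standardizer=Standardizer(mean=arrays["std_mean"], scale=arrays["std_scale"]),
        feature_config=feature_config,
    )
    return NoduleRetrievalResults(model=None, db=db, diagnostics=None, seed=int(meta["seed"]))


# ---------------------------------------------------------------------------
# images


def write_image_pair(img: NoduleImage, directory) -> tuple[Path, Path]:
    """Write ``<id>_img.png`` and ``<id>_mask.png`` as 8-bit grayscale PNGs."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    img_path = d / f"{img.id}_img.png"
    mask_path = d / f"{img.id}_mask.png"
    Image.fromarray(np.round(img.pixels * 255).astype(np.uint8), mode="L").save(img_path)
    Image.fromarray((img.mask.astype(np.uint8)) * 255, mode="L").save(mask_path)
    return img_path, mask_path


def read_image_pair(img_path, mask_path, label: int = 0, image_id: str | None = None) -> NoduleImage:
    """Read a grayscale image (8/16-bit PNG or TIFF) plus its binary mask.

    Intensities are rescaled to [0, 1] by the container's full range; any
    nonzero mask pixel is foreground.
    """
    im = Image.open(img_path)
    arr = np.asarray(im, dtype=float)
    if arr.ndim == 3:  # tolerate grayscale saved with redundant channels
        arr = arr[..., 0]
    full = 65535.0 if arr.max() > 255 else 255.0
    pixels = np.clip(arr / full, 0.0, 1.0)
    mask = np.asarray(Image.open(mask_path)) > 0
    if mask.ndim == 3:
        mask = mask[..., 0]
    if image_id is None:
        image_id = Path(img_path).stem.removesuffix("_img")
    return NoduleImage(pixels=pixels, mask=mask, label=int(label), id=image_id)


def write_dataset(images: list[NoduleImage], directory) -> Path:
    """Write every image pair plus ``labels.csv`` (columns: id, label)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for img in images:
        write_image_pair(img, d)
    table = pd.DataFrame({"id": [i.id for i in images], "label": [i.label for i in images]})
    out = d / "labels.csv"
    table.to_csv(out, index=False)
    return out


def read_dataset(directory) -> list[NoduleImage]:
    """Read back a directory written by :func:`write_dataset`."""
    d = Path(directory)
    table = pd.read_csv(d / "labels.csv")
    return [
        read_image_pair(d / f"{row.id}_img.png", d / f"{row.id}_mask.png", row.label, row.id)
        for row in table.itertuples()
    ]
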
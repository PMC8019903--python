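"""End-to-end plumbing: raw inputs -> feature views -> datasets -> models.

This module glues the encoders of :mod:`melmp.seqfeat` to the learning
stack: it featurizes a set of proteins into the four aligned view matrices,
reads/writes feature TSVs, assembles :class:`~melmp.learners.LabeledDataset`
objects, and persists/loads stacked models.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError, MelmpError
from .fusion import VIEW_ORDER, StackedModel
from .learners import LabeledDataset, TrainedSubModel
from .seqfeat import (
    AcfParams,
    ProfileMatrix,
    PropertyTable,
    ProteinRecord,
    aa_features,
    pssm_aggregate,
    read_ascii_pssm,
    read_fasta,
    read_property_table,
    read_ss_file,
    seq_features,
    ss_features,
)


def featurize_records(
    records: list[ProteinRecord],
    profiles: dict[str, ProfileMatrix],
    table: PropertyTable,
    ss_map: dict[str, str],
    acf: AcfParams = AcfParams(),
) -> dict[str, np.ndarray]:
    """Compute the four view matrices for aligned records."""
    seq_rows, pssm_rows, aa_rows, ss_rows = [], [], [], []
    for rec in records:
        if rec.id not in profiles:
            raise MelmpError(f"no profile for protein {rec.id!r}")
        if rec.id not in ss_map:
            raise MelmpError(f"no secondary-structure string for {rec.id!r}")
        seq_rows.append(seq_features(rec, acf).values)
        pssm_rows.append(pssm_aggregate(profiles[rec.id]).values)
        aa_rows.append(aa_features(rec, table).values)
        ss_rows.append(ss_features(ss_map[rec.id]).values)
    return {
        "Seq": np.vstack(seq_rows),
        "PSSM": np.vstack(pssm_rows),
        "AA": np.vstack(aa_rows),
        "SS": np.vstack(ss_rows),
    }


def read_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if not {"id", "label"} <= set(df.columns):
        raise FormatError(f"{Path(path).name}: expected columns 'id' and 'label'")
    return dict(zip(df["id"].astype(str), df["label"].astype(int)))


def build_dataset(
    fasta: str | Path,
    pssm_dir: str | Path,
    aaindex: str | Path,
    ss: str | Path,
    labels: str | Path | dict[str, int] | None = None,
    acf: AcfParams = AcfParams(),
) -> tuple[LabeledDataset, list[ProteinRecord]]:
    """Featurize a raw input bundle into an aligned dataset.

    Without labels, all labels are set to -1 (prediction-only use).
    """
    records = read_fasta(fasta)
    profiles = {
        rec.id: read_ascii_pssm(Path(pssm_dir) / f"{rec.id}.pssm") for rec in records
    }
    table = read_property_table(aaindex)
    ss_map = read_ss_file(ss)
    views = featurize_records(records, profiles, table, ss_map, acf)
    if labels is None:
        y = np.full(len(records), -1)
    else:
        label_map = labels if isinstance(labels, dict) else read_labels(labels)
        missing = [r.id for r in records if r.id not in label_map]
        if missing:
            raise MelmpError(f"no label for records {missing[:5]}")
        y = np.array([label_map[r.id] for r in records])
    return (
        LabeledDataset(ids=[r.id for r in records], views=views, labels=y),
        records,
    )


# ---------------------------------------------------------------------------
# feature TSV round trip


def write_features_tsv(
    ids: list[str], matrix: np.ndarray, view: str, path: str | Path
) -> None:
    """Write one view as TSV: id column plus ``<view>_0001...`` columns."""
    cols = [f"{view}_{i + 1:04d}" for i in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=cols)
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_features_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise FormatError(f"{Path(path).name}: missing 'id' column")
    ids = df["id"].astype(str).tolist()
    return ids, df.drop(columns="id").to_numpy(dtype=float)


def write_feature_dir(data: LabeledDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for view in VIEW_ORDER:
        write_features_tsv(data.ids, data.views[view], view, outdir / f"{view}.tsv")


def read_feature_dir(
    feature_dir: str | Path, labels: str | Path | dict[str, int] | None = None
) -> LabeledDataset:
    feature_dir = Path(feature_dir)
    ids = None
    views = {}
    for view in VIEW_ORDER:
        vids, mat = read_features_tsv(feature_dir / f"{view}.tsv")
        if ids is None:
            ids = vids
        elif vids != ids:
            raise MelmpError(f"view {view}: id order differs from other views")
        views[view] = mat
    if labels is None:
        y = np.full(len(ids), -1)
    else:
        label_map = labels if isinstance(labels, dict) else read_labels(labels)
        y = np.array([label_map[i] for i in ids])
    return LabeledDataset(ids=ids, views=views, labels=y)


# ---------------------------------------------------------------------------
# model persistence


def save_stacked(model: StackedModel, outdir: str | Path) -> None:
    """Persist a stacked model: JSON metadata plus serialized sub-models."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "package_version": __version__,
        "meta_kind": model.meta_kind,
        "threshold": model.threshold,
        "intercept": model.intercept,
        "weights": model.weights.tolist(),
        "views": {
            view: {
                "n_features": sm.n_features,
                "family": sm.spec.resolved_family(),
                "seed": sm.spec.seed,
            }
            for view, sm in model.submodels.items()
        },
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    for view, sm in model.submodels.items():
        joblib.dump(sm, outdir / f"submodel_{view}.joblib")


def load_stacked(model_dir: str | Path) -> StackedModel:
    """Load a persisted stacked model, checking the metadata for consistency."""
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "metadata.json").read_text())
    if meta.get("format_version") != 1:
        raise FormatError(f"unsupported model format {meta.get('format_version')}")
    submodels: dict[str, TrainedSubModel] = {}
    for view, info in meta["views"].items():
        sm = joblib.load(model_dir / f"submodel_{view}.joblib")
        if sm.n_features != info["n_features"]:
            raise MelmpError(
                f"view {view}: serialized feature length {sm.n_features} "
                f"does not match metadata {info['n_features']}"
            )
        submodels[view] = sm
    return StackedModel(
        submodels=submodels,
        weights=np.asarray(meta["weights"]),
        intercept=meta["intercept"],
        meta_kind=meta["meta_kind"],
        threshold=meta["threshold"],
    )
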
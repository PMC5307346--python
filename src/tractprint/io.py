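"""File formats: NIfTI-1 volumes, TSV tables, JSON sidecars.

Conventions
-----------
* A :class:`~tractprint.volumes.LabelVolume` is a NIfTI file (integer
  datatype) plus a label-table TSV with columns
  ``label, region_name, hemisphere, tissue_class``.
* A :class:`~tractprint.volumes.SeedTemplate` is a uint8 NIfTI mask plus a
  JSON sidecar carrying name / provenance / hemisphere.
* :class:`~tractprint.synthetic.StreamlineSamples` are a long-form TSV
  ``subject_id, seed_voxel_index, target_label, count`` (zero counts
  omitted) plus a JSON sidecar with S, the grid shape, and the full seed
  voxel list; unreached mass is reconstructed as ``S - sum(counts)``.
* Fingerprints, consistency tables and sub-parcellation assignments are
  plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fingerprint import FingerprintMatrix
from .group import GroupConsistencyTable
from .synthetic import StreamlineSamples
from .volumes import LabelVolume, OverlapReport, RegionInfo, SeedTemplate


# -- label volumes ----------------------------------------------------------

def save_label_volume(volume: LabelVolume, nifti_path, table_path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.int32), volume.affine)
    nib.save(img, str(nifti_path))
    rows = [
        {
            "label": lab,
            "region_name": info.name,
            "hemisphere": info.hemisphere,
            "tissue_class": info.tissue_class,
        }
        for lab, info in sorted(volume.label_table.items())
    ]
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def load_label_volume(nifti_path, table_path) -> LabelVolume:
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(table_path, sep="\t")
    label_table = {
        int(r.label): RegionInfo(str(r.region_name), str(r.hemisphere),
                                 str(r.tissue_class))
        for r in table.itertuples()
    }
    return LabelVolume(data=data, affine=np.asarray(img.affine),
                       label_table=label_table)


# -- seed templates ---------------------------------------------------------

def save_template(template: SeedTemplate, nifti_path, sidecar_path) -> None:
    img = nib.Nifti1Image(template.mask.astype(np.uint8), np.eye(4))
    nib.save(img, str(nifti_path))
    Path(sidecar_path).write_text(json.dumps(
        {
            "name": template.name,
            "provenance": template.provenance,
            "hemisphere": template.hemisphere,
        },
        indent=2,
    ))


def load_template(nifti_path, sidecar_path) -> SeedTemplate:
    img = nib.load(str(nifti_path))
    meta = json.loads(Path(sidecar_path).read_text())
    return SeedTemplate(
        mask=np.asarray(img.dataobj) > 0,
        name=meta["name"],
        provenance=meta["provenance"],
        hemisphere=meta["hemisphere"],
    )


# -- streamline samples -----------------------------------------------------

def save_samples(samples: StreamlineSamples, tsv_path, sidecar_path) -> None:
    vox_rep = np.repeat(samples.voxel_index, samples.region_labels.size)
    lab_rep = np.tile(samples.region_labels, samples.voxel_index.size)
    cnt = samples.counts.ravel()
    nz = cnt > 0
    pd.DataFrame(
        {
            "subject_id": samples.subject_id,
            "seed_voxel_index": vox_rep[nz],
            "target_label": lab_rep[nz],
            "count": cnt[nz],
        }
    ).to_csv(tsv_path, sep="\t", index=False)
    Path(sidecar_path).write_text(json.dumps(
        {
            "subject_id": samples.subject_id,
            "S": int(samples.S),
            "grid_shape": list(samples.grid_shape),
            "voxel_index": samples.voxel_index.tolist(),
            "region_labels": samples.region_labels.tolist(),
        }
    ))


def load_samples(tsv_path, sidecar_path) -> StreamlineSamples:
    meta = json.loads(Path(sidecar_path).read_text())
    voxels = np.asarray(meta["voxel_index"], dtype=np.int64)
    labels = np.asarray(meta["region_labels"], dtype=np.int64)
    counts = np.zeros((voxels.size, labels.size), dtype=np.int64)
    table = pd.read_csv(tsv_path, sep="\t")
    rows = np.searchsorted(voxels, table["seed_voxel_index"].to_numpy())
    cols = np.searchsorted(labels, table["target_label"].to_numpy())
    counts[rows, cols] = table["count"].to_numpy()
    return StreamlineSamples(
        subject_id=meta["subject_id"],
        S=int(meta["S"]),
        grid_shape=tuple(meta["grid_shape"]),
        voxel_index=voxels,
        region_labels=labels,
        counts=counts,
        unreached=meta["S"] - counts.sum(axis=1),
    )


# -- fingerprints and tables ------------------------------------------------

def save_fingerprint(matrix: FingerprintMatrix, path) -> None:
    rows = []
    for i, seed in enumerate(matrix.seed_entities):
        for j, lab in enumerate(matrix.region_labels.tolist()):
            rows.append(
                {
                    "subject_id": matrix.subject_id,
                    "seed_entity": seed,
                    "target_label": lab,
                    "target_region": matrix.region_names[j],
                    "streamline_count": int(matrix.counts[i, j]),
                    "value": float(matrix.values[i, j]),
                    "stage": matrix.stage,
                    "seed_size": int(matrix.seed_sizes[i]),
                    "S": int(matrix.S),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_fingerprint(path) -> FingerprintMatrix:
    table = pd.read_csv(path, sep="\t")
    seeds = list(dict.fromkeys(table.seed_entity))
    labels = np.sort(table.target_label.unique())
    names: dict[int, str] = {}
    counts = np.zeros((len(seeds), labels.size), dtype=np.int64)
    values = np.zeros((len(seeds), labels.size))
    sizes = np.zeros(len(seeds), dtype=np.int64)
    for r in table.itertuples():
        i = seeds.index(r.seed_entity)
        j = int(np.searchsorted(labels, r.target_label))
        counts[i, j] = r.streamline_count
        values[i, j] = r.value
        sizes[i] = r.seed_size
        names[int(r.target_label)] = str(r.target_region)
    return FingerprintMatrix(
        seed_entities=seeds,
        region_labels=labels,
        region_names=[names[int(l)] for l in labels],
        counts=counts,
        values=values,
        seed_sizes=sizes,
        S=int(table.S.iloc[0]),
        stage=str(table.stage.iloc[0]),
        subject_id=str(table.subject_id.iloc[0]),
    )


def save_overlap_report(report: OverlapReport, path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)


def save_consistency_table(table: GroupConsistencyTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def load_consistency_table(path, group_frac: float) -> GroupConsistencyTable:
    return GroupConsistencyTable(frame=pd.read_csv(path, sep="\t"),
                                 group_frac=group_frac)
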
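"""Geometry layer: labelled volumes, seed templates and template surgery.

All volumes in a pipeline run live on one shared voxel grid; registration
and resampling between grids are deliberately out of scope, so grid
identity is enforced with a strict shape check rather than an affine
comparison.  Voxel indices are 0-based and masks/labels are
nearest-neighbour valued (a voxel belongs to exactly one region; there are
no partial-volume fractions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

HEMISPHERES = ("left", "right", "midline")
TISSUE_CLASSES = ("grey", "white", "csf", "background")
PROVENANCES = ("functional", "structural", "merged", "cleansed")

#: row names used for aggregate (non-region) entries of an overlap report
WHITE_MATTER_ROW = "white matter"
CSF_ROW = "csf"
UNLABELLED_ROW = "unlabelled"


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


@dataclass(frozen=True)
class RegionInfo:
    """Metadata for one labelled region."""

    name: str
    hemisphere: str
    tissue_class: str

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")


@dataclass
class LabelVolume:
    """A 3-D integer-labelled image with a label table.

    Parameters
    ----------
    data
        3-D array of non-negative integer labels.  Label 0 is background /
        unlabelled and never appears in ``label_table``.
    affine
        4x4 voxel-to-world map (NIfTI convention).
    label_table
        Mapping label -> :class:`RegionInfo` for every nonzero label that
        occurs in ``data``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label_table: dict[int, RegionInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label data must be a 3-D array")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer-valued")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if 0 in self.label_table:
            raise ValueError("label 0 is background and may not be listed")
        present = set(np.unique(self.data).tolist()) - {0}
        listed = set(self.label_table)
        if present - listed:
            raise ValueError(f"unlisted labels in data: {sorted(present - listed)}")
        if listed - present:
            raise ValueError(
                f"listed regions with zero voxels: {sorted(listed - present)}"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def labels(self) -> list[int]:
        return sorted(self.label_table)

    def region_voxel_counts(self) -> dict[int, int]:
        """Number of voxels per listed label (``n_r``)."""
        values, counts = np.unique(self.data[self.data > 0], return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def label_of(self, name: str) -> int:
        for lab, info in self.label_table.items():
            if info.name == name:
                return lab
        raise KeyError(f"no region named {name!r}")

    def mask_of(self, label: int) -> np.ndarray:
        if label not in self.label_table:
            raise KeyError(f"label {label} not in label table")
        return self.data == label

    def labels_with_tissue(self, tissue_class: str) -> list[int]:
        return sorted(
            lab for lab, info in self.label_table.items()
            if info.tissue_class == tissue_class
        )

    def grey_mask(self) -> np.ndarray:
        """Boolean mask of voxels belonging to any grey-matter region."""
        grey = self.labels_with_tissue("grey")
        return np.isin(self.data, grey)


@dataclass
class SeedTemplate:
    """Binary seed mask on the grid of a reference :class:`LabelVolume`."""

    mask: np.ndarray
    name: str
    provenance: str
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("template mask must be a 3-D array")
        if not self.mask.any():
            raise ValueError(f"template {self.name!r} has no voxels set")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"template hemisphere must be left or right")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_indices(self) -> np.ndarray:
        """Flat (raveled, C-order) indices of the set voxels, ascending."""
        return np.flatnonzero(self.mask.ravel())


@dataclass
class OverlapReport:
    """Where a seed template's voxels fall on an atlas.

    ``rows`` maps a region name (or the aggregate rows ``"white matter"``,
    ``"csf"``, ``"unlabelled"``) to the exact fraction of template voxels it
    holds; presentation rounding happens only in :meth:`formatted`.
    """

    rows: list[tuple[str, float]]
    total_voxels: int
    template_name: str = ""
    atlas_like: str = ""

    def fraction(self, row_name: str) -> float:
        for name, frac in self.rows:
            if name == row_name:
                return frac
        return 0.0

    def formatted(self) -> list[tuple[str, str]]:
        """Rows with percentages rounded to integers; nonzero fractions
        rounding to 0 are rendered ``"< 1%"``."""
        out = []
        for name, frac in self.rows:
            pct = frac * 100.0
            rounded = int(np.floor(pct + 0.5))
            if rounded == 0 and pct > 0:
                out.append((name, "< 1%"))
            else:
                out.append((name, f"{rounded}%"))
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "row": [n for n, _ in self.rows],
                "fraction": [f for _, f in self.rows],
                "percent": [p for _, p in self.formatted()],
            }
        )


def _check_shared_grid(template: SeedTemplate, atlas: LabelVolume) -> None:
    if template.grid_shape != atlas.grid_shape:
        raise GridMismatchError(
            f"template grid {template.grid_shape} != atlas grid {atlas.grid_shape}"
        )


def overlap_table(template: SeedTemplate, atlas: LabelVolume) -> OverlapReport:
    """Audit where a seed template sits on an atlas.

    Grey-matter regions get one row each (by name); white-matter and CSF
    regions are pooled into aggregate rows, and voxels outside every listed
    region are reported as ``"unlabelled"``.  Fractions are relative to the
    template's voxel count and sum to 1 exactly.
    """
    _check_shared_grid(template, atlas)
    labels_under = atlas.data[template.mask]
    total = labels_under.size
    values, counts = np.unique(labels_under, return_counts=True)

    rows: dict[str, float] = {}
    for lab, cnt in zip(values.tolist(), counts.tolist()):
        frac = cnt / total
        if lab == 0:
            rows[UNLABELLED_ROW] = rows.get(UNLABELLED_ROW, 0.0) + frac
            continue
        info = atlas.label_table[lab]
        if info.tissue_class == "white":
            rows[WHITE_MATTER_ROW] = rows.get(WHITE_MATTER_ROW, 0.0) + frac
        elif info.tissue_class == "csf":
            rows[CSF_ROW] = rows.get(CSF_ROW, 0.0) + frac
        else:
            rows[info.name] = rows.get(info.name, 0.0) + frac

    # region rows first, by decreasing share; aggregates trail in fixed order
    aggregates = [
        (n, rows.pop(n)) for n in (WHITE_MATTER_ROW, CSF_ROW, UNLABELLED_ROW)
        if n in rows
    ]
    region_rows = sorted(rows.items(), key=lambda kv: (-kv[1], kv[0]))
    return OverlapReport(
        rows=region_rows + aggregates,
        total_voxels=total,
        template_name=template.name,
    )


def subtract_template_from_parcellation(
    parcellation: LabelVolume, template: SeedTemplate
) -> LabelVolume:
    """Zero out every template voxel of a parcellation.

    Seed-template voxels must not double as connectivity targets —
    otherwise a seed would accrue a connectivity measure to itself — so
    they are removed from the parcellation before fingerprinting.  Regions
    annihilated entirely are dropped from the label table with a warning.
    """
    _check_shared_grid(template, parcellation)
    new_data = parcellation.data.copy()
    new_data[template.mask] = 0
    surviving = set(np.unique(new_data).tolist()) - {0}
    new_table = {}
    for lab, info in parcellation.label_table.items():
        if lab in surviving:
            new_table[lab] = info
        else:
            logger.warning(
                "region %r (label %d) fully removed by template %r",
                info.name, lab, template.name,
            )
    return LabelVolume(data=new_data, affine=parcellation.affine, label_table=new_table)


def extract_parcellation(atlas: LabelVolume,
                         tissue_class: str = "grey") -> LabelVolume:
    """Project an atlas onto the regions of one tissue class.

    Used to derive the grey-matter parcellation that fingerprinting
    targets from a full atlas that also labels white-matter and CSF
    compartments; voxels of other tissue classes become background.
    """
    keep = set(atlas.labels_with_tissue(tissue_class))
    if not keep:
        raise ValueError(f"atlas has no {tissue_class!r} regions")
    new_data = np.where(np.isin(atlas.data, sorted(keep)), atlas.data, 0)
    table = {lab: info for lab, info in atlas.label_table.items() if lab in keep}
    return LabelVolume(data=new_data, affine=atlas.affine, label_table=table)


def restrict_to_grey(template: SeedTemplate, atlas: LabelVolume) -> SeedTemplate:
    """Grey-matter cleansing: keep only voxels lying in grey regions.

    White-matter, CSF and unlabelled voxels of the template are dropped;
    the result carries provenance ``"cleansed"``.
    """
    _check_shared_grid(template, atlas)
    cleansed = template.mask & atlas.grey_mask()
    if not cleansed.any():
        raise ValueError(
            f"template {template.name!r} contains no grey-matter voxels"
        )
    return SeedTemplate(
        mask=cleansed,
        name=f"{template.name} (grey)",
        provenance="cleansed",
        hemisphere=template.hemisphere,
    )
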
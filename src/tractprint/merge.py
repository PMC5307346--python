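"""Template merging and connectivity-based sub-parcellation.

The merged seed template unites the structural seed with the primary-area,
grey-matter part of the functional seed.  Its voxels are then classified
by their streamline counts: a voxel is *connected* to a target when at
least ``voxel_class_frac`` of its S samples reach it (1250 of 5000 at the
defaults), and connected voxels are hard-assigned to the secondary target
receiving their largest count (winner-take-all; ties go to the lowest
region label).  Per-subject assignments are combined into a consensus by
the same at-least-``group_frac``-of-subjects rule used for connections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .synthetic import StreamlineSamples
from .volumes import LabelVolume, SeedTemplate

logger = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass
class SubParcellation:
    """Hard assignment of seed voxels to connectivity targets.

    ``assigned_target`` holds a target region label per voxel, or
    ``UNASSIGNED`` (-1) where the voxel is not connected to any target at
    the classification cutoff.  ``fibre_fractions`` (counts / S) is kept
    for per-subject results and is ``None`` for a group consensus, which
    aggregates hard labels rather than counts.
    """

    grid_shape: tuple[int, int, int]
    voxel_index: np.ndarray            # (n,) flat indices, ascending
    target_labels: np.ndarray          # (m,) candidate targets, ascending
    connected_mask: np.ndarray         # (n,) bool
    assigned_target: np.ndarray        # (n,) label or UNASSIGNED
    fibre_fractions: np.ndarray | None = None   # (n, m)
    cutoff: int | None = None          # streamline-count cutoff used

    def __post_init__(self) -> None:
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        self.target_labels = np.asarray(self.target_labels, dtype=np.int64)
        self.connected_mask = np.asarray(self.connected_mask, dtype=bool)
        self.assigned_target = np.asarray(self.assigned_target, dtype=np.int64)
        n = self.voxel_index.size
        if self.connected_mask.shape != (n,) or self.assigned_target.shape != (n,):
            raise ValueError("per-voxel arrays do not match voxel count")
        if ((self.assigned_target != UNASSIGNED) & ~self.connected_mask).any():
            raise ValueError("assignment on a voxel not classified as connected")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_index.size)

    def target_masks(self) -> dict[int, np.ndarray]:
        """One boolean volume per target: its assigned sub-region."""
        out: dict[int, np.ndarray] = {}
        for lab in self.target_labels.tolist():
            mask = np.zeros(int(np.prod(self.grid_shape)), dtype=bool)
            mask[self.voxel_index[self.assigned_target == lab]] = True
            out[lab] = mask.reshape(self.grid_shape)
        return out

    def to_frame(self) -> pd.DataFrame:
        i, j, k = np.unravel_index(self.voxel_index, self.grid_shape)
        frame = pd.DataFrame(
            {
                "i": i, "j": j, "k": k,
                "connected": self.connected_mask,
                "assigned_target": self.assigned_target,
            }
        )
        if self.fibre_fractions is not None:
            for col, lab in enumerate(self.target_labels.tolist()):
                frame[f"frac_{lab}"] = self.fibre_fractions[:, col]
        return frame


def labels_under_template(template: SeedTemplate,
                          atlas: LabelVolume) -> list[int]:
    """Region labels occurring under a template mask (0 excluded)."""
    under = atlas.data[template.mask]
    return sorted(set(under[under > 0].tolist()))


def build_merged_template(
    structural: SeedTemplate,
    functional: SeedTemplate,
    atlas: LabelVolume,
    primary_region_labels: set[int] | frozenset[int],
    *,
    keep_unlabelled_grey: np.ndarray | None = None,
    name: str = "mOCN",
) -> SeedTemplate:
    """Union the structural seed with the primary grey part of the
    functional seed.

    Functional-seed voxels survive only when they lie in a grey-matter
    region listed in ``primary_region_labels``; secondary-area spill-over
    and non-grey contamination are taken away.  ``keep_unlabelled_grey``
    optionally supplies a boolean grey-tissue mask so that unlabelled but
    grey functional voxels may also be kept.
    """
    if structural.grid_shape != functional.grid_shape:
        raise ValueError("structural and functional templates on different grids")
    if tuple(structural.grid_shape) != tuple(atlas.grid_shape):
        raise ValueError("templates and atlas on different grids")
    unknown = set(primary_region_labels) - set(atlas.label_table)
    if unknown:
        raise ValueError(f"primary labels missing from atlas: {sorted(unknown)}")
    primary_grey = sorted(
        lab for lab in primary_region_labels
        if atlas.label_table[lab].tissue_class == "grey"
    )
    keep = functional.mask & np.isin(atlas.data, primary_grey)
    if keep_unlabelled_grey is not None:
        keep |= functional.mask & (atlas.data == 0) & keep_unlabelled_grey
    merged = structural.mask | keep
    if not merged.any():
        raise ValueError("merged template is empty")
    return SeedTemplate(
        mask=merged,
        name=name,
        provenance="merged",
        hemisphere=structural.hemisphere,
    )


def _class_cutoff(config: PipelineConfig) -> int:
    """Streamline-count cutoff for voxel classification (integer; a
    fractional product is rounded up and logged)."""
    exact = config.voxel_class_frac * config.S
    cutoff = math.ceil(exact)
    if cutoff != exact:
        logger.info(
            "voxel_class_frac * S = %.3f is fractional; using ceiling %d",
            exact, cutoff,
        )
    return cutoff


def _candidate_rows(samples: StreamlineSamples, candidates) -> np.ndarray:
    if isinstance(candidates, SeedTemplate):
        return samples.rows_for_mask(candidates.mask)
    if isinstance(candidates, np.ndarray) and candidates.dtype == bool:
        return samples.rows_for_mask(candidates)
    return np.array([samples.row_of(v) for v in candidates], dtype=np.int64)


def classify_seed_voxels(
    samples: StreamlineSamples,
    candidates,
    target_labels,
    config: PipelineConfig,
) -> SubParcellation:
    """Binarise candidate voxels by their streamline count to a target
    template.

    A voxel is classified as connected when the samples reaching the
    target's regions total at least ``voxel_class_frac * S`` (1250 of 5000
    at the defaults).  ``target_labels`` is the set of region labels
    standing for the target template (see :func:`labels_under_template`);
    the whole set is pooled into a single count, so no per-target
    assignment is made at this stage.
    """
    rows = _candidate_rows(samples, candidates)
    labels = np.array(sorted(int(l) for l in target_labels), dtype=np.int64)
    if labels.size == 0:
        raise ValueError("no target labels given")
    cols = np.array([samples.column_of(int(l)) for l in labels])
    pooled = samples.counts[np.ix_(rows, cols)].sum(axis=1)
    cutoff = _class_cutoff(config)
    connected = pooled >= cutoff
    return SubParcellation(
        grid_shape=samples.grid_shape,
        voxel_index=samples.voxel_index[rows],
        target_labels=labels,
        connected_mask=connected,
        assigned_target=np.full(rows.size, UNASSIGNED, dtype=np.int64),
        fibre_fractions=(samples.counts[np.ix_(rows, cols)] / samples.S),
        cutoff=cutoff,
    )


def subparcellate_by_targets(
    samples: StreamlineSamples,
    merged: SeedTemplate,
    secondary_targets,
    config: PipelineConfig,
) -> SubParcellation:
    """Partition a merged seed template by dominant secondary target.

    Each voxel whose largest secondary-target streamline count reaches the
    classification cutoff is assigned to that target (lowest label on
    exact ties); the rest stay unassigned.
    """
    labels = np.array(sorted(int(l) for l in secondary_targets), dtype=np.int64)
    if labels.size == 0:
        raise ValueError("no secondary targets given")
    rows = samples.rows_for_mask(merged.mask)
    cols = np.array([samples.column_of(int(l)) for l in labels])
    counts = samples.counts[np.ix_(rows, cols)]
    cutoff = _class_cutoff(config)
    best = counts.max(axis=1)
    connected = best >= cutoff
    # argmax returns the first maximum; labels are ascending, so exact ties
    # resolve to the lowest label
    assigned = np.where(connected, labels[np.argmax(counts, axis=1)], UNASSIGNED)
    return SubParcellation(
        grid_shape=samples.grid_shape,
        voxel_index=samples.voxel_index[rows],
        target_labels=labels,
        connected_mask=connected,
        assigned_target=assigned,
        fibre_fractions=counts / samples.S,
        cutoff=cutoff,
    )


def group_subparcellation(
    subparcellations: list[SubParcellation],
    config: PipelineConfig,
) -> SubParcellation:
    """Consensus sub-parcellation across subjects.

    A voxel's consensus target is the one it was assigned to in at least
    ``group_frac`` of subjects; if several targets qualify (possible only
    at the boundary), the most frequent wins, then the lowest label.
    Voxels with no qualifying target stay unassigned.
    """
    if not subparcellations:
        raise ValueError("no sub-parcellations given")
    first = subparcellations[0]
    for sp in subparcellations[1:]:
        if not np.array_equal(sp.voxel_index, first.voxel_index) or not (
            np.array_equal(sp.target_labels, first.target_labels)
        ):
            raise ValueError("sub-parcellations on different voxel/target sets")
    n_total = len(subparcellations)
    labels = first.target_labels
    votes = np.zeros((first.n_voxels, labels.size), dtype=np.int64)
    for sp in subparcellations:
        for col, lab in enumerate(labels.tolist()):
            votes[:, col] += sp.assigned_target == lab
    need = config.group_frac * n_total
    qualifies = votes >= need - 1e-9
    assigned = np.full(first.n_voxels, UNASSIGNED, dtype=np.int64)
    any_q = qualifies.any(axis=1)
    if any_q.any():
        masked = np.where(qualifies, votes, -1)
        # first argmax among columns -> most votes, lowest label on ties
        winner = np.argmax(masked, axis=1)
        assigned[any_q] = labels[winner[any_q]]
    return SubParcellation(
        grid_shape=first.grid_shape,
        voxel_index=first.voxel_index,
        target_labels=labels,
        connected_mask=assigned != UNASSIGNED,
        assigned_target=assigned,
        fibre_fractions=None,
        cutoff=first.cutoff,
    )
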
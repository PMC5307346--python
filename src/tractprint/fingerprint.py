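"""Per-subject connectivity fingerprints.

The connection probability from a seed entity i (a seed template, or a
parcellation region used as a seed) to a target region j is

    P_ij = (streamlines from i terminating in j) / (S * n_i)

with S samples per seed voxel and n_i seed voxels, i.e. the mean over seed
voxels of the per-voxel endpoint proportion.  Raw fingerprints are
row-thresholded (a connection survives when its streamline count is at
least ``row_threshold_frac`` of the row maximum) and may then be
normalised by target-region size for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .config import PipelineConfig
from .synthetic import StreamlineSamples
from .volumes import LabelVolume, SeedTemplate

logger = logging.getLogger(__name__)

STAGES = ("raw", "thresholded", "normalised")


class SeedOverlapError(ValueError):
    """The seed template still overlaps parcellation regions."""


@dataclass
class FingerprintMatrix:
    """Seed-entity x target-region connectivity values.

    ``counts`` holds integer streamline counts (zeroed alongside ``values``
    when thresholding, so the two stay consistent); ``values`` holds the
    stage-dependent quantity: raw/thresholded P_ij, or the size-normalised
    display value after :func:`normalize_fingerprint`.
    """

    seed_entities: list[str]
    region_labels: np.ndarray
    region_names: list[str]
    counts: np.ndarray           # (k, m) streamline counts
    values: np.ndarray           # (k, m) stage-dependent values
    seed_sizes: np.ndarray       # (k,) seed voxels per row
    S: int
    stage: str = "raw"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        self.values = np.asarray(self.values, dtype=float)
        self.seed_sizes = np.asarray(self.seed_sizes, dtype=np.int64)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        k, m = self.counts.shape
        if len(self.seed_entities) != k or self.seed_sizes.size != k:
            raise ValueError("row bookkeeping does not match counts")
        if self.region_labels.size != m or len(self.region_names) != m:
            raise ValueError("column bookkeeping does not match counts")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("connectivity values must lie in [0, 1]")

    @property
    def n_targets(self) -> int:
        return int(self.region_labels.size)

    def row(self, seed_entity: str) -> np.ndarray:
        return self.values[self.seed_entities.index(seed_entity)]

    def value(self, seed_entity: str, label: int) -> float:
        i = self.seed_entities.index(seed_entity)
        j = int(np.flatnonzero(self.region_labels == label)[0])
        return float(self.values[i, j])


def voxel_connectivity(samples: StreamlineSamples, voxel, target_label: int
                       ) -> float:
    """Proportion of a voxel's S streamline samples reaching a region."""
    row = samples.row_of(voxel)
    col = samples.column_of(target_label)
    return float(samples.counts[row, col]) / samples.S


def region_connectivity(samples: StreamlineSamples, seed_voxels,
                        target_label: int) -> float:
    """P_ij for a seed voxel set: summed counts over S * n.

    ``seed_voxels`` may be a boolean mask on the samples grid or a
    sequence of voxels (flat indices or (i, j, k) triples).
    """
    if isinstance(seed_voxels, np.ndarray) and seed_voxels.dtype == bool:
        rows = samples.rows_for_mask(seed_voxels)
    else:
        rows = np.array([samples.row_of(v) for v in seed_voxels], dtype=np.int64)
    n = rows.size
    if n == 0:
        raise ValueError("empty seed region")
    col = samples.column_of(target_label)
    return float(samples.counts[rows, col].sum()) / (samples.S * n)


def threshold_connections(matrix: FingerprintMatrix,
                          config: PipelineConfig) -> FingerprintMatrix:
    """Apply the per-row relative streamline-count threshold.

    Each seed row's cutoff is ``row_threshold_frac`` times its own maximum
    streamline count; entries strictly below the cutoff are zeroed, entries
    exactly at it are kept (a *minimum* value).  Comparisons use the
    integer counts, so the boundary is unambiguous.
    """
    if matrix.stage != "raw":
        raise ValueError(f"can only threshold a raw matrix, got {matrix.stage!r}")
    counts = matrix.counts.copy()
    values = matrix.values.copy()
    for i in range(counts.shape[0]):
        row_max = counts[i].max()
        if row_max == 0:
            logger.warning(
                "seed %r: all-zero fingerprint row, nothing to threshold",
                matrix.seed_entities[i],
            )
            continue
        cutoff = config.row_threshold_frac * row_max
        drop = counts[i] < cutoff
        counts[i, drop] = 0
        values[i, drop] = 0.0
    return replace(matrix, counts=counts, values=values, stage="thresholded")


def normalize_fingerprint(matrix: FingerprintMatrix,
                          parcellation: LabelVolume) -> FingerprintMatrix:
    """Divide each entry by the target region's voxel count, then rescale
    each row to a maximum of 1 for display."""
    if matrix.stage not in ("raw", "thresholded"):
        raise ValueError(f"cannot normalise a {matrix.stage!r} matrix")
    sizes = parcellation.region_voxel_counts()
    try:
        n_j = np.array([sizes[int(lab)] for lab in matrix.region_labels],
                       dtype=float)
    except KeyError as exc:
        raise KeyError(f"target label {exc} missing from parcellation") from exc
    values = matrix.values / n_j
    row_max = values.max(axis=1, keepdims=True)
    scale = np.where(row_max > 0, row_max, 1.0)
    return replace(matrix, values=values / scale, stage="normalised")


def build_fingerprint(
    samples: StreamlineSamples,
    seed: SeedTemplate,
    parcellation: LabelVolume,
    config: PipelineConfig,
) -> FingerprintMatrix:
    """Fingerprint a seed template against every parcellation region.

    The seed's voxels must already have been subtracted from the
    parcellation (see ``subtract_template_from_parcellation``); otherwise
    the seed would accrue a connectivity measure to itself, and a
    :class:`SeedOverlapError` naming the offending regions is raised.
    A seed coinciding with a removed region yields N-1 targets on an
    N-region parcellation; an external seed yields all N.
    """
    if tuple(seed.grid_shape) != tuple(parcellation.grid_shape):
        raise ValueError("seed and parcellation grids differ")
    under = parcellation.data[seed.mask]
    overlapping = sorted(set(under[under > 0].tolist()))
    if overlapping:
        names = [parcellation.label_table[l].name for l in overlapping]
        raise SeedOverlapError(
            f"seed {seed.name!r} overlaps parcellation regions {names}; "
            "subtract the template from the parcellation first"
        )
    rows = samples.rows_for_mask(seed.mask)
    n = rows.size
    labels = np.array(parcellation.labels, dtype=np.int64)
    cols = np.array([samples.column_of(int(l)) for l in labels])
    counts = samples.counts[np.ix_(rows, cols)].sum(axis=0)[None, :]
    values = counts / float(samples.S * n)
    raw = FingerprintMatrix(
        seed_entities=[seed.name],
        region_labels=labels,
        region_names=[parcellation.label_table[int(l)].name for l in labels],
        counts=counts,
        values=values,
        seed_sizes=np.array([n]),
        S=samples.S,
        stage="raw",
        subject_id=samples.subject_id,
    )
    return threshold_connections(raw, config)
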
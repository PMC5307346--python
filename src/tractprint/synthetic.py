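"""Synthetic phantom and stochastic tractography simulator.

Real probabilistic tractography propagates streamlines through a diffusion
field; every quantity the fingerprinting pipeline consumes, however, is the
*count* of sampled streamlines from a seed voxel that terminate in each
target region.  The simulator therefore generates endpoint counts directly:

* each seed voxel belongs to a *voxel class* (e.g. "the white-matter
  contaminated part of the functional template") with a planted vector of
  region-connection probabilities ``p``;
* per subject, a class-specific probability vector is drawn from a
  Dirichlet perturbation of ``p`` with concentration ``kappa`` (``kappa =
  None`` disables between-subject variability);
* per seed voxel, ``S`` streamline endpoints are drawn from a multinomial
  over target regions plus an explicit "unreached" slot, so that the total
  connection probability of a voxel may be below 1.

Everything is deterministic given ``(rng_seed, subject index)``; subjects
use independent RNG substreams, so subject k's data do not change when the
cohort grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .volumes import LabelVolume, RegionInfo, SeedTemplate, extract_parcellation

UNLABELLED_LOCATION = "unlabelled"


@dataclass(frozen=True)
class RegionSpec:
    """One region of the phantom parcellation."""

    name: str
    hemisphere: str
    tissue_class: str
    n_voxels: int


@dataclass(frozen=True)
class TemplateComponent:
    """A block of template voxels sharing one planted connectivity class.

    ``location`` is either a region name (the component's voxels are taken
    from that region) or ``"unlabelled"`` (taken from background voxels).
    """

    voxel_class: str
    n_voxels: int
    location: str


@dataclass(frozen=True)
class TemplateSpec:
    name: str
    provenance: str
    hemisphere: str
    components: tuple[TemplateComponent, ...]


@dataclass
class PhantomSpec:
    """Complete recipe for a phantom cohort.

    ``planted_connectivity`` maps voxel class -> {target region name: p};
    for every class the probabilities must sum to at most 1, the remainder
    being streamlines that reach no labelled region.
    """

    grid_shape: tuple[int, int, int]
    regions: tuple[RegionSpec, ...]
    templates: tuple[TemplateSpec, ...]
    planted_connectivity: dict[str, dict[str, float]]
    kappa: float | None = 300.0
    n_subjects: int = 16
    S: int = 5000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.kappa is not None and not math.isinf(self.kappa):
            if self.kappa <= 0:
                raise ValueError("kappa must be positive (or None for none)")
        region_names = {r.name for r in self.regions}
        for cls, targets in self.planted_connectivity.items():
            total = sum(targets.values())
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"class {cls!r}: planted probabilities sum to {total} > 1"
                )
            if any(p < 0 for p in targets.values()):
                raise ValueError(f"class {cls!r}: negative probability")
            unknown = set(targets) - region_names
            if unknown:
                raise ValueError(f"class {cls!r}: unknown targets {sorted(unknown)}")
        for tpl in self.templates:
            for comp in tpl.components:
                if comp.voxel_class not in self.planted_connectivity:
                    raise ValueError(
                        f"template {tpl.name!r}: class {comp.voxel_class!r} "
                        "has no planted connectivity entry"
                    )

    @property
    def no_variability(self) -> bool:
        return self.kappa is None or math.isinf(self.kappa)


@dataclass
class GroundTruth:
    """Planted structure retained for recovery tests."""

    #: class -> flat voxel indices (ascending)
    voxel_classes: dict[str, np.ndarray]
    #: class -> {region name: planted p}
    planted: dict[str, dict[str, float]]
    #: sorted union of all template voxels (flat indices)
    seed_voxels: np.ndarray
    #: class name per entry of ``seed_voxels``
    class_by_voxel: np.ndarray

    def dominant_target(self, voxel_class: str,
                        among: Sequence[str] | None = None) -> str | None:
        """Region receiving the largest planted probability for a class,
        optionally restricted to a candidate list; None if all zero."""
        table = self.planted[voxel_class]
        cand = {r: p for r, p in table.items() if among is None or r in among}
        if not cand or max(cand.values()) == 0:
            return None
        best = max(cand.values())
        return min(r for r, p in cand.items() if p == best)


@dataclass
class Phantom:
    spec: PhantomSpec
    #: full atlas, including white-matter / CSF compartments
    label_volume: LabelVolume
    #: grey-regions-only view of the atlas: what fingerprints target
    parcellation: LabelVolume
    templates: dict[str, SeedTemplate]
    truth: GroundTruth


@dataclass
class StreamlineSamples:
    """Per-subject streamline endpoint counts for a set of seed voxels."""

    subject_id: str
    S: int
    grid_shape: tuple[int, int, int]
    voxel_index: np.ndarray          # (n,) flat C-order indices, ascending
    region_labels: np.ndarray        # (m,) target labels, ascending
    counts: np.ndarray               # (n, m) endpoints per region
    unreached: np.ndarray            # (n,) endpoints outside every region

    def __post_init__(self) -> None:
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.unreached = np.asarray(self.unreached, dtype=np.int64)
        if self.counts.shape != (self.voxel_index.size, self.region_labels.size):
            raise ValueError("counts shape does not match voxels x regions")
        if (self.counts < 0).any() or (self.unreached < 0).any():
            raise ValueError("negative streamline counts")
        total = self.counts.sum(axis=1) + self.unreached
        if not (total == self.S).all():
            raise ValueError("streamline counts do not sum to S for every voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_index.size)

    def column_of(self, label: int) -> int:
        idx = np.searchsorted(self.region_labels, label)
        if idx >= self.region_labels.size or self.region_labels[idx] != label:
            raise KeyError(f"no samples for target label {label}")
        return int(idx)

    def row_of(self, voxel) -> int:
        """Row index for a voxel given as flat index or (i, j, k) triple."""
        flat = self._flatten(voxel)
        idx = np.searchsorted(self.voxel_index, flat)
        if idx >= self.voxel_index.size or self.voxel_index[idx] != flat:
            raise KeyError(f"no samples for seed voxel {voxel}")
        return int(idx)

    def _flatten(self, voxel) -> int:
        if np.isscalar(voxel) or isinstance(voxel, (int, np.integer)):
            return int(voxel)
        return int(np.ravel_multi_index(tuple(voxel), self.grid_shape))

    def rows_for_mask(self, mask: np.ndarray) -> np.ndarray:
        """Row indices covering every set voxel of a mask (same grid)."""
        if tuple(mask.shape) != tuple(self.grid_shape):
            raise ValueError("mask grid does not match samples grid")
        wanted = np.flatnonzero(mask.ravel())
        pos = np.searchsorted(self.voxel_index, wanted)
        ok = (pos < self.voxel_index.size) & (
            self.voxel_index[np.minimum(pos, self.voxel_index.size - 1)] == wanted
        )
        if not ok.all():
            missing = wanted[~ok]
            raise KeyError(
                f"{missing.size} mask voxels have no streamline samples "
                f"(first: flat index {int(missing[0])})"
            )
        return pos


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the label volume, seed templates and ground truth of a spec.

    Region voxels are laid out as consecutive runs in flat C-order — the
    pipeline is purely count-based, so spatial shape is irrelevant — and
    template components take deterministic slices of their source region
    (or of the unlabelled pool), making the construction reproducible
    without randomness.
    """
    n_total = int(np.prod(spec.grid_shape))
    needed = sum(r.n_voxels for r in spec.regions)
    if needed > n_total:
        raise ValueError(
            f"region layout needs {needed} voxels but grid has {n_total}"
        )
    flat = np.zeros(n_total, dtype=np.int32)
    label_table: dict[int, RegionInfo] = {}
    region_slices: dict[str, np.ndarray] = {}
    cursor = 0
    for lab, reg in enumerate(spec.regions, start=1):
        run = np.arange(cursor, cursor + reg.n_voxels)
        flat[run] = lab
        label_table[lab] = RegionInfo(reg.name, reg.hemisphere, reg.tissue_class)
        region_slices[reg.name] = run
        cursor += reg.n_voxels
    region_slices[UNLABELLED_LOCATION] = np.arange(cursor, n_total)

    volume = LabelVolume(
        data=flat.reshape(spec.grid_shape),
        affine=np.eye(4),
        label_table=label_table,
    )

    # allocate template component voxels; a shared per-location offset keeps
    # picks disjoint across components and templates
    offsets: dict[str, int] = {}
    templates: dict[str, SeedTemplate] = {}
    class_voxels: dict[str, list[np.ndarray]] = {}
    for tpl in spec.templates:
        mask = np.zeros(n_total, dtype=bool)
        for comp in tpl.components:
            if comp.location not in region_slices:
                raise ValueError(
                    f"template {tpl.name!r}: unknown location {comp.location!r}"
                )
            pool = region_slices[comp.location]
            start = offsets.get(comp.location, 0)
            if start + comp.n_voxels > pool.size:
                raise ValueError(
                    f"template {tpl.name!r}: location {comp.location!r} "
                    f"exhausted ({comp.n_voxels} wanted, "
                    f"{pool.size - start} left)"
                )
            picked = pool[start:start + comp.n_voxels]
            offsets[comp.location] = start + comp.n_voxels
            mask[picked] = True
            class_voxels.setdefault(comp.voxel_class, []).append(picked)
        templates[tpl.name] = SeedTemplate(
            mask=mask.reshape(spec.grid_shape),
            name=tpl.name,
            provenance=tpl.provenance,
            hemisphere=tpl.hemisphere,
        )

    voxel_classes = {
        cls: np.sort(np.concatenate(chunks))
        for cls, chunks in class_voxels.items()
    }
    seed_voxels = np.sort(np.concatenate(list(voxel_classes.values())))
    class_by_voxel = np.empty(seed_voxels.size, dtype=object)
    for cls, vox in voxel_classes.items():
        class_by_voxel[np.searchsorted(seed_voxels, vox)] = cls

    truth = GroundTruth(
        voxel_classes=voxel_classes,
        planted={c: dict(t) for c, t in spec.planted_connectivity.items()},
        seed_voxels=seed_voxels,
        class_by_voxel=class_by_voxel,
    )
    return Phantom(
        spec=spec,
        label_volume=volume,
        parcellation=extract_parcellation(volume),
        templates=templates,
        truth=truth,
    )


def _subject_rng(spec: PhantomSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed, spawn_key=(subject_index,))
    )


def simulate_tractography(
    phantom: Phantom, subject_index: int, subject_id: str | None = None
) -> StreamlineSamples:
    """Simulate one subject's streamline endpoint counts.

    For every voxel class, a subject-level probability vector is drawn from
    ``Dirichlet(kappa * p)`` restricted to the planted support (so planted
    zeros stay exactly zero), then each seed voxel draws ``S`` multinomial
    endpoints from it.
    """
    spec = phantom.spec
    if subject_id is None:
        subject_id = f"sub-{subject_index + 1:02d}"
    rng = _subject_rng(spec, subject_index)

    labels = np.array(phantom.label_volume.labels, dtype=np.int64)
    name_to_col = {
        phantom.label_volume.label_table[lab].name: j
        for j, lab in enumerate(labels.tolist())
    }
    seed_voxels = phantom.truth.seed_voxels
    counts = np.zeros((seed_voxels.size, labels.size), dtype=np.int64)
    unreached = np.zeros(seed_voxels.size, dtype=np.int64)

    for cls in sorted(phantom.truth.voxel_classes):
        vox = phantom.truth.voxel_classes[cls]
        rows = np.searchsorted(seed_voxels, vox)
        planted = phantom.truth.planted[cls]
        theta = np.zeros(labels.size + 1)
        for region, p in planted.items():
            theta[name_to_col[region]] = p
        theta[-1] = max(0.0, 1.0 - theta[:-1].sum())
        if not spec.no_variability:
            support = theta > 0
            alpha = spec.kappa * theta[support]
            draw = rng.gamma(shape=alpha)
            if draw.sum() > 0:
                theta = theta.copy()
                theta[support] = draw / draw.sum()
        draws = rng.multinomial(spec.S, theta / theta.sum(), size=vox.size)
        counts[rows, :] = draws[:, :-1]
        unreached[rows] = draws[:, -1]

    return StreamlineSamples(
        subject_id=subject_id,
        S=spec.S,
        grid_shape=spec.grid_shape,
        voxel_index=seed_voxels,
        region_labels=labels,
        counts=counts,
        unreached=unreached,
    )


def make_cohort(spec: PhantomSpec, phantom: Phantom | None = None
                ) -> list[StreamlineSamples]:
    """Simulate the whole cohort (``spec.n_subjects`` subjects)."""
    if phantom is None:
        phantom = make_phantom(spec)
    return [
        simulate_tractography(phantom, i) for i in range(spec.n_subjects)
    ]


# ---------------------------------------------------------------------------
# default phantom: an AAL-like 90-region parcellation with one structural
# and one functional seed template in the left hemisphere

#: regions given meaningful names; all others are generic cortical filler
_NAMED_REGIONS = (
    "Olfactory", "Piriform", "Amygdala", "Hippocampus", "ParaHippocampal",
    "Putamen", "Pallidum", "Thalamus", "Frontal_Sup_Orb", "Cingulum_Ant",
    "Insula", "Caudate", "Rectus", "Temporal_Pole_Sup", "Fusiform", "Lingual",
)
_NAMED_SIZE = 64      # voxels per named region
_GENERIC_SIZE = 8     # voxels per filler region
_N_PER_HEMI = 45
_WHITE_VOXELS = 1200
_CSF_VOXELS = 300


def default_planted_connectivity() -> dict[str, dict[str, float]]:
    """Planted region-connection probabilities for the default phantom.

    The structural seed carries an anterior profile (orbitofrontal /
    anterior cingulate dominated) and a posterior profile (hippocampus /
    amygdala dominated); the functional seed's grey components connect to
    secondary olfactory areas, while its white-matter contamination alone
    drives pallidum and thalamus connections and its unlabelled voxels
    drive fusiform/lingual ones — so grey-matter cleansing removes exactly
    those connections.
    """
    return {
        "soc_anterior": {
            "Frontal_Sup_Orb_L": 0.40, "Cingulum_Ant_L": 0.10, "Insula_L": 0.05,
        },
        "soc_posterior": {
            "Hippocampus_L": 0.40, "Amygdala_L": 0.10, "ParaHippocampal_L": 0.05,
        },
        "foc_amygdala": {
            "Hippocampus_L": 0.35, "Putamen_L": 0.10, "Temporal_Pole_Sup_L": 0.05,
        },
        "foc_piriform": {"Frontal_Sup_Orb_L": 0.35, "Amygdala_L": 0.10},
        "foc_putamen": {"Caudate_L": 0.15},
        "foc_parahippocampal": {"Hippocampus_L": 0.15},
        "foc_hippocampus": {"ParaHippocampal_L": 0.15},
        "foc_white": {"Pallidum_L": 0.20, "Thalamus_L": 0.10},
        "foc_csf": {},
        "foc_unlabelled": {"Fusiform_L": 0.10, "Lingual_L": 0.05},
    }


def default_phantom_spec(
    *,
    n_subjects: int = 16,
    kappa: float | None = 300.0,
    S: int = 5000,
    rng_seed: int = 0,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    planted_connectivity: dict[str, dict[str, float]] | None = None,
) -> PhantomSpec:
    """The stock desk-scale phantom.

    90 grey regions (45 per hemisphere, 8–64 voxels each) plus one
    white-matter and one CSF compartment; a structural seed template
    coinciding exactly with the left olfactory region, and a functional
    seed template whose composition mimics a functionally-defined ROI:
    mostly amygdala and piriform with putamen / parahippocampal /
    hippocampal spill-over plus white-matter, CSF and unlabelled
    contamination.
    """
    regions: list[RegionSpec] = []
    for hemi, suffix in (("left", "_L"), ("right", "_R")):
        for name in _NAMED_REGIONS:
            regions.append(RegionSpec(name + suffix, hemi, "grey", _NAMED_SIZE))
        for k in range(_N_PER_HEMI - len(_NAMED_REGIONS)):
            regions.append(
                RegionSpec(f"Ctx_{k + 1:02d}{suffix}", hemi, "grey", _GENERIC_SIZE)
            )
    regions.append(RegionSpec("White_Matter", "midline", "white", _WHITE_VOXELS))
    regions.append(RegionSpec("CSF", "midline", "csf", _CSF_VOXELS))

    soc = TemplateSpec(
        name="sOCN_L", provenance="structural", hemisphere="left",
        components=(
            TemplateComponent("soc_anterior", _NAMED_SIZE // 2, "Olfactory_L"),
            TemplateComponent("soc_posterior", _NAMED_SIZE - _NAMED_SIZE // 2,
                              "Olfactory_L"),
        ),
    )
    foc = TemplateSpec(
        name="fOCN_L", provenance="functional", hemisphere="left",
        components=(
            TemplateComponent("foc_amygdala", 37, "Amygdala_L"),
            TemplateComponent("foc_piriform", 8, "Piriform_L"),
            TemplateComponent("foc_putamen", 9, "Putamen_L"),
            TemplateComponent("foc_parahippocampal", 7, "ParaHippocampal_L"),
            TemplateComponent("foc_hippocampus", 6, "Hippocampus_L"),
            TemplateComponent("foc_white", 15, "White_Matter"),
            TemplateComponent("foc_csf", 3, "CSF"),
            TemplateComponent("foc_unlabelled", 15, UNLABELLED_LOCATION),
        ),
    )
    return PhantomSpec(
        grid_shape=grid_shape,
        regions=tuple(regions),
        templates=(soc, foc),
        planted_connectivity=(
            planted_connectivity
            if planted_connectivity is not None
            else default_planted_connectivity()
        ),
        kappa=kappa,
        n_subjects=n_subjects,
        S=S,
        rng_seed=rng_seed,
    )


# -- YAML round-trip --------------------------------------------------------

def spec_to_yaml(spec: PhantomSpec, path: str | Path) -> None:
    doc = asdict(spec)
    doc["grid_shape"] = list(spec.grid_shape)
    doc["regions"] = [asdict(r) for r in spec.regions]
    doc["templates"] = [
        {**asdict(t), "components": [asdict(c) for c in t.components]}
        for t in spec.templates
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return PhantomSpec(
        grid_shape=tuple(doc["grid_shape"]),
        regions=tuple(RegionSpec(**r) for r in doc["regions"]),
        templates=tuple(
            TemplateSpec(
                name=t["name"], provenance=t["provenance"],
                hemisphere=t["hemisphere"],
                components=tuple(TemplateComponent(**c) for c in t["components"]),
            )
            for t in doc["templates"]
        ),
        planted_connectivity=doc["planted_connectivity"],
        kappa=doc.get("kappa"),
        n_subjects=doc.get("n_subjects", 16),
        S=doc.get("S", 5000),
        rng_seed=doc.get("rng_seed", 0),
    )
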
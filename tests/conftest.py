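import numpy as np
import pytest

import tractprint as tp


def random_label_volume(rng, shape=(6, 6, 6), n_grey=4, n_white=1, n_csf=1,
                        fill=0.7):
    """A random small atlas: labels scattered over the grid, some
    background left, every listed label present at least once."""
    n_regions = n_grey + n_white + n_csf
    n_total = int(np.prod(shape))
    n_labelled = max(n_regions, int(fill * n_total))
    flat = np.zeros(n_total, dtype=np.int32)
    where = rng.choice(n_total, size=n_labelled, replace=False)
    labels = np.concatenate([
        np.arange(1, n_regions + 1),                        # each at least once
        rng.integers(1, n_regions + 1, size=n_labelled - n_regions),
    ])
    flat[where] = labels
    table = {}
    for lab in range(1, n_regions + 1):
        if lab <= n_grey:
            tissue, name = "grey", f"Grey_{lab:02d}"
        elif lab <= n_grey + n_white:
            tissue, name = "white", f"White_{lab:02d}"
        else:
            tissue, name = "csf", f"CSF_{lab:02d}"
        table[lab] = tp.RegionInfo(name, "left", tissue)
    return tp.LabelVolume(data=flat.reshape(shape), label_table=table)


def random_template(rng, volume, n_voxels=12, name="tpl"):
    n_total = volume.data.size
    where = rng.choice(n_total, size=n_voxels, replace=False)
    mask = np.zeros(n_total, dtype=bool)
    mask[where] = True
    return tp.SeedTemplate(mask=mask.reshape(volume.grid_shape), name=name,
                           provenance="functional")


def make_samples(counts, S=5000, voxel_index=None, region_labels=None,
                 subject_id="sub-01", grid_shape=(6, 6, 6)):
    """Hand-built StreamlineSamples from a counts matrix."""
    counts = np.asarray(counts, dtype=np.int64)
    n, m = counts.shape
    if voxel_index is None:
        voxel_index = np.arange(n)
    if region_labels is None:
        region_labels = np.arange(1, m + 1)
    return tp.StreamlineSamples(
        subject_id=subject_id, S=S, grid_shape=grid_shape,
        voxel_index=np.asarray(voxel_index),
        region_labels=np.asarray(region_labels),
        counts=counts, unreached=S - counts.sum(axis=1),
    )


def make_matrix(counts, S=5000, seed_sizes=None, stage="raw",
                region_labels=None, seed_entities=None):
    """Hand-built FingerprintMatrix from a streamline-count matrix."""
    counts = np.asarray(counts, dtype=np.int64)
    k, m = counts.shape
    if seed_sizes is None:
        seed_sizes = np.ones(k, dtype=np.int64)
    if region_labels is None:
        region_labels = np.arange(1, m + 1)
    if seed_entities is None:
        seed_entities = [f"seed{i}" for i in range(k)]
    values = counts / (S * np.asarray(seed_sizes)[:, None])
    return tp.FingerprintMatrix(
        seed_entities=seed_entities,
        region_labels=np.asarray(region_labels),
        region_names=[f"R{l}" for l in np.asarray(region_labels).tolist()],
        counts=counts, values=values,
        seed_sizes=np.asarray(seed_sizes), S=S, stage=stage,
    )


def mini_spec(**kw):
    """A 6^3 phantom with 3 grey regions and both template kinds; cheap
    enough for loops of hundreds of simulations."""
    regions = (
        tp.RegionSpec("A_L", "left", "grey", 4),
        tp.RegionSpec("B_L", "left", "grey", 6),
        tp.RegionSpec("C_L", "left", "grey", 5),
        tp.RegionSpec("WM", "midline", "white", 10),
        tp.RegionSpec("CSF", "midline", "csf", 4),
    )
    templates = (
        tp.TemplateSpec(
            "tplS", "structural", "left",
            (tp.TemplateComponent("s", 4, "A_L"),),
        ),
        tp.TemplateSpec(
            "tplF", "functional", "left",
            (
                tp.TemplateComponent("fb", 3, "B_L"),
                tp.TemplateComponent("fw", 2, "WM"),
                tp.TemplateComponent("fc", 1, "CSF"),
                tp.TemplateComponent("fu", 2, "unlabelled"),
            ),
        ),
    )
    planted = {
        "s": {"B_L": 0.3, "C_L": 0.1},
        "fb": {"C_L": 0.2},
        "fw": {"C_L": 0.5},
        "fc": {},
        "fu": {"B_L": 0.2},
    }
    defaults = dict(
        grid_shape=(6, 6, 6), regions=regions, templates=templates,
        planted_connectivity=planted, kappa=50.0, n_subjects=4,
        S=1000, rng_seed=11,
    )
    defaults.update(kw)
    return tp.PhantomSpec(**defaults)


@pytest.fixture
def config():
    return tp.PipelineConfig()


@pytest.fixture(scope="session")
def phantom():
    """The stock desk-scale phantom (no-variability variant is built where
    a test needs it)."""
    return tp.make_phantom(tp.default_phantom_spec(n_subjects=4, rng_seed=3))


@pytest.fixture(scope="session")
def cohort(phantom):
    return tp.make_cohort(phantom.spec, phantom)
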
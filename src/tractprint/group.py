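"""Cohort-level aggregation of per-subject fingerprints.

A connection is *present* in a subject when it survives that subject's
per-row streamline threshold; it is *retained* at group level when present
in at least ``group_frac`` of subjects (the at-least-half-of-subjects rule
by default).  Summaries report the elementwise mean and sample standard
deviation of the normalised fingerprints across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .fingerprint import FingerprintMatrix

logger = logging.getLogger(__name__)


def _round_half_up_pct(fraction: float) -> int:
    return int(np.floor(fraction * 100.0 + 0.5))


@dataclass
class GroupConsistencyTable:
    """Per-connection subject-presence table."""

    frame: pd.DataFrame   # seed_entity, target_label, target_region,
                          # n_present, n_total, fraction, retained
    group_frac: float

    def retained_targets(self, seed_entity: str) -> list[str]:
        f = self.frame
        sel = f[(f.seed_entity == seed_entity) & f.retained]
        return sel.target_region.tolist()

    def formatted(self) -> pd.DataFrame:
        """Table-style view: integer percentages (half-up), a dash for
        connections below the retention threshold."""
        f = self.frame.copy()
        f["percent"] = [
            f"{_round_half_up_pct(fr)}%" if ret else "—"
            for fr, ret in zip(f.fraction, f.retained)
        ]
        return f[["seed_entity", "target_region", "percent"]]


def _check_aligned(fingerprints: list[FingerprintMatrix], stage: str) -> None:
    if not fingerprints:
        raise ValueError("no fingerprints given")
    first = fingerprints[0]
    for fp in fingerprints:
        if fp.stage != stage:
            raise ValueError(f"expected stage {stage!r}, got {fp.stage!r}")
        if fp.seed_entities != first.seed_entities or not np.array_equal(
            fp.region_labels, first.region_labels
        ):
            raise ValueError("fingerprints have heterogeneous seed/target sets")


def consistency(fingerprints: list[FingerprintMatrix],
                config: PipelineConfig) -> GroupConsistencyTable:
    """Count, per connection, the subjects in which it survives
    thresholding, and flag retention under the group fraction rule."""
    _check_aligned(fingerprints, "thresholded")
    first = fingerprints[0]
    n_total = len(fingerprints)
    present = np.zeros_like(first.values, dtype=np.int64)
    for fp in fingerprints:
        present += (fp.counts > 0).astype(np.int64)
    rows = []
    for i, seed in enumerate(first.seed_entities):
        for j, lab in enumerate(first.region_labels.tolist()):
            n_present = int(present[i, j])
            frac = n_present / n_total
            rows.append(
                {
                    "seed_entity": seed,
                    "target_label": lab,
                    "target_region": first.region_names[j],
                    "n_present": n_present,
                    "n_total": n_total,
                    "fraction": frac,
                    "retained": frac >= config.group_frac,
                }
            )
    return GroupConsistencyTable(frame=pd.DataFrame(rows),
                                 group_frac=config.group_frac)


def fingerprint_summary(fingerprints: list[FingerprintMatrix]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean and sample SD (ddof=1) of normalised fingerprints.

    Returns arrays shaped like one fingerprint's ``values``.  A single
    subject yields zero SD with a warning.
    """
    _check_aligned(fingerprints, "normalised")
    stack = np.stack([fp.values for fp in fingerprints])
    mean = stack.mean(axis=0)
    if stack.shape[0] < 2:
        logger.warning("single-subject cohort: standard deviation set to 0")
        sd = np.zeros_like(mean)
    else:
        sd = stack.std(axis=0, ddof=1)
    return mean, sd


def compare_templates(table_a: GroupConsistencyTable,
                      table_b: GroupConsistencyTable) -> pd.DataFrame:
    """Side-by-side retention for two template variants.

    Connections retained under A but not B are flagged
    ``lost_after_cleansing`` — the raw-versus-grey-cleansed comparison this
    serves reveals connections carried purely by non-grey contamination.
    """
    a = table_a.frame.set_index("target_label")
    b = table_b.frame.set_index("target_label")
    common = a.index.union(b.index)
    if not a.index.equals(b.index):
        # tables must live on one target universe; tolerate ordering only
        if set(a.index) != set(b.index):
            raise ValueError("consistency tables target different region sets")
        b = b.loc[a.index]
    out = pd.DataFrame(
        {
            "target_region": a.target_region,
            "seed_a": a.seed_entity,
            "seed_b": b.seed_entity,
            "fraction_a": a.fraction,
            "fraction_b": b.fraction,
            "retained_a": a.retained,
            "retained_b": b.retained,
        },
        index=a.index,
    )
    out["lost_after_cleansing"] = out.retained_a & ~out.retained_b
    out["gained_after_cleansing"] = ~out.retained_a & out.retained_b
    return out.reset_index()


def plot_fingerprint_summary(mean: np.ndarray, sd: np.ndarray,
                             region_names: list[str], seed_entity: str,
                             path) -> None:
    """Bar plot of a seed's mean normalised connectivity with SD whiskers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m, s = np.asarray(mean).ravel(), np.asarray(sd).ravel()
    fig, ax = plt.subplots(figsize=(max(6, len(region_names) * 0.18), 4))
    x = np.arange(len(region_names))
    ax.bar(x, m, yerr=s, color="steelblue", ecolor="lightsteelblue")
    ax.set_xticks(x)
    ax.set_xticklabels(region_names, rotation=90, fontsize=5)
    ax.set_ylabel("normalised connectivity")
    ax.set_title(f"{seed_entity}: mean ± SD across subjects")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
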
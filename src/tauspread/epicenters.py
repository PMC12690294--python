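"""Individualized tau epicenter detection.

Within each subject, TPI values over the retained regions are z-scored
(sample SD, n−1) and regions with z at or above a threshold (default
1.645, the 95th percentile of a standard normal) are that subject's
epicenters — an outlier definition that lets the number of epicenters
vary across subjects. A canonical group alternative is the bilateral
entorhinal cortex. Sensitivity thresholds 1.96 and 2.32 are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import icc_2_1

logger = logging.getLogger(__name__)

__all__ = [
    "EpicenterSet",
    "detect_epicenters",
    "canonical_epicenters",
    "epicenter_frequency",
    "DEFAULT_Z_THRESHOLD",
    "SENSITIVITY_Z_THRESHOLDS",
]

DEFAULT_Z_THRESHOLD = 1.645
SENSITIVITY_Z_THRESHOLDS = (1.645, 1.96, 2.32)


@dataclass(frozen=True)
class EpicenterSet:
    """A subject's epicenters with their within-subject z-scores.

    ``subject`` is "canonical" for the group entorhinal set. ``degenerate``
    marks a zero-variance TPI row (empty set, subject to be excluded).
    """

    subject: str
    regions: tuple[str, ...]
    zscores: dict[str, float]
    threshold: float
    degenerate: bool = False

    def __len__(self) -> int:
        return len(self.regions)


def detect_epicenters(
    tpi_row: pd.Series,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    subject: str = "",
) -> EpicenterSet:
    """Identify epicenters as within-subject TPI z-score outliers.

    z_r = (TPI_r − mean) / SD with sample SD (ddof=1); a region is an
    epicenter iff z_r >= z_threshold. A zero-SD row yields an empty,
    degenerate set (warning, not an exception). An empty set is allowed —
    such subjects are excluded from statistical stages downstream.
    """
    x = tpi_row.to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(f"need >=3 retained regions, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite TPI for subject {subject!r}")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("subject %r has zero TPI variance; no epicenters",
                       subject)
        return EpicenterSet(subject, (), {}, z_threshold, degenerate=True)
    z = (x - x.mean()) / sd
    keep = z >= z_threshold
    regions = tuple(str(r) for r in tpi_row.index[keep])
    zscores = {str(r): float(v) for r, v in zip(tpi_row.index, z)}
    return EpicenterSet(subject, regions, zscores, z_threshold)


def canonical_epicenters(
    retained_regions,
    erc_labels: tuple[str, str] = ("ERC_L", "ERC_R"),
) -> EpicenterSet:
    """The canonical group epicenter set: bilateral entorhinal cortex.

    Both entorhinal labels must be present among the retained regions;
    the set is identical for every subject.
    """
    retained = set(map(str, retained_regions))
    missing = [lab for lab in erc_labels if lab not in retained]
    if missing:
        raise ValueError(
            f"canonical epicenter label(s) {missing} not among retained "
            "regions; check the label map")
    return EpicenterSet("canonical", tuple(erc_labels),
                        {lab: float("nan") for lab in erc_labels},
                        threshold=float("nan"))


def epicenter_frequency(
    sets,
    regions,
    fold_labels: dict[str, int] | None = None,
):
    """Per-region epicenter proportions, optionally with fold agreement.

    The proportion for a region is the share of subjects (with >=1
    epicenter) that include it. When ``fold_labels`` maps subjects to
    folds, also returns ICC(2,1) agreement: pairwise between fold
    frequency vectors and between each fold and the pooled vector.
    """
    regions = [str(r) for r in regions]
    nonempty = [s for s in sets if len(s) > 0]
    if not nonempty:
        raise ValueError("no non-empty epicenter sets")

    def freq(subset):
        counts = pd.Series(0.0, index=regions)
        for s in subset:
            for r in s.regions:
                counts[r] += 1
        return counts / len(subset)

    overall = freq(nonempty)
    if fold_labels is None:
        return overall

    folds = sorted(set(fold_labels.values()))
    by_fold = pd.DataFrame(
        {f: freq([s for s in nonempty if fold_labels.get(s.subject) == f])
         for f in folds})
    pairwise = {}
    for i, fa in enumerate(folds):
        for fb in folds[i + 1:]:
            m = by_fold[[fa, fb]].to_numpy()
            pairwise[(fa, fb)] = icc_2_1(m).icc
    vs_pooled = {
        f: icc_2_1(np.column_stack([by_fold[f].to_numpy(),
                                    overall.to_numpy()])).icc
        for f in folds}
    return overall, by_fold, pairwise, vs_pooled
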
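"""Group-consistency backbone thresholding.

Deterministic tractography produces spurious connections (normalization error,
partial-volume effects).  Before any topological computation, edges are kept
only when present in more than a stated fraction of subjects — the
"consistency backbone".  One mask is computed per study (subjects pooled
across groups by default) and applied to all four weightings of every subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConnectomeMatrix, StudyCohort, ValidationError

__all__ = ["BackboneMask", "consistency_mask", "apply_mask", "binarize",
           "apply_mask_cohort"]


@dataclass(frozen=True)
class BackboneMask:
    mask: np.ndarray          # N x N boolean, symmetric, False diagonal
    threshold: float
    n_subjects_used: int

    def __post_init__(self) -> None:
        m = self.mask
        if m.dtype != bool or not np.array_equal(m, m.T) or np.any(np.diag(m)):
            raise ValidationError("mask must be boolean, symmetric, with a "
                                  "False diagonal")

    @property
    def n_edges(self) -> int:
        return int(self.mask.sum() // 2)


def consistency_mask(cohort: StudyCohort, threshold: float = 0.75, *,
                     scope: str = "pooled", strict: bool = True,
                     presence_weighting: str = "FN") -> BackboneMask:
    """Keep edge (i, j) iff the fraction of subjects with a nonzero
    ``presence_weighting`` entry exceeds ``threshold``.

    ``scope="pooled"`` judges presence over all subjects together (default);
    ``scope="per-group"`` requires the criterion within every group, which is
    stricter.  ``strict`` selects > (default, reading "above 75%" literally)
    vs >= comparison.
    """
    if not cohort.subjects or len(cohort.subjects) < 2:
        raise ValidationError("backbone needs at least 2 subjects")
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie in (0, 1)")
    if scope not in ("pooled", "per-group"):
        raise ValidationError(f"unknown scope {scope!r}")

    stack = cohort.stack(presence_weighting) > 0
    cmp = np.greater if strict else np.greater_equal

    if scope == "pooled":
        frac = stack.mean(axis=0)
        mask = cmp(frac, threshold)
    else:
        labels = cohort.group_labels()
        mask = np.ones(stack.shape[1:], dtype=bool)
        for g in cohort.groups:
            frac = stack[labels == g].mean(axis=0)
            mask &= cmp(frac, threshold)
    np.fill_diagonal(mask, False)
    return BackboneMask(mask=mask, threshold=threshold,
                        n_subjects_used=len(cohort.subjects))


def apply_mask(m: ConnectomeMatrix, mask: BackboneMask) -> ConnectomeMatrix:
    """Zero every entry outside the mask; entries inside are unchanged."""
    if m.values.shape != mask.mask.shape:
        raise ValidationError(
            f"mask shape {mask.mask.shape} != matrix shape {m.values.shape}")
    vals = np.where(mask.mask, m.values, 0.0)
    return m.copy_with(vals)


def binarize(m: ConnectomeMatrix) -> ConnectomeMatrix:
    """Entry -> 1 if > 0 else 0; idempotent."""
    return m.copy_with((m.values > 0).astype(float), weighting="binary")


def apply_mask_cohort(cohort: StudyCohort, mask: BackboneMask) -> StudyCohort:
    """Apply one backbone mask to every weighting of every subject."""
    from .core import Subject
    subjects = [
        Subject(s.subject_id, s.group,
                {w: apply_mask(m, mask) for w, m in s.matrices.items()})
        for s in cohort.subjects
    ]
    return StudyCohort(subjects, cohort.atlas, meta=dict(cohort.meta))
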
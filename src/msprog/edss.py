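"""EDSS scale utilities.

The Expanded Disability Status Scale runs 0-10 in 0.5 steps.  The package
collapses it to three ordinal classes spanning the clinically meaningful
milestones EDSS 4.0 (limited ambulation) and 6.0 (ambulatory aid required):

* ``C1`` — EDSS <= 3.0 (no to mild disability)
* ``C2`` — EDSS 3.5-5.5 (moderate disability, limited impairment)
* ``C3`` — EDSS >= 6.0 (severe disability, ambulatory aid)
"""

from __future__ import annotations

import numpy as np

CLASSES = ("C1", "C2", "C3")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

#: Valid EDSS scores: 0.0, 0.5, ..., 10.0
VALID_EDSS = np.arange(0.0, 10.5, 0.5)


def validate_edss(scores) -> np.ndarray:
    """Check scores lie in [0, 10] on the half-point grid; return as array."""
    arr = np.asarray(scores, dtype=float)
    if arr.size and (
        np.any(arr < 0) or np.any(arr > 10) or np.any(np.abs(arr * 2 - np.round(arr * 2)) > 1e-9)
    ):
        bad = arr[(arr < 0) | (arr > 10) | (np.abs(arr * 2 - np.round(arr * 2)) > 1e-9)]
        raise ValueError(f"EDSS scores must be in 0-10 in 0.5 steps; offending values: {bad[:5]}")
    return arr


def edss_to_class(scores) -> np.ndarray:
    """Map numeric EDSS to class labels C1 (<=3.0), C2 (3.5-5.5), C3 (>=6.0)."""
    arr = validate_edss(scores)
    out = np.where(arr <= 3.0, "C1", np.where(arr < 6.0, "C2", "C3"))
    return out if np.ndim(scores) else out.item()


def class_edss_values(cls: str) -> np.ndarray:
    """All EDSS scores belonging to a class (used by the simulator)."""
    if cls == "C1":
        return np.arange(0.0, 3.5, 0.5)
    if cls == "C2":
        return np.arange(3.5, 6.0, 0.5)
    if cls == "C3":
        return np.arange(6.0, 10.5, 0.5)
    raise ValueError(f"unknown EDSS class {cls!r}")
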
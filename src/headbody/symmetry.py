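"""Mirror-symmetry analysis of marginal head and body orientation tuning.

Each unit's 8 x 8 mean-response matrix is normalized by its maximum over
the 64 stimuli and averaged over the other factor's levels, giving an
8-vector of marginal tuning per axis (head or body).  Across units, every
orientation then has a population vector of marginal responses; the
orientation-by-orientation distance matrix is ``1 - Pearson r`` between
those population vectors.  Mirror-symmetric populations show small
distances between reflected lateral orientations (e.g. 90 vs 270 degrees).
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import UnitRecording
from .stimuli import ORIENTATIONS
from .tuning import mean_response_matrix

__all__ = ["marginal_tuning", "population_marginals", "mirror_distance_matrix",
           "distance_table"]


def marginal_tuning(unit_matrix: np.ndarray, axis: str = "head") -> Optional[np.ndarray]:
    """Max-normalized marginal tuning vector over one factor.

    ``unit_matrix`` is the unit's 8 x 8 (head x body) mean-response matrix.
    The matrix is first normalized by its maximum over all 64 stimuli and
    then averaged across the other factor (normalize-then-average; the
    order matters for non-uniform responses).  Returns ``None`` when the
    unit's maximum response is not positive (unit excluded).
    """
    m = np.asarray(unit_matrix, dtype=float)
    if m.shape != (8, 8):
        raise ValueError("expected an 8 x 8 response matrix")
    peak = m.max()
    if peak <= 0:
        return None
    norm = m / peak
    if axis == "head":
        return norm.mean(axis=1)
    if axis == "body":
        return norm.mean(axis=0)
    raise ValueError(f"unknown axis {axis!r}")


def population_marginals(
    units: Iterable[UnitRecording],
    axis: str = "head",
    pose: str = "P1",
    centering: str = "MC",
    kind: str = "net",
) -> np.ndarray:
    """(n_units, 8) marginal tuning array, excluding non-driven units."""
    rows = []
    for u in units:
        v = marginal_tuning(mean_response_matrix(u, pose, centering, kind), axis)
        if v is not None:
            rows.append(v)
    if len(rows) < 2:
        raise ValueError("need at least 2 units with positive responses")
    return np.array(rows)


def mirror_distance_matrix(population_marginals: np.ndarray) -> np.ndarray:
    """8 x 8 matrix of ``1 - Pearson r`` between orientations' population
    marginal-tuning vectors; symmetric with zero diagonal, entries in
    [0, 2].  Entries are NaN when an orientation has zero variance across
    units."""
    m = np.asarray(population_marginals, dtype=float)
    if m.ndim != 2 or m.shape[1] != 8 or m.shape[0] < 2:
        raise ValueError("expected (n_units >= 2, 8) marginals")
    out = np.zeros((8, 8))
    sd = m.std(axis=0)
    for i in range(8):
        for j in range(i + 1, 8):
            if sd[i] == 0 or sd[j] == 0:
                d = float("nan")
            else:
                d = 1.0 - float(np.corrcoef(m[:, i], m[:, j])[0, 1])
            out[i, j] = out[j, i] = d
    return out


def distance_table(matrix: np.ndarray, axis: str = "head") -> pd.DataFrame:
    """Long-format tidy view of a distance matrix."""
    rows = []
    for i, oi in enumerate(ORIENTATIONS):
        for j, oj in enumerate(ORIENTATIONS):
            rows.append({"axis": axis, "orientation_a": oi, "orientation_b": oj,
                         "distance": matrix[i, j]})
    return pd.DataFrame(rows)
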
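"""Monkey-sum index, head x body interaction ANOVA and reliability machinery.

The monkey-sum index contrasts the net response to a whole monkey with the
summed net responses to its isolated head and body presented at matched
locations::

    MSI = (M - (B + H)) / (|M| + |B + H|)

MSI = -1 when the monkey is silent but the parts drive the unit, +1 for
the converse, and 0 for exact additivity.

Head x body interaction is tested with a balanced two-way ANOVA on
per-trial spike counts, by default variance-stabilized with
``sqrt(count + 3/8)`` (the Anscombe-type transform for Poisson counts).
The interaction structure itself is isolated as the residuals of the 8 x 8
mean-response matrix from the additive model ``head mean + body mean -
grand mean`` (double centering), and compared across centerings by Pearson
correlation.  Split-half reliabilities (Spearman-Brown corrected, averaged
over random splits) provide the attenuation correction for such
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .screening import baseline_rates, net_rates, response_rates
from .simulate import UnitRecording
from .stimuli import ORIENTATIONS, StimulusCondition, monkey_condition

__all__ = [
    "msi",
    "msi_case_select",
    "msi_table",
    "variance_stabilize",
    "two_way_anova",
    "headbody_anova",
    "additive_residuals",
    "mean_response_matrix",
    "centering_correlation",
    "residual_correlation",
    "split_half_reliability",
    "reliability_normalized_correlation",
    "InteractionResult",
]


def msi(m_net: float, b_net: float, h_net: float) -> float:
    """Monkey-sum index; NaN when the denominator is zero (case dropped)."""
    s = b_net + h_net
    denom = abs(m_net) + abs(s)
    if denom == 0:
        return float("nan")
    return float((m_net - s) / denom)


def _significant_excitatory(unit: UnitRecording, cond: StimulusCondition,
                            alpha: float) -> bool:
    base = baseline_rates(unit, cond, "baseline100")
    resp = response_rates(unit, cond)
    if np.all(base == base[0]) and np.all(resp == resp[0]) and base[0] == resp[0]:
        return False
    p = stats.ranksums(resp, base).pvalue
    return bool(p < alpha and resp.mean() > base.mean())


def msi_case_select(
    unit: UnitRecording,
    monkey_cond: StimulusCondition,
    head_cond: StimulusCondition,
    body_cond: StimulusCondition,
    alpha: float = 0.05,
) -> bool:
    """A case enters the MSI analysis when the monkey, head or body image
    drives a significant excitatory response (Wilcoxon rank-sum on the
    per-trial baseline vs response window rates)."""
    return any(
        _significant_excitatory(unit, c, alpha)
        for c in (monkey_cond, head_cond, body_cond)
    )


def _matched_triples(pose: str, centering: str,
                     grid: Sequence[StimulusCondition]):
    """(monkey, head, body) condition triples at matched locations."""
    by_key: Dict[tuple, StimulusCondition] = {}
    for c in grid:
        if c.pose == pose and c.centering == centering and c.inversion == "upright":
            by_key[(c.part, c.body_orientation, c.head_orientation,
                    c.anchor_orientation)] = c
    triples = []
    for c in grid:
        if (c.part != "monkey" or c.pose != pose or c.centering != centering
                or c.inversion != "upright"):
            continue
        b, h = c.body_orientation, c.head_orientation
        if centering == "MC":
            head = by_key.get(("head", None, h, b))
            body = by_key.get(("body", b, None, None))
        else:
            head = by_key.get(("head", None, h, None))
            body = by_key.get(("body", b, None, h))
        if head is not None and body is not None:
            triples.append((c, head, body))
    return triples


def msi_table(
    units: Iterable[UnitRecording],
    grid: Sequence[StimulusCondition],
    pose: str = "P1",
    centering: str = "MC",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-case MSI table over all matched monkey/head/body triples.

    Rows are (unit, orientation) cases that pass the case-selection screen
    and have a defined index; ``M``, ``B`` and ``H`` are mean net rates.
    """
    rows = []
    for unit in units:
        for m_cond, h_cond, b_cond in _matched_triples(pose, centering, grid):
            if m_cond not in unit.counts:
                continue
            if not msi_case_select(unit, m_cond, h_cond, b_cond, alpha=alpha):
                continue
            m = float(net_rates(unit, m_cond).mean())
            b = float(net_rates(unit, b_cond).mean())
            h = float(net_rates(unit, h_cond).mean())
            value = msi(m, b, h)
            if np.isnan(value):
                continue
            rows.append({
                "unit_id": unit.unit_id, "pose": pose, "centering": centering,
                "body_orientation": m_cond.body_orientation,
                "angle": m_cond.angle, "M": m, "B": b, "H": h, "msi": value,
            })
    return pd.DataFrame(rows)


def variance_stabilize(count):
    """Poisson variance-stabilizing transform ``sqrt(count + 3/8)``."""
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be nonnegative")
    return np.sqrt(count + 0.375)


def two_way_anova(data: np.ndarray) -> Dict[str, float]:
    """Balanced fixed-effects two-way ANOVA on ``data[a, b, n]``.

    Closed-form sums of squares for a complete balanced design (cross-checked
    against statsmodels' ``anova_lm`` in the test suite).  Returns F and p
    for both main effects and the interaction.
    """
    data = np.asarray(data, dtype=float)
    a, b, n = data.shape
    if n < 2:
        raise ValueError("need replicate trials in each cell")
    grand = data.mean()
    cell = data.mean(axis=2)
    row = cell.mean(axis=1)
    col = cell.mean(axis=0)
    ss_a = n * b * np.sum((row - grand) ** 2)
    ss_b = n * a * np.sum((col - grand) ** 2)
    ss_ab = n * np.sum((cell - row[:, None] - col[None, :] + grand) ** 2)
    ss_e = np.sum((data - cell[:, :, None]) ** 2)
    df_a, df_b, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    ms_e = ss_e / df_e
    out = {}
    for name, ss, df in (("a", ss_a, df_a), ("b", ss_b, df_b), ("ab", ss_ab, df_ab)):
        if ms_e == 0:
            out[f"F_{name}"], out[f"p_{name}"] = float("nan"), float("nan")
        else:
            F = (ss / df) / ms_e
            out[f"F_{name}"] = float(F)
            out[f"p_{name}"] = float(stats.f.sf(F, df, df_e))
    return out


def additive_residuals(mean_matrix: np.ndarray) -> np.ndarray:
    """Residuals from the additive model ``row mean + column mean - grand mean``.

    Row and column means of the result are zero to machine precision; the
    operator is idempotent.
    """
    m = np.asarray(mean_matrix, dtype=float)
    return m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + m.mean()


@dataclass
class InteractionResult:
    unit_id: str
    pose: str
    centering: str
    p_head: float
    p_body: float
    p_interaction: float
    residuals: np.ndarray  # 8 x 8, head orientation x body orientation


def _count_cube(unit: UnitRecording, pose: str, centering: str,
                inversion: str = "upright") -> np.ndarray:
    """Response-window counts arranged as (head, body, trial)."""
    first = monkey_condition(pose, ORIENTATIONS[0], 0, centering, inversion)
    if first not in unit.counts:
        raise ValueError("missing monkey conditions for this pose/centering")
    n = unit.counts[first].shape[0]
    cube = np.empty((8, 8, n), dtype=float)
    for i, h in enumerate(ORIENTATIONS):
        for j, b in enumerate(ORIENTATIONS):
            cond = StimulusCondition(pose=pose, part="monkey", body_orientation=b,
                                     head_orientation=h, centering=centering,
                                     inversion=inversion)
            if cond not in unit.counts:
                raise ValueError(f"missing cell {cond}")
            cube[i, j] = unit.counts[cond][:, 2]
    return cube


def headbody_anova(
    unit: UnitRecording,
    pose: str = "P1",
    centering: str = "MC",
    transform: bool = True,
    inversion: str = "upright",
) -> InteractionResult:
    """Two-way head x body orientation ANOVA on per-trial spike counts.

    ``transform=True`` (default, the reported variant) applies
    ``sqrt(count + 3/8)`` first.  Residuals are the double-centered 8 x 8
    matrix of cell means on the same scale as the ANOVA input.
    """
    cube = _count_cube(unit, pose, centering, inversion)
    if transform:
        cube = variance_stabilize(cube)
    res = two_way_anova(cube)
    return InteractionResult(
        unit_id=unit.unit_id,
        pose=pose,
        centering=centering,
        p_head=res["p_a"],
        p_body=res["p_b"],
        p_interaction=res["p_ab"],
        residuals=additive_residuals(cube.mean(axis=2)),
    )


def mean_response_matrix(
    unit: UnitRecording,
    pose: str = "P1",
    centering: str = "MC",
    kind: str = "net",
    inversion: str = "upright",
) -> np.ndarray:
    """8 x 8 (head x body orientation) matrix of mean responses."""
    mat = np.empty((8, 8))
    for i, h in enumerate(ORIENTATIONS):
        for j, b in enumerate(ORIENTATIONS):
            cond = StimulusCondition(pose=pose, part="monkey", body_orientation=b,
                                     head_orientation=h, centering=centering,
                                     inversion=inversion)
            rates = net_rates(unit, cond) if kind == "net" else response_rates(unit, cond)
            mat[i, j] = rates.mean()
    return mat


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def centering_correlation(unit: UnitRecording, pose: str = "P1",
                          kind: str = "net") -> float:
    """Pearson r of the 64 mean condition responses between MC and HC."""
    mc = mean_response_matrix(unit, pose, "MC", kind).ravel()
    hc = mean_response_matrix(unit, pose, "HC", kind).ravel()
    return _pearson(mc, hc)


def residual_correlation(unit: UnitRecording, pose: str = "P1",
                         transform: bool = True) -> float:
    """Pearson r between the MC and HC additive-model residual vectors."""
    res = []
    for centering in ("MC", "HC"):
        cube = _count_cube(unit, pose, centering)
        if transform:
            cube = variance_stabilize(cube)
        res.append(additive_residuals(cube.mean(axis=2)).ravel())
    return _pearson(res[0], res[1])


def split_half_reliability(
    unit: UnitRecording,
    conditions: Sequence[StimulusCondition],
    n_splits: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean Spearman-Brown corrected split-half Pearson correlation.

    Each split halves the trials of every condition at random, correlates
    the half-mean raw response rates across conditions, and corrects with
    ``2 r / (1 + r)``.  Degenerate splits (zero variance) are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = [response_rates(unit, c) for c in conditions]
    n = len(rates[0])
    half = n // 2
    vals = []
    for _ in range(n_splits):
        h1 = np.empty(len(rates))
        h2 = np.empty(len(rates))
        for k, r in enumerate(rates):
            perm = rng.permutation(n)
            h1[k] = r[perm[:half]].mean()
            h2[k] = r[perm[half:]].mean()
        r_half = _pearson(h1, h2)
        if np.isnan(r_half):
            continue
        vals.append(2 * r_half / (1 + r_half))
    return float(np.mean(vals)) if vals else float("nan")


def reliability_normalized_correlation(r: float, rel_a: float, rel_b: float) -> float:
    """Attenuation correction ``r / sqrt(rel_a * rel_b)``.

    Requires positive reliabilities; the result may exceed 1 for noisy
    small samples and is deliberately not clipped.
    """
    if rel_a <= 0 or rel_b <= 0:
        raise ValueError("reliabilities must be positive")
    return float(r / np.sqrt(rel_a * rel_b))
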
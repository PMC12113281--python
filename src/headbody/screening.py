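"""Firing-rate extraction and unit responsiveness / selectivity screening.

Units enter the analyses only if they pass a screen.  For the single-unit
experiment the screen is a split-plot ANOVA (within-trial factor: baseline
versus response window; between-trial factor: stimulus) with an excitatory
best-stimulus response.  The probe experiments add a Kruskal-Wallis test
across stimuli on raw response rates and a z-score criterion
``(meanRespStim - meanBaseAll) / stdBaseAll > 3`` for at least one
stimulus, where the mean and SD of the baseline are taken across the
per-stimulus mean baseline rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import UnitRecording
from .stimuli import BASELINE100_S, BASELINE200_S, RESPONSE_S, StimulusCondition


def response_rates(unit: UnitRecording, cond: StimulusCondition) -> np.ndarray:
    """Per-trial raw response-window rates, spikes/s."""
    return unit.counts[cond][:, 2] / RESPONSE_S


def baseline_rates(unit: UnitRecording, cond: StimulusCondition,
                   window: str = "baseline100") -> np.ndarray:
    if window == "baseline100":
        return unit.counts[cond][:, 0] / BASELINE100_S
    if window == "baseline200":
        return unit.counts[cond][:, 1] / BASELINE200_S
    raise ValueError(f"unknown window {window!r}")


def net_rates(unit: UnitRecording, cond: StimulusCondition) -> np.ndarray:
    """Per-trial net rates: response minus the 100-ms pre-stimulus baseline."""
    return response_rates(unit, cond) - baseline_rates(unit, cond, "baseline100")


def compute_rates(unit: UnitRecording) -> pd.DataFrame:
    """Tidy per-trial rate table (baseline100/baseline200/response/net, spikes/s)."""
    rows = []
    for cond, counts in unit.counts.items():
        if np.any(counts < 0):
            raise ValueError(f"negative counts for {cond}")
        for t in range(counts.shape[0]):
            b100, b200, resp = counts[t]
            rows.append({
                "unit_id": unit.unit_id,
                "pose": cond.pose,
                "part": cond.part,
                "body_orientation": cond.body_orientation,
                "head_orientation": cond.head_orientation,
                "centering": cond.centering,
                "inversion": cond.inversion,
                "anchor_orientation": cond.anchor_orientation,
                "trial_index": t,
                "baseline100_rate": b100 / BASELINE100_S,
                "baseline200_rate": b200 / BASELINE200_S,
                "response_rate": resp / RESPONSE_S,
                "net_rate": resp / RESPONSE_S - b100 / BASELINE100_S,
            })
    return pd.DataFrame(rows)


def splitplot_responsiveness(
    unit: UnitRecording, conditions: Sequence[StimulusCondition]
) -> Tuple[float, float, bool]:
    """Split-plot ANOVA of window (baseline-200 ms vs response) by stimulus.

    Returns ``(p_window, p_interaction, excitatory)``; ``excitatory`` is
    True when the best stimulus (largest mean response rate) responds above
    its mean baseline.  Degenerate data yield NaN p-values (unit fails).
    """
    import pingouin as pg

    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    recs = []
    uid = 0
    for si, cond in enumerate(conditions):
        base = baseline_rates(unit, cond, "baseline200")
        resp = response_rates(unit, cond)
        if len(base) < 2:
            raise ValueError("need at least 2 trials per condition")
        for b, r in zip(base, resp):
            recs.append((uid, si, "baseline", b))
            recs.append((uid, si, "response", r))
            uid += 1
    df = pd.DataFrame(recs, columns=["trial", "stimulus", "window", "rate"])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(data=df, dv="rate", within="window",
                                 between="stimulus", subject="trial")
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        p_main = float(aov.loc[aov["Source"] == "window", pcol].iloc[0])
        p_inter = float(aov.loc[aov["Source"] == "Interaction", pcol].iloc[0])
    except Exception:
        p_main, p_inter = float("nan"), float("nan")
    mean_resp = np.array([response_rates(unit, c).mean() for c in conditions])
    best = int(np.argmax(mean_resp))
    excitatory = bool(net_rates(unit, conditions[best]).mean() > 0)
    return p_main, p_inter, excitatory


def kruskal_selectivity(
    unit: UnitRecording, conditions: Sequence[StimulusCondition]
) -> float:
    """Kruskal-Wallis p-value across stimuli on raw per-trial response rates."""
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    groups = [response_rates(unit, c) for c in conditions]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all rates identical
        return float("nan")


def zscore_screen(
    unit: UnitRecording, conditions: Sequence[StimulusCondition]
) -> float:
    """Max per-stimulus z-score ``(meanRespStim - meanBaseAll) / stdBaseAll``.

    ``stdBaseAll`` is the SD across the per-stimulus mean baseline rates;
    returns NaN when that SD is zero (the unit then fails the screen).
    """
    mean_resp = np.array([response_rates(unit, c).mean() for c in conditions])
    mean_base = np.array([baseline_rates(unit, c, "baseline100").mean()
                          for c in conditions])
    std_base = mean_base.std(ddof=1)
    if std_base == 0:
        return float("nan")
    z = (mean_resp - mean_base.mean()) / std_base
    return float(z.max())


def category_filter(category_nets: Mapping[str, float]) -> bool:
    """Selectivity-test category criterion: net response to monkey, face or
    body at least twice the matched object control (inclusive)."""
    for cat in ("monkey", "face", "body"):
        if category_nets[cat] >= 2.0 * category_nets[f"{cat}_control"]:
            return True
    return False


@dataclass
class ScreeningVerdict:
    unit_id: str
    splitplot_p_main: float
    splitplot_p_interaction: float
    excitatory: bool
    kruskal_p: float = float("nan")
    max_z: float = float("nan")
    passed: bool = False


def screen_unit(
    unit: UnitRecording,
    conditions: Sequence[StimulusCondition],
    experiment: str = "E1",
    alpha: float = 0.05,
) -> ScreeningVerdict:
    """Full conjunctive screen for one unit.

    ``E1``: split-plot responsiveness (window main effect or interaction,
    p < alpha) and an excitatory best-stimulus response.  ``E2``/``E3``:
    additionally Kruskal-Wallis p < alpha and max z-score > 3.
    """
    p_main, p_inter, excit = splitplot_responsiveness(unit, conditions)
    responsive = ((p_main < alpha) or (p_inter < alpha)) and excit
    kw = mz = float("nan")
    passed = bool(responsive)
    if experiment in ("E2", "E3"):
        kw = kruskal_selectivity(unit, conditions)
        mz = zscore_screen(unit, conditions)
        passed = bool(responsive and (kw < alpha) and (mz > 3.0))
    return ScreeningVerdict(
        unit_id=unit.unit_id,
        splitplot_p_main=p_main,
        splitplot_p_interaction=p_inter,
        excitatory=excit,
        kruskal_p=kw,
        max_z=mz,
        passed=passed,
    )


def screen_population(
    units: Iterable[UnitRecording],
    conditions: Sequence[StimulusCondition],
    experiment: str = "E1",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screening verdicts for a whole population, one row per unit."""
    rows = []
    for u in units:
        v = screen_unit(u, conditions, experiment=experiment, alpha=alpha)
        rows.append({
            "unit_id": v.unit_id,
            "region": u.region,
            "subject": u.subject,
            "splitplot_p_main": v.splitplot_p_main,
            "splitplot_p_interaction": v.splitplot_p_interaction,
            "excitatory": v.excitatory,
            "kruskal_p": v.kruskal_p,
            "max_z": v.max_z,
            "passed": v.passed,
        })
    return pd.DataFrame(rows)
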
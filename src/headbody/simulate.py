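"""Synthetic unit populations with controllable head-body conjunctive tuning.

Each simulated unit fires Poisson spike counts whose expected rate is

``baseline + part_weight * a * gain * core``

where the driven ``core`` combines peak-normalized von Mises tuning bumps
for head orientation ``f_H`` and body orientation ``f_B``:

* whole monkey: ``(1 - w_conj) * (f_H + f_B) / 2 + w_conj * f_H * f_B``
* isolated head: ``f_H``; isolated body: ``f_B``
* ``a = a_inv`` for inverted stimuli, 1 for upright.

``w_conj = 0`` makes the expected whole-monkey response exactly additive in
head and body terms (zero interaction); ``w_conj = 1`` makes it purely
conjunctive.  Mirror symmetry is introduced by blending each tuning bump
with its reflection: ``f(theta) -> (1 - m) * vm(theta) + m * (vm(theta) +
vm(-theta)) / 2``, so ``m_mirror = 1`` makes the expected rate invariant
under joint reflection of head and body orientation.  Position (centering)
tolerance is a mixture: away from the reference centering the tuned core is
scaled by ``c_tol`` and a fixed per-unit random pattern is mixed in with
weight ``1 - c_tol``, reproducing graded MC-HC tuning correlations without
modeling retinotopy.  Units are statistically independent (the downstream
pseudo-population construction discards noise correlations anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .stimuli import (
    BASELINE100_S,
    BASELINE200_S,
    RESPONSE_S,
    INVERSIONS,
    PARTS,
    POSES,
    StimulusCondition,
)

REFERENCE_CENTERING = "MC"


@dataclass(frozen=True)
class TuningParams:
    """Generative parameters of one synthetic unit.

    Angles in degrees, concentrations dimensionless (>= 0), ``gain`` and
    ``baseline`` in spikes/s.  ``part_weights`` gives the relative drive of
    (monkey, head, body) stimuli; (1, 0.5, 0.5) makes net monkey response
    equal the summed net part responses when ``w_conj = 0``.
    """

    mu_head: float = 0.0
    mu_body: float = 0.0
    kappa_head: float = 2.0
    kappa_body: float = 2.0
    w_conj: float = 0.0
    m_mirror: float = 0.0
    c_tol: float = 1.0
    a_inv: float = 1.0
    gain: float = 30.0
    baseline: float = 10.0
    part_weights: Tuple[float, float, float] = (1.0, 0.5, 0.5)
    pattern_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("w_conj", "m_mirror", "c_tol", "a_inv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("kappa_head", "kappa_body", "gain", "baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.part_weights) != 3 or any(not 0 <= w <= 1 for w in self.part_weights):
            raise ValueError("part_weights must be three values in [0, 1]")


@dataclass
class UnitRecording:
    """Trial-wise spike counts of one unit over a set of stimulus conditions.

    ``counts[cond]`` is an integer array of shape ``(n_trials, 3)`` holding
    the 100-ms baseline, 200-ms baseline and 250-ms response-window counts.
    """

    unit_id: str
    region: str = "aSTS"
    subject: str = "M1"
    counts: Dict[StimulusCondition, np.ndarray] = field(default_factory=dict)

    @property
    def conditions(self) -> List[StimulusCondition]:
        return list(self.counts)

    def n_trials(self, cond: StimulusCondition) -> int:
        return self.counts[cond].shape[0]


def _vm(theta_deg: np.ndarray | float, mu_deg: float, kappa: float):
    """von Mises bump normalized to peak 1 (flat when kappa = 0)."""
    return np.exp(kappa * (np.cos(np.radians(np.asarray(theta_deg, float) - mu_deg)) - 1.0))


def _mirror_factor(theta: float, mu: float, kappa: float, m: float) -> float:
    plain = _vm(theta, mu, kappa)
    if m == 0.0:
        return float(plain)
    sym = 0.5 * (_vm(theta, mu, kappa) + _vm(-theta, mu, kappa))
    return float((1.0 - m) * plain + m * sym)


def _condition_token(cond: StimulusCondition) -> Tuple[int, ...]:
    def enc(v: Optional[int]) -> int:
        return 8 if v is None else v // 45

    return (
        POSES.index(cond.pose),
        PARTS.index(cond.part),
        enc(cond.body_orientation),
        enc(cond.head_orientation),
        enc(cond.anchor_orientation),
        INVERSIONS.index(cond.inversion),
    )


def _unit_pattern(params: TuningParams, cond: StimulusCondition) -> float:
    """Fixed per-unit pseudo-random drive in [0, 1) for non-reference centerings."""
    seed = (params.pattern_seed,) + _condition_token(cond)
    return float(np.random.default_rng(seed).uniform())


def expected_rate(params: TuningParams, cond: StimulusCondition) -> float:
    """Expected response-window firing rate (spikes/s) for one condition."""
    fH = lambda h: _mirror_factor(h, params.mu_head, params.kappa_head, params.m_mirror)
    fB = lambda b: _mirror_factor(b, params.mu_body, params.kappa_body, params.m_mirror)
    if cond.part == "monkey":
        h, b = cond.head_orientation, cond.body_orientation
        core = (1 - params.w_conj) * 0.5 * (fH(h) + fB(b)) + params.w_conj * fH(h) * fB(b)
        pw = params.part_weights[0]
    elif cond.part == "head":
        core = fH(cond.head_orientation)
        pw = params.part_weights[1]
    else:
        core = fB(cond.body_orientation)
        pw = params.part_weights[2]
    if cond.centering != REFERENCE_CENTERING:
        core = params.c_tol * core + (1 - params.c_tol) * _unit_pattern(params, cond)
    a = params.a_inv if cond.inversion == "inverted" else 1.0
    rate = params.baseline + pw * a * params.gain * core
    if rate < 0:
        raise ValueError("negative expected rate (invalid construction)")
    return float(rate)


def simulate_unit(
    params: TuningParams,
    grid: Sequence[StimulusCondition],
    n_trials: int = 8,
    seed: int | np.random.Generator = 0,
    unit_id: str = "u000",
    region: str = "aSTS",
    subject: str = "M1",
) -> UnitRecording:
    """Poisson spike counts for every condition of ``grid``.

    Baseline windows draw from the baseline rate only; the response window
    from the condition's expected rate, each scaled by its window duration.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts: Dict[StimulusCondition, np.ndarray] = {}
    for cond in grid:
        rate = expected_rate(params, cond)
        lam = np.array([
            params.baseline * BASELINE100_S,
            params.baseline * BASELINE200_S,
            rate * RESPONSE_S,
        ])
        counts[cond] = rng.poisson(lam, size=(n_trials, 3)).astype(np.int64)
    return UnitRecording(unit_id=unit_id, region=region, subject=subject, counts=counts)


def default_param_sampler(
    w_conj: float = 0.5,
    m_mirror: float = 0.0,
    c_tol: float = 0.7,
    a_inv: float = 1.0,
    gain: float = 40.0,
    baseline: float = 10.0,
    kappa_range: Tuple[float, float] = (1.0, 3.0),
    part_weights: Tuple[float, float, float] = (1.0, 0.5, 0.5),
) -> Callable[[np.random.Generator], TuningParams]:
    """Sampler of unit parameters with random preferred orientations.

    Preferred head and body orientations are drawn independently and
    uniformly on the circle and concentrations uniformly in ``kappa_range``;
    everything else is shared across the population, so a sweep of e.g.
    ``w_conj`` changes exactly one population property.
    """

    def sample(rng: np.random.Generator) -> TuningParams:
        return TuningParams(
            mu_head=float(rng.uniform(0, 360)),
            mu_body=float(rng.uniform(0, 360)),
            kappa_head=float(rng.uniform(*kappa_range)),
            kappa_body=float(rng.uniform(*kappa_range)),
            w_conj=w_conj,
            m_mirror=m_mirror,
            c_tol=c_tol,
            a_inv=a_inv,
            gain=gain,
            baseline=baseline,
            part_weights=part_weights,
            pattern_seed=int(rng.integers(0, 2**31 - 1)),
        )

    return sample


def simulate_population(
    n_units: int,
    param_sampler: Callable[[np.random.Generator], TuningParams],
    grid: Sequence[StimulusCondition],
    n_trials: int = 8,
    seed: int = 0,
    region: str = "aSTS",
    subjects: Sequence[str] = ("M1", "M2"),
) -> List[UnitRecording]:
    """i.i.d. units from ``param_sampler`` with alternating subject labels."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_units):
        params = param_sampler(rng)
        units.append(
            simulate_unit(
                params,
                grid,
                n_trials=n_trials,
                seed=rng,
                unit_id=f"u{i:03d}",
                region=region,
                subject=subjects[i % len(subjects)],
            )
        )
    return units
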
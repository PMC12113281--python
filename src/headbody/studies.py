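"""Canonical synthetic study conditions.

The validation studies exercise the analysis chain on populations with
known ground truth.  Their generative conditions are fixed here once so
the test suite, the acceptance script and the examples all draw from the
same populations:

* decoding studies use strongly driven units (baseline 10 spikes/s, gain
  60 spikes/s, von Mises concentrations 1.5-3), the regime in which the
  population contrasts of interest are clearly expressed;
* ANOVA calibration uses moderately driven units (gain 20 spikes/s): the
  square-root transform's additive null holds to first order only when
  the response modulation is moderate relative to baseline (the transform
  is concave, so strong rate-additive modulation acquires a small genuine
  interaction on the transformed scale).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

from .simulate import UnitRecording, default_param_sampler, simulate_population
from .stimuli import ORIENTATIONS, StimulusCondition, monkey_conditions

DECODING_BASELINE = 10.0
DECODING_GAIN = 60.0
DECODING_KAPPA = (1.5, 3.0)
CALIBRATION_BASELINE = 10.0
CALIBRATION_GAIN = 20.0


def decoding_population(
    n_units: int = 60,
    w_conj: float = 1.0,
    m_mirror: float = 0.0,
    a_inv: float = 1.0,
    c_tol: float = 1.0,
    seed: int = 0,
    grid: Optional[Sequence[StimulusCondition]] = None,
    angles: Sequence[int] = (0, 180),
    pose: str = "P1",
    centering: str = "MC",
    inversions: Sequence[str] = ("upright",),
    gain: float = DECODING_GAIN,
) -> List[UnitRecording]:
    """A population under the standard decoding-study conditions."""
    if grid is None:
        grid = [c for inv in inversions
                for c in monkey_conditions(pose, centering, angles=angles,
                                           inversion=inv)]
    sampler = default_param_sampler(
        w_conj=w_conj, m_mirror=m_mirror, a_inv=a_inv, c_tol=c_tol,
        gain=gain, baseline=DECODING_BASELINE, kappa_range=DECODING_KAPPA,
    )
    return simulate_population(n_units, sampler, grid, seed=seed)


def calibration_population(
    n_units: int = 500,
    w_conj: float = 0.0,
    seed: int = 0,
    pose: str = "P1",
    centering: str = "MC",
) -> List[UnitRecording]:
    """Rate-additive Poisson units for type-I calibration of the
    head x body interaction ANOVA."""
    grid = monkey_conditions(pose, centering)
    sampler = default_param_sampler(
        w_conj=w_conj, c_tol=1.0, gain=CALIBRATION_GAIN,
        baseline=CALIBRATION_BASELINE,
    )
    return simulate_population(n_units, sampler, grid, seed=seed)
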
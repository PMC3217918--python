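"""Synthetic ratio time courses and the packaged mammosphere fixture.

The generator draws noisy observations of the model's ratio trajectory
r(t) at a stated parameter set, observation schedule, and noise level --
the same statistical structure the fitting pipeline assumes -- so every
stage can be exercised without external data.  The default noise model is
multiplicative lognormal on the ratio: observed ratios in a long-term
culture span three orders of magnitude (0.04 to ~66 here) and
flow-cytometry proportion error is approximately relative.  An additive
Gaussian mode matches the Gaussian likelihood exactly.

``table1_fixture`` returns the published 12-point MCF-7 mammosphere time
course (day 0 sorting purity 96.2% CSCs, i.e. r0 = 0.0395, through day 160
at 1.5%), stored verbatim at the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .inference import TimeCourse
from .model import RateParams, ratio_to_percent, ratio_trajectory

__all__ = ["SimDesign", "generate_timecourse", "table1_fixture",
           "TABLE1_TIMES"]

# observation schedule of the packaged experiment (days)
TABLE1_TIMES = (0, 28, 52, 70, 84, 92, 105, 117, 128, 137, 150, 160)


@dataclass(frozen=True)
class SimDesign:
    """Design of one simulated time course.

    Defaults mimic the packaged experiment: 12 observations over 160 days
    starting from a sorted population of 96.2% CSCs (r0 = 0.0395), with 5%
    multiplicative lognormal noise on the ratio.
    """

    params: RateParams = RateParams(k1=0.2, k2=0.22, a=0.01, b=0.001)
    r0: float = 0.0395
    times: tuple[float, ...] = TABLE1_TIMES
    noise: str = "lognormal"  # or "additive"
    noise_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.noise not in ("lognormal", "additive"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not (self.r0 >= 0):
            raise ValueError("r0 must be >= 0")


def generate_timecourse(design: SimDesign) -> TimeCourse:
    """Draw one noisy observation of the ratio trajectory.

    Lognormal mode multiplies the model curve by exp(sigma * Z); additive
    mode adds sigma * Z and clips at zero to respect ratio non-negativity.
    Reproducible for a fixed seed; at noise_scale 0 the exact model curve
    is returned.
    """
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.times, float)
    curve = ratio_trajectory(design.params, design.r0)(times)
    if design.noise_scale == 0:
        observed = curve
    elif design.noise == "lognormal":
        observed = curve * np.exp(design.noise_scale
                                  * rng.standard_normal(times.size))
    else:
        observed = np.clip(curve + design.noise_scale
                           * rng.standard_normal(times.size), 0.0, None)
    return TimeCourse(times=times, ratio=observed,
                      percent=ratio_to_percent(observed))


def table1_fixture() -> TimeCourse:
    """The packaged 12-row mammosphere time course, at printed precision."""
    with resources.files("cscdrift.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return TimeCourse(times=df["time_days"].to_numpy(float),
                      ratio=df["ratio"].to_numpy(float),
                      percent=df["csc_percent"].to_numpy(float))
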
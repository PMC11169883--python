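"""Synthetic measurement-campaign generator.

The real sensor dataset behind the moisture models is not publicly deposited,
so this module emulates the measurement campaign it came from: 16 wet-basis
moisture levels between 5.64% and 23.52%, three replicate 720 g samples per
level, ambient temperatures of 15, 22 and 33 degC and volume duty cycles of
0, 1/6, 1/4, 1/3 and 1/2 -- a 16 x 3 x 3 x 5 factorial of 720 records.

The noiseless capacitance surface is anchored to the empirical straight line
``C = 0.30744 W + 17.28085`` (pF) at the reference condition (22 degC, duty
1/3) and extended multiplicatively along the other two axes:

    C(W, T, v) = (0.30744 W + 17.28085)
                 * [1 + k_T (T - 22) (1 + lambda W)]
                 * [1 + k_v (v - 1/3)]            for v > 0,

so capacitance increases with temperature (more steeply at high moisture) and
with duty cycle, matching the qualitative trends reported for the physical
sensor.  At duty cycle 0 the plates are empty and the record is an air
baseline carrying no moisture information.  Measurement noise is additive
i.i.d. Gaussian.  The multiplicative form and its coefficients are this
package's own invention -- the source measurements give trends, not an
equation -- and every coefficient is exposed in :class:`NoiseModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .dielectric import linear_calibration

__all__ = [
    "MOISTURE_LEVELS_PERCENT",
    "TEMPERATURES_C",
    "DUTY_CYCLES",
    "CampaignDesign",
    "NoiseModel",
    "expected_capacitance",
    "generate_campaign",
    "split_train_test",
    "difference_channels",
    "CAMPAIGN_COLUMNS",
]

#: The 16 prepared wet-basis moisture levels (%), including the as-harvested
#: initial level 14.42%.
MOISTURE_LEVELS_PERCENT = (
    5.64, 8.36, 8.62, 11.65, 12.04, 12.17, 13.57, 14.42,
    15.99, 16.26, 17.65, 19.52, 21.51, 22.58, 23.27, 23.52,
)

TEMPERATURES_C = (15.0, 22.0, 33.0)
DUTY_CYCLES = (0.0, 1.0 / 6.0, 1.0 / 4.0, 1.0 / 3.0, 1.0 / 2.0)

CAMPAIGN_COLUMNS = (
    "sample_id",
    "moisture_percent",
    "temperature_C",
    "duty_cycle",
    "capacitance_pF",
    "replicate",
)

#: Reference condition at which the linear calibration was fitted.
_REF_TEMPERATURE_C = 22.0
_REF_DUTY_CYCLE = 1.0 / 3.0


@dataclass(frozen=True)
class CampaignDesign:
    """Factorial layout of the measurement campaign (720 records by default)."""

    moisture_levels_percent: tuple = MOISTURE_LEVELS_PERCENT
    replicates_per_level: int = 3
    temperatures_C: tuple = TEMPERATURES_C
    duty_cycles: tuple = DUTY_CYCLES

    def __post_init__(self) -> None:
        levels = self.moisture_levels_percent
        if list(levels) != sorted(levels):
            raise ValueError("moisture levels must be sorted ascending")
        if len(set(levels)) != len(levels):
            raise ValueError("moisture levels must be distinct")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")

    @property
    def n_records(self) -> int:
        return (
            len(self.moisture_levels_percent)
            * self.replicates_per_level
            * len(self.temperatures_C)
            * len(self.duty_cycles)
        )


@dataclass(frozen=True)
class NoiseModel:
    """Noise level and the non-reference-axis response coefficients.

    sigma_capacitance : additive Gaussian noise SD, pF (0.4 default).
    temp_coefficient : fractional capacitance change per degC away from the
        22 degC reference (k_T = 0.004).
    moisture_gain : extra temperature sensitivity per moisture percent
        (lambda = 0.05), making the temperature trend steeper for wet grain.
    duty_coefficient : fractional change per unit duty cycle away from the
        1/3 reference (k_v = 0.6).
    baseline_air : empty-plate (duty 0) capacitance, pF.
    seed : default RNG seed for :func:`generate_campaign`.

    All coefficients are package inventions (no measured equation exists for
    these axes); they are positive so the generated surface rises with
    moisture, temperature and duty cycle.
    """

    sigma_capacitance: float = 0.4
    temp_coefficient: float = 0.004
    moisture_gain: float = 0.05
    duty_coefficient: float = 0.6
    baseline_air: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_capacitance < 0:
            raise ValueError("sigma_capacitance must be >= 0")
        for name in ("temp_coefficient", "moisture_gain", "duty_coefficient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (monotone response contract)")


def expected_capacitance(w_percent, temperature_C, duty_cycle, noise: NoiseModel = NoiseModel()):
    """Noiseless mean capacitance (pF) of the generator surface.

    Exactly the linear calibration at the (22 degC, duty 1/3) reference;
    the air baseline at duty 0.  Vectorized over all three inputs.
    """
    w = np.asarray(w_percent, dtype=float)
    t = np.asarray(temperature_C, dtype=float)
    v = np.asarray(duty_cycle, dtype=float)
    w, t, v = np.broadcast_arrays(w, t, v)
    base = linear_calibration(w)
    temp_factor = 1.0 + noise.temp_coefficient * (t - _REF_TEMPERATURE_C) * (
        1.0 + noise.moisture_gain * w
    )
    duty_factor = 1.0 + noise.duty_coefficient * (v - _REF_DUTY_CYCLE)
    c = np.where(v > 0, base * temp_factor * duty_factor, noise.baseline_air)
    return float(c) if c.ndim == 0 else c


def generate_campaign(
    design: CampaignDesign = CampaignDesign(),
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the full factorial campaign as a tidy record table.

    Row order is deterministic (levels, replicates, temperatures, duty
    cycles, nested in that order) and the noise stream is fixed by ``seed``
    (falling back to ``noise.seed``), so identical inputs give identical
    tables.
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    rows = []
    for li, w in enumerate(design.moisture_levels_percent, start=1):
        for rep in range(1, design.replicates_per_level + 1):
            sample_id = f"M{li:02d}R{rep}"
            for t in design.temperatures_C:
                for v in design.duty_cycles:
                    rows.append((sample_id, w, t, v, rep))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "moisture_percent", "temperature_C", "duty_cycle", "replicate"]
    )
    mean = expected_capacitance(
        frame["moisture_percent"].to_numpy(),
        frame["temperature_C"].to_numpy(),
        frame["duty_cycle"].to_numpy(),
        noise,
    )
    eta = rng.normal(0.0, noise.sigma_capacitance, size=len(frame)) if noise.sigma_capacitance > 0 else 0.0
    frame["capacitance_pF"] = mean + eta
    return frame[list(CAMPAIGN_COLUMNS)]


def split_train_test(
    records: pd.DataFrame,
    test_fraction: float = 0.25,
    seed: int | None = None,
    stratify_by: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/prediction split (3:1 by default).

    The test-set size is ``floor(n * test_fraction)`` (720 records -> 540
    training / 180 prediction); any remainder therefore stays in the training
    set.  Deterministic given ``seed``.  Simple random by default; pass a
    column name to stratify.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n_test = int(len(records) * test_fraction)
    if n_test < 1:
        raise ValueError(f"too few records ({len(records)}) for test_fraction={test_fraction}")
    strat = records[stratify_by] if stratify_by is not None else None
    train, test = train_test_split(
        records, test_size=n_test, random_state=seed, shuffle=True, stratify=strat
    )
    return train, test


def difference_channels(detection, reference) -> np.ndarray:
    """Elementwise detection-minus-reference channel differencing.

    Subtracting the simultaneously sampled reference (air) channel rejects
    common-mode drift: adding the same offset to both channels leaves the
    output unchanged.
    """
    det = np.asarray(detection, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if det.shape != ref.shape:
        raise ValueError(f"channel length mismatch: {det.shape} vs {ref.shape}")
    return det - ref
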
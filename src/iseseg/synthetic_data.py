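"""Synthetic inputs for the whole pipeline.

Generates everything the analysis consumes — clone karyotypes with a
known truth, GS-class counts drawn from the segregation model at chosen
(tb, cb), and realistic fluorescence event vectors — so that mixture
decomposition, parameter fitting and the G-tests can all be exercised
and validated end to end without instrument data.

A simulated sample mimics a propidium-iodide measurement: each male GS
class produces a Gaussian event peak centred at its genome size scaled
so that the diploid female internal standard sits at a fixed reference
channel; peak width is set by a coefficient of variation chosen inside
the empirically realistic 1.7-3.95% range; a configurable fraction of
events is uniform debris.  Stage series (synchronized eggs, accumulated
eggs, hatched males) share one underlying class distribution unless
per-class viability weights are configured, which emulates selective
mortality during male embryonic development.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mixture import FluorescenceSample
from .segmodel import (
    ClassDistribution,
    IseKaryotype,
    SegParams,
    class_distribution,
    male_genome_size,
)
from .stats import ClassCounts

__all__ = [
    "SimConfig",
    "REFERENCE_CHANNEL",
    "STAGES",
    "class_positions",
    "simulate_clone_sample",
    "simulate_stage_series",
    "simulate_hatching_table",
]

#: Fluorescence channel at which the female internal-standard peak is
#: placed (arbitrary units; instrument channels are arbitrary anyway).
REFERENCE_CHANNEL = 1000.0

STAGES = ("sync", "accum", "hatched")


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to simulate one clone's measurement.

    ``n_events_per_male`` sets how many nuclei each male contributes to
    the fluorescence trace; ``female_events`` how many the pooled
    internal-standard females contribute.  ``stage_effects`` maps a
    stage label to per-class relative viability weights (renormalised
    internally); stages without an entry reproduce the meiotic truth.
    """

    karyotype: IseKaryotype
    params: SegParams
    seed: int
    n_males: int = 200
    n_events_per_male: int = 25
    female_events: int = 2000
    cv_percent: float = 2.5
    background_fraction: float = 0.05
    stage_effects: Optional[Mapping[str, Sequence[float]]] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.5 <= self.cv_percent <= 6.0):
            raise ValueError("cv_percent must lie in [0.5, 6]")
        if not (0.0 <= self.background_fraction <= 0.5):
            raise ValueError("background_fraction must lie in [0, 0.5]")
        if self.n_males < 1 or self.n_events_per_male < 1:
            raise ValueError("n_males and n_events_per_male must be >= 1")


def class_positions(karyotype: IseKaryotype,
                    reference: float = REFERENCE_CHANNEL) -> np.ndarray:
    """Expected fluorescence peak position of every male GS class.

    Male genome size relative to the female 2C, scaled to the channel
    where the female internal standard peaks.  An ISE-free clone's males
    peak at exactly half the female signal.
    """
    rel = np.array(
        [male_genome_size(k, karyotype)[1] for k in range(karyotype.n_ise + 1)]
    )
    return rel * reference


def _sample_events(
    rng: np.random.Generator,
    counts: np.ndarray,
    positions: np.ndarray,
    cv_percent: float,
    n_events_per_male: int,
    female_events: int,
    background_fraction: float,
) -> np.ndarray:
    parts = []
    for k, c in enumerate(counts):
        m = int(c) * n_events_per_male
        if m:
            loc = positions[k]
            parts.append(rng.normal(loc, cv_percent / 100.0 * loc, size=m))
    if female_events:
        parts.append(
            rng.normal(
                REFERENCE_CHANNEL,
                cv_percent / 100.0 * REFERENCE_CHANNEL,
                size=female_events,
            )
        )
    signal = np.concatenate(parts)
    f = background_fraction
    n_bg = int(round(f / (1.0 - f) * signal.size)) if f > 0 else 0
    bg = rng.uniform(0.2 * REFERENCE_CHANNEL, 1.2 * REFERENCE_CHANNEL, size=n_bg)
    events = np.concatenate([signal, bg])
    np.clip(events, 1e-6, None, out=events)
    rng.shuffle(events)
    return events


def _stage_distribution(
    base: ClassDistribution, viability: Optional[Sequence[float]]
) -> ClassDistribution:
    if viability is None:
        return base
    v = np.asarray(viability, dtype=float)
    if v.shape != base.freqs.shape:
        raise ValueError(
            f"viability weights need {base.freqs.size} entries, got {v.size}"
        )
    if np.any(v < 0) or v.sum() <= 0:
        raise ValueError("viability weights must be nonnegative, not all zero")
    f = base.freqs * v
    return ClassDistribution(n_ise=base.n_ise, freqs=f / f.sum())


def simulate_clone_sample(
    config: SimConfig,
    stage: str = "hatched",
) -> tuple[FluorescenceSample, ClassDistribution, ClassCounts]:
    """One simulated flow-cytometry measurement of a clone's males.

    Class counts are multinomial draws from the segregation model at the
    configured (tb, cb) (modulated by the stage's viability weights, if
    any); each male then contributes a burst of normally-spread events
    at its class position.  Returns the event sample together with the
    exact generating class distribution and the drawn counts, so
    downstream estimates can be compared against the truth.  Identical
    configs (including seed) give identical output.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    kar = config.karyotype
    rng = np.random.default_rng((config.seed, STAGES.index(stage)))
    base = class_distribution(kar.n_ise, config.params)
    effects = config.stage_effects or {}
    truth = _stage_distribution(base, effects.get(stage))
    counts = rng.multinomial(config.n_males, truth.freqs)

    positions = class_positions(kar)
    spacing = np.diff(positions)
    too_close = spacing < 2.0 * (config.cv_percent / 100.0) * positions[1:]
    if np.any(too_close):
        warnings.warn(
            "adjacent GS-class peaks are closer than 2 CVs; classes may "
            "not be resolvable by mixture decomposition",
            stacklevel=2,
        )

    events = _sample_events(
        rng,
        counts,
        positions,
        config.cv_percent,
        config.n_events_per_male,
        config.female_events,
        config.background_fraction,
    )
    sample = FluorescenceSample(
        events=events,
        clone_id=kar.clone_id,
        stage=stage,
        female_peak_position=REFERENCE_CHANNEL,
        n_individuals=config.n_males,
    )
    return sample, truth, ClassCounts(counts=counts, stage=stage)


def simulate_stage_series(
    config: SimConfig,
) -> dict:
    """Simulate the three developmental stages of one clone.

    Returns ``{stage: (sample, truth, counts)}`` for sync, accum and
    hatched males.  Without stage effects all three share the meiotic
    class distribution, so their fitted frequencies should agree within
    sampling error; viability weights decreasing in k deplete high-ISE
    classes in later stages, a U-shape broadens the hatched
    distribution.
    """
    return {stage: simulate_clone_sample(config, stage=stage) for stage in STAGES}


def simulate_hatching_table(
    clones: Sequence[tuple[float, str]],
    rate_model: Mapping[str, float],
    n_eggs: int,
    seed: int,
) -> pd.DataFrame:
    """Egg-level Bernoulli hatching outcomes across clones.

    ``clones`` lists (female 2C genome size in Mb, sex of the eggs);
    ``rate_model`` supplies ``intercept`` and ``male_gs_slope`` on the
    logit scale, the slope per 100 Mb of genome size centred at
    ``gs_center`` (default 500 Mb).  Male hatching probability varies
    with genome size; female hatching is flat — the generator for
    testing any binomial regression of hatching rate on sex x GS.
    """
    rng = np.random.default_rng(seed)
    intercept = float(rate_model["intercept"])
    slope = float(rate_model["male_gs_slope"])
    center = float(rate_model.get("gs_center", 500.0))
    rows = []
    for clone_idx, (gs, sex) in enumerate(clones):
        if sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
        logit = intercept + (slope * (gs - center) / 100.0 if sex == "male" else 0.0)
        p = 1.0 / (1.0 + np.exp(-logit))
        hatched = rng.random(n_eggs) < p
        for egg_id, h in enumerate(hatched):
            rows.append(
                {
                    "clone": clone_idx,
                    "female_2c_mb": gs,
                    "sex": sex,
                    "egg_id": egg_id,
                    "hatched": bool(h),
                }
            )
    return pd.DataFrame(
        rows, columns=["clone", "female_2c_mb", "sex", "egg_id", "hatched"]
    )
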
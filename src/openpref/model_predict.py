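"""Predicted mean preference-strength trajectories for choice and no-choice
conditions, given a parameter set and an experimental timing design.

A trial runs in two stages: the state evolves from stimulus onset for the
first-stage duration; in the choice condition it then collapses onto the
observed response (left/right, with model-implied probabilities), in the
no-choice condition it is left untouched; finally it evolves for the
attention-decay-rescaled delay and the expected strength is read out.  The
choice-condition prediction pools the two collapsed branches with weights
``(pL, pR)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import measurement as meas
from .dynamics import (LindbladGenerator, ModelParams, build_generator,
                       evolve, evolved_diagonal, initial_state)

Condition = Literal["choice", "no_choice"]


@dataclass(frozen=True)
class TimingDesign:
    """Trial timing of one experiment.

    ``first_stage`` is the stimulus-onset-to-first-response duration in
    seconds, either a fixed value or a ``(lo, hi)`` uniform range;
    ``delays`` are the rating delays measured from the first response;
    ``grid_step`` is the resolution of dense prediction grids.
    """

    first_stage: float | tuple[float, float]
    delays: tuple[float, ...]
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "delays", tuple(float(d) for d in self.delays))
        if any(d <= 0 for d in self.delays):
            raise ValueError("delays must be positive")
        lo, hi = self.first_stage_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid first stage {self.first_stage}")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")

    @property
    def first_stage_range(self) -> tuple[float, float]:
        if isinstance(self.first_stage, (tuple, list)):
            lo, hi = self.first_stage
            return float(lo), float(hi)
        return float(self.first_stage), float(self.first_stage)

    @property
    def first_stage_midpoint(self) -> float:
        lo, hi = self.first_stage_range
        return 0.5 * (lo + hi)

    def delay_grid(self) -> np.ndarray:
        """Dense delay grid from the shortest to the longest design delay."""
        lo, hi = min(self.delays), max(self.delays)
        return np.arange(lo, hi + 1e-9, self.grid_step)


#: fixed Experiment 1 design: 5 s first stage, six discrete rating delays
EXPERIMENT1_DESIGN = TimingDesign(first_stage=5.0,
                                  delays=(3.0, 6.0, 9.0, 18.0, 30.0, 45.0))
#: Experiment 2 design: 4-6 s uniform first stage, 2-50 s uniform delays
#: (represented by a 1 s grid of nominal delays)
EXPERIMENT2_DESIGN = TimingDesign(first_stage=(4.0, 6.0),
                                  delays=tuple(np.arange(2.0, 51.0)))


@dataclass
class MeanTrajectory:
    """Per-condition mean preference strength indexed by rating delay."""

    delay: np.ndarray
    strength: np.ndarray
    condition: str

    def to_frame(self, experiment: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "condition": self.condition,
            "delay_s": self.delay,
            "strength_points": self.strength,
        })
        if experiment is not None:
            df.insert(0, "experiment", experiment)
        return df


def _effective_durations(delays: Sequence[float], t1: float, params: ModelParams,
                         decay_convention: str) -> np.ndarray:
    return np.array([
        meas.effective_duration(t1 + d, t1, params.lambda_decay,
                                decay_convention)
        for d in delays
    ])


def _stage_one(params: ModelParams, t1: float,
               gen: LindbladGenerator | None = None):
    gen = gen or build_generator(params)
    rho1 = evolve(initial_state(params), gen, t1)
    return gen, rho1


def predict_no_choice(params: ModelParams, design: TimingDesign,
                      delays: Iterable[float] | None = None,
                      decay_convention: str = "post_response",
                      first_stage: float | None = None,
                      gen: LindbladGenerator | None = None) -> MeanTrajectory:
    """Trajectory when the first response is an option-unrelated click.

    The state is never collapsed: it evolves through the first stage and then
    for each delay's effective duration.
    """
    delays = np.asarray(list(delays) if delays is not None else design.delays)
    t1 = first_stage if first_stage is not None else design.first_stage_midpoint
    gen, rho1 = _stage_one(params, t1, gen)
    taus = _effective_durations(delays, t1, params, decay_convention)
    smap = meas.strength_map(params.scale, params.s_max)
    pops = evolved_diagonal(rho1, gen, taus)
    return MeanTrajectory(delay=delays, strength=pops @ smap,
                          condition="no_choice")


def predict_choice(params: ModelParams, design: TimingDesign,
                   delays: Iterable[float] | None = None,
                   decay_convention: str = "post_response",
                   first_stage: float | None = None,
                   gen: LindbladGenerator | None = None) -> MeanTrajectory:
    """Trajectory when a binary choice is elicited at the first response.

    Both collapsed branches evolve for the effective delay and their strength
    profiles are pooled with the model-implied response probabilities.
    """
    delays = np.asarray(list(delays) if delays is not None else design.delays)
    t1 = first_stage if first_stage is not None else design.first_stage_midpoint
    gen, rho1 = _stage_one(params, t1, gen)
    pL, pR = meas.choice_probabilities(rho1, params.scale)
    taus = _effective_durations(delays, t1, params, decay_convention)
    smap = meas.strength_map(params.scale, params.s_max)
    pooled = np.zeros((len(delays), params.n))
    for p, resp in ((pL, "L"), (pR, "R")):
        if p <= 1e-12:
            continue
        branch = meas.collapse(rho1, resp, params.scale)
        pooled += p * evolved_diagonal(branch, gen, taus)
    pooled /= pooled.sum(axis=1, keepdims=True)
    return MeanTrajectory(delay=delays, strength=pooled @ smap,
                          condition="choice")


def predict_design_average(params: ModelParams, design: TimingDesign,
                           condition: Condition,
                           delays: Iterable[float] | None = None,
                           decay_convention: str = "post_response",
                           quadrature: str = "midpoint") -> MeanTrajectory:
    """Condition trajectory averaged over a variable first-stage duration.

    ``midpoint`` (default) evaluates at the centre of the first-stage range;
    ``three_point`` averages the trajectories at the range's endpoints and
    midpoint.  For a fixed first stage both reduce to the plain predictions.
    """
    fn = predict_choice if condition == "choice" else predict_no_choice
    lo, hi = design.first_stage_range
    if quadrature == "midpoint" or lo == hi:
        return fn(params, design, delays=delays,
                  decay_convention=decay_convention,
                  first_stage=design.first_stage_midpoint)
    if quadrature != "three_point":
        raise ValueError(f"unknown quadrature {quadrature!r}")
    gen = build_generator(params)
    nodes = (lo, 0.5 * (lo + hi), hi)
    trajs = [fn(params, design, delays=delays,
                decay_convention=decay_convention, first_stage=t1, gen=gen)
             for t1 in nodes]
    strength = np.mean([t.strength for t in trajs], axis=0)
    return MeanTrajectory(delay=trajs[0].delay, strength=strength,
                          condition=condition)


def predict_both(params: ModelParams, design: TimingDesign,
                 delays: Iterable[float] | None = None,
                 decay_convention: str = "post_response") -> pd.DataFrame:
    """Tidy frame of choice and no-choice trajectories on shared delays."""
    gen = build_generator(params)
    nc = predict_no_choice(params, design, delays=delays,
                           decay_convention=decay_convention, gen=gen)
    ch = predict_choice(params, design, delays=delays,
                        decay_convention=decay_convention, gen=gen)
    return pd.concat([nc.to_frame(), ch.to_frame()], ignore_index=True)
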
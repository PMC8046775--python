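"""Trial-level synthetic datasets with the statistical structure of the two
preference-tracking experiments.

Experiment 1: between-subjects choice/no-choice, pairs of restaurant
gift cards described by four attributes, a fixed 5 s first stage, rating
delays of 3/6/9/18/30/45 s on a +/-30 scale, 48 trials per participant
including four catch trials whose option pairs are dominated on every
attribute.  Experiment 2: within-subject blocks, monetary gambles (payoff
loosely negatively correlated with win probability), first response at
4-6 s uniform, rating prompt 2-50 s uniform after the first response, +/-10
scale, with ratings incentivised by mapping them onto the probability of
playing the right-hand gamble.

Trial outcomes are sampled from the generative model itself: the state
evolves to the first response, is collapsed in the choice condition (with
the model-implied response probabilities), evolves for the decay-rescaled
delay, and a rating level is drawn from the state's level distribution.
The signed rating is the rounded logistic strength of the drawn level with
the sign of its side of the midpoint (fair coin at the midpoint).  The
model's rating distribution is the only noise source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import measurement as meas
from .dynamics import (LindbladGenerator, ModelParams, build_generator,
                       evolve, initial_state)
from .model_predict import (EXPERIMENT1_DESIGN, EXPERIMENT2_DESIGN,
                            TimingDesign)

#: fraction of simulated participants who ignore the attributes on catch
#: trials, and their probability of picking the dominated option there
INATTENTIVE_FRACTION = 0.11
P_DOMINATED_INATTENTIVE = 0.75


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def generate_gift_cards(n_pairs: int, seed: int,
                        n_dominated: int = 0) -> pd.DataFrame:
    """Pseudo-random gift-card pairs over the printed attribute ranges.

    Attributes: card value ($10-30), restaurant star rating (1-5), average
    meal cost ($5-25, lower better), distance from campus (0.1-10.1 miles,
    lower better).  The last ``n_dominated`` pairs are constructed so the
    right-hand option is strictly worse on all four attributes (catch
    trials).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_pairs):
        dominated = k >= n_pairs - n_dominated
        for _ in range(200):
            a = dict(value=rng.uniform(10, 30), stars=rng.uniform(1, 5),
                     meal_cost=rng.uniform(5, 25), distance=rng.uniform(0.1, 10.1))
            if dominated:
                b = dict(
                    value=rng.uniform(10, a["value"] - 1e-6)
                    if a["value"] > 10.5 else None,
                    stars=rng.uniform(1, a["stars"] - 1e-6)
                    if a["stars"] > 1.5 else None,
                    meal_cost=rng.uniform(a["meal_cost"] + 1e-6, 25)
                    if a["meal_cost"] < 24.5 else None,
                    distance=rng.uniform(a["distance"] + 1e-6, 10.1)
                    if a["distance"] < 9.6 else None,
                )
                if any(v is None for v in b.values()):
                    continue
            else:
                b = dict(value=rng.uniform(10, 30), stars=rng.uniform(1, 5),
                         meal_cost=rng.uniform(5, 25),
                         distance=rng.uniform(0.1, 10.1))
            break
        else:  # pragma: no cover - construction always succeeds in practice
            raise RuntimeError("could not construct stimulus pair")
        rows.append({"pair": k, "is_catch": dominated,
                     **{f"left_{a_}": v for a_, v in a.items()},
                     **{f"right_{a_}": v for a_, v in b.items()}})
    return pd.DataFrame(rows)


def is_dominated_pair(row: pd.Series) -> bool:
    """True when the right option is strictly worse on all four attributes."""
    return bool(row["right_value"] < row["left_value"]
                and row["right_stars"] < row["left_stars"]
                and row["right_meal_cost"] > row["left_meal_cost"]
                and row["right_distance"] > row["left_distance"])


def generate_catch_trials(n: int, seed: int,
                          p_dominated: float = 0.0) -> pd.DataFrame:
    """Dominated gift-card pairs plus a simulated (in)attentive chooser.

    ``p_dominated`` is the probability that the simulated participant picks
    the dominated option on each catch trial.
    """
    if n < 1:
        raise ValueError("need n >= 1 catch trials")
    stim = generate_gift_cards(n, seed, n_dominated=n)
    rng = np.random.default_rng(seed + 1)
    stim["chose_dominated"] = rng.random(n) < p_dominated
    return stim


def generate_gambles(n_pairs: int, seed: int) -> pd.DataFrame:
    """Gamble pairs with payoff loosely negatively correlated with win
    probability (limits the rate of dominated pairs)."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_pairs):
        out = {}
        for side in ("left", "right"):
            p = rng.uniform(0.05, 0.95)
            # payoff scales inversely with p, with multiplicative noise
            payoff = 100.0 / p * np.exp(rng.normal(0.0, 0.35))
            out[f"{side}_payoff"] = float(np.round(np.clip(payoff, 20, 2000)))
            out[f"{side}_prob"] = round(p, 2)
        rows.append({"pair": k, **out})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# incentive rules
# ---------------------------------------------------------------------------

def incentive_play_probability(rating: float) -> float:
    """Probability of playing the right-hand gamble implied by a rating on
    the 21-point (+/-10) scale: the linear map ``(rating + 10) / 20``."""
    if not -10 <= rating <= 10:
        raise ValueError(f"rating {rating} outside the +/-10 scale")
    return (rating + 10.0) / 20.0


def play_gamble(payoff: float, win_prob: float, seed: int) -> float:
    """Play one gamble: a uniform draw of ``1 - win_prob`` or higher wins the
    payoff, lower wins nothing."""
    if not 0.0 <= win_prob <= 1.0:
        raise ValueError("win probability must lie in [0, 1]")
    u = float(np.random.default_rng(seed).random())
    return float(payoff) if u >= 1.0 - win_prob else 0.0


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _signed_rating(level: int, smap: np.ndarray, mid: int,
                   rng: np.random.Generator) -> int:
    mag = int(round(smap[level - 1]))
    if level > mid:
        return mag
    if level < mid:
        return -mag
    return mag if rng.random() < 0.5 else -mag


class _TrialSampler:
    """Caches propagated states so per-trial sampling is cheap.

    For a given generator, the spectral decomposition is computed once; the
    level distribution after an arbitrary second-stage duration needs only a
    small matrix product per branch.
    """

    def __init__(self, params: ModelParams, decay_convention: str):
        self.params = params
        self.decay_convention = decay_convention
        self.gen: LindbladGenerator = build_generator(params)
        self.smap = meas.strength_map(params.scale, params.s_max)
        self._stage1: dict[float, dict] = {}
        w, V, _ = self.gen.spectral()
        n = params.n
        self._diag_rows = V[np.arange(n) * n + np.arange(n), :]
        self._w = w

    def _first_stage(self, t1: float) -> dict:
        key = round(t1, 3)
        if key not in self._stage1:
            rho1 = evolve(initial_state(self.params), self.gen, t1)
            pL, pR = meas.choice_probabilities(rho1, self.params.scale)
            entry = {"rho": rho1, "pL": pL, "pR": pR, "proj": {}}
            _, _, Vinv = self.gen.spectral()
            entry["y"] = {"none": Vinv @ rho1.reshape(-1)}
            for resp, p in (("L", pL), ("R", pR)):
                if p > 1e-12:
                    branch = meas.collapse(rho1, resp, self.params.scale)
                    entry["y"][resp] = Vinv @ branch.reshape(-1)
            self._stage1[key] = entry
        return self._stage1[key]

    def level_probs(self, t1: float, branch: str, tau: float) -> np.ndarray:
        entry = self._first_stage(t1)
        y = entry["y"][branch]
        p = np.real(self._diag_rows @ (np.exp(self._w * tau) * y))
        p[p < 0] = 0.0
        return p / p.sum()

    def sample_trial(self, condition: str, t1: float, delay: float,
                     rng: np.random.Generator) -> tuple[str | None, int]:
        entry = self._first_stage(t1)
        tau = meas.effective_duration(t1 + delay, t1,
                                      self.params.lambda_decay,
                                      self.decay_convention)
        if condition == "choice":
            resp = "R" if rng.random() < entry["pR"] else "L"
            probs = self.level_probs(t1, resp, tau)
        else:
            resp = None
            probs = self.level_probs(t1, "none", tau)
        level = int(rng.choice(self.params.n, p=probs)) + 1
        rating = _signed_rating(level, self.smap, self.params.scale.mid, rng)
        return resp, rating


def generate_experiment(params: ModelParams, design: TimingDesign,
                        n_participants: int, n_trials: int, seed: int,
                        experiment: int = 1,
                        conditions: str = "between",
                        decay_convention: str = "post_response",
                        n_catch: int = 0) -> pd.DataFrame:
    """Simulate a full experiment as a tidy trial table.

    ``conditions="between"`` assigns each participant to one condition
    (alternating); ``"within"`` alternates conditions across blocks within
    each participant.  For Experiment-1-style designs delays are drawn
    uniformly from the design's discrete set; for ranges (``len(delays) >
    12``) delays are drawn uniformly from the continuous span.  ``n_catch``
    dominated-pair catch trials are appended per participant; a fixed
    fraction of simulated participants is inattentive and picks the
    dominated option with high probability.
    """
    rng = np.random.default_rng(seed)
    sampler = _TrialSampler(params, decay_convention)
    lo, hi = design.first_stage_range
    dmin, dmax = min(design.delays), max(design.delays)
    continuous = len(design.delays) > 12
    rows = []
    block_size = max(n_trials // 8, 1)
    for pid in range(n_participants):
        inattentive = rng.random() < INATTENTIVE_FRACTION
        if conditions == "between":
            p_cond = "choice" if pid % 2 == 0 else "no_choice"
        for k in range(n_trials):
            if conditions == "within":
                cond = "choice" if (k // block_size) % 2 == 0 else "no_choice"
            else:
                cond = p_cond
            t1 = rng.uniform(lo, hi) if hi > lo else lo
            delay = (rng.uniform(dmin, dmax) if continuous
                     else float(rng.choice(design.delays)))
            resp, rating = sampler.sample_trial(cond, t1, delay, rng)
            rows.append({
                "participant": f"p{pid:03d}", "experiment": experiment,
                "block": k // block_size, "condition": cond,
                "t1_s": round(t1, 3), "delay_s": round(delay, 3),
                "first_response": resp if resp else ("L" if rng.random() < 0.5
                                                    else "R"),
                "rating": rating, "is_catch": False,
                "scale_max": params.s_max,
            })
        for c in range(n_catch):
            p_dom = P_DOMINATED_INATTENTIVE if inattentive else 0.02
            chose_dominated = rng.random() < p_dom
            rows.append({
                "participant": f"p{pid:03d}", "experiment": experiment,
                "block": -1, "condition": "catch",
                "t1_s": round(rng.uniform(lo, hi), 3) if hi > lo else lo,
                "delay_s": float(rng.choice(design.delays)) if not continuous
                else round(rng.uniform(dmin, dmax), 3),
                "first_response": "R" if chose_dominated else "L",
                "rating": 0, "is_catch": True,
                "scale_max": params.s_max,
            })
    return pd.DataFrame(rows)


def generate_experiment1(params: ModelParams, n_participants: int = 105,
                         seed: int = 0, n_catch: int = 4) -> pd.DataFrame:
    """Experiment-1-style dataset: between-subjects, 48 trials, 5 s first
    stage, six discrete delays, +/-30 scale, four catch trials."""
    return generate_experiment(params, EXPERIMENT1_DESIGN,
                               n_participants=n_participants, n_trials=48,
                               seed=seed, experiment=1, conditions="between",
                               n_catch=n_catch)


def generate_experiment2(params: ModelParams, n_participants: int = 62,
                         seed: int = 0) -> pd.DataFrame:
    """Experiment-2-style dataset: within-subject blocks (8 x 20 trials),
    4-6 s first stage, 2-50 s continuous delays, +/-10 scale."""
    return generate_experiment(params, EXPERIMENT2_DESIGN,
                               n_participants=n_participants, n_trials=160,
                               seed=seed, experiment=2, conditions="within")


def exclusion_filter(trials: pd.DataFrame,
                     threshold: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants who chose the dominated option on at least
    ``threshold`` of their catch trials.

    Catch trials are rows with ``is_catch`` where ``first_response == "R"``
    encodes a dominated choice (the dominated option is always on the
    right in generated catch pairs).  Returns ``(retained_trials, log)``
    where ``log`` has one row per participant with the dominated-choice
    count and exclusion flag.
    """
    if "is_catch" not in trials.columns or not trials["is_catch"].any():
        import warnings
        warnings.warn("no catch trials present; retaining all participants")
        log = pd.DataFrame({
            "participant": trials["participant"].unique(),
            "n_catch": 0, "n_dominated": 0, "excluded": False})
        return trials.copy(), log
    catch = trials[trials["is_catch"]]
    counts = (catch.assign(dom=catch["first_response"] == "R")
              .groupby("participant")
              .agg(n_catch=("dom", "size"), n_dominated=("dom", "sum"))
              .reset_index())
    counts["excluded"] = counts["n_dominated"] >= threshold
    all_p = pd.DataFrame({"participant": trials["participant"].unique()})
    log = all_p.merge(counts, on="participant", how="left").fillna(
        {"n_catch": 0, "n_dominated": 0, "excluded": False})
    excluded = set(log.loc[log["excluded"], "participant"])
    retained = trials[~trials["participant"].isin(excluded)
                      & ~trials["is_catch"]].copy()
    return retained, log
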
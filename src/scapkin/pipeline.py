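"""End-to-end drivers: simulated trials -> angles -> events -> statistics.

This module wires the stages together the way the study analysed its
recordings: reconstruct the angle system from markers, low-pass filter
and segment, keep the second elevation per block and direction, read the
peak, and feed the peaks to the mixed-model effects layer. It exists so
the analysis scripts, the tests and the acceptance harness all exercise
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from scapkin import effects, events, kinematics, synthetic_cohort
from scapkin.kinematics import AngleSeries
from scapkin.synthetic_cohort import (
    Cohort,
    EffectProfile,
    SimulatedTrial,
    TrialPlan,
    make_cohort,
    parse_condition,
    simulate_trial,
)

HEADLINE_CONDITIONS = ("none", "therapist", f"orthosis-level-{synthetic_cohort.N_ORTHOSIS_LEVELS}")


def trial_angles(trial: SimulatedTrial) -> AngleSeries:
    """Angle system of a simulated trial recomputed from its markers."""
    return kinematics.compute_angles(trial.markers)


def trial_peak_record(trial: SimulatedTrial) -> dict:
    """Process one trial through filtering and segmentation to its peak.

    Returns one record per elevation event found (normally exactly one),
    carrying the peak gravitational/corrected elevation and the trunk
    compensation at the peak frame.
    """
    angles = trial_angles(trial)
    evs = events.extract_elevations(
        angles,
        direction=trial.plan.direction,
        condition=trial.plan.condition,
        trial=f"{trial.plan.participant}-b{trial.plan.block_index}-r{trial.plan.repetition}",
    )
    if len(evs) != 1:
        raise RuntimeError(
            f"expected one elevation per simulated trial, found {len(evs)}"
        )
    ev = evs[0]
    kind, level = parse_condition(trial.plan.condition)
    return {
        "participant": trial.plan.participant,
        "condition": trial.plan.condition,
        "support": kind,
        "force_level": level,
        "direction": trial.plan.direction,
        "repetition": trial.plan.repetition,
        "block_index": trial.plan.block_index,
        "peak_theta_g": ev.peak_theta_g,
        "peak_kappa": ev.peak_kappa,
        "peak_theta": ev.peak_theta,
        "comp_ratio": effects.normalized_trunk_compensation(
            ev.peak_kappa, ev.peak_theta_g
        ),
        "_event": ev,
    }


def rom_observations(
    cohort: Cohort,
    conditions: Optional[Sequence[str]] = None,
    keep_events: bool = False,
) -> pd.DataFrame:
    """Analysed peaks of a cohort: second elevation per block x direction.

    ``conditions`` restricts simulation to a subset of condition labels
    (e.g. the headline baseline/therapist/strongest-orthosis blocks).
    """
    by_participant = {p.id: p for p in cohort.participants}
    plans = [
        pl
        for pl in cohort.plans
        if conditions is None or pl.condition in conditions
    ]
    records = []
    for pl in plans:
        trial = simulate_trial(by_participant[pl.participant], pl)
        records.append(trial_peak_record(trial))
    df = pd.DataFrame(records)

    analysed = []
    for _, group in df.groupby(["participant", "block_index", "direction"], sort=False):
        group = group.sort_values("repetition")
        ev = events.select_analysed_elevation(list(group["_event"]))
        row = group.iloc[list(group["_event"]).index(ev)].to_dict()
        analysed.append(row)
    out = pd.DataFrame(analysed).reset_index(drop=True)
    if not keep_events:
        out = out.drop(columns="_event")
    return out


def headline_observations(obs: pd.DataFrame, orthosis_level: str = "strongest") -> pd.DataFrame:
    """Collapse the analysed peaks to the support levels entering the LMM.

    The Orthosis support level is represented by one block per
    participant: the strongest force level by default (the setting the
    study's participants rated most helpful), or the empirically best
    level per participant and direction with ``orthosis_level="best"``.
    """
    base = obs[obs["support"].isin(["none", "therapist"])]
    orth = obs[obs["support"] == "orthosis"]
    if orthosis_level == "strongest":
        orth = orth[orth["force_level"] == synthetic_cohort.N_ORTHOSIS_LEVELS]
    elif orthosis_level == "best":
        idx = orth.groupby(["participant", "direction"])["peak_theta"].idxmax()
        orth = orth.loc[idx]
    else:
        raise ValueError("orthosis_level must be 'strongest' or 'best'")
    return pd.concat([base, orth], ignore_index=True)


def condition_effects(
    obs: pd.DataFrame, use_t: bool = False
) -> tuple[effects.LMMFit, list[effects.EffectEstimate]]:
    """Fit the random-intercept LMM on analysed peaks and return contrasts."""
    fit = effects.fit_random_intercept_lmm(obs, response="peak_theta")
    return fit, effects.posthoc_contrasts(fit, use_t=use_t)


def compensation_changes(obs: pd.DataFrame) -> pd.DataFrame:
    """Percent change of normalized trunk compensation vs baseline.

    One row per participant x direction x assisted support level, using
    the mean compensation ratio across that cell's analysed elevations.
    """
    ratios = (
        obs.groupby(["participant", "direction", "support"])["comp_ratio"]
        .mean()
        .unstack("support")
    )
    rows = []
    for (participant, direction), r in ratios.iterrows():
        for support in ("orthosis", "therapist"):
            if support in r and np.isfinite(r[support]) and np.isfinite(r["none"]):
                rows.append(
                    {
                        "participant": participant,
                        "direction": direction,
                        "support": support,
                        "baseline_ratio": r["none"],
                        "condition_ratio": r[support],
                        "percent_change": effects.compensation_percent_change(
                            r["none"], r[support]
                        ),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class RecoveryResult:
    """Per-replicate condition-effect estimates from the full pipeline."""

    estimates: pd.DataFrame  # one row per replicate

    def summary(self) -> pd.DataFrame:
        """Monte-Carlo mean and standard error of each estimate."""
        mean = self.estimates.mean()
        se = self.estimates.std(ddof=1) / np.sqrt(len(self.estimates))
        return pd.DataFrame({"mean": mean, "mc_se": se})


def run_replicate(seed: int, n_participants: int = 8, profile: Optional[EffectProfile] = None) -> dict:
    """One full-pipeline replicate: cohort -> markers -> LMM estimates."""
    cohort = make_cohort(n_participants=n_participants, profile=profile, seed=seed)
    obs = rom_observations(cohort, conditions=HEADLINE_CONDITIONS)
    head = headline_observations(obs)
    _, contrasts = condition_effects(head)
    out = {"seed": seed}
    for c in contrasts:
        out[f"{c.contrast.split('-')[0]}_{c.direction}"] = c.mean
    comp = compensation_changes(obs)
    for (support, direction), grp in comp.groupby(["support", "direction"]):
        out[f"comp_change_{support}_{direction}"] = grp["percent_change"].mean()
    return out


def parameter_recovery(
    n_replicates: int = 100,
    n_participants: int = 8,
    seed: int = 0,
    profile: Optional[EffectProfile] = None,
) -> RecoveryResult:
    """Monte-Carlo parameter recovery over replicate synthetic cohorts.

    Each replicate runs the complete pipeline (marker simulation, angle
    reconstruction, filtering, segmentation, second-elevation selection,
    REML mixed model, contrasts) on a fresh cohort; replicate seeds are
    derived deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_replicates)
    rows = [run_replicate(int(s), n_participants=n_participants, profile=profile) for s in seeds]
    return RecoveryResult(estimates=pd.DataFrame(rows).set_index("seed"))
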
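"""Synthetic generators emulating the four behavioral experiment designs.

The human datasets behind the original study are not publicly deposited, so
these generators are the package's study conditions: they reproduce each
task's prior, context transformations, noise regime, block structure, and
(for the length task) discrete response options, and drive the observer
chains in :mod:`obsact.simulate`.

* **exp1_rsg_g15** — time-interval reproduction ("Ready, Set, Go"):
  11-point discrete uniform prior on [600, 1000] ms, identity (gain 1) vs.
  remapped (gain 1.5) contexts, scalar (Weber) noise.
* **exp2_rsg_g075** — same task with remapped gain 0.75.
* **exp3_reach_rot60** — center-out reaching: 11-point angular prior 45
  degrees wide centered straight ahead, identity vs. a 60-degree rotation
  (correct = sample + 60), additive noise, 150-trial blocks with the first
  25 trials of each block excluded as adaptation transients.
* **exp4_length_g15** — length identification: 7-point prior on [4, 7]
  degrees visual angle, gain 1 vs. 1.5, scalar noise, responses snapped to
  29 evenly spaced choice options ([2, 9] deg identity, [3, 13.5] deg
  remapped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .estimator import EstimatorGrid
from .noise import NoiseModel
from .priors import DISCRETE, PriorSpec, Transform
from .simulate import ObserverParams, inference_prior_for, simulate_trials

__all__ = [
    "ExperimentSpec",
    "CohortSpec",
    "EXPERIMENT_IDS",
    "make_experiment_spec",
    "make_strategy_probe_spec",
    "generate_subject",
    "generate_cohort",
    "snap_to_choice",
]

EXPERIMENT_IDS = ("exp1_rsg_g15", "exp2_rsg_g075", "exp3_reach_rot60", "exp4_length_g15")


@dataclass(frozen=True)
class ExperimentSpec:
    """Task geometry of one experiment: prior, per-context transforms, noise
    regime, block structure, adaptation exclusion, and optional per-context
    discrete choice sets."""

    id: str
    units: str
    sample_prior: PriorSpec
    contexts: Mapping[str, Transform]
    noise_kind: str
    blocks_per_session: int
    trials_per_block: int
    adaptation_exclusion: int = 0
    choice_sets: Optional[Mapping[str, np.ndarray]] = None

    def transform(self, context: str) -> Transform:
        if context not in self.contexts:
            raise KeyError(f"unknown context {context!r}; expected one of {sorted(self.contexts)}")
        return self.contexts[context]


def make_experiment_spec(experiment_id: str) -> ExperimentSpec:
    """Fully populated :class:`ExperimentSpec` for one of the four designs."""
    if experiment_id == "exp1_rsg_g15":
        return ExperimentSpec(
            id=experiment_id,
            units="ms",
            sample_prior=PriorSpec(600.0, 1000.0, DISCRETE, 11),
            contexts={"identity": Transform("gain", 1.0), "remapped": Transform("gain", 1.5)},
            noise_kind="scalar",
            blocks_per_session=1,
            trials_per_block=600,
        )
    if experiment_id == "exp2_rsg_g075":
        return ExperimentSpec(
            id=experiment_id,
            units="ms",
            sample_prior=PriorSpec(600.0, 1000.0, DISCRETE, 11),
            contexts={"identity": Transform("gain", 1.0), "remapped": Transform("gain", 0.75)},
            noise_kind="scalar",
            blocks_per_session=1,
            trials_per_block=600,
        )
    if experiment_id == "exp3_reach_rot60":
        return ExperimentSpec(
            id=experiment_id,
            units="deg_angle",
            sample_prior=PriorSpec(-22.5, 22.5, DISCRETE, 11),
            contexts={"identity": Transform("offset", 0.0), "remapped": Transform("offset", 60.0)},
            noise_kind="additive",
            blocks_per_session=2,
            trials_per_block=150,
            adaptation_exclusion=25,
        )
    if experiment_id == "exp4_length_g15":
        return ExperimentSpec(
            id=experiment_id,
            units="deg_visual",
            sample_prior=PriorSpec(4.0, 7.0, DISCRETE, 7),
            contexts={"identity": Transform("gain", 1.0), "remapped": Transform("gain", 1.5)},
            noise_kind="scalar",
            blocks_per_session=2,
            trials_per_block=150,
            choice_sets={
                "identity": np.linspace(2.0, 9.0, 29),
                "remapped": np.linspace(3.0, 13.5, 29),
            },
        )
    raise ValueError(f"unknown experiment id {experiment_id!r}; expected one of {EXPERIMENT_IDS}")


def make_strategy_probe_spec(offset: float = -450.0) -> ExperimentSpec:
    """Task design on which early vs. late inference are identifiable from a
    single context.

    Whenever the noise family is closed under the context transformation
    (scalar noise with a gain; additive noise with a gain or offset) the
    early- and late-inference model families are exactly likelihood-
    equivalent, so the four standard designs cannot separate them from one
    context alone.  Scalar (Weber) noise combined with an additive remapping
    breaks that symmetry: the pre-inference noise of a late observer scales
    with the *shifted* magnitude, whereas an early observer's scales with
    the original sample.  Shifting the [600, 1000] ms prior down to
    [150, 550] ms (offset -450) makes the Weber heteroscedasticity contrast
    strong enough for reliable single-table strategy recovery at one
    session's worth of trials.
    """
    shifted_lower = 600.0 + min(offset, 0.0)
    if shifted_lower <= 0:
        raise ValueError("offset would push the remapped support to non-positive values")
    return ExperimentSpec(
        id="probe_rsg_offset",
        units="ms",
        sample_prior=PriorSpec(600.0, 1000.0, DISCRETE, 11),
        contexts={"identity": Transform("offset", 0.0), "remapped": Transform("offset", float(offset))},
        noise_kind="scalar",
        blocks_per_session=1,
        trials_per_block=600,
    )


def snap_to_choice(value, choice_set) -> np.ndarray | float:
    """Nearest element of the (sorted) choice set; exact midpoints resolve to
    the smaller option; values beyond the ends clamp to the extremes."""
    choices = np.asarray(choice_set, dtype=float)
    if choices.size == 0:
        raise ValueError("choice set must be non-empty")
    choices = np.sort(choices)
    v = np.atleast_1d(np.asarray(value, dtype=float))
    # argmin returns the first (smaller) option on exact distance ties
    idx = np.argmin(np.abs(v[:, None] - choices[None, :]), axis=1)
    out = choices[idx]
    return float(out[0]) if np.ndim(value) == 0 else out


def generate_subject(
    spec: ExperimentSpec,
    context: str,
    params: ObserverParams,
    n_trials: int,
    seed,
    grid: EstimatorGrid | None = None,
    subject_id: str = "S01",
    adaptation_transient: bool = False,
) -> pd.DataFrame:
    """Simulate one subject in one context of an experiment.

    Delegates the generative chain to :func:`obsact.simulate.simulate_trials`
    with the spec's prior and transform, then fills in block/session/trial
    structure, tags the first ``adaptation_exclusion`` trials of each block,
    and (length task) snaps productions to the context's choice set *after*
    the production noise — the fitted model treats the response as
    continuous, the limiting case of infinitely many options.

    With ``adaptation_transient=True`` an exponentially decaying
    under-compensation (time constant 10 trials) is added at the start of
    each remapped rotation block, emulating visuomotor adaptation and
    motivating the 25-trial exclusion.  Off by default.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if params.noise_pre.kind != spec.noise_kind or params.noise_post.kind != spec.noise_kind:
        raise ValueError(
            f"noise kind mismatch: experiment {spec.id} uses {spec.noise_kind!r} noise, "
            f"got pre={params.noise_pre.kind!r}, post={params.noise_post.kind!r}"
        )
    transform = spec.transform(context)
    table = simulate_trials(
        params,
        transform,
        spec.sample_prior,
        n_trials,
        seed,
        grid=grid,
        subject_id=subject_id,
        context=context,
        units=spec.units,
    )
    idx = np.arange(n_trials)
    block = idx // spec.trials_per_block
    table["block"] = block + 1
    table["session"] = block // spec.blocks_per_session + 1
    trial_in_block = idx % spec.trials_per_block + 1
    table["trial"] = trial_in_block

    if adaptation_transient and transform.kind == "offset" and transform.value != 0:
        # early trials under-compensate the rotation, recovering with tau = 10 trials
        table["produced"] = table["produced"] - transform.value * np.exp(-(trial_in_block - 1) / 10.0)

    if spec.adaptation_exclusion > 0:
        mask = trial_in_block <= spec.adaptation_exclusion
        table.loc[mask, "excluded_reason"] = "adaptation"

    if spec.choice_sets is not None:
        table["produced"] = snap_to_choice(table["produced"].to_numpy(), spec.choice_sets[context])
    return table


@dataclass(frozen=True)
class CohortSpec:
    """Per-subject parameter ranges for a simulated cohort.

    Noise parameters are drawn uniformly from the given ranges (Weber
    fractions for scalar tasks, SDs in stimulus units for additive tasks).
    ``mtn_extra_range`` draws the extra mental-transformation noise injected
    only in the remapped context — folded into the pre-inference noise for
    late-inference subjects and into the post-inference noise for
    early-inference subjects.  ``offset_sd`` is the SD of the per-subject
    constant response offset, in stimulus units.
    """

    n_subjects: int = 11
    strategy: str = "late"
    pre_range: tuple[float, float] = (0.08, 0.16)
    post_range: tuple[float, float] = (0.05, 0.09)
    mtn_extra_range: tuple[float, float] = (0.0, 0.0)
    lapse_rate: float = 0.02
    offset_sd: float = 10.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("pre_range", "post_range", "mtn_extra_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi")

    def draw_params(self, subject_index: int, noise_kind: str) -> tuple[ObserverParams, ObserverParams, np.random.Generator]:
        """(identity-context params, remapped-context params, spawned rng) for
        one subject; fully determined by (master_seed, subject_index)."""
        rng = np.random.default_rng([self.master_seed, subject_index])
        pre = float(rng.uniform(*self.pre_range))
        post = float(rng.uniform(*self.post_range))
        mtn = float(rng.uniform(*self.mtn_extra_range))
        offset = float(rng.normal(0.0, self.offset_sd)) if self.offset_sd > 0 else 0.0
        base_pre = NoiseModel(noise_kind, pre)
        base_post = NoiseModel(noise_kind, post)
        identity = ObserverParams(self.strategy, base_pre, base_post, self.lapse_rate, offset)
        if self.strategy == "early":
            remapped = ObserverParams(self.strategy, base_pre, base_post.combined(mtn), self.lapse_rate, offset)
        else:
            remapped = ObserverParams(self.strategy, base_pre.combined(mtn), base_post, self.lapse_rate, offset)
        return identity, remapped, rng


def generate_cohort(
    spec: ExperimentSpec,
    cohort: CohortSpec,
    contexts=("identity", "remapped"),
    trials_per_context: int = 600,
    grid: EstimatorGrid | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate a cohort: map subject_id -> trial table over the requested
    contexts, with subject-specific parameters drawn from the cohort spec.
    Bit-reproducible from ``cohort.master_seed``."""
    contexts = list(contexts)
    if not contexts:
        raise ValueError("context list must be non-empty")
    out: dict[str, pd.DataFrame] = {}
    for i in range(cohort.n_subjects):
        subject_id = f"S{i + 1:02d}"
        identity_params, remapped_params, rng = cohort.draw_params(i, spec.noise_kind)
        pieces = []
        for ctx in contexts:
            params = remapped_params if ctx == "remapped" else identity_params
            seed = int(rng.integers(0, 2**31))
            pieces.append(
                generate_subject(
                    spec, ctx, params, trials_per_context, seed, grid=grid, subject_id=subject_id
                )
            )
        out[subject_id] = pd.concat(pieces, ignore_index=True)
    return out
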
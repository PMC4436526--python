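"""End-to-end orchestration: simulate a dyad, clean it, analyze coupling.

``simulate_dyad`` produces a raw actor/imitator pair for one crossed
condition, including the video condition's measurement artifacts (the
actor's board tilted 13 degrees, so raw positions arrive rotated, and the
imitator's behavioral lag inflated by the 111 ms presentation latency)
which the preprocessing stage is then responsible for undoing.
``analyze_dyad`` runs cleaning, trial segmentation, DV derivation and
per-trial coupling, returning tidy per-trial results ready for
:func:`dyadkin.stats.build_condition_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, PreprocessConfig, ScenarioConfig
from .core import CrossedCondition, Difficulty, Feedback, Recording, TrialWindow
from .coupling import trial_coupling
from .kinematics import DV_NAMES, derive_dvs
from .preprocess import preprocess_recording, rotate_xy, segment_trials
from .synth import BoardGeometry, GroundTruth, synth_actor, synth_imitator

log = logging.getLogger(__name__)


def scenario_params(
    condition: CrossedCondition, scenario: ScenarioConfig | None = None
) -> tuple[float, float, float]:
    """(behavioral lag s, coupling noise mm, gain) for one design cell."""
    sc = scenario or ScenarioConfig()
    lag = (
        sc.lag_face_to_face_s
        if condition.feedback == Feedback.face_to_face
        else sc.lag_video_s
    )
    noise = (
        sc.noise_face_to_face_mm
        if condition.feedback == Feedback.face_to_face
        else sc.noise_video_mm
    )
    if condition.difficulty == Difficulty.complex:
        lag += sc.lag_complex_extra_s
        noise += sc.noise_complex_extra_mm
    return lag, noise, sc.gain


@dataclass
class DyadSession:
    actor: Recording
    imitator: Recording
    actor_truth: GroundTruth
    imitator_truth: GroundTruth


def simulate_dyad(
    condition: CrossedCondition,
    rng: np.random.Generator,
    *,
    scenario: ScenarioConfig | None = None,
    board: BoardGeometry | None = None,
    person_id: str = "pair01",
    lag_s: float | None = None,
    noise_sd: float | None = None,
    gain: float | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
) -> DyadSession:
    """Simulate one raw session (actor + imitator) for a design cell.

    Behavioral parameters default to the condition scenario but can be
    overridden (e.g. noiseless dyads for lag-recovery checks).  In the
    video condition the raw actor positions are rotated 13 degrees
    anticlockwise (the tilted board) and the imitator lag includes the
    presentation latency, so the cleaned data only match after the
    preprocessing corrections.
    """
    sc = scenario or ScenarioConfig()
    board = board or BoardGeometry()
    pp = preprocess_cfg or PreprocessConfig()
    base_lag, base_noise, base_gain = scenario_params(condition, sc)
    lag_s = base_lag if lag_s is None else lag_s
    noise_sd = base_noise if noise_sd is None else noise_sd
    gain = base_gain if gain is None else gain

    actor, actor_gt = synth_actor(
        board,
        condition.difficulty,
        rng,
        n_trials=sc.n_trials,
        trial_s=sc.trial_s,
        rest_s=sc.rest_s,
        feedback=condition.feedback,
        person_id=f"{person_id}_actor",
    )

    total_lag = lag_s
    if condition.feedback == Feedback.video:
        # The imitator sees the actor only after the projection latency.
        total_lag = lag_s + round(pp.video_latency_s * actor.sample_rate) / actor.sample_rate
    imitator, imit_gt = synth_imitator(
        actor, total_lag, noise_sd, gain, rng, person_id=f"{person_id}_imitator"
    )
    imit_gt.true_lag_s = lag_s  # behavioral lag; latency is an artifact
    imit_gt.trial_windows = actor_gt.trial_windows
    imit_gt.trial_spans = actor_gt.trial_spans

    if condition.feedback == Feedback.video:
        # Tilted board: raw actor positions arrive rotated anticlockwise,
        # i.e. the inverse of the clockwise cleaning rotation.
        from .core import TRACKERS

        for tracker in TRACKERS:
            xs, ys = f"{tracker}_x", f"{tracker}_y"
            x, y = rotate_xy(
                actor.data[xs].to_numpy(),
                actor.data[ys].to_numpy(),
                -pp.rotation_deg,
            )
            actor.data[xs], actor.data[ys] = x, y
        sx, sy = rotate_xy(
            actor.start_point[:1], actor.start_point[1:2], -pp.rotation_deg
        )
        actor.start_point = np.array([sx[0], sy[0], actor.start_point[2]])

    return DyadSession(actor, imitator, actor_gt, imit_gt)


@dataclass
class DyadAnalysis:
    actor_clean: Recording
    imitator_clean: Recording
    windows: list[TrialWindow]
    actor_dvs: pd.DataFrame
    imitator_dvs: pd.DataFrame
    trial_results: pd.DataFrame  # tidy: dv, trial, r_abs, lag_s + metadata
    spike_report: dict[str, dict[str, int]]


def analyze_dyad(
    actor: Recording,
    imitator: Recording,
    preprocess_cfg: PreprocessConfig | None = None,
    analysis_cfg: AnalysisConfig | None = None,
    *,
    dvs: tuple[str, ...] = DV_NAMES,
    exclude_trials: set[int] | None = None,
    person_id: str | None = None,
) -> DyadAnalysis:
    """Clean both recordings, segment trials on the actor, couple the DVs.

    Trial windows are detected on the cleaned actor and applied to the
    imitator.  ``dvs`` restricts the analysis to a subset of the seven
    dependent variables; ``exclude_trials`` drops trials (0-based) before
    averaging (e.g. an aborted final trial).
    """
    pp = preprocess_cfg or PreprocessConfig()
    an = analysis_cfg or AnalysisConfig()
    actor_clean, actor_flags = preprocess_recording(actor, pp)
    imit_clean, imit_flags = preprocess_recording(imitator, pp)
    windows = segment_trials(actor_clean, pp)
    actor_dvs = derive_dvs(actor_clean)
    imit_dvs = derive_dvs(imit_clean)

    pid = person_id or actor.person_id
    rows = []
    for dv in dvs:
        tc = trial_coupling(
            actor_dvs[dv].to_numpy(),
            imit_dvs[dv].to_numpy(),
            windows,
            actor.sample_rate,
            an.max_lag_s,
            an.min_overlap_frac,
            exclude_trials=exclude_trials,
        )
        for i, res in enumerate(tc.per_trial):
            rows.append(
                {
                    "person_id": pid,
                    "feedback": actor.feedback.value,
                    "difficulty": actor.difficulty.value,
                    "dv": dv,
                    "trial": i,
                    "r_abs": res.r_abs_max if res else np.nan,
                    "lag_s": res.lag_at_max_s if res else np.nan,
                    "signed_r": res.signed_r_at_max if res else np.nan,
                }
            )
    return DyadAnalysis(
        actor_clean=actor_clean,
        imitator_clean=imit_clean,
        windows=windows,
        actor_dvs=actor_dvs,
        imitator_dvs=imit_dvs,
        trial_results=pd.DataFrame(rows),
        spike_report={"actor": actor_flags, "imitator": imit_flags},
    )


def run_synthetic_experiment(
    n_pairs: int,
    seed: int,
    *,
    scenario: ScenarioConfig | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
    analysis_cfg: AnalysisConfig | None = None,
    dvs: tuple[str, ...] = DV_NAMES,
) -> pd.DataFrame:
    """Simulate and analyze ``n_pairs`` dyads across all four conditions.

    Returns the concatenated tidy per-trial table over persons and
    conditions, ready for condition summarization and the 2x2 tests.
    """
    from .core import CONDITIONS

    rng = np.random.default_rng(seed)
    frames = []
    for pair in range(n_pairs):
        pid = f"pair{pair + 1:02d}"
        for cond in CONDITIONS:
            session = simulate_dyad(
                cond, rng, scenario=scenario, person_id=pid,
                preprocess_cfg=preprocess_cfg,
            )
            analysis = analyze_dyad(
                session.actor, session.imitator,
                preprocess_cfg, analysis_cfg, dvs=dvs, person_id=pid,
            )
            frames.append(analysis.trial_results)
    return pd.concat(frames, ignore_index=True)
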
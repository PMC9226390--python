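"""Synthetic behavioral studies with the structure the analysis assumes.

The generator emulates a 41-participant session of 120 digit-span trials
plus a 108-trial audiovisual-dominance pre-test.  Each participant carries
latent traits on the logit scale — a baseline encoding ability (the random
intercept), an audio-support gain, a rhythm gain (zero by default, matching
the null rhythm finding the analysis is designed to detect), a per-session
learning slope (the random Order slope), and a distractor-intrusion
tendency that audio support counteracts.  Questionnaire covariates are
derived from the latent traits plus noise so that subgroup analyses and the
person-level modeling stages have real signal to find.  Recall answers are
produced by independent per-target encoding, distractor intrusion, and
digit substitution noise, emitted in presentation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import (
    BLANK,
    PretestSlot,
    TrialSequence,
    TrialSlot,
    build_pretest_schedule,
    build_schedule,
    generate_sequences,
)
from .scoring import score_trial


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale and effect-size parameters of the synthetic experiment."""

    n_participants: int = 41
    n_sequences: int = 30
    seed: int = 0
    # planted effects (logit scale, per indicator / per scaled-order unit)
    audio_log_or: float = 0.3
    rhythm_log_or: float = 0.0
    encode_base_mean: float = 0.6
    intercept_sd: float = 0.7
    learning_slope_mean: float = 0.3
    slope_sd: float = 0.15
    audio_gain_sd: float = 0.15
    rhythm_gain_sd: float = 0.10
    # recall noise
    intrusion_base: float = 0.12
    intrusion_sd: float = 0.3
    substitution_prob: float = 0.02
    # pre-test reaction times (ms)
    rt_shift_ms: float = 150.0
    rt_fast_ms: float = 350.0
    rt_slow_ms: float = 450.0
    rt_av_facilitation_ms: float = 40.0
    rt_log_sd: float = 0.25
    pretest_error_rate: float = 0.03
    pretest_lapse_rate: float = 0.02
    # stimulus generation
    blank_probability: float = 0.1

    def __post_init__(self):
        for name in ("intrusion_base", "substitution_prob",
                     "pretest_error_rate", "pretest_lapse_rate",
                     "blank_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("intercept_sd", "slope_sd", "audio_gain_sd",
                     "rhythm_gain_sd", "intrusion_sd", "rt_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ParticipantProfile:
    id: int
    # latent traits
    encode_base: float
    audio_gain: float
    rhythm_gain: float
    learning_slope: float
    intrusion_logit: float
    dominance_latent: str  # AUD | VIS
    # observed covariates
    covariates: dict = field(default_factory=dict)


def _scale_order(order, n_trials: int = 120) -> np.ndarray:
    """Map trial rank 1..n onto [-1, 1] for the learning-slope term."""
    center = (n_trials + 1) / 2
    return (np.asarray(order, float) - center) / (n_trials - center)


def _six_point(rng: np.random.Generator, center: np.ndarray, noise: float = 0.9):
    raw = center + rng.normal(0, noise, size=np.shape(center))
    return np.clip(np.round(raw), 0, 5).astype(int)


def sample_participants(
    config: SimulationConfig, rng: np.random.Generator
) -> list[ParticipantProfile]:
    """Draw participant latent traits and linked questionnaire covariates.

    Covariate marginals: age normal 23.71 +/- 2.69 truncated to [18, 30],
    sex balanced, music education ~ 28/41, dominance split in half.
    Perceived task/memory difficulty fall with encoding ability; perceived
    sound and rhythm support rise with the respective gains.
    """
    n = config.n_participants
    z = rng.normal(size=(n, 5))
    encode_base = config.encode_base_mean + config.intercept_sd * z[:, 0]
    audio_gain = config.audio_log_or + config.audio_gain_sd * z[:, 1]
    rhythm_gain = config.rhythm_log_or + config.rhythm_gain_sd * z[:, 2]
    slope = config.learning_slope_mean + config.slope_sd * z[:, 3]
    intrusion = logit(config.intrusion_base) + config.intrusion_sd * z[:, 4]

    dominance = np.array(["AUD"] * (n // 2 + n % 2) + ["VIS"] * (n // 2))
    rng.shuffle(dominance)
    sex = np.array(["F"] * (n // 2) + ["M"] * (n - n // 2))
    rng.shuffle(sex)
    age = np.empty(n)
    for i in range(n):
        while True:
            a = rng.normal(23.71, 2.69)
            if 18 <= a <= 30:
                age[i] = round(a, 1)
                break
    handed = np.where(rng.random(n) < 0.9, "R", "L")
    mus_edu = rng.random(n) < 28 / 41
    mus_active = rng.random(n) < 0.4
    activity = rng.integers(1, 6, size=n)
    caffeine = rng.random(n) < 0.5
    valence = np.round(rng.uniform(-1, 1, size=n), 2)
    arousal = np.round(rng.uniform(-1, 1, size=n), 2)
    ns_center = np.where(rng.random(n) < 0.5, 3.0, 7.0)
    nss = np.clip(ns_center[:, None] + rng.normal(0, 1.2, size=(n, 5)), 0, 10).round(1)

    eb_std = (encode_base - config.encode_base_mean) / max(config.intercept_sd, 1e-8)
    task_diff = _six_point(rng, 2.5 - 1.2 * eb_std)
    mem_diff = _six_point(rng, 2.5 - 0.8 * eb_std)
    tired = _six_point(rng, 2.5 - 1.0 * (slope - config.learning_slope_mean)
                       / max(config.slope_sd, 1e-8) * 0.5)
    sound_supp = _six_point(
        rng, 2.5 + 1.5 * (audio_gain - config.audio_log_or) / max(config.audio_gain_sd, 1e-8) * 0.8
    )
    rhythm_supp = _six_point(
        rng, 2.5 + 1.5 * (rhythm_gain - config.rhythm_log_or) / max(config.rhythm_gain_sd, 1e-8) * 0.8
    )

    profiles = []
    for i in range(n):
        cov = {
            "Sex": sex[i],
            "Age": float(age[i]),
            "Handedness": handed[i],
            "MusActive": bool(mus_active[i]),
            "MusEducation": bool(mus_edu[i]),
            "M-Valence": float(valence[i]),
            "M-Arousal": float(arousal[i]),
            "Activity": int(activity[i]),
            "Caffeine": bool(caffeine[i]),
            "PercTiredness": int(tired[i]),
            "PercMemoryDifficulty": int(mem_diff[i]),
            "PercTaskDifficulty": int(task_diff[i]),
            "PercRhythmSupport": int(rhythm_supp[i]),
            "PercSoundSupport": int(sound_supp[i]),
        }
        cov.update({f"NSS{j + 1}": float(nss[i, j]) for j in range(5)})
        profiles.append(
            ParticipantProfile(
                id=i + 1,
                encode_base=float(encode_base[i]),
                audio_gain=float(audio_gain[i]),
                rhythm_gain=float(rhythm_gain[i]),
                learning_slope=float(slope[i]),
                intrusion_logit=float(intrusion[i]),
                dominance_latent=str(dominance[i]),
                covariates=cov,
            )
        )
    return profiles


def covariates_frame(profiles: Sequence[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"participant": p.id, **p.covariates,
               "dominance_latent": p.dominance_latent}
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_pretest(
    profile: ParticipantProfile,
    schedule: Sequence[PretestSlot],
    rng: np.random.Generator,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Reaction-time log for one participant's dominance pre-test.

    RT = shift + lognormal(log scale, sigma); the dominant modality gets the
    faster unimodal scale and the audiovisual scale sits a facilitation
    margin below the faster unimodal one (multisensory benefit).  A small
    error rate and occasional slow lapses exercise the cleaning rules.
    """
    if profile.dominance_latent == "VIS":
        scale = {"Vi": config.rt_fast_ms, "Au": config.rt_slow_ms}
    else:
        scale = {"Au": config.rt_fast_ms, "Vi": config.rt_slow_ms}
    scale["AV"] = min(scale["Au"], scale["Vi"]) - config.rt_av_facilitation_ms
    rows = []
    for slot in schedule:
        rt = config.rt_shift_ms + np.exp(
            rng.normal(np.log(scale[slot.modality]), config.rt_log_sd)
        )
        if rng.random() < config.pretest_lapse_rate:
            rt += rng.uniform(800, 1500)
        rows.append(
            {
                "participant": profile.id,
                "index": slot.index,
                "modality": slot.modality,
                "object": slot.obj,
                "rt_ms": float(round(rt, 1)),
                "correct": bool(rng.random() >= config.pretest_error_rate),
            }
        )
    return pd.DataFrame(rows)


def simulate_recall(
    profile: ParticipantProfile,
    trial_slot: TrialSlot,
    sequence: TrialSequence,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> tuple[int, ...]:
    """One recalled answer: encoding, intrusion, and substitution noise.

    Each target is encoded independently with probability
    ``logistic(encode_base + audio_gain*audio + rhythm_gain*rhythm +
    learning_slope*scaled_order)``; each non-blank distractor intrudes with
    probability ``logistic(intrusion_logit - audio_gain*audio)`` (audio
    helps reject distractors).  Retained items are emitted in presentation
    order; each emitted digit is replaced by a uniform random digit with the
    substitution probability.  Blanks are never emitted.
    """
    cond = trial_slot.condition
    audio = float(cond.audio_support)
    rhythm = float(cond.rhythmic)
    n_trials = 4 * config.n_sequences
    enc_logit = (
        profile.encode_base
        + profile.audio_gain * audio
        + profile.rhythm_gain * rhythm
        + profile.learning_slope * float(_scale_order(trial_slot.order, n_trials))
    )
    p_enc = expit(enc_logit)
    p_intr = expit(profile.intrusion_logit - profile.audio_gain * audio)
    emitted: list[int] = []
    for target, gap in zip(sequence.targets, sequence.gaps):
        if rng.random() < p_enc:
            emitted.append(target)
        for d in gap:
            if d != BLANK and rng.random() < p_intr:
                emitted.append(d)
    answer = [
        int(rng.integers(1, 10)) if rng.random() < config.substitution_prob else d
        for d in emitted
    ]
    return tuple(answer)


@dataclass
class StudyBundle:
    config: SimulationConfig
    sequences: list[TrialSequence]
    schedule: pd.DataFrame  # participant, order, condition, sequence_id
    answers: pd.DataFrame  # participant, order, condition, sequence_id, answer
    pretest: pd.DataFrame
    covariates: pd.DataFrame
    profiles: list[ParticipantProfile]

    @property
    def seed(self) -> int:
        return self.config.seed

    def sequence_by_id(self, sequence_id: int) -> TrialSequence:
        return self.sequences[sequence_id - 1]


def simulate_study(config: SimulationConfig | None = None) -> StudyBundle:
    """Generate a complete synthetic study, reproducible from the seed.

    All participants see the same 30 sequences, each in its own
    pseudo-randomized order; answers, pre-test logs and the covariate table
    come from a single seeded random stream.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    sequences = generate_sequences(
        rng, config.n_sequences, blank_probability=config.blank_probability
    )
    profiles = sample_participants(config, rng)
    sched_rows, ans_rows, pre_frames = [], [], []
    for profile in profiles:
        slots = build_schedule(sequences, rng)
        pre_sched = build_pretest_schedule(rng)
        pre_frames.append(simulate_pretest(profile, pre_sched, rng, config))
        for slot in slots:
            seq = sequences[slot.sequence_id - 1]
            answer = simulate_recall(profile, slot, seq, rng, config)
            sched_rows.append(
                {"participant": profile.id, "order": slot.order,
                 "condition": slot.condition.code, "sequence_id": slot.sequence_id}
            )
            ans_rows.append(
                {"participant": profile.id, "order": slot.order,
                 "condition": slot.condition.code, "sequence_id": slot.sequence_id,
                 "answer": "".join(map(str, answer))}
            )
    return StudyBundle(
        config=config,
        sequences=sequences,
        schedule=pd.DataFrame(sched_rows),
        answers=pd.DataFrame(ans_rows),
        pretest=pd.concat(pre_frames, ignore_index=True),
        covariates=covariates_frame(profiles),
        profiles=profiles,
    )


def score_study(bundle: StudyBundle, *, derive_clusters: bool = True) -> pd.DataFrame:
    """Score every answer and join participant covariates.

    With ``derive_clusters`` the Dominance label is taken from the pre-test
    k-means pipeline and NoiseSensitivity from 2-means on the NSS items,
    exactly as the analysis would derive them from raw data; otherwise the
    simulator's latent dominance is used directly.
    """
    from .dominance import dominance_pipeline
    from .nonparam import cluster_noise_sensitivity

    rows = []
    for r in bundle.answers.itertuples(index=False):
        seq = bundle.sequence_by_id(r.sequence_id)
        answer = tuple(int(c) for c in r.answer)
        s = score_trial(seq, answer)
        rows.append(
            {"participant": r.participant, "order": r.order,
             "condition": r.condition, "sequence_id": r.sequence_id,
             "per_digit": s.per_digit, "levenshtein": s.levenshtein,
             "distraction": s.distraction}
        )
    scored = pd.DataFrame(rows)
    cov = bundle.covariates.copy()
    if derive_clusters:
        dom = dominance_pipeline(bundle.pretest, rng_seed=bundle.seed)
        cov = cov.merge(
            dom.assignments[["participant", "label"]].rename(
                columns={"label": "Dominance"}
            ),
            on="participant", how="left",
        )
        items = cov.set_index("participant")[[f"NSS{i}" for i in range(1, 6)]]
        ns = cluster_noise_sensitivity(items, rng_seed=bundle.seed)
        cov = cov.merge(ns.rename("NoiseSensitivity"), left_on="participant",
                        right_index=True, how="left")
    else:
        cov["Dominance"] = cov["dominance_latent"]
    return scored.merge(cov, on="participant", how="left")
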
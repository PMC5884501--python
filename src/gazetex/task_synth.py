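"""Synthetic number-search task layouts and scanpath simulation.

The visual-search stimulus is a question with a 7-digit target number and
four comparison numbers of lengths 2-5 shown right-aligned; the correct
answer is the length of the longest comparison that matches the target's
suffix.  Subjects scan the target, the comparisons and finally click one
of five answer options, so a random clicker scores 1/5.

The simulator gives each synthetic subject an idiosyncratic oculomotor
profile — Gamma-distributed fixation durations, a linear saccade
amplitude-duration main sequence with a minimum-jerk velocity profile,
within-fixation Ornstein-Uhlenbeck drift, sample-level tremor, and biased
region-visit preferences.  Between-subject spread of these parameters is
controlled by a single ``separation`` knob (0 = identical subjects), and
a second session recorded after a multi-week gap is emulated by
multiplicative jitter of the profile ("template aging").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .gaze_core import (GazeDataError, GazeRecording, ScreenGeometry,
                        degrees_to_pixels, pixels_to_degrees)

TARGET_LENGTH = 7
COMPARISON_LENGTHS = (2, 3, 4, 5)
#: Answer-option labels; the four answer lengths plus a distractor, so a
#: random click is correct with probability 1/5.
OPTION_LABELS = ("2", "3", "4", "5", "none")

# Minimum-jerk profiles peak at 1.875 * amplitude / duration.
MINJERK_PEAK_FACTOR = 1.875


@dataclass(frozen=True)
class Rect:
    """Axis-aligned screen rectangle in pixels (x, y = top-left corner)."""

    x: float
    y: float
    w: float
    h: float

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)


@dataclass
class QuestionLayout:
    """One number-search question: digits plus screen rectangles.

    ``comparisons`` may be empty for degenerate single-region layouts
    used in simulator tests; generated layouts always carry the four
    comparison numbers and satisfy the answer rule.
    """

    target: str
    comparisons: list[tuple[str, Rect]]
    answer_options: list[tuple[str, Rect]]
    correct_answer: int
    target_rect: Rect = Rect(860, 100, 200, 60)

    def __post_init__(self) -> None:
        if len(self.target) != TARGET_LENGTH or not self.target.isdigit():
            raise ValueError("target must be a 7-digit string")
        if self.comparisons:
            match = longest_suffix_match(self.target,
                                         [c for c, _ in self.comparisons])
            if match != self.correct_answer:
                raise ValueError(
                    f"correct_answer {self.correct_answer} does not equal the "
                    f"longest suffix match {match}")

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "correct_answer": self.correct_answer,
            "target_rect": vars(self.target_rect),
            "comparisons": [(c, vars(r)) for c, r in self.comparisons],
            "answer_options": [(o, vars(r)) for o, r in self.answer_options],
        }


def longest_suffix_match(target: str, comparisons: Sequence[str]) -> int:
    """Length of the longest comparison equal to the target's suffix.

    Comparisons are matched right-aligned against the target; returns 0
    when none matches.
    """
    if not target.isdigit():
        raise ValueError("target must contain digits only")
    best = 0
    for comp in comparisons:
        if not comp.isdigit():
            raise ValueError("comparisons must contain digits only")
        if len(comp) <= len(target) and target.endswith(comp):
            best = max(best, len(comp))
    return best


# ---------------------------------------------------------------------------
# Layout generation (fixed template mirroring the stimulus: target on top,
# comparisons in two columns, answer options in a bottom row)
# ---------------------------------------------------------------------------

_COMPARISON_SLOTS = [
    Rect(560, 280, 220, 60), Rect(1140, 280, 220, 60),
    Rect(560, 420, 220, 60), Rect(1140, 420, 220, 60),
]
_OPTION_SLOTS = [Rect(260 + 290 * i, 760, 180, 60) for i in range(5)]


def make_layout(correct_answer: int, seed: int) -> QuestionLayout:
    """Generate one question whose answer is ``correct_answer`` (2-5).

    Comparisons of length <= correct_answer are exact suffixes of the
    target; longer comparisons are decoys whose leading digit is altered
    so they cannot match.  Deterministic per seed.
    """
    if correct_answer not in COMPARISON_LENGTHS:
        raise ValueError("correct_answer must be in {2, 3, 4, 5}")
    rng = np.random.default_rng(seed)
    target = "".join(str(d) for d in rng.integers(0, 10, TARGET_LENGTH))
    comparisons = []
    for length in COMPARISON_LENGTHS:
        suffix = target[-length:]
        if length <= correct_answer:
            comparisons.append(suffix)
        else:
            # break the match in the leading digit only
            wrong = (int(suffix[0]) + int(rng.integers(1, 10))) % 10
            comparisons.append(str(wrong) + suffix[1:])
    order = rng.permutation(len(comparisons))
    placed = [(comparisons[k], _COMPARISON_SLOTS[s]) for s, k in enumerate(order)]
    options = list(zip(OPTION_LABELS, _OPTION_SLOTS))
    return QuestionLayout(target=target, comparisons=placed,
                          answer_options=options,
                          correct_answer=correct_answer)


# ---------------------------------------------------------------------------
# Oculomotor profiles
# ---------------------------------------------------------------------------

@dataclass
class OculomotorProfile:
    """Per-subject oculomotor idiosyncrasy parameters.

    Fixation durations follow Gamma(shape, scale) seconds; saccade
    duration follows the linear main sequence
    ``duration_ms = intercept + slope * amplitude_deg``; ``drift_sd_deg``
    is the stationary SD of slow within-fixation drift, and
    ``tremor_sd_deg`` the SD of white sample-level noise.
    ``saccade_curvature`` is the signed lateral bulge of the saccade
    path as a fraction of its amplitude (saccade trajectories curve
    idiosyncratically), ``landing_bias_*_deg`` a systematic offset of
    fixation landing positions relative to the viewed region's centre
    (preferred-viewing-position bias), and ``scan_bias`` weights the
    visit preference over comparison slots.
    """

    subject_id: str
    fixation_duration_shape: float = 6.0
    fixation_duration_scale: float = 0.04
    saccade_duration_slope_ms_per_deg: float = 2.2
    saccade_duration_intercept_ms: float = 21.0
    drift_sd_deg: float = 0.10
    tremor_sd_deg: float = 0.05
    saccade_curvature: float = 0.0
    landing_bias_x_deg: float = 0.0
    landing_bias_y_deg: float = 0.0
    scan_bias: np.ndarray = field(
        default_factory=lambda: np.full(len(_COMPARISON_SLOTS),
                                        1.0 / len(_COMPARISON_SLOTS)))
    revisit_prob: float = 0.3

    def __post_init__(self) -> None:
        self.scan_bias = np.asarray(self.scan_bias, dtype=float)
        if np.any(self.scan_bias <= 0):
            raise ValueError("scan_bias weights must be positive")
        self.scan_bias = self.scan_bias / self.scan_bias.sum()
        for name in ("fixation_duration_shape", "fixation_duration_scale",
                     "saccade_duration_slope_ms_per_deg",
                     "saccade_duration_intercept_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.drift_sd_deg < 0 or self.tremor_sd_deg < 0:
            raise ValueError("noise SDs must be non-negative")

    def mean_fixation_duration(self) -> float:
        return self.fixation_duration_shape * self.fixation_duration_scale

    def perturb(self, sd: float, rng: np.random.Generator) -> "OculomotorProfile":
        """Multiplicative log-normal jitter of every scale parameter.

        Used to emulate template aging between recording sessions;
        ``sd = 0`` returns an identical profile.
        """
        if sd < 0:
            raise ValueError("sd must be non-negative")

        def jitter(v: float) -> float:
            return float(v * math.exp(sd * rng.standard_normal()))

        return replace(
            self,
            fixation_duration_shape=jitter(self.fixation_duration_shape),
            fixation_duration_scale=jitter(self.fixation_duration_scale),
            saccade_duration_slope_ms_per_deg=jitter(
                self.saccade_duration_slope_ms_per_deg),
            saccade_duration_intercept_ms=jitter(
                self.saccade_duration_intercept_ms),
            drift_sd_deg=jitter(self.drift_sd_deg),
            tremor_sd_deg=jitter(self.tremor_sd_deg),
            saccade_curvature=(self.saccade_curvature
                               + sd * 0.2 * rng.standard_normal()),
            landing_bias_x_deg=(self.landing_bias_x_deg
                                + sd * 0.7 * rng.standard_normal()),
            landing_bias_y_deg=(self.landing_bias_y_deg
                                + sd * 0.7 * rng.standard_normal()),
            scan_bias=self.scan_bias * np.exp(sd * rng.standard_normal(
                self.scan_bias.shape)),
            revisit_prob=float(np.clip(
                self.revisit_prob * math.exp(sd * rng.standard_normal()),
                0.01, 0.95)),
        )


#: Population geometric means and log-scale spreads (at separation = 1) of
#: the profile parameters.  Values are typical of adult visual search:
#: ~240 ms mean fixations, ~21 ms + 2.2 ms/deg saccade main sequence.
_COHORT_HYPERPRIOR = {
    "fixation_duration_shape": (6.0, 0.30),
    "fixation_duration_scale": (0.04, 0.30),
    "saccade_duration_slope_ms_per_deg": (2.2, 0.25),
    "saccade_duration_intercept_ms": (21.0, 0.15),
    "drift_sd_deg": (0.10, 0.30),
    "tremor_sd_deg": (0.05, 0.30),
}


def make_cohort(n_subjects: int, seed: int,
                separation: float = 1.0) -> list[OculomotorProfile]:
    """Draw a cohort of subject profiles from the population hyperprior.

    Each scale parameter is log-normal around its population value with
    log-SD proportional to ``separation``; ``separation = 0`` collapses
    the cohort onto identical profiles.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        params = {
            name: base * math.exp(separation * sd * rng.standard_normal())
            for name, (base, sd) in _COHORT_HYPERPRIOR.items()
        }
        # strongly idiosyncratic visit preferences: at separation=1 each
        # subject has a stable habitual scan order with occasional swaps,
        # matching the stereotyped scanning strategies seen in humans
        bias = np.exp(separation * 1.5 * rng.standard_normal(
            len(_COMPARISON_SLOTS)))
        # logit-normal re-checking habit: spreads toward stable
        # near-always / near-never habits as separation grows
        logit = math.log(0.3 / 0.7) + separation * 2.5 * rng.standard_normal()
        revisit = float(1.0 / (1.0 + math.exp(-logit)))
        # geometric idiosyncrasies (zero-mean, vanish at separation=0):
        # saccade-path curvature and preferred landing offset
        curvature = separation * 0.2 * rng.standard_normal()
        bias_x, bias_y = separation * 0.7 * rng.standard_normal(2)
        profiles.append(OculomotorProfile(
            subject_id=f"S{i + 1:03d}", scan_bias=bias,
            revisit_prob=revisit, saccade_curvature=curvature,
            landing_bias_x_deg=float(bias_x),
            landing_bias_y_deg=float(bias_y), **params))
    return profiles


# ---------------------------------------------------------------------------
# Scanpath simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedSaccade:
    """Ground-truth saccade metadata emitted by the simulator."""

    amplitude_deg: float
    duration_s: float

    @property
    def peak_velocity_deg_s(self) -> float:
        return MINJERK_PEAK_FACTOR * self.amplitude_deg / self.duration_s


@dataclass
class ScanpathEvents:
    """Ground-truth event metadata of one simulated scanpath."""

    saccades: list[SimulatedSaccade]
    fixation_durations_s: list[float]


def _visit_plan(layout: QuestionLayout, profile: OculomotorProfile,
                accuracy: float, rng: np.random.Generator
                ) -> tuple[list[Rect], bool]:
    """Region-visit order: target, biased comparison tour, answer click."""
    plan = [layout.target_rect]
    n_comp = len(layout.comparisons)
    if n_comp:
        weights = profile.scan_bias
        if len(weights) != n_comp:
            weights = np.full(n_comp, 1.0 / n_comp)
        # biased random permutation via the Gumbel-max trick
        keys = np.log(weights) + rng.gumbel(size=n_comp)
        for idx in np.argsort(-keys):
            plan.append(layout.comparisons[idx][1])
            if rng.random() < profile.revisit_prob:
                plan.append(layout.target_rect)
    correct = rng.random() < accuracy
    labels = [label for label, _ in layout.answer_options]
    target_label = str(layout.correct_answer)
    if correct and target_label in labels:
        choice = labels.index(target_label)
    else:
        others = [i for i, lab in enumerate(labels) if lab != target_label]
        choice = int(rng.choice(others)) if others else 0
        correct = correct and not others
    plan.append(layout.answer_options[choice][1])
    clicked_correct = labels[choice] == target_label
    return plan, clicked_correct


def simulate_scanpath(profile: OculomotorProfile, visit_rects: Sequence[Rect],
                      rate_hz: float, geometry: ScreenGeometry, seed: int,
                      invalid_prob: float = 0.035,
                      ) -> tuple[GazeRecording, ScanpathEvents]:
    """Simulate alternating fixations and saccades over a visit sequence.

    Fixations land at the region centre plus Gaussian scatter of SD
    ``drift_sd_deg`` and drift around the landing point as a discrete
    Ornstein-Uhlenbeck process with that stationary SD; saccades follow
    a straight minimum-jerk path whose duration obeys the profile's main
    sequence.  White tremor noise is added to every sample and samples
    drop out (``valid = False``) independently with ``invalid_prob``.
    """
    if rate_hz < 30:
        raise ValueError("rate_hz must be at least 30")
    if not visit_rects:
        raise ValueError("visit sequence must be non-empty")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    drift_px = degrees_to_pixels(geometry, profile.drift_sd_deg)
    tremor_px = degrees_to_pixels(geometry, profile.tremor_sd_deg)

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    saccades: list[SimulatedSaccade] = []
    fixation_durations: list[float] = []
    pos = None
    ou_phi = math.exp(-dt / 0.1)  # drift time constant 100 ms
    ou_step = drift_px * math.sqrt(max(0.0, 1.0 - ou_phi ** 2))
    bias_px = np.array([
        math.copysign(degrees_to_pixels(geometry,
                                        abs(profile.landing_bias_x_deg)),
                      profile.landing_bias_x_deg),
        math.copysign(degrees_to_pixels(geometry,
                                        abs(profile.landing_bias_y_deg)),
                      profile.landing_bias_y_deg),
    ])

    for rect in visit_rects:
        cx, cy = rect.center
        landing = (np.array([cx, cy]) + bias_px
                   + rng.normal(0.0, drift_px, 2))
        if pos is not None:
            # saccade from current position to the landing point
            amp_px = float(np.hypot(*(landing - pos)))
            amp_deg = pixels_to_degrees(geometry, amp_px)
            dur_ms = (profile.saccade_duration_intercept_ms
                      + profile.saccade_duration_slope_ms_per_deg * amp_deg)
            dur_s = dur_ms / 1000.0
            n = max(1, round(dur_s * rate_hz))
            tau = (np.arange(1, n + 1)) / n
            s = 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5  # minimum jerk
            path = pos[None, :] + s[:, None] * (landing - pos)[None, :]
            if profile.saccade_curvature != 0.0 and amp_px > 0:
                # idiosyncratic lateral bulge, maximal mid-flight
                direction = (landing - pos) / amp_px
                normal = np.array([-direction[1], direction[0]])
                bulge = (profile.saccade_curvature * amp_px
                         * np.sin(np.pi * s))
                path = path + bulge[:, None] * normal[None, :]
            xs.append(path[:, 0])
            ys.append(path[:, 1])
            saccades.append(SimulatedSaccade(amplitude_deg=amp_deg,
                                            duration_s=dur_s))
        # fixation at the landing point
        fix_dur = rng.gamma(profile.fixation_duration_shape,
                            profile.fixation_duration_scale)
        n_fix = max(2, round(fix_dur * rate_hz))
        fixation_durations.append(n_fix / rate_hz)
        fix = np.empty((n_fix, 2))
        p = landing.copy()
        for i in range(n_fix):
            fix[i] = p
            p = landing + ou_phi * (p - landing) + rng.normal(0.0, 1.0, 2) * ou_step
        xs.append(fix[:, 0])
        ys.append(fix[:, 1])
        pos = fix[-1]

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if tremor_px > 0:
        x = x + rng.normal(0.0, tremor_px, x.shape)
        y = y + rng.normal(0.0, tremor_px, y.shape)
    t = np.arange(len(x)) * dt
    valid = rng.random(len(x)) >= invalid_prob
    if valid.sum() < 2:  # keep recordings renderable
        valid[:2] = True
    rec = GazeRecording(t=t, x=x, y=y, valid=valid, rate_hz=rate_hz,
                        subject_id=profile.subject_id)
    return rec, ScanpathEvents(saccades=saccades,
                               fixation_durations_s=fixation_durations)


def simulate_question(profile: OculomotorProfile, layout: QuestionLayout,
                      rate_hz: float, geometry: ScreenGeometry, seed: int,
                      accuracy: float = 0.9, invalid_prob: float = 0.035,
                      return_info: bool = False):
    """Simulate one subject answering one question.

    Returns the :class:`GazeRecording`; with ``return_info=True`` also a
    dict carrying the ground-truth saccade list and whether the clicked
    option was correct.
    """
    if geometry.width_px < 2 or geometry.height_px < 2:
        raise ValueError("degenerate screen geometry")
    rng = np.random.default_rng(seed)
    plan, clicked_correct = _visit_plan(layout, profile, accuracy, rng)
    rec, events = simulate_scanpath(
        profile, plan, rate_hz, geometry,
        seed=int(rng.integers(2 ** 31)), invalid_prob=invalid_prob)
    if return_info:
        return rec, {"correct": clicked_correct, "events": events,
                     "saccades": events.saccades,
                     "reaction_time_s": rec.duration}
    return rec


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionPlan:
    """Bookkeeping of a full data-collection session structure.

    The study-replica default is 58 subjects x 2 trials x 4 tests x 40
    questions = 18,560 recordings.
    """

    n_subjects: int = 58
    n_trials: int = 2
    tests_per_trial: int = 4
    questions_per_test: int = 40
    rate_hz: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_trials", "tests_per_trial",
                     "questions_per_test"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def total_recordings(self) -> int:
        return (self.n_subjects * self.n_trials * self.tests_per_trial
                * self.questions_per_test)


def simulate_session(plan: SessionPlan, geometry: ScreenGeometry,
                     separation: float = 1.0, aging_sd: float = 0.0,
                     accuracy: float = 0.9, invalid_prob: float = 0.035,
                     n_kinds: int = 4,
                     ) -> tuple[list[GazeRecording], pd.DataFrame]:
    """Simulate a full cohort session and return recordings + summary.

    Trial 2 uses profiles perturbed by ``aging_sd`` multiplicative
    jitter, emulating the multi-week gap between recording sessions.
    The summary table carries per-subject/trial mean reaction time and
    accuracy rate.  Question kinds (answer lengths 2-5) are balanced.
    """
    ss = np.random.SeedSequence(plan.seed)
    cohort_seed, layout_seed, *rest = ss.generate_state(3)
    profiles = make_cohort(plan.n_subjects, seed=int(cohort_seed),
                           separation=separation)
    rng = np.random.default_rng(int(layout_seed))
    kinds = list(COMPARISON_LENGTHS[:n_kinds]) or list(COMPARISON_LENGTHS)

    recordings: list[GazeRecording] = []
    rows = []
    for s_idx, profile in enumerate(profiles):
        subject_rng = np.random.default_rng(ss.spawn(1)[0])
        for trial in range(1, plan.n_trials + 1):
            p = profile
            if trial > 1 and aging_sd > 0:
                p = profile.perturb(aging_sd, subject_rng)
            rts, corrects = [], []
            q_counter = 0
            for test in range(plan.tests_per_trial):
                for q in range(plan.questions_per_test):
                    kind = kinds[q_counter % len(kinds)]
                    q_counter += 1
                    layout = make_layout(kind, seed=int(rng.integers(2 ** 31)))
                    rec, info = simulate_question(
                        p, layout, plan.rate_hz, geometry,
                        seed=int(rng.integers(2 ** 31)), accuracy=accuracy,
                        invalid_prob=invalid_prob, return_info=True)
                    rec.subject_id = profile.subject_id
                    rec.trial = trial
                    rec.question_id = f"T{test + 1}Q{q + 1}"
                    recordings.append(rec)
                    rts.append(info["reaction_time_s"])
                    corrects.append(info["correct"])
            rows.append({
                "subject": profile.subject_id, "trial": trial,
                "mean_reaction_time_s": float(np.mean(rts)),
                "accuracy_rate": float(np.mean(corrects)),
                "n_questions": len(rts),
            })
    summary = pd.DataFrame(rows)
    return recordings, summary
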
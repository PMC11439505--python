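"""Synthetic play-log cohorts for tablet-based cognitive-training studies.

Real trial logs of this kind record, for every participant and study day,
how long the participant played, how many sessions they opened, the highest
task level they reached and how many tasks they completed.  Participants are
prescribed a weekly schedule (typically 5 play days out of 7, 45-60 minutes
per day), and daily adherence is defined by a minimum play-time threshold.
This module generates cohorts with that statistical structure -- weekly
periodicity, heterogeneous per-participant playing archetypes, and a
controllable amount of between-participant and between-study distribution
shift -- so the whole prediction pipeline can be exercised and tested
without access to any human data.

Four archetypes are modelled, mirroring the qualitatively distinct playing
patterns such studies report:

``non_player``
    rarely or never opens the app.
``consistent``
    plays nearly every scheduled day for about the prescribed duration.
``consistent_with_lapses``
    plays consistently but misses contiguous runs of days; lapse runs are
    geometric with a configurable mean length, giving the characteristic
    light bands in Gramian-angular-field images.
``erratic``
    plays on and off with no regard for the schedule and highly variable
    session lengths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "DayRecord",
    "ParticipantLog",
    "ArchetypeSpec",
    "CohortSpec",
    "ARCHETYPES",
    "generate_participant",
    "generate_cohort",
    "make_benchmark_pair",
]

#: Column order of the per-day feature block used throughout the package.
FEATURE_NAMES = ("duration", "sessions", "max_level", "tasks")

#: Minutes-per-day prescription that the default archetypes are calibrated to.
REFERENCE_PRESCRIPTION = 45.0


@dataclass(frozen=True)
class DayRecord:
    """One participant-day of play: the four predictors used by the models."""

    day_index: int
    duration: float  # minutes played
    sessions: int
    max_level: int
    tasks: int

    def __post_init__(self):
        if self.duration < 0 or self.sessions < 0 or self.max_level < 0 or self.tasks < 0:
            raise ValueError(f"negative value in day record {self}")
        if self.duration == 0 and (self.sessions != 0 or self.tasks != 0):
            raise ValueError(f"zero duration with nonzero activity in {self}")


@dataclass
class ParticipantLog:
    """Ordered daily play records for one participant.

    ``day_index`` runs 1..n_days consecutively; a day the participant did
    not play is a real record with all-zero variables, not a missing row.
    """

    participant_id: str
    study_id: str
    days: list[DayRecord]
    gap_days: list[int] = field(default_factory=list)  # zero-filled calendar gaps

    def __post_init__(self):
        for i, rec in enumerate(self.days, start=self.days[0].day_index if self.days else 1):
            if rec.day_index != i:
                raise ValueError(
                    f"participant {self.participant_id!r}: day_index not consecutive "
                    f"(expected {i}, found {rec.day_index})"
                )

    @property
    def n_days(self) -> int:
        return len(self.days)

    def durations(self) -> np.ndarray:
        """Daily minutes played, as a float vector."""
        return np.array([d.duration for d in self.days], dtype=float)

    def features(self) -> np.ndarray:
        """(n_days, 4) array in :data:`FEATURE_NAMES` order."""
        return np.array(
            [[d.duration, d.sessions, d.max_level, d.tasks] for d in self.days],
            dtype=float,
        )

    def slice_days(self, start: int, stop: int) -> "ParticipantLog":
        """Sub-log covering day_index ``start``..``stop`` inclusive."""
        sub = [d for d in self.days if start <= d.day_index <= stop]
        return ParticipantLog(self.participant_id, self.study_id, sub,
                              [g for g in self.gap_days if start <= g <= stop])


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one playing archetype.

    Parameters
    ----------
    play_probability
        Long-run probability of playing on a scheduled day.
    mean_duration, duration_sd
        Minutes played on a played day: Gaussian truncated at zero.
    lapse_run_length
        Mean length (days) of contiguous missed-day runs; only the
        ``consistent_with_lapses`` dynamics use it.
    level_growth_rate
        Expected increase of the maximum task level per played day.
    """

    name: str
    play_probability: float
    mean_duration: float
    duration_sd: float
    lapse_run_length: float = 1.0
    level_growth_rate: float = 0.3
    tasks_per_minute: float = 0.35
    two_session_prob: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.play_probability <= 1.0:
            raise ConfigurationError(
                f"play_probability must be in [0, 1], got {self.play_probability}")
        if self.mean_duration < 0:
            raise ConfigurationError("mean_duration must be >= 0")
        if self.lapse_run_length < 1.0:
            raise ConfigurationError("lapse_run_length must be >= 1 day")


ARCHETYPES: dict[str, ArchetypeSpec] = {
    "non_player": ArchetypeSpec("non_player", 0.05, 8.0, 6.0, 10.0, 0.05),
    "consistent": ArchetypeSpec("consistent", 0.95, 45.0, 8.0, 1.0, 0.5),
    "consistent_with_lapses": ArchetypeSpec(
        "consistent_with_lapses", 0.75, 45.0, 10.0, 3.0, 0.4),
    "erratic": ArchetypeSpec("erratic", 0.5, 25.0, 18.0, 2.0, 0.2),
}


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``shift`` scales per-participant jitter of the archetype parameters
    (additive on play probability and mean duration), emulating the fact
    that every participant's data come from a different distribution.
    ``prescribed_minutes`` applies a study-level multiplicative shift on
    durations relative to the 45-minute reference prescription, which is
    how the two real trials differed (45- vs 60-minute sessions).
    """

    n_participants: int
    n_days: int = 60
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: {k: 0.25 for k in ARCHETYPES})
    schedule_days_per_week: int = 5
    prescribed_minutes: float = 45.0
    shift: float = 0.0
    seed: int = 0
    study_id: str = "study1"

    # jitter ranges at shift=1.0
    PROB_JITTER: float = 0.25
    DURATION_JITTER: float = 15.0
    RATE_LOG_JITTER: float = 0.6  # +/- on log scale for rate-type parameters

    def __post_init__(self):
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype_mix must sum to 1, got {total:.6g}")
        for name in self.archetype_mix:
            if name not in ARCHETYPES:
                raise ConfigurationError(f"unknown archetype {name!r}")
        if not 1 <= self.schedule_days_per_week <= 7:
            raise ConfigurationError("schedule_days_per_week must be in 1..7")


def _scheduled(day_index: int, days_per_week: int) -> bool:
    """Prescribed-schedule indicator: first `days_per_week` days of each week."""
    return (day_index - 1) % 7 < days_per_week


def _play_indicator(arch: ArchetypeSpec, n_days: int, days_per_week: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Binary played/not-played sequence for each of n_days.

    ``consistent_with_lapses`` follows a two-state run process: play runs
    alternate with geometric lapse runs of mean ``lapse_run_length`` days,
    with the lapse-onset hazard chosen so the long-run scheduled-day play
    fraction equals ``play_probability``.  ``erratic`` ignores the schedule
    entirely.  The other archetypes are Bernoulli on scheduled days only.
    """
    played = np.zeros(n_days, dtype=bool)
    if arch.name == "consistent_with_lapses" and 0.0 < arch.play_probability < 1.0:
        p, L = arch.play_probability, arch.lapse_run_length
        onset = (1.0 - p) / (p * L)  # hazard of starting a lapse after a played day
        onset = min(max(onset, 0.0), 1.0)
        in_lapse = rng.random() > p
        for i in range(n_days):
            day = i + 1
            if not _scheduled(day, days_per_week):
                continue
            if in_lapse:
                played[i] = False
                if rng.random() < 1.0 / L:  # geometric lapse length, mean L
                    in_lapse = False
            else:
                played[i] = True
                if rng.random() < onset:
                    in_lapse = True
        return played
    for i in range(n_days):
        day = i + 1
        if arch.name != "erratic" and not _scheduled(day, days_per_week):
            continue  # off-schedule days stay zero for schedule-following archetypes
        played[i] = rng.random() < arch.play_probability
    return played


def generate_participant(archetype: ArchetypeSpec | str, n_days: int,
                         schedule_days_per_week: int = 5, seed: int = 0,
                         participant_id: str = "p0",
                         study_id: str = "study1") -> ParticipantLog:
    """Generate one participant's daily log under a playing archetype.

    Durations on played days are Gaussian(mean_duration, duration_sd)
    truncated at zero (re-drawn rejection-free by clipping at a 1-minute
    floor so a "played" day is never a zero record); sessions are 1 on
    played days; tasks scale with duration plus Poisson noise; the maximum
    level reached is a monotone noisy ramp evaluated on played days.
    Identical ``(archetype, n_days, schedule, seed)`` yield identical logs.
    """
    if isinstance(archetype, str):
        try:
            archetype = ARCHETYPES[archetype]
        except KeyError:
            raise ConfigurationError(
                f"unknown archetype {archetype!r}; known: {sorted(ARCHETYPES)}"
            ) from None
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    played = _play_indicator(archetype, n_days, schedule_days_per_week, rng)

    days: list[DayRecord] = []
    level = 0.0
    for i in range(n_days):
        if played[i]:
            duration = archetype.mean_duration + archetype.duration_sd * rng.standard_normal()
            duration = float(max(duration, 1.0))
            sessions = 1 + int(rng.random() < archetype.two_session_prob)
            tasks = int(1 + rng.poisson(archetype.tasks_per_minute * duration))
            level += max(archetype.level_growth_rate + 0.2 * rng.standard_normal(), 0.0)
            max_level = int(round(level))
        else:
            duration, sessions, tasks, max_level = 0.0, 0, 0, 0
        days.append(DayRecord(i + 1, round(duration, 2), sessions, max_level, tasks))
    return ParticipantLog(participant_id, study_id, days)


def _jittered(arch: ArchetypeSpec, spec: CohortSpec,
              rng: np.random.Generator) -> ArchetypeSpec:
    """Per-participant parameter jitter plus the per-study duration scale.

    The jitter models the fact that each participant's data come from
    their own distribution: additive jitter on play probability and mean
    duration, and multiplicative (log-uniform) jitter on the parameters
    that shape how the four observed variables relate to each other
    (duration variability, task-completion rate, session splitting, level
    progression).  The latter group is covariate shift: it changes the
    feature distribution while leaving the play/no-play temporal dynamics
    of the archetype intact.
    """
    scale = spec.prescribed_minutes / REFERENCE_PRESCRIPTION
    p = arch.play_probability
    mean = arch.mean_duration * scale
    sd = arch.duration_sd
    tpm = arch.tasks_per_minute
    growth = arch.level_growth_rate
    two_sess = arch.two_session_prob
    if spec.shift > 0:
        s = spec.shift
        p = float(np.clip(p + s * rng.uniform(-spec.PROB_JITTER,
                                              spec.PROB_JITTER), 0.0, 1.0))
        mean = float(max(mean + s * rng.uniform(-spec.DURATION_JITTER,
                                                spec.DURATION_JITTER), 0.0))
        sd = float(sd * np.exp(s * rng.uniform(-spec.RATE_LOG_JITTER,
                                               spec.RATE_LOG_JITTER)))
        tpm = float(tpm * np.exp(s * rng.uniform(-spec.RATE_LOG_JITTER,
                                                 spec.RATE_LOG_JITTER)))
        growth = float(growth * np.exp(s * rng.uniform(-spec.RATE_LOG_JITTER,
                                                       spec.RATE_LOG_JITTER)))
        two_sess = float(np.clip(two_sess + s * rng.uniform(-0.2, 0.2), 0.0, 1.0))
    return dataclasses.replace(arch, play_probability=p, mean_duration=mean,
                               duration_sd=sd, tasks_per_minute=tpm,
                               level_growth_rate=growth,
                               two_session_prob=two_sess)


def generate_cohort(spec: CohortSpec) -> list[ParticipantLog]:
    """Generate ``spec.n_participants`` logs; fully reproducible from ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    names = sorted(spec.archetype_mix)
    probs = np.array([spec.archetype_mix[n] for n in names])
    assigned = assign_rng.choice(names, size=spec.n_participants, p=probs)

    logs = []
    child_seeds = root.spawn(spec.n_participants + 1)[1:]
    for i, (name, ss) in enumerate(zip(assigned, child_seeds)):
        rng = np.random.default_rng(ss)
        arch = _jittered(ARCHETYPES[name], spec, rng)
        log = generate_participant(
            arch, spec.n_days, spec.schedule_days_per_week,
            seed=int(rng.integers(2**31)),
            participant_id=f"{spec.study_id}_p{i:03d}", study_id=spec.study_id)
        log.archetype = str(name)  # provenance for recovery tests
        logs.append(log)
    return logs


def make_benchmark_pair(n_participants: int = 20, n_days: int = 60,
                        shift: float = 1.0, seed: int = 0,
                        cross_study: bool = False
                        ) -> list[ParticipantLog] | tuple[list[ParticipantLog], list[ParticipantLog]]:
    """Cohorts for the transfer-benefit benchmark.

    Participants fall into cluster-coherent archetypes whose temporal
    dynamics (weekly schedule, lapse persistence) are transferable across
    participants, while ``shift`` jitters each participant's play
    probability and session length -- so pooling source data helps, but
    only after the per-participant distribution shift is addressed.
    With ``cross_study=True`` returns two cohorts differing in the study
    prescription (45 vs 60 minutes) as in a two-trial transfer setting.
    """
    mix = {"consistent": 0.3, "consistent_with_lapses": 0.45, "erratic": 0.25}
    spec = CohortSpec(n_participants=n_participants, n_days=n_days,
                      archetype_mix=mix, shift=shift, seed=seed,
                      study_id="study1")
    if not cross_study:
        return generate_cohort(spec)
    spec2 = dataclasses.replace(
        spec, seed=seed + 1, study_id="study2", prescribed_minutes=60.0)
    return generate_cohort(spec), generate_cohort(spec2)
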
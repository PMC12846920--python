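"""Three-phase ABC conditioning schedules.

The experiment has three cues whose roles across phases define three
contingency types: CS++ (threatening in acquisition and extinction), CS+-
(threatening in acquisition, safe in extinction) and CS-- (always safe).
Learning phases present each cue 24 times (72 trials), the test phase 16 times
(48 trials, never reinforced).  Reinforced cues carry the aversive US on
exactly half of their presentations.  Presentation order is pseudo-random with
at most three consecutive repetitions of the same cue, and cues are paired
with phase-specific context videos (4/4/8) in a balanced, role-independent way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "ROLES",
    "TrialTiming",
    "DesignConfig",
    "TrialSpec",
    "TrialSchedule",
    "Experiment",
    "valence_of",
    "generate_phase_schedule",
    "generate_experiment",
    "validate_schedule",
]

PHASES = ("acquisition", "extinction", "test")
ROLES = ("CS++", "CS+-", "CS--")
LEARNING_PHASES = ("acquisition", "extinction")


@dataclass(frozen=True)
class TrialTiming:
    """Within-trial event timing in seconds, relative to trial start."""

    fixation: float = 0.5
    video_alone: float = 2.0
    cue: float = 1.75
    us: float = 1.0
    iti: float = 1.5

    @property
    def video_onset(self) -> float:
        return self.fixation

    @property
    def cue_onset(self) -> float:
        return self.fixation + self.video_alone

    @property
    def us_onset(self) -> float:
        return self.cue_onset + self.cue

    @property
    def trial_length(self) -> float:
        return self.us_onset + self.us + self.iti


@dataclass(frozen=True)
class DesignConfig:
    n_cues: int = 3
    reps_per_cue_learning: int = 24
    reps_per_cue_test: int = 16
    reinforcement_rate: float = 0.5
    contexts_per_phase: dict = field(
        default_factory=lambda: {"acquisition": 4, "extinction": 4, "test": 8}
    )
    max_run_length: int = 3
    timing: TrialTiming = field(default_factory=TrialTiming)

    def __post_init__(self):
        n_us = self.reinforcement_rate * self.reps_per_cue_learning
        if abs(n_us - round(n_us)) > 1e-9:
            raise ValueError(
                "reinforcement_rate x reps_per_cue_learning must be an integer"
            )
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")

    def reps(self, phase: str) -> int:
        return self.reps_per_cue_test if phase == "test" else self.reps_per_cue_learning

    def n_trials(self, phase: str) -> int:
        return self.n_cues * self.reps(phase)


@dataclass(frozen=True)
class TrialSpec:
    phase: str
    index: int          # 1-based within phase
    cue_id: int
    role: str
    current_valence: str
    context_id: int
    us: bool
    onsets: dict        # event name -> time in s relative to trial start


@dataclass
class TrialSchedule:
    phase: str
    trials: list
    seed: int
    design: DesignConfig

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row = {
                "phase": t.phase,
                "index": t.index,
                "cue_id": t.cue_id,
                "role": t.role,
                "valence": t.current_valence,
                "context_id": t.context_id,
                "us": t.us,
            }
            row.update({f"onset_{k}": v for k, v in t.onsets.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_frame().to_dict(orient="records"), fh, indent=1)


@dataclass
class Experiment:
    acquisition: TrialSchedule
    extinction: TrialSchedule
    test: TrialSchedule
    counterbalance: dict  # cue_id -> role
    design: DesignConfig
    seed: int

    @property
    def phases(self) -> dict:
        return {
            "acquisition": self.acquisition,
            "extinction": self.extinction,
            "test": self.test,
        }

    def schedule(self, phase: str) -> TrialSchedule:
        return self.phases[phase]

    def total_us(self) -> int:
        return sum(t.us for s in self.phases.values() for t in s.trials)


def valence_of(role: str, phase: str) -> str:
    """Current pairing status of a cue role in a phase.

    CS++ is reinforced in both learning phases; CS+- only in acquisition;
    CS-- never.  During the (unreinforced) test the expected contingency is
    used: CS++ remains CS+, the others are CS-.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    if phase == "acquisition":
        return "CS+" if role in ("CS++", "CS+-") else "CS-"
    if phase == "extinction":
        return "CS+" if role == "CS++" else "CS-"
    if phase == "test":
        return "CS+" if role == "CS++" else "CS-"
    raise ValueError(f"unknown phase {phase!r}")


def _sequence_with_run_limit(cue_ids, reps, max_run, rng, max_retries=10_000):
    """Random cue order with per-cue counts and bounded same-cue runs.

    Rejection-samples random permutations; if the retry cap is exhausted,
    falls back to randomized backtracking (always terminates for max_run >= 1
    provided a valid arrangement exists).
    """
    base = np.repeat(cue_ids, reps)

    def max_run_of(seq):
        best = run = 1
        for a, b in zip(seq[:-1], seq[1:]):
            run = run + 1 if a == b else 1
            best = max(best, run)
        return best

    for _ in range(max_retries):
        seq = rng.permutation(base)
        if max_run_of(seq) <= max_run:
            return list(seq)

    # randomized backtracking
    counts = {c: reps for c in cue_ids}
    seq: list = []

    def feasible(counts, last, run):
        # a cue with k remaining needs at least k + (k-1)*... interleavings;
        # loose but sufficient check: max count <= (slots+max_run-1)//max_run share
        total = sum(counts.values())
        if total == 0:
            return True
        mx = max(counts.values())
        blocks = -(-mx // max_run)          # ceil
        others = total - mx
        return others >= blocks - 1

    def rec():
        if sum(counts.values()) == 0:
            return True
        last = seq[-1] if seq else None
        run = 0
        if last is not None:
            for s in reversed(seq):
                if s == last:
                    run += 1
                else:
                    break
        options = [c for c in cue_ids if counts[c] > 0 and not (c == last and run >= max_run)]
        rng.shuffle(options)
        for c in options:
            counts[c] -= 1
            seq.append(c)
            if feasible(counts, c, 1) and rec():
                return True
            seq.pop()
            counts[c] += 1
        return False

    if not rec():
        raise ValueError("cue-order constraints are unsatisfiable for this design")
    return seq


def _balanced_contexts(order, cue_ids, n_contexts, rng):
    """Context ids per trial, balanced per cue (each cue sees each context
    equally often, remainder spread by at most one)."""
    context_ids = np.arange(1, n_contexts + 1)
    out = np.zeros(len(order), int)
    for cue in cue_ids:
        idx = np.flatnonzero(np.asarray(order) == cue)
        reps = len(idx)
        base, extra = divmod(reps, n_contexts)
        pool = np.repeat(context_ids, base)
        if extra:
            pool = np.concatenate([pool, rng.choice(context_ids, extra, replace=False)])
        rng.shuffle(pool)
        out[idx] = pool
    return out


def generate_phase_schedule(
    phase: str,
    design: DesignConfig | None = None,
    counterbalance: dict | None = None,
    seed: int = 0,
    context_offset: int = 0,
) -> TrialSchedule:
    """One pseudo-randomized phase schedule.

    ``counterbalance`` is a bijection cue_id -> role; ``context_offset`` shifts
    context ids so that pools are disjoint across phases.
    """
    design = design or DesignConfig()
    cue_ids = list(range(1, design.n_cues + 1))
    if counterbalance is None:
        counterbalance = dict(zip(cue_ids, ROLES))
    if sorted(counterbalance) != cue_ids or sorted(counterbalance.values()) != sorted(ROLES):
        raise ValueError("counterbalance must be a bijection of cue ids onto roles")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")

    rng = np.random.default_rng(seed)
    reps = design.reps(phase)
    order = _sequence_with_run_limit(cue_ids, reps, design.max_run_length, rng)
    contexts = _balanced_contexts(order, cue_ids, design.contexts_per_phase[phase], rng)

    # US positions: for each reinforced cue, exactly rate*reps of its ordinal slots
    us_flags = np.zeros(len(order), bool)
    if phase in LEARNING_PHASES:
        n_us = round(design.reinforcement_rate * reps)
        for cue in cue_ids:
            if valence_of(counterbalance[cue], phase) == "CS+":
                idx = np.flatnonzero(np.asarray(order) == cue)
                us_flags[rng.choice(idx, size=n_us, replace=False)] = True

    tm = design.timing
    trials = []
    for i, cue in enumerate(order):
        role = counterbalance[cue]
        onsets = {
            "fixation": 0.0,
            "video": tm.video_onset,
            "cue": tm.cue_onset,
            "end": tm.us_onset + tm.us,
        }
        if us_flags[i]:
            onsets["us"] = tm.us_onset
        trials.append(
            TrialSpec(
                phase=phase,
                index=i + 1,
                cue_id=int(cue),
                role=role,
                current_valence=valence_of(role, phase),
                context_id=int(contexts[i] + context_offset),
                us=bool(us_flags[i]),
                onsets=onsets,
            )
        )
    return TrialSchedule(phase=phase, trials=trials, seed=seed, design=design)


def generate_experiment(design: DesignConfig | None = None, seed: int = 0) -> Experiment:
    """Full three-phase experiment with a random cue-role counterbalance and
    disjoint per-phase context pools."""
    design = design or DesignConfig()
    rng = np.random.default_rng(seed)
    cue_ids = list(range(1, design.n_cues + 1))
    roles = list(ROLES)
    rng.shuffle(roles)
    counterbalance = dict(zip(cue_ids, roles))

    child_seeds = rng.integers(0, 2**31 - 1, size=3)
    offset = 0
    schedules = {}
    for phase, s in zip(PHASES, child_seeds):
        schedules[phase] = generate_phase_schedule(
            phase, design, counterbalance, seed=int(s), context_offset=offset
        )
        offset += design.contexts_per_phase[phase]
    return Experiment(
        acquisition=schedules["acquisition"],
        extinction=schedules["extinction"],
        test=schedules["test"],
        counterbalance=counterbalance,
        design=design,
        seed=seed,
    )


def validate_schedule(schedule: TrialSchedule) -> list[str]:
    """Constraint report; empty list iff the schedule satisfies all invariants."""
    design = schedule.design
    trials = schedule.trials
    phase = schedule.phase
    violations = []

    reps = design.reps(phase)
    counts = {}
    for t in trials:
        counts[t.cue_id] = counts.get(t.cue_id, 0) + 1
    for cue, n in counts.items():
        if n != reps:
            violations.append(f"cue {cue}: {n} trials, expected {reps}")
    if len(trials) != design.n_trials(phase):
        violations.append(f"{len(trials)} trials, expected {design.n_trials(phase)}")

    run, last = 0, None
    for t in trials:
        run = run + 1 if t.cue_id == last else 1
        last = t.cue_id
        if run > design.max_run_length:
            violations.append(f"run length > {design.max_run_length} at trial {t.index}")
            break

    if phase == "test":
        if any(t.us for t in trials):
            violations.append("US in test phase")
    else:
        n_us_expected = round(design.reinforcement_rate * reps)
        for cue in counts:
            cue_trials = [t for t in trials if t.cue_id == cue]
            n_us = sum(t.us for t in cue_trials)
            if cue_trials[0].current_valence == "CS+":
                if n_us != n_us_expected:
                    violations.append(
                        f"cue {cue}: {n_us} US deliveries, expected {n_us_expected}"
                    )
            elif n_us:
                violations.append(f"cue {cue} is CS- but has US deliveries")

    # context balance: per cue, each context count within +-1 of any other
    ctx_ids = sorted({t.context_id for t in trials})
    if len(ctx_ids) != design.contexts_per_phase[phase]:
        violations.append(
            f"{len(ctx_ids)} contexts, expected {design.contexts_per_phase[phase]}"
        )
    for cue in counts:
        ctx_counts = [sum(1 for t in trials if t.cue_id == cue and t.context_id == c)
                      for c in ctx_ids]
        if max(ctx_counts) - min(ctx_counts) > 1:
            violations.append(f"cue {cue}: context counts unbalanced {ctx_counts}")

    return violations
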
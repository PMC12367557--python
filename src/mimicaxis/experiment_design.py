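"""Seeded session layouts and trial sequences for the four experiments.

Feeding-station sessions use a 7 x 7 array of lidded Petri dishes; a layout
places each session's stimulus multiset uniformly at random over the grid
(given an integer seed) and records, per dish, the stimulus code, whether
the dish is rewarded (models V100/A100 are never rewarded; fly and mimic
stimuli always are) and whether it sits on the array perimeter (birds
preferentially open perimeter dishes, so the flag is carried into the
statistical analysis).

The generators reproduce the published stimulus counts exactly:

* discrimination ability - training 15 M100 / 15 V100 / 19 empty; testing
  17 V100, 10 M100 and 2 each of the 11 novel phenotypes (49 dishes).
* multiple models - training 25 M100 plus 24 wasps (all V100 in the 1M
  treatment; 12 V100 + 12 A100 in 2M); testing 20 wasps (20 V100 or
  10 + 10), 10 M100, and 19 mimics spread over the seven intermediate and
  extrapolated types by largest-remainder rounding (five types get 3, two
  get 2; which two is a seeded draw).
* generalization - training 12 M100 / 12 V100 / 25 empty; testing swaps
  half of each species' printed stimuli for real specimens.
* chick trait-salience trials - 16 presentations: 6 rewarded fly (all
  traits poor), 6 unrewarded wasp (all perfect) and 4 rewarded probes
  drawn without replacement from the 31 trait combinations, in seeded
  random order.
* invertebrate trials - nine presentations alternating five axis probes
  (odd positions, random order) with four reinforcement presentations
  (two M100 and two V100, random order).

Every layout and sequence is a pure function of (experiment, phase,
treatment, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axis_engine import enumerate_trait_combinations

GRID_ROWS = 7
GRID_COLS = 7

MODEL_CODES = frozenset({"V100", "A100"})
EMPTY = "empty"

DISCRIMINATION_TEST_PHENOTYPES = (
    "M75/V25", "M50/V50", "M25/V75",
    "S100", "S75/V25", "S50/V50", "S25/V75",
    "C100", "C75/V25", "C50/V50", "C25/V75",
)
MULTIMODEL_MIMICS = (
    "A150/V-50", "A125/V-25", "A75/V25", "A50/V50",
    "A25/V75", "A-25/V125", "A-50/V150",
)
INVERTEBRATE_AXIS = ("M100", "M75/V25", "M50/V50", "M25/V75", "V100")


class DesignError(ValueError):
    """Raised for unknown phases or treatments."""


@dataclass
class Dish:
    position: tuple[int, int]
    stimulus: str
    rewarded: bool
    edge: bool
    real_specimen: bool = False


@dataclass
class SessionLayout:
    grid_rows: int
    grid_cols: int
    dishes: list[Dish]
    seed: int
    experiment: str
    phase: str
    treatment: str | None = None

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.dishes:
            out[d.stimulus] = out.get(d.stimulus, 0) + 1
        return out

    def stimulus_dishes(self) -> list[Dish]:
        return [d for d in self.dishes if d.stimulus != EMPTY]


@dataclass
class Presentation:
    stimulus: str
    rewarded: bool
    probe: bool


@dataclass
class TrialSequence:
    presentations: list[Presentation]
    seed: int
    phase: str = "testing"


def _is_rewarded(code: str) -> bool:
    return code not in MODEL_CODES and code != EMPTY


def _place(
    stimuli: list[tuple[str, bool]],
    seed: int,
    experiment: str,
    phase: str,
    treatment: str | None = None,
    rows: int = GRID_ROWS,
    cols: int = GRID_COLS,
) -> SessionLayout:
    """Scatter a stimulus multiset uniformly over the grid; rest empty."""
    n_cells = rows * cols
    if len(stimuli) > n_cells:
        raise DesignError(f"{len(stimuli)} stimuli do not fit a {rows}x{cols} grid")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    cells: list[tuple[str, bool]] = [(EMPTY, False)] * n_cells
    for slot, stim in zip(order, stimuli):
        cells[slot] = stim
    dishes = []
    for idx, (code, real) in enumerate(cells):
        r, c = divmod(idx, cols)
        dishes.append(
            Dish(
                position=(r, c),
                stimulus=code,
                rewarded=_is_rewarded(code),
                edge=r in (0, rows - 1) or c in (0, cols - 1),
                real_specimen=real,
            )
        )
    return SessionLayout(rows, cols, dishes, seed, experiment, phase, treatment)


def layout_discrimination(phase: str, seed: int) -> SessionLayout:
    """Discrimination-ability session layout (training or testing)."""
    if phase == "training":
        stimuli = [("M100", False)] * 15 + [("V100", False)] * 15
    elif phase == "testing":
        stimuli = [("V100", False)] * 17 + [("M100", False)] * 10
        for code in DISCRIMINATION_TEST_PHENOTYPES:
            stimuli += [(code, False)] * 2
    else:
        raise DesignError(f"unknown phase {phase!r}")
    return _place(stimuli, seed, "discrimination", phase)


def layout_multiple_models(phase: str, treatment: str, seed: int) -> SessionLayout:
    """Multiple-models session layout for the 1M or 2M treatment."""
    if treatment not in ("1M", "2M"):
        raise DesignError(f"unknown treatment {treatment!r}")
    rng = np.random.default_rng(seed)
    if phase == "training":
        wasps = ["V100"] * 24 if treatment == "1M" else ["V100"] * 12 + ["A100"] * 12
        stimuli = [("M100", False)] * 25 + [(w, False) for w in wasps]
    elif phase == "testing":
        wasps = ["V100"] * 20 if treatment == "1M" else ["V100"] * 10 + ["A100"] * 10
        # 19 mimics over 7 types, largest remainder: floor gives 2 each
        # (14), the 5 leftover go to a seeded choice of types
        counts = {code: 2 for code in MULTIMODEL_MIMICS}
        bonus = rng.choice(len(MULTIMODEL_MIMICS), size=5, replace=False)
        for k in bonus:
            counts[MULTIMODEL_MIMICS[k]] += 1
        mimics = [code for code in MULTIMODEL_MIMICS for _ in range(counts[code])]
        stimuli = (
            [(w, False) for w in wasps]
            + [("M100", False)] * 10
            + [(m, False) for m in mimics]
        )
    else:
        raise DesignError(f"unknown phase {phase!r}")
    # a fresh generator keeps placement independent of the bonus draw
    return _place(stimuli, int(rng.integers(2**31)), "multiple_models", phase, treatment)


def layout_generalization(phase: str, seed: int) -> SessionLayout:
    """Generalization-test layout; testing swaps half the prints for specimens."""
    if phase == "training":
        stimuli = [("M100", False)] * 12 + [("V100", False)] * 12
    elif phase == "testing":
        stimuli = []
        for code in ("M100", "V100"):
            stimuli += [(code, False)] * 6 + [(code, True)] * 6
    else:
        raise DesignError(f"unknown phase {phase!r}")
    return _place(stimuli, seed, "generalization", phase)


def format_trait_code(levels: dict[str, str]) -> str:
    """Compact label for a trait-combination stimulus, e.g. S0/P50/C100/Z100."""
    pct = {"poor": 0, "good": 50, "perfect": 100}
    letters = {"shape": "S", "pattern": "P", "colour": "C", "size": "Z"}
    return "/".join(
        f"{letters[t]}{pct[levels[t]]}" for t in ("shape", "pattern", "colour", "size")
    )


ALL_POOR = {t: "poor" for t in ("shape", "colour", "pattern", "size")}
ALL_PERFECT = {t: "perfect" for t in ("shape", "colour", "pattern", "size")}


def chick_trial_sequence(
    phase: str, probe_pool: list[dict[str, str]] | None = None, seed: int = 0
) -> TrialSequence:
    """One chick trial: 16 presentations.

    Training: 16 binary fly-versus-wasp choices.  Testing: 6 rewarded fly,
    6 unrewarded wasp and 4 rewarded probes drawn without replacement from
    the trait-combination pool, in seeded random order.  Probes are always
    rewarded, including the all-perfect combination (a perfect Batesian
    mimic of the unrewarded wasp).
    """
    rng = np.random.default_rng(seed)
    if phase == "training":
        presentations = [
            Presentation("choice:" + format_trait_code(ALL_POOR) + "|" +
                         format_trait_code(ALL_PERFECT), True, False)
            for _ in range(16)
        ]
        return TrialSequence(presentations, seed, phase)
    if phase != "testing":
        raise DesignError(f"unknown phase {phase!r}")
    pool = probe_pool if probe_pool is not None else enumerate_trait_combinations()
    if len(pool) < 4:
        raise DesignError("probe pool must contain at least 4 combinations")
    picks = rng.choice(len(pool), size=4, replace=False)
    presentations = (
        [Presentation(format_trait_code(ALL_POOR), True, False)] * 6
        + [Presentation(format_trait_code(ALL_PERFECT), False, False)] * 6
        + [Presentation(format_trait_code(pool[k]), True, True) for k in picks]
    )
    order = rng.permutation(16)
    return TrialSequence([presentations[k] for k in order], seed, phase)


def invertebrate_sequence(seed: int) -> TrialSequence:
    """Nine-presentation invertebrate test: probes alternate with reinforcement.

    Positions 1, 3, 5, 7, 9 (1-based) are the five axis points in seeded
    random order; positions 2, 4, 6, 8 are reinforcement presentations
    (two M100 and two V100, seeded random order).
    """
    rng = np.random.default_rng(seed)
    probes = [INVERTEBRATE_AXIS[k] for k in rng.permutation(5)]
    reinforcement = ["M100", "M100", "V100", "V100"]
    reinforcement = [reinforcement[k] for k in rng.permutation(4)]
    presentations = []
    for k in range(9):
        if k % 2 == 0:
            code = probes[k // 2]
            presentations.append(Presentation(code, _is_rewarded(code), True))
        else:
            code = reinforcement[k // 2]
            presentations.append(Presentation(code, _is_rewarded(code), False))
    return TrialSequence(presentations, seed)
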
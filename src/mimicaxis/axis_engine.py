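"""Axis orchestration: stimulus codes, trait combinations and axis geometry.

A mimicry axis is the one-parameter family of phenotypes between two
scanned endpoints.  A stimulus code such as ``M25/V75`` names the two
endpoints by their genus initial and gives each endpoint's percentage
weight; the weights always sum to 100 and may leave [0, 100] for
extrapolated stimuli (for example ``A150/V-50``).  The axis position ``p``
of a stimulus is the weight of the second-named endpoint, so the per-trait
interpolation weight is ``w = p / 100``.

For the trait-salience design, each of shape, colour, pattern and size is
set independently to poor (0, fly-like), good (0.5, halfway) or perfect
(1, wasp-like), subject to the constraint that poor and good levels never
co-occur within one stimulus; that yields 2^4 + 2^4 - 1 = 31 distinct
combinations (the all-perfect map being the shared element).

Axis geometry helpers measure the distance from a stimulus to its nearest
model phenotype in percentage-point units and classify stimuli as
intermediate (strictly between models at 0 and 100) or extrapolated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .mesh_io import ColouredMesh, quantize_colour
from .pattern_morph import (
    PatternField,
    interpolate_pattern,
    interpolate_segment_colours,
)
from .shape_morph import CorrespondedPair, interpolate_shape
from .stimulus_assembly import (
    AppendageSpec,
    BaseSpec,
    BodyMetrics,
    assemble_stimulus,
    interpolate_scalar,
    make_antenna,
    make_leg,
)

TRAITS = ("shape", "colour", "pattern", "size")
LEVEL_WEIGHTS = {"poor": 0.0, "good": 0.5, "perfect": 1.0}
_LEVEL_ORDER = {"poor": 0, "good": 1, "perfect": 2}


class CodeError(ValueError):
    """Raised for malformed or inconsistent stimulus codes."""


@dataclass(frozen=True)
class StimulusCode:
    """Two endpoint letters plus percentage weights summing to 100."""

    letters: tuple[str, str]
    weights: tuple[float, float]

    def __post_init__(self) -> None:
        if self.letters[0] == self.letters[1]:
            raise CodeError("endpoint letters must be distinct")
        if abs(self.weights[0] + self.weights[1] - 100.0) > 1e-9:
            raise CodeError(
                f"weights {self.weights} must sum to 100"
            )

    @property
    def position(self) -> float:
        """Axis position p = weight of the second-named endpoint."""
        return self.weights[1]


_CODE_RE = re.compile(r"^([A-Za-z])(-?\d+)/([A-Za-z])(-?\d+)$")


def parse_code(text: str) -> StimulusCode:
    """Parse ``M25/V75``-style codes; both ASCII '-' and U+2212 accepted."""
    cleaned = text.strip().replace("−", "-")
    match = _CODE_RE.match(cleaned)
    if match is None:
        raise CodeError(f"malformed stimulus code {text!r}")
    l1, w1, l2, w2 = match.groups()
    return StimulusCode((l1, l2), (float(w1), float(w2)))


def format_code(code: StimulusCode) -> str:
    return (
        f"{code.letters[0]}{code.weights[0]:g}/"
        f"{code.letters[1]}{code.weights[1]:g}"
    )


@dataclass
class StimulusSpec:
    """One point on an axis, with optional per-trait weight overrides."""

    code: StimulusCode
    trait_weights: dict[str, float] = field(default_factory=dict)
    trait_levels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        default = self.code.position / 100.0
        if self.trait_levels is not None:
            for trait, level in self.trait_levels.items():
                if level not in LEVEL_WEIGHTS:
                    raise CodeError(f"unknown trait level {level!r}")
                self.trait_weights[trait] = LEVEL_WEIGHTS[level]
        for trait in TRAITS:
            self.trait_weights.setdefault(trait, default)
        unknown = set(self.trait_weights) - set(TRAITS)
        if unknown:
            raise CodeError(f"unknown traits {sorted(unknown)}")


@dataclass
class AxisSpec:
    """Named axis: endpoint letters, stimulus positions, model positions."""

    letter_a: str
    letter_b: str
    positions: list[float]
    model_positions: frozenset = frozenset({100.0})

    def code_at(self, p: float) -> StimulusCode:
        return StimulusCode((self.letter_a, self.letter_b), (100.0 - p, p))


def enumerate_trait_combinations() -> list[dict[str, str]]:
    """All trait-level maps where poor and good never co-occur.

    Combinations of poor with perfect, or good with perfect, over the four
    traits: 2^4 + 2^4 - 1 = 31 maps, sorted lexicographically over
    (shape, pattern, colour, size) with poor < good < perfect.
    """
    combos = []
    seen = set()
    for allowed in (("poor", "perfect"), ("good", "perfect")):
        stack = [{}]
        for trait in TRAITS:
            stack = [dict(m, **{trait: lv}) for m in stack for lv in allowed]
        for m in stack:
            key = tuple(m[t] for t in TRAITS)
            if key not in seen:
                seen.add(key)
                combos.append(m)
    sort_traits = ("shape", "pattern", "colour", "size")
    combos.sort(key=lambda m: tuple(_LEVEL_ORDER[m[t]] for t in sort_traits))
    return combos


def distance_to_nearest_model(p: float, model_positions) -> float:
    """Axis distance (percentage points) to the nearest model phenotype."""
    models = list(model_positions)
    if not models:
        raise CodeError("model position set is empty")
    return float(min(abs(p - m) for m in models))


def is_intermediate(p: float) -> bool:
    """True iff the stimulus lies strictly between models at 0 and 100."""
    return 0.0 < p < 100.0


def generate_axis(
    axis: AxisSpec,
    pair: CorrespondedPair,
    field_a: PatternField,
    field_b: PatternField,
    metrics: BodyMetrics,
    appendages: AppendageSpec | None = None,
    overrides: dict[float, StimulusSpec] | None = None,
    with_base: bool = False,
    base: BaseSpec | None = None,
) -> list[ColouredMesh]:
    """Build one assembled stimulus per axis position.

    For each position ``p`` the four traits are interpolated at their own
    weights (default ``p/100`` each, overridable per position through
    ``overrides``): shape through the vertex correspondence, pattern
    through the signed distance maps, colour through the segment medians,
    and size through the body-length scaling of the final assembly.
    Changing one trait's weight leaves the other components untouched.
    """
    appendages = appendages or AppendageSpec()
    overrides = overrides or {}
    stimuli = []
    for p in axis.positions:
        spec = overrides.get(p) or StimulusSpec(code=axis.code_at(p))
        tw = spec.trait_weights
        try:
            verts = interpolate_shape(pair, tw["shape"], method="linear")
            labels = interpolate_pattern(field_a, field_b, tw["pattern"])
            seg_cols = interpolate_segment_colours(field_a, field_b, tw["colour"])
            colours = quantize_colour(seg_cols[labels - 1])
            body = ColouredMesh(
                verts, pair.shared_faces.copy(), colours, name=format_code(spec.code)
            )
            antenna_len = interpolate_scalar(
                appendages.antenna_length_A, appendages.antenna_length_B, tw["shape"]
            )
            parts = [
                make_leg(appendages, seg_cols) for _ in range(6)
            ] + [make_antenna(appendages, antenna_len) for _ in range(2)]
            stimulus = assemble_stimulus(
                body, parts, metrics, tw["size"], with_base=with_base, base=base
            )
        except Exception as exc:
            raise type(exc)(f"axis position {p}: {exc}") from exc
        stimulus.name = format_code(spec.code)
        stimuli.append(stimulus)
    return stimuli
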
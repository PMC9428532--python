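"""Study-design bookkeeping: conditions, vocabulary, sentence lists, timing.

The design crosses three ways of applying reverberation (to the speech,
to the noise, or to both) with per-application RT lists and two noise
modulations.  The lowest-RT cells are physically identical across
applications (with near-anechoic reverberation everywhere, "speech
only", "noise only" and "both" coincide), so they are counted once per
modulation; with the default five-point SNR grid this yields 14 unique
condition combinations and 70 condition-by-SNR cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "APPLICATIONS",
    "MODULATIONS",
    "DEFAULT_SNR_GRID",
    "MATRIX_VOCABULARY",
    "Design",
    "Combo",
    "Cell",
    "MatrixVocabulary",
    "default_design",
    "enumerate_combos",
    "enumerate_conditions",
    "build_sentence_list",
    "estimate_session_time",
]

APPLICATIONS: tuple[str, ...] = ("speech_only", "noise_only", "both")
MODULATIONS: tuple[str, ...] = ("stationary", "modulated")
DEFAULT_SNR_GRID: tuple[float, ...] = (-16.0, -12.0, -8.0, -4.0, 0.0)

#: Closed-set matrix vocabulary: 5 categories x 10 words.
MATRIX_VOCABULARY: dict[str, tuple[str, ...]] = {
    "name": ("Agnès", "Charlotte", "Emile", "Etienne", "Eugène",
             "Félix", "Jean-Luc", "Julien", "Michel", "Sophie"),
    "verb": ("achète", "attrape", "demande", "déplace", "dessine",
             "propose", "ramasse", "ramène", "reprend", "voudrait"),
    "numeral": ("deux", "trois", "cinq", "six", "sept",
                "huit", "neuf", "onze", "douze", "quinze"),
    "object": ("anneaux", "ballons", "classeurs", "crayons", "jetons",
               "livres", "pions", "piquets", "rubans", "vélos"),
    "colour": ("blancs", "bleus", "bruns", "gris", "jaunes",
               "mauves", "noirs", "roses", "rouges", "verts"),
}

CATEGORY_ORDER: tuple[str, ...] = ("name", "verb", "numeral", "object",
                                   "colour")


class Combo(NamedTuple):
    """A unique reverberation-condition combination."""

    application: str
    rt: float
    modulation: str


class Cell(NamedTuple):
    """A condition x SNR measurement cell."""

    application: str
    rt: float
    modulation: str
    snr: float

    @property
    def combo(self) -> Combo:
        return Combo(self.application, self.rt, self.modulation)


@dataclass(frozen=True)
class MatrixVocabulary:
    """The 5 x 10 closed-set vocabulary."""

    words: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(MATRIX_VOCABULARY))

    def __post_init__(self):
        if set(self.words) != set(CATEGORY_ORDER):
            raise ValueError(
                f"expected categories {CATEGORY_ORDER}, got "
                f"{tuple(self.words)}")
        all_words = [w for ws in self.words.values() for w in ws]
        if len(all_words) != 50 or len(set(all_words)) != 50:
            raise ValueError("vocabulary must hold 50 distinct words "
                             "(10 per category)")

    @property
    def n_words(self) -> int:
        return sum(len(ws) for ws in self.words.values())

    @property
    def chance_level(self) -> float:
        """Per-word probability correct under uniform guessing."""
        return 1.0 / len(self.words["name"])


@dataclass(frozen=True)
class Design:
    """The tested-conditions design."""

    applications: tuple[str, ...] = APPLICATIONS
    rts_by_application: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "speech_only": (0.15, 0.5, 0.8, 1.1, 1.5),
            "noise_only": (0.15, 1.5),
            "both": (0.15, 1.5),
        })
    modulations: tuple[str, ...] = MODULATIONS
    snr_grid: tuple[float, ...] = DEFAULT_SNR_GRID
    sentences_per_cell: int = 10
    reference_rt: float = 0.15

    def __post_init__(self):
        for app in self.applications:
            if app not in self.rts_by_application:
                raise ValueError(f"no RT list for application {app!r}")
            if self.reference_rt not in self.rts_by_application[app]:
                raise ValueError(
                    f"reference RT {self.reference_rt} missing from "
                    f"{app!r} RT list")


def default_design() -> Design:
    return Design()


def enumerate_combos(design: Design) -> list[Combo]:
    """Unique (application, rt, modulation) combos, reference-RT cells
    collapsed across applications (tagged ``application="reference"``)."""
    if not design.applications or not design.modulations:
        raise ValueError("empty design")
    combos: list[Combo] = []
    seen = set()
    for mod in design.modulations:
        key = ("reference", design.reference_rt, mod)
        seen.add(key)
        combos.append(Combo(*key))
    for app in design.applications:
        for rt in design.rts_by_application[app]:
            if rt == design.reference_rt:
                continue
            for mod in design.modulations:
                key = (app, rt, mod)
                if key not in seen:
                    seen.add(key)
                    combos.append(Combo(*key))
    return combos


def enumerate_conditions(design: Design) -> list[Cell]:
    """All unique condition x SNR cells of the design."""
    if not design.snr_grid:
        raise ValueError("empty SNR grid")
    return [
        Cell(c.application, c.rt, c.modulation, snr)
        for c in enumerate_combos(design)
        for snr in design.snr_grid
    ]


def build_sentence_list(vocab: MatrixVocabulary,
                        rng_seed: int) -> list[tuple[str, ...]]:
    """Ten 5-word sentences using each of the 50 words exactly once.

    Words appear in category order (name-verb-numeral-object-colour);
    each category's ten words are independently permuted across the ten
    sentences.
    """
    rng = np.random.default_rng(rng_seed)
    perms = {
        cat: rng.permutation(list(vocab.words[cat]))
        for cat in CATEGORY_ORDER
    }
    return [
        tuple(str(perms[cat][i]) for cat in CATEGORY_ORDER)
        for i in range(10)
    ]


def estimate_session_time(design: Design,
                          seconds_per_sentence: float = 12.0) -> float:
    """Total measurement time in minutes."""
    if seconds_per_sentence <= 0:
        raise ValueError("seconds_per_sentence must be positive")
    n_cells = len(enumerate_conditions(design)) if design.snr_grid else 0
    return n_cells * design.sentences_per_cell * seconds_per_sentence / 60.0
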
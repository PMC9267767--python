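"""Core domain types shared across the pipeline.

The unit of observation is a single stimulus presentation to a single
subject (:class:`TrialResponse`). A noun is presented auditorily and the
subject responds with an associated verb; responses are coded into a
four-way taxonomy: ``related_verb`` (correct), ``not_a_verb``,
``unrelated_verb``, or ``missing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Diagnostic groups: healthy controls plus the three PPA variants
#: (logopenic, semantic, non-fluent/agrammatic).
GROUPS: tuple[str, ...] = ("HC", "lvPPA", "svPPA", "nfvPPA")

#: Patient groups only (classification never sees HC rows).
PATIENT_GROUPS: tuple[str, ...] = ("lvPPA", "svPPA", "nfvPPA")

#: The four-way response taxonomy. Only ``related_verb`` counts as correct.
CODES: tuple[str, ...] = ("related_verb", "not_a_verb", "unrelated_verb", "missing")


@dataclass
class StimulusNorms:
    """Psycholinguistic norms for one noun stimulus.

    All fields are optional: real norm tables routinely have gaps, and only
    the predictors requested by an analysis need to be present.
    """

    n_letters: int | None = None
    n_syllables: int | None = None
    n_phonemes: int | None = None
    freq_log: float | None = None
    semantic_neighborhood: float | None = None
    concreteness: float | None = None
    familiarity: float | None = None
    imageability: float | None = None
    age_of_acquisition: float | None = None


#: Column order used by the norms CSV reader/writer.
NORM_FIELDS: tuple[str, ...] = (
    "n_letters",
    "n_syllables",
    "n_phonemes",
    "freq_log",
    "semantic_neighborhood",
    "concreteness",
    "familiarity",
    "imageability",
    "age_of_acquisition",
)

#: Integer-valued norm fields (counts).
COUNT_FIELDS: tuple[str, ...] = ("n_letters", "n_syllables", "n_phonemes")


@dataclass
class Stimulus:
    """One noun stimulus, optionally with its psycholinguistic norms."""

    noun: str
    norms: StimulusNorms | None = None

    def __post_init__(self) -> None:
        if not self.noun:
            raise ValueError("stimulus noun must be non-empty")


@dataclass
class TrialResponse:
    """One presentation of one noun to one subject.

    ``response_code`` is ``None`` until the trial is coded (either by a
    human rater upstream or by the rule-based auto-coder).
    ``response_lemma`` holds the normalized head token of the response:
    the head verb for verb responses ("take out" -> "take"), or the noun
    form for not-a-verb responses.
    """

    subject_id: str
    group: str
    noun: str
    presentation: int
    response_raw: str = ""
    response_code: str | None = None
    response_lemma: str | None = None
    rt_s: float | None = None

    def __post_init__(self) -> None:
        if self.presentation not in (1, 2):
            raise ValueError(f"presentation must be 1 or 2, got {self.presentation!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.response_code is not None and self.response_code not in CODES:
            raise ValueError(f"unknown response code {self.response_code!r}")

    @property
    def coded(self) -> bool:
        return self.response_code is not None

    @property
    def correct(self) -> bool:
        return self.response_code == "related_verb"


@dataclass
class SubjectRecord:
    """Per-subject metadata: diagnostic group and neuropsychological scores.

    ``neuropsych`` maps measure name to score. The by-subject correlation
    analysis expects (when requested) the keys ``single_word_comprehension``,
    ``phonemic_fluency``, ``semantic_fluency`` and ``trails_total_time``.
    """

    subject_id: str
    group: str
    neuropsych: dict[str, float] = field(default_factory=dict)


@dataclass
class EmbeddingTable:
    """Word-embedding lookup: word -> real vector, one shared dimension."""

    dimension: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("embedding dimension must be positive")
        for word, vec in self.vectors.items():
            if len(vec) != self.dimension:
                raise ValueError(
                    f"vector for {word!r} has length {len(vec)}, expected {self.dimension}"
                )

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[word]
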
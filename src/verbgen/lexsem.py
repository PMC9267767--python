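"""Lexico-semantic response features.

Three fine-grained features distinguish the PPA variants beyond raw error
rates:

* **unique-verb dispersion** — per noun and cohort, how many distinct
  related verbs were produced (semantic-variant patients scatter more);
* **light-verb percentage** — share of a subject's related responses whose
  head verb is a semantically impoverished "light" verb (do, take, get...);
* **not-a-verb decomposition** — among a subject's not-a-verb responses,
  how many are plain repetitions of the stimulus noun and how many are
  semantically related nouns, judged by embedding cosine similarity above
  a threshold (default 0.3, calibratable to the pooled median).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import StateError
from .lemmas import LIGHT_VERBS, lemmatize
from .types import EmbeddingTable, TrialResponse

logger = logging.getLogger(__name__)

DEFAULT_SIMILARITY_THRESHOLD = 0.3


@dataclass
class NotVerbDecomposition:
    """Breakdown of one subject's not-a-verb responses.

    ``n_repetitions + n_semantically_related + n_unrelated + n_uncovered``
    equals the number of not-a-verb trials examined; ``n_uncovered`` counts
    responses (or stimuli) missing from the embedding table.
    """

    n_repetitions: int
    n_semantically_related: int
    n_unrelated: int
    n_uncovered: int
    threshold_used: float

    @property
    def total(self) -> int:
        return (self.n_repetitions + self.n_semantically_related
                + self.n_unrelated + self.n_uncovered)


@dataclass
class LexsemProfile:
    """Per-subject lexico-semantic feature vector."""

    subject_id: str
    group: str
    pct_light_verbs: float | None
    n_repetitions: int
    n_semantically_related: int
    n_uncovered: int
    threshold_used: float


def unique_verb_count(trials: Iterable[TrialResponse], noun: str) -> int:
    """Distinct related-verb lemmas a cohort produced for ``noun``."""
    lemmas = {
        t.response_lemma or lemmatize(t.response_raw.split()[0])
        for t in trials
        if t.noun == noun and t.response_code == "related_verb"
    }
    return len(lemmas)


def unique_verb_dispersion(trials: Sequence[TrialResponse], by: str = "noun"
                           ) -> dict[str, int]:
    """Unique related-verb counts, reduced per noun (default) or per subject."""
    if by not in ("noun", "subject"):
        raise ValueError(f"unknown reduction {by!r}")
    groups: dict[str, set[str]] = {}
    for t in trials:
        if t.response_code != "related_verb":
            continue
        key = t.noun if by == "noun" else t.subject_id
        lemma = t.response_lemma or lemmatize(t.response_raw.split()[0])
        groups.setdefault(key, set()).add(lemma)
    return {key: len(lemmas) for key, lemmas in groups.items()}


def light_verb_pct(trials: Iterable[TrialResponse],
                   light_verbs: Sequence[str] = LIGHT_VERBS) -> float | None:
    """Percentage of related-verb responses headed by a light verb.

    Phrasal responses match on their head ("take out" -> take). Returns
    ``None`` when the subject produced no related responses; such subjects
    are dropped from group statistics rather than scored 0.
    """
    light = set(light_verbs)
    n_related = 0
    n_light = 0
    for t in trials:
        if t.response_code != "related_verb":
            continue
        n_related += 1
        lemma = t.response_lemma or lemmatize(t.response_raw.split()[0])
        if lemma in light:
            n_light += 1
    if n_related == 0:
        return None
    return 100.0 * n_light / n_related


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def not_verb_decomposition(trials: Iterable[TrialResponse], emb: EmbeddingTable,
                           threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                           ) -> NotVerbDecomposition:
    """Classify not-a-verb responses as repetitions / related / unrelated.

    A repetition is a response whose lemma equals the stimulus noun (its
    similarity would trivially be 1, so repetitions are excluded from the
    semantically-related count). Non-repetitions present in the embedding
    table count as semantically related iff cosine similarity is *strictly*
    above ``threshold``. Responses (or nouns) absent from the table are
    logged and tallied in ``n_uncovered``.
    """
    n_rep = n_rel = n_unrel = n_uncov = 0
    for t in trials:
        if t.response_code != "not_a_verb":
            continue
        lemma = t.response_lemma or lemmatize(t.response_raw.split()[0])
        if lemma == t.noun:
            n_rep += 1
            continue
        if lemma not in emb or t.noun not in emb:
            logger.warning("embedding coverage miss: %r or %r absent", lemma, t.noun)
            n_uncov += 1
            continue
        sim = cosine_similarity(emb.vector(lemma), emb.vector(t.noun))
        if sim > threshold:
            n_rel += 1
        else:
            n_unrel += 1
    return NotVerbDecomposition(n_repetitions=n_rep, n_semantically_related=n_rel,
                                n_unrelated=n_unrel, n_uncovered=n_uncov,
                                threshold_used=threshold)


def notverb_similarities(trials: Iterable[TrialResponse], emb: EmbeddingTable
                         ) -> list[float]:
    """Cosine similarities of all covered non-repetition not-a-verb responses.

    Pool these across all cohorts to calibrate the relatedness threshold.
    """
    sims: list[float] = []
    for t in trials:
        if t.response_code != "not_a_verb":
            continue
        lemma = t.response_lemma or lemmatize(t.response_raw.split()[0])
        if lemma == t.noun or lemma not in emb or t.noun not in emb:
            continue
        sims.append(cosine_similarity(emb.vector(lemma), emb.vector(t.noun)))
    return sims


def calibrate_threshold(similarities: Sequence[float]) -> float:
    """Median of the pooled similarity values (the data-driven threshold)."""
    if len(similarities) == 0:
        raise StateError("no similarity values to calibrate a threshold from")
    return float(np.median(np.asarray(similarities, dtype=float)))


def lexsem_profile(trials: Sequence[TrialResponse], emb: EmbeddingTable,
                   threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                   light_verbs: Sequence[str] = LIGHT_VERBS) -> LexsemProfile:
    """All lexico-semantic features for one subject's coded trials."""
    subjects = {t.subject_id for t in trials}
    if len(subjects) != 1:
        raise ValueError(f"trials span multiple subjects: {sorted(subjects)}")
    decomp = not_verb_decomposition(trials, emb, threshold)
    return LexsemProfile(
        subject_id=trials[0].subject_id,
        group=trials[0].group,
        pct_light_verbs=light_verb_pct(trials, light_verbs),
        n_repetitions=decomp.n_repetitions,
        n_semantically_related=decomp.n_semantically_related,
        n_uncovered=decomp.n_uncovered,
        threshold_used=threshold,
    )


def lexsem_profiles(trials: Sequence[TrialResponse], emb: EmbeddingTable,
                    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                    light_verbs: Sequence[str] = LIGHT_VERBS) -> list[LexsemProfile]:
    by_subject: dict[str, list[TrialResponse]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    return [lexsem_profile(ts, emb, threshold, light_verbs) for ts in by_subject.values()]
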
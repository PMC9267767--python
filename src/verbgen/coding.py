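"""Response coding, per-subject error profiles, outlier exclusion, consistency.

The four-way taxonomy mirrors how verb-generation responses are scored in
clinical practice: a response is a *related verb* (correct), a *not-a-verb*
(e.g. "baseball" for "ball"), an *unrelated verb* (e.g. "eat" for "ball"),
or *missing*. Human raters coded the original study; this module accepts
pre-assigned codes for real data (never overwritten) and provides a
transparent rule-based auto-coder, driven by a reference lexicon of
acceptable verbs per noun, for synthetic and exploratory use. Articulatory
errors and phonological paraphasias are handled upstream (pre-assigned
codes or exception lists); the auto-coder does no phonetic matching.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, StateError
from .io import normalize_token
from .lemmas import LIGHT_VERBS, lemmatize
from .types import TrialResponse

#: Exception phrases seeded from the control-normed adjudications:
#: "be careful" rejected for knife/scissor, "go in" rejected for house,
#: "do" accepted for laundry.
DEFAULT_REJECTED_PHRASES: frozenset[tuple[str, str]] = frozenset(
    {("knife", "be careful"), ("scissor", "be careful"), ("house", "go in")}
)
DEFAULT_ACCEPTED_EXCEPTIONS: frozenset[tuple[str, str]] = frozenset({("laundry", "do")})


def _normalize_phrase(text: str) -> str:
    """Normalize a response phrase and strip a leading infinitive marker."""
    phrase = normalize_token(text)
    if phrase.startswith("to ") and len(phrase) > 3:
        phrase = phrase[3:]
    return phrase


@dataclass
class CodingRules:
    """Configuration for the rule-based auto-coder.

    ``reference_lexicon`` maps each noun to its acceptable verb lemmas (by
    default the verbs produced by at least one control for that noun).
    ``extra_verbs`` extends the global verb vocabulary used to separate
    unrelated verbs from non-verbs.
    """

    reference_lexicon: dict[str, set[str]]
    accept_phrasal: bool = True
    rejected_phrases: set[tuple[str, str]] = field(
        default_factory=lambda: set(DEFAULT_REJECTED_PHRASES))
    accepted_exceptions: set[tuple[str, str]] = field(
        default_factory=lambda: set(DEFAULT_ACCEPTED_EXCEPTIONS))
    extra_verbs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.rejected_phrases = {
            (normalize_token(n), _normalize_phrase(p)) for n, p in self.rejected_phrases}
        self.accepted_exceptions = {
            (normalize_token(n), _normalize_phrase(p)) for n, p in self.accepted_exceptions}
        overlap = self.rejected_phrases & self.accepted_exceptions
        if overlap:
            raise ConfigError(f"phrases both rejected and accepted: {sorted(overlap)}")

    def verb_vocabulary(self) -> set[str]:
        """All lemmas the coder treats as verbs."""
        vocab: set[str] = set(LIGHT_VERBS) | set(self.extra_verbs)
        for verbs in self.reference_lexicon.values():
            vocab |= verbs
        return vocab


def code_response(trial: TrialResponse, rules: CodingRules) -> TrialResponse:
    """Assign the four-way code to one trial (pre-assigned codes are kept).

    Order of the rules: empty -> missing; explicitly rejected phrase ->
    unrelated_verb; explicitly accepted phrase -> related_verb; head-verb
    lemma in the noun's lexicon -> related_verb; head lemma in the global
    verb vocabulary -> unrelated_verb; otherwise not_a_verb. With
    ``accept_phrasal`` off, multi-word responses are never related.
    """
    if trial.response_code is not None:
        return trial
    noun = trial.noun
    if noun not in rules.reference_lexicon:
        raise ConfigError(f"noun {noun!r} absent from the reference lexicon")
    phrase = _normalize_phrase(trial.response_raw)
    if not phrase:
        return dataclasses.replace(trial, response_code="missing", response_lemma=None)
    head = lemmatize(phrase.split()[0])
    multiword = " " in phrase
    if (noun, phrase) in rules.rejected_phrases:
        code = "unrelated_verb"
    elif (noun, phrase) in rules.accepted_exceptions:
        code = "related_verb"
    elif head in rules.reference_lexicon[noun] and (rules.accept_phrasal or not multiword):
        code = "related_verb"
    elif head in rules.verb_vocabulary():
        code = "unrelated_verb"
    else:
        code = "not_a_verb"
    return dataclasses.replace(trial, response_code=code, response_lemma=head)


def code_trials(trials: Iterable[TrialResponse], rules: CodingRules) -> list[TrialResponse]:
    return [code_response(t, rules) for t in trials]


@dataclass
class SubjectProfile:
    """Per-subject accuracy and error-pattern summary.

    The four category percentages partition all trials and sum to 100.
    ``pct_error_consistency`` is the share of stimulus pairs (a noun
    presented twice) with both presentations incorrect;
    ``pct_error_type_consistency`` is, among those consistently-erred
    pairs, the share with the same error type on both presentations
    (``None`` when a subject has no consistently-erred pairs).
    """

    subject_id: str
    group: str
    n_trials: int
    pct_correct: float
    pct_not_verb: float
    pct_unrelated_verb: float
    pct_missing: float
    pct_error_consistency: float | None
    pct_error_type_consistency: float | None
    mean_rt_s: float | None

    def error_percentages(self) -> dict[str, float]:
        return {
            "not_verb": self.pct_not_verb,
            "unrelated_verb": self.pct_unrelated_verb,
            "missing": self.pct_missing,
        }


def subject_profile(trials: Sequence[TrialResponse], rt_correct_only: bool = True
                    ) -> SubjectProfile:
    """Summarize one subject's coded trials into a :class:`SubjectProfile`."""
    if not trials:
        raise StateError("no trials supplied")
    subjects = {t.subject_id for t in trials}
    if len(subjects) != 1:
        raise ValueError(f"trials span multiple subjects: {sorted(subjects)}")
    for t in trials:
        if not t.coded:
            raise StateError(f"uncoded trial for subject {t.subject_id}, noun {t.noun!r}")
    n = len(trials)
    counts = {"related_verb": 0, "not_a_verb": 0, "unrelated_verb": 0, "missing": 0}
    for t in trials:
        counts[t.response_code] += 1  # type: ignore[index]

    by_noun: dict[str, dict[int, str]] = {}
    for t in trials:
        by_noun.setdefault(t.noun, {})[t.presentation] = t.response_code  # type: ignore[arg-type]
    pairs = [codes for codes in by_noun.values() if 1 in codes and 2 in codes]
    both_wrong = [c for c in pairs if c[1] != "related_verb" and c[2] != "related_verb"]
    pct_err_cons = 100.0 * len(both_wrong) / len(pairs) if pairs else None
    if both_wrong:
        same_type = sum(1 for c in both_wrong if c[1] == c[2])
        pct_type_cons = 100.0 * same_type / len(both_wrong)
    else:
        pct_type_cons = None

    if rt_correct_only:
        rts = [t.rt_s for t in trials if t.correct and t.rt_s is not None]
    else:
        rts = [t.rt_s for t in trials if t.rt_s is not None]
    mean_rt = float(np.mean(rts)) if rts else None

    return SubjectProfile(
        subject_id=trials[0].subject_id,
        group=trials[0].group,
        n_trials=n,
        pct_correct=100.0 * counts["related_verb"] / n,
        pct_not_verb=100.0 * counts["not_a_verb"] / n,
        pct_unrelated_verb=100.0 * counts["unrelated_verb"] / n,
        pct_missing=100.0 * counts["missing"] / n,
        pct_error_consistency=pct_err_cons,
        pct_error_type_consistency=pct_type_cons,
        mean_rt_s=mean_rt,
    )


def subject_profiles(trials: Iterable[TrialResponse], rt_correct_only: bool = True
                     ) -> list[SubjectProfile]:
    """Group coded trials by subject and profile each one."""
    by_subject: dict[str, list[TrialResponse]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    return [subject_profile(ts, rt_correct_only) for ts in by_subject.values()]


@dataclass
class OutlierReport:
    """Result of the 2-SD accuracy screen.

    ``group_means``/``group_sds`` record the reference statistics actually
    used, keyed by reference cohort name ("HC" and "patients" in the
    default pooled mode, group labels in per-group mode).
    """

    kept: list[str]
    excluded: dict[str, float]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    n_sd: float


def exclude_outliers(profiles: Sequence[SubjectProfile],
                     mode: str = "pooled_patients_and_hc",
                     n_sd: float = 2.0) -> OutlierReport:
    """Single-pass exclusion of subjects whose accuracy is > ``n_sd`` SDs out.

    In the default mode the reference cohorts are (a) all patients pooled
    and (b) controls. The screen is one-shot: means/SDs are computed once
    on the full cohort and never recomputed on the kept set. "Outside" is
    strict: a subject exactly at mean +/- n_sd*SD is kept. A zero-variance
    cohort excludes any subject deviating from the (constant) mean.
    """
    if mode not in ("pooled_patients_and_hc", "per_group"):
        raise ValueError(f"unknown mode {mode!r}")
    cohorts: dict[str, list[SubjectProfile]] = {}
    for p in profiles:
        if mode == "per_group":
            key = p.group
        else:
            key = "HC" if p.group == "HC" else "patients"
        cohorts.setdefault(key, []).append(p)
    kept: list[str] = []
    excluded: dict[str, float] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name, members in cohorts.items():
        if len(members) < 3:
            raise StateError(f"reference cohort {name!r} has fewer than 3 subjects")
        values = np.array([m.pct_correct for m in members], dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        means[name] = mean
        sds[name] = sd
        for m in members:
            deviation = abs(m.pct_correct - mean)
            is_out = deviation > n_sd * sd if sd > 0 else deviation > 0
            if is_out:
                excluded[m.subject_id] = m.pct_correct
            else:
                kept.append(m.subject_id)
    return OutlierReport(kept=kept, excluded=excluded, group_means=means,
                         group_sds=sds, n_sd=n_sd)


def lexicon_from_trials(trials: Iterable[TrialResponse],
                        group: str = "HC",
                        related_only: bool = False) -> dict[str, set[str]]:
    """Build a reference lexicon from (control) trials: for each noun, the
    verb lemmas produced at least once.

    With ``related_only`` off (the default for bootstrapping from raw
    control data), every verb response counts; coded trials contribute
    their lemma, uncoded ones the head token of the raw response.
    """
    lexicon: dict[str, set[str]] = {}
    for t in trials:
        if t.group != group:
            continue
        lexicon.setdefault(t.noun, set())
        if t.response_code == "missing" or t.response_code == "not_a_verb":
            continue
        if related_only and t.response_code != "related_verb":
            continue
        phrase = _normalize_phrase(t.response_raw)
        if not phrase:
            continue
        lemma = t.response_lemma or lemmatize(phrase.split()[0])
        lexicon[t.noun].add(lemma)
    return lexicon
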
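"""Control-derived noun agreement indices: response entropy, ASI, CSI.

For every noun, the control cohort's verb responses define a distribution
over verb lemmas. Three indices summarize it:

* **response entropy** (H-index), in bits: ``E = sum_i p_i * log2(1/p_i)``
  over the k distinct verbs with proportions ``p_i``. 0 bits means perfect
  agreement (everyone produced the same verb); 1 bit means two verbs at
  equal frequency. Entropy conflates retrieval and competition demands.
* **ASI** (Association Strength Index): the percentage of responses that
  are the modal verb — higher means a stronger noun-verb association.
* **CSI** (Competition Strength Index): the ratio of the modal response
  percentage to the runner-up percentage — higher means less competition
  from alternatives.

By default distributions pool both presentations and include all verb
responses (related and unrelated); missing and not-a-verb trials never
enter. Flags restrict to related verbs only or to a single presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .errors import EmptyDistributionError, StateError
from .lemmas import lemmatize
from .types import TrialResponse

#: Codes whose responses enter a response distribution.
_VERB_CODES = ("related_verb", "unrelated_verb")


@dataclass
class ResponseDistribution:
    """Counts of verb lemmas produced by controls for one noun."""

    noun: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise EmptyDistributionError(f"no verb responses for noun {self.noun!r}")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all counts must be >= 1")

    @property
    def n_responses(self) -> int:
        return sum(self.counts.values())

    @property
    def k(self) -> int:
        """Number of distinct verbs generated."""
        return len(self.counts)


@dataclass
class NounAgreementProfile:
    """Per-noun agreement summary: entropy (bits), ASI (%), CSI (ratio)."""

    noun: str
    k: int
    entropy: float
    asi: float
    csi: float
    modal_verb: str


def response_distribution(trials: Iterable[TrialResponse], noun: str,
                          include_unrelated: bool = True,
                          presentations: Sequence[int] = (1, 2),
                          ) -> ResponseDistribution:
    """Pool a cohort's coded verb responses for one noun into counts.

    ``include_unrelated`` controls whether unrelated-verb responses enter
    the distribution (default yes: the index counts *different verbs
    generated*, not different correct verbs). ``presentations`` selects
    which of the two presentations to pool (both by default); restricting
    to ``(1,)`` gives a per-subject first-response distribution.
    """
    codes = _VERB_CODES if include_unrelated else ("related_verb",)
    counts: dict[str, int] = {}
    for t in trials:
        if t.noun != noun or t.presentation not in presentations:
            continue
        if not t.coded:
            raise StateError(f"uncoded trial for noun {noun!r}")
        if t.response_code not in codes:
            continue
        lemma = t.response_lemma or lemmatize(t.response_raw.split()[0])
        counts[lemma] = counts.get(lemma, 0) + 1
    return ResponseDistribution(noun=noun, counts=counts)


def entropy(dist: ResponseDistribution) -> float:
    """Shannon entropy of the response distribution, in bits."""
    return float(stats.entropy(list(dist.counts.values()), base=2))


def asi(dist: ResponseDistribution) -> float:
    """Association Strength Index: modal response share, as a percentage."""
    return 100.0 * max(dist.counts.values()) / dist.n_responses


def csi(dist: ResponseDistribution) -> float:
    """Competition Strength Index: modal over runner-up percentage.

    With a single distinct verb the runner-up percentage is imputed as one
    hypothetical dissenting response, ``100 / n_responses``, keeping CSI
    finite (it then equals ``n_responses``).
    """
    ordered = sorted(dist.counts.values(), reverse=True)
    p1 = 100.0 * ordered[0] / dist.n_responses
    if len(ordered) == 1:
        p2 = 100.0 / dist.n_responses
    else:
        p2 = 100.0 * ordered[1] / dist.n_responses
    return p1 / p2


def noun_profile(dist: ResponseDistribution) -> NounAgreementProfile:
    """All three indices for one noun; modal ties break lexicographically."""
    top = max(dist.counts.values())
    modal = min(v for v, c in dist.counts.items() if c == top)
    return NounAgreementProfile(
        noun=dist.noun, k=dist.k, entropy=entropy(dist), asi=asi(dist),
        csi=csi(dist), modal_verb=modal,
    )


def agreement_profiles(trials: Sequence[TrialResponse],
                       nouns: Sequence[str] | None = None,
                       include_unrelated: bool = True,
                       presentations: Sequence[int] = (1, 2),
                       ) -> list[NounAgreementProfile]:
    """Agreement profile for every noun in (control) ``trials``."""
    if nouns is None:
        seen: dict[str, None] = {}
        for t in trials:
            seen.setdefault(t.noun)
        nouns = list(seen)
    return [
        noun_profile(response_distribution(trials, noun, include_unrelated, presentations))
        for noun in nouns
    ]
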
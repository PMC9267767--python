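"""Light-verb inventory and the bundled inflection table.

Light verbs are semantically impoverished, high-frequency predicates
(do, take, get, ...) contrasted with "heavy" specific verbs (fold, throw,
spend). Responses arrive as surface forms, so a small inflection table maps
common inflected forms of the light verbs (and a few other frequent verbs)
back to their lemma. This is deliberately a lookup table, not a tagger:
anything absent from the table is returned unchanged.
"""

from __future__ import annotations

#: The predetermined light-verb list used by the lexico-semantic analysis.
LIGHT_VERBS: tuple[str, ...] = (
    "be",
    "bring",
    "come",
    "do",
    "get",
    "give",
    "go",
    "have",
    "make",
    "move",
    "put",
    "see",
    "take",
    "use",
)

# form -> lemma; covers the light verbs' irregular and regular inflections.
_BASE_INFLECTIONS: dict[str, str] = {
    # be
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be",
    # bring
    "brings": "bring", "brought": "bring", "bringing": "bring",
    # come
    "comes": "come", "came": "come", "coming": "come",
    # do
    "does": "do", "did": "do", "done": "do", "doing": "do",
    # get
    "gets": "get", "got": "get", "gotten": "get", "getting": "get",
    # give
    "gives": "give", "gave": "give", "given": "give", "giving": "give",
    # go
    "goes": "go", "went": "go", "gone": "go", "going": "go",
    # have
    "has": "have", "had": "have", "having": "have",
    # make
    "makes": "make", "made": "make", "making": "make",
    # move
    "moves": "move", "moved": "move", "moving": "move",
    # put
    "puts": "put", "putting": "put",
    # see
    "sees": "see", "saw": "see", "seen": "see", "seeing": "see",
    # take
    "takes": "take", "took": "take", "taken": "take", "taking": "take",
    # use
    "uses": "use", "used": "use", "using": "use",
    # a few frequent non-light verbs seen in verb-generation responses
    "throws": "throw", "threw": "throw", "thrown": "throw", "throwing": "throw",
    "kicks": "kick", "kicked": "kick", "kicking": "kick",
    "eats": "eat", "ate": "eat", "eaten": "eat", "eating": "eat",
    "folds": "fold", "folded": "fold", "folding": "fold",
    "spends": "spend", "spent": "spend", "spending": "spend",
    "sleeps": "sleep", "slept": "sleep", "sleeping": "sleep",
    "runs": "run", "ran": "run", "running": "run",
    "drives": "drive", "drove": "drive", "driven": "drive", "driving": "drive",
}


def lemmatize(token: str, extra: dict[str, str] | None = None) -> str:
    """Map a surface form to its lemma via the bundled inflection table.

    ``extra`` lets callers extend the table (e.g. from a lexicon file);
    unknown forms are returned unchanged.
    """
    token = token.strip().casefold()
    if extra and token in extra:
        return extra[token]
    return _BASE_INFLECTIONS.get(token, token)
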
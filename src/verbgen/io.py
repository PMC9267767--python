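"""Readers and writers for the tabular and embedding formats.

Formats
-------
trials (TSV/CSV)
    long format, one row per stimulus presentation; columns
    ``subject_id, group, noun, presentation, response_raw`` plus optional
    ``response_code, response_lemma, rt_s``.
norms (CSV)
    one row per noun: ``noun`` plus the :data:`verbgen.types.NORM_FIELDS`.
subjects (CSV)
    ``subject_id, group`` plus one numeric column per neuropsych measure.
embeddings (text)
    the standard word-vector format: one word followed by D
    whitespace-separated floats per line; an optional "N D" count header
    line is tolerated.
lexicon (TSV)
    ``noun<TAB>verb,verb,...`` (acceptable verb lemmas per noun).

Delimiters are auto-detected from the extension (``.tsv`` -> tab,
anything else -> comma) and can be overridden. Tokens (nouns, responses)
are case-folded and whitespace-normalized on ingest; responses keep their
internal spaces so phrasal verbs survive.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError
from .types import (
    CODES,
    COUNT_FIELDS,
    GROUPS,
    NORM_FIELDS,
    EmbeddingTable,
    StimulusNorms,
    SubjectRecord,
    TrialResponse,
)

_TRIAL_REQUIRED = ("subject_id", "group", "noun", "presentation", "response_raw")
_TRIAL_OPTIONAL = ("response_code", "response_lemma", "rt_s")


def _delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith(".tsv") else ","


def normalize_token(text: str) -> str:
    """Case-fold and collapse whitespace, keeping internal single spaces."""
    return " ".join(str(text).split()).casefold()


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    return pd.read_csv(path, sep=_delimiter(path, delimiter), dtype=str, keep_default_na=False)


def read_trials(path: str | Path, delimiter: str | None = None) -> list[TrialResponse]:
    """Read a long-format trial table into :class:`TrialResponse` records."""
    df = _read_table(path, delimiter)
    for col in _TRIAL_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"trials file {path}: missing required column {col!r}")
    trials: list[TrialResponse] = []
    seen: set[tuple[str, str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        group = str(row.group).strip()
        if group not in GROUPS:
            raise FormatError(f"trials file {path}, line {i}: unknown group {group!r}")
        try:
            presentation = int(str(row.presentation).strip())
        except ValueError as exc:
            raise FormatError(
                f"trials file {path}, line {i}: non-integer presentation {row.presentation!r}"
            ) from exc
        code = None
        if "response_code" in df.columns:
            raw_code = str(getattr(row, "response_code")).strip()
            if raw_code:
                if raw_code not in CODES:
                    raise FormatError(
                        f"trials file {path}, line {i}: unknown response code {raw_code!r}"
                    )
                code = raw_code
        lemma = None
        if "response_lemma" in df.columns:
            raw_lemma = normalize_token(getattr(row, "response_lemma"))
            lemma = raw_lemma or None
        rt = None
        if "rt_s" in df.columns:
            raw_rt = str(getattr(row, "rt_s")).strip()
            if raw_rt:
                try:
                    rt = float(raw_rt)
                except ValueError as exc:
                    raise FormatError(
                        f"trials file {path}, line {i}: non-numeric rt_s {raw_rt!r}"
                    ) from exc
        trial = TrialResponse(
            subject_id=str(row.subject_id).strip(),
            group=group,
            noun=normalize_token(row.noun),
            presentation=presentation,
            response_raw=normalize_token(row.response_raw),
            response_code=code,
            response_lemma=lemma,
            rt_s=rt,
        )
        key = (trial.subject_id, trial.noun, trial.presentation)
        if key in seen:
            raise IntegrityError(
                f"trials file {path}: duplicate (subject, noun, presentation) {key}"
            )
        seen.add(key)
        trials.append(trial)
    return trials


def write_trials(trials: Iterable[TrialResponse], path: str | Path,
                 delimiter: str | None = None) -> None:
    """Write trials back out; ``read_trials`` round-trips the result."""
    rows = []
    for t in trials:
        rows.append(
            {
                "subject_id": t.subject_id,
                "group": t.group,
                "noun": t.noun,
                "presentation": t.presentation,
                "response_raw": t.response_raw,
                "response_code": t.response_code or "",
                "response_lemma": t.response_lemma or "",
                "rt_s": "" if t.rt_s is None else repr(float(t.rt_s)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_delimiter(path, delimiter), index=False)


def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Parse a plain-text word-vector file.

    Duplicate words keep the first occurrence (with a warning); an
    inconsistent vector length raises :class:`FormatError` naming the line.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    continue  # count header, e.g. "4000 300"
                except ValueError:
                    pass
            word = parts[0].casefold()
            try:
                vec = np.array([float(x) for x in parts[1:]], dtype=float)
            except ValueError as exc:
                raise FormatError(
                    f"embeddings file {path}, line {lineno}: non-numeric vector entry"
                ) from exc
            if vec.size == 0:
                raise FormatError(f"embeddings file {path}, line {lineno}: no vector values")
            if dim is None:
                dim = int(vec.size)
            elif vec.size != dim:
                raise FormatError(
                    f"embeddings file {path}, line {lineno}: vector length {vec.size} "
                    f"!= expected dimension {dim}"
                )
            if word in vectors:
                warnings.warn(f"duplicate embedding for {word!r}; keeping first occurrence")
                continue
            vectors[word] = vec
    if dim is None:
        raise FormatError(f"embeddings file {path}: no vectors found")
    return EmbeddingTable(dimension=dim, vectors=vectors)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for word, vec in table.vectors.items():
            fh.write(word + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def read_stimulus_norms(path: str | Path, delimiter: str | None = None
                        ) -> dict[str, StimulusNorms]:
    """Read the per-noun psycholinguistic norms CSV into a noun-keyed map."""
    df = _read_table(path, delimiter)
    if "noun" not in df.columns:
        raise FormatError(f"norms file {path}: missing required column 'noun'")
    norms: dict[str, StimulusNorms] = {}
    for i, row in df.iterrows():
        noun = normalize_token(row["noun"])
        if noun in norms:
            raise IntegrityError(f"norms file {path}: duplicate noun {noun!r}")
        kwargs: dict[str, float | int | None] = {}
        for field in NORM_FIELDS:
            if field not in df.columns:
                continue
            cell = str(row[field]).strip()
            if not cell:
                continue
            try:
                value = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"norms file {path}: non-numeric value {cell!r} in column {field!r}"
                ) from exc
            kwargs[field] = int(value) if field in COUNT_FIELDS else value
        norms[noun] = StimulusNorms(**kwargs)
    return norms


def write_stimulus_norms(norms: dict[str, StimulusNorms], path: str | Path,
                         delimiter: str | None = None) -> None:
    rows = []
    for noun, n in norms.items():
        row = {"noun": noun}
        for field in NORM_FIELDS:
            value = getattr(n, field)
            row[field] = "" if value is None else (
                str(value) if field in COUNT_FIELDS else repr(float(value)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_delimiter(path, delimiter), index=False)


def read_subjects(path: str | Path, delimiter: str | None = None) -> list[SubjectRecord]:
    """Read the per-subject neuropsych CSV; blank cells become absent keys."""
    df = _read_table(path, delimiter)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise FormatError(f"subjects file {path}: missing required column {col!r}")
    measures = [c for c in df.columns if c not in ("subject_id", "group")]
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["subject_id"]).strip()
        if sid in seen:
            raise IntegrityError(f"subjects file {path}: duplicate subject_id {sid!r}")
        seen.add(sid)
        scores: dict[str, float] = {}
        for m in measures:
            cell = str(row[m]).strip()
            if not cell:
                continue
            try:
                scores[m] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"subjects file {path}: non-numeric value {cell!r} in column {m!r}"
                ) from exc
        records.append(SubjectRecord(subject_id=sid, group=str(row["group"]).strip(),
                                     neuropsych=scores))
    return records


def write_subjects(records: Sequence[SubjectRecord], path: str | Path,
                   delimiter: str | None = None) -> None:
    measures: list[str] = []
    for r in records:
        for m in r.neuropsych:
            if m not in measures:
                measures.append(m)
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group}
        for m in measures:
            v = r.neuropsych.get(m)
            row[m] = "" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_delimiter(path, delimiter), index=False)


def read_lexicon(path: str | Path) -> dict[str, set[str]]:
    """Read a reference lexicon: ``noun<TAB>verb,verb,...`` per line."""
    lexicon: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"lexicon file {path}, line {lineno}: expected 2 tab fields")
            noun = normalize_token(parts[0])
            if noun in lexicon:
                raise IntegrityError(f"lexicon file {path}: duplicate noun {noun!r}")
            lexicon[noun] = {normalize_token(v) for v in parts[1].split(",") if v.strip()}
    return lexicon


def write_lexicon(lexicon: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for noun in sorted(lexicon):
            fh.write(f"{noun}\t{','.join(sorted(lexicon[noun]))}\n")
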
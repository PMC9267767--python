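"""Group-level statistics: ANOVAs with Tukey post hoc, corrected correlations.

Implements the cohort comparisons of the behavioral analysis: a one-way
ANOVA over overall accuracy (and over per-subject mean RT), a mixed
group x error-type ANOVA (group between subjects, error type within,
since every subject contributes all three error percentages), Tukey HSD
pairwise contrasts, and Bonferroni-corrected Pearson correlation families
(6 by-item psycholinguistic predictors, 3 by-subject neuropsych measures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .coding import SubjectProfile
from .errors import StateError
from .types import SubjectRecord, TrialResponse

DEFAULT_ALPHA = 0.05


def _p_unc(row) -> float:
    """Uncorrected p from a pingouin ANOVA row (column name varies by version)."""
    return row["p_unc"] if "p_unc" in row.index else row["p-unc"]

#: The six by-item predictors, in reporting order.
BY_ITEM_PREDICTORS: tuple[str, ...] = (
    "freq_log", "n_phonemes", "semantic_neighborhood", "asi", "csi", "entropy")

#: The three by-subject neuropsych predictors.
BY_SUBJECT_PREDICTORS: tuple[str, ...] = (
    "single_word_comprehension", "fluency_ratio", "trails_total_time")


@dataclass
class Effect:
    name: str
    f: float
    df_num: float
    df_den: float
    p: float


@dataclass
class AnovaResult:
    design: str
    effects: list[Effect]
    note: str | None = None

    def effect(self, name: str) -> Effect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass
class PairwisePair:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float


@dataclass
class PairwiseResult:
    pairs: list[PairwisePair]

    def pair(self, a: str, b: str) -> PairwisePair:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p
        raise KeyError((a, b))


@dataclass
class CorrelationRow:
    predictor: str
    r: float
    p_raw: float
    p_adj: float
    m: int
    survives: bool
    n: int
    note: str | None = None


@dataclass
class CorrelationTable:
    rows: list[CorrelationRow]
    family_size: int
    alpha: float

    def row(self, predictor: str) -> CorrelationRow:
        for r in self.rows:
            if r.predictor == predictor:
                return r
        raise KeyError(predictor)


def _as_group_arrays(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]
                     ) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        names = list(groups.keys())
        arrays = [np.asarray(groups[n], dtype=float) for n in names]
    else:
        names = [f"group{i}" for i in range(len(groups))]
        arrays = [np.asarray(g, dtype=float) for g in groups]
    return names, arrays


def oneway_anova(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]
                 ) -> AnovaResult:
    """Classical between-groups one-way ANOVA (F = MS_between / MS_within).

    All values identical across all groups makes F 0/0; the result is
    reported as NaN with an explanatory note rather than raised.
    """
    names, arrays = _as_group_arrays(groups)
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, a in zip(names, arrays):
        if len(a) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    df_num = len(arrays) - 1
    df_den = sum(len(a) for a in arrays) - len(arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return AnovaResult(
            design="one_way",
            effects=[Effect("group", float("nan"), df_num, df_den, float("nan"))],
            note="F undefined: all values identical across groups",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant within-group input warnings
        f, p = sps.f_oneway(*arrays)
    return AnovaResult(design="one_way",
                       effects=[Effect("group", float(f), df_num, df_den, float(p))])


def tukey_hsd(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
              alpha: float = DEFAULT_ALPHA) -> PairwiseResult:
    """Tukey HSD adjusted pairwise contrasts using the pooled within MS."""
    names, arrays = _as_group_arrays(groups)
    endog = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(a) for n, a in zip(names, arrays)])
    res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
    uniq = list(res.groupsunique)
    pairs = []
    idx = 0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            pairs.append(PairwisePair(
                group_a=str(uniq[i]), group_b=str(uniq[j]),
                mean_diff=float(res.meandiffs[idx]),
                p_adj=float(res.pvalues[idx]),
            ))
            idx += 1
    return PairwiseResult(pairs=pairs)


def group_by_errortype_anova(profiles: Sequence[SubjectProfile]) -> AnovaResult:
    """Mixed-design ANOVA of error-type percentages (group x error type).

    Diagnostic group is a between-subject factor, error type (not-a-verb,
    unrelated verb, missing) within-subject; subjects with missing error
    percentages are excluded with a warning. A single group degenerates to
    a one-way repeated-measures ANOVA on error type.
    """
    rows = []
    for p in profiles:
        errs = p.error_percentages()
        if any(v is None or np.isnan(v) for v in errs.values()):
            warnings.warn(f"subject {p.subject_id}: missing error percentages, excluded")
            continue
        for etype, value in errs.items():
            rows.append({"subject": p.subject_id, "group": p.group,
                         "error_type": etype, "pct": value})
    if not rows:
        raise StateError("no usable subjects")
    data = pd.DataFrame(rows)
    n_groups = data["group"].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n_groups == 1:
            aov = pg.rm_anova(data=data, dv="pct", within="error_type", subject="subject",
                              detailed=True)
            row = aov.loc[aov["Source"] == "error_type"].iloc[0]
            return AnovaResult(
                design="one_way_within",
                effects=[Effect("error_type", float(row["F"]), float(row["DF"]),
                                float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0]),
                                float(_p_unc(row)))],
                note="single group: reduced to within-subject one-way design",
            )
        aov = pg.mixed_anova(data=data, dv="pct", within="error_type",
                             subject="subject", between="group")
    name_map = {"group": "group", "error_type": "error_type", "Interaction": "interaction"}
    effects = []
    for _, row in aov.iterrows():
        name = name_map.get(str(row["Source"]), str(row["Source"]))
        effects.append(Effect(name, float(row["F"]), float(row["DF1"]),
                              float(row["DF2"]), float(_p_unc(row))))
    return AnovaResult(design="group_by_errortype", effects=effects)


def _correlation_table(y: pd.Series, predictors: pd.DataFrame, family_size: int,
                       alpha: float, min_n: int) -> CorrelationTable:
    rows: list[CorrelationRow] = []
    for col in predictors.columns:
        joined = pd.concat([y.rename("_y"), predictors[col]], axis=1).dropna()
        n = len(joined)
        if n < min_n:
            rows.append(CorrelationRow(col, float("nan"), float("nan"), float("nan"),
                                       family_size, False, n,
                                       note=f"fewer than {min_n} complete pairs"))
            continue
        x = joined[col].to_numpy(dtype=float)
        yy = joined["_y"].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(yy) == 0:
            rows.append(CorrelationRow(col, float("nan"), float("nan"), float("nan"),
                                       family_size, False, n, note="zero variance"))
            continue
        r, p = sps.pearsonr(x, yy)
        p_adj = min(1.0, family_size * float(p))
        rows.append(CorrelationRow(col, float(r), float(p), p_adj, family_size,
                                   survives=float(p) <= alpha / family_size, n=n))
    return CorrelationTable(rows=rows, family_size=family_size, alpha=alpha)


def by_item_correlations(item_accuracy: pd.Series, predictors: pd.DataFrame,
                         family_size: int | None = None,
                         alpha: float = DEFAULT_ALPHA) -> CorrelationTable:
    """Pearson correlations of per-noun accuracy with item predictors.

    ``item_accuracy`` is indexed by noun (accuracy pooled across the
    subjects of one variant); ``predictors`` holds one column per
    psycholinguistic predictor (canonically the six in
    :data:`BY_ITEM_PREDICTORS`). Bonferroni family size defaults to the
    number of predictor columns.
    """
    m = family_size if family_size is not None else predictors.shape[1]
    return _correlation_table(item_accuracy, predictors, m, alpha, min_n=4)


def fluency_ratio(phonemic: float | None, semantic: float | None) -> float:
    """Phonemic / semantic fluency ratio; NaN when undefined (zero/missing)."""
    if phonemic is None or semantic is None or semantic == 0:
        return float("nan")
    return phonemic / semantic


def neuropsych_predictors(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    """The three by-subject predictors, one row per subject.

    Columns: single-word comprehension, phonemic/semantic fluency ratio
    (subjects with zero semantic fluency excluded via NaN), trails total
    time. Missing scores become NaN and are handled pairwise-complete.
    """
    rows = {}
    for s in subjects:
        np_ = s.neuropsych
        rows[s.subject_id] = {
            "single_word_comprehension": np_.get("single_word_comprehension", float("nan")),
            "fluency_ratio": fluency_ratio(np_.get("phonemic_fluency"),
                                           np_.get("semantic_fluency")),
            "trails_total_time": np_.get("trails_total_time", float("nan")),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def by_subject_correlations(subject_accuracy: pd.Series, predictors: pd.DataFrame,
                            family_size: int = 3,
                            alpha: float = DEFAULT_ALPHA) -> CorrelationTable:
    """Pearson correlations of per-subject accuracy with neuropsych scores.

    ``subject_accuracy`` is indexed by subject id; ``predictors`` as built
    by :func:`neuropsych_predictors`. Deletion is pairwise-complete and
    the complete-pair n is reported per row.
    """
    return _correlation_table(subject_accuracy, predictors, family_size, alpha, min_n=3)


def per_item_accuracy(trials: Iterable[TrialResponse]) -> pd.Series:
    """Per-noun percentage correct, pooled over the supplied trials."""
    totals: dict[str, int] = {}
    correct: dict[str, int] = {}
    for t in trials:
        if not t.coded:
            raise StateError("uncoded trial")
        totals[t.noun] = totals.get(t.noun, 0) + 1
        if t.correct:
            correct[t.noun] = correct.get(t.noun, 0) + 1
    return pd.Series({n: 100.0 * correct.get(n, 0) / tot for n, tot in totals.items()},
                     name="pct_correct")


def per_subject_accuracy(trials: Iterable[TrialResponse]) -> pd.Series:
    """Per-subject percentage correct."""
    totals: dict[str, int] = {}
    correct: dict[str, int] = {}
    for t in trials:
        if not t.coded:
            raise StateError("uncoded trial")
        totals[t.subject_id] = totals.get(t.subject_id, 0) + 1
        if t.correct:
            correct[t.subject_id] = correct.get(t.subject_id, 0) + 1
    return pd.Series({s: 100.0 * correct.get(s, 0) / tot for s, tot in totals.items()},
                     name="pct_correct")
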
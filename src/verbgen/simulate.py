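"""Synthetic cohort generator.

Emulates the statistical structure of a verb-generation norming/patient
study so the full pipeline runs and is tested without access to clinical
data: 50 nouns presented twice; a control cohort whose per-noun verb
choices follow a truncated-geometric popularity law whose decay is tuned
so realized response entropies span a target range (default 0.1-2.7 bits);
three patient cohorts whose per-subject error mixes are drawn from
zero-truncated normals at published group means/SDs (locations calibrated
so the post-truncation means match, accuracy taken as the complement to
100%); and a toy embedding table with planted cosine similarities for the
semantically-related-noun analysis.

The vocabulary is synthetic token strings ("noun07", "verb113",
"noun07kin" for the planted semantic associate of noun07) plus the real
light-verb inventory, so no lexical resources are downloaded. Every
generator is a pure function of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError
from .io import (write_embeddings, write_lexicon, write_stimulus_norms,
                 write_subjects, write_trials)
from .lemmas import LIGHT_VERBS
from .types import (EmbeddingTable, Stimulus, StimulusNorms, SubjectRecord,
                    TrialResponse)

#: Norm sampling ranges (uniform), matching the published stimulus set.
NORM_RANGES: dict[str, tuple[float, float]] = {
    "n_letters": (3, 8),
    "n_syllables": (1, 2),
    "n_phonemes": (2, 6),
    "freq_log": (3.4, 8.3),
    "semantic_neighborhood": (28.7, 362.9),
    "concreteness": (3.78, 6.88),
    "familiarity": (4.49, 6.94),
    "imageability": (3.81, 6.92),
    "age_of_acquisition": (1.49, 4.17),
}

# substream ids, so each generator draws from an independent stream
_STREAM_STIMULI = 1
_STREAM_HC = 2
_STREAM_PATIENTS = 3
_STREAM_EMBED = 4
_STREAM_NEURO = 5


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level generation settings.

    ``agreement_range`` is the span of per-noun target entropies (bits)
    the control popularity vectors are tuned to cover; ``verbs_per_noun``
    bounds the per-noun candidate verb pool (k), so max entropy is
    log2(k).
    """

    seed: int
    n_nouns: int = 50
    presentations: int = 2
    n_controls: int = 29
    verbs_per_noun: int = 12
    agreement_range: tuple[float, float] = (0.1, 2.7)
    hc_missing_rate: float = 0.02
    hc_rt_mean_s: float = 1.5
    hc_rt_sd_s: float = 0.4
    embedding_dim: int = 50

    def __post_init__(self) -> None:
        if self.n_nouns < 1:
            raise ConfigError("n_nouns must be >= 1")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer and is mandatory")
        lo, hi = self.agreement_range
        if not (0 <= lo <= hi <= np.log2(self.verbs_per_noun) + 1e-9):
            raise ConfigError("agreement_range must lie within [0, log2(verbs_per_noun)]")


@dataclass(frozen=True)
class CohortSpec:
    """One patient cohort's generative parameters.

    ``error_mix_mean``/``sd`` order: (pct_correct, pct_not_verb,
    pct_unrelated_verb, pct_missing); means must sum to 100 (+/-0.5 to
    absorb published rounding). ``dispersion`` is a temperature on the
    noun's verb-popularity vector (1 = controls' law, >1 flatter, i.e.
    more scattered verb choices). ``frequency_effect`` is a logistic slope
    tying item-level correctness to (centered) log frequency.
    """

    group: str
    n_subjects: int
    error_mix_mean: tuple[float, float, float, float]
    error_mix_sd: tuple[float, float, float, float]
    dispersion: float = 1.0
    light_verb_rate: float = 0.02
    related_noun_rate: float = 0.3
    repetition_rate: float = 0.25
    frequency_effect: float = 0.0
    rt_mean_s: float = 2.0
    rt_sd_s: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.error_mix_mean) - 100.0) > 0.5:
            raise ConfigError(
                f"error mix means must sum to 100, got {sum(self.error_mix_mean)}")
        for r in (self.light_verb_rate, self.related_noun_rate, self.repetition_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")


def default_cohort_specs() -> dict[str, CohortSpec]:
    """The three variant cohorts at their published error-mix moments.

    Sample sizes are the post-exclusion cohort sizes (19/28/24). Structural
    knobs encode the reported contrasts: svPPA gets wider verb-choice
    dispersion, a higher light-verb rate (8.7% vs ~2%) and a frequency
    effect sized for an item-level r around 0.5; lvPPA gets the highest
    planted rate of semantically related nouns among its not-a-verb
    errors. RT moments are the reported per-variant means/SDs.
    """
    return {
        "lvPPA": CohortSpec(
            group="lvPPA", n_subjects=19,
            error_mix_mean=(45.1, 37.9, 3.9, 13.1),
            error_mix_sd=(23.1, 21.2, 3.0, 12.0),
            dispersion=1.0, light_verb_rate=0.019, related_noun_rate=0.50,
            repetition_rate=0.25, frequency_effect=0.0,
            rt_mean_s=2.20, rt_sd_s=0.47),
        "svPPA": CohortSpec(
            group="svPPA", n_subjects=28,
            error_mix_mean=(63.9, 17.3, 7.6, 11.3),
            error_mix_sd=(22.8, 19.6, 7.0, 9.9),
            dispersion=3.0, light_verb_rate=0.087, related_noun_rate=0.25,
            repetition_rate=0.25, frequency_effect=0.1,
            rt_mean_s=2.03, rt_sd_s=0.59),
        "nfvPPA": CohortSpec(
            group="nfvPPA", n_subjects=24,
            error_mix_mean=(79.2, 7.8, 2.1, 11.0),
            error_mix_sd=(15.2, 7.9, 2.5, 12.4),
            dispersion=1.0, light_verb_rate=0.023, related_noun_rate=0.20,
            repetition_rate=0.25, frequency_effect=0.0,
            rt_mean_s=1.86, rt_sd_s=0.40),
    }


@dataclass
class SimulatedStimuli:
    """Stimuli plus the latent per-noun verb-popularity law."""

    stimuli: list[Stimulus]
    verb_pools: dict[str, list[str]]
    popularity: dict[str, np.ndarray]
    decay: dict[str, float]

    @property
    def nouns(self) -> list[str]:
        return [s.noun for s in self.stimuli]

    def norms(self) -> dict[str, StimulusNorms]:
        return {s.noun: s.norms for s in self.stimuli}

    def lexicon(self) -> dict[str, set[str]]:
        """Ground-truth reference lexicon: each noun's candidate verb pool."""
        return {n: set(pool) for n, pool in self.verb_pools.items()}


def _geometric_probs(decay: float, k: int) -> np.ndarray:
    w = decay ** np.arange(k, dtype=float)
    return w / w.sum()


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _decay_for_entropy(target_bits: float, k: int) -> float:
    """Invert the geometric-law entropy: find decay q with H(q, k) = target.

    H is 0 at q -> 0 and log2(k) at q = 1 and increases monotonically in
    between; plain bisection to 1e-10.
    """
    if target_bits <= 0:
        return 1e-12
    if target_bits >= np.log2(k):
        return 1.0
    lo, hi = 1e-12, 1.0
    for _ in range(100):
        mid = (lo + hi) / 2
        if _entropy_bits(_geometric_probs(mid, k)) < target_bits:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Lognormal draw parameterized by its own mean and SD."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_stimuli(cfg: GeneratorConfig) -> SimulatedStimuli:
    """Draw nouns, norms (uniform within the declared ranges), verb pools,
    and a popularity vector per noun tuned to a target entropy drawn
    uniformly over ``cfg.agreement_range``."""
    rng = np.random.default_rng([cfg.seed, _STREAM_STIMULI])
    n = cfg.n_nouns
    k = cfg.verbs_per_noun
    global_pool = [f"verb{j:03d}" for j in range(max(4 * n, 2 * k))]
    stimuli: list[Stimulus] = []
    verb_pools: dict[str, list[str]] = {}
    popularity: dict[str, np.ndarray] = {}
    decay: dict[str, float] = {}
    for i in range(n):
        noun = f"noun{i:02d}"
        norms = StimulusNorms(
            n_letters=int(rng.integers(*NORM_RANGES["n_letters"], endpoint=True)),
            n_syllables=int(rng.integers(*NORM_RANGES["n_syllables"], endpoint=True)),
            n_phonemes=int(rng.integers(*NORM_RANGES["n_phonemes"], endpoint=True)),
            freq_log=float(rng.uniform(*NORM_RANGES["freq_log"])),
            semantic_neighborhood=float(rng.uniform(*NORM_RANGES["semantic_neighborhood"])),
            concreteness=float(rng.uniform(*NORM_RANGES["concreteness"])),
            familiarity=float(rng.uniform(*NORM_RANGES["familiarity"])),
            imageability=float(rng.uniform(*NORM_RANGES["imageability"])),
            age_of_acquisition=float(rng.uniform(*NORM_RANGES["age_of_acquisition"])),
        )
        stimuli.append(Stimulus(noun=noun, norms=norms))
        pool = list(rng.choice(global_pool, size=k, replace=False))
        target = float(rng.uniform(*cfg.agreement_range))
        q = _decay_for_entropy(target, k)
        verb_pools[noun] = pool
        popularity[noun] = _geometric_probs(q, k)
        decay[noun] = q
    return SimulatedStimuli(stimuli=stimuli, verb_pools=verb_pools,
                            popularity=popularity, decay=decay)


def generate_hc_responses(sim: SimulatedStimuli, cfg: GeneratorConfig
                          ) -> list[TrialResponse]:
    """Coded control trials: each control samples a verb per presentation
    from the noun's popularity vector; a small rate of missing trials."""
    rng = np.random.default_rng([cfg.seed, _STREAM_HC])
    trials: list[TrialResponse] = []
    for s in range(cfg.n_controls):
        sid = f"hc{s:02d}"
        for noun in sim.nouns:
            pool = sim.verb_pools[noun]
            probs = sim.popularity[noun]
            for pres in range(1, cfg.presentations + 1):
                if rng.random() < cfg.hc_missing_rate:
                    trials.append(TrialResponse(sid, "HC", noun, pres, "",
                                                response_code="missing"))
                    continue
                verb = pool[int(rng.choice(len(pool), p=probs))]
                trials.append(TrialResponse(
                    sid, "HC", noun, pres, verb, response_code="related_verb",
                    response_lemma=verb,
                    rt_s=_lognormal(rng, cfg.hc_rt_mean_s, cfg.hc_rt_sd_s)))
    return trials


@lru_cache(maxsize=None)
def _clipped_normal_location(target_mean: float, sd: float) -> float:
    """Location mu such that E[max(N(mu, sd), 0)] equals ``target_mean``.

    Clipping a normal at zero inflates its mean; drawing from the
    calibrated location removes that bias so cohort moments recover the
    planted means even when the mean is within a couple of SDs of zero.
    """
    if sd == 0 or target_mean <= 0:
        return target_mean
    def clipped_mean(mu: float) -> float:
        z = mu / sd
        return mu * sps.norm.cdf(z) + sd * sps.norm.pdf(z)
    lo, hi = target_mean - 10 * sd, target_mean
    for _ in range(80):
        mid = (lo + hi) / 2
        if clipped_mean(mid) < target_mean:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _draw_error_mix(rng: np.random.Generator, spec: CohortSpec,
                    max_retries: int = 100) -> np.ndarray:
    """One subject's (correct, not_verb, unrelated, missing) percentages.

    The three error components are drawn from zero-truncated normals whose
    locations are calibrated so the post-truncation means equal the
    planted means; correct is the complement to 100 (the published
    accuracy SD is, compositionally, the SD of the error sum). Draws whose
    errors exceed 100 are resampled with bounded retries, then projected
    onto the simplex as a last resort.
    """
    err_mean = spec.error_mix_mean[1:]
    err_sd = np.asarray(spec.error_mix_sd[1:], dtype=float)
    mus = np.array([_clipped_normal_location(m, s)
                    for m, s in zip(err_mean, err_sd)])
    for _ in range(max_retries):
        errs = np.clip(rng.normal(mus, err_sd), 0.0, None)
        correct = 100.0 - errs.sum()
        if correct >= 0.0:
            return np.concatenate([[correct], errs])
    errs = np.clip(rng.normal(mus, err_sd), 0.0, None)
    if errs.sum() == 0:
        errs = np.asarray(err_mean, dtype=float)
    return np.concatenate([[0.0], 100.0 * errs / errs.sum()])


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_patient_cohort(spec: CohortSpec, sim: SimulatedStimuli,
                            cfg: GeneratorConfig) -> list[TrialResponse]:
    """Coded trials for one patient cohort.

    Per subject an error mix is drawn around the cohort moments; each
    trial's outcome is then sampled with item-level correctness modulated
    by ``frequency_effect * (freq_log - mean freq)`` through a logistic
    link. Related responses come from the noun's popularity vector at the
    cohort's dispersion temperature, with light-verb substitution at
    ``light_verb_rate``; not-a-verb responses split into repetitions,
    planted semantic associates ("<noun>kin") and unrelated noun tokens.
    """
    rng = np.random.default_rng(
        [cfg.seed, _STREAM_PATIENTS, zlib.crc32(spec.group.encode())])
    freqs = {s.noun: s.norms.freq_log for s in sim.stimuli}
    freq_mean = float(np.mean(list(freqs.values())))
    nouns = sim.nouns
    trials: list[TrialResponse] = []
    for i in range(spec.n_subjects):
        sid = f"{spec.group.lower()}{i:02d}"
        mix = _draw_error_mix(rng, spec)
        p_correct = np.clip(mix[0] / 100.0, 0.01, 0.99)
        err = mix[1:]
        err_probs = err / err.sum() if err.sum() > 0 else np.array([1 / 3] * 3)
        base_logit = np.log(p_correct / (1 - p_correct))
        for noun in nouns:
            pool = sim.verb_pools[noun]
            probs = sim.popularity[noun] ** (1.0 / spec.dispersion)
            probs = probs / probs.sum()
            p_item = float(_sigmoid(
                base_logit + spec.frequency_effect * (freqs[noun] - freq_mean)))
            for pres in range(1, cfg.presentations + 1):
                rt = _lognormal(rng, spec.rt_mean_s, spec.rt_sd_s)
                if rng.random() < p_item:
                    if rng.random() < spec.light_verb_rate:
                        verb = LIGHT_VERBS[int(rng.integers(len(LIGHT_VERBS)))]
                    else:
                        verb = pool[int(rng.choice(len(pool), p=probs))]
                    trials.append(TrialResponse(
                        sid, spec.group, noun, pres, verb,
                        response_code="related_verb", response_lemma=verb, rt_s=rt))
                    continue
                etype = ("not_a_verb", "unrelated_verb", "missing")[
                    int(rng.choice(3, p=err_probs))]
                if etype == "missing":
                    trials.append(TrialResponse(sid, spec.group, noun, pres, "",
                                                response_code="missing"))
                elif etype == "unrelated_verb":
                    own = set(pool)
                    others = [n for n in nouns if n != noun]
                    while True:
                        other = others[int(rng.integers(len(others)))]
                        candidates = [v for v in sim.verb_pools[other] if v not in own]
                        if candidates:
                            verb = candidates[int(rng.integers(len(candidates)))]
                            break
                    trials.append(TrialResponse(
                        sid, spec.group, noun, pres, verb,
                        response_code="unrelated_verb", response_lemma=verb, rt_s=rt))
                else:
                    u = rng.random()
                    if u < spec.repetition_rate:
                        word = noun
                    elif u < spec.repetition_rate + spec.related_noun_rate:
                        word = f"{noun}kin"
                    else:
                        others = [n for n in nouns if n != noun]
                        word = others[int(rng.integers(len(others)))]
                    trials.append(TrialResponse(
                        sid, spec.group, noun, pres, word,
                        response_code="not_a_verb", response_lemma=word, rt_s=rt))
    return trials


def generate_embeddings(vocab: Sequence[str], cfg: GeneratorConfig,
                        planted_pairs: Sequence[tuple[str, str, float]] = (),
                        ) -> EmbeddingTable:
    """Random unit vectors, with selected word pairs planted at a target
    cosine similarity: ``b = s*a + sqrt(1-s^2)*u`` with ``u`` a unit vector
    orthogonal to ``a``, so the realized cosine equals ``s`` exactly (up
    to float error)."""
    rng = np.random.default_rng([cfg.seed, _STREAM_EMBED])
    d = cfg.embedding_dim
    targets: dict[str, tuple[str, float]] = {}
    for a, b, s in planted_pairs:
        if not -1.0 <= s <= 1.0:
            raise ConfigError(f"target similarity {s} outside [-1, 1]")
        if b in targets and (targets[b][0] != a or targets[b][1] != s):
            raise ConfigError(f"conflicting planted targets for {b!r}")
        targets[b] = (a, s)
    vectors: dict[str, np.ndarray] = {}

    def _unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    for word in vocab:
        if word not in targets:
            vectors[word] = _unit(rng.standard_normal(d))
    for b, (a, s) in targets.items():
        if a not in vectors:
            raise ConfigError(f"planted pair anchor {a!r} not in vocabulary")
        va = vectors[a]
        if abs(s) == 1.0:
            vectors[b] = np.sign(s) * va.copy()
            continue
        noise = rng.standard_normal(d)
        noise -= np.dot(noise, va) * va
        vectors[b] = s * va + np.sqrt(1.0 - s**2) * _unit(noise)
    return EmbeddingTable(dimension=d, vectors=vectors)


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, generated from one seed."""

    config: GeneratorConfig
    specs: dict[str, CohortSpec]
    stimuli: SimulatedStimuli
    trials: list[TrialResponse] = field(repr=False)
    subjects: list[SubjectRecord] = field(repr=False)
    embeddings: EmbeddingTable = field(repr=False)

    @property
    def hc_trials(self) -> list[TrialResponse]:
        return [t for t in self.trials if t.group == "HC"]

    @property
    def patient_trials(self) -> list[TrialResponse]:
        return [t for t in self.trials if t.group != "HC"]


def _neuropsych_scores(rng: np.random.Generator, accuracy_pct: float
                       ) -> dict[str, float]:
    """Toy neuropsych covariates: comprehension tracks task accuracy,
    trails time anti-correlates with it, fluencies are noisy."""
    acc = accuracy_pct / 100.0
    return {
        "single_word_comprehension": float(np.clip(rng.normal(5 + 11 * acc, 1.5), 0, 16)),
        "phonemic_fluency": float(np.clip(rng.normal(4 + 12 * acc, 3.0), 0.5, 30)),
        "semantic_fluency": float(np.clip(rng.normal(4 + 14 * acc, 4.0), 0.5, 35)),
        "trails_total_time": float(np.clip(rng.normal(25 + 90 * (1 - acc), 15.0), 5, 200)),
    }


def generate_dataset(cfg: GeneratorConfig,
                     specs: dict[str, CohortSpec] | None = None,
                     related_similarity_range: tuple[float, float] = (0.4, 0.9),
                     ) -> SimulatedDataset:
    """One complete synthetic study: stimuli, control and patient trials,
    neuropsych covariates, and an embedding table with each noun's "kin"
    associate planted above the relatedness threshold."""
    if specs is None:
        specs = default_cohort_specs()
    sim = generate_stimuli(cfg)
    trials = generate_hc_responses(sim, cfg)
    for spec in specs.values():
        trials.extend(generate_patient_cohort(spec, sim, cfg))

    plant_rng = np.random.default_rng([cfg.seed, _STREAM_EMBED, 1])
    planted = [(noun, f"{noun}kin", float(plant_rng.uniform(*related_similarity_range)))
               for noun in sim.nouns]
    vocab = list(sim.nouns) + [f"{n}kin" for n in sim.nouns]
    embeddings = generate_embeddings(vocab, cfg, planted)

    neuro_rng = np.random.default_rng([cfg.seed, _STREAM_NEURO])
    totals: dict[str, list[int]] = {}
    groups: dict[str, str] = {}
    for t in trials:
        totals.setdefault(t.subject_id, [0, 0])
        totals[t.subject_id][0] += 1
        totals[t.subject_id][1] += int(t.correct)
        groups[t.subject_id] = t.group
    subjects = [
        SubjectRecord(sid, groups[sid],
                      _neuropsych_scores(neuro_rng, 100.0 * c / n))
        for sid, (n, c) in totals.items()
    ]
    return SimulatedDataset(config=cfg, specs=specs, stimuli=sim, trials=trials,
                            subjects=subjects, embeddings=embeddings)


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.tsv",
        "norms": out / "norms.csv",
        "subjects": out / "subjects.csv",
        "embeddings": out / "embeddings.txt",
        "lexicon": out / "lexicon.tsv",
    }
    write_trials(ds.trials, paths["trials"])
    write_stimulus_norms(ds.stimuli.norms(), paths["norms"])
    write_subjects(ds.subjects, paths["subjects"])
    write_embeddings(ds.embeddings, paths["embeddings"])
    write_lexicon(ds.stimuli.lexicon(), paths["lexicon"])
    return paths


def plant_outliers(profiles, subject_ids: Sequence[str], low_pct: float = 5.0):
    """Return profiles with the named subjects' accuracy forced to an
    extreme low value (the difference moved into missing trials, so
    percentage closure still holds) — for exercising the outlier screen."""
    out = []
    for p in profiles:
        if p.subject_id in subject_ids:
            shift = p.pct_correct - low_pct
            out.append(replace(p, pct_correct=low_pct,
                               pct_missing=p.pct_missing + shift))
        else:
            out.append(p)
    return out
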
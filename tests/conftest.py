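"""Shared fixtures: small synthetic datasets and coding rules."""

from __future__ import annotations

import dataclasses

import pytest

import verbgen as vg


def make_trial(sid="s1", group="svPPA", noun="ball", pres=1, raw="", code=None,
               lemma=None, rt=None) -> vg.TrialResponse:
    return vg.TrialResponse(subject_id=sid, group=group, noun=noun,
                            presentation=pres, response_raw=raw,
                            response_code=code, response_lemma=lemma, rt_s=rt)


@pytest.fixture(scope="session")
def ball_rules() -> vg.CodingRules:
    """Small hand-written reference lexicon for coder tests."""
    return vg.CodingRules(reference_lexicon={
        "ball": {"throw", "kick", "hit"},
        "trash": {"take", "throw", "empty"},
        "laundry": {"fold", "wash"},
        "knife": {"cut"},
        "scissor": {"cut"},
        "house": {"live", "build"},
        "cash": {"spend", "get"},
    }, extra_verbs={"eat"})  # caller-supplied verbs extend the verb vocabulary


@pytest.fixture(scope="session")
def tiny_config() -> vg.GeneratorConfig:
    return vg.GeneratorConfig(seed=11, n_nouns=12, n_controls=10)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config) -> vg.SimulatedDataset:
    """A small but complete synthetic study shared across test modules."""
    specs = {g: dataclasses.replace(s, n_subjects=8)
             for g, s in vg.default_cohort_specs().items()}
    return vg.generate_dataset(tiny_config, specs)


@pytest.fixture(scope="session")
def tiny_profiles(tiny_dataset) -> list[vg.SubjectProfile]:
    return vg.subject_profiles(tiny_dataset.trials)
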
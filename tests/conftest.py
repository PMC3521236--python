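import pytest

from isomirkit import pipeline, synthdata


@pytest.fixture(scope="session")
def recovery_study():
    """The full-depth synthetic study used by recovery and conservation tests.

    100,000 reads per library under the default study conditions, analyzed
    end to end once per session.
    """
    cfg = synthdata.study_config(seed=1, n_reads=100_000)
    study = synthdata.generate_paired_study(cfg)
    params = pipeline.AnalysisParams(adapter=cfg.adapter)
    result = pipeline.analyze_study(
        study.reads,
        study.references.hairpins,
        study.references.annotations,
        study.references.reference_sets,
        params,
    )
    return cfg, study, result


@pytest.fixture(scope="session")
def small_study():
    """A light study (8k reads/library) for plumbing-level tests."""
    cfg = synthdata.study_config(seed=7, n_reads=8_000)
    study = synthdata.generate_paired_study(cfg)
    return cfg, study
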
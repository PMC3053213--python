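import numpy as np
import pytest

from tvidex.dataio import ExpressionMatrix, SampleManifest, SampleRecord


def make_record(sample_id, subject_id, group, time_days, timepoint, age=60.0, sex="F"):
    return SampleRecord(sample_id, subject_id, group, time_days, timepoint, age, sex)


@pytest.fixture
def tiny_manifest():
    """3 subjects x up to 3 timepoints, both groups present."""
    recs = []
    layout = [
        ("P1", "ISR", [("BL", 0.0), ("EF", 18.0), ("LF", 182.0)]),
        ("P2", "NO_ISR", [("BL", 0.0), ("EF", 21.0)]),
        ("P3", "NO_ISR", [("BL", 0.0), ("LF", 175.0)]),
    ]
    for subj, group, visits in layout:
        for tp, t in visits:
            recs.append(make_record(f"{subj}_{tp}", subj, group, t, tp))
    return SampleManifest(recs)


@pytest.fixture
def tiny_matrix(tiny_manifest):
    rng = np.random.default_rng(0)
    samples = tiny_manifest.sample_ids
    values = rng.uniform(7, 10, size=(3, len(samples)))
    return ExpressionMatrix(["201222_s_at", "203605_at", "218047_at"], samples, values)


def null_cohort(n_subjects=40, seed=0, n_probes=50, **spec_kw):
    """Convenience: an all-null simulated cohort (manifest, matrix, truth)."""
    from tvidex.synthetic_cohort import (
        CohortDesign,
        SignalSpec,
        simulate_expression,
        simulate_manifest,
    )

    design = CohortDesign(
        n_subjects=n_subjects,
        isr_fraction=1 / 3,
        retention_early=0.7,
        retention_late=0.8,
        exact_counts=True,
    )
    manifest = simulate_manifest(design, seed)
    spec = SignalSpec(n_probes=n_probes, **spec_kw)
    matrix, truth = simulate_expression(manifest, spec, seed + 1)
    return manifest, matrix, truth
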
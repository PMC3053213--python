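"""Synthetic longitudinal cohort generator with per-probe ground truth.

Builds sample manifests emulating two study designs — a three-timepoint
discovery cohort ("cardiogene" template: baseline, early follow-up at 2-4
weeks, late follow-up at 5-7 or ~12 months with nested attrition) and a
two-timepoint replication cohort ("decode" template: baseline plus one
~6-month follow-up) — and expression matrices containing null probes, group
main-effect probes, and group-by-time interaction probes on top of subject
random effects, age/sex covariate effects, and a detection floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    GROUP_ISR,
    GROUP_NOISR,
    ExpressionMatrix,
    SampleManifest,
    SampleRecord,
)
from .errors import ValidationError

PROBE_LABEL_NULL = "null"
PROBE_LABEL_MAIN = "main_effect"
PROBE_LABEL_INTERACTION = "interaction"


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of the simulated longitudinal design."""

    template: str = "custom"
    n_subjects: int = 60
    isr_fraction: float = 1.0 / 6.0
    early_window_days: tuple[float, float] = (14.0, 28.0)
    late_window_days: tuple[float, float] = (150.0, 210.0)
    late_alt_window_days: tuple[float, float] = (350.0, 380.0)
    p_late_at_12mo: float = 0.15
    retention_early: float = 0.65
    retention_late: float = 0.8  # conditional on EF when nest_late_in_early
    nest_late_in_early: bool = True
    exact_counts: bool = False
    age_mean: float = 65.0
    age_sd: float = 10.0
    female_fraction: float = 0.32

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for name in ("isr_fraction", "p_late_at_12mo", "retention_early",
                     "retention_late", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("early_window_days", "late_window_days", "late_alt_window_days"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be a positive interval, got {(lo, hi)}")
        if self.early_window_days[1] >= self.late_window_days[0]:
            raise ValidationError("early and late windows must not overlap")
        if self.late_window_days[1] >= self.late_alt_window_days[0]:
            raise ValidationError("late and alternate-late windows must not overlap")
        if self.age_sd < 0:
            raise ValidationError("age_sd must be >= 0")


#: Discovery-cohort template: 312 subjects at baseline, 203 with early
#: follow-up, 166 with both follow-ups (attrition nested), 52 ISR, 100 female.
CARDIOGENE = CohortDesign(
    template="cardiogene",
    n_subjects=312,
    isr_fraction=52 / 312,
    retention_early=203 / 312,
    retention_late=166 / 203,
    nest_late_in_early=True,
    exact_counts=True,
    p_late_at_12mo=0.15,
    age_mean=65.6,
    age_sd=10.4,
    female_fraction=100 / 312,
)

#: Replication-cohort template: 97 subjects at baseline, 86 with a single
#: ~6-month follow-up, 28 ISR, 19 female.
DECODE = CohortDesign(
    template="decode",
    n_subjects=97,
    isr_fraction=28 / 97,
    retention_early=0.0,
    retention_late=86 / 97,
    nest_late_in_early=False,
    exact_counts=True,
    p_late_at_12mo=0.0,
    age_mean=64.8,
    age_sd=10.0,
    female_fraction=19 / 97,
)

TEMPLATES = {"cardiogene": CARDIOGENE, "decode": DECODE}


def design_from_template(template: str, **overrides) -> CohortDesign:
    if template == "custom":
        return CohortDesign(template="custom", **overrides)
    try:
        base = TEMPLATES[template]
    except KeyError:
        raise ValidationError(f"unknown cohort template {template!r}") from None
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SignalSpec:
    """Per-probe signal structure of the simulated expression matrix.

    Fractions designate probe classes; the remainder are null.  Interaction
    probes diverge linearly from a shared baseline, reaching
    ``delta_interaction`` at the cohort's maximum follow-up time.
    ``beta_age_sd``/``beta_sex_sd`` are the SDs of per-probe covariate
    coefficients drawn from centered normals.  Floor-designated probes are
    generated below the detection threshold ``floor_value``; all values are
    clipped from below at ``floor_value - clip_margin``.
    """

    n_probes: int = 200
    frac_main_effect: float = 0.0
    frac_interaction: float = 0.0
    delta_main: float = 1.0
    delta_interaction: float = 1.0
    sigma_noise: float = 0.5
    sigma_subject: float = 0.3
    beta_age_sd: float = 0.0
    beta_sex_sd: float = 0.0
    mu_range: tuple[float, float] = (7.0, 12.0)
    floor_value: float = 6.0
    frac_floor_probes: float = 0.0
    floor_mu_offset: tuple[float, float] = (-2.0, -1.0)
    clip_margin: float = 2.0
    shared_subject_effect: bool = False

    def validate(self) -> None:
        if self.n_probes < 0:
            raise ValidationError("n_probes must be >= 0")
        fracs = (self.frac_main_effect, self.frac_interaction, self.frac_floor_probes)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValidationError("probe-class fractions must lie in [0, 1]")
        if self.frac_main_effect + self.frac_interaction + self.frac_floor_probes > 1:
            raise ValidationError("probe-class fractions must sum to <= 1")
        if min(self.sigma_noise, self.sigma_subject) < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.clip_margin < 0:
            raise ValidationError("clip_margin must be >= 0")


@dataclass
class GroundTruth:
    """Per-probe generating label and true effect size."""

    probe_ids: list[str]
    labels: list[str]
    deltas: np.ndarray
    floor_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.probe_ids) == len(self.labels) == len(self.deltas)):
            raise ValidationError("ground truth arrays must have equal length")

    def probes_with_label(self, label: str) -> list[str]:
        return [p for p, lab in zip(self.probe_ids, self.labels) if lab == label]


def _pick(rng: np.random.Generator, n: int, fraction: float, exact: bool) -> np.ndarray:
    """Boolean inclusion mask of size n: exact count or per-item Bernoulli."""
    mask = np.zeros(n, dtype=bool)
    if exact:
        k = int(round(fraction * n))
        mask[rng.choice(n, size=k, replace=False)] = True
    else:
        mask = rng.random(n) < fraction
    return mask


def simulate_manifest(design: CohortDesign, seed: int) -> SampleManifest:
    """Draw a manifest from the design; deterministic given the seed.

    Every subject contributes a baseline record at day 0.  Follow-up
    availability follows the retention probabilities (exactly, when
    ``exact_counts``), with late follow-up nested within early follow-up when
    ``nest_late_in_early``.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    width = max(4, len(str(n)))
    subjects = [f"S{i + 1:0{width}d}" for i in range(n)]

    isr = _pick(rng, n, design.isr_fraction, design.exact_counts)
    female = _pick(rng, n, design.female_fraction, design.exact_counts)
    ages = np.clip(rng.normal(design.age_mean, design.age_sd, size=n), 18.0, 95.0)

    has_ef = _pick(rng, n, design.retention_early, design.exact_counts)
    if design.nest_late_in_early:
        ef_idx = np.flatnonzero(has_ef)
        has_lf = np.zeros(n, dtype=bool)
        if ef_idx.size:
            sub = _pick(rng, ef_idx.size, design.retention_late, design.exact_counts)
            has_lf[ef_idx[sub]] = True
    else:
        has_lf = _pick(rng, n, design.retention_late, design.exact_counts)

    ef_times = rng.uniform(*design.early_window_days, size=n)
    lf_main = rng.uniform(*design.late_window_days, size=n)
    lf_alt = rng.uniform(*design.late_alt_window_days, size=n)
    at_12mo = rng.random(n) < design.p_late_at_12mo
    lf_times = np.where(at_12mo, lf_alt, lf_main)

    records = []
    for i, subj in enumerate(subjects):
        group = GROUP_ISR if isr[i] else GROUP_NOISR
        sex = "F" if female[i] else "M"
        age = round(float(ages[i]), 1)
        records.append(
            SampleRecord(f"{subj}_BL", subj, group, 0.0, "BL", age, sex)
        )
        if has_ef[i]:
            records.append(
                SampleRecord(
                    f"{subj}_EF", subj, group, round(float(ef_times[i]), 2), "EF", age, sex
                )
            )
        if has_lf[i]:
            records.append(
                SampleRecord(
                    f"{subj}_LF", subj, group, round(float(lf_times[i]), 2), "LF", age, sex
                )
            )
    return SampleManifest(records)


def simulate_expression(
    manifest: SampleManifest, spec: SignalSpec, seed: int
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a probes x samples log2 matrix with known per-probe truth.

    Value for probe g on sample (i, t):
    ``mu_g + beta_age_g*(age_i - mean age) + beta_sex_g*sex_i + b_ig
    + f_g(group_i, t) + eps`` where ``f_g`` is 0 (null), a constant ISR
    offset (main effect), or a linear-in-time ISR divergence (interaction).
    """
    spec.validate()
    if len(manifest) == 0:
        raise ValidationError("manifest is empty")
    rng = np.random.default_rng(seed)

    n_samples = len(manifest)
    n_probes = spec.n_probes
    probe_ids = [f"{200000 + i}_at" for i in range(n_probes)]

    # class assignment: shuffle probes, slice into main/interaction/floor/null
    order = rng.permutation(n_probes)
    n_main = int(round(spec.frac_main_effect * n_probes))
    n_int = int(round(spec.frac_interaction * n_probes))
    n_floor = int(round(spec.frac_floor_probes * n_probes))
    labels = np.array([PROBE_LABEL_NULL] * n_probes, dtype=object)
    labels[order[:n_main]] = PROBE_LABEL_MAIN
    labels[order[n_main:n_main + n_int]] = PROBE_LABEL_INTERACTION
    floor_mask = np.zeros(n_probes, dtype=bool)
    floor_mask[order[n_main + n_int:n_main + n_int + n_floor]] = True

    deltas = np.zeros(n_probes)
    deltas[labels == PROBE_LABEL_MAIN] = spec.delta_main
    deltas[labels == PROBE_LABEL_INTERACTION] = spec.delta_interaction

    mu = rng.uniform(*spec.mu_range, size=n_probes)
    lo_off, hi_off = spec.floor_mu_offset
    mu[floor_mask] = spec.floor_value + rng.uniform(lo_off, hi_off, size=n_floor)

    beta_age = (
        rng.normal(0.0, spec.beta_age_sd, size=n_probes)
        if spec.beta_age_sd > 0 else np.zeros(n_probes)
    )
    beta_sex = (
        rng.normal(0.0, spec.beta_sex_sd, size=n_probes)
        if spec.beta_sex_sd > 0 else np.zeros(n_probes)
    )

    times = manifest.times()
    t_max = float(times.max()) if times.max() > 0 else 1.0
    is_isr = manifest.groups() == GROUP_ISR
    ages = manifest.ages()
    age_c = ages - ages.mean()
    sex = manifest.sex_codes()

    subjects = manifest.subject_ids
    uniq_subjects = list(dict.fromkeys(subjects))
    subj_index = np.array([uniq_subjects.index(s) for s in subjects])

    if spec.shared_subject_effect:
        b_subj = rng.normal(0.0, spec.sigma_subject, size=len(uniq_subjects))
        b = np.tile(b_subj[subj_index], (n_probes, 1))
    else:
        b = rng.normal(0.0, spec.sigma_subject, size=(n_probes, len(uniq_subjects)))
        b = b[:, subj_index]

    f = np.zeros((n_probes, n_samples))
    f[labels == PROBE_LABEL_MAIN] = spec.delta_main * is_isr
    ramp = (times / t_max) * is_isr
    f[labels == PROBE_LABEL_INTERACTION] = spec.delta_interaction * ramp

    values = (
        mu[:, None]
        + beta_age[:, None] * age_c[None, :]
        + beta_sex[:, None] * sex[None, :]
        + b
        + f
        + rng.normal(0.0, spec.sigma_noise, size=(n_probes, n_samples))
    )
    np.clip(values, spec.floor_value - spec.clip_margin, None, out=values)

    matrix = ExpressionMatrix(probe_ids, manifest.sample_ids, values)
    truth = GroundTruth(
        probe_ids=probe_ids,
        labels=list(labels),
        deltas=deltas,
        floor_probes=[p for p, m in zip(probe_ids, floor_mask) if m],
    )
    return matrix, truth


def ground_truth_table(gt: GroundTruth, path: str | Path) -> None:
    """Write ground truth as TSV ``probe_id, label, delta, is_floor``."""
    floor = set(gt.floor_probes)
    with Path(path).open("w") as fh:
        fh.write("probe_id\tlabel\tdelta\tis_floor\n")
        for probe, label, delta in zip(gt.probe_ids, gt.labels, gt.deltas):
            fh.write(f"{probe}\t{label}\t{delta:.10g}\t{int(probe in floor)}\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    # keep_default_na=False: the literal label "null" must survive parsing
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "label": str},
                     keep_default_na=False)
    return GroundTruth(
        probe_ids=df["probe_id"].tolist(),
        labels=df["label"].tolist(),
        deltas=df["delta"].to_numpy(dtype=float),
        floor_probes=df.loc[df["is_floor"] == 1, "probe_id"].tolist(),
    )
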
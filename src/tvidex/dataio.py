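"""Tabular input/output: expression matrices, sample manifests, annotation, results.

All external tables are plain tab-delimited text.  The expression matrix has a
``probe_id`` first column and one column per sample; the manifest carries the
longitudinal design (subject, group, time in days, timepoint label, age, sex);
annotation files map probes to gene symbols and to category terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

MISSING_TOKEN = "NA"

GROUP_ISR = "ISR"
GROUP_NOISR = "NO_ISR"
_GROUP_ALIASES = {
    "ISR": GROUP_ISR,
    "NO_ISR": GROUP_NOISR,
    "NOISR": GROUP_NOISR,
    "NO-ISR": GROUP_NOISR,
    "NON_ISR": GROUP_NOISR,
    "NONISR": GROUP_NOISR,
}

TIMEPOINTS = ("BL", "EF", "LF")
SEXES = ("F", "M")

RESULT_COLUMNS = (
    "probe",
    "gene",
    "RSS0",
    "RSS1",
    "statistic",
    "p",
    "q",
    "pattern",
    "selected",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probes x samples table of log2 normalized intensities.

    ``values`` is a float array with NaN marking missing entries; row ``i``
    corresponds to ``probe_ids[i]`` and column ``j`` to ``sample_ids[j]``.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.probe_ids)
        if dup is not None:
            raise ValidationError(f"duplicate probe id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample id: {dup!r}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in matrix") from None

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.probe_index(p) for p in probes]
        return ExpressionMatrix(list(probes), list(self.sample_ids), self.values[idx])

    def reorder_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.probe_ids), list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleRecord:
    """One expression profile: a (subject, timepoint) blood draw."""

    sample_id: str
    subject_id: str
    group: str
    time_days: float
    timepoint: str
    age: float
    sex: str

    def __post_init__(self) -> None:
        if self.group not in (GROUP_ISR, GROUP_NOISR):
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown group label {self.group!r}"
            )
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown timepoint {self.timepoint!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"sample {self.sample_id!r}: unknown sex {self.sex!r}")
        if not math.isfinite(self.time_days) or self.time_days < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: time_days must be finite and >= 0"
            )
        if (self.timepoint == "BL") != (self.time_days == 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: time_days == 0 must hold exactly for "
                f"timepoint BL (got {self.timepoint} at day {self.time_days})"
            )


@dataclass
class SampleManifest:
    """Ordered collection of :class:`SampleRecord` defining the design."""

    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_sample: set[str] = set()
        seen_visit: set[tuple[str, str]] = set()
        group_of: dict[str, str] = {}
        for rec in self.records:
            if rec.sample_id in seen_sample:
                raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
            seen_sample.add(rec.sample_id)
            visit = (rec.subject_id, rec.timepoint)
            if visit in seen_visit:
                raise ValidationError(
                    f"subject {rec.subject_id!r} has more than one {rec.timepoint} record"
                )
            seen_visit.add(visit)
            prev = group_of.setdefault(rec.subject_id, rec.group)
            if prev != rec.group:
                raise ValidationError(
                    f"subject {rec.subject_id!r} has inconsistent group labels"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def times(self) -> np.ndarray:
        return np.array([r.time_days for r in self.records], dtype=float)

    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.records], dtype=object)

    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.records], dtype=float)

    def sex_codes(self) -> np.ndarray:
        """Sex as a 0/1 regressor (F=0, M=1)."""
        return np.array([1.0 if r.sex == "M" else 0.0 for r in self.records])

    def subset(self, sample_ids: Iterable[str]) -> "SampleManifest":
        keep = set(sample_ids)
        return SampleManifest([r for r in self.records if r.sample_id in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "subject_id": [r.subject_id for r in self.records],
                "group": [r.group for r in self.records],
                "time_days": [r.time_days for r in self.records],
                "timepoint": [r.timepoint for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )


@dataclass
class AnnotationMap:
    """Probe-level annotation: gene symbols and category terms."""

    probe_to_gene: dict[str, str] = field(default_factory=dict)
    probe_to_terms: dict[str, set[str]] = field(default_factory=dict)

    def gene_terms(self) -> dict[str, set[str]]:
        """Collapse probe-level term annotation to gene symbols."""
        out: dict[str, set[str]] = {}
        for probe, terms in self.probe_to_terms.items():
            gene = self.probe_to_gene.get(probe)
            if gene is None:
                continue
            out.setdefault(gene, set()).update(terms)
        return out


@dataclass
class ManifestSummary:
    n_subjects: int
    n_per_timepoint: dict[str, int]
    n_total_profiles: int
    n_per_group: dict[str, int]
    n_per_sex: dict[str, int]


@dataclass
class ProbeGeneMapping:
    mapped: dict[str, str]
    unmapped: list[str]
    n_distinct_genes: int


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def read_expression_matrix(
    path: str | Path, missing_token: str = MISSING_TOKEN
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column probe id, header = samples)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed table ({exc})") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a probe id column plus sample columns")
    probe_col = df.columns[0]
    probes = df[probe_col].tolist()
    dup = _first_duplicate(probes)
    if dup is not None:
        raise ValidationError(f"{path}: duplicate probe id {dup!r}")
    sample_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        for i, cell in enumerate(col):
            if not isinstance(cell, str):  # pandas fills short rows with float NaN
                raise ParseError(
                    f"{path}: ragged row for probe {probes[i]!r} "
                    f"(missing field in column {sample_ids[j]!r})"
                )
            if cell == missing_token:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at probe {probes[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(probes, sample_ids, values)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, missing_token: str = MISSING_TOKEN
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe, row in zip(matrix.probe_ids, matrix.values):
            cells = [
                missing_token if not math.isfinite(v) else _fmt(v) for v in row
            ]
            fh.write(probe + "\t" + "\t".join(cells) + "\n")


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


_MANIFEST_COLUMNS = ("sample_id", "subject_id", "group", "time_days", "timepoint", "age", "sex")


def normalize_group_label(label: str) -> str:
    key = str(label).strip().upper().replace(" ", "_").replace("-", "_")
    key = key.replace("__", "_")
    canon = _GROUP_ALIASES.get(key) or _GROUP_ALIASES.get(key.replace("_", ""))
    if canon is None:
        raise ValidationError(f"unknown group label {label!r}")
    return canon


def read_sample_manifest(path: str | Path) -> SampleManifest:
    """Read and validate a TSV manifest of sample records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: manifest lacks required column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    subject_id=row["subject_id"],
                    group=normalize_group_label(row["group"]),
                    time_days=float(row["time_days"]),
                    timepoint=str(row["timepoint"]).strip().upper(),
                    age=float(row["age"]),
                    sex=str(row["sex"]).strip().upper(),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    return SampleManifest(records)


def write_sample_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def summarize_manifest(manifest: SampleManifest) -> ManifestSummary:
    """Subject and profile counts; order-independent."""
    per_tp = {tp: 0 for tp in TIMEPOINTS}
    subjects: dict[str, SampleRecord] = {}
    for rec in manifest.records:
        per_tp[rec.timepoint] += 1
        subjects.setdefault(rec.subject_id, rec)
    per_group = {GROUP_ISR: 0, GROUP_NOISR: 0}
    per_sex = {"F": 0, "M": 0}
    for rec in subjects.values():
        per_group[rec.group] += 1
        per_sex[rec.sex] += 1
    return ManifestSummary(
        n_subjects=len(subjects),
        n_per_timepoint=per_tp,
        n_total_profiles=sum(per_tp.values()),
        n_per_group=per_group,
        n_per_sex=per_sex,
    )


def read_annotation(
    gene_path: str | Path | None = None, term_path: str | Path | None = None
) -> AnnotationMap:
    """Read probe→gene and probe→term TSVs (one pair per line, with header)."""
    ann = AnnotationMap()
    if gene_path is not None:
        df = pd.read_csv(gene_path, sep="\t", dtype=str, keep_default_na=False)
        probe_col, gene_col = df.columns[0], df.columns[1]
        ann.probe_to_gene = dict(zip(df[probe_col], df[gene_col]))
    if term_path is not None:
        df = pd.read_csv(term_path, sep="\t", dtype=str, keep_default_na=False)
        probe_col, term_col = df.columns[0], df.columns[1]
        for probe, term in zip(df[probe_col], df[term_col]):
            ann.probe_to_terms.setdefault(probe, set()).add(term)
    return ann


def write_annotation(ann: AnnotationMap, gene_path=None, term_path=None) -> None:
    if gene_path is not None:
        with Path(gene_path).open("w") as fh:
            fh.write("probe_id\tgene_symbol\n")
            for probe in sorted(ann.probe_to_gene):
                fh.write(f"{probe}\t{ann.probe_to_gene[probe]}\n")
    if term_path is not None:
        with Path(term_path).open("w") as fh:
            fh.write("probe_id\tterm_id\n")
            for probe in sorted(ann.probe_to_terms):
                for term in sorted(ann.probe_to_terms[probe]):
                    fh.write(f"{probe}\t{term}\n")


def map_probes_to_genes(
    probes: Sequence[str], ann: AnnotationMap | Mapping[str, str]
) -> ProbeGeneMapping:
    """Map probe ids to gene symbols, reporting unmapped probes separately.

    The distinct-symbol count covers mapped probes only.
    """
    table = ann.probe_to_gene if isinstance(ann, AnnotationMap) else dict(ann)
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for probe in probes:
        gene = table.get(probe)
        if gene is None or gene == "":
            unmapped.append(probe)
        else:
            mapped[probe] = gene
    return ProbeGeneMapping(
        mapped=mapped,
        unmapped=unmapped,
        n_distinct_genes=len(set(mapped.values())),
    )


def write_results_table(results, path: str | Path) -> None:
    """Write per-probe test results as TSV with a stable column order."""
    if results is None:
        raise ValidationError("results must not be None")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.probe_id,
                        r.gene_symbol or "",
                        _fmt(r.rss_null),
                        _fmt(r.rss_alt),
                        _fmt(r.statistic),
                        _fmt(r.p_value),
                        _fmt(r.q_value) if r.q_value is not None else "",
                        r.pattern,
                        "1" if r.selected else "0",
                    ]
                )
                + "\n"
            )


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "gene": str, "pattern": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: results table lacks column(s) {missing}")
    return df
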
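"""Genome-wide scan orchestration: per-probe tests, FDR, patterns, baseline test."""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from .dataio import GROUP_ISR, GROUP_NOISR, ExpressionMatrix, SampleManifest
from .errors import ValidationError
from .tvi_core import SplineBasis, TviFit, TviTester, build_tvi_basis

logger = logging.getLogger(__name__)

PATTERN_CONSISTENT_ISR = "CONSISTENT_ISR_GT"
PATTERN_CONSISTENT_NOISR = "CONSISTENT_NOISR_GT"
PATTERN_DIVERGENT_ISR = "DIVERGENT_ISR_GT"
PATTERN_DIVERGENT_NOISR = "DIVERGENT_NOISR_GT"
PATTERN_UNDETERMINED = "UNDETERMINED"

_ZERO_TOL = 1e-12


@dataclass
class GeneTestResult:
    probe_id: str
    rss_null: float
    rss_alt: float
    statistic: float
    p_value: float
    q_value: float | None = None
    pattern: str = PATTERN_UNDETERMINED
    selected: bool = False
    gene_symbol: str | None = None


@dataclass
class ScanConfig:
    """Configuration of the per-probe time-course scan."""

    degree: int = 1
    knot_policy: str = "median_followup"
    knot: float | None = None
    n_bootstrap: int = 10_000
    scheme: str = "subject_block_residual"
    seed: int = 0
    alpha: float = 0.05
    fdr_method: str = "bh"
    threads: int = 1
    grid_size: int = 101


def probe_seed(master_seed: int, probe_id: str) -> np.random.SeedSequence:
    """Per-probe seed derived from the probe identifier, not its position,
    so that scan results are invariant to probe ordering and to parallel
    execution layout."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(probe_id.encode())])


def fdr_qvalues(p_values, method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values in the input order.

    ``bh``: Benjamini-Hochberg step-up with enforced monotonicity.
    ``storey``: BH-style q-values scaled by a smoother-estimated null
    proportion pi0.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if method not in ("bh", "storey"):
        raise ValidationError(f"unknown FDR method {method!r}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    if method == "storey":
        q = np.clip(_storey_pi0(p) * q, 0.0, 1.0)
    return q


def _storey_pi0(p: np.ndarray) -> float:
    """Null-proportion estimate: quadratic smooth of pi0(lambda) at lambda->max."""
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if p.size < 20:
        return float(np.clip(pi0_l.min(), 1.0 / p.size, 1.0))
    coeffs = np.polyfit(lambdas, pi0_l, deg=2)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(np.clip(pi0, 1.0 / p.size, 1.0))


def select_significant(results, alpha: float = 0.05) -> list[str]:
    """Probes with q strictly below alpha, ordered by (q, probe id)."""
    chosen = [r for r in results if r.q_value is not None and r.q_value < alpha]
    chosen.sort(key=lambda r: (r.q_value, r.probe_id))
    return [r.probe_id for r in chosen]


def classify_pattern(
    fit_isr: TviFit,
    fit_noisr: TviFit,
    basis: SplineBasis,
    grid_size: int = 101,
) -> str:
    """Label the relationship between the two fitted group curves.

    Curves are compared on a uniform grid over the basis domain.  A constant
    nonzero sign of (ISR - non-ISR) everywhere gives a CONSISTENT label with
    that direction; any sign variation (including boundary touches) gives a
    DIVERGENT label directed by the time-averaged difference; identically
    zero difference is UNDETERMINED.
    """
    if fit_isr.basis != basis or fit_noisr.basis != basis:
        raise ValidationError("group fits must share the classification basis")
    grid = np.linspace(basis.domain[0], basis.domain[1], grid_size)
    diff = fit_isr.curve(grid) - fit_noisr.curve(grid)
    signs = np.zeros(diff.size, dtype=int)
    signs[diff > _ZERO_TOL] = 1
    signs[diff < -_ZERO_TOL] = -1
    nonzero = signs[signs != 0]
    if nonzero.size == 0:
        return PATTERN_UNDETERMINED
    if np.all(signs == nonzero[0]):
        return PATTERN_CONSISTENT_ISR if nonzero[0] > 0 else PATTERN_CONSISTENT_NOISR
    mean_diff = float(diff.mean())
    if abs(mean_diff) <= _ZERO_TOL:
        return PATTERN_UNDETERMINED
    return PATTERN_DIVERGENT_ISR if mean_diff > 0 else PATTERN_DIVERGENT_NOISR


def _test_one_probe(
    tester: TviTester,
    basis: SplineBasis,
    matrix_row: np.ndarray,
    probe_id: str,
    times: np.ndarray,
    groups: np.ndarray,
    subjects: list[str],
    config: ScanConfig,
) -> GeneTestResult:
    y = matrix_row
    seed = probe_seed(config.seed, probe_id)
    finite = np.isfinite(y)
    if not finite.all():
        # pairwise-complete slow path: rebuild the tester on observed samples
        if finite.sum() < 3 or len(set(groups[finite])) < 2:
            return GeneTestResult(
                probe_id, float("nan"), float("nan"), float("nan"), 1.0,
                pattern=PATTERN_UNDETERMINED,
            )
        sub_tester = TviTester(
            times[finite],
            groups[finite],
            basis,
            subject_ids=[s for s, f in zip(subjects, finite) if f],
            scheme=config.scheme,
        )
        test = sub_tester.bootstrap(y[finite], config.n_bootstrap, seed)
        fits = sub_tester.group_fits(y[finite])
    else:
        test = tester.bootstrap(y, config.n_bootstrap, seed)
        fits = tester.group_fits(y)
    pattern = classify_pattern(
        fits[GROUP_ISR], fits[GROUP_NOISR], basis, config.grid_size
    )
    return GeneTestResult(
        probe_id=probe_id,
        rss_null=test.rss_null,
        rss_alt=test.rss_alt,
        statistic=test.statistic,
        p_value=test.p_value,
        pattern=pattern,
    )


def run_timecourse_scan(
    matrix: ExpressionMatrix,
    manifest: SampleManifest,
    config: ScanConfig | None = None,
    gene_map: dict[str, str] | None = None,
) -> list[GeneTestResult]:
    """Per-probe RSS-ratio bootstrap tests with FDR adjustment and patterns.

    The spline basis is built once from the manifest's sampling times and
    shared across probes.  Deterministic for a given config seed, independent
    of probe order and of the number of threads.
    """
    config = config or ScanConfig()
    if set(matrix.sample_ids) != set(manifest.sample_ids):
        raise ValidationError("matrix samples do not match manifest samples")
    if matrix.n_probes == 0:
        return []
    mat = matrix.reorder_samples(manifest.sample_ids)
    times = manifest.times()
    groups = manifest.groups()
    subjects = manifest.subject_ids
    basis = build_tvi_basis(
        times, degree=config.degree, knot_policy=config.knot_policy, knot=config.knot
    )
    logger.info(
        "scan: %d probes, %d samples, knot=%.3g days, B=%d",
        mat.n_probes, mat.n_samples, basis.knot_days, config.n_bootstrap,
    )
    tester = TviTester(
        times, groups, basis, subject_ids=subjects, scheme=config.scheme
    )

    def work(i: int) -> GeneTestResult:
        return _test_one_probe(
            tester, basis, mat.values[i], mat.probe_ids[i],
            times, groups, subjects, config,
        )

    if config.threads and config.threads > 1:
        results = Parallel(n_jobs=config.threads, prefer="threads")(
            delayed(work)(i) for i in range(mat.n_probes)
        )
    else:
        results = [work(i) for i in range(mat.n_probes)]

    q = fdr_qvalues([r.p_value for r in results], method=config.fdr_method)
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.selected = qv < config.alpha
        if gene_map is not None:
            r.gene_symbol = gene_map.get(r.probe_id)
    return results


@dataclass
class BaselineResult:
    probe_id: str
    difference: float
    statistic: float
    p_value: float
    q_value: float | None = None


@dataclass
class BaselineComparison:
    results: list[BaselineResult] = field(default_factory=list)
    missing_probes: list[str] = field(default_factory=list)


def baseline_comparison(
    matrix: ExpressionMatrix,
    manifest: SampleManifest,
    probe_list: list[str],
) -> BaselineComparison:
    """Welch two-sample comparison of baseline expression per listed probe.

    The difference reported is mean(ISR) - mean(non-ISR) at baseline;
    p-values are BH-adjusted within the probe list.  Probes absent from the
    matrix are recorded as missing, not fatal.
    """
    bl_ids = [r.sample_id for r in manifest.records if r.timepoint == "BL"]
    bl_groups = np.array(
        [r.group for r in manifest.records if r.timepoint == "BL"], dtype=object
    )
    if not bl_ids:
        raise ValidationError("no baseline samples in manifest")
    if len(set(bl_groups)) < 2:
        raise ValidationError("baseline samples must include both groups")
    mat = matrix.reorder_samples([s for s in bl_ids if s in matrix.sample_ids])
    if mat.n_samples != len(bl_ids):
        raise ValidationError("matrix lacks some baseline samples of the manifest")

    out = BaselineComparison()
    isr_mask = bl_groups == GROUP_ISR
    for probe in probe_list:
        try:
            row = mat.values[mat.probe_index(probe)]
        except KeyError:
            out.missing_probes.append(probe)
            continue
        a = row[isr_mask]
        b = row[~isr_mask]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        diff = float(a.mean() - b.mean())
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            stat, p = (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            stat, p = float(stat), float(p)
        out.results.append(BaselineResult(probe, diff, stat, max(p, 1e-300)))
    if out.results:
        q = fdr_qvalues([r.p_value for r in out.results], method="bh")
        for r, qv in zip(out.results, q):
            r.q_value = float(qv)
    return out
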
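"""Time-varying intercept model: spline basis, nested fits, RSS-ratio test.

The mean expression level is modelled as a piecewise-polynomial function of
days since the intervention with a single interior knot placed at the median
follow-up time.  Under the null hypothesis one curve is fitted to both
outcome groups pooled; under the alternative each group receives its own
curve.  The test statistic is the relative improvement in residual sum of
squares, T = (RSS_null - RSS_alt) / RSS_alt, calibrated by a residual
bootstrap built from the pooled (null) fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

SCHEME_BLOCK = "subject_block_residual"
SCHEME_IID = "iid_residual"

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class SplineBasis:
    """One-interior-knot spline basis on a time domain, degree 0 or 1.

    Degree 0 yields two piecewise-constant indicator functions split at the
    knot (dimension 2); degree 1 yields three piecewise-linear hat functions
    (an overall intercept plus a two-dimensional spline part).  Both
    constructions form a partition of unity with nonnegative entries.
    """

    knot_days: float
    degree: int
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        t0, t1 = self.domain
        if self.degree not in (0, 1):
            raise ValidationError(f"degree must be 0 or 1, got {self.degree}")
        if not t0 < self.knot_days < t1:
            raise ValidationError(
                f"knot {self.knot_days} must lie strictly inside the domain {self.domain}"
            )

    @property
    def dimension(self) -> int:
        return 2 if self.degree == 0 else 3

    def design_matrix(self, times: Sequence[float]) -> np.ndarray:
        """Evaluate the basis at ``times`` -> (n, dimension) design matrix."""
        t = np.asarray(times, dtype=float)
        t0, t1 = self.domain
        if t.size and (t.min() < t0 - 1e-9 or t.max() > t1 + 1e-9):
            raise ValidationError(
                f"times outside basis domain {self.domain}: "
                f"[{t.min()}, {t.max()}]"
            )
        k = self.knot_days
        if self.degree == 0:
            pre = (t < k).astype(float)
            return np.column_stack([pre, 1.0 - pre])
        left = t <= k
        B = np.zeros((t.size, 3))
        B[left, 0] = (k - t[left]) / (k - t0)
        B[left, 1] = (t[left] - t0) / (k - t0)
        B[~left, 1] = (t1 - t[~left]) / (t1 - k)
        B[~left, 2] = (t[~left] - k) / (t1 - k)
        return B


def build_tvi_basis(
    times: Sequence[float],
    degree: int = 1,
    knot_policy: str = "median_followup",
    knot: float | None = None,
) -> SplineBasis:
    """Construct the model basis from the observed sampling times.

    ``knot_policy='median_followup'`` places the single interior knot at the
    median of the strictly positive (follow-up) times; ``'fixed'`` uses the
    supplied ``knot``.
    """
    t = np.asarray(times, dtype=float)
    if np.unique(t).size < 2:
        raise ValidationError("need at least two distinct sampling times")
    t0, t1 = float(t.min()), float(t.max())
    if knot_policy == "median_followup":
        followup = t[t > 0]
        if followup.size == 0:
            raise ValidationError("median_followup knot needs at least one time > 0")
        k = float(np.median(followup))
    elif knot_policy == "fixed":
        if knot is None:
            raise ValidationError("knot_policy='fixed' requires a knot value")
        k = float(knot)
    else:
        raise ValidationError(f"unknown knot_policy {knot_policy!r}")
    if not t0 < k < t1:
        raise ValidationError(
            f"knot {k} lies outside the observed time range ({t0}, {t1})"
        )
    return SplineBasis(knot_days=k, degree=degree, domain=(t0, t1))


@dataclass
class TviFit:
    """Least-squares spline fit for one probe (possibly rank-deficient)."""

    coefficients: np.ndarray
    fitted_values: np.ndarray
    rss: float
    n_obs: int
    rank: int
    basis: SplineBasis | None = None

    def curve(self, grid: Sequence[float]) -> np.ndarray:
        if self.basis is None:
            raise ValidationError("fit carries no basis; cannot evaluate a curve")
        return self.basis.design_matrix(grid) @ self.coefficients


@dataclass
class TviTest:
    rss_null: float
    rss_alt: float
    statistic: float
    p_value: float | None = None
    n_bootstrap: int = 0
    seed: int | None = None
    degenerate: bool = False


def fit_curve(
    y: Sequence[float], times: Sequence[float], basis: SplineBasis
) -> TviFit:
    """Minimum-norm least-squares fit of the spline curve to one probe.

    Rank-deficient designs (e.g. two distinct timepoints under the degree-1
    basis) are permitted; the RSS is invariant to the particular minimum-norm
    solution.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size == 0:
        raise ValidationError("empty input")
    if y.size != t.size:
        raise ValidationError("y and times must have equal length")
    X = basis.design_matrix(t)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return TviFit(
        coefficients=beta,
        fitted_values=fitted,
        rss=rss,
        n_obs=int(y.size),
        rank=int(rank),
        basis=basis,
    )


def _orth(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (SVD with relative tolerance)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return U[:, :0]
    r = int(np.sum(s > _RANK_TOL * s[0]))
    return U[:, :r]


class TviTester:
    """Reusable RSS-ratio tester for a fixed design (times, groups, subjects).

    Precomputes orthonormal column-space bases of the pooled and per-group
    design matrices plus the subject-block structure so that per-probe
    bootstrap p-values reduce to a handful of matrix products.
    """

    def __init__(
        self,
        times: Sequence[float],
        groups: Sequence[str],
        basis: SplineBasis,
        subject_ids: Sequence[str] | None = None,
        scheme: str = SCHEME_BLOCK,
    ):
        self.times = np.asarray(times, dtype=float)
        self.groups = np.asarray(groups, dtype=object)
        self.basis = basis
        self.scheme = scheme
        if scheme not in (SCHEME_BLOCK, SCHEME_IID):
            raise ValidationError(f"unknown bootstrap scheme {scheme!r}")
        self.group_labels = sorted(set(self.groups))
        if len(self.group_labels) < 2:
            raise ValidationError("both groups must be non-empty")
        n = self.times.size
        X = basis.design_matrix(self.times)
        self._U_pool = _orth(X)
        self._masks = [self.groups == g for g in self.group_labels]
        self._U_groups = [_orth(X[m]) for m in self._masks]

        if scheme == SCHEME_BLOCK:
            if subject_ids is None:
                raise ValidationError(
                    "subject_block_residual scheme requires subject identifiers"
                )
            self._blocks = self._build_blocks(list(subject_ids))
        else:
            self._blocks = None
        self.n_obs = n

    def _build_blocks(self, subject_ids: list[str]) -> list[np.ndarray]:
        """Group observation slots into per-subject blocks, then bucket the
        blocks by size so donors always match the recipient's slot count.

        Returns a list of (m_subjects, block_size) index arrays.
        """
        by_subject: dict[str, list[int]] = {}
        for i, s in enumerate(subject_ids):
            by_subject.setdefault(s, []).append(i)
        by_size: dict[int, list[list[int]]] = {}
        for slots in by_subject.values():
            slots = sorted(slots, key=lambda i: self.times[i])
            by_size.setdefault(len(slots), []).append(slots)
        return [np.array(v, dtype=int) for v in by_size.values()]

    # -- core RSS machinery -------------------------------------------------

    def _rss_obs(self, y: np.ndarray, U: np.ndarray) -> float:
        proj = U @ (U.T @ y)
        return float(np.sum((y - proj) ** 2))

    def statistic(self, y: Sequence[float]) -> TviTest:
        """Observed RSS-ratio statistic (no p-value)."""
        y = np.asarray(y, dtype=float)
        if y.size != self.n_obs:
            raise ValidationError("y length does not match the design")
        rss_null = self._rss_obs(y, self._U_pool)
        rss_alt = sum(
            self._rss_obs(y[m], U) for m, U in zip(self._masks, self._U_groups)
        )
        # nesting holds mathematically; guard against roundoff
        rss_alt = min(rss_alt, rss_null)
        if rss_alt == 0.0:
            return TviTest(rss_null, rss_alt, float("inf"), degenerate=True)
        T = (rss_null - rss_alt) / rss_alt
        return TviTest(rss_null, rss_alt, T)

    def _resample_residuals(
        self, resid: np.ndarray, n_boot: int, rng: np.random.Generator
    ) -> np.ndarray:
        n = resid.size
        if self.scheme == SCHEME_IID:
            idx = rng.integers(0, n, size=(n_boot, n))
            return resid[idx]
        E = np.empty((n_boot, n))
        for slots in self._blocks:
            m = slots.shape[0]
            donor = rng.integers(0, m, size=(n_boot, m))
            E[:, slots.reshape(-1)] = resid[slots][donor].reshape(n_boot, -1)
        return E

    def bootstrap(
        self, y: Sequence[float], n_bootstrap: int, seed
    ) -> TviTest:
        """Bootstrap p-value for the RSS-ratio statistic.

        Null resamples are ``fitted_null + resampled residuals`` with group
        labels held fixed; p uses the add-one convention
        ``(1 + #{T* >= T_obs}) / (n_bootstrap + 1)``.
        """
        if n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")
        y = np.asarray(y, dtype=float)
        obs = self.statistic(y)
        rng = np.random.default_rng(seed)

        U = self._U_pool
        fitted = U @ (U.T @ y)
        resid = y - fitted
        E = self._resample_residuals(resid, n_bootstrap, rng)
        Y = fitted[None, :] + E

        sq_total = np.einsum("bi,bi->b", Y, Y)
        proj = Y @ U
        rss_null = sq_total - np.einsum("bi,bi->b", proj, proj)
        rss_alt = np.zeros(n_bootstrap)
        for m, Ug in zip(self._masks, self._U_groups):
            Yg = Y[:, m]
            sq = np.einsum("bi,bi->b", Yg, Yg)
            pg = Yg @ Ug
            rss_alt += sq - np.einsum("bi,bi->b", pg, pg)
        np.clip(rss_null, 0.0, None, out=rss_null)
        np.clip(rss_alt, 0.0, None, out=rss_alt)
        np.minimum(rss_alt, rss_null, out=rss_alt)
        with np.errstate(divide="ignore", invalid="ignore"):
            T = np.where(
                rss_alt > 0, (rss_null - rss_alt) / np.where(rss_alt > 0, rss_alt, 1.0),
                np.inf,
            )
        exceed = int(np.sum(T >= obs.statistic))
        p = (1.0 + exceed) / (n_bootstrap + 1.0)
        seed_repr = seed if isinstance(seed, int) else None
        return TviTest(
            rss_null=obs.rss_null,
            rss_alt=obs.rss_alt,
            statistic=obs.statistic,
            p_value=p,
            n_bootstrap=n_bootstrap,
            seed=seed_repr,
            degenerate=obs.degenerate,
        )

    def group_fits(self, y: Sequence[float]) -> dict[str, TviFit]:
        """Per-group minimum-norm spline fits (for pattern classification)."""
        y = np.asarray(y, dtype=float)
        out = {}
        for g, m in zip(self.group_labels, self._masks):
            out[g] = fit_curve(y[m], self.times[m], self.basis)
        return out


def tvi_statistic(
    y: Sequence[float],
    times: Sequence[float],
    groups: Sequence[str],
    basis: SplineBasis,
) -> TviTest:
    """RSS-ratio statistic: pooled fit vs separate per-group fits."""
    tester = TviTester(times, groups, basis, scheme=SCHEME_IID)
    return tester.statistic(y)


def bootstrap_pvalue(
    y: Sequence[float],
    times: Sequence[float],
    groups: Sequence[str],
    basis: SplineBasis,
    n_bootstrap: int,
    seed,
    scheme: str = SCHEME_BLOCK,
    subject_ids: Sequence[str] | None = None,
) -> TviTest:
    """One-shot bootstrap p-value (see :meth:`TviTester.bootstrap`)."""
    tester = TviTester(times, groups, basis, subject_ids=subject_ids, scheme=scheme)
    return tester.bootstrap(y, n_bootstrap, seed)
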
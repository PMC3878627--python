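"""Seed-match selection, hyperparameter initialization and m/z partitioning.

The alignment model is anchored by a small set of *seed matches*: peptide
sequences confidently identified in every run being aligned.  Averaging
each seed group's coordinates across runs yields "implied" peptide
positions; a robust linear regression of each run's measured coordinates
on the implied positions gives that run's approximate shift and scale,
and the regression residuals calibrate the covariance priors.  Seed
groups stay matched throughout sampling.

Large alignments are split at m/z "deserts" — stretches of the warped
mass-to-charge axis empty over at least five bins of one match standard
deviation — so that splits can be aligned independently without ever
separating features that could plausibly match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .features import FeatureSet, MeasuredFeature

__all__ = [
    "SeedGroup",
    "SeedMatchSet",
    "Hyperparameters",
    "PartitionPlan",
    "InitializationError",
    "select_seed_matches",
    "init_shift_scale_priors",
    "init_covariance_priors",
    "init_hyperparameters",
    "compute_mz_deserts",
]

# discard seed groups with m/z or rt residuals beyond this many robust
# standard deviations (normal-consistent MAD, i.e. MAD * 1.4826)
OUTLIER_MAD_FACTOR = 4.0
MAD_TO_SD = 1.4826
# relative diagonal jitter applied when seed residuals are degenerate
JITTER_SCALE = 1e-6


class InitializationError(ValueError):
    """Seed matches insufficient or degenerate for hyperparameter fitting."""


@dataclass
class SeedGroup:
    sequence: str
    members: tuple[MeasuredFeature, ...]  # exactly one per dataset
    mean_score: float


@dataclass
class SeedMatchSet:
    groups: list[SeedGroup]
    dimension_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.groups)

    def implied_peptides(self) -> np.ndarray:
        """Cross-dataset mean coordinates per group, shape (G, D)."""
        return np.array(
            [
                np.mean([m.coord_vector(self.dimension_names) for m in g.members], axis=0)
                for g in self.groups
            ]
        )

    def member_matrix(self, dataset_index: int) -> np.ndarray:
        """Measured coordinates of each group's member in one dataset, (G, D)."""
        out = []
        for g in self.groups:
            (m,) = [m for m in g.members if m.dataset_index == dataset_index]
            out.append(m.coord_vector(self.dimension_names))
        return np.array(out)


@dataclass
class Hyperparameters:
    """All fixed prior parameters of the alignment model.

    Shapes: shift/scale entries are (n_datasets, D); covariance scales are
    (D, D).  ``alpha`` is the Dirichlet-process concentration, set to the
    total feature count N.  ``a0``/``b0`` parameterize the Gamma prior on
    the exponential rate of the product-ion similarity score.
    """

    a: np.ndarray  # shift prior means
    b: np.ndarray  # shift prior variances
    e: np.ndarray  # scale prior means
    f: np.ndarray  # scale prior variances
    s: np.ndarray  # residual-covariance inverse-Wishart scale
    t: float  # its degrees of freedom
    g: np.ndarray  # latent-covariance inverse-Wishart scale
    h: float  # its degrees of freedom
    lam: np.ndarray  # latent-mean prior mean
    r: np.ndarray  # latent-mean prior covariance
    alpha: float
    a0: float = 1.0
    b0: float = 1.0

    def __post_init__(self) -> None:
        d = len(self.lam)
        if not (np.all(self.b > 0) and np.all(self.f > 0)):
            raise InitializationError("shift/scale prior variances must be > 0")
        if self.t < d or self.h < d:
            raise InitializationError(
                "inverse-Wishart degrees of freedom must be >= dimension count"
            )
        if self.alpha <= 0:
            raise InitializationError("concentration alpha must be > 0")
        # r must be usable as a covariance
        np.linalg.cholesky(self.r)


@dataclass
class PartitionPlan:
    boundaries: np.ndarray  # ordered m/z split points (may be empty)
    memberships: list[list[np.ndarray]] = field(default_factory=list)
    # memberships[split][dataset] = indices into that dataset's feature list

    @property
    def n_splits(self) -> int:
        return len(self.boundaries) + 1


def _common_dims(datasets: Sequence[FeatureSet]) -> tuple[str, ...]:
    dims = set(datasets[0].dimension_names)
    for fs in datasets[1:]:
        dims &= set(fs.dimension_names)
    return tuple(m for m in ("mz", "rt", "drift") if m in dims)


def select_seed_matches(
    datasets: Sequence[FeatureSet],
    n_seeds: int = 15,
    dims: Optional[Sequence[str]] = None,
) -> SeedMatchSet:
    """Pick the top *n_seeds* identifications shared by all datasets.

    A candidate group is one sequence (with one charge state) identified in
    every dataset; if a dataset identifies the sequence more than once its
    highest-scoring feature represents it.  Groups are ranked by mean
    identification score; groups whose m/z or rt residuals (member minus
    group mean) are gross outliers — beyond ``OUTLIER_MAD_FACTOR`` times the
    median absolute deviation of that dimension's residuals — are discarded
    as probable wrong identifications.
    """
    dims = tuple(dims) if dims is not None else _common_dims(datasets)
    # sequence+charge -> dataset -> best-scoring identified feature
    candidates: dict[tuple[str, Optional[int]], dict[int, MeasuredFeature]] = {}
    for d, fs in enumerate(datasets):
        for feat in fs.features:
            if feat.sequence is None:
                continue
            key = (feat.sequence.upper(), feat.charge)
            best = candidates.setdefault(key, {}).get(d)
            score = feat.id_score if feat.id_score is not None else 0.0
            if best is None or score > (best.id_score or 0.0):
                candidates[key][d] = feat

    groups = []
    for (seq, _charge), by_ds in candidates.items():
        if len(by_ds) < len(datasets):
            continue
        members = tuple(by_ds[d] for d in range(len(datasets)))
        scores = [m.id_score for m in members if m.id_score is not None]
        groups.append(
            SeedGroup(sequence=seq, members=members, mean_score=float(np.mean(scores)) if scores else 0.0)
        )
    if not groups:
        raise InitializationError(
            "no identification is shared by all datasets; cannot seed the model"
        )

    groups = _discard_outlier_groups(groups, dims)
    groups.sort(key=lambda grp: (-grp.mean_score, grp.sequence))
    groups = groups[:n_seeds]
    if len(groups) < 3:
        raise InitializationError(
            f"only {len(groups)} usable seed group(s); at least 3 are needed "
            "to fit shift/scale priors"
        )
    return SeedMatchSet(groups=groups, dimension_names=dims)


def _discard_outlier_groups(groups: list[SeedGroup], dims) -> list[SeedGroup]:
    check_dims = [m for m in ("mz", "rt") if m in dims]
    resid = {m: [] for m in check_dims}
    for g in groups:
        coords = np.array([mem.coord_vector(check_dims) for mem in g.members])
        dev = coords - coords.mean(axis=0)
        for k, m in enumerate(check_dims):
            resid[m].append(dev[:, k])
    keep = np.ones(len(groups), dtype=bool)
    for k, m in enumerate(check_dims):
        all_res = np.concatenate(resid[m])
        mad = np.median(np.abs(all_res - np.median(all_res))) * MAD_TO_SD
        if mad <= 0:  # identical replicates: nothing to flag
            continue
        for gi, dev in enumerate(resid[m]):
            if np.any(np.abs(dev - np.median(all_res)) > OUTLIER_MAD_FACTOR * mad):
                keep[gi] = False
    return [g for g, k in zip(groups, keep) if k]


def _robust_line(x: np.ndarray, y: np.ndarray):
    """Bisquare IRLS fit of y = a + e*x; returns (a, e, se_a**2, se_e**2)."""
    if np.ptp(x) == 0:
        raise InitializationError(
            "implied seed coordinates have zero variance; regression is degenerate"
        )
    X = sm.add_constant(x)
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
    a, e = fit.params
    se = fit.bse
    # guard: perfect fits yield zero standard errors; keep priors proper
    floor = JITTER_SCALE * max(1.0, float(np.mean(y**2)))
    return float(a), float(e), max(float(se[0] ** 2), floor), max(float(se[1] ** 2), floor)


def init_shift_scale_priors(
    seeds: SeedMatchSet, n_datasets: int, frozen_scale_dims: Sequence[str] = ()
):
    """Per-dataset, per-dimension shift/scale prior means and variances.

    Robust regression of each dataset's measured seed coordinates on the
    implied (cross-dataset mean) coordinates: intercept -> a_d, slope ->
    e_d, with prior variances set tightly to the squared standard errors.
    Dimensions listed in *frozen_scale_dims* keep their scale fixed at 1.
    """
    if len(seeds) < 3:
        raise InitializationError("need at least 3 seed groups")
    implied = seeds.implied_peptides()
    D = len(seeds.dimension_names)
    a = np.zeros((n_datasets, D))
    b = np.zeros((n_datasets, D))
    e = np.ones((n_datasets, D))
    f = np.zeros((n_datasets, D))
    for d in range(n_datasets):
        measured = seeds.member_matrix(d)
        for k, dim in enumerate(seeds.dimension_names):
            a_dk, e_dk, var_a, var_e = _robust_line(implied[:, k], measured[:, k])
            if dim in frozen_scale_dims:
                # re-fit shift only, with slope pinned to 1
                resid = measured[:, k] - implied[:, k]
                a_dk, e_dk = float(np.median(resid)), 1.0
                var_a = max(
                    float(np.var(resid, ddof=1) / len(resid)),
                    JITTER_SCALE * max(1.0, float(np.mean(measured[:, k] ** 2))),
                )
                var_e = JITTER_SCALE
            a[d, k], e[d, k], b[d, k], f[d, k] = a_dk, e_dk, var_a, var_e
    return a, b, e, f


def init_covariance_priors(seeds: SeedMatchSet, warp) -> tuple:
    """Inverse-Wishart and latent-mean prior settings from seed residuals.

    Degrees of freedom t = h = (#seed groups - 1); scale matrices are the
    summed outer products of de-warped seed residuals (measured coordinates
    mapped back through the fitted shift/scale, minus the implied peptide).
    Degenerate (all-zero) residual accumulations receive a small diagonal
    jitter to keep the priors proper.
    """
    a, _b, e, _f = warp
    implied = seeds.implied_peptides()
    G, D = implied.shape
    S = np.zeros((D, D))
    n_datasets = a.shape[0]
    for d in range(n_datasets):
        measured = seeds.member_matrix(d)
        dewarped = (measured - a[d]) / e[d]
        resid = dewarped - implied
        S += resid.T @ resid
    mean_sq = np.mean(implied**2, axis=0)
    if np.trace(S) <= 0 or np.linalg.matrix_rank(S) < D:
        S = S + JITTER_SCALE * np.diag(np.maximum(mean_sq, 1.0))
    t = h = float(max(G - 1, D))
    return S.copy(), t, S.copy(), h


def init_hyperparameters(
    datasets: Sequence[FeatureSet],
    seeds: SeedMatchSet,
    frozen_scale_dims: Sequence[str] = (),
    a0: float = 1.0,
    b0: float = 1.0,
) -> Hyperparameters:
    """Full hyperparameter initialization from seed matches.

    The latent-mean prior is centred at the empirical mean of all measured
    coordinates with covariance equal to the summed squared deviations from
    that mean (a deliberately diffuse prior), and the DP concentration is
    set to the total number of features N.
    """
    dims = seeds.dimension_names
    warp = init_shift_scale_priors(seeds, len(datasets), frozen_scale_dims)
    s, t, g, h = init_covariance_priors(seeds, warp)
    allX = np.vstack([fs.coord_matrix(dims) for fs in datasets])
    lam = allX.mean(axis=0)
    dev = allX - lam
    r = dev.T @ dev
    if np.linalg.matrix_rank(r) < len(dims):
        r = r + JITTER_SCALE * np.eye(len(dims)) * max(1.0, float(np.mean(allX**2)))
    return Hyperparameters(
        a=warp[0], b=warp[1], e=warp[2], f=warp[3],
        s=s, t=t, g=g, h=h, lam=lam, r=r,
        alpha=float(len(allX)), a0=a0, b0=b0,
    )


def seed_match_sd(seeds: SeedMatchSet, warp, dim: str = "mz") -> float:
    """Standard deviation of de-warped seed residuals in one dimension."""
    a, _b, e, _f = warp
    k = seeds.dimension_names.index(dim)
    implied = seeds.implied_peptides()
    res = []
    for d in range(a.shape[0]):
        measured = seeds.member_matrix(d)
        res.append((measured[:, k] - a[d, k]) / e[d, k] - implied[:, k])
    res = np.concatenate(res)
    return float(np.std(res, ddof=1))


def find_deserts(values: np.ndarray, bin_width: float, min_run: int) -> list[float]:
    """Midpoints of maximal runs of >= *min_run* consecutive empty bins.

    Bins of *bin_width* span the value range; runs touching the range ends
    are ignored (a boundary there would not separate anything).
    """
    if len(values) == 0 or bin_width <= 0:
        return []
    lo, hi = float(np.min(values)), float(np.max(values))
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    deserts = []
    run_start = None
    for i, c in enumerate(list(counts) + [1]):  # sentinel closes final run
        if c == 0 and run_start is None:
            run_start = i
        elif c != 0 and run_start is not None:
            run_len = i - run_start
            interior = run_start > 0 and i < len(counts)
            if run_len >= min_run and interior:
                deserts.append(0.5 * (edges[run_start] + edges[i]))
            run_start = None
    return deserts


def compute_mz_deserts(
    datasets: Sequence[FeatureSet],
    seeds: SeedMatchSet,
    warp=None,
    max_splits: int = 250,
    min_run: int = 5,
) -> PartitionPlan:
    """Partition features at m/z deserts of the approximately de-warped data.

    All datasets' m/z values, de-warped by the seed-derived approximate
    shift/scale, are histogrammed in bins one match standard deviation
    wide; runs of >= *min_run* empty bins are deserts and a split boundary
    is placed at each desert midpoint.  If more than *max_splits* splits
    would result, only the boundaries of the widest deserts are kept.
    """
    if warp is None:
        warp = init_shift_scale_priors(seeds, len(datasets))
    sd = seed_match_sd(seeds, warp, "mz")
    if sd <= 0:
        raise InitializationError("m/z match standard deviation must be > 0")
    k = seeds.dimension_names.index("mz")
    a, _b, e, _f = warp
    warped = [
        (fs.coord_matrix(("mz",))[:, 0] - a[d, k]) / e[d, k]
        for d, fs in enumerate(datasets)
    ]
    allmz = np.concatenate(warped) if warped else np.array([])

    deserts = find_deserts(allmz, sd, min_run)
    boundaries = np.array(sorted(deserts))
    if len(boundaries) + 1 > max_splits:
        # rank deserts by their margin to the nearest feature, keep widest
        n_keep = max_splits - 1
        if n_keep <= 0:
            boundaries = np.array([])
        else:
            margins = [np.min(np.abs(allmz - bnd)) for bnd in boundaries]
            keep = np.argsort(margins)[-n_keep:]
            boundaries = np.sort(boundaries[np.sort(keep)])

    memberships = []
    edges = np.concatenate(([-np.inf], boundaries, [np.inf]))
    for si in range(len(edges) - 1):
        per_ds = []
        for d in range(len(datasets)):
            w = warped[d]
            per_ds.append(np.flatnonzero((w > edges[si]) & (w <= edges[si + 1])))
        memberships.append(per_ds)
    return PartitionPlan(boundaries=boundaries, memberships=memberships)
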
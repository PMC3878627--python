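"""Product-ion intensity profiles and their exponential similarity model.

Each feature's fragment spectrum is reduced to its (at most) 50 most
intense product ions and binned over K fixed fragment-m/z bins whose
upper limits sit, where possible, in fragment-m/z deserts.  The binned
intensities are normalized to sum to one, so the profile is invariant to
uniform intensity rescaling.  Two profiles are compared by the sum of
squared differences psi, modelled as Exponential(gamma) with a conjugate
Gamma(a0, b0) prior on the rate — small distances are rewarded, and the
rate adapts to the typical within-peptide profile variability.

A latent peptide's profile is the elementwise mean of its members'
profiles; a peptide with no fragment evidence carries the *blank*
profile, uniform at 1/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import FeatureSet
from .preprocess import SeedMatchSet, find_deserts

__all__ = [
    "ProfileBins",
    "determine_profile_bins",
    "compute_profile",
    "blank_profile",
    "profile_similarity",
    "update_latent_profile",
    "sample_gamma_rate",
]

TOP_N_FRAGMENTS = 50
DEFAULT_K = 250
#: minimum run of empty sd-width bins that counts as a fragment-m/z desert
DESERT_MIN_RUN = 3


@dataclass
class ProfileBins:
    """K ordered fragment-m/z bin upper limits; bin k is (B[k-1], B[k]]."""

    upper_limits: np.ndarray
    lower_edge: float  # lower edge of bin 1

    def __post_init__(self) -> None:
        b = np.asarray(self.upper_limits, dtype=float)
        if b.ndim != 1 or len(b) < 1:
            raise ValueError("need at least one bin")
        if np.any(np.diff(b) <= 0):
            raise ValueError("bin upper limits must be strictly increasing")
        self.upper_limits = b

    @property
    def K(self) -> int:
        return len(self.upper_limits)


def blank_profile(K: int) -> np.ndarray:
    return np.full(K, 1.0 / K)


def _seed_fragment_sd(datasets: Sequence[FeatureSet], seeds: SeedMatchSet) -> float:
    """Fragment-m/z match standard deviation from seed groups.

    Within each seed group, each member's top fragments are matched to the
    nearest fragment of the group's first member; the sd of those nearest-
    neighbour differences estimates fragment m/z reproducibility.
    """
    diffs = []
    for g in seeds.groups:
        ref = sorted(g.members[0].fragments, key=lambda f: -f[1])[:TOP_N_FRAGMENTS]
        if not ref:
            continue
        ref_mz = np.sort([m for m, _ in ref])
        for other in g.members[1:]:
            top = sorted(other.fragments, key=lambda f: -f[1])[:TOP_N_FRAGMENTS]
            for mz, _ in top:
                j = np.searchsorted(ref_mz, mz)
                cand = [ref_mz[k] for k in (j - 1, j) if 0 <= k < len(ref_mz)]
                if cand:
                    diffs.append(min((mz - c for c in cand), key=abs))
    if len(diffs) < 2:
        return 0.0
    return float(np.std(diffs, ddof=1))


def determine_profile_bins(
    datasets: Sequence[FeatureSet],
    seeds: SeedMatchSet | None = None,
    K: int = DEFAULT_K,
) -> ProfileBins:
    """Choose K bin upper limits spanning the observed fragment m/z range.

    Ideal limits are equally spaced at 1/K of the spanning range; each
    interior limit is moved to the nearest fragment-m/z desert (a run of
    >= 3 empty bins of one fragment match-sd width).  When there are too
    few deserts (or no seed fragment data), equal-width limits are used.
    """
    frag_mz = np.array(
        [mz for fs in datasets for f in fs.features for mz, _ in f.fragments]
    )
    if len(frag_mz) == 0:
        raise ValueError("no fragment data present in any dataset")
    lo, hi = float(frag_mz.min()), float(frag_mz.max())
    ideal = lo + (hi - lo) * np.arange(1, K + 1) / K
    if K == 1:
        return ProfileBins(upper_limits=np.array([hi]), lower_edge=lo)

    sd = _seed_fragment_sd(datasets, seeds) if seeds is not None else 0.0
    deserts = np.array(find_deserts(frag_mz, sd, DESERT_MIN_RUN)) if sd > 0 else np.array([])

    limits = ideal.copy()
    if len(deserts) < K - 1:
        warnings.warn(
            f"only {len(deserts)} fragment-m/z deserts for {K} bins; "
            "using equal-width bin limits",
            stacklevel=2,
        )
    if len(deserts) >= K - 1:
        used = np.zeros(len(deserts), dtype=bool)
        for i in range(K - 1):  # last limit stays at the range top
            order = np.argsort(np.abs(deserts - ideal[i]))
            for j in order:
                if not used[j]:
                    limits[i] = deserts[j]
                    used[j] = True
                    break
        limits[:-1] = np.sort(limits[:-1])
        if np.any(np.diff(limits) <= 0):  # desert snap collapsed bins
            limits = ideal.copy()
    return ProfileBins(upper_limits=limits, lower_edge=lo)


def top_fragments(
    fragments: Sequence[tuple[float, float]], n: int = TOP_N_FRAGMENTS
) -> list[tuple[float, float]]:
    """The n most intense fragments; intensity ties broken by lower m/z."""
    return sorted(fragments, key=lambda f: (-f[1], f[0]))[:n]


def compute_profile(
    fragments: Sequence[tuple[float, float]],
    bins: ProfileBins,
    top_n: int = TOP_N_FRAGMENTS,
) -> np.ndarray:
    """K-vector of binned, normalized product-ion intensities.

    Intensities of the <= *top_n* most intense fragments are summed per
    half-open bin (B[k-1], B[k]] and divided by the total retained
    intensity.  An empty fragment list yields the blank profile.
    Fragments below the first bin's lower edge fall in bin 1; fragments
    above the last limit are clipped into bin K.
    """
    if len(fragments) == 0:
        return blank_profile(bins.K)
    kept = top_fragments(fragments, top_n)
    mz = np.array([m for m, _ in kept])
    inten = np.array([i for _, i in kept])
    # bin k has upper limit B[k]; searchsorted with side='left' makes the
    # interval half-open on the left: m in (B[k-1], B[k]] -> k
    idx = np.searchsorted(bins.upper_limits, mz, side="left")
    idx = np.minimum(idx, bins.K - 1)
    prof = np.bincount(idx, weights=inten, minlength=bins.K)
    return prof / prof.sum()


def profile_similarity(y: np.ndarray, w: np.ndarray) -> float:
    """psi = sum of squared differences; in [0, 2] for normalized profiles."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.shape != w.shape:
        raise ValueError(f"profile length mismatch: {y.shape} vs {w.shape}")
    d = y - w
    return float(d @ d)


def update_latent_profile(member_profiles: Sequence[np.ndarray], K: int) -> np.ndarray:
    """Elementwise mean of member profiles; blank profile if no members."""
    if len(member_profiles) == 0:
        return blank_profile(K)
    return np.mean(np.asarray(member_profiles, dtype=float), axis=0)


def sample_gamma_rate(
    scores: Sequence[float],
    prior: tuple[float, float] = (1.0, 1.0),
    rng: np.random.Generator | None = None,
) -> float:
    """Draw the exponential rate gamma from its conjugate Gamma posterior.

    With n observed scores summing to S, the posterior is
    Gamma(a0 + n, b0 + S) in the shape/rate parameterization.
    """
    a0, b0 = prior
    if a0 <= 0 or b0 <= 0:
        raise ValueError("gamma prior hyperparameters must be > 0")
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0):
        raise ValueError("similarity scores must be nonnegative")
    rng = np.random.default_rng() if rng is None else rng
    shape = a0 + len(scores)
    rate = b0 + float(scores.sum())
    return float(rng.gamma(shape, 1.0 / rate))
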
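"""Collapsed Gibbs sampler for the shift/scale Dirichlet-process GMM.

The model: each measured feature x_{d,i} (m/z, rt and optionally drift
time) is a per-dataset linear warp of a latent peptide value,

    x_{d,i} = eta_d + z_{c_{d,i}} * beta_d + eps_{d,i},
    eps ~ N(0, Sigma),   z_j ~ N(mu_j, sigma),   mu_j ~ N(lambda, r),

with a Chinese-restaurant-process prior over the assignment indicators
c_{d,i} and the constraint that a latent peptide holds at most one
measurement per dataset.  The per-measurement latent value z is always
integrated out, so the likelihood of x under component j is

    N(x | eta_d + mu_j * beta_d,  B_d),   B_d = diag(beta_d) sigma diag(beta_d) + Sigma,

and the birth (new-component) weight uses the further marginal over mu.
When fragment data are present every assignment weight also carries an
Exponential(gamma) factor on the profile distance psi.

Fitting runs burn-in sweeps at temperature T=1 followed by simulated
annealing (assignment probabilities raised to 1/T; parameter full
conditionals sharpened the same way), returning the final low-temperature
state as the MAP estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.stats import invwishart

from .features import FeatureSet
from .preprocess import Hyperparameters, SeedMatchSet
from .profiles import ProfileBins, blank_profile, compute_profile

__all__ = [
    "AlignmentData",
    "ModelState",
    "SamplerConfig",
    "likelihood_existing",
    "likelihood_new",
    "crp_weights",
    "sample_assignment",
    "update_latent_means",
    "update_shift_scale",
    "update_covariances",
    "update_gamma_rate",
    "run_mcmc",
]

LOG2PI = float(np.log(2.0 * np.pi))


class NumericalStateError(RuntimeError):
    """A covariance in the sampler state stopped being positive definite."""


class ConfigError(ValueError):
    pass


@dataclass
class SamplerConfig:
    """Fitting controls (see docs/methods.md for the reasoning).

    burn_in sweeps run at T=1; anneal_sweeps follow with T_k =
    max(anneal_rate**k, t_min).  The boolean flags allow freezing blocks
    of parameters at their current values (used for diagnostics and for
    assignment-only resampling).
    """

    burn_in: int = 200
    anneal_sweeps: int = 200
    anneal_rate: float = 0.95
    t_min: float = 0.05
    temper_parameters: bool = True
    sample_warp: bool = True
    sample_covariances: bool = True
    sample_latent_means: bool = True
    sample_gamma: bool = True

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.anneal_sweeps < 0:
            raise ConfigError("sweep counts must be nonnegative")
        if not (0 < self.anneal_rate < 1):
            raise ConfigError("anneal_rate must be in (0, 1)")
        if not (0 < self.t_min <= 1):
            raise ConfigError("t_min must be in (0, 1]")


@dataclass
class AlignmentData:
    """Flattened view of all datasets' features for the sampler."""

    X: np.ndarray  # (N, D) coordinates
    ds: np.ndarray  # (N,) dataset index
    dims: tuple[str, ...]
    n_datasets: int
    dataset_labels: list[str]
    feature_ids: np.ndarray  # (N,) feature_index within its dataset
    Y: Optional[np.ndarray] = None  # (N, K) measured profiles, or None
    bins: Optional[ProfileBins] = None

    @property
    def N(self) -> int:
        return len(self.X)

    @property
    def D(self) -> int:
        return self.X.shape[1]

    @property
    def use_fragments(self) -> bool:
        return self.Y is not None

    def key(self, i: int) -> tuple[str, int]:
        return (self.dataset_labels[self.ds[i]], int(self.feature_ids[i]))


def build_data(
    datasets: Sequence[FeatureSet],
    dims: Sequence[str],
    bins: Optional[ProfileBins] = None,
    subset: Optional[Sequence[np.ndarray]] = None,
) -> AlignmentData:
    """Assemble sampler input from FeatureSets.

    *subset*, when given, selects per-dataset feature positions (as from a
    PartitionPlan split).  With *bins*, each feature's fragment spectrum
    is turned into a normalized profile; features without fragments get
    the blank profile.
    """
    dims = tuple(dims)
    rows, dsi, fids, profs = [], [], [], []
    for d, fs in enumerate(datasets):
        positions = subset[d] if subset is not None else range(len(fs.features))
        for pos in positions:
            f = fs.features[pos]
            rows.append(f.coord_vector(dims))
            dsi.append(d)
            fids.append(f.feature_index)
            if bins is not None:
                profs.append(compute_profile(f.fragments, bins))
    X = np.array(rows) if rows else np.empty((0, len(dims)))
    return AlignmentData(
        X=X,
        ds=np.array(dsi, dtype=np.intp),
        dims=dims,
        n_datasets=len(datasets),
        dataset_labels=[fs.dataset_label for fs in datasets],
        feature_ids=np.array(fids, dtype=np.intp),
        Y=np.array(profs) if bins is not None else None,
        bins=bins,
    )


class ModelState:
    """All current parameter values plus the component bookkeeping.

    Components live in growable arrays: ``mu`` (means), ``members``
    (feature row per dataset, -1 when vacant), ``counts``, ``active``,
    and, with fragments, ``prof_sum`` so that a component's profile
    w_j = prof_sum_j / counts_j is always the mean of its members'
    measured profiles.
    """

    def __init__(
        self,
        data: AlignmentData,
        hp: Hyperparameters,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.data = data
        self.hp = hp
        D = data.D
        # initialize parameters at their prior centres
        self.eta = hp.a.copy()
        self.beta = hp.e.copy()
        self.Sigma = hp.s / max(hp.t - D - 1.0, hp.t)
        self.sigma_lat = hp.g / max(hp.h - D - 1.0, hp.h)
        self.gamma = hp.a0 / hp.b0
        self.T = 1.0

        cap = 64
        self.mu = np.zeros((cap, D))
        self.members = np.full((cap, data.n_datasets), -1, dtype=np.intp)
        self.counts = np.zeros(cap, dtype=np.intp)
        self.active = np.zeros(cap, dtype=bool)
        self.frozen_comp = np.zeros(cap, dtype=bool)
        if data.use_fragments:
            self.prof_sum = np.zeros((cap, data.Y.shape[1]))
        else:
            self.prof_sum = None
        self.c = np.full(data.N, -1, dtype=np.intp)
        self.frozen_feat = np.zeros(data.N, dtype=bool)
        #: when set (assignment-only mode), component profiles are read from
        #: this (cap, K) array instead of the live member averages
        self.frozen_profiles: Optional[np.ndarray] = None
        #: (eta, beta) draws recorded over the second half of burn-in; their
        #: spread estimates the marginal posterior sd of the warp at T=1
        self.warp_trace: list[tuple[np.ndarray, np.ndarray]] = []
        self._free: list[int] = list(range(cap - 1, -1, -1))
        self._rng = rng
        self._caches_stale = True

    # -- component bookkeeping ------------------------------------------

    def _grow(self) -> None:
        old = len(self.active)
        new = old * 2
        self.mu = np.vstack([self.mu, np.zeros((old, self.data.D))])
        self.members = np.vstack(
            [self.members, np.full((old, self.data.n_datasets), -1, dtype=np.intp)]
        )
        self.counts = np.concatenate([self.counts, np.zeros(old, dtype=np.intp)])
        self.active = np.concatenate([self.active, np.zeros(old, dtype=bool)])
        self.frozen_comp = np.concatenate(
            [self.frozen_comp, np.zeros(old, dtype=bool)]
        )
        if self.prof_sum is not None:
            self.prof_sum = np.vstack(
                [self.prof_sum, np.zeros((old, self.prof_sum.shape[1]))]
            )
        self._free.extend(range(new - 1, old - 1, -1))

    def new_component(self, mu: np.ndarray, frozen: bool = False) -> int:
        if not self._free:
            self._grow()
        j = self._free.pop()
        self.mu[j] = mu
        self.members[j] = -1
        self.counts[j] = 0
        self.active[j] = True
        self.frozen_comp[j] = frozen
        if self.prof_sum is not None:
            self.prof_sum[j] = 0.0
        return j

    def drop_component(self, j: int) -> None:
        self.active[j] = False
        self._free.append(j)

    def active_components(self) -> np.ndarray:
        return np.flatnonzero(self.active)

    def add_member(self, i: int, j: int) -> None:
        d = self.data.ds[i]
        if self.members[j, d] >= 0:
            raise NumericalStateError(
                f"component {j} already holds a feature of dataset {d}"
            )
        self.members[j, d] = i
        self.counts[j] += 1
        self.c[i] = j
        if self.prof_sum is not None:
            self.prof_sum[j] += self.data.Y[i]

    def remove_member(self, i: int, drop_if_empty: bool = True) -> None:
        j = self.c[i]
        if j < 0:
            return
        d = self.data.ds[i]
        self.members[j, d] = -1
        self.counts[j] -= 1
        self.c[i] = -1
        if self.prof_sum is not None:
            self.prof_sum[j] -= self.data.Y[i]
        if self.counts[j] == 0 and drop_if_empty:
            self.drop_component(j)

    def component_profile(self, j: int) -> np.ndarray:
        if self.prof_sum is None:
            raise ValueError("fragments are not enabled")
        if self.counts[j] == 0:
            return blank_profile(self.prof_sum.shape[1])
        return self.prof_sum[j] / self.counts[j]

    # -- per-dataset Gaussian caches ------------------------------------

    def refresh_caches(self) -> None:
        """(Re)build Cholesky factors of B_d and the birth covariance."""
        D = self.data.D
        self._chol_B, self._logdet_B = [], []
        self._chol_Bnew, self._logdet_Bnew = [], []
        self._mean_new = []
        self._P = []  # diag(beta) B^-1 diag(beta), for mu conditionals
        for d in range(self.data.n_datasets):
            Db = np.diag(self.beta[d])
            B = Db @ self.sigma_lat @ Db + self.Sigma
            Bnew = Db @ (self.sigma_lat + self.hp.r) @ Db + self.Sigma
            try:
                L = np.linalg.cholesky(B)
                Ln = np.linalg.cholesky(Bnew)
            except np.linalg.LinAlgError as exc:
                raise NumericalStateError(
                    f"B_d not positive definite for dataset {d}"
                ) from exc
            self._chol_B.append(L)
            self._logdet_B.append(2.0 * float(np.sum(np.log(np.diag(L)))))
            self._chol_Bnew.append(Ln)
            self._logdet_Bnew.append(2.0 * float(np.sum(np.log(np.diag(Ln)))))
            self._mean_new.append(self.eta[d] + self.beta[d] * self.hp.lam)
            Binv = cho_solve((L, True), np.eye(D))
            self._P.append(Db @ Binv @ Db)
        self._caches_stale = False

    def _require_caches(self) -> None:
        if self._caches_stale:
            self.refresh_caches()

    # -- log densities ---------------------------------------------------

    def loglik_existing_many(self, i: int, comp_idx: np.ndarray) -> np.ndarray:
        """log N(x_i | eta_d + mu_j beta_d, B_d) for each j in comp_idx."""
        self._require_caches()
        d = self.data.ds[i]
        A = self.eta[d] + self.mu[comp_idx] * self.beta[d]
        diff = self.data.X[i] - A  # (J, D)
        sol = solve_triangular(self._chol_B[d], diff.T, lower=True)
        quad = np.sum(sol**2, axis=0)
        return -0.5 * (self.data.D * LOG2PI + self._logdet_B[d] + quad)

    def loglik_new_one(self, i: int) -> float:
        """Closed-form marginal over mu: log N(x | eta + lam*beta, beta(sigma+r)beta + Sigma)."""
        self._require_caches()
        d = self.data.ds[i]
        diff = self.data.X[i] - self._mean_new[d]
        sol = solve_triangular(self._chol_Bnew[d], diff, lower=True)
        return float(
            -0.5 * (self.data.D * LOG2PI + self._logdet_Bnew[d] + sol @ sol)
        )


# -- spec-level operations (thin functional wrappers) ---------------------


def likelihood_existing(state: ModelState, i: int, j: int) -> float:
    """Log density of feature *i* under existing component *j* (z collapsed)."""
    return float(state.loglik_existing_many(i, np.array([j]))[0])


def likelihood_new(state: ModelState, i: int) -> float:
    """Log marginal density of feature *i* under a brand-new component."""
    return state.loglik_new_one(i)


def crp_weights(state: ModelState, i: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Constrained CRP prior weights for feature *i*.

    Returns (component indices, their weights n_j/(N-1+alpha) with the
    one-per-dataset indicator applied, weight for a new component
    alpha/(N-1+alpha)).  Feature *i* must currently be unassigned.
    """
    act = state.active_components()
    denom = state.data.N - 1 + state.hp.alpha
    w = state.counts[act] / denom
    blocked = state.members[act, state.data.ds[i]] >= 0
    w = np.where(blocked, 0.0, w)
    return act, w, state.hp.alpha / denom


def _gumbelless_choice(rng: np.random.Generator, logw: np.ndarray) -> int:
    m = np.max(logw)
    p = np.exp(logw - m)
    p_sum = p.sum()
    u = rng.random() * p_sum
    return int(np.searchsorted(np.cumsum(p), u, side="right").clip(0, len(p) - 1))


def _draw_mu_birth(state: ModelState, i: int, rng: np.random.Generator) -> np.ndarray:
    """mu for a newborn component, from its conditional given member i."""
    hp = state.hp
    d = state.data.ds[i]
    rinv = np.linalg.inv(hp.r)
    prec = rinv + state._P[d]
    L = np.linalg.cholesky(prec)
    Db = np.diag(state.beta[d])
    Binv_dx = cho_solve(
        (state._chol_B[d], True), state.data.X[i] - state.eta[d]
    )
    rhs = rinv @ hp.lam + Db @ Binv_dx
    mean = cho_solve((L, True), rhs)
    eps = rng.standard_normal(state.data.D)
    dev = solve_triangular(L, eps, lower=True, trans="T") * np.sqrt(state.T)
    return mean + dev


def sample_assignment(
    state: ModelState,
    i: int,
    rng: np.random.Generator,
    tally: Optional[dict] = None,
    allow_birth_instantiation: bool = True,
) -> int:
    """Gibbs update of c_i from its full conditional at temperature state.T.

    Feature *i* must have been removed from its component first.  Returns
    the chosen component index, or -1 when "new" is drawn and
    *allow_birth_instantiation* is False (assignment-only mode, where
    births are tallied as unmatched instead of instantiated).
    """
    data = state.data
    act = state.active_components()
    n_act = len(act)
    logw = np.empty(n_act + 1)
    if n_act:
        with np.errstate(divide="ignore"):  # empty tracked components get 0 mass
            logw[:n_act] = np.log(state.counts[act]) + state.loglik_existing_many(
                i, act
            )
        blocked = state.members[act, data.ds[i]] >= 0
        logw[:n_act][blocked] = -np.inf
    logw[n_act] = np.log(state.hp.alpha) + state.loglik_new_one(i)

    if data.use_fragments:
        y = data.Y[i]
        if n_act:
            if state.frozen_profiles is not None:
                W = state.frozen_profiles[act]
            else:
                W = state.prof_sum[act] / np.maximum(state.counts[act], 1)[:, None]
            psi = np.sum((W - y) ** 2, axis=1)
            logw[:n_act] += np.log(state.gamma) - state.gamma * psi
        psi0 = float(np.sum((y - blank_profile(len(y))) ** 2))
        logw[n_act] += np.log(state.gamma) - state.gamma * psi0

    choice = _gumbelless_choice(rng, logw / state.T)

    if choice == n_act:  # new component
        if tally is not None:
            tally["new"] = tally.get("new", 0) + 1
        if not allow_birth_instantiation:
            return -1
        state._require_caches()
        mu = _draw_mu_birth(state, i, rng)
        j = state.new_component(mu)
        state.add_member(i, j)
        return j
    j = int(act[choice])
    if tally is not None:
        tally[j] = tally.get(j, 0) + 1
    state.add_member(i, j)
    return j


# -- conjugate parameter updates ------------------------------------------


def update_latent_means(state: ModelState, rng: np.random.Generator) -> None:
    """Draw each mu_j from its normal full conditional (members collapsed in z).

    Precision = r^-1 + sum_d in members diag(beta_d) B_d^-1 diag(beta_d);
    at temperature T the conditional covariance is scaled by T.
    """
    state._require_caches()
    hp = state.hp
    data = state.data
    rinv = np.linalg.inv(hp.r)
    rinv_lam = rinv @ hp.lam
    # per-feature information vectors h_i = diag(beta) B^-1 (x_i - eta)
    H = np.empty_like(data.X)
    for d in range(data.n_datasets):
        sel = data.ds == d
        if not np.any(sel):
            continue
        diff = data.X[sel] - state.eta[d]
        Binv_diff = cho_solve((state._chol_B[d], True), diff.T).T
        H[sel] = Binv_diff * state.beta[d]
    sqT = np.sqrt(state.T)
    for j in state.active_components():
        if state.counts[j] == 0:  # transient empties are dropped, not updated
            state.drop_component(j)
            continue
        prec = rinv.copy()
        rhs = rinv_lam.copy()
        for d in range(data.n_datasets):
            i = state.members[j, d]
            if i >= 0:
                prec += state._P[d]
                rhs += H[i]
        L = np.linalg.cholesky(prec)
        mean = cho_solve((L, True), rhs)
        eps = rng.standard_normal(data.D)
        state.mu[j] = mean + solve_triangular(L, eps, lower=True, trans="T") * sqT


def update_shift_scale(state: ModelState, rng: np.random.Generator) -> None:
    """Draw eta_d and beta_d per dimension from their conjugate conditionals.

    The Gaussian regression of x on the assigned components' means uses
    the current marginal residual variance B_d[m,m] as a plug-in, which
    makes both updates normal-normal; the conditional variance is scaled
    by the annealing temperature.
    """
    state._require_caches()
    data = state.data
    hp = state.hp
    for d in range(data.n_datasets):
        sel = np.flatnonzero((data.ds == d) & (state.c >= 0))
        if len(sel) == 0:
            continue
        mu_sel = state.mu[state.c[sel]]
        x_sel = data.X[sel]
        Db = np.diag(state.beta[d])
        B = Db @ state.sigma_lat @ Db + state.Sigma
        for m in range(data.D):
            v = B[m, m]
            # shift
            t_res = x_sel[:, m] - state.beta[d, m] * mu_sel[:, m]
            prec = 1.0 / hp.b[d, m] + len(sel) / v
            mean = (hp.a[d, m] / hp.b[d, m] + t_res.sum() / v) / prec
            state.eta[d, m] = mean + rng.standard_normal() * np.sqrt(state.T / prec)
            # scale, conditioned on the fresh shift
            u_res = x_sel[:, m] - state.eta[d, m]
            prec_b = 1.0 / hp.f[d, m] + float(mu_sel[:, m] @ mu_sel[:, m]) / v
            mean_b = (
                hp.e[d, m] / hp.f[d, m] + float(mu_sel[:, m] @ u_res) / v
            ) / prec_b
            state.beta[d, m] = mean_b + rng.standard_normal() * np.sqrt(
                state.T / prec_b
            )
    state._caches_stale = True


def _tempered_invwishart(
    Psi: np.ndarray, nu: float, T: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw from IW(Psi, nu) sharpened to power 1/T (T=1: plain draw)."""
    p = Psi.shape[0]
    nu_T = (nu + p + 1.0) / T - p - 1.0
    Psi_T = Psi / T
    draw = invwishart.rvs(df=nu_T, scale=Psi_T, random_state=rng)
    return np.atleast_2d(draw)


def update_covariances(state: ModelState, rng: np.random.Generator) -> None:
    """Inverse-Wishart updates of Sigma (residual) and sigma (latent spread).

    The latent values z_{d,i} are sampled transiently from their exact
    Gaussian conditionals (given x, mu, Sigma, sigma) to form the residual
    outer products x - eta - z*beta and deviations z - mu, then discarded;
    assignments always use the z-collapsed likelihood.
    """
    data = state.data
    hp = state.hp
    D = data.D
    assigned = np.flatnonzero(state.c >= 0)
    if len(assigned) == 0:
        state.Sigma = _tempered_invwishart(hp.s, hp.t, state.T, rng)
        state.sigma_lat = _tempered_invwishart(hp.g, hp.h, state.T, rng)
        state._caches_stale = True
        return

    try:
        sig_inv = np.linalg.inv(state.sigma_lat)
        Sig_inv = np.linalg.inv(state.Sigma)
    except np.linalg.LinAlgError as exc:
        raise NumericalStateError("covariance became singular") from exc

    Z = np.empty((data.N, D))
    for d in range(data.n_datasets):
        sel = assigned[data.ds[assigned] == d]
        if len(sel) == 0:
            continue
        Db = np.diag(state.beta[d])
        Q = sig_inv + Db @ Sig_inv @ Db
        L = np.linalg.cholesky(Q)
        mu_sel = state.mu[state.c[sel]]
        rhs = mu_sel @ sig_inv + (data.X[sel] - state.eta[d]) @ Sig_inv @ Db
        mean = cho_solve((L, True), rhs.T).T
        eps = rng.standard_normal((len(sel), D))
        dev = solve_triangular(L, eps.T, lower=True, trans="T").T
        Z[sel] = mean + dev * np.sqrt(state.T)

    res = np.empty((len(assigned), D))
    lat_dev = np.empty((len(assigned), D))
    for pos, i in enumerate(assigned):
        d = data.ds[i]
        res[pos] = data.X[i] - state.eta[d] - state.beta[d] * Z[i]
        lat_dev[pos] = Z[i] - state.mu[state.c[i]]

    S_post = hp.s + res.T @ res
    g_post = hp.g + lat_dev.T @ lat_dev
    n = len(assigned)
    for mat in (S_post, g_post):
        if np.any(~np.isfinite(mat)):
            raise NumericalStateError("non-finite covariance accumulation")
    state.Sigma = _tempered_invwishart(_pd_jitter(S_post), hp.t + n, state.T, rng)
    state.sigma_lat = _tempered_invwishart(_pd_jitter(g_post), hp.h + n, state.T, rng)
    state._caches_stale = True


def _pd_jitter(mat: np.ndarray) -> np.ndarray:
    try:
        np.linalg.cholesky(mat)
        return mat
    except np.linalg.LinAlgError:
        return mat + 1e-9 * np.trace(mat) / len(mat) * np.eye(len(mat))


def update_gamma_rate(state: ModelState, rng: np.random.Generator) -> None:
    """Conjugate Gamma update of the profile-score exponential rate."""
    if not state.data.use_fragments:
        return
    hp = state.hp
    assigned = np.flatnonzero(state.c >= 0)
    W = state.prof_sum[state.c[assigned]] / state.counts[state.c[assigned], None]
    psi = np.sum((state.data.Y[assigned] - W) ** 2, axis=1)
    shape = hp.a0 + len(psi)
    rate = hp.b0 + float(psi.sum())
    shape_T = (shape - 1.0) / state.T + 1.0
    rate_T = rate / state.T
    state.gamma = float(rng.gamma(shape_T, 1.0 / rate_T))


# -- driver ----------------------------------------------------------------


def make_seed_components(
    state: ModelState, seeds: SeedMatchSet, row_of: dict[tuple[int, int], int]
) -> None:
    """Create one frozen component per seed group; members stay fixed.

    *row_of* maps (dataset_index, feature_index) to sampler row.  Seed
    groups whose members are not all present in this data subset (a
    partition split) are skipped for that split.
    """
    for g in seeds.groups:
        rows = [
            row_of.get((m.dataset_index, m.feature_index)) for m in g.members
        ]
        if any(r is None for r in rows):
            continue
        dewarped = []
        for m, r in zip(g.members, rows):
            d = m.dataset_index
            x = state.data.X[r]
            dewarped.append((x - state.eta[d]) / state.beta[d])
        j = state.new_component(np.mean(dewarped, axis=0), frozen=True)
        for r in rows:
            state.add_member(r, j)
            state.frozen_feat[r] = True


def sweep_assignments(
    state: ModelState, rng: np.random.Generator
) -> None:
    """One random-order Gibbs pass over all non-seed features."""
    order = rng.permutation(state.data.N)
    for i in order:
        if state.frozen_feat[i]:
            continue
        state.remove_member(i)
        sample_assignment(state, i, rng)


def sweep_parameters(
    state: ModelState, rng: np.random.Generator, config: SamplerConfig
) -> None:
    if config.sample_latent_means:
        update_latent_means(state, rng)
    if config.sample_warp:
        update_shift_scale(state, rng)
    if config.sample_covariances:
        update_covariances(state, rng)
    if config.sample_gamma:
        update_gamma_rate(state, rng)


def run_mcmc(
    data: AlignmentData,
    hp: Hyperparameters,
    config: SamplerConfig,
    rng: np.random.Generator,
    seeds: Optional[SeedMatchSet] = None,
    row_of: Optional[dict] = None,
) -> ModelState:
    """Fit the model: burn-in at T=1, then simulated annealing to the MAP.

    Seed-group assignments are fixed for the whole run.  Features start
    unassigned and are placed by an initial sequential CRP pass; every
    subsequent sweep revisits features in a fresh random order.  The
    returned state (at the lowest temperature) is the MAP estimate.
    """
    state = ModelState(data, hp)
    if seeds is not None:
        if row_of is None:
            row_of = {
                (int(data.ds[i]), int(data.feature_ids[i])): i
                for i in range(data.N)
            }
        make_seed_components(state, seeds, row_of)
    state.refresh_caches()

    # sequential initial placement
    for i in rng.permutation(data.N):
        if state.frozen_feat[i]:
            continue
        sample_assignment(state, i, rng)

    for k in range(config.burn_in):
        state.T = 1.0
        sweep_assignments(state, rng)
        sweep_parameters(state, rng, config)
        if k >= config.burn_in // 2:
            state.warp_trace.append((state.eta.copy(), state.beta.copy()))

    for k in range(1, config.anneal_sweeps + 1):
        t_k = max(config.anneal_rate**k, config.t_min)
        state.T = t_k
        sweep_assignments(state, rng)
        # optionally temper only the assignment draws
        state.T = t_k if config.temper_parameters else 1.0
        sweep_parameters(state, rng, config)
        state.T = t_k
    return state
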
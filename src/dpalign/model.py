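"""Model/Results interface for cross-run peptide feature alignment.

:class:`PeptideAlignmentModel` is built from per-run feature tables and
an alignment mode; :meth:`~PeptideAlignmentModel.fit` runs the full
procedure — seed selection, hyperparameter initialization, m/z-desert
partitioning, per-split collapsed Gibbs sampling with simulated
annealing, assignment-only resampling and greedy consensus — and
returns a :class:`PeptideAlignmentResults` holding the matched groups,
their probabilities, the recovered warp parameters with conditional
posterior spreads, and a ``summary()``.

    >>> model = PeptideAlignmentModel(datasets, mode="MZ-RT")
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import consensus as cns
from . import features as fio
from . import preprocess as pre
from . import profiles as prof
from . import sampler as smp

__all__ = ["MODES", "PeptideAlignmentModel", "PeptideAlignmentResults"]

#: alignment modes: coordinate dimensions used and whether product-ion
#: profiles enter the likelihood
MODES: dict[str, tuple[tuple[str, ...], bool]] = {
    "MZ-RT": (("mz", "rt"), False),
    "MZ-IM": (("mz", "drift"), False),
    "MZ-RT-IM": (("mz", "rt", "drift"), False),
    "MZ-RT-IM-HE": (("mz", "rt", "drift"), True),
}


class ModeError(ValueError):
    """Requested mode needs a coordinate or fragment data the input lacks."""


@dataclass
class _SplitFit:
    split_index: int
    state: smp.ModelState
    proportions: cns.AssignmentProportions
    alignment: cns.AlignmentResult
    n_features: int


class PeptideAlignmentModel:
    """Bayesian DPGMM alignment of peptide features across runs.

    Parameters
    ----------
    datasets
        One :class:`~dpalign.features.FeatureSet` per run.
    mode
        One of ``MZ-RT``, ``MZ-IM``, ``MZ-RT-IM``, ``MZ-RT-IM-HE``.
    n_seeds
        Number of seed ("given") matches used to initialize priors.
    K
        Product-ion profile length (fragment modes only).
    """

    def __init__(
        self,
        datasets: Sequence[fio.FeatureSet],
        mode: str = "MZ-RT",
        n_seeds: int = 15,
        K: int = prof.DEFAULT_K,
        max_splits: int = 250,
        frozen_scale_dims: Sequence[str] = (),
        a0: float = 1.0,
        b0: float = 1.0,
    ) -> None:
        if mode not in MODES:
            raise ModeError(f"unknown mode {mode!r}; choose from {sorted(MODES)}")
        self.datasets = list(datasets)
        if len(self.datasets) < 1:
            raise ValueError("need at least one dataset")
        self.mode = mode
        self.dims, self.use_fragments = MODES[mode]
        for fs in self.datasets:
            missing = set(self.dims) - set(fs.dimension_names)
            if missing:
                raise ModeError(
                    f"mode {mode} requires column(s) {sorted(missing)} absent "
                    f"from dataset {fs.dataset_label!r}"
                )
            if self.use_fragments and not any(f.fragments for f in fs.features):
                raise ModeError(
                    f"mode {mode} requires fragment data; dataset "
                    f"{fs.dataset_label!r} has none"
                )
        self.n_seeds = n_seeds
        self.K = K
        self.max_splits = max_splits
        self.frozen_scale_dims = tuple(frozen_scale_dims)
        self.a0 = a0
        self.b0 = b0

    @classmethod
    def from_tables(
        cls,
        paths: Sequence,
        fragment_paths: Optional[Sequence] = None,
        labels: Optional[Sequence[str]] = None,
        **kwargs,
    ) -> "PeptideAlignmentModel":
        datasets = []
        for d, path in enumerate(paths):
            datasets.append(
                fio.read_feature_table(
                    path,
                    fragment_path=fragment_paths[d] if fragment_paths else None,
                    dataset_label=labels[d] if labels else str(path),
                    dataset_index=d,
                )
            )
        return cls(datasets, **kwargs)

    # ------------------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        burn_in: int = 200,
        anneal_sweeps: int = 200,
        anneal_rate: float = 0.95,
        t_min: float = 0.05,
        assignment_sweeps: int = 500,
        workers: int = 1,
        temper_parameters: bool = True,
    ) -> "PeptideAlignmentResults":
        """Run the full alignment; deterministic for a given *seed*."""
        n_datasets = len(self.datasets)
        if n_datasets > 1:
            seeds = pre.select_seed_matches(
                self.datasets, n_seeds=self.n_seeds, dims=self.dims
            )
        else:
            seeds = None

        if seeds is not None:
            hp = pre.init_hyperparameters(
                self.datasets,
                seeds,
                frozen_scale_dims=self.frozen_scale_dims,
                a0=self.a0,
                b0=self.b0,
            )
            plan = pre.compute_mz_deserts(
                self.datasets,
                seeds,
                warp=(hp.a, hp.b, hp.e, hp.f),
                max_splits=self.max_splits,
            )
        else:  # single dataset: identity-warp default priors
            hp = _default_single_dataset_hp(self.datasets[0], self.dims, self.a0, self.b0)
            plan = pre.PartitionPlan(
                boundaries=np.array([]),
                memberships=[[np.arange(len(fs)) for fs in self.datasets]],
            )

        bins = None
        if self.use_fragments:
            bins = prof.determine_profile_bins(self.datasets, seeds, K=self.K)

        config = smp.SamplerConfig(
            burn_in=burn_in,
            anneal_sweeps=anneal_sweeps,
            anneal_rate=anneal_rate,
            t_min=t_min,
            temper_parameters=temper_parameters,
        )

        jobs = []
        for si in range(plan.n_splits):
            subset = plan.memberships[si]
            if sum(len(ix) for ix in subset) == 0:
                continue
            jobs.append((si, subset))

        if workers > 1 and len(jobs) > 1:
            from joblib import Parallel, delayed

            fits = Parallel(n_jobs=workers)(
                delayed(_fit_split)(
                    self.datasets, self.dims, bins, subset, hp, config, seeds,
                    seed, si, assignment_sweeps,
                )
                for si, subset in jobs
            )
        else:
            fits = [
                _fit_split(
                    self.datasets, self.dims, bins, subset, hp, config, seeds,
                    seed, si, assignment_sweeps,
                )
                for si, subset in jobs
            ]

        merged = cns.AlignmentResult()
        next_id = 0
        for f in fits:
            remap = {}
            for latent_id in sorted(f.alignment.groups):
                remap[latent_id] = next_id
                merged.groups[next_id] = f.alignment.groups[latent_id]
                next_id += 1
        return PeptideAlignmentResults(
            model=self,
            hyperparameters=hp,
            seeds=seeds,
            partition=plan,
            split_fits=fits,
            alignment=merged,
            fit_seed=seed,
        )


def _default_single_dataset_hp(fs, dims, a0, b0) -> pre.Hyperparameters:
    X = fs.coord_matrix(dims)
    D = len(dims)
    lam = X.mean(axis=0) if len(X) else np.zeros(D)
    dev = X - lam
    r = dev.T @ dev + 1e-6 * np.eye(D)
    scale = np.diag(np.maximum(np.var(X, axis=0), 1e-6)) if len(X) else np.eye(D)
    return pre.Hyperparameters(
        a=np.zeros((1, D)),
        b=np.full((1, D), 1e-6),
        e=np.ones((1, D)),
        f=np.full((1, D), 1e-6),
        s=scale * D,
        t=float(D + 2),
        g=scale * D,
        h=float(D + 2),
        lam=lam,
        r=r,
        alpha=float(max(len(X), 1)),
        a0=a0,
        b0=b0,
    )


def _fit_split(
    datasets, dims, bins, subset, hp, config, seeds, seed, split_index, assignment_sweeps
) -> _SplitFit:
    rng = np.random.default_rng(np.random.SeedSequence([seed, split_index]))
    data = smp.build_data(datasets, dims, bins=bins, subset=subset)
    state = smp.run_mcmc(data, hp, config, rng, seeds=seeds)
    props = cns.assignment_only_sampling(state, n_iters=assignment_sweeps, rng=rng)
    alignment = cns.greedy_alignment(props)
    return _SplitFit(
        split_index=split_index,
        state=state,
        proportions=props,
        alignment=alignment,
        n_features=data.N,
    )


class PeptideAlignmentResults:
    """Fitted alignment: matched groups, probabilities, MAP parameters."""

    def __init__(
        self, model, hyperparameters, seeds, partition, split_fits, alignment, fit_seed
    ) -> None:
        self.model = model
        self.hyperparameters = hyperparameters
        self.seeds = seeds
        self.partition = partition
        self.split_fits = split_fits
        self.alignment = alignment
        self.fit_seed = fit_seed

    # -- parameter estimates -------------------------------------------

    @property
    def shifts(self) -> np.ndarray:
        """Feature-weighted MAP shift per dataset and dimension."""
        return self._weighted_param("eta")

    @property
    def scales(self) -> np.ndarray:
        return self._weighted_param("beta")

    def _weighted_param(self, name: str) -> np.ndarray:
        tot = sum(f.n_features for f in self.split_fits)
        acc = None
        for f in self.split_fits:
            val = getattr(f.state, name) * (f.n_features / tot)
            acc = val if acc is None else acc + val
        return acc

    def warp_posterior_sd(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior sd of shift and scale for the largest split.

        Estimated from the T=1 burn-in trace of the warp draws (marginal
        posterior spread); if the trace is too short, falls back to the
        conjugate full-conditional sd at the MAP state (prior precision +
        data precision with the MAP residual variance as plug-in), which
        is narrower because it conditions on all other parameters.
        """
        f = max(self.split_fits, key=lambda s: s.n_features)
        state = f.state
        if len(state.warp_trace) >= 10:
            etas = np.array([tr[0] for tr in state.warp_trace])
            betas = np.array([tr[1] for tr in state.warp_trace])
            return etas.std(axis=0, ddof=1), betas.std(axis=0, ddof=1)
        hp = state.hp
        data = state.data
        D = data.D
        sd_eta = np.zeros((data.n_datasets, D))
        sd_beta = np.zeros((data.n_datasets, D))
        for d in range(data.n_datasets):
            sel = np.flatnonzero((data.ds == d) & (state.c >= 0))
            Db = np.diag(state.beta[d])
            B = Db @ state.sigma_lat @ Db + state.Sigma
            mu_sel = state.mu[state.c[sel]]
            for m in range(D):
                v = B[m, m]
                sd_eta[d, m] = 1.0 / np.sqrt(1.0 / hp.b[d, m] + len(sel) / v)
                sd_beta[d, m] = 1.0 / np.sqrt(
                    1.0 / hp.f[d, m] + float(mu_sel[:, m] @ mu_sel[:, m]) / v
                )
        return sd_eta, sd_beta

    # -- match outputs --------------------------------------------------

    def match_table(self) -> pd.DataFrame:
        rows = [
            {
                "latent_id": latent_id,
                "dataset_label": m.dataset_label,
                "feature_id": m.feature_id,
                "assignment_probability": m.probability,
            }
            for latent_id, members in sorted(self.alignment.groups.items())
            for m in members
        ]
        return pd.DataFrame(
            rows,
            columns=["latent_id", "dataset_label", "feature_id", "assignment_probability"],
        )

    def pairwise_table(self, threshold: float = 0.0) -> pd.DataFrame:
        rows = [
            {
                "dataset_a": a[0],
                "feature_a": a[1],
                "dataset_b": b[0],
                "feature_b": b[1],
                "match_probability": p,
            }
            for a, b, p in self.alignment.pairwise_matches(threshold=threshold)
        ]
        return pd.DataFrame(
            rows,
            columns=["dataset_a", "feature_a", "dataset_b", "feature_b", "match_probability"],
        )

    def seed_pairs(self) -> list[frozenset]:
        """Cross-dataset pairs held fixed as seed matches (for exclusion
        from evaluation)."""
        if self.seeds is None:
            return []
        out = []
        for g in self.seeds.groups:
            mems = [
                (self.model.datasets[m.dataset_index].dataset_label, m.feature_index)
                for m in g.members
            ]
            for x in range(len(mems)):
                for y in range(x + 1, len(mems)):
                    out.append(frozenset((mems[x], mems[y])))
        return out

    def save(self, path, pairwise_path=None, threshold: float = 0.0) -> None:
        fio.write_alignment(
            self.alignment, path, pairwise_path=pairwise_path, threshold=threshold
        )

    def summary(self) -> str:
        model = self.model
        n_feats = [len(fs) for fs in model.datasets]
        lines = [
            "Peptide feature alignment (DPGMM, collapsed Gibbs + annealing)",
            "=" * 62,
            f"mode:            {model.mode}  (dims: {', '.join(model.dims)}"
            + (", product-ion profiles)" if model.use_fragments else ")"),
            f"datasets:        {len(model.datasets)}  "
            f"({', '.join(fs.dataset_label for fs in model.datasets)})",
            f"features:        {sum(n_feats)}  {n_feats}",
            f"seed matches:    {0 if self.seeds is None else len(self.seeds)}",
            f"m/z splits:      {len(self.split_fits)}",
            f"matched groups:  {len(self.alignment.groups)}",
            f"fit seed:        {self.fit_seed}",
            "",
            "Per-dataset warp (MAP estimate +/- conditional posterior sd):",
        ]
        sd_eta, sd_beta = self.warp_posterior_sd()
        eta, beta = self.shifts, self.scales
        for d, fs in enumerate(model.datasets):
            for m, dim in enumerate(model.dims):
                lines.append(
                    f"  {fs.dataset_label:>12s} {dim:>5s}: shift "
                    f"{eta[d, m]:+.4f} +/- {sd_eta[d, m]:.4f}   scale "
                    f"{beta[d, m]:.4f} +/- {sd_beta[d, m]:.4f}"
                )
        return "\n".join(lines)
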
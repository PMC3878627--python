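"""From MAP state to final matches.

After annealing, all parameters are frozen at their MAP values and only
the assignment indicators are resampled at T=1.  The frequency with
which each measurement lands on each MAP latent peptide estimates its
conditional assignment probability (given the MAP parameters); draws of
a brand-new component are tallied as "unmatched" mass.  A greedy pass
over these proportions then produces the final one-to-one alignment, and
the match probability of two measurements from different runs is the
product of their individual assignment probabilities for the shared
latent peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .sampler import ModelState, sample_assignment

__all__ = [
    "AssignmentProportions",
    "GroupMember",
    "AlignmentResult",
    "assignment_only_sampling",
    "greedy_alignment",
    "pairwise_match_probability",
]


@dataclass
class AssignmentProportions:
    """Assignment frequencies from assignment-only resampling.

    ``freq[m, n]`` is the fraction of sweeps in which measurement row n
    was assigned to tracked latent peptide m; ``unmatched[n]`` is the
    fraction in which a new (untracked) component was drawn.  Rows and
    columns are indexed by ``latent_ids`` and ``measurement_keys``
    ((dataset_label, feature_id) per sampler row).
    """

    latent_ids: list[int]
    measurement_keys: list[tuple[str, int]]
    dataset_of: np.ndarray  # (N,) dataset index per measurement
    freq: np.ndarray  # (M, N)
    unmatched: np.ndarray  # (N,)

    def probability(self, measurement: int, latent: int) -> float:
        return float(self.freq[self.latent_ids.index(latent), measurement])


@dataclass
class GroupMember:
    dataset_label: str
    feature_id: int
    probability: float


@dataclass
class AlignmentResult:
    """Final matched groups: latent id -> chosen member per dataset."""

    groups: dict[int, list[GroupMember]] = field(default_factory=dict)

    def pairwise_matches(
        self, threshold: float = 0.0
    ) -> Iterator[tuple[tuple[str, int], tuple[str, int], float]]:
        """All cross-dataset member pairs with match probability >= threshold."""
        for latent_id in sorted(self.groups):
            members = self.groups[latent_id]
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    a, b = members[x], members[y]
                    if a.dataset_label == b.dataset_label:
                        continue
                    p = a.probability * b.probability
                    if p >= threshold:
                        yield (
                            (a.dataset_label, a.feature_id),
                            (b.dataset_label, b.feature_id),
                            p,
                        )

    def group_of(self) -> dict[tuple[str, int], int]:
        return {
            (m.dataset_label, m.feature_id): latent_id
            for latent_id, members in self.groups.items()
            for m in members
        }


def assignment_only_sampling(
    map_state: ModelState, n_iters: int = 500, rng: Optional[np.random.Generator] = None
) -> AssignmentProportions:
    """Resample only the component indicators at T=1, tallying frequencies.

    The latent peptide set is fixed to the MAP components (means and
    profiles frozen; empty components are kept so the index set is
    stable), and all other parameters stay at their MAP values.  Seed
    features keep their fixed assignment and tally it with probability 1.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    state = map_state
    state.T = 1.0
    data = state.data

    tracked = list(map(int, state.active_components()))
    col_of = {j: m for m, j in enumerate(tracked)}
    freq_counts = np.zeros((len(tracked), data.N))
    unmatched_counts = np.zeros(data.N)

    # freeze component profiles at their MAP member averages
    if state.prof_sum is not None:
        state.frozen_profiles = state.prof_sum / np.maximum(state.counts, 1)[:, None]

    # snapshot the MAP assignment so the state can be restored afterwards
    snap = (
        state.c.copy(),
        state.members.copy(),
        state.counts.copy(),
        None if state.prof_sum is None else state.prof_sum.copy(),
    )

    try:
        for _sweep in range(n_iters):
            order = rng.permutation(data.N)
            for i in order:
                if state.frozen_feat[i]:
                    freq_counts[col_of[state.c[i]], i] += 1
                    continue
                state.remove_member(i, drop_if_empty=False)
                j = sample_assignment(
                    state, i, rng, allow_birth_instantiation=False
                )
                if j < 0:
                    unmatched_counts[i] += 1
                else:
                    freq_counts[col_of[j], i] += 1
    finally:
        state.frozen_profiles = None
        state.c, state.members, state.counts = snap[0], snap[1], snap[2]
        if snap[3] is not None:
            state.prof_sum = snap[3]

    return AssignmentProportions(
        latent_ids=tracked,
        measurement_keys=[data.key(i) for i in range(data.N)],
        dataset_of=data.ds.copy(),
        freq=freq_counts / n_iters,
        unmatched=unmatched_counts / n_iters,
    )


def greedy_alignment(props: AssignmentProportions) -> AlignmentResult:
    """Deterministic greedy consensus from assignment proportions.

    Repeatedly select the globally best (latent peptide, measurement)
    frequency; complete that latent peptide's group with each remaining
    dataset's best measurement; then zero out the chosen measurements and
    the latent peptide.  Ties break on lowest latent id, then lowest
    (dataset, measurement) index.
    """
    F = props.freq.copy()
    M, N = F.shape
    result = AlignmentResult()
    if M == 0 or N == 0:
        return result
    ds = props.dataset_of
    n_datasets = int(ds.max()) + 1 if N else 0

    while True:
        best = F.max()
        if best <= 0:
            break
        cand = np.argwhere(F == best)
        # ties: lowest latent id, then lowest (dataset, feature) position
        cand = sorted(
            cand,
            key=lambda mn: (
                props.latent_ids[mn[0]],
                ds[mn[1]],
                props.measurement_keys[mn[1]],
            ),
        )
        m_star, n_star = map(int, cand[0])
        chosen = {int(ds[n_star]): n_star}
        for d in range(n_datasets):
            if d == ds[n_star]:
                continue
            sel = np.flatnonzero(ds == d)
            if len(sel) == 0:
                continue
            row = F[m_star, sel]
            if row.max() <= 0:
                continue
            n_d = int(sel[np.argmax(row)])
            chosen[d] = n_d
        members = []
        for d in sorted(chosen):
            n = chosen[d]
            label, fid = props.measurement_keys[n]
            members.append(
                GroupMember(
                    dataset_label=label, feature_id=fid, probability=float(F[m_star, n])
                )
            )
            F[:, n] = 0.0
        F[m_star, :] = 0.0
        result.groups[props.latent_ids[m_star]] = members
    return result


def pairwise_match_probability(
    props: AssignmentProportions, a: int, b: int, latent_id: int
) -> float:
    """P(both measurements a and b arise from the same latent peptide j) =
    P(a -> j) * P(b -> j).  a and b must come from different datasets."""
    if props.dataset_of[a] == props.dataset_of[b]:
        raise ValueError("measurements must come from different datasets")
    m = props.latent_ids.index(latent_id)
    return float(props.freq[m, a] * props.freq[m, b])
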
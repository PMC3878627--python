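"""Reading, validating and writing peptide feature tables.

A *feature* is one detected peptide ion in one LC-MS run: a coordinate
vector (precursor m/z in Thomson, retention time in minutes and, for
ion-mobility experiments, drift time in milliseconds), an intensity, and
optionally a charge state, an amino-acid sequence with an identification
score, and a list of product-ion (fragment) peaks.

Tables are tab-separated text with a mandatory header.  Feature tables
carry the columns ``feature_id, mz, rt, [drift], intensity, [charge],
[sequence], [score]``; fragment tables carry ``feature_id, frag_mz,
frag_intensity``.  Intensity is read and written but never used by the
alignment model itself, which operates on coordinates and fragments only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasuredFeature",
    "FeatureSet",
    "FeatureTableError",
    "read_feature_table",
    "write_feature_table",
    "write_alignment",
    "read_alignment",
]

#: canonical coordinate order; a dataset uses a contiguous prefix-free
#: subset of these (mz always, rt and drift when measured)
DIMENSIONS = ("mz", "rt", "drift")


class FeatureTableError(ValueError):
    """Malformed feature/fragment table (missing column, bad value, bad link)."""


@dataclass
class MeasuredFeature:
    """One measured peptide feature x_{d,i}."""

    dataset_index: int
    feature_index: int
    coords: dict[str, float]
    intensity: float
    charge: Optional[int] = None
    sequence: Optional[str] = None
    id_score: Optional[float] = None
    fragments: list[tuple[float, float]] = field(default_factory=list)

    def coord_vector(self, dims: Sequence[str]) -> np.ndarray:
        return np.array([self.coords[m] for m in dims], dtype=float)


@dataclass
class FeatureSet:
    """All features of one dataset (one LC-MS run)."""

    dataset_label: str
    features: list[MeasuredFeature]
    dimension_names: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [f.feature_index for f in self.features]
        if len(ids) != len(set(ids)):
            raise FeatureTableError(
                f"duplicate feature_id in dataset {self.dataset_label!r}"
            )
        for f in self.features:
            if set(f.coords) != set(self.dimension_names):
                raise FeatureTableError(
                    f"feature {f.feature_index} of {self.dataset_label!r} has "
                    f"dimensions {sorted(f.coords)} but the dataset declares "
                    f"{sorted(self.dimension_names)}"
                )
            _validate_feature(f, self.dataset_label)

    def __len__(self) -> int:
        return len(self.features)

    def coord_matrix(self, dims: Optional[Sequence[str]] = None) -> np.ndarray:
        dims = tuple(dims) if dims is not None else self.dimension_names
        if not self.features:
            return np.empty((0, len(dims)))
        return np.array([f.coord_vector(dims) for f in self.features])

    def by_id(self, feature_index: int) -> MeasuredFeature:
        for f in self.features:
            if f.feature_index == feature_index:
                return f
        raise KeyError(feature_index)


def _validate_feature(f: MeasuredFeature, label: str) -> None:
    if not f.coords.get("mz", 1.0) > 0:
        raise FeatureTableError(f"{label}: feature {f.feature_index}: mz must be > 0")
    if f.coords.get("rt", 0.0) < 0:
        raise FeatureTableError(f"{label}: feature {f.feature_index}: rt must be >= 0")
    if f.coords.get("drift", 0.0) < 0:
        raise FeatureTableError(
            f"{label}: feature {f.feature_index}: drift must be >= 0"
        )
    if not f.intensity > 0:
        raise FeatureTableError(
            f"{label}: feature {f.feature_index}: intensity must be > 0"
        )
    for mz, inten in f.fragments:
        if not (mz > 0 and inten > 0):
            raise FeatureTableError(
                f"{label}: feature {f.feature_index}: fragment m/z and "
                "intensity must be > 0"
            )


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError as exc:
        raise FeatureTableError(f"{path}: empty file (no header)") from exc


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FeatureTableError(
            f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column "
            f"{col!r} at line {row}"
        )
    return vals.to_numpy()


def read_feature_table(
    path,
    fragment_path=None,
    dataset_label: Optional[str] = None,
    dataset_index: int = 0,
) -> FeatureSet:
    """Read one dataset's feature table (and optional fragment table).

    Raises :class:`FeatureTableError` for a missing mandatory column
    (``mz``, ``rt``), a non-numeric coordinate (reported with its line
    number), or a fragment row referencing an unknown ``feature_id``.
    """
    df = _read_tsv(path)
    missing = {"feature_id", "mz", "rt"} - set(df.columns)
    if missing:
        raise FeatureTableError(f"{path}: missing mandatory column(s) {sorted(missing)}")

    dims = ["mz", "rt"] + (["drift"] if "drift" in df.columns else [])
    label = dataset_label if dataset_label is not None else str(path)

    numeric = {m: _numeric(df, m, path) for m in dims}
    intensity = (
        _numeric(df, "intensity", path)
        if "intensity" in df.columns
        else np.ones(len(df))
    )
    charge = _numeric(df, "charge", path) if "charge" in df.columns else None
    score = _numeric(df, "score", path) if "score" in df.columns else None

    fragments: dict[str, list[tuple[float, float]]] = {}
    if fragment_path is not None:
        fdf = _read_tsv(fragment_path)
        fmissing = {"feature_id", "frag_mz", "frag_intensity"} - set(fdf.columns)
        if fmissing:
            raise FeatureTableError(
                f"{fragment_path}: missing column(s) {sorted(fmissing)}"
            )
        fmz = _numeric(fdf, "frag_mz", fragment_path)
        fint = _numeric(fdf, "frag_intensity", fragment_path)
        known = set(df["feature_id"])
        for fid, m, inten in zip(fdf["feature_id"], fmz, fint):
            if fid not in known:
                raise FeatureTableError(
                    f"{fragment_path}: fragment references unknown feature_id "
                    f"{fid!r}"
                )
            fragments.setdefault(fid, []).append((float(m), float(inten)))

    if len(df) and df["feature_id"].str.fullmatch(r"\d+").all():
        index_of = {fid: int(fid) for fid in df["feature_id"]}
    else:  # non-integer ids: assign row order, keep table order stable
        index_of = {fid: pos for pos, fid in enumerate(df["feature_id"])}

    feats = []
    for row_pos in range(len(df)):
        fid = df["feature_id"].iloc[row_pos]
        seq = None
        if "sequence" in df.columns:
            raw = df["sequence"].iloc[row_pos]
            if isinstance(raw, str) and raw.strip():
                seq = raw.strip()
        feats.append(
            MeasuredFeature(
                dataset_index=dataset_index,
                feature_index=index_of[fid],
                coords={m: float(numeric[m][row_pos]) for m in dims},
                intensity=float(intensity[row_pos]),
                charge=None
                if charge is None or np.isnan(charge[row_pos])
                else int(charge[row_pos]),
                sequence=seq,
                id_score=None
                if score is None or np.isnan(score[row_pos])
                else float(score[row_pos]),
                fragments=fragments.get(fid, []),
            )
        )
    return FeatureSet(dataset_label=label, features=feats, dimension_names=tuple(dims))


def write_feature_table(fs: FeatureSet, path, fragment_path=None) -> None:
    """Write a FeatureSet back to the TSV schema read_feature_table accepts."""
    rows = []
    for f in fs.features:
        row = {"feature_id": f.feature_index}
        row.update({m: repr(f.coords[m]) for m in fs.dimension_names})
        row["intensity"] = repr(f.intensity)
        row["charge"] = "" if f.charge is None else f.charge
        row["sequence"] = "" if f.sequence is None else f.sequence
        row["score"] = "" if f.id_score is None else repr(f.id_score)
        rows.append(row)
    cols = ["feature_id", *fs.dimension_names, "intensity", "charge", "sequence", "score"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    if fragment_path is not None:
        frows = [
            {"feature_id": f.feature_index, "frag_mz": repr(m), "frag_intensity": repr(i)}
            for f in fs.features
            for m, i in f.fragments
        ]
        pd.DataFrame(
            frows, columns=["feature_id", "frag_mz", "frag_intensity"]
        ).to_csv(fragment_path, sep="\t", index=False)


def write_alignment(result, path, pairwise_path=None, threshold: float = 0.0) -> None:
    """Write an AlignmentResult: one row per (latent peptide, measurement).

    Columns: ``latent_id, dataset_label, feature_id, assignment_probability``.
    With *pairwise_path*, also writes all within-group cross-dataset pairs as
    ``dataset_a, feature_a, dataset_b, feature_b, match_probability`` at
    match probability >= *threshold*.
    """
    rows = [
        {
            "latent_id": latent_id,
            "dataset_label": m.dataset_label,
            "feature_id": m.feature_id,
            "assignment_probability": repr(m.probability),
        }
        for latent_id, members in sorted(result.groups.items())
        for m in members
    ]
    pd.DataFrame(
        rows,
        columns=["latent_id", "dataset_label", "feature_id", "assignment_probability"],
    ).to_csv(path, sep="\t", index=False)

    if pairwise_path is not None:
        prows = []
        for a, b, p in result.pairwise_matches(threshold=threshold):
            prows.append(
                {
                    "dataset_a": a[0],
                    "feature_a": a[1],
                    "dataset_b": b[0],
                    "feature_b": b[1],
                    "match_probability": repr(p),
                }
            )
        pd.DataFrame(
            prows,
            columns=["dataset_a", "feature_a", "dataset_b", "feature_b", "match_probability"],
        ).to_csv(pairwise_path, sep="\t", index=False)


def read_alignment(path):
    """Re-read an alignment TSV into an AlignmentResult (import deferred to
    avoid a cycle with :mod:`dpalign.consensus`)."""
    from .consensus import AlignmentResult, GroupMember

    df = pd.read_csv(path, sep="\t")
    groups: dict[int, list] = {}
    for _, row in df.iterrows():
        groups.setdefault(int(row["latent_id"]), []).append(
            GroupMember(
                dataset_label=str(row["dataset_label"]),
                feature_id=int(row["feature_id"]),
                probability=float(row["assignment_probability"]),
            )
        )
    return AlignmentResult(groups=groups)
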
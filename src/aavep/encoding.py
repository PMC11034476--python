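"""Averaged-descriptor feature encoding of protein sequences.

A sequence is represented by the arithmetic mean of per-residue descriptor
vectors, either over the full sequence (75 columns with the complete
registry) or separately within each domain of a partition (12 domains x
3 z-scales = 36 columns in the default domain-wise mode). The encoding is
deliberately alignment-free: a point mutation moves the mutated domain's
features by (alt - wt descriptor vector) / domain length and leaves every
other feature untouched.

:class:`DescriptorEncoder` is the scikit-learn face of the encoding (a
stateless transformer over lists of sequences); :func:`build_matrix`
assembles the labeled wild-type + mutant feature matrix that the modeling
layer consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from . import descriptors as desc
from .descriptors import DescriptorTable, STANDARD_RESIDUES, UnsupportedResidueError
from .domains import DomainPartition, split_domains
from .variants import (
    ProteinSequence,
    VariantRecord,
    WildTypeMismatchError,
    apply_variant,
)

__all__ = [
    "FeatureMatrix",
    "DescriptorEncoder",
    "encode_full",
    "encode_domains",
    "build_matrix",
    "standardize",
    "pca_variance",
]

_RES_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}


def _residue_indices(seq: ProteinSequence) -> np.ndarray:
    idx = np.empty(len(seq), dtype=np.intp)
    for i, ch in enumerate(seq.residues):
        j = _RES_INDEX.get(ch)
        if j is None:
            raise UnsupportedResidueError(ch, position=i + 1, seq_id=seq.seq_id)
        idx[i] = j
    return idx


def _table_matrix(table: DescriptorTable) -> np.ndarray:
    return np.array([table.values[r] for r in STANDARD_RESIDUES], dtype=float)


def encode_full(
    seq: ProteinSequence, tables: Sequence[DescriptorTable] | None = None
) -> pd.Series:
    """Mean of each descriptor component over all residues of the sequence.

    With the default full registry the result has 75 uniquely named values
    (``set.component``). Permutation-invariant by construction.
    """
    tables = desc.full_registry() if tables is None else list(tables)
    idx = _residue_indices(seq)
    parts, names = [], []
    for t in tables:
        parts.append(_table_matrix(t)[idx].mean(axis=0))
        names.extend(t.feature_names)
    return pd.Series(np.concatenate(parts), index=names, name=seq.seq_id)


def encode_domains(
    seq: ProteinSequence, p: DomainPartition, table: DescriptorTable | None = None
) -> pd.Series:
    """Per-domain componentwise means, concatenated in domain order.

    Feature names are ``d<k>.<component>`` with domains ascending and
    components in table order; 36 values for 12 domains under Z3.
    """
    table = desc.get_table("Z3") if table is None else table
    mat = _table_matrix(table)
    pieces = split_domains(seq, p)
    values, names = [], []
    for k, piece in enumerate(pieces, start=1):
        sub = ProteinSequence(f"{seq.seq_id}.d{k}", piece)
        values.append(mat[_residue_indices(sub)].mean(axis=0))
        names.extend(f"d{k}.{c}" for c in table.component_names)
    return pd.Series(np.concatenate(values), index=names, name=seq.seq_id)


@dataclass
class FeatureMatrix:
    """Labeled feature matrix over wild-type and mutant sequences.

    ``data`` holds one row per sequence (index = row ids such as
    ``SLC6A8:K4R``); ``labels`` is aligned to rows with pathogenic = 1,
    benign = 0 (NaN for unlabeled rows kept for prediction only);
    ``provenance`` counts records dropped or merged during assembly.
    """

    data: pd.DataFrame
    labels: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("labels must be aligned to feature rows")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()

    def labeled(self) -> "FeatureMatrix":
        """Restrict to rows with a binary label."""
        mask = self.labels.notna()
        return FeatureMatrix(self.data[mask], self.labels[mask].astype(int), dict(self.provenance))

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(len(out.columns), "__label__", self.labels)
        out.to_csv(path, sep="\t", index_label="row_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="row_id")
        labels = df.pop("__label__")
        return cls(df, labels)


_LABEL_CODE = {"benign": 0, "pathogenic": 1}


class DescriptorEncoder(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer mapping protein sequences to descriptor means.

    Parameters
    ----------
    mode : {"full", "domainwise"}
        Full-sequence registry means, or per-domain z-scale means.
    sets : list of str, optional
        Descriptor set names; defaults to the full registry in ``full``
        mode and ``["Z3"]`` in ``domainwise`` mode (domain-wise encodings
        use a single table).
    partitions : dict, optional
        ``seq_id -> DomainPartition``; required in domain-wise mode.
    """

    def __init__(
        self,
        mode: Literal["full", "domainwise"] = "full",
        sets: list[str] | None = None,
        partitions: dict[str, DomainPartition] | None = None,
    ):
        self.mode = mode
        self.sets = sets
        self.partitions = partitions

    def _tables(self) -> list[DescriptorTable]:
        if self.sets is not None:
            return [desc.get_table(s) for s in self.sets]
        return desc.full_registry() if self.mode == "full" else [desc.get_table("Z3")]

    def fit(self, X: Sequence[ProteinSequence], y=None) -> "DescriptorEncoder":
        if self.mode not in ("full", "domainwise"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "domainwise":
            if self.partitions is None:
                raise ValueError("domainwise mode requires partitions")
            tabs = self._tables()
            if len(tabs) != 1:
                raise ValueError("domainwise mode uses exactly one descriptor set")
        self.feature_names_out_ = list(self._encode_one(X[0]).index) if len(X) else []
        return self

    def _encode_one(self, seq: ProteinSequence) -> pd.Series:
        if self.mode == "full":
            return encode_full(seq, self._tables())
        p = self.partitions.get(seq.seq_id)
        if p is None:
            raise KeyError(f"no domain partition for sequence {seq.seq_id!r}")
        return encode_domains(seq, p, self._tables()[0])

    def transform(self, X: Sequence[ProteinSequence]) -> pd.DataFrame:
        rows = [self._encode_one(s) for s in X]
        return pd.DataFrame(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)


def build_matrix(
    wildtypes: Iterable[ProteinSequence],
    variants: Iterable[VariantRecord],
    mode: Literal["full", "domainwise"] = "domainwise",
    partitions: dict[str, DomainPartition] | None = None,
    sets: list[str] | None = None,
) -> FeatureMatrix:
    """Assemble the labeled matrix: one row per wild type plus one per mutant.

    Wild-type rows are labeled benign. Mutant rows carry their record's
    label. Records whose annotated wild-type residue mismatches the
    sequence are dropped and counted (``provenance['wt_mismatch']``), as
    are duplicate ``(seq_id, variant)`` records
    (``provenance['duplicate']``). A mutant keeps its wild type's domain
    partition: point substitutions do not move domain boundaries.
    """
    wt_map = {s.seq_id: s for s in wildtypes}
    enc = DescriptorEncoder(mode=mode, sets=sets, partitions=partitions)
    log = {"wt_mismatch": 0, "duplicate": 0, "missing_wildtype": 0}

    seqs: list[ProteinSequence] = []
    row_ids: list[str] = []
    labels: list[float] = []
    part_map: dict[str, DomainPartition] = {}

    for s in wt_map.values():
        seqs.append(s)
        row_ids.append(s.seq_id)
        labels.append(_LABEL_CODE["benign"])
        if mode == "domainwise":
            if partitions is None or s.seq_id not in partitions:
                raise ValueError(f"domainwise mode: no partition for wild type {s.seq_id!r}")
            part_map[s.seq_id] = partitions[s.seq_id]

    seen: set[tuple[str, str]] = set()
    for v in variants:
        key = (v.seq_id, v.notation)
        if key in seen:
            log["duplicate"] += 1
            continue
        seen.add(key)
        wt = wt_map.get(v.seq_id)
        if wt is None:
            log["missing_wildtype"] += 1
            continue
        try:
            mut = apply_variant(wt, v)
        except WildTypeMismatchError:
            log["wt_mismatch"] += 1
            continue
        row_id = f"{v.seq_id}:{v.notation}"
        seqs.append(ProteinSequence(row_id, mut.residues))
        row_ids.append(row_id)
        labels.append(_LABEL_CODE.get(v.label, np.nan))
        if mode == "domainwise":
            part_map[row_id] = DomainPartition(
                row_id, partitions[v.seq_id].boundaries, partitions[v.seq_id].seq_length
            )

    enc.partitions = part_map if mode == "domainwise" else None
    enc.fit(seqs)
    data = enc.transform(seqs)
    data.index = pd.Index(row_ids, name="row_id")
    return FeatureMatrix(data, pd.Series(labels, index=data.index, name="label"), log)


def standardize(
    m: FeatureMatrix, scaler: StandardScaler | None = None
) -> tuple[FeatureMatrix, StandardScaler]:
    """Column-wise zero-mean unit-scale transform (population sd, divide-by-n).

    Fits on ``m`` when no scaler is supplied; otherwise applies the given
    (training-fitted) scaler so held-out rows never leak into the fit.
    Zero-variance columns keep scale 1 and become all-zero, with a warning.
    """
    if scaler is None:
        scaler = StandardScaler()
        scaler.fit(m.X)
        zero = np.flatnonzero(scaler.var_ == 0)
        if zero.size:
            warnings.warn(
                f"{zero.size} zero-variance feature(s) left unscaled: "
                f"{[m.feature_names[i] for i in zero[:5]]}...",
                RuntimeWarning,
                stacklevel=2,
            )
    data = pd.DataFrame(scaler.transform(m.X), index=m.data.index, columns=m.data.columns)
    return FeatureMatrix(data, m.labels.copy(), dict(m.provenance)), scaler


def pca_variance(m: FeatureMatrix) -> np.ndarray:
    """Explained-variance ratios of the (standardized) matrix, descending."""
    if m.data.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    return PCA().fit(m.X).explained_variance_ratio_
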
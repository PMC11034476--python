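"""Per-residue amino-acid descriptor tables and the set registry.

Descriptor sets map each of the 20 standard residues to a short numeric
property vector. The two z-scale sets carry published values transcribed
into versioned TSV fixtures: the 3-component z-scales of Hellberg et al.
(lipophilicity, steric bulk, electronic properties) and the extended
5-component z-scales of Sandberg et al. ``ZBinned`` is a coarse-grained
variant of Z3 derived by tercile binning. The remaining sets registered to
reach the canonical 75-column full-sequence encoding (ProtFP variants,
T-scales, ST-scales, VHSE, MS-WHIM, FASGAI, BLOSUM indices) are
deterministic synthetic stand-ins with the conventional dimensions; their
fixture files and docstrings are labelled synthetic and they carry no
published physicochemical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

STANDARD_RESIDUES = tuple("ARNDCQEGHILKMFPSTWYV")

__all__ = [
    "DescriptorTable",
    "UnknownDescriptorSetError",
    "UnsupportedResidueError",
    "available_sets",
    "get_table",
    "residue_vector",
    "full_registry",
    "registry_feature_names",
]


class UnknownDescriptorSetError(KeyError):
    """Requested descriptor set is not registered."""


class UnsupportedResidueError(ValueError):
    """Residue code outside the 20 standard one-letter codes."""

    def __init__(self, residue: str, position: int | None = None, seq_id: str | None = None):
        self.residue = residue
        self.position = position
        self.seq_id = seq_id
        ctx = ""
        if position is not None:
            ctx += f" at position {position}"
        if seq_id is not None:
            ctx += f" in sequence {seq_id!r}"
        super().__init__(f"unsupported residue {residue!r}{ctx}; expected one of the 20 standard codes")


@dataclass(frozen=True)
class DescriptorTable:
    """Immutable per-residue descriptor set.

    Parameters
    ----------
    set_name : str
        Registry identifier, e.g. ``"Z3"``.
    component_names : tuple of str
        Names of the vector components, e.g. ``("z1", "z2", "z3")``.
    values : mapping
        One numeric vector per standard residue.
    """

    set_name: str
    component_names: tuple[str, ...]
    values: Mapping[str, tuple[float, ...]] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_RESIDUES):
            missing = set(STANDARD_RESIDUES) - set(self.values)
            extra = set(self.values) - set(STANDARD_RESIDUES)
            raise ValueError(
                f"descriptor set {self.set_name!r} must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for res, vec in self.values.items():
            if len(vec) != self.dimension:
                raise ValueError(
                    f"residue {res!r} in set {self.set_name!r} has {len(vec)} components, "
                    f"expected {self.dimension}"
                )

    @property
    def dimension(self) -> int:
        return len(self.component_names)

    @property
    def feature_names(self) -> list[str]:
        """Qualified, registry-unique column names (``set.component``)."""
        return [f"{self.set_name}.{c}" for c in self.component_names]

    def vector(self, residue: str, position: int | None = None, seq_id: str | None = None) -> np.ndarray:
        return residue_vector(self, residue, position=position, seq_id=seq_id)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.values[r] for r in STANDARD_RESIDUES],
            index=list(STANDARD_RESIDUES),
            columns=list(self.component_names),
        )


def _load_fixture(fname: str, set_name: str) -> DescriptorTable:
    with resources.files("aavep.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return DescriptorTable(
        set_name=set_name,
        component_names=tuple(df.columns),
        values={r: tuple(float(x) for x in df.loc[r]) for r in df.index},
    )


# Registry order is canonical: it fixes the 75-column concatenation order of
# the full-sequence encoding.
_REGISTRY_FILES: dict[str, str] = {
    "Z3": "z3.tsv",
    "Z5": "z5.tsv",
    "ZBinned": "zbinned.tsv",
    "ProtFP-PCA3": "protfp_pca3_synthetic.tsv",
    "ProtFP-PCA5": "protfp_pca5_synthetic.tsv",
    "ProtFP-PCA8": "protfp_pca8_synthetic.tsv",
    "ProtFP-Feature": "protfp_feature_synthetic.tsv",
    "T": "tscales_synthetic.tsv",
    "ST": "stscales_synthetic.tsv",
    "VHSE": "vhse_synthetic.tsv",
    "MS-WHIM": "mswhim_synthetic.tsv",
    "FASGAI": "fasgai_synthetic.tsv",
    "BLOSUM": "blosum_synthetic.tsv",
}

_CACHE: dict[str, DescriptorTable] = {}


def available_sets() -> list[str]:
    return list(_REGISTRY_FILES)


def get_table(set_name: str) -> DescriptorTable:
    """Return the registered descriptor table for ``set_name``.

    Raises
    ------
    UnknownDescriptorSetError
        If the name is not registered; the message lists available sets.
    """
    if set_name not in _REGISTRY_FILES:
        raise UnknownDescriptorSetError(
            f"unknown descriptor set {set_name!r}; available: {', '.join(available_sets())}"
        )
    if set_name not in _CACHE:
        _CACHE[set_name] = _load_fixture(_REGISTRY_FILES[set_name], set_name)
    return _CACHE[set_name]


def residue_vector(
    table: DescriptorTable,
    residue: str,
    position: int | None = None,
    seq_id: str | None = None,
) -> np.ndarray:
    """Descriptor vector for one residue; lowercase input is folded to upper.

    Ambiguity and non-standard codes (X, U, B, Z, J, O, ``*``, gaps) are
    never imputed — they raise :class:`UnsupportedResidueError` carrying the
    offending code and, when supplied, its position context.
    """
    res = residue.upper()
    if res not in table.values:
        raise UnsupportedResidueError(residue, position=position, seq_id=seq_id)
    return np.asarray(table.values[res], dtype=float)


def full_registry() -> list[DescriptorTable]:
    """All registered sets in canonical order (75 columns in total)."""
    return [get_table(name) for name in _REGISTRY_FILES]


def registry_feature_names(tables: list[DescriptorTable] | None = None) -> list[str]:
    tables = full_registry() if tables is None else tables
    names: list[str] = []
    for t in tables:
        names.extend(t.feature_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names across descriptor sets")
    return names
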
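"""Domain partitions and MSA-based transfer of reference cut points.

Transporter families sharing a common fold (e.g. the 12-transmembrane-domain
LeuT fold of the SLC6 family) can be segmented once on a reference member
and the segmentation propagated to every homolog through a multiple sequence
alignment. A cut between residues b-1 and b is stored as the boundary value
b, i.e. "the domain starting at residue b"; a 12-domain partition therefore
carries 11 boundaries. Reference cut points are configuration, not computed:
they come from structure inspection upstream and are read from a small YAML
file.

Gap rule: when the alignment column holding a reference boundary is a gap in
a member, the member's boundary moves right to its next aligned residue.
This keeps domains contiguous and covering, at the cost of allowing an
empty domain when a member has a long deletion; empty domains fail loudly
unless explicitly allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .variants import ProteinSequence

__all__ = [
    "DomainPartition",
    "transfer_cutpoints",
    "split_domains",
    "read_alignment",
    "read_partition_config",
    "write_partition_config",
]


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA (gap ``-`` or ``.``) into member -> row."""
    from Bio import SeqIO

    msa = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not msa:
        raise ValueError(f"no alignment records in {path}")
    if len({len(s) for s in msa.values()}) != 1:
        raise ValueError(f"alignment rows in {path} have unequal lengths")
    return msa


@dataclass(frozen=True)
class DomainPartition:
    """Contiguous, covering segmentation of one sequence into domains."""

    seq_id: str
    boundaries: tuple[int, ...]
    seq_length: int

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"boundaries must be strictly increasing, got {b}")
        if b and (b[0] < 2 or b[-1] > self.seq_length):
            raise ValueError(
                f"boundaries {b} out of range for sequence length {self.seq_length}"
            )

    @property
    def n_domains(self) -> int:
        return len(self.boundaries) + 1

    def domain_of(self, position: int) -> int:
        """1-based domain index containing a 1-based residue position."""
        if not (1 <= position <= self.seq_length):
            raise IndexError(f"position {position} outside 1..{self.seq_length}")
        idx = 1
        for b in self.boundaries:
            if position >= b:
                idx += 1
        return idx

    def ranges(self) -> list[tuple[int, int]]:
        """Inclusive 1-based (start, end) per domain."""
        starts = [1, *self.boundaries]
        ends = [*(b - 1 for b in self.boundaries), self.seq_length]
        return list(zip(starts, ends))


def split_domains(seq: ProteinSequence, p: DomainPartition) -> list[str]:
    """Cut a sequence into its domains; concatenation restores the input."""
    if p.seq_length != len(seq):
        raise ValueError(
            f"partition for {p.seq_id!r} expects length {p.seq_length}, "
            f"sequence {seq.seq_id!r} has {len(seq)}"
        )
    pieces = [seq.residues[s - 1 : e] for s, e in p.ranges()]
    if any(not piece for piece in pieces):
        raise ValueError(f"partition of {seq.seq_id!r} produces a zero-length domain")
    return pieces


def _column_to_position(aligned: str) -> list[int | None]:
    """Ungapped 1-based residue position per alignment column (None on gaps)."""
    out: list[int | None] = []
    pos = 0
    for ch in aligned:
        if ch in "-.":
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def transfer_cutpoints(
    msa: dict[str, str],
    reference_id: str,
    ref_partition: DomainPartition,
    allow_empty: bool = False,
) -> dict[str, DomainPartition]:
    """Propagate reference domain boundaries to every MSA member.

    Parameters
    ----------
    msa : dict
        Aligned sequences (gap character ``-`` or ``.``), equal lengths.
    reference_id : str
        Member whose ungapped sequence the reference partition describes.
    ref_partition : DomainPartition
        Boundaries on the ungapped reference sequence.
    allow_empty : bool
        If True, members where a transferred boundary collides (empty
        domain) keep duplicate-resolved boundaries shifted minimally right;
        default is to raise.

    Returns a partition per member, reference included, each valid for the
    member's ungapped length.
    """
    if reference_id not in msa:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("alignment members have unequal lengths")

    ref_cols = _column_to_position(msa[reference_id])
    ref_len = sum(c is not None for c in ref_cols)
    if ref_partition.seq_length != ref_len:
        raise ValueError(
            f"reference partition length {ref_partition.seq_length} != ungapped "
            f"reference length {ref_len}"
        )
    # alignment column (0-based) of each reference boundary residue
    pos_to_col = {p: i for i, p in enumerate(ref_cols) if p is not None}
    boundary_cols = [pos_to_col[b] for b in ref_partition.boundaries]

    out: dict[str, DomainPartition] = {}
    for member, aligned in msa.items():
        cols = _column_to_position(aligned)
        m_len = sum(c is not None for c in cols)
        bounds: list[int] = []
        for col in boundary_cols:
            # gap rule: next non-gap column to the right
            j = col
            while j < len(cols) and cols[j] is None:
                j += 1
            if j == len(cols):
                # boundary beyond the member's last residue: domain(s) empty
                bounds.append(m_len + 1)
            else:
                bounds.append(cols[j])
        fixed: list[int] = []
        for b in bounds:
            if fixed and b <= fixed[-1]:
                if not allow_empty:
                    raise ValueError(
                        f"member {member!r}: transferred boundaries collide at {b} "
                        "(empty domain); pass allow_empty=True to shift"
                    )
                b = fixed[-1] + 1
            fixed.append(b)
        if fixed and fixed[-1] > m_len:
            raise ValueError(
                f"member {member!r}: boundary {fixed[-1]} beyond ungapped length {m_len}"
            )
        out[member] = DomainPartition(member, tuple(fixed), m_len)
    return out


def read_partition_config(path: str | Path) -> tuple[str, tuple[int, ...]]:
    """Read ``{reference_id, boundaries}`` from a YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        ref = str(cfg["reference_id"])
        bounds = tuple(int(b) for b in cfg["boundaries"])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"partition config {path} needs 'reference_id' and 'boundaries'") from exc
    return ref, bounds


def write_partition_config(reference_id: str, boundaries: tuple[int, ...], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"reference_id": reference_id, "boundaries": list(boundaries)}, fh)
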
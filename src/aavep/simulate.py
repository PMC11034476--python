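"""Synthetic transporter-family fixtures with planted pathogenicity signal.

The generator emulates a paralog family sharing a 12-domain architecture
(in the spirit of sodium-dependent transporter families with a conserved
12-transmembrane-helix fold): one ancestor sequence, members derived by
independent per-site substitution, and occasional short insertions placed
only at domain junctions so the true per-member partitions stay known and
the emitted alignment is exact by construction.

Planted variants encode pathogenicity through descriptor-space
displacement — the very quantity the downstream encoding averages.
Pathogenic variants sit inside designated sensitive domains and favor
substitutions that move the residue far in 3-component z-scale space;
benign variants sit anywhere and favor conservative substitutions. The
``effect_size`` parameter is the inverse temperature of that preference:
0 removes the signal entirely (both classes drawn identically — the null
dataset), large values make the substitution choice nearly deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .descriptors import STANDARD_RESIDUES, get_table
from .domains import DomainPartition, write_partition_config
from .variants import ProteinSequence, VariantRecord, write_fasta, write_variant_table

__all__ = ["SyntheticFamily", "generate_family", "generate_variants", "write_family"]

# Domain lengths loosely shaped like a compact transporter: longer terminal
# domains, helix-sized core domains. Short enough to keep end-to-end tests
# fast while leaving each domain's mean features sensitive to one mutation.
DEFAULT_DOMAIN_LENGTHS: tuple[int, ...] = (40, 20, 22, 18, 24, 20, 26, 15, 21, 19, 23, 32)

_AA = np.array(list(STANDARD_RESIDUES))
_MAX_INDEL = 3


@dataclass
class SyntheticFamily:
    """A generated family: wild types, true partitions, exact alignment."""

    wildtypes: list[ProteinSequence]
    partitions: dict[str, DomainPartition]
    msa: dict[str, str]
    ancestor: str

    @property
    def reference_id(self) -> str:
        return self.wildtypes[0].seq_id

    def member(self, seq_id: str) -> ProteinSequence:
        for s in self.wildtypes:
            if s.seq_id == seq_id:
                return s
        raise KeyError(seq_id)


def generate_family(
    n_members: int = 12,
    domain_lengths: tuple[int, ...] = DEFAULT_DOMAIN_LENGTHS,
    divergence: float = 0.1,
    seed: int = 0,
) -> SyntheticFamily:
    """Sample a paralog family with known domain partitions.

    Parameters
    ----------
    n_members : int
        Number of family members.
    domain_lengths : tuple of int
        Ancestor length of each of the 12 (generally N) domains; each >= 3.
    divergence : float
        Per-site substitution probability in [0, 0.5); also the
        per-junction probability of a short (1-3 residue) insertion, so a
        divergence of 0 yields members identical to the ancestor.
    seed : int
        Seeds all randomness.
    """
    if any(l < 3 for l in domain_lengths):
        raise ValueError("every domain length must be >= 3")
    if not (0 <= divergence < 0.5):
        raise ValueError("divergence must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_dom = len(domain_lengths)
    anc_domains = [rng.choice(_AA, size=l) for l in domain_lengths]
    width = len(str(max(n_members, 1)))

    # member domain = substituted ancestor domain (+ insertion at its end)
    member_domains: dict[str, list[np.ndarray]] = {}
    insertions: dict[str, list[np.ndarray]] = {}
    for i in range(n_members):
        mid = f"mem{i + 1:0{width}d}"
        doms, ins = [], []
        for k, anc in enumerate(anc_domains):
            d = anc.copy()
            hit = rng.random(len(d)) < divergence
            for j in np.flatnonzero(hit):
                choices = _AA[_AA != d[j]]
                d[j] = rng.choice(choices)
            extra = np.array([], dtype=_AA.dtype)
            if k < n_dom - 1 and rng.random() < divergence:
                extra = rng.choice(_AA, size=rng.integers(1, _MAX_INDEL + 1))
            doms.append(np.concatenate([d, extra]))
            ins.append(extra)
        member_domains[mid] = doms
        insertions[mid] = ins

    wildtypes, partitions, msa = [], {}, {}
    slot = [
        max(len(insertions[m][k]) for m in insertions) for k in range(n_dom)
    ]
    for mid, doms in member_domains.items():
        residues = "".join("".join(d) for d in doms)
        wildtypes.append(ProteinSequence(mid, residues, "synthetic family member"))
        lengths = [len(d) for d in doms]
        bounds = tuple(np.cumsum(lengths)[:-1] + 1)
        partitions[mid] = DomainPartition(mid, tuple(int(b) for b in bounds), len(residues))
        cols = []
        for k, d in enumerate(doms):
            core = len(anc_domains[k])
            cols.append("".join(d[:core]))
            pad = slot[k] - len(insertions[mid][k])
            cols.append("".join(d[core:]) + "-" * pad)
        msa[mid] = "".join(cols)
    return SyntheticFamily(wildtypes, partitions, msa, "".join("".join(d) for d in anc_domains))


def _z3_distance_matrix() -> np.ndarray:
    z3 = get_table("Z3")
    mat = np.array([z3.values[r] for r in STANDARD_RESIDUES])
    diff = mat[:, None, :] - mat[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def generate_variants(
    family: SyntheticFamily,
    n_benign: int = 150,
    n_pathogenic: int = 100,
    sensitive_domains: set[int] = frozenset({8}),
    effect_size: float = 6.0,
    seed: int = 0,
) -> list[VariantRecord]:
    """Plant labeled point mutations with a domain-localized signal.

    Pathogenic variants sample positions inside ``sensitive_domains`` and
    alternates with probability proportional to
    ``exp(effect_size * d/d_max)`` where ``d`` is the z-scale Euclidean
    displacement from the wild-type residue; benign variants sample
    positions anywhere and alternates with weight
    ``exp(-effect_size * d/d_max)``. With ``effect_size == 0`` both
    classes are drawn from the identical null distribution (uniform
    position anywhere, uniform alternate). Every record is guaranteed to
    pass wild-type verification, and (member, variant) pairs are unique.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    dist = _z3_distance_matrix()
    d_norm = dist / dist.max()
    res_idx = {r: i for i, r in enumerate(STANDARD_RESIDUES)}

    def positions_for(member: ProteinSequence, pathogenic: bool) -> np.ndarray:
        p = family.partitions[member.seq_id]
        if pathogenic and effect_size > 0:
            pos = []
            for k, (s, e) in enumerate(p.ranges(), start=1):
                if k in sensitive_domains:
                    pos.extend(range(s, e + 1))
            return np.array(pos, dtype=int)
        return np.arange(1, len(member) + 1)

    if effect_size > 0 and sensitive_domains:
        n_sensitive = sum(
            len(positions_for(m, True)) for m in family.wildtypes
        )
        if n_sensitive * 19 < n_pathogenic:
            raise ValueError(
                f"sensitive domains too short: {n_sensitive} positions cannot host "
                f"{n_pathogenic} distinct pathogenic variants"
            )

    records: list[VariantRecord] = []
    used: set[tuple[str, int, str]] = set()
    for label, n_req in (("pathogenic", n_pathogenic), ("benign", n_benign)):
        sign = 1.0 if label == "pathogenic" else -1.0
        made, attempts = 0, 0
        while made < n_req:
            attempts += 1
            if attempts > 200 * n_req:
                raise ValueError(
                    f"could not place {n_req} distinct {label} variants; "
                    "domains too short for the requested counts"
                )
            member = family.wildtypes[rng.integers(len(family.wildtypes))]
            pos = int(rng.choice(positions_for(member, label == "pathogenic")))
            wt = member.residues[pos - 1]
            wi = res_idx[wt]
            weights = np.exp(sign * effect_size * d_norm[wi])
            weights[wi] = 0.0
            weights /= weights.sum()
            alt = str(rng.choice(_AA, p=weights))
            key = (member.seq_id, pos, alt)
            if key in used:
                continue
            used.add(key)
            records.append(
                VariantRecord(
                    seq_id=member.seq_id,
                    position=pos,
                    wt_residue=wt,
                    alt_residue=alt,
                    label=label,
                    source="synthetic",
                )
            )
            made += 1
    return records


def write_family(
    family: SyntheticFamily, out_dir: str | Path, variants: list[VariantRecord] | None = None
) -> dict[str, Path]:
    """Emit the fixture files the real pipeline consumes.

    Writes wild-type FASTA, aligned FASTA, the reference partition config,
    and (optionally) the variant table; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "wildtypes": out / "wildtypes.fasta",
        "msa": out / "family_aligned.fasta",
        "partition": out / "reference_partition.yaml",
    }
    write_fasta(family.wildtypes, paths["wildtypes"])
    with open(paths["msa"], "w") as fh:
        for mid, row in family.msa.items():
            fh.write(f">{mid}\n{row}\n")
    ref = family.reference_id
    write_partition_config(ref, family.partitions[ref].boundaries, paths["partition"])
    if variants is not None:
        paths["variants"] = out / "variants.tsv"
        write_variant_table(variants, paths["variants"])
    return paths
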
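"""Core/stalk/knob domain partition and atom selection.

The partition of an antibody variable fragment into a globular *core*
(heavy-chain part + light chain), a two-stranded *stalk* and a distal
*knob* comes from explicit configuration — residue ranges per chain —
rather than automatic detection, because in practice the boundaries are
derived from a structure-based alignment that is curated by hand.

Residue identifiers are opaque strings (Kabat insertion codes such as
"100F" occur); ranges are therefore resolved positionally against the file
order of the chain, never numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import IncompleteBackboneError, PartitionError, UnknownResidueError
from .structure_io import Topology

__all__ = [
    "DomainPartition",
    "AtomSelection",
    "parse_domain_config",
    "select_atoms",
    "DOMAIN_NAMES",
    "ATOM_SUBSETS",
]

Residue = tuple[str, str]  # (chain_id, residue_number)

DOMAIN_NAMES = ("core", "core_heavy", "core_light", "stalk", "knob", "entire")
ATOM_SUBSETS = ("backbone", "heavy", "all")
BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass(frozen=True)
class DomainPartition:
    """Disjoint named residue sets defining the analysis domains.

    ``stalk_n`` and ``stalk_c`` are the N- and C-terminal stalk strands
    flanking the knob in heavy-chain sequence; ``stalk`` is their ordered
    concatenation.
    """

    core_heavy: tuple[Residue, ...]
    core_light: tuple[Residue, ...]
    stalk_n: tuple[Residue, ...]
    knob: tuple[Residue, ...]
    stalk_c: tuple[Residue, ...]

    @property
    def stalk(self) -> tuple[Residue, ...]:
        return self.stalk_n + self.stalk_c

    @property
    def core(self) -> tuple[Residue, ...]:
        return self.core_heavy + self.core_light

    @property
    def entire(self) -> tuple[Residue, ...]:
        return self.core_heavy + self.core_light + self.stalk_n + self.knob + self.stalk_c

    def residues_for(self, domain_name: str) -> tuple[Residue, ...]:
        if domain_name not in DOMAIN_NAMES:
            raise PartitionError(
                f"unknown domain '{domain_name}'; expected one of {DOMAIN_NAMES}"
            )
        return getattr(self, domain_name)

    def knob_residues_adjacent_to_stalk(self, n: int = 2) -> tuple[Residue, ...]:
        """The *n* knob residues at each end bordering the stalk strands."""
        if len(self.knob) <= 2 * n:
            return self.knob
        return self.knob[:n] + self.knob[-n:]


@dataclass(frozen=True)
class AtomSelection:
    """Resolved atom indices into a topology for one domain and subset."""

    domain_name: str
    atom_subset: str
    indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or (len(idx) > 1 and not np.all(np.diff(idx) > 0)):
            raise PartitionError("selection indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


def _resolve_ranges(
    chain_id: str,
    ranges: Sequence[Sequence],
    topology: Topology,
    domain: str,
) -> tuple[Residue, ...]:
    chain_res = topology.chain_residues(chain_id)
    pos = {r: i for i, r in enumerate(chain_res)}
    out: list[Residue] = []
    missing: list[str] = []
    for rng in ranges:
        start, stop = str(rng[0]), str(rng[1])
        if start not in pos or stop not in pos:
            missing.extend(r for r in (start, stop) if r not in pos)
            continue
        i, j = pos[start], pos[stop]
        if j < i:
            raise PartitionError(
                f"domain '{domain}': range {start}-{stop} reversed in chain "
                f"{chain_id} file order"
            )
        out.extend((chain_id, r) for r in chain_res[i : j + 1])
    if missing:
        raise UnknownResidueError(
            f"domain '{domain}': residues not found in chain {chain_id}: "
            + ", ".join(sorted(set(missing)))
        )
    return tuple(out)


def parse_domain_config(config, topology: Topology) -> DomainPartition:
    """Build a validated :class:`DomainPartition` from a config document.

    ``config`` is either a mapping (parsed YAML) or a path to a YAML file.
    Expected shape::

        domains:
          core_heavy: {chain: H, residues: [["2", "96"]]}
          core_light: {chain: L, residues: [["3", "107"]]}
          stalk_n:    {chain: H, residues: [["97", "99"]]}
          knob:       {chain: H, residues: [["100", "100X"]]}
          stalk_c:    {chain: H, residues: [["101", "104"]]}

    Ranges are inclusive and resolved by chain file order. Validation
    enforces: every residue exists; the five sets are pairwise disjoint;
    stalk_n, knob, stalk_c are contiguous and consecutive in heavy-chain
    order (the knob lies between the two stalk strands).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if "domains" in config:
        config = config["domains"]
    required = ("core_heavy", "core_light", "stalk_n", "knob", "stalk_c")
    missing = [k for k in required if k not in config]
    if missing:
        raise PartitionError(f"domain config missing sections: {missing}")
    resolved: dict[str, tuple[Residue, ...]] = {}
    for name in required:
        section = config[name]
        resolved[name] = _resolve_ranges(
            str(section["chain"]), section["residues"], topology, name
        )
    # pairwise disjointness
    names = list(required)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            overlap = set(resolved[names[i]]) & set(resolved[names[j]])
            if overlap:
                raise PartitionError(
                    f"domains '{names[i]}' and '{names[j]}' overlap on "
                    f"{sorted(overlap)}"
                )
    # stalk_n + knob + stalk_c contiguous in heavy-chain file order
    hc = resolved["stalk_n"] + resolved["knob"] + resolved["stalk_c"]
    chain_ids = {c for c, _ in hc}
    if len(chain_ids) != 1:
        raise PartitionError("stalk and knob must lie on a single (heavy) chain")
    (chain,) = chain_ids
    chain_res = topology.chain_residues(chain)
    pos = {r: i for i, r in enumerate(chain_res)}
    positions = [pos[r] for _, r in hc]
    if positions != list(range(positions[0], positions[0] + len(positions))):
        raise PartitionError(
            "stalk_n, knob, stalk_c must be contiguous and consecutive in "
            "heavy-chain file order (knob between the two stalk strands)"
        )
    return DomainPartition(
        core_heavy=resolved["core_heavy"],
        core_light=resolved["core_light"],
        stalk_n=resolved["stalk_n"],
        knob=resolved["knob"],
        stalk_c=resolved["stalk_c"],
    )


def select_atoms(
    topology: Topology,
    partition: DomainPartition,
    domain_name: str,
    atom_subset: str = "backbone",
) -> AtomSelection:
    """Resolve a (domain, subset) pair to ordered atom indices.

    Subsets: ``backbone`` = atoms named N, CA, C per residue (O excluded;
    minimal rotation-defining set), ``heavy`` = all non-hydrogen atoms,
    ``all`` = everything. ``entire`` selects all residues declared in the
    partition. Under ``backbone``, a residue missing any of N/CA/C raises
    :class:`IncompleteBackboneError`.
    """
    if atom_subset not in ATOM_SUBSETS:
        raise PartitionError(
            f"unknown atom subset '{atom_subset}'; expected one of {ATOM_SUBSETS}"
        )
    wanted = set(partition.residues_for(domain_name))
    resnum = topology.residue_number
    indices: list[int] = []
    per_residue_backbone: dict[Residue, set[str]] = {r: set() for r in wanted}
    for i in range(topology.n_atoms):
        res = (str(topology.chain_id[i]), str(resnum[i]))
        if res not in wanted:
            continue
        name = str(topology.atom_name[i])
        element = str(topology.element[i]).upper()
        if atom_subset == "backbone":
            if name in BACKBONE_ATOMS:
                indices.append(i)
                per_residue_backbone[res].add(name)
        elif atom_subset == "heavy":
            if element not in ("H", "D"):
                indices.append(i)
        else:
            indices.append(i)
    if atom_subset == "backbone":
        incomplete = [
            r for r, seen in per_residue_backbone.items() if seen != set(BACKBONE_ATOMS)
        ]
        if incomplete:
            raise IncompleteBackboneError(
                "residues with incomplete backbone (need N, CA, C): "
                + ", ".join(f"{c}:{r}" for c, r in sorted(incomplete))
            )
    return AtomSelection(
        domain_name=domain_name,
        atom_subset=atom_subset,
        indices=np.array(sorted(indices), dtype=int),
    )
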
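"""Species-bound clusters (SBCs) across the clustering hierarchy.

An SBC for species *s* is a cluster, found at any difference threshold d in
the nested partition family, that contains every ESV assigned to *s* and no
ESV assigned to any other species.  Unassigned ESVs may ride along.  A
species with a single assigned ESV is always an SBC (its singleton at d = 0
qualifies).  Because the partitions are nested, the qualifying cluster for a
species, when it exists at a given d, is unique, and qualifying member-sets
grow monotonically with d.

When several distinct member-sets qualify for one species (the cluster can
absorb more unassigned ESVs as d rises), the reported SBC is the set that
persists over the widest d range, with ties broken by larger membership and
then by smallest member id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .core_io import EsvRecord, PresenceMatrix
from .swarmclust import PartitionHierarchy

__all__ = [
    "UNASSIGNED",
    "SpeciesAssignment",
    "SbcRecord",
    "assign_species",
    "find_sbcs",
    "merge_presence_by_sbc",
    "sbc_summary",
]

UNASSIGNED = "UNASSIGNED"
SBP_THRESHOLD = 0.8


@dataclass
class SpeciesAssignment:
    """ESV -> species map after thresholding the species-level bootstrap."""

    assignment: dict[str, str]
    threshold: float = SBP_THRESHOLD

    def species_members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for esv, sp in self.assignment.items():
            if sp != UNASSIGNED:
                out.setdefault(sp, set()).add(esv)
        return out


@dataclass
class SbcRecord:
    """One species-bound cluster with the d range where its member-set occurs."""

    species: str
    members: frozenset[str]
    d_min: int
    d_max: int

    def __post_init__(self) -> None:
        if self.d_min > self.d_max:
            raise ValueError("d_min > d_max")


def assign_species(
    records: Sequence[EsvRecord], threshold: float = SBP_THRESHOLD
) -> SpeciesAssignment:
    """Threshold species-level bootstrap proportions into assignments.

    An ESV is assigned iff its sBP >= threshold (default 0.8); everything
    else, including ESVs without taxonomy, is UNASSIGNED.
    """
    assignment = {}
    for r in records:
        if r.species is not None and r.sbp is not None and r.sbp >= threshold:
            assignment[r.esv_id] = r.species
        else:
            assignment[r.esv_id] = UNASSIGNED
    return SpeciesAssignment(assignment=assignment, threshold=threshold)


def find_sbcs(
    hierarchy: PartitionHierarchy,
    assign: SpeciesAssignment,
    selection: Literal["widest", "lowest_d"] = "widest",
) -> list[SbcRecord]:
    """Enumerate species-bound clusters over the partition hierarchy.

    For each species, every partition is scanned for the cluster containing
    all of the species' assigned ESVs; the cluster qualifies when it contains
    no ESV assigned to another species.  Qualifying member-sets are grouped
    into maximal runs of consecutive d with identical membership (nesting
    guarantees each set occupies one contiguous run).  ``selection`` picks
    the reported set: the widest-persisting run (default) or the first
    qualifying run at the lowest d.
    """
    esvs = set(hierarchy.partitions[0].assignment)
    unknown = set(assign.assignment) - esvs
    if unknown:
        raise ValueError(f"assignment covers ESVs absent from the hierarchy: {sorted(unknown)[:5]}")

    by_species = assign.species_members()
    out: list[SbcRecord] = []
    for species in sorted(by_species):
        assigned = by_species[species]
        foreign = {
            e for e, sp in assign.assignment.items() if sp not in (UNASSIGNED, species)
        }
        runs: list[list] = []  # [members, d_min, d_max]
        for part in hierarchy.partitions:
            anchor = next(iter(assigned))
            cluster = set(part.clusters[part.assignment[anchor]])
            qualifies = assigned <= cluster and not (cluster & foreign)
            if qualifies:
                members = frozenset(cluster)
                if runs and runs[-1][0] == members and runs[-1][2] == part.d - 1:
                    runs[-1][2] = part.d
                else:
                    runs.append([members, part.d, part.d])
        if not runs:
            continue
        if selection == "widest":
            best = min(
                runs, key=lambda r: (-(r[2] - r[1]), -len(r[0]), min(r[0]))
            )
        elif selection == "lowest_d":
            best = min(runs, key=lambda r: r[1])
        else:
            raise ValueError(f"unknown selection rule {selection!r}")
        out.append(SbcRecord(species=species, members=best[0], d_min=best[1], d_max=best[2]))
    return out


def merge_presence_by_sbc(presence: PresenceMatrix, sbcs: Sequence[SbcRecord]) -> PresenceMatrix:
    """One presence column per SBC: logical OR over member ESV columns.

    ESVs not belonging to any SBC drop out of this representation.  Guards
    against overlapping membership even though records drawn from a single
    hierarchy cannot overlap.
    """
    seen: set[str] = set()
    for sbc in sbcs:
        overlap = seen & sbc.members
        if overlap:
            raise ValueError(f"SBC membership overlap at {sorted(overlap)[:5]}")
        seen |= sbc.members
        missing = sbc.members - set(presence.features)
        if missing:
            raise ValueError(f"SBC members missing from presence matrix: {sorted(missing)[:5]}")
    cols = {
        sbc.species: presence.df[list(sbc.members)].any(axis=1) for sbc in sbcs
    }
    return PresenceMatrix(pd.DataFrame(cols, index=presence.df.index, dtype=bool))


def sbc_summary(assign: SpeciesAssignment, sbcs: Sequence[SbcRecord]) -> dict:
    """Recovery bookkeeping: how many assigned species came back as SBCs."""
    n_species = len(assign.species_members())
    return {
        "n_species_assigned": n_species,
        "n_recovered": len(sbcs),
        "n_not_recovered": n_species - len(sbcs),
        "n_member_esvs": sum(len(s.members) for s in sbcs),
    }
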
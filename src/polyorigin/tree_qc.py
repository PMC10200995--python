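"""Gene-family tree selection before origin analysis.

A tree enters the origin-assignment stage only if

1. it contains at least one sequence of every diploid species,
2. the outgroup species is present,
3. the reference polyploid contributes at least two gene copies and every
   other polyploid species at least one, and
4. every internal node carries a support value strictly greater than the
   threshold (default 70; a support of exactly 70 is rejected).  Nodes with
   *absent* support fail this criterion; the root and leaf branches carry
   no support and are exempt.

Trees are not re-rooted here: all criteria are topology-independent counts
plus a support scan.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .sections import SectionMap

REASON_MISSING_DIPLOID = "missing_diploid"
REASON_MISSING_OUTGROUP = "missing_outgroup"
REASON_INSUFFICIENT_REFERENCE = "insufficient_reference_copies"
REASON_MISSING_OTHER_POLYPLOID = "missing_other_polyploid"
REASON_LOW_SUPPORT = "low_support"


@dataclass
class FilterReport:
    """Partition of the input tree set into kept and rejected trees."""

    kept: list = field(default_factory=list)
    rejected: dict = field(default_factory=dict)  # tree id -> reason code

    def __len__(self) -> int:
        return len(self.kept) + len(self.rejected)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tree_id\tstatus\treason\n")
            for tid in self.kept:
                fh.write(f"{tid}\tkept\t.\n")
            for tid, reason in self.rejected.items():
                fh.write(f"{tid}\trejected\t{reason}\n")


def _rejection_reason(gft, section_map: SectionMap, min_support: float) -> str | None:
    species_of = section_map.resolve_leaves(gft.leaf_labels())
    counts = Counter(species_of.values())

    missing_diploids = section_map.diploid_species - counts.keys()
    if missing_diploids:
        return REASON_MISSING_DIPLOID
    if counts[section_map.outgroup_species] == 0:
        return REASON_MISSING_OUTGROUP
    ref = section_map.reference_polyploid
    if ref is not None and counts[ref] < 2:
        return REASON_INSUFFICIENT_REFERENCE
    for poly in section_map.polyploid_species:
        if poly != ref and counts[poly] == 0:
            return REASON_MISSING_OTHER_POLYPLOID
    for node in gft.internal_nodes(exclude_seed=True):
        if node.support is None or not node.support > min_support:
            return REASON_LOW_SUPPORT
    return None


def filter_trees(trees, section_map: SectionMap, min_support: float = 70) -> FilterReport:
    """Apply the selection criteria; every tree lands in ``kept`` or ``rejected``.

    The support criterion uses strict inequality (``support > min_support``).
    Raises :class:`~polyorigin.errors.MappingError` if any leaf species is
    not covered by ``section_map``.
    """
    report = FilterReport()
    for gft in trees:
        reason = _rejection_reason(gft, section_map, min_support)
        if reason is None:
            report.kept.append(gft.id)
        else:
            report.rejected[gft.id] = reason
    return report
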
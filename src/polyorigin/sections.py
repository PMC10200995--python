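"""Species-to-section mapping with ploidy classes.

The unit of interest throughout the pipeline is the taxonomic *section*: a
named clade of diploid species that is a candidate subgenome donor for the
polyploids under study.  A :class:`SectionMap` records, for every species,
its section and its ploidy class (``diploid``, ``polyploid`` or
``outgroup``), plus two special designations:

* the *reference polyploid* — the focal allopolyploid that must contribute
  two gene copies (homeologs) to every analysed gene family;
* the *control polyploid* — a polyploid of independently known parentage
  (e.g. an allotetraploid whose two diploid parents are established), used
  downstream as a sanity check on the tagging machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import MappingError, ScenarioError

DIPLOID = "diploid"
POLYPLOID = "polyploid"
OUTGROUP = "outgroup"

_PLOIDY_CLASSES = {DIPLOID, POLYPLOID, OUTGROUP}


@dataclass(frozen=True)
class SectionMap:
    """Immutable species → (section, ploidy) lookup.

    Parameters
    ----------
    section_of:
        Mapping species name → section name.
    ploidy_of:
        Mapping species name → one of ``diploid``/``polyploid``/``outgroup``.
        Exactly one species must be the outgroup.
    reference_polyploid:
        Species required to carry >= 2 gene copies per family (optional).
    control_polyploid:
        Polyploid with known parent sections (optional).
    expected_parent_sections:
        The known parents of the control polyploid.
    """

    section_of: dict
    ploidy_of: dict
    reference_polyploid: str | None = None
    control_polyploid: str | None = None
    expected_parent_sections: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if set(self.section_of) != set(self.ploidy_of):
            raise ScenarioError("section_of and ploidy_of must cover the same species")
        bad = {p for p in self.ploidy_of.values() if p not in _PLOIDY_CLASSES}
        if bad:
            raise ScenarioError(f"unknown ploidy classes: {sorted(bad)}")
        outgroups = [s for s, p in self.ploidy_of.items() if p == OUTGROUP]
        if len(outgroups) != 1:
            raise ScenarioError(
                f"exactly one outgroup species required, found {len(outgroups)}"
            )
        for role, sp in (
            ("reference_polyploid", self.reference_polyploid),
            ("control_polyploid", self.control_polyploid),
        ):
            if sp is not None and self.ploidy_of.get(sp) != POLYPLOID:
                raise ScenarioError(f"{role} {sp!r} is not a polyploid species")
        object.__setattr__(
            self, "expected_parent_sections", frozenset(self.expected_parent_sections)
        )

    # -- lookups ---------------------------------------------------------

    @property
    def species(self) -> frozenset:
        return frozenset(self.section_of)

    @property
    def outgroup_species(self) -> str:
        return next(s for s, p in self.ploidy_of.items() if p == OUTGROUP)

    @property
    def diploid_species(self) -> frozenset:
        return frozenset(s for s, p in self.ploidy_of.items() if p == DIPLOID)

    @property
    def polyploid_species(self) -> frozenset:
        return frozenset(s for s, p in self.ploidy_of.items() if p == POLYPLOID)

    @property
    def diploid_sections(self) -> frozenset:
        return frozenset(self.section_of[s] for s in self.diploid_species)

    def is_diploid(self, species: str) -> bool:
        return self.ploidy_of.get(species) == DIPLOID

    def is_polyploid(self, species: str) -> bool:
        return self.ploidy_of.get(species) == POLYPLOID

    def species_of_leaf(self, leaf_label: str) -> str:
        """Resolve a gene-tree leaf label to a species.

        Labels are either a bare species name or ``<species>_<copy index>``.
        """
        if leaf_label in self.section_of:
            return leaf_label
        base = leaf_label.rsplit("_", 1)[0]
        if base in self.section_of:
            return base
        raise MappingError(f"leaf label {leaf_label!r} matches no known species")

    def resolve_leaves(self, leaf_labels) -> dict:
        """Map every label to a species; raise listing *all* failures."""
        out, bad = {}, []
        for lab in leaf_labels:
            try:
                out[lab] = self.species_of_leaf(lab)
            except MappingError:
                bad.append(lab)
        if bad:
            raise MappingError(f"unmappable leaf labels: {sorted(bad)}")
        return out

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "section_of": dict(self.section_of),
            "ploidy_of": dict(self.ploidy_of),
            "reference_polyploid": self.reference_polyploid,
            "control_polyploid": self.control_polyploid,
            "expected_parent_sections": sorted(self.expected_parent_sections),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectionMap":
        return cls(
            section_of=dict(d["section_of"]),
            ploidy_of=dict(d["ploidy_of"]),
            reference_polyploid=d.get("reference_polyploid"),
            control_polyploid=d.get("control_polyploid"),
            expected_parent_sections=frozenset(d.get("expected_parent_sections", ())),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SectionMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_tsv(self, path) -> None:
        """Write ``species<TAB>section<TAB>ploidy<TAB>flags`` rows."""
        with open(path, "w") as fh:
            fh.write("species\tsection\tploidy\tflags\n")
            for sp in sorted(self.section_of):
                flags = []
                if sp == self.reference_polyploid:
                    flags.append("reference")
                if sp == self.control_polyploid:
                    flags.append(
                        "control:" + "|".join(sorted(self.expected_parent_sections))
                    )
                fh.write(
                    f"{sp}\t{self.section_of[sp]}\t{self.ploidy_of[sp]}\t"
                    f"{','.join(flags) or '.'}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "SectionMap":
        section_of, ploidy_of = {}, {}
        reference = control = None
        expected: frozenset = frozenset()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("species"):
                raise MappingError(f"{path}: expected a 'species' header line")
            for line in fh:
                if not line.strip():
                    continue
                sp, section, ploidy, flags = line.rstrip("\n").split("\t")
                section_of[sp] = section
                ploidy_of[sp] = ploidy
                for flag in flags.split(","):
                    if flag == "reference":
                        reference = sp
                    elif flag.startswith("control:"):
                        control = sp
                        expected = frozenset(
                            x for x in flag[len("control:"):].split("|") if x
                        )
        return cls(section_of, ploidy_of, reference, control, expected)
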
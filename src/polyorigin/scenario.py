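"""Ground-truthed allopolyploidy scenarios for simulation.

A :class:`ScenarioTruth` fixes everything the synthetic-data generator needs
to emulate the study system: the candidate donor sections and their diploid
species, the polyploids with the true donor section of each subgenome, the
outgroup, the true Ks modes for dated species pairs, and the per-donor
probability that a gene family retains the corresponding homeolog (the
"origin mixture", which injects gene-tree discordance directly at the
homeolog-retention level).

The default scenario mirrors a genus with four candidate donor sections
(Alatae, Sylvestres, Noctiflorae, Petunioides), a fifth diploid section
(Tomentosae), a reference allopolyploid with Alatae + Noctiflorae
subgenomes, further polyploids of mixed parentage, a control allotetraploid
of known Sylvestres x Tomentosae parentage, and a Solanum outgroup.  The
true Ks modes are the study-system values (e.g. 0.279 for the
Solanum-Nicotiana split, 0.068 for Alatae-Sylvestres), so the dated ages
produced downstream land in the empirically familiar 5-30 Mya range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import ScenarioError
from .sections import DIPLOID, OUTGROUP, POLYPLOID, SectionMap

#: Calibration constants: Solanum-Nicotiana split.
CALIBRATION_KS = 0.279
CALIBRATION_AGE_MYA = 29.5


def canonical_pair(a: str, b: str) -> tuple:
    """Unordered species pair, canonicalized by sorting."""
    return tuple(sorted((a, b)))


@dataclass(frozen=True)
class ScenarioTruth:
    """Complete truth record for one simulated allopolyploidy scenario."""

    sections: tuple
    species_per_section: dict
    polyploid_species: tuple
    subgenome_origins: dict  # polyploid -> tuple of (subgenome label, donor section)
    outgroup: str
    outgroup_section: str = "Outgroup"
    true_ks_peaks: dict = field(default_factory=dict)  # pair -> Ks mode
    true_dates: dict = field(default_factory=dict)  # pair/node -> age (Mya)
    origin_mixture: dict = field(default_factory=dict)  # donor section -> retention p
    reference_polyploid: str | None = None
    control_polyploid: str | None = None

    def __post_init__(self):
        sections = set(self.sections)
        if set(self.species_per_section) != sections:
            raise ScenarioError("species_per_section keys must equal sections")
        for poly in self.polyploid_species:
            if poly not in self.subgenome_origins:
                raise ScenarioError(f"no subgenome origins for polyploid {poly!r}")
        for poly, subs in self.subgenome_origins.items():
            if poly not in self.polyploid_species:
                raise ScenarioError(f"{poly!r} has origins but is not a polyploid")
            for label, donor in subs:
                if donor not in sections:
                    raise ScenarioError(
                        f"subgenome {poly}/{label}: unknown donor section {donor!r}"
                    )
        for donor, p in self.origin_mixture.items():
            if not (0.0 <= p <= 1.0):
                raise ScenarioError(f"origin_mixture[{donor!r}]={p} outside [0,1]")
        diploids = {s for spp in self.species_per_section.values() for s in spp}
        if self.outgroup in diploids or self.outgroup in self.polyploid_species:
            raise ScenarioError("outgroup must be a dedicated species")
        for role, sp in (
            ("reference_polyploid", self.reference_polyploid),
            ("control_polyploid", self.control_polyploid),
        ):
            if sp is not None and sp not in self.polyploid_species:
                raise ScenarioError(f"{role} {sp!r} is not in polyploid_species")
        canon = {canonical_pair(*k): v for k, v in self.true_ks_peaks.items()}
        object.__setattr__(self, "true_ks_peaks", canon)

    # -- derived views ---------------------------------------------------

    @property
    def diploid_species(self) -> tuple:
        return tuple(
            s for sec in self.sections for s in self.species_per_section[sec]
        )

    def retention_probability(self, donor_section: str) -> float:
        return self.origin_mixture.get(donor_section, 1.0)

    def section_map(self) -> SectionMap:
        """Project the scenario onto the pipeline's species/section mapping."""
        section_of, ploidy_of = {}, {}
        for sec, spp in self.species_per_section.items():
            for sp in spp:
                section_of[sp] = sec
                ploidy_of[sp] = DIPLOID
        for poly in self.polyploid_species:
            section_of[poly] = "Polyploid"
            ploidy_of[poly] = POLYPLOID
        section_of[self.outgroup] = self.outgroup_section
        ploidy_of[self.outgroup] = OUTGROUP
        expected = frozenset()
        if self.control_polyploid is not None:
            expected = frozenset(
                donor for _, donor in self.subgenome_origins[self.control_polyploid]
            )
        return SectionMap(
            section_of=section_of,
            ploidy_of=ploidy_of,
            reference_polyploid=self.reference_polyploid,
            control_polyploid=self.control_polyploid,
            expected_parent_sections=expected,
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sections": list(self.sections),
            "species_per_section": {
                k: list(v) for k, v in self.species_per_section.items()
            },
            "polyploid_species": list(self.polyploid_species),
            "subgenome_origins": {
                k: [list(x) for x in v] for k, v in self.subgenome_origins.items()
            },
            "outgroup": self.outgroup,
            "outgroup_section": self.outgroup_section,
            "true_ks_peaks": {"|".join(k): v for k, v in self.true_ks_peaks.items()},
            "true_dates": {
                "|".join(k) if isinstance(k, tuple) else k: v
                for k, v in self.true_dates.items()
            },
            "origin_mixture": dict(self.origin_mixture),
            "reference_polyploid": self.reference_polyploid,
            "control_polyploid": self.control_polyploid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioTruth":
        return cls(
            sections=tuple(d["sections"]),
            species_per_section={
                k: tuple(v) for k, v in d["species_per_section"].items()
            },
            polyploid_species=tuple(d["polyploid_species"]),
            subgenome_origins={
                k: tuple(tuple(x) for x in v)
                for k, v in d["subgenome_origins"].items()
            },
            outgroup=d["outgroup"],
            outgroup_section=d.get("outgroup_section", "Outgroup"),
            true_ks_peaks={
                tuple(k.split("|")): v for k, v in d.get("true_ks_peaks", {}).items()
            },
            true_dates={
                (tuple(k.split("|")) if "|" in k else k): v
                for k, v in d.get("true_dates", {}).items()
            },
            origin_mixture=dict(d.get("origin_mixture", {})),
            reference_polyploid=d.get("reference_polyploid"),
            control_polyploid=d.get("control_polyploid"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_scenario() -> ScenarioTruth:
    """The stock study-system scenario used by tests and the CLI.

    Ks modes follow the study system's peaks; ages derive from the linear
    calibration ``age = Ks * 29.5 / 0.279``.
    """
    peaks = {
        ("Nala", "Nsyl"): 0.068,   # Alatae-Sylvestres split
        ("Nnoc", "Nobt"): 0.052,   # Noctiflorae-Petunioides split
        ("Nben", "Nben"): 0.095,   # reference-polyploid homeolog pairs
        ("Nafr", "Nafr"): 0.096,
        ("Nfor", "Nfor"): 0.101,
        ("Ncav", "Ncav"): 0.107,
        ("Slyc", "Nsyl"): 0.279,   # Solanum-Nicotiana calibration split
    }
    dates = {
        canonical_pair(a, b): ks * CALIBRATION_AGE_MYA / CALIBRATION_KS
        for (a, b), ks in peaks.items()
    }
    return ScenarioTruth(
        sections=("Alatae", "Sylvestres", "Noctiflorae", "Petunioides", "Tomentosae"),
        species_per_section={
            "Alatae": ("Nala", "Nlan"),
            "Sylvestres": ("Nsyl",),
            "Noctiflorae": ("Nnoc", "Ngla"),
            "Petunioides": ("Nobt", "Nacu"),
            "Tomentosae": ("Ntom", "Noto"),
        },
        polyploid_species=("Nben", "Nafr", "Ncav", "Nfor", "Ntab"),
        subgenome_origins={
            "Nben": (("a", "Alatae"), ("n", "Noctiflorae")),
            "Nafr": (("n", "Noctiflorae"), ("s", "Sylvestres")),
            "Ncav": (("a", "Alatae"), ("p", "Petunioides")),
            "Nfor": (("a", "Alatae"), ("s", "Sylvestres")),
            "Ntab": (("s", "Sylvestres"), ("t", "Tomentosae")),
        },
        outgroup="Slyc",
        outgroup_section="Solanum",
        true_ks_peaks=peaks,
        true_dates=dates,
        origin_mixture={
            "Alatae": 0.9,
            "Sylvestres": 0.7,
            "Noctiflorae": 0.8,
            "Petunioides": 0.6,
            "Tomentosae": 0.95,
        },
        reference_polyploid="Nben",
        control_polyploid="Ntab",
    )
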
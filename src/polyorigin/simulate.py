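"""Ground-truthed synthetic inputs for every pipeline stage.

Four generators emulate the study's data structures so the downstream
stages can be exercised against a known truth without any external data:

* gene-family trees under an allopolyploidy scenario, built on a fixed
  section backbone with multiplicative lognormal branch-length jitter —
  the pipeline consumes trees, not sequences, so discordance is injected
  directly through homeolog retention (the scenario's origin mixture)
  rather than via coalescent simulation;
* Ks tables as lognormal samples whose *mode* equals the scenario's true
  peak (lognormal: positive support and the right skew of empirical Ks
  distributions);
* mosaic plastome-like alignments with fixed recombination breakpoints,
  where each recombinant copies one parent-group lineage outside the
  breakpoints and another inside them;
* BED-like gene-locus tables with per-chromosome origin mixtures.

All generators are deterministic under a fixed seed, byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ScenarioError
from .recombination import PlastomeAlignment
from .scenario import ScenarioTruth
from .treeio import GeneFamilyTree

_BASE_BRANCH_LENGTH = 0.1


# ---------------------------------------------------------------------------
# gene-family trees


class _Node:
    __slots__ = ("name", "children", "parent", "length", "support")

    def __init__(self, name=None, children=None, length=_BASE_BRANCH_LENGTH):
        self.name = name
        self.children = children or []
        self.parent = None
        self.length = length
        self.support = None
        for child in self.children:
            child.parent = self

    def add_child(self, child):
        child.parent = self
        self.children.append(child)

    def replace_child(self, old, new):
        idx = self.children.index(old)
        new.parent = self
        self.children[idx] = new

    def is_leaf(self):
        return not self.children

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()


def _ladder(nodes):
    """((n1,n2),n3)... left-ladder join of a node list."""
    current = nodes[0]
    for node in nodes[1:]:
        current = _Node(children=[current, node])
    return current


def _to_newick(node, is_root=False) -> str:
    if node.is_leaf():
        return f"{node.name}:{node.length:.6g}"
    inner = ",".join(_to_newick(c) for c in node.children)
    if is_root:
        return f"({inner})"
    support = "" if node.support is None else (
        str(int(node.support))
        if float(node.support) == int(node.support)
        else f"{node.support:g}"
    )
    return f"({inner}){support}:{node.length:.6g}"


@dataclass
class SyntheticTreeSet:
    """Simulated gene-family trees plus the per-leaf donor truth."""

    trees: list  # GeneFamilyTree
    truth_tags: dict  # tree id -> {polyploid leaf label -> donor section}
    scenario: ScenarioTruth

    def newick_lines(self) -> list:
        return [gft.as_newick() for gft in self.trees]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "trees.nwk", "w") as fh:
            for line in self.newick_lines():
                fh.write(line + "\n")
        with open(outdir / "truth_tags.tsv", "w") as fh:
            fh.write("tree_id\tleaf\tdonor_section\n")
            for tid in sorted(self.truth_tags):
                for leaf in sorted(self.truth_tags[tid]):
                    fh.write(f"{tid}\t{leaf}\t{self.truth_tags[tid][leaf]}\n")
        self.scenario.to_json(outdir / "scenario.json")


def read_truth_tags(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            tid, leaf, donor = line.rstrip("\n").split("\t")
            out.setdefault(tid, {})[leaf] = donor
    return out


def simulate_gene_family_trees(
    truth: ScenarioTruth,
    n_families: int,
    noise: float = 0.0,
    support_range=(90.0, 100.0),
    seed: int | None = None,
    nest_prob: float = 0.2,
) -> SyntheticTreeSet:
    """Simulate gene-family trees with known homeolog origins.

    Every tree carries one leaf per diploid species, two leaves for the
    reference polyploid, 1-2 leaves for other polyploids (homeolog
    retention follows the scenario's origin mixture), and the outgroup.
    Each polyploid leaf is grafted sister to its true donor section's
    clade, or — with probability ``nest_prob`` — inside it (sister to a
    random diploid leaf of the section).  Branch lengths are multiplied by
    a lognormal factor with log-sd ``noise``; node supports are drawn
    uniformly in ``support_range``.
    """
    if n_families < 1:
        raise ScenarioError("n_families must be >= 1")
    lo, hi = support_range
    if not (0 <= lo <= hi <= 100):
        raise ScenarioError("support_range must lie within [0, 100]")
    if noise < 0:
        raise ScenarioError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    trees, truth_tags = [], {}
    for fam in range(1, n_families + 1):
        tree_id = f"F{fam:04d}"
        gft, tags = _simulate_one_tree(
            truth, rng, noise, (float(lo), float(hi)), nest_prob, tree_id
        )
        trees.append(gft)
        truth_tags[tree_id] = tags
    return SyntheticTreeSet(trees=trees, truth_tags=truth_tags, scenario=truth)


def _simulate_one_tree(truth, rng, noise, support_range, nest_prob, tree_id):
    # backbone: ladder of section clades (sorted), each a ladder of species
    section_clades = {}
    clade_nodes = []
    for section in sorted(truth.sections):
        leaves = [_Node(name=sp) for sp in sorted(truth.species_per_section[section])]
        clade = leaves[0] if len(leaves) == 1 else _ladder(leaves)
        section_clades[section] = clade
        clade_nodes.append(clade)
    ingroup = _ladder(clade_nodes)
    root = _Node(children=[ingroup, _Node(name=truth.outgroup)])

    # graft polyploid homeologs onto their true donor clades
    tags = {}
    for poly in sorted(truth.polyploid_species):
        subs = truth.subgenome_origins[poly]
        if poly == truth.reference_polyploid:
            retained = list(subs)
        else:
            retained = [
                sub
                for sub in subs
                if rng.random() < truth.retention_probability(sub[1])
            ]
            if not retained:
                retained = [subs[int(rng.integers(len(subs)))]]
        for k, (_, donor) in enumerate(retained, start=1):
            leaf = _Node(name=f"{poly}_{k}")
            tags[leaf.name] = donor
            clade = section_clades[donor]
            nest = rng.random() < nest_prob
            if nest:
                species = sorted(truth.species_per_section[donor])
                target_name = species[int(rng.integers(len(species)))]
                target = next(
                    nd
                    for nd in clade.preorder()
                    if nd.is_leaf() and nd.name == target_name
                )
            else:
                target = clade
            parent = target.parent
            cherry = _Node(children=[target, leaf])
            parent.replace_child(target, cherry)
            # section_clades keeps pointing at the original clade, so later
            # sister grafts attach below earlier ones (closest to the clade)

    # branch-length jitter (multiplicative lognormal, mean-one) and supports
    for node in root.preorder():
        if node is root:
            continue
        factor = (
            1.0
            if noise == 0
            else float(np.exp(noise * rng.standard_normal() - 0.5 * noise * noise))
        )
        node.length = _BASE_BRANCH_LENGTH * factor
        if not node.is_leaf():
            node.support = round(float(rng.uniform(*support_range)), 1)
    newick = _to_newick(root, is_root=True) + ";"
    return GeneFamilyTree.from_newick(newick, tree_id), tags


# ---------------------------------------------------------------------------
# Ks tables


def simulate_ks_table(
    truth: ScenarioTruth,
    n_pairs_per_comparison: int,
    sd: float = 0.2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Lognormal Ks samples whose mode equals each pair's true peak.

    With log-sd ``sd``, a lognormal with median ``m`` has its mode at
    ``m * exp(-sd^2)``; the generator therefore sets the median to
    ``peak * exp(sd^2)`` so the distribution peaks exactly at the
    scenario's true Ks value — the quantity the downstream KDE + argmax
    step estimates.
    """
    if sd <= 0:
        raise ScenarioError("sd must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for (a, b), peak in sorted(truth.true_ks_peaks.items()):
        if n_pairs_per_comparison == 0:
            continue
        z = rng.standard_normal(n_pairs_per_comparison)
        ks = peak * np.exp(sd * sd) * np.exp(sd * z)
        for value in ks:
            rows.append((a, b, float(value), a == b))
    return pd.DataFrame(rows, columns=["species_a", "species_b", "ks", "homeolog"])


# ---------------------------------------------------------------------------
# mosaic alignments


@dataclass
class MosaicAlignmentTruth:
    """A simulated alignment with known recombination breakpoints."""

    alignment: PlastomeAlignment
    breakpoints: list  # (start, end) 1-based inclusive, copied from parent B
    parent_divergence: float
    attachments: dict = field(default_factory=dict)  # recombinant -> (A leaf, B leaf)


def _mutate(seq: np.ndarray, p: float, rng) -> np.ndarray:
    if p <= 0:
        return seq.copy()
    seq = seq.copy()
    mask = rng.random(seq.size) < p
    n = int(mask.sum())
    if n:
        seq[mask] = (seq[mask] + rng.integers(1, 4, size=n)) % 4
    return seq


def _evolve_group(consensus: np.ndarray, n: int, mut_rate: float, rng) -> list:
    """Random bifurcating descent from a group consensus sequence."""
    out = [None] * n

    def recurse(indices, seq):
        seq = _mutate(seq, mut_rate, rng)
        if len(indices) == 1:
            out[indices[0]] = seq
            return
        k = int(rng.integers(1, len(indices)))
        recurse(indices[:k], seq)
        recurse(indices[k:], seq)

    recurse(list(range(n)), consensus)
    return out


def _validate_breakpoints(breakpoints, length):
    prev_end = 0
    for start, end in breakpoints:
        if not (1 <= start <= end <= length):
            raise ScenarioError(f"breakpoint ({start},{end}) outside [1,{length}]")
        if start <= prev_end:
            raise ScenarioError("breakpoints must be sorted and disjoint")
        prev_end = end


def simulate_mosaic_alignment(
    length: int,
    n_taxa_per_parent: int,
    parent_divergence: float,
    breakpoints,
    mut_rate: float = 0.01,
    seed: int | None = None,
    n_recombinants: int | None = None,
) -> MosaicAlignmentTruth:
    """Simulate a recombinant ("mosaic") alignment with known breakpoints.

    Two parent groups (``A*``, ``B*``) diverge by ``parent_divergence``
    substitutions/site and each evolves internal structure at per-branch
    rate ``mut_rate``.  Each recombinant row (``R*``) copies a randomly
    chosen A lineage outside the breakpoint intervals and a randomly
    chosen B lineage inside them, then accrues private mutations.  An
    empty breakpoint list yields a clonal (null) alignment in which the
    recombinant group is simply extra A lineages.
    """
    breakpoints = [tuple(bp) for bp in breakpoints]
    _validate_breakpoints(breakpoints, length)
    if n_taxa_per_parent < 1:
        raise ScenarioError("n_taxa_per_parent must be >= 1")
    if n_recombinants is None:
        n_recombinants = n_taxa_per_parent
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=length).astype(np.uint8)
    parent_a = _mutate(root, parent_divergence / 2.0, rng)
    parent_b = _mutate(root, parent_divergence / 2.0, rng)
    group_a = _evolve_group(parent_a, n_taxa_per_parent, mut_rate, rng)
    group_b = _evolve_group(parent_b, n_taxa_per_parent, mut_rate, rng)

    taxa = [f"A{i + 1}" for i in range(n_taxa_per_parent)]
    rows = list(group_a)
    taxa += [f"B{i + 1}" for i in range(n_taxa_per_parent)]
    rows += list(group_b)
    attachments = {}
    for r in range(n_recombinants):
        ia = int(rng.integers(n_taxa_per_parent))
        ib = int(rng.integers(n_taxa_per_parent))
        seq = group_a[ia].copy()
        for start, end in breakpoints:
            seq[start - 1 : end] = group_b[ib][start - 1 : end]
        seq = _mutate(seq, mut_rate, rng)
        name = f"R{r + 1}"
        taxa.append(name)
        rows.append(seq)
        attachments[name] = (f"A{ia + 1}", f"B{ib + 1}")

    alignment = PlastomeAlignment(taxa=taxa, matrix=np.vstack(rows))
    return MosaicAlignmentTruth(
        alignment=alignment,
        breakpoints=list(breakpoints),
        parent_divergence=parent_divergence,
        attachments=attachments,
    )


# ---------------------------------------------------------------------------
# gene loci


def simulate_gene_loci(
    truth: ScenarioTruth,
    chromosomes,
    per_chromosome_mixture: dict,
    n_genes: int,
    seed: int | None = None,
    gene_length: int = 1000,
) -> pd.DataFrame:
    """BED-like locus table with per-chromosome origin mixtures.

    ``chromosomes`` is a list of (name, length); ``per_chromosome_mixture``
    maps chromosome name -> {origin: proportion} with proportions summing
    to 1 (tolerance 1e-9).  Genes are apportioned to chromosomes
    proportionally to length and placed uniformly; each gene's origin is
    drawn from its chromosome's mixture.
    """
    chromosomes = list(chromosomes)
    for name, _ in chromosomes:
        mixture = per_chromosome_mixture.get(name)
        if mixture is None:
            raise ScenarioError(f"no origin mixture for chromosome {name!r}")
        total = sum(mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ScenarioError(
                f"chromosome {name!r}: origin proportions sum to {total}, not 1"
            )
    columns = ["chrom", "start", "end", "gene_id", "origin"]
    if n_genes == 0:
        return pd.DataFrame(columns=columns)
    rng = np.random.default_rng(seed)
    lengths = np.array([ln for _, ln in chromosomes], dtype=float)
    counts = rng.multinomial(n_genes, lengths / lengths.sum())
    rows = []
    gene_no = 0
    for (name, ln), count in zip(chromosomes, counts):
        mixture = per_chromosome_mixture[name]
        origins = sorted(mixture)
        probs = np.array([mixture[o] for o in origins], dtype=float)
        probs = probs / probs.sum()
        glen = min(gene_length, ln)
        choice = rng.choice(len(origins), size=count, p=probs)
        starts = rng.integers(0, max(ln - glen, 0) + 1, size=count)
        for start, oi in zip(np.sort(starts), choice):
            gene_no += 1
            rows.append(
                (name, int(start), int(start) + glen, f"g{gene_no:06d}", origins[oi])
            )
    return pd.DataFrame(rows, columns=columns)
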
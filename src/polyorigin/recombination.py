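"""Pairwise homoplasy index (Phi) recombination scanning for plastomes.

Under clonal (tree-like) evolution, nearby alignment columns share one
genealogy, so parsimony-informative sites close together should be mutually
*compatible* (each pair explicable on a single tree without homoplasy).
Recombination splices segments with different genealogies, producing
incompatible site pairs whose incompatibility depends on physical distance.
Phi is the mean incompatibility over all informative-site pairs within a
column distance ``w``; significance comes from permuting the ordering of
the informative columns (which destroys the distance structure but keeps
the site patterns) and asking how often the permuted Phi is as small as
observed.

Pair compatibility is decided exactly for multistate characters via
acyclicity of the state intersection graph (for binary characters this is
the four-gamete test).  Taxa with a gap or ``N`` at either column are
dropped from that pair's pattern; a pair reduced to fewer than four taxa is
not evaluable and is skipped (distinct from being compatible).

The module also partitions plastome alignments into the canonical LSC /
SSC / inverted-repeat regions and merges significant scan windows into
reportable recombinant regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import NotEvaluableError, PolyOriginError

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
_MISSING = frozenset((4, 5))
_DECODE = "ACGT-N"


@dataclass
class PlastomeAlignment:
    """Equal-length aligned sequences over {A,C,G,T,-,N} (case-insensitive).

    Columns are addressed 1-based inclusive in all user-facing coordinates;
    the internal matrix is 0-based.
    """

    taxa: list
    matrix: np.ndarray  # (n_taxa, n_columns) uint8 codes

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise PolyOriginError("matrix shape must be (n_taxa, n_columns)")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])

    @classmethod
    def from_strings(cls, taxa, sequences) -> "PlastomeAlignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise PolyOriginError("all rows must have equal length")
        try:
            matrix = np.array(
                [[_CODE[c] for c in seq.upper()] for seq in sequences],
                dtype=np.uint8,
            )
        except KeyError as exc:
            raise PolyOriginError(f"invalid alignment character: {exc}") from exc
        return cls(taxa=list(taxa), matrix=matrix)

    @classmethod
    def from_fasta(cls, path) -> "PlastomeAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise PolyOriginError(f"{path}: no sequences")
        return cls.from_strings(
            [r.id for r in records], [str(r.seq) for r in records]
        )

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(
                Seq("".join(_DECODE[c] for c in row)), id=taxon, description=""
            )
            for taxon, row in zip(self.taxa, self.matrix)
        ]
        SeqIO.write(records, str(path), "fasta")

    def slice_columns(self, start: int, end: int) -> "PlastomeAlignment":
        """Columns ``start..end`` (1-based inclusive), taxon order preserved."""
        if not (1 <= start <= end <= self.n_columns):
            raise PolyOriginError(
                f"interval ({start},{end}) outside alignment 1..{self.n_columns}"
            )
        return PlastomeAlignment(
            taxa=list(self.taxa), matrix=self.matrix[:, start - 1 : end].copy()
        )

    def concat(self, other: "PlastomeAlignment") -> "PlastomeAlignment":
        if self.taxa != other.taxa:
            raise PolyOriginError("cannot concatenate alignments with different taxa")
        return PlastomeAlignment(
            taxa=list(self.taxa), matrix=np.hstack([self.matrix, other.matrix])
        )


def partition_alignment(
    alignment: PlastomeAlignment, partition: dict, merge_ir: bool = False
) -> dict:
    """Slice the alignment into named structural regions.

    ``partition`` maps region name -> (start, end), 1-based inclusive.
    Intervals must lie within the alignment and not overlap.  With
    ``merge_ir=True`` the regions named ``IRa`` and ``IRb`` are
    concatenated into a single ``IR`` sub-alignment.
    """
    intervals = sorted(partition.items(), key=lambda kv: kv[1][0])
    prev_end = 0
    for name, (start, end) in intervals:
        if not (1 <= start <= end <= alignment.n_columns):
            raise PolyOriginError(
                f"region {name}: ({start},{end}) outside alignment"
            )
        if start <= prev_end:
            raise PolyOriginError(f"region {name} overlaps a previous region")
        prev_end = end
    out = {
        name: alignment.slice_columns(start, end)
        for name, (start, end) in partition.items()
    }
    if merge_ir and "IRa" in out and "IRb" in out:
        out["IR"] = out.pop("IRa").concat(out.pop("IRb"))
    return out


def informative_sites(alignment: PlastomeAlignment) -> np.ndarray:
    """0-based indices of parsimony-informative columns.

    A column is informative iff >= 2 states are each present in >= 2 taxa;
    gaps and N never count as states.
    """
    m = alignment.matrix
    counts = np.stack([(m == s).sum(axis=0) for s in range(4)])  # (4, n_cols)
    return np.nonzero((counts >= 2).sum(axis=0) >= 2)[0]


def pair_incompatibility(column_i, column_j):
    """0 if the two site patterns can coevolve on some tree without homoplasy.

    Exact test: build the bipartite state intersection graph (states of
    column i vs states of column j, one edge per observed state combination
    among taxa without missing data) — the pair is compatible iff the graph
    is acyclic.  Returns ``None`` (not evaluable) when fewer than 4 taxa
    remain after dropping missing data.
    """
    a = np.asarray(column_i, dtype=np.uint8)
    b = np.asarray(column_j, dtype=np.uint8)
    keep = (a < 4) & (b < 4)
    if keep.sum() < 4:
        return None
    combos = set(zip(a[keep].tolist(), b[keep].tolist()))
    # union-find cycle detection on the bipartite graph
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for sa, sb in combos:
        u, v = ("i", sa), ("j", sb)
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru == rv:
            return 1
        parent[ru] = rv
    return 0


def _pattern_ids(matrix: np.ndarray, sites: np.ndarray):
    """Assign an integer id to each informative column's pattern."""
    cols = [tuple(matrix[:, s]) for s in sites]
    uniq: dict = {}
    pids = np.empty(len(cols), dtype=np.int64)
    patterns = []
    for k, col in enumerate(cols):
        if col not in uniq:
            uniq[col] = len(patterns)
            patterns.append(np.array(col, dtype=np.uint8))
        pids[k] = uniq[col]
    return pids, patterns


def _incompatibility_matrix(patterns) -> np.ndarray:
    """Dense unique-pattern incompatibility matrix (NaN = not evaluable)."""
    n = len(patterns)
    ic = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i, n):
            val = pair_incompatibility(patterns[i], patterns[j])
            ic[i, j] = ic[j, i] = np.nan if val is None else float(val)
    return ic


def _near_pairs(positions: np.ndarray, w: int):
    """Index pairs (into the site list) with column distance <= w."""
    ia, ja = [], []
    k = len(positions)
    j0 = 0
    for i in range(k):
        for j in range(i + 1, k):
            if positions[j] - positions[i] > w:
                break
            ia.append(i)
            ja.append(j)
    return np.asarray(ia, dtype=np.int64), np.asarray(ja, dtype=np.int64)


def phi_statistic(alignment: PlastomeAlignment, w: int = 100) -> float:
    """Mean pair incompatibility over informative-site pairs within ``w`` columns.

    Distance is measured in original alignment columns.  Raises
    :class:`NotEvaluableError` when no evaluable pair exists (distinct from
    Phi = 0).
    """
    sites = informative_sites(alignment)
    pids, patterns = _pattern_ids(alignment.matrix, sites)
    ia, ja = _near_pairs(sites, w)
    if ia.size == 0:
        raise NotEvaluableError("no informative-site pairs within window")
    ic = _incompatibility_matrix(patterns)
    vals = ic[pids[ia], pids[ja]]
    if np.all(np.isnan(vals)):
        raise NotEvaluableError("all near pairs unevaluable (missing data)")
    return float(np.nanmean(vals))


@dataclass
class PhiTestResult:
    phi: float
    p_value: float
    n_informative: int
    n_pairs: int
    n_perm: int


def phi_permutation_test(
    alignment: PlastomeAlignment,
    w: int = 100,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PhiTestResult:
    """Permutation test for recombination: low observed Phi is the signal.

    The ordering of informative-site columns is permuted ``n_perm`` times
    (patterns keep their identity, positions keep theirs); the add-one
    estimator ``p = (1 + #{phi_perm <= phi_obs}) / (n_perm + 1)`` avoids
    p = 0.  Deterministic under a fixed seed.
    """
    if n_perm < 1:
        raise PolyOriginError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    sites = informative_sites(alignment)
    pids, patterns = _pattern_ids(alignment.matrix, sites)
    ia, ja = _near_pairs(sites, w)
    if ia.size == 0:
        raise NotEvaluableError("no informative-site pairs within window")
    ic = _incompatibility_matrix(patterns)
    obs_vals = ic[pids[ia], pids[ja]]
    if np.all(np.isnan(obs_vals)):
        raise NotEvaluableError("all near pairs unevaluable (missing data)")
    phi_obs = float(np.nanmean(obs_vals))
    k = len(sites)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        vals = ic[pids[perm[ia]], pids[perm[ja]]]
        phi_perm = np.nanmean(vals)
        if phi_perm <= phi_obs + 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PhiTestResult(
        phi=phi_obs,
        p_value=p,
        n_informative=int(k),
        n_pairs=int(ia.size),
        n_perm=n_perm,
    )


@dataclass
class Window:
    start: int  # 1-based inclusive
    end: int
    n_informative: int
    phi: float | None
    p_value: float | None

    @property
    def evaluable(self) -> bool:
        return self.p_value is not None


@dataclass
class WindowScanResult:
    windows: list
    regions: list  # merged (start, end) 1-based inclusive
    n_perm: int
    seed: int | None

    def windows_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start\tend\tn_informative\tphi\tp_value\n")
            for win in self.windows:
                phi = "NA" if win.phi is None else f"{win.phi:.6f}"
                p = "NA" if win.p_value is None else f"{win.p_value:.6g}"
                fh.write(f"{win.start}\t{win.end}\t{win.n_informative}\t{phi}\t{p}\n")

    def regions_to_bed(self, path, name: str = "recombinant") -> None:
        """0-based half-open BED (converted from 1-based inclusive)."""
        with open(path, "w") as fh:
            for start, end in self.regions:
                fh.write(f"{name}\t{start - 1}\t{end}\n")

    def regions_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start\tend\tlength\n")
            for start, end in self.regions:
                fh.write(f"{start}\t{end}\t{end - start + 1}\n")


def merge_significant_windows(
    windows, p_threshold: float = 0.01, min_region_len: int = 5000
) -> list:
    """Merge overlapping/adjacent significant windows into maximal intervals.

    Only intervals with length (end - start + 1) strictly greater than
    ``min_region_len`` are reported.
    """
    sig = sorted(
        (w for w in windows if w.evaluable and w.p_value < p_threshold),
        key=lambda w: (w.start, w.end),
    )
    merged = []
    for win in sig:
        if merged and win.start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], win.end)
        else:
            merged.append([win.start, win.end])
    return [(s, e) for s, e in merged if e - s + 1 > min_region_len]


def scan_and_merge(
    alignment: PlastomeAlignment,
    window_len: int = 1000,
    step: int = 250,
    w: int = 100,
    n_perm: int = 1000,
    seed: int | None = None,
    p_threshold: float = 0.01,
    min_region_len: int = 5000,
) -> WindowScanResult:
    """Sliding-window Phi tests plus region merging.

    Windows of ``window_len`` columns advance by ``step``; a final window
    flush with the alignment end is added if needed.  Windows where Phi is
    not evaluable get ``p = None`` and never contribute to regions.
    """
    if window_len < w:
        raise PolyOriginError("window_len must be >= w")
    length = alignment.n_columns
    starts = list(range(1, max(length - window_len + 1, 1) + 1, step))
    if starts and starts[-1] + window_len - 1 < length:
        starts.append(length - window_len + 1)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(len(starts))
    windows = []
    for start, child in zip(starts, child_seeds):
        end = min(start + window_len - 1, length)
        sub = alignment.slice_columns(start, end)
        n_inf = int(informative_sites(sub).size)
        try:
            res = phi_permutation_test(
                sub, w=w, n_perm=n_perm, rng=np.random.default_rng(child)
            )
            windows.append(Window(start, end, n_inf, res.phi, res.p_value))
        except NotEvaluableError:
            windows.append(Window(start, end, n_inf, None, None))
    regions = merge_significant_windows(windows, p_threshold, min_region_len)
    return WindowScanResult(windows=windows, regions=regions, n_perm=n_perm, seed=seed)
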
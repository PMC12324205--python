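"""Structure-derived direct/indirect benchmark with complex-disjoint splits.

Interaction tables list protein pairs attested by an experimental
structure, together with the parent structure id and per-chain sequence
coverage.  The builder

1. keeps entries of type ``structure`` whose chains both reach the
   coverage minimum (default 80%),
2. groups entries into complexes by structure id,
3. clusters complexes that share any protein (Jaccard > 0) into
   protein-disjoint clusters — the greedy merge equals the connected
   components of the overlap graph, so the partition is order-independent,
4. assigns the largest cluster (most direct pairs) to training and the
   rest to test, and
5. labels pairs: train positives are direct pairs within >=3-subunit
   complexes; train negatives are all other pairs of train-cluster
   proteins that are not direct anywhere (inter-complex pairs included);
   test labels come only from >=5-subunit complexes, with negatives
   strictly intra-complex (an extended inter-complex negative list is
   emitted separately).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from .pairs import pair_key

log = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "protein_a": "PROT1",
    "protein_b": "PROT2",
    "entry_type": "TYPE",
    "structure_id": "PDB_ID",
    "coverage_a": "COVERAGE1",
    "coverage_b": "COVERAGE2",
}


@dataclass(frozen=True)
class InteractionEntry:
    protein_a: str
    protein_b: str
    entry_type: str
    structure_id: str
    coverage_a: float
    coverage_b: float

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("accessions must be nonempty")
        for cov in (self.coverage_a, self.coverage_b):
            if not (0.0 <= cov <= 100.0):
                raise ValueError("coverage must lie in [0, 100]")


@dataclass
class BenchmarkComplex:
    structure_id: str
    members: set[str] = field(default_factory=set)
    direct_edges: set[str] = field(default_factory=set)  # canonical pair keys


@dataclass
class LabeledPairs:
    train_positives: set[str]
    train_negatives: set[str]
    test_positives: set[str]
    test_negatives: set[str]
    test_negatives_extended: set[str]


def parse_interactions(
    path: str | Path,
    columns: dict[str, str] | None = None,
    structure_only: bool = True,
) -> list[InteractionEntry]:
    """Parse a tab-separated interaction table into entries.

    Only rows whose type column equals ``structure`` are retained by
    default (rows backed by homology models are excluded).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table lacks required columns: {missing}")
    entries = []
    for _, row in df.iterrows():
        entry = InteractionEntry(
            protein_a=str(row[colmap["protein_a"]]),
            protein_b=str(row[colmap["protein_b"]]),
            entry_type=str(row[colmap["entry_type"]]),
            structure_id=str(row[colmap["structure_id"]]),
            coverage_a=float(row[colmap["coverage_a"]]),
            coverage_b=float(row[colmap["coverage_b"]]),
        )
        if structure_only and entry.entry_type != "structure":
            continue
        entries.append(entry)
    return entries


def coverage_filter(
    entries: list[InteractionEntry], min_cov: float = 80.0
) -> list[InteractionEntry]:
    """Keep entries where both chains reach the coverage minimum (inclusive)."""
    return [e for e in entries if min(e.coverage_a, e.coverage_b) >= min_cov]


def complexes_from_entries(entries: list[InteractionEntry]) -> list[BenchmarkComplex]:
    """Group entries into complexes by their parent structure id."""
    by_id: dict[str, BenchmarkComplex] = {}
    for e in entries:
        cpx = by_id.setdefault(e.structure_id, BenchmarkComplex(e.structure_id))
        cpx.members.update((e.protein_a, e.protein_b))
        cpx.direct_edges.add(pair_key(e.protein_a, e.protein_b))
    return [by_id[sid] for sid in sorted(by_id)]


def cluster_complexes(
    complexes: list[BenchmarkComplex],
) -> tuple[list[list[BenchmarkComplex]], dict[int, str]]:
    """Greedy protein-overlap clustering plus a train/test split.

    Complexes are processed in descending subunit count (ties by
    structure id); a complex joins — and merges — every existing cluster
    it shares a protein with, so the final clusters are exactly the
    connected components of the Jaccard>0 overlap graph and any two
    clusters are protein-disjoint.  The cluster with the most distinct
    direct pairs (ties by protein count) trains; the rest test.
    """
    if not complexes:
        raise ValueError("need at least one complex")
    ordered = sorted(complexes, key=lambda c: (-len(c.members), c.structure_id))
    clusters: list[list[BenchmarkComplex]] = []
    cluster_proteins: list[set[str]] = []
    for cpx in ordered:
        hits = [i for i, prot in enumerate(cluster_proteins) if prot & cpx.members]
        if not hits:
            clusters.append([cpx])
            cluster_proteins.append(set(cpx.members))
            continue
        target = hits[0]
        clusters[target].append(cpx)
        cluster_proteins[target] |= cpx.members
        for i in reversed(hits[1:]):
            clusters[target].extend(clusters.pop(i))
            cluster_proteins[target] |= cluster_proteins.pop(i)

    def cluster_rank(cluster: list[BenchmarkComplex]) -> tuple[int, int]:
        pairs: set[str] = set()
        prots: set[str] = set()
        for c in cluster:
            pairs |= c.direct_edges
            prots |= c.members
        return (len(pairs), len(prots))

    train_idx = max(range(len(clusters)), key=lambda i: cluster_rank(clusters[i]))
    split = {i: ("train" if i == train_idx else "test") for i in range(len(clusters))}
    if len(clusters) == 1:
        log.warning("single cluster: test side of the split is empty")
    return clusters, split


def build_labels(
    clusters: list[list[BenchmarkComplex]],
    split: dict[int, str],
    train_min_subunits: int = 3,
    test_min_subunits: int = 5,
) -> LabeledPairs:
    """Direct/indirect pair labels under the subunit-minimum filters.

    Dimers are never labeled (a dimer's single pair is trivially direct).
    Direct pairs attested only by too-small complexes are excluded from
    negatives rather than relabeled.
    """
    all_direct: set[str] = set()
    for cluster in clusters:
        for cpx in cluster:
            all_direct |= cpx.direct_edges

    train_pos: set[str] = set()
    train_prot: set[str] = set()
    test_pos: set[str] = set()
    test_neg: set[str] = set()
    test_prot: set[str] = set()
    test_complex_pairs: set[str] = set()

    for i, cluster in enumerate(clusters):
        side = split.get(i)
        if side == "train":
            for cpx in cluster:
                train_prot |= cpx.members
                if len(cpx.members) >= train_min_subunits:
                    train_pos |= cpx.direct_edges
        elif side == "test":
            for cpx in cluster:
                test_prot |= cpx.members
                if len(cpx.members) >= test_min_subunits:
                    intra = {
                        pair_key(a, b) for a, b in combinations(sorted(cpx.members), 2)
                    }
                    test_complex_pairs |= intra
                    test_pos |= cpx.direct_edges
                    test_neg |= intra - all_direct

    train_all = {
        pair_key(a, b) for a, b in combinations(sorted(train_prot), 2)
    }
    train_neg = train_all - train_pos - all_direct
    train_pairs = train_pos | train_neg

    # cluster disjointness already guarantees this; kept as a guard
    test_pos = (test_pos - train_pairs) & test_complex_pairs
    test_neg -= train_pairs

    test_all = {pair_key(a, b) for a, b in combinations(sorted(test_prot), 2)}
    test_neg_ext = test_neg | (test_all - all_direct - train_pairs - test_complex_pairs)

    if not train_pos:
        log.warning("empty training positives")
    if not test_pos:
        log.warning("empty test positives")
    return LabeledPairs(
        train_positives=train_pos,
        train_negatives=train_neg,
        test_positives=test_pos,
        test_negatives=test_neg,
        test_negatives_extended=test_neg_ext,
    )


def build_benchmark(
    entries: list[InteractionEntry],
    min_cov: float = 80.0,
    train_min_subunits: int = 3,
    test_min_subunits: int = 5,
) -> tuple[LabeledPairs, list[list[BenchmarkComplex]], dict[int, str]]:
    """Full pipeline: coverage filter -> complexes -> clusters -> labels."""
    filtered = coverage_filter(entries, min_cov=min_cov)
    complexes = complexes_from_entries(filtered)
    clusters, split = cluster_complexes(complexes)
    labels = build_labels(
        clusters,
        split,
        train_min_subunits=train_min_subunits,
        test_min_subunits=test_min_subunits,
    )
    return labels, clusters, split


def write_pair_list(pairs: set[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in sorted(pairs)))


def read_pair_list(path: str | Path) -> set[str]:
    return {
        pair_key(*line.split(" ")) for line in Path(path).read_text().splitlines() if line
    }
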
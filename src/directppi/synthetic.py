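"""Synthetic worlds with planted direct/indirect contact structure.

Generates every input class the pipeline consumes — bait–prey experiment
compendia, CF-MS elution matrices, structure-derived interaction tables,
coordinate models with per-residue confidence, and crosslink tables —
from a ground-truth set of protein complexes whose direct-contact edges
are known.  All generators are pure functions of their arguments
including the seed.

Generative choices (documented in docs/methods.md):

* Baits are drawn uniformly; preys join an experiment independently with
  probability ``p_direct`` (bait's direct partners), ``p_indirect``
  (co-complex members without an interface) or ``p_background``.
* Included preys carry Poisson(10) PSM-like counts, so presence rules
  such as ">= 4 PSMs" are exercisable.
* Elution profiles are interface-level Gaussian mixtures: every direct
  edge gets its own elution center and a protein's profile sums bumps
  (height 100) over its incident edges, mimicking subcomplexes that
  survive fractionation.  Direct partners therefore share a peak center
  exactly; indirect partners share none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .pairs import pair_key


@dataclass(frozen=True)
class CoOccurrenceRates:
    p_direct: float = 0.8
    p_indirect: float = 0.3
    p_background: float = 0.02

    def __post_init__(self) -> None:
        probs = (self.p_direct, self.p_indirect, self.p_background)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("rates must lie in [0, 1]")
        if not (self.p_direct >= self.p_indirect >= self.p_background):
            raise ValueError("need p_direct >= p_indirect >= p_background")


@dataclass(frozen=True)
class ElutionParams:
    n_fractions: int = 60
    peak_width: float = 2.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_fractions < 3:
            raise ValueError("need at least 3 fractions")
        if self.peak_width <= 0 or self.noise_scale < 0:
            raise ValueError("peak_width must be > 0 and noise_scale >= 0")


@dataclass(frozen=True)
class Complex:
    id: str
    members: tuple[str, ...]
    direct_edges: tuple[tuple[str, str], ...]

    def direct_pair_keys(self) -> set[str]:
        return {pair_key(a, b) for a, b in self.direct_edges}

    def indirect_pair_keys(self) -> set[str]:
        return {
            pair_key(a, b) for a, b in combinations(self.members, 2)
        } - self.direct_pair_keys()


@dataclass(frozen=True)
class SyntheticWorld:
    complexes: tuple[Complex, ...]
    proteins: tuple[str, ...]
    seed: int
    rates: CoOccurrenceRates = field(default_factory=CoOccurrenceRates)
    elution_params: ElutionParams = field(default_factory=ElutionParams)

    def direct_pairs(self) -> set[str]:
        out: set[str] = set()
        for cpx in self.complexes:
            out |= cpx.direct_pair_keys()
        return out

    def indirect_pairs(self) -> set[str]:
        out: set[str] = set()
        for cpx in self.complexes:
            out |= cpx.indirect_pair_keys()
        return out - self.direct_pairs()


def _topology_edges(members: list[str], topology: str) -> list[tuple[str, str]]:
    if topology == "chain":
        return list(zip(members, members[1:]))
    if topology == "ring":
        edges = list(zip(members, members[1:]))
        if len(members) > 2:
            edges.append((members[-1], members[0]))
        return edges
    if topology == "clique":
        return list(combinations(members, 2))
    raise ValueError(f"unknown topology {topology!r}")


def make_world(
    n_complexes: int = 20,
    size_range: tuple[int, int] = (5, 8),
    topology: str = "chain",
    rates: CoOccurrenceRates | None = None,
    seed: int = 0,
    elution_params: ElutionParams | None = None,
) -> SyntheticWorld:
    """Build a world of disjoint complexes with planted direct edges."""
    lo, hi = size_range
    if lo < 2 or hi < lo:
        raise ValueError("size range must satisfy 2 <= min <= max")
    if n_complexes < 1:
        raise ValueError("need at least one complex")
    rates = rates or CoOccurrenceRates()
    elution_params = elution_params or ElutionParams()
    rng = np.random.default_rng(seed)

    complexes: list[Complex] = []
    proteins: list[str] = []
    counter = 0
    for j in range(n_complexes):
        size = int(rng.integers(lo, hi + 1))
        members = [f"P{counter + i:04d}" for i in range(size)]
        counter += size
        proteins.extend(members)
        complexes.append(
            Complex(
                id=f"SYN{j:04d}",
                members=tuple(members),
                direct_edges=tuple(_topology_edges(members, topology)),
            )
        )
    return SyntheticWorld(
        complexes=tuple(complexes),
        proteins=tuple(proteins),
        seed=seed,
        rates=rates,
        elution_params=elution_params,
    )


def simulate_compendium(
    world: SyntheticWorld, n_experiments: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate a bait–prey experiment membership table.

    Each experiment draws a uniform bait; every other protein joins
    independently at the planted rate for its relation to the bait.
    Rows: (experiment_id, bait_id, prey_id, psm_count); the bait appears
    as its own prey record.
    """
    if n_experiments < 1:
        raise ValueError("need at least one experiment")
    if not world.proteins:
        raise ValueError("world has no proteins")
    rng = np.random.default_rng(seed)

    complex_of: dict[str, Complex] = {}
    neighbors: dict[str, set[str]] = {p: set() for p in world.proteins}
    for cpx in world.complexes:
        for p in cpx.members:
            complex_of[p] = cpx
        for a, b in cpx.direct_edges:
            neighbors[a].add(b)
            neighbors[b].add(a)

    records: list[tuple[str, str, str, int]] = []
    proteins = np.asarray(world.proteins)
    for e in range(n_experiments):
        eid = f"exp{e:05d}"
        bait = str(proteins[rng.integers(len(proteins))])
        bait_cpx = complex_of[bait].members
        records.append((eid, bait, bait, int(rng.poisson(10))))
        for prey in world.proteins:
            if prey == bait:
                continue
            if prey in neighbors[bait]:
                p = world.rates.p_direct
            elif prey in bait_cpx:
                p = world.rates.p_indirect
            else:
                p = world.rates.p_background
            if rng.random() < p:
                records.append((eid, bait, prey, int(rng.poisson(10))))
    return pd.DataFrame(
        records, columns=["experiment_id", "bait_id", "prey_id", "psm_count"]
    )


def gaussian_profile(
    center: float, peak_width: float, n_fractions: int, height: float = 100.0
) -> np.ndarray:
    """A single Gaussian elution bump over the fraction grid."""
    x = np.arange(n_fractions, dtype=float)
    return height * np.exp(-0.5 * ((x - center) / peak_width) ** 2)


def simulate_elution(world: SyntheticWorld, seed: int = 0) -> pd.DataFrame:
    """Simulate one CF-MS elution matrix (protein rows x fraction columns).

    Each direct edge draws an elution center; a protein's noise-free
    profile is the sum of bumps over its incident edges (proteins without
    edges get a lone monomer bump).  Counts are integer, nonnegative, and
    Poisson-corrupted when ``noise_scale > 0``.
    """
    ep = world.elution_params
    rng = np.random.default_rng(seed)
    margin = max(1.0, 2 * ep.peak_width)
    lo, hi = margin, ep.n_fractions - 1 - margin
    if hi <= lo:
        lo, hi = 0.0, float(ep.n_fractions - 1)

    edge_center: dict[str, float] = {}
    for cpx in world.complexes:
        for a, b in cpx.direct_edges:
            edge_center[pair_key(a, b)] = float(rng.uniform(lo, hi))

    profiles = np.zeros((len(world.proteins), ep.n_fractions))
    index = {p: i for i, p in enumerate(world.proteins)}
    touched = np.zeros(len(world.proteins), dtype=bool)
    for key, center in edge_center.items():
        a, b = key.split(" ")
        bump = gaussian_profile(center, ep.peak_width, ep.n_fractions)
        for p in (a, b):
            profiles[index[p]] += bump
            touched[index[p]] = True
    for p, i in index.items():
        if not touched[i]:
            profiles[i] = gaussian_profile(
                float(rng.uniform(lo, hi)), ep.peak_width, ep.n_fractions
            )

    if ep.noise_scale > 0:
        noisy = profiles + ep.noise_scale * (rng.poisson(profiles) - profiles)
    else:
        noisy = profiles
    counts = np.maximum(0, np.rint(noisy)).astype(int)
    return pd.DataFrame(
        counts,
        index=pd.Index(world.proteins, name="protein_id"),
        columns=[f"F{i+1}" for i in range(ep.n_fractions)],
    )


def make_benchmark_table(world: SyntheticWorld) -> pd.DataFrame:
    """Interaction table (structure-database dialect) for the world.

    One row per direct edge; the synthetic structure id is the parent
    complex id, type is ``structure``, per-chain coverage defaults 100%.
    """
    rows = []
    for cpx in world.complexes:
        for a, b in cpx.direct_edges:
            rows.append((a, b, "structure", cpx.id, 100.0, 100.0))
    return pd.DataFrame(
        rows, columns=["PROT1", "PROT2", "TYPE", "PDB_ID", "COVERAGE1", "COVERAGE2"]
    )


def make_toy_model(
    interface_contacts: int,
    mean_conf: float = 80.0,
    seed: int = 0,
    n_residues: int = 12,
    contact_offset: float = 5.0,
):
    """Two-chain coordinate model with an exact number of 8Å contacts.

    Chain A residues sit 20Å apart along x; the first ``interface_contacts``
    chain-B residues are placed ``contact_offset`` Å from their chain-A
    counterparts (one contact each under the 8Å representative-atom rule)
    and the rest 100Å away.  B-factors carry per-residue confidence around
    ``mean_conf``.  Returns (StructureModel, crosslink DataFrame); the
    crosslink table links one close residue pair and one distant pair.
    """
    from .structures import ModelChain, ModelResidue, StructureModel

    if not (0.0 <= mean_conf <= 100.0):
        raise ValueError("mean_conf must lie in [0, 100]")
    if interface_contacts < 0 or interface_contacts > n_residues:
        raise ValueError(
            f"cannot place {interface_contacts} contacts with {n_residues} residues"
        )
    if not (0.0 < contact_offset <= 8.0) and interface_contacts > 0:
        raise ValueError("contact_offset must lie in (0, 8] to form contacts")
    rng = np.random.default_rng(seed)

    def conf() -> float:
        return float(np.clip(rng.normal(mean_conf, 5.0), 0.0, 100.0))

    chain_a = []
    chain_b = []
    for i in range(n_residues):
        x = 20.0 * i
        chain_a.append(
            ModelResidue("GLY", i + 1, {"CA": np.array([x, 0.0, 0.0])}, conf())
        )
        y = contact_offset if i < interface_contacts else 100.0
        chain_b.append(
            ModelResidue("GLY", i + 1, {"CA": np.array([x, y, 0.0])}, conf())
        )
    model = StructureModel(
        chains={"A": ModelChain("A", tuple(chain_a)), "B": ModelChain("B", tuple(chain_b))}
    )

    xl_rows = [
        ("CHAINA", 1, "SYNPEPA", "CHAINB", 1, "SYNPEPB"),
        ("CHAINA", 1, "SYNPEPA", "CHAINB", n_residues, "SYNPEPC"),
    ]
    crosslinks = pd.DataFrame(
        xl_rows,
        columns=["protein1", "residue1", "peptide1", "protein2", "residue2", "peptide2"],
    )
    return model, crosslinks


# ---------------------------------------------------------------------------
# plain-text writers / readers (lossless round-trips with the pipeline inputs)

def write_compendium(compendium: pd.DataFrame, path: str | Path) -> None:
    compendium.to_csv(path, sep="\t", index=False)


def read_compendium(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"experiment_id": str, "bait_id": str, "prey_id": str})


def write_elut(elut: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated .elut: header = fraction labels, first col = protein id."""
    elut.to_csv(path, sep="\t", index_label="protein_id")


def read_elut(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")


def write_interactions(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_crosslinks(crosslinks: pd.DataFrame, path: str | Path) -> None:
    crosslinks.to_csv(path, index=False)


def read_crosslinks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"protein1": str, "protein2": str})
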
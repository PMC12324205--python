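"""Inter-protein crosslink sets, overlap Z-scores, and model satisfaction.

Crosslinking MS identifies covalently linked residue pairs between
spatially proximal proteins, an orthogonal line of evidence for direct
contact.  The analysis here (i) collapses multiple residue-level links
per protein pair into one non-redundant pair, (ii) removes pairs whose
identified peptides also occur verbatim in the partner sequence (a
possible intra-protein self-link misassigned across paralogs), (iii)
scores a network's overlap with the crosslink pairs against a resampled
null of random pairs over the crosslink protein universe, and (iv)
checks residue-level satisfaction on coordinate models via C-alpha
distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pairs import pair_key, split_pair_key
from .structures import StructureModel

log = logging.getLogger(__name__)

REQUIRED_XL_COLUMNS = ("protein1", "residue1", "peptide1", "protein2", "residue2", "peptide2")


class DegenerateNullError(ValueError):
    """Raised when the resampled null has zero spread."""


@dataclass(frozen=True)
class CrosslinkRecord:
    residue_a: int
    residue_b: int
    peptide_a: str
    peptide_b: str


@dataclass
class CrosslinkSet:
    pairs: dict[str, list[CrosslinkRecord]] = field(default_factory=dict)

    @property
    def protein_universe(self) -> set[str]:
        out: set[str] = set()
        for key in self.pairs:
            out.update(split_pair_key(key))
        return out

    def pair_keys(self) -> set[str]:
        return set(self.pairs)


def reduce_crosslinks(raw: pd.DataFrame) -> CrosslinkSet:
    """Collapse residue-level links into one entry per unordered pair.

    Intra-protein links are dropped; malformed rows are skipped with a
    logged warning.  Residue-level records are kept as annotations.
    """
    missing = [c for c in REQUIRED_XL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"crosslink table lacks columns: {missing}")
    out = CrosslinkSet()
    for idx, row in raw.iterrows():
        try:
            pa, pb = str(row["protein1"]), str(row["protein2"])
            record = CrosslinkRecord(
                residue_a=int(row["residue1"]),
                residue_b=int(row["residue2"]),
                peptide_a=str(row["peptide1"]),
                peptide_b=str(row["peptide2"]),
            )
        except (TypeError, ValueError) as exc:
            log.warning("skipping malformed crosslink row %s: %s", idx, exc)
            continue
        if pa == pb:
            continue  # not an inter-protein link
        key = pair_key(pa, pb)
        if pa > pb:  # store residues in canonical pair order
            record = CrosslinkRecord(
                record.residue_b, record.residue_a, record.peptide_b, record.peptide_a
            )
        out.pairs.setdefault(key, []).append(record)
    return out


def exclude_selflinks(
    xl: CrosslinkSet, sequences: Mapping[str, str]
) -> CrosslinkSet:
    """Drop pairs whose peptide matches the partner protein's sequence.

    A peptide from protein A occurring verbatim in protein B (or vice
    versa) makes the link ambiguous with an intra-protein self-link.
    Pairs with a missing sequence are retained with a warning — a data
    gap should not silently shrink the set.
    """
    kept = CrosslinkSet()
    for key, records in xl.pairs.items():
        a, b = split_pair_key(key)
        seq_a, seq_b = sequences.get(a), sequences.get(b)
        if seq_a is None or seq_b is None:
            log.warning("missing sequence for %s; pair retained", key)
            kept.pairs[key] = list(records)
            continue
        ambiguous = any(
            rec.peptide_a in seq_b or rec.peptide_b in seq_a for rec in records
        )
        if not ambiguous:
            kept.pairs[key] = list(records)
    return kept


@dataclass(frozen=True)
class OverlapResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    n_resamples: int
    seed: int


def overlap_zscore(
    network_top: set[str],
    xl: CrosslinkSet,
    n_resamples: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    """Z-score of a network's crosslink overlap against a resampled null.

    Each null draw samples ``|xl|`` unordered pairs uniformly without
    replacement from all pairs over the crosslink protein universe and
    intersects them with the network.
    """
    if not xl.pairs:
        raise ValueError("crosslink set is empty")
    if not network_top:
        raise ValueError("network pair set is empty")
    universe = sorted(xl.protein_universe)
    candidates = [
        pair_key(a, b) for i, a in enumerate(universe) for b in universe[i + 1 :]
    ]
    n_pairs = len(xl.pairs)
    if n_pairs > len(candidates):
        raise ValueError("more crosslink pairs than possible pairs (corrupt set)")

    observed = len(network_top & xl.pair_keys())
    in_network = np.fromiter(
        (key in network_top for key in candidates), dtype=bool, count=len(candidates)
    )
    rng = np.random.default_rng(seed)
    draws = np.empty(n_resamples, dtype=float)
    for r in range(n_resamples):
        idx = rng.choice(len(candidates), size=n_pairs, replace=False)
        draws[r] = in_network[idx].sum()
    mean = float(draws.mean())
    sd = float(draws.std(ddof=0))
    if sd == 0.0:
        if observed == mean:
            z = 0.0  # no spread and no deviation: no evidence either way
        else:
            raise DegenerateNullError(
                "null overlap distribution has zero spread; Z-score undefined"
            )
    else:
        z = (observed - mean) / sd
    return OverlapResult(
        observed=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        n_resamples=n_resamples,
        seed=seed,
    )


@dataclass(frozen=True)
class SatisfactionRecord:
    pair: str
    residue_a: int
    residue_b: int
    distance: float | None
    status: str  # satisfied | violated | unmapped


def check_satisfaction(
    model: StructureModel,
    xl_records: Sequence[tuple[str, int, str, int]],
    threshold: float = 35.0,
    chain_map: Mapping[str, str] | None = None,
    residue_offsets: Mapping[str, int] | None = None,
) -> list[SatisfactionRecord]:
    """C-alpha distance check of crosslinks against a coordinate model.

    ``xl_records`` holds (protein_a, residue_a, protein_b, residue_b);
    ``chain_map`` maps protein ids to chain ids (identity by default) and
    ``residue_offsets`` shifts crosslink residue numbering onto the
    model's.  Links whose chain or residue (or its C-alpha) cannot be
    resolved are reported ``unmapped`` and never counted as violated.
    """
    chain_map = dict(chain_map or {})
    residue_offsets = dict(residue_offsets or {})
    out: list[SatisfactionRecord] = []
    for prot_a, res_a, prot_b, res_b in xl_records:
        key = pair_key(prot_a, prot_b)

        def locate(protein: str, resnum: int) -> np.ndarray | None:
            chain = model.chains.get(chain_map.get(protein, protein))
            if chain is None:
                return None
            res = chain.residue(resnum + residue_offsets.get(protein, 0))
            if res is None:
                return None
            return res.atoms.get("CA")

        ca_a = locate(prot_a, int(res_a))
        ca_b = locate(prot_b, int(res_b))
        if ca_a is None or ca_b is None:
            out.append(SatisfactionRecord(key, int(res_a), int(res_b), None, "unmapped"))
            continue
        dist = float(np.linalg.norm(ca_a - ca_b))
        status = "satisfied" if dist <= threshold else "violated"
        out.append(SatisfactionRecord(key, int(res_a), int(res_b), dist, status))
    return out


def satisfaction_counts(records: Sequence[SatisfactionRecord]) -> dict[str, int]:
    counts = {"satisfied": 0, "violated": 0, "unmapped": 0}
    for rec in records:
        counts[rec.status] += 1
    return counts


def write_reduced(xl: CrosslinkSet, path: str | Path) -> None:
    rows = []
    for key in sorted(xl.pairs):
        a, b = split_pair_key(key)
        for rec in xl.pairs[key]:
            rows.append((a, rec.residue_a, rec.peptide_a, b, rec.residue_b, rec.peptide_b))
    pd.DataFrame(rows, columns=list(REQUIRED_XL_COLUMNS)).to_csv(path, index=False)
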
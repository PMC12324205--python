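"""Predicted-complex coordinate models, interface statistics, and pDockQ.

pDockQ scores the plausibility of a predicted two-chain interface from
the mean per-residue confidence (plDDT, stored in the B-factor field) of
interface residues and the log of the cross-chain contact count:

    x = <plDDT over interface residues> * ln(contacts)
    pDockQ = L / (1 + exp(-k (x - x0))) + b

A cross-chain residue pair is a contact when representative atoms
(C-beta; C-alpha for glycine) lie within the cutoff (default 8Å).  The
sigmoid constants originate from the FoldDock project's published
scoring script and are configurable in :class:`PDockQParams`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import gemmi
import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PDockQParams:
    L: float = 0.724
    k: float = 0.052
    x0: float = 152.611
    b: float = 0.018
    cutoff: float = 8.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass(frozen=True)
class ModelResidue:
    name: str
    number: int
    atoms: Mapping[str, np.ndarray]  # atom name -> xyz (Å)
    plddt: float

    def representative_atom(self) -> np.ndarray | None:
        """C-beta, falling back to C-alpha (glycine has no C-beta)."""
        if self.name != "GLY" and "CB" in self.atoms:
            return self.atoms["CB"]
        return self.atoms.get("CA")


@dataclass(frozen=True)
class ModelChain:
    id: str
    residues: tuple[ModelResidue, ...]

    def residue(self, number: int) -> ModelResidue | None:
        for res in self.residues:
            if res.number == number:
                return res
        return None


@dataclass(frozen=True)
class StructureModel:
    chains: Mapping[str, ModelChain]

    def __post_init__(self) -> None:
        for chain in self.chains.values():
            for res in chain.residues:
                for xyz in res.atoms.values():
                    if not np.all(np.isfinite(xyz)):
                        raise ValueError("non-finite coordinates")


@dataclass(frozen=True)
class InterfaceSummary:
    contact_count: int
    interface_residues: Mapping[str, tuple[int, ...]]
    mean_interface_plddt: float

    @property
    def x(self) -> float:
        if self.contact_count == 0:
            return 0.0
        return self.mean_interface_plddt * math.log(self.contact_count)


def read_model(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF coordinate file (first model only).

    Per-residue confidence is taken from the B-factor field (mean over
    the residue's atoms); files carrying 0–1 plDDT throughout are
    rescaled to 0–100 with a logged notice.
    """
    path = Path(path)
    fmt = format or ("mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")
    try:
        if fmt == "mmcif":
            structure = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt == "pdb":
            structure = gemmi.read_pdb(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"{path}: no models")

    model = structure[0]
    chains: dict[str, ModelChain] = {}
    max_b = 0.0
    for chain in model:
        residues = []
        for res in chain:
            atoms = {at.name: np.array([at.pos.x, at.pos.y, at.pos.z]) for at in res}
            if not atoms:
                continue
            bvals = [at.b_iso for at in res]
            plddt = float(np.mean(bvals))
            max_b = max(max_b, max(bvals, default=0.0))
            residues.append(ModelResidue(res.name, res.seqid.num, atoms, plddt))
        if residues:
            chains[chain.name] = ModelChain(chain.name, tuple(residues))
    if not chains:
        raise ValueError(f"{path}: no residues")
    if 0.0 < max_b <= 1.0:
        log.info("%s: B-factors all <= 1.0; rescaling confidence x100", path)
        chains = {
            cid: ModelChain(
                cid,
                tuple(
                    ModelResidue(r.name, r.number, r.atoms, r.plddt * 100.0)
                    for r in ch.residues
                ),
            )
            for cid, ch in chains.items()
        }
    return StructureModel(chains=chains)


def write_model(model: StructureModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as PDB or mmCIF, confidence in the B-factor column."""
    path = Path(path)
    fmt = format or ("mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")
    structure = gemmi.Structure()
    structure.name = "synthetic"
    gmodel = gemmi.Model("1")
    for cid, chain in model.chains.items():
        gchain = gemmi.Chain(cid)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[:1])
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.b_iso = res.plddt
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    structure.add_model(gmodel)
    structure.setup_entities()
    if fmt == "pdb":
        structure.write_pdb(str(path))
    elif fmt == "mmcif":
        structure.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def interface_contacts(
    model: StructureModel, params: PDockQParams = PDockQParams()
) -> InterfaceSummary:
    """Count cross-chain representative-atom contacts within the cutoff."""
    if len(model.chains) < 2:
        raise ValueError("interface statistics need at least two chains")

    chain_ids = sorted(model.chains)
    reps: dict[str, list[tuple[int, np.ndarray, float]]] = {}
    for cid in chain_ids:
        entries = []
        for res in model.chains[cid].residues:
            xyz = res.representative_atom()
            if xyz is not None:
                entries.append((res.number, xyz, res.plddt))
        reps[cid] = entries

    contacts = 0
    iface: dict[str, set[int]] = {cid: set() for cid in chain_ids}
    plddt_of: dict[tuple[str, int], float] = {}
    for i, ca in enumerate(chain_ids):
        for cb in chain_ids[i + 1 :]:
            if not reps[ca] or not reps[cb]:
                continue
            xa = np.array([e[1] for e in reps[ca]])
            xb = np.array([e[1] for e in reps[cb]])
            d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
            for ia, ib in zip(*np.nonzero(d <= params.cutoff)):
                contacts += 1
                na, _, pa = reps[ca][ia]
                nb, _, pb = reps[cb][ib]
                iface[ca].add(na)
                iface[cb].add(nb)
                plddt_of[(ca, na)] = pa
                plddt_of[(cb, nb)] = pb

    mean_plddt = float(np.mean(list(plddt_of.values()))) if plddt_of else 0.0
    return InterfaceSummary(
        contact_count=int(contacts),
        interface_residues={cid: tuple(sorted(v)) for cid, v in iface.items()},
        mean_interface_plddt=mean_plddt,
    )


def pdockq(summary: InterfaceSummary, params: PDockQParams = PDockQParams()) -> float:
    """Sigmoid interface-quality score; 0 by convention with no contacts."""
    if summary.contact_count == 0:
        return 0.0
    return params.L / (1.0 + math.exp(-params.k * (summary.x - params.x0))) + params.b


def pdockq_for_model(
    model: StructureModel, params: PDockQParams = PDockQParams()
) -> tuple[InterfaceSummary, float]:
    summary = interface_contacts(model, params)
    return summary, pdockq(summary, params)
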
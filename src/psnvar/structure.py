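"""Parse protein structures into residue lists with side-chain centroids.

Each residue becomes one vertex of the downstream contact network and is
represented by the unweighted mean of its side-chain heavy-atom positions;
glycine, having no side chain, is represented by its C-alpha. Parsing is
deterministic and keeps the file order of residues within the selected chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

#: Backbone heavy atoms excluded from the side-chain centroid.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is a crystallographic stand-in for methionine
    "MSE": "M",
}

STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"


class StructureError(ValueError):
    """Raised for unusable structure input (missing chain, no residues)."""


@dataclass(frozen=True)
class ResidueNode:
    """One structure residue: identity, position and side-chain centroid."""

    chain_id: str
    seq_index: int          # 1-based ordinal within the parsed chain
    resnum: str             # author residue number + insertion code
    aa: str                 # one-letter amino acid
    centroid: np.ndarray    # (3,) coordinates in Angstrom

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        if self.aa not in STANDARD_AA:
            raise ValueError(f"non-standard amino acid {self.aa!r}")
        if not np.all(np.isfinite(self.centroid)):
            raise ValueError("centroid must be finite")


@dataclass
class StructureModel:
    """An ordered chain of residues; ``n_residues`` is the network size N."""

    protein_id: str
    chain_id: str
    residues: list[ResidueNode]
    source: Path | None = field(default=None, compare=False)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int | str, convention: str = "index") -> ResidueNode:
        """Look up a residue by 1-based chain index or author residue number.

        ``convention`` is ``"index"`` (default: position = 1-based ordinal in
        the parsed chain) or ``"author"`` (position matched against the file's
        residue number with insertion code).
        """
        if convention == "index":
            pos = int(position)
            if not 1 <= pos <= self.n_residues:
                raise StructureError(
                    f"position {pos} outside chain {self.chain_id} (1..{self.n_residues})"
                )
            return self.residues[pos - 1]
        if convention == "author":
            key = str(position).strip()
            for res in self.residues:
                if res.resnum == key:
                    return res
            raise StructureError(
                f"author residue number {key!r} not found in chain {self.chain_id}"
            )
        raise ValueError(f"unknown position convention {convention!r}")


def residue_centroid(
    atoms: Sequence[tuple[str, Sequence[float]]], aa: str
) -> np.ndarray | None:
    """Side-chain centroid of one residue.

    ``atoms`` is a sequence of (atom name, xyz). Heavy side-chain atoms are all
    atoms except backbone N/CA/C/O/OXT and hydrogens; their unweighted mean is
    returned. Glycine uses CA. A non-glycine residue with no side-chain heavy
    atoms falls back to CA with a warning; a residue with no usable atoms at
    all yields ``None`` (caller drops it).
    """
    named = {}
    side = []
    for name, xyz in atoms:
        name = name.strip()
        if _is_hydrogen(name):
            continue
        named.setdefault(name, np.asarray(xyz, dtype=float))
        if name not in BACKBONE_ATOMS:
            side.append(np.asarray(xyz, dtype=float))
    if aa == "G":
        if "CA" in named:
            return named["CA"]
        return _mean_or_none(side, named)
    if side:
        return np.mean(side, axis=0)
    if "CA" in named:
        logger.warning("residue %s has no side-chain atoms; falling back to CA", aa)
        return named["CA"]
    return _mean_or_none([], named)


def _mean_or_none(side: list[np.ndarray], named: dict[str, np.ndarray]) -> np.ndarray | None:
    pool = side if side else list(named.values())
    if not pool:
        return None
    return np.mean(pool, axis=0)


def _is_hydrogen(name: str) -> bool:
    stripped = name.lstrip("0123456789")
    return stripped[:1] in ("H", "D")


def parse_structure(
    pdb_source: str | Path,
    chain: str | None = None,
    model_index: int = 0,
    protein_id: str | None = None,
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel` for one chain.

    Only the model selected by ``model_index`` (default: first) is read.
    HETATM groups and waters are skipped, except MSE which is mapped to MET.
    For alternate locations the highest-occupancy conformer is kept (ties:
    first listed), which is Biopython's selection rule.
    """
    pdb_source = Path(pdb_source)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(protein_id or pdb_source.stem, str(pdb_source))
    models = list(structure)
    if not models:
        raise StructureError(f"{pdb_source}: no models found")
    try:
        model = models[model_index]
    except IndexError:
        raise StructureError(
            f"{pdb_source}: model index {model_index} out of range ({len(models)} models)"
        ) from None

    chains = {c.id: c for c in model}
    if chain is None:
        chain_obj = next(iter(model))
        logger.info("%s: no chain given, using first chain %r", pdb_source.name, chain_obj.id)
    elif chain in chains:
        chain_obj = chains[chain]
    else:
        raise StructureError(
            f"{pdb_source}: chain {chain!r} not found; available chains: "
            + ", ".join(sorted(chains))
        )

    residues: list[ResidueNode] = []
    for res in chain_obj:
        hetflag, resseq, icode = res.id
        resname = res.get_resname().strip()
        if hetflag == "W":
            continue
        if resname not in THREE_TO_ONE:
            if hetflag == " ":
                logger.warning(
                    "%s %s: skipping non-standard residue %s %s",
                    pdb_source.name, chain_obj.id, resname, resseq,
                )
            continue
        aa = THREE_TO_ONE[resname]
        atoms = [(a.get_name(), a.get_coord()) for a in res.get_atoms()]
        centroid = residue_centroid(atoms, aa)
        if centroid is None:
            logger.warning(
                "%s %s: residue %s %s has no atoms; dropped",
                pdb_source.name, chain_obj.id, resname, resseq,
            )
            continue
        residues.append(
            ResidueNode(
                chain_id=chain_obj.id,
                seq_index=len(residues) + 1,
                resnum=f"{resseq}{icode}".strip(),
                aa=aa,
                centroid=centroid,
            )
        )
    if not residues:
        raise StructureError(f"{pdb_source}: chain {chain_obj.id} has no standard residues")
    return StructureModel(
        protein_id=protein_id or pdb_source.stem,
        chain_id=chain_obj.id,
        residues=residues,
        source=pdb_source,
    )


def residues_to_tsv(model: StructureModel) -> str:
    """TSV dump of the parsed residues (chain, seq_index, resnum, aa, x, y, z)."""
    lines = ["chain\tseq_index\tresnum\taa\tx\ty\tz"]
    for r in model.residues:
        x, y, z = r.centroid
        lines.append(f"{r.chain_id}\t{r.seq_index}\t{r.resnum}\t{r.aa}\t{x:.3f}\t{y:.3f}\t{z:.3f}")
    return "\n".join(lines) + "\n"
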
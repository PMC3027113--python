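"""Per-substitution feature assembly.

The full feature vector of one single amino acid polymorphism (SAP) has 42
named entries, in fixed order:

* conservation (7): pssm_wild, pssm_mutant, freq_wild, freq_mutant,
  det_pssm, det_freq, entropy (differences are mutant - wild);
* topology (4): degree, clustering, closeness, betweenness_scaled of the
  mutated site on the wild-type structure network;
* environment (25): for each of the five most conserved direct neighbours
  (ascending entropy, ties by ascending sequence index) the block
  [degree, clustering, closeness, betweenness_scaled, entropy]; sites with
  fewer than five neighbours are zero-padded;
* auxiliary (6): pam250 substitution score, wild-type solvent accessible
  area (A^2), aggregation propensity of wild and mutant and their change,
  and an HLA-family indicator.

All structural features come from the wild-type structure only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net_mod
from .conservation import ProfileMatrix, conservation_features
from .network import ContactNetwork
from .structure import STANDARD_AA, StructureModel

logger = logging.getLogger(__name__)

ENV_BLOCK = ("degree", "clustering", "closeness", "betweenness_scaled", "entropy")

CONSERVATION_NAMES = ("pssm_wild", "pssm_mutant", "freq_wild", "freq_mutant",
                      "det_pssm", "det_freq", "entropy")
TOPOLOGY_NAMES = ("degree", "clustering", "closeness", "betweenness_scaled")
ENVIRONMENT_NAMES = tuple(f"env{r}_{f}" for r in range(1, 6) for f in ENV_BLOCK)
AUXILIARY_NAMES = ("pam250", "sasa_wild", "agg_wild", "agg_mutant", "agg_change",
                   "hla_flag")

#: The documented, stable schema of the full feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    CONSERVATION_NAMES + TOPOLOGY_NAMES + ENVIRONMENT_NAMES + AUXILIARY_NAMES
)
N_FEATURES = len(FEATURE_NAMES)   # 42


class FeatureError(ValueError):
    """Raised when a record cannot be featurized."""


class WildTypeMismatch(FeatureError):
    """The variant table's wild-type residue disagrees with the structure."""


@dataclass(frozen=True)
class SapRecord:
    """One variant: where it is, what it changes, and (optionally) its class."""

    protein_id: str
    structure_file: str
    chain: str
    position: int
    wild: str
    mutant: str
    label: str | None = None       # "disease" | "polymorphism"

    def __post_init__(self) -> None:
        if self.wild == self.mutant:
            raise ValueError("wild and mutant residues must differ")
        for aa in (self.wild, self.mutant):
            if aa not in STANDARD_AA:
                raise ValueError(f"non-standard amino acid {aa!r}")
        if self.label is not None and self.label not in ("disease", "polymorphism"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class AuxTables:
    """Optional auxiliary inputs, preprocessed into in-memory tables.

    ``sasa``: (protein_id, seq_index) -> accessible area in A^2 (e.g. from a
    DSSP run exported to TSV). ``aggregation``: (protein_id, position, wild,
    mutant) -> (agg_wild, agg_mutant). ``hla_ids``: protein ids belonging to
    the HLA family.
    """

    sasa: dict[tuple[str, int], float] = field(default_factory=dict)
    aggregation: dict[tuple[str, int, str, str], tuple[float, float]] = field(
        default_factory=dict)
    hla_ids: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# PAM250

_PAM250: dict[tuple[str, str], float] | None = None


def _load_pam250() -> dict[tuple[str, str], float]:
    global _PAM250
    if _PAM250 is None:
        text = resources.files("psnvar.data").joinpath("pam250.txt").read_text()
        rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        header = rows[0].split()
        table: dict[tuple[str, str], float] = {}
        for line in rows[1:]:
            parts = line.split()
            a = parts[0]
            for b, v in zip(header, parts[1:]):
                table[(a, b)] = float(v)
        _PAM250 = table
    return _PAM250


def pam250_score(wild: str, mutant: str) -> float:
    """Substitution score from the shipped PAM250 log-odds matrix."""
    table = _load_pam250()
    try:
        return table[(wild, mutant)]
    except KeyError:
        raise FeatureError(f"no PAM250 entry for pair ({wild!r}, {mutant!r})") from None


# ---------------------------------------------------------------------------
# Solvent accessibility fallback (rolling-probe, probe radius 1.4 A)

_SASA_CACHE: dict[tuple[str, str], dict[int, float]] = {}


def compute_sasa(pdb_path: str | Path, chain: str | None = None) -> dict[int, float]:
    """Per-residue accessible surface area via the Shrake-Rupley rolling-probe
    algorithm (probe 1.4 A), keyed by 1-based index within the chain.

    Used as a fallback when no precomputed accessibility table is supplied.
    """
    key = (str(pdb_path), chain or "")
    if key in _SASA_CACHE:
        return _SASA_CACHE[key]
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    structure = PDBParser(QUIET=True).get_structure("s", str(pdb_path))
    model = next(iter(structure))
    ShrakeRupley(probe_radius=1.40).compute(model, level="R")
    chain_obj = model[chain] if chain is not None else next(iter(model))
    out: dict[int, float] = {}
    idx = 0
    for res in chain_obj:
        if res.id[0] not in (" ", "H_MSE"):
            continue
        idx += 1
        out[idx] = float(res.sasa)
    _SASA_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# Feature blocks

def environment_features(net: ContactNetwork, profile: ProfileMatrix,
                         pos: int,
                         _bc_cache: dict[int, float] | None = None) -> np.ndarray:
    """25-vector describing the five most conserved direct neighbours.

    Neighbours are ranked by ascending entropy (lower = more conserved), ties
    by ascending sequence index; each selected neighbour contributes
    [degree, clustering, closeness, betweenness_scaled, entropy] and missing
    blocks are zero-filled.
    """
    if not net.has_vertex(pos):
        raise FeatureError(f"position {pos} not in network")
    nbrs = net_mod.neighbors(net, pos)
    ranked = sorted(nbrs, key=lambda j: (profile.entropy(j), j))[:5]
    vec = np.zeros(25)
    for slot, j in enumerate(ranked):
        topo = net_mod.topology_features(net, j, _bc_cache=_bc_cache)
        vec[slot * 5: slot * 5 + 5] = (*topo.as_tuple(), profile.entropy(j))
    return vec


def auxiliary_features(record: SapRecord, aux: AuxTables | None = None,
                       model: StructureModel | None = None,
                       seq_index: int | None = None,
                       ) -> tuple[float, float, float, float, int]:
    """(sasa_wild, agg_wild, agg_mutant, agg_change, hla_flag) for a record.

    Accessibility comes from the supplied table when present, otherwise from
    the internal rolling-probe computation on the wild-type structure (0 if no
    structure is available). Missing aggregation entries default to 0 with a
    warning; the HLA flag is set from the configured protein-id list.
    """
    aux = aux or AuxTables()
    idx = seq_index if seq_index is not None else record.position

    sasa = aux.sasa.get((record.protein_id, idx))
    if sasa is None:
        if aux.sasa:
            logger.warning("no accessibility entry for %s position %s; using fallback",
                           record.protein_id, idx)
        source = model.source if model is not None else None
        if source is not None:
            sasa = compute_sasa(source, model.chain_id).get(idx, 0.0)
        else:
            sasa = 0.0

    agg = aux.aggregation.get((record.protein_id, record.position,
                               record.wild, record.mutant))
    if agg is None:
        if aux.aggregation:
            logger.warning("no aggregation entry for %s %s%d%s; defaulting to 0",
                           record.protein_id, record.wild, record.position,
                           record.mutant)
        agg_wild = agg_mutant = 0.0
    else:
        agg_wild, agg_mutant = agg

    hla_flag = int(record.protein_id in aux.hla_ids)
    return float(sasa), float(agg_wild), float(agg_mutant), \
        float(agg_mutant - agg_wild), hla_flag


def assemble(record: SapRecord, model: StructureModel, net: ContactNetwork,
             profile: ProfileMatrix, aux: AuxTables | None = None,
             position_convention: str = "index",
             _bc_cache: dict[int, float] | None = None) -> pd.Series:
    """Full 42-entry feature vector of one variant, as a named Series.

    The record's wild-type residue must match the parsed residue at the
    mapped position; otherwise the record is rejected (raises
    :class:`WildTypeMismatch`), mirroring the removal of variants whose
    structural mapping is inconsistent.
    """
    residue = model.residue_at(record.position, position_convention)
    if residue.aa != record.wild:
        raise WildTypeMismatch(
            f"{record.protein_id} position {record.position}: structure has "
            f"{residue.aa}, variant table says {record.wild}"
        )
    pos = residue.seq_index
    cons = conservation_features(profile, pos, record.wild, record.mutant)
    topo = net_mod.topology_features(net, pos, _bc_cache=_bc_cache)
    env = environment_features(net, profile, pos, _bc_cache=_bc_cache)
    sasa, agg_w, agg_m, agg_c, hla = auxiliary_features(
        record, aux, model=model, seq_index=pos)
    values = np.concatenate([
        cons.as_tuple(), topo.as_tuple(), env,
        [pam250_score(record.wild, record.mutant), sasa, agg_w, agg_m, agg_c, hla],
    ])
    return pd.Series(values, index=list(FEATURE_NAMES), name=_record_id(record))


def _record_id(record: SapRecord) -> str:
    return f"{record.protein_id}:{record.wild}{record.position}{record.mutant}"


# ---------------------------------------------------------------------------
# Table-level pipeline

def read_variant_table(path: str | Path) -> list[SapRecord]:
    """Read a tab-separated variant table into records.

    Columns: protein_id, structure_file, chain, position, wild, mutant and an
    optional label column (disease/polymorphism).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "structure_file", "chain", "position", "wild", "mutant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FeatureError(f"variant table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(SapRecord(
            protein_id=row["protein_id"], structure_file=row["structure_file"],
            chain=row["chain"], position=int(row["position"]),
            wild=row["wild"], mutant=row["mutant"],
            label=row["label"] if "label" in df.columns and pd.notna(row.get("label"))
            else None,
        ))
    return records


def read_aux_tables(sasa_path: str | Path | None = None,
                    aggregation_path: str | Path | None = None,
                    hla_path: str | Path | None = None) -> AuxTables:
    """Load optional auxiliary TSVs into an :class:`AuxTables`.

    sasa TSV: protein_id, seq_index, sasa. aggregation TSV: protein_id,
    position, wild, mutant, agg_wild, agg_mutant. hla: one protein id per line.
    """
    aux = AuxTables()
    if sasa_path is not None:
        df = pd.read_csv(sasa_path, sep="\t")
        aux.sasa = {(str(r.protein_id), int(r.seq_index)): float(r.sasa)
                    for r in df.itertuples()}
    if aggregation_path is not None:
        df = pd.read_csv(aggregation_path, sep="\t")
        aux.aggregation = {
            (str(r.protein_id), int(r.position), str(r.wild), str(r.mutant)):
                (float(r.agg_wild), float(r.agg_mutant))
            for r in df.itertuples()}
    if hla_path is not None:
        ids = [ln.strip() for ln in Path(hla_path).read_text().splitlines()
               if ln.strip() and not ln.startswith("#")]
        aux.hla_ids = frozenset(ids)
    return aux


def featurize_table(records: list[SapRecord], structures_dir: str | Path,
                    profiles_dir: str | Path, aux: AuxTables | None = None,
                    cutoff: float = net_mod.DEFAULT_CUTOFF,
                    position_convention: str = "index",
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Featurize a variant table against a directory of structures/profiles.

    Profiles are looked up as ``<profiles_dir>/<protein_id>.pssm``. Returns
    (features, rejects): the feature matrix, one row per accepted record with
    the label (if any) in column ``label``, and a table of rejected records
    with reasons.
    """
    from .conservation import parse_pssm
    from .structure import parse_structure

    structures_dir = Path(structures_dir)
    profiles_dir = Path(profiles_dir)
    cache: dict[tuple[str, str], tuple] = {}
    rows, labels, rejects = [], [], []
    for rec in records:
        key = (rec.structure_file, rec.chain)
        try:
            if key not in cache:
                model = parse_structure(structures_dir / rec.structure_file,
                                        chain=rec.chain, protein_id=rec.protein_id)
                graph = net_mod.build_network(model, cutoff=cutoff)
                profile = parse_pssm(profiles_dir / f"{rec.protein_id}.pssm")
                bc = net_mod.all_betweenness_scaled(graph)
                cache[key] = (model, graph, profile, bc)
            model, graph, profile, bc = cache[key]
            row = assemble(rec, model, graph, profile, aux,
                           position_convention=position_convention, _bc_cache=bc)
        except (FeatureError, ValueError, OSError) as exc:
            rejects.append({"protein_id": rec.protein_id, "position": rec.position,
                            "wild": rec.wild, "mutant": rec.mutant,
                            "reason": str(exc)})
            continue
        rows.append(row)
        labels.append(rec.label)
    features = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if any(lbl is not None for lbl in labels):
        features["label"] = labels
    rejects_df = pd.DataFrame(rejects,
                              columns=["protein_id", "position", "wild", "mutant",
                                       "reason"])
    return features, rejects_df
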
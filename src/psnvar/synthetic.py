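"""Synthetic structures, profiles and labeled variant datasets.

Real inputs to the pipeline are crystal structures, iterated-search sequence
profiles and externally computed per-residue tables. This module fabricates
all of them with controllable statistical structure so that every stage of
the pipeline can be exercised and validated end to end:

* :func:`gen_structure` writes a compact self-avoiding random chain as a PDB
  file (C-alpha step 3.8 A, side-chain pseudo-atoms placed symmetrically
  around an intended centroid, glycines present to exercise the C-alpha
  rule); a packing-density knob controls how globular, and hence how densely
  contacted, the chain is.
* :func:`gen_profile` writes a profile in the search-tool ASCII dialect whose
  per-position sharpness can be coupled to network closeness, emulating the
  empirical tendency of topologically central residues to be conserved.
* :func:`gen_dataset` samples substitution sites and draws disease labels
  from a logistic model on (closeness, entropy, degree) with configured
  effect sizes, saving the ground truth for recovery tests.

Everything is driven by one seed and is byte-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import network as net_mod
from .conservation import ALPHABET, ProfileMatrix
from .structure import ResidueNode, StructureModel

CA_STEP = 3.8          # A, consecutive C-alpha spacing
MIN_CA_SEP = 4.0       # A, clash distance for non-adjacent C-alphas
SIDECHAIN_OFFSET = 1.8  # A, centroid offset from C-alpha

# crude hydrophobicity-flavoured aggregation propensity per amino acid
_AGG_BASE = {
    "A": 12.0, "R": 0.0, "N": 2.0, "D": 0.0, "C": 18.0, "Q": 3.0, "E": 0.5,
    "G": 6.0, "H": 4.0, "I": 30.0, "L": 28.0, "K": 0.0, "M": 22.0, "F": 32.0,
    "P": 0.0, "S": 5.0, "T": 8.0, "W": 26.0, "Y": 20.0, "V": 27.0,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    ``effect_sizes`` are log-odds coefficients per standard deviation of the
    site's (closeness, entropy, degree); ``class_balance`` is the disease
    fraction of the variant pool; ``closeness_coupling`` ties profile
    sharpness to network closeness (0 decouples them).
    """

    n_proteins: int = 20
    residues_range: tuple[int, int] = (60, 120)
    packing_density: float = 0.55
    conservation_concentration: float = 8.0
    closeness_coupling: float = 1.0
    n_saps: int = 2000
    effect_sizes: tuple[float, float, float] = (2.5, -2.5, 0.0)
    class_balance: float = 0.61
    hla_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_saps < 1:
            raise ValueError("sizes must be positive")
        lo, hi = self.residues_range
        if lo < 5 or hi < lo:
            raise ValueError("bad residues_range")


@dataclass
class GeneratedStructure:
    """Bookkeeping for one generated chain (ground truth for round-trips)."""

    protein_id: str
    path: Path
    sequence: str
    ca_coords: np.ndarray         # (n, 3)
    centroids: np.ndarray         # (n, 3) intended side-chain centroids

    def as_model(self) -> StructureModel:
        residues = [
            ResidueNode(chain_id="A", seq_index=i + 1, resnum=str(i + 1),
                        aa=aa, centroid=self.centroids[i])
            for i, aa in enumerate(self.sequence)
        ]
        return StructureModel(protein_id=self.protein_id, chain_id="A",
                              residues=residues, source=self.path)


ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _walk_chain(n: int, packing: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding biased random walk for the C-alpha trace."""
    coords = [np.zeros(3)]
    for _ in range(1, n):
        placed = False
        for _attempt in range(60):
            g = rng.normal(size=3)
            direction = _unit(_unit(g) - packing * _unit(coords[-1]))
            candidate = coords[-1] + CA_STEP * direction
            prev = np.array(coords[:-1]) if len(coords) > 1 else None
            if prev is None or np.min(np.linalg.norm(prev - candidate, axis=1)) >= MIN_CA_SEP:
                coords.append(candidate)
                placed = True
                break
        if not placed:
            # escape outward from a jammed pocket
            coords.append(coords[-1] + CA_STEP * _unit(coords[-1] + rng.normal(size=3)))
    return np.array(coords)


def _format_atom(serial: int, name: str, resname: str, chain: str, resseq: int,
                 xyz: np.ndarray, element: str) -> str:
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {name_field} {resname} {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2}")


def gen_structure(cfg: SimConfig, path: str | Path, protein_id: str,
                  n_residues: int | None = None,
                  rng: np.random.Generator | None = None) -> GeneratedStructure:
    """Write one synthetic chain as a PDB file and return its ground truth.

    Coordinates are printed with 3 decimals, so parsed centroids agree with
    the intended ones to ~1e-3 A.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if n_residues is None:
        n_residues = int(rng.integers(cfg.residues_range[0], cfg.residues_range[1] + 1))
    aas = list(ALPHABET)
    sequence = [aas[int(k)] for k in rng.integers(0, 20, size=n_residues)]
    if "G" not in sequence:                      # always exercise the CA rule
        sequence[int(rng.integers(0, n_residues))] = "G"
    ca = _walk_chain(n_residues, cfg.packing_density, rng)

    centroids = np.empty((n_residues, 3))
    lines = ["HEADER    SYNTHETIC CHAIN"]
    serial = 1
    for i, aa in enumerate(sequence):
        resname = ONE_TO_THREE[aa]
        resseq = i + 1
        offset = SIDECHAIN_OFFSET * _unit(rng.normal(size=3))
        intended = ca[i] + offset if aa != "G" else ca[i]
        backbone = [("N", ca[i] + np.array([-1.2, 0.45, 0.0]), "N"),
                    ("CA", ca[i], "C"),
                    ("C", ca[i] + np.array([1.2, 0.45, 0.0]), "C"),
                    ("O", ca[i] + np.array([1.4, 1.6, 0.0]), "O")]
        side: list[tuple[str, np.ndarray, str]] = []
        if aa == "A":
            side = [("CB", intended, "C")]
        elif aa != "G":
            span = 0.7 * _unit(np.cross(offset, rng.normal(size=3)))
            side = [("CB", intended + span, "C"), ("CG", intended - span, "C")]
        for name, xyz, element in backbone + side:
            lines.append(_format_atom(serial, name, resname, "A", resseq, xyz, element))
            serial += 1
        # the file carries 3-decimal coordinates; record what a parser will see
        if aa == "G":
            centroids[i] = np.round(ca[i], 3)
        elif aa == "A":
            centroids[i] = np.round(intended, 3)
        else:
            centroids[i] = (np.round(intended + span, 3) + np.round(intended - span, 3)) / 2
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return GeneratedStructure(protein_id=protein_id, path=path,
                              sequence="".join(sequence), ca_coords=ca,
                              centroids=centroids)


def gen_profile(cfg: SimConfig, structure: GeneratedStructure,
                path: str | Path, rng: np.random.Generator | None = None,
                closeness_by_pos: np.ndarray | None = None) -> ProfileMatrix:
    """Write a synthetic sequence profile in the search-tool ASCII dialect.

    Per-position frequency vectors are Dirichlet draws whose mass on the
    wild-type residue grows with ``conservation_concentration``; when
    ``closeness_coupling`` is nonzero the concentration is modulated by the
    position's network closeness, so central positions come out more
    conserved. Returns the matrix exactly as a parser will read it back
    (percentages floored to integers).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = len(structure.sequence)
    if closeness_by_pos is None and cfg.closeness_coupling != 0.0:
        graph = net_mod.build_network(structure.as_model())
        closeness_by_pos = np.array([net_mod.closeness(graph, i + 1) for i in range(n)])
    if closeness_by_pos is not None and cfg.closeness_coupling != 0.0:
        z = closeness_by_pos - closeness_by_pos.mean()
        sd = closeness_by_pos.std()
        z = z / sd if sd > 0 else z
        conc = cfg.conservation_concentration * np.exp(cfg.closeness_coupling * z)
    else:
        conc = np.full(n, cfg.conservation_concentration)

    background = 0.05
    score_rows, pct_rows = [], []
    for i, aa in enumerate(structure.sequence):
        alpha = np.ones(20)
        alpha[ALPHABET.index(aa)] += max(conc[i] - 1.0, 0.0)
        p = rng.dirichlet(alpha)
        pct = np.floor(100 * p).astype(int)         # "rounded down", as the tool prints
        scores = np.clip(np.round(2 * np.log2((p + 1e-4) / background)), -12, 12)
        score_rows.append(scores.astype(int))
        pct_rows.append(pct)

    header = ("Last position-specific scoring matrix computed, weighted observed "
              "percentages rounded down, information per position, and relative "
              "weight of gapless real matches to pseudocounts")
    cols = "            " + "   ".join(ALPHABET) + "    " + "   ".join(ALPHABET)
    lines = ["", header, cols]
    for i, aa in enumerate(structure.sequence):
        srow = " ".join(f"{v:3d}" for v in score_rows[i])
        prow = " ".join(f"{v:3d}" for v in pct_rows[i])
        lines.append(f"{i + 1:5d} {aa}  {srow}  {prow}   0.50 1.00")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1340     0.3180", ""]
    Path(path).write_text("\n".join(lines) + "\n")
    return ProfileMatrix(scores=np.array(score_rows, dtype=float),
                         percents=np.array(pct_rows, dtype=float))


@dataclass
class SimOutput:
    """Paths and ground truth of one generated dataset."""

    out_dir: Path
    structures: list[GeneratedStructure]
    variants_path: Path
    sasa_path: Path
    aggregation_path: Path
    hla_path: Path
    truth_path: Path
    truth: dict = field(repr=False, default_factory=dict)


def _solve_intercept(logits: np.ndarray, target: float) -> float:
    """Bisection for the intercept that sets the mean Bernoulli rate."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2
        rate = float(np.mean(1.0 / (1.0 + np.exp(-(logits + mid)))))
        if rate < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def gen_dataset(cfg: SimConfig, out_dir: str | Path) -> SimOutput:
    """Generate structures, profiles, a labeled variant table, auxiliary
    tables and the ground-truth record under ``out_dir``.

    Disease labels are Bernoulli draws from a logistic model on the site's
    standardized (closeness, entropy, degree) with the configured effect
    sizes; the intercept is solved so the expected disease fraction equals
    ``class_balance``.
    """
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    (out_dir / "profiles").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    structures: list[GeneratedStructure] = []
    site_feats = {}          # protein_id -> (closeness[], entropy[], degree[])
    for k in range(cfg.n_proteins):
        pid = f"P{k + 1:04d}"
        gen = gen_structure(cfg, out_dir / "structures" / f"{pid}.pdb", pid, rng=rng)
        model = gen.as_model()
        graph = net_mod.build_network(model)
        n = model.n_residues
        cl = np.array([net_mod.closeness(graph, i + 1) for i in range(n)])
        dg = np.array([net_mod.degree(graph, i + 1) for i in range(n)], dtype=float)
        profile = gen_profile(cfg, gen, out_dir / "profiles" / f"{pid}.pssm",
                              rng=rng, closeness_by_pos=cl)
        ent = np.array([profile.entropy(i + 1) for i in range(n)])
        structures.append(gen)
        site_feats[pid] = (cl, ent, dg)

    # sample substitution sites (protein, position, mutant) without duplicates
    pool = [(s.protein_id, i) for s in structures for i in range(len(s.sequence))]
    seen: set[tuple[str, int, str]] = set()
    sites: list[tuple[str, int, str, str]] = []
    seq_by_pid = {s.protein_id: s.sequence for s in structures}
    while len(sites) < cfg.n_saps:
        pid, i = pool[int(rng.integers(0, len(pool)))]
        wild = seq_by_pid[pid][i]
        choices = [a for a in ALPHABET if a != wild]
        mutant = choices[int(rng.integers(0, 19))]
        key = (pid, i, mutant)
        if key in seen:
            continue
        seen.add(key)
        sites.append((pid, i + 1, wild, mutant))

    feats = np.array([
        [site_feats[pid][0][pos - 1], site_feats[pid][1][pos - 1],
         site_feats[pid][2][pos - 1]]
        for pid, pos, _, _ in sites
    ])
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    betas = np.asarray(cfg.effect_sizes, dtype=float)
    logits = z @ betas
    b0 = _solve_intercept(logits, cfg.class_balance)
    probs = 1.0 / (1.0 + np.exp(-(logits + b0)))
    labels = np.where(rng.random(len(sites)) < probs, "disease", "polymorphism")

    variants_path = out_dir / "variants.tsv"
    with variants_path.open("w") as fh:
        fh.write("protein_id\tstructure_file\tchain\tposition\twild\tmutant\tlabel\n")
        for (pid, pos, wild, mutant), lbl in zip(sites, labels):
            fh.write(f"{pid}\t{pid}.pdb\tA\t{pos}\t{wild}\t{mutant}\t{lbl}\n")

    # auxiliary tables: plausible fabrications in the shapes the pipeline eats
    sasa_path = out_dir / "aux_sasa.tsv"
    with sasa_path.open("w") as fh:
        fh.write("protein_id\tseq_index\tsasa\n")
        for s in structures:
            dg = site_feats[s.protein_id][2]
            for i in range(len(s.sequence)):
                val = max(0.0, 130.0 - 9.0 * dg[i] + rng.normal(0, 12))
                fh.write(f"{s.protein_id}\t{i + 1}\t{val:.2f}\n")

    aggregation_path = out_dir / "aux_agg.tsv"
    with aggregation_path.open("w") as fh:
        fh.write("protein_id\tposition\twild\tmutant\tagg_wild\tagg_mutant\n")
        for pid, pos, wild, mutant in sites:
            aw = max(0.0, _AGG_BASE[wild] + rng.normal(0, 3))
            am = max(0.0, _AGG_BASE[mutant] + rng.normal(0, 3))
            fh.write(f"{pid}\t{pos}\t{wild}\t{mutant}\t{aw:.2f}\t{am:.2f}\n")

    hla_path = out_dir / "hla_ids.txt"
    n_hla = max(1, int(math.ceil(cfg.hla_fraction * cfg.n_proteins)))
    hla_ids = [s.protein_id for s in structures[:n_hla]]
    hla_path.write_text("\n".join(hla_ids) + "\n")

    truth = {
        "effect_sizes": {"closeness": betas[0], "entropy": betas[1],
                         "degree": betas[2]},
        "intercept": b0,
        "standardization": {"mean": mu.tolist(), "sd": sd.tolist()},
        "class_balance": cfg.class_balance,
        "n_saps": len(sites),
        "disease_fraction": float(np.mean(labels == "disease")),
        "seed": cfg.seed,
    }
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return SimOutput(out_dir=out_dir, structures=structures,
                     variants_path=variants_path, sasa_path=sasa_path,
                     aggregation_path=aggregation_path, hla_path=hla_path,
                     truth_path=truth_path, truth=truth)
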
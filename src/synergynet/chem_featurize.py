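"""SMILES → the four drug modalities.

Each drug enters the model in four representations computed from its
SMILES string with RDKit:

* a 256-bit radius-2 Morgan (ECFP-like) fingerprint,
* an atom sequence: one feature row per heavy atom, in SMILES parse order,
* a molecular graph (bond adjacency + the same atom features) together
  with its order-1/2/3 degree-normalised power-graph supports,
* a 3-D atomic point cloud from a seeded distance-geometry conformer,
  zero-padded to a fixed length.

Featurization is pure: identical inputs give identical arrays; an optional
cache keyed by drug id avoids recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator

from .config import FeaturizerConfig
from .graph_power import MolecularGraph, PowerGraphSet, build_power_set, pair_graph

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FeaturizationError",
    "SmilesParseError",
    "CapacityError",
    "ConformerError",
    "DrugRecord",
    "AtomSequence",
    "PointCloud",
    "DrugPairFeatures",
    "ATOM_FEATURE_WIDTH",
    "morgan_fingerprint",
    "concat_fingerprints",
    "atom_sequence",
    "molecular_graph",
    "point_cloud",
    "featurize_pair",
    "PairFeaturizer",
]


class FeaturizationError(ValueError):
    pass


class SmilesParseError(FeaturizationError):
    pass


class CapacityError(FeaturizationError):
    pass


class ConformerError(FeaturizationError):
    pass


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str


@dataclass
class AtomSequence:
    features: np.ndarray  # (N, C), rows in atom-index order

    @property
    def length(self) -> int:
        return self.features.shape[0]


@dataclass
class PointCloud:
    coords: np.ndarray       # (n, 3) in Angstrom, rows >= true_atom_count are zero
    true_atom_count: int


@dataclass
class DrugPairFeatures:
    """The full four-modality bundle for one ordered drug pair."""

    fp_a: np.ndarray
    fp_b: np.ndarray
    seq_a: AtomSequence
    seq_b: AtomSequence
    graph_a: MolecularGraph
    graph_b: MolecularGraph
    graph_pair: MolecularGraph
    powers_a: PowerGraphSet
    powers_b: PowerGraphSet
    powers_pair: PowerGraphSet
    cloud_a: PointCloud
    cloud_b: PointCloud


# atom feature block layout (one-hot blocks + scalars); C = 27
_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]  # + other
_DEGREES = list(range(6))
_HYBRID = [Chem.HybridizationType.SP, Chem.HybridizationType.SP2,
           Chem.HybridizationType.SP3]  # + other
_NUM_H = list(range(5))
ATOM_FEATURE_WIDTH = (len(_ELEMENTS) + 1) + len(_DEGREES) + 1 \
    + (len(_HYBRID) + 1) + 1 + len(_NUM_H)


def _parse(smiles: str, include_explicit_h: bool = False) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    if mol.GetNumAtoms() < 1:
        raise SmilesParseError(f"molecule has no atoms: {smiles!r}")
    if include_explicit_h:
        mol = Chem.AddHs(mol)
    return mol


def _one_hot(value, choices) -> list[float]:
    row = [0.0] * (len(choices) + 1)
    try:
        row[choices.index(value)] = 1.0
    except ValueError:
        row[-1] = 1.0
    return row


def _atom_row(atom: Chem.Atom) -> list[float]:
    row = _one_hot(atom.GetSymbol(), _ELEMENTS)
    deg = _one_hot(atom.GetDegree(), _DEGREES)[:-1]  # degree > 5 folds into 5
    if atom.GetDegree() > 5:
        deg[-1] = 1.0
    row += deg
    row.append(float(atom.GetFormalCharge()))
    row += _one_hot(atom.GetHybridization(), _HYBRID)
    row.append(1.0 if atom.GetIsAromatic() else 0.0)
    nh = _one_hot(min(atom.GetTotalNumHs(), 4), _NUM_H)[:-1]
    row += nh
    return row


def morgan_fingerprint(smiles: str, bits: int = 256, radius: int = 2) -> np.ndarray:
    """Radius-2 circular fingerprint hashed to a fixed-length bit vector.

    Invariant to SMILES rewriting of the same molecule (RDKit canonical
    atom invariants), deterministic per molecule.
    """
    mol = _parse(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.float64)


def concat_fingerprints(fp_a: np.ndarray, fp_b: np.ndarray) -> np.ndarray:
    """Order-sensitive splice H_m = fp_a || fp_b."""
    fp_a, fp_b = np.asarray(fp_a), np.asarray(fp_b)
    if fp_a.shape != fp_b.shape or fp_a.ndim != 1:
        raise FeaturizationError(
            f"fingerprint shape mismatch: {fp_a.shape} vs {fp_b.shape}")
    return np.concatenate([fp_a, fp_b])


def atom_sequence(smiles: str, max_atoms: int,
                  include_explicit_h: bool = False) -> AtomSequence:
    mol = _parse(smiles, include_explicit_h)
    if mol.GetNumAtoms() > max_atoms:
        raise CapacityError(
            f"molecule {smiles!r} has {mol.GetNumAtoms()} atoms "
            f"> max_atoms={max_atoms}")
    rows = [_atom_row(atom) for atom in mol.GetAtoms()]
    return AtomSequence(features=np.asarray(rows, dtype=np.float64))


def molecular_graph(smiles: str, config: FeaturizerConfig | None = None
                    ) -> tuple[MolecularGraph, PowerGraphSet]:
    """Bond graph (any bond order → edge) + its normalised power supports.

    Node features are the same rows as :func:`atom_sequence` — the sequence
    and graph views of a drug are consistent by construction.
    """
    config = config or FeaturizerConfig()
    mol = _parse(smiles, config.include_explicit_h)
    n = mol.GetNumAtoms()
    adjacency = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = adjacency[j, i] = 1.0
    seq = atom_sequence(smiles, max_atoms=max(n, config.max_atoms),
                        include_explicit_h=config.include_explicit_h)
    graph = MolecularGraph(adjacency=adjacency, node_features=seq.features)
    powers = build_power_set(graph, power_mode=config.power_mode,
                             add_self_loops=config.add_self_loops)
    return graph, powers


def point_cloud(smiles: str, n: int, seed: int,
                relax: bool = True) -> PointCloud:
    """Seeded ETKDG conformer, heavy-atom coordinates zero-padded to n rows."""
    mol = _parse(smiles)
    m = mol.GetNumAtoms()
    if m > n:
        raise CapacityError(
            f"molecule {smiles!r} has {m} atoms > cloud length n={n}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise ConformerError(f"3D embedding failed for {smiles!r}")
    if relax:
        try:
            AllChem.MMFFOptimizeMolecule(molh, maxIters=500)
        except Exception as exc:  # pragma: no cover - rare force-field gaps
            raise ConformerError(f"relaxation failed for {smiles!r}: {exc}")
    conf = molh.GetConformer()
    coords = np.zeros((n, 3))
    for i in range(m):  # heavy atoms keep their pre-AddHs indices
        pos = conf.GetAtomPosition(i)
        coords[i] = (pos.x, pos.y, pos.z)
    if not np.all(np.isfinite(coords)):
        raise ConformerError(f"non-finite coordinates for {smiles!r}")
    return PointCloud(coords=coords, true_atom_count=m)


def featurize_pair(drug_a: DrugRecord, drug_b: DrugRecord,
                   config: FeaturizerConfig | None = None) -> DrugPairFeatures:
    """All four modalities for an ordered drug pair (order is preserved)."""
    return PairFeaturizer(config).pair(drug_a, drug_b)


class PairFeaturizer:
    """Featurizer with a per-drug cache keyed by drug_id."""

    def __init__(self, config: FeaturizerConfig | None = None):
        self.config = config or FeaturizerConfig()
        self._cache: dict[str, dict] = {}

    def single(self, drug: DrugRecord) -> dict:
        if drug.drug_id in self._cache:
            return self._cache[drug.drug_id]
        cfg = self.config
        try:
            feats = {
                "fp": morgan_fingerprint(drug.smiles, cfg.fp_bits, cfg.fp_radius),
                "seq": atom_sequence(drug.smiles, cfg.max_atoms,
                                     cfg.include_explicit_h),
                "cloud": point_cloud(drug.smiles, cfg.cloud_points,
                                     cfg.conformer_seed, cfg.relax_conformer),
            }
            feats["graph"], feats["powers"] = molecular_graph(drug.smiles, cfg)
        except FeaturizationError as exc:
            raise type(exc)(f"drug {drug.drug_id!r}: {exc}") from exc
        self._cache[drug.drug_id] = feats
        return feats

    def pair(self, drug_a: DrugRecord, drug_b: DrugRecord) -> DrugPairFeatures:
        fa, fb = self.single(drug_a), self.single(drug_b)
        g_pair = pair_graph(fa["graph"], fb["graph"])
        powers_pair = build_power_set(g_pair, power_mode=self.config.power_mode,
                                      add_self_loops=self.config.add_self_loops)
        return DrugPairFeatures(
            fp_a=fa["fp"], fp_b=fb["fp"],
            seq_a=fa["seq"], seq_b=fb["seq"],
            graph_a=fa["graph"], graph_b=fb["graph"], graph_pair=g_pair,
            powers_a=fa["powers"], powers_b=fb["powers"],
            powers_pair=powers_pair,
            cloud_a=fa["cloud"], cloud_b=fb["cloud"],
        )
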
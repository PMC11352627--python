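"""Synthetic fixture generator.

Emulates the shapes and statistical structure of a drug-combination
synergy screen — a few tens of drugs, a few tens of cell lines, thousands
of (drug A, drug B, cell line, score) quadruples, dense real expression
factors, sparse binary mutations, and a score marginal concentrated near
zero with a long positive tail (roughly the [−50, 75] range seen in
Loewe-score screens) — without downloading anything.

The generating function is known and documented so learnability is a
testable property. For an ordered pair with fingerprints f_a, f_b, atom
counts n_a, n_b, order-2 power-graph densities d_a, d_b and a cell line
with z-scored expression factors g:

    t  = Tanimoto(f_a, f_b)                      (fingerprint overlap)
    s  = n_a · n_b                               (graph-size interaction)
    p  = |n_a − n_b|                             (size mismatch: a count-based
                                                  pair term; binary
                                                  fingerprints collapse
                                                  repeated atom environments
                                                  and max pooling cannot
                                                  count, while a recurrent
                                                  sequence encoder integrates
                                                  over atom positions)
    e  = g · w / √k                              (expression projection,
                                                  w a fixed seeded unit vector)
    u  = 0.55·z(e) + 0.20·z(s) + 0.45·z(p) + 0.10·z(t) + 0.12·z(s)·z(e)
    v  = u + tail_weight · softplus(1.5·u) / 1.5
    score = score_center + SCORE_SD · z(v) + Normal(0, noise_sd)

z(·) standardises each component exactly over the uniform distribution on
(unordered pair × cell) combinations, via enumeration at dataset build
time, so the marginal mean is score_center and the noiseless signal has
standard deviation SCORE_SD by construction. Every term is symmetric in
drug order. The default noise_sd makes the best achievable (Bayes)
Pearson correlation SCORE_SD/√(SCORE_SD² + noise_sd²) ≈ 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_featurize import (DrugPairFeatures, DrugRecord, PairFeaturizer,
                             morgan_fingerprint)
from .config import FeaturizerConfig
from .data_io import (CellLineProfile, DatasetBundle, SynergyExample,
                      load_bundle)
from .encoders import zscore

__all__ = [
    "SyntheticSpec",
    "SignalCalibration",
    "sample_molecules",
    "synth_omics",
    "synth_synergy",
    "calibrate_signal",
    "make_dataset",
    "SCORE_SD",
]

SCORE_SD = 15.0  # sd of the noiseless signal, on the synergy-score scale

# rings/linkers/terminals compose left-to-right into valid SMILES; every
# combination is parse-checked at generation time anyway. Linear and
# branched assemblies of the same fragments share almost all radius-2
# atom environments yet differ strongly in multi-hop connectivity, so the
# vocabulary spans exactly the structural variation the power-graph
# encoder is meant to resolve.
_RINGS = [
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccsc1", "c1cc[nH]c1",
    "c1ccc2ccccc2c1", "C1CCNCC1", "C1CCOC1", "C1CCCCC1", "c1ccoc1",
]
_LINKERS = ["", "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC",
            "OC", "N", "CN", "C(=O)", "C(=O)N", "S", "CC(=O)O", "C=C"]
_TERMINALS = ["", "C", "O", "N", "Cl", "F", "C(F)(F)F", "C#N", "C(C)C",
              "CO", "CCC", "CCCC", "c1ccccc1", "c1ccncc1"]
_CHAIN_ENDS = ["", "O", "N", "C"]
# substituents for branched assembly around a central carbon; repeated CH2
# environments along chains collapse to the same fingerprint bits, so
# chain length varies atom counts without varying fingerprints much
_SUBSTITUENTS = [
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "C1CCOC1", "C", "CC", "CCC",
    "CCCC", "CCCCC", "CCO", "CN", "CO", "CC(C)C", "CCN",
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic screen."""

    n_drugs: int = 24
    n_cells: int = 25
    n_examples: int = 2000
    expr_factors: int = 16
    mut_genes: int = 64
    noise_sd: float = 4.9      # Bayes PCC ≈ 0.95 against SCORE_SD = 15
    score_center: float = 5.0
    score_tail_weight: float = 0.6
    max_atoms: int = 28
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_cells", "n_examples", "expr_factors",
                     "mut_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def sample_molecules(n: int, seed: int, max_atoms: int = 28
                     ) -> list[DrugRecord]:
    """n distinct, parseable, drug-like SMILES from a scaffold vocabulary."""
    from rdkit import Chem
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[DrugRecord] = []
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("vocabulary exhausted; lower n or raise max_atoms")
        mode = rng.random()
        if mode < 0.5:
            # ring + plain CH2 chain: size varies while the fingerprint
            # barely moves (repeated chain environments share bits)
            chain = "C" * int(rng.integers(0, 11))
            smiles = (_RINGS[rng.integers(len(_RINGS))] + chain
                      + _CHAIN_ENDS[rng.integers(len(_CHAIN_ENDS))])
        elif mode < 0.75:
            smiles = (_RINGS[rng.integers(len(_RINGS))]
                      + _LINKERS[rng.integers(len(_LINKERS))]
                      + _TERMINALS[rng.integers(len(_TERMINALS))])
        else:
            a, b, c = (_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
                       for _ in range(3))
            smiles = f"C({a})({b}){c}"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or not 3 <= mol.GetNumAtoms() <= max_atoms:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        if not _embeddable(canonical):
            continue
        seen.add(canonical)
        records.append(DrugRecord(f"drug_{len(records):03d}", canonical))
    return records


def _embeddable(smiles: str) -> bool:
    """Cheap 3-D embedding check so every vocabulary molecule featurizes."""
    from rdkit import Chem
    from rdkit.Chem import AllChem
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 1
    return AllChem.EmbedMolecule(mol, params) == 0


def synth_omics(n_cells: int, k: int, m: int, seed: int
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlated Gaussian expression factors + Bernoulli(0.02) mutations."""
    rng = np.random.default_rng(seed)
    mixing = rng.normal(size=(k, k)) / np.sqrt(k)
    expr = rng.normal(size=(n_cells, k)) @ mixing
    mut = (rng.random(size=(n_cells, m)) < 0.02).astype(int)
    cells = [f"cell_{i:03d}" for i in range(n_cells)]
    expr_df = pd.DataFrame(expr, index=cells,
                           columns=[f"factor_{j}" for j in range(k)])
    mut_df = pd.DataFrame(mut, index=cells,
                          columns=[f"gene_{j}" for j in range(m)])
    expr_df.index.name = mut_df.index.name = "cell_id"
    return expr_df, mut_df


# -- signal ------------------------------------------------------------------


def _pair_components(fp_a, fp_b, graph_a, graph_b) -> tuple[float, float, float]:
    """(tanimoto, size product, size mismatch) for one unordered pair."""
    inter = float(np.minimum(fp_a, fp_b).sum())
    union = float(np.maximum(fp_a, fp_b).sum())
    t = inter / union if union else 0.0
    s = graph_a.atom_count * graph_b.atom_count
    p = float(abs(graph_a.atom_count - graph_b.atom_count))
    return t, float(s), p


@dataclass
class SignalCalibration:
    """Exact component moments over the uniform (pair × cell) distribution."""

    means: dict = field(default_factory=dict)  # component -> (mean, sd)
    v_mean: float = 0.0
    v_sd: float = 1.0
    w: np.ndarray = None  # fixed unit projection vector for expression

    def z(self, name: str, value: float) -> float:
        mean, sd = self.means[name]
        return (value - mean) / sd if sd > 0 else 0.0


def _softplus(x: np.ndarray | float) -> np.ndarray | float:
    return np.logaddexp(0.0, x)


def _raw_v(t, s, p, e, calib: SignalCalibration, tail_weight: float):
    zt, zs = calib.z("t", t), calib.z("s", s)
    zp, ze = calib.z("p", p), calib.z("e", e)
    u = 0.55 * ze + 0.20 * zs + 0.45 * zp + 0.10 * zt + 0.12 * zs * ze
    return u + tail_weight * _softplus(1.5 * u) / 1.5


def calibrate_signal(pair_feats: dict, cell_exprs: np.ndarray,
                     spec: SyntheticSpec) -> SignalCalibration:
    """Enumerate all (pair, cell) combinations and freeze exact moments.

    pair_feats: {(a, b): (tanimoto, size, density)} over unordered pairs.
    """
    rng = np.random.default_rng(spec.seed + 7919)
    k = cell_exprs.shape[1]
    w = rng.normal(size=k)
    w /= np.linalg.norm(w)
    calib = SignalCalibration(w=w)
    comps = np.array(list(pair_feats.values()))  # (n_pairs, 3): t, s, p
    es = cell_exprs @ w / np.sqrt(k)
    for i, name in enumerate(("t", "s", "p")):
        calib.means[name] = (float(comps[:, i].mean()),
                             float(comps[:, i].std()))
    calib.means["e"] = (float(es.mean()), float(es.std()))
    # v moments over the full product grid
    vs = np.array([
        _raw_v(t, s, p, e, calib, spec.score_tail_weight)
        for (t, s, p) in comps for e in es
    ])
    calib.v_mean = float(vs.mean())
    calib.v_sd = float(vs.std()) or 1.0
    return calib


def synth_synergy(pair: DrugPairFeatures, cell: CellLineProfile,
                  spec: SyntheticSpec, calib: SignalCalibration,
                  rng: np.random.Generator | None = None) -> float:
    """Ground-truth score for one (pair, cell); symmetric in drug order."""
    t, s, p = _pair_components(pair.fp_a, pair.fp_b, pair.graph_a, pair.graph_b)
    e = float(cell.expr @ calib.w / np.sqrt(len(cell.expr)))
    v = _raw_v(t, s, p, e, calib, spec.score_tail_weight)
    score = spec.score_center + SCORE_SD * (v - calib.v_mean) / calib.v_sd
    if rng is not None and spec.noise_sd > 0:
        score += rng.normal(0.0, spec.noise_sd)
    return float(score)


# -- dataset ------------------------------------------------------------------

_TISSUES = ["lung", "breast", "colon", "skin", "ovary"]


def make_dataset(spec: SyntheticSpec, outdir) -> DatasetBundle:
    """Write a complete synthetic screen and return it re-read via data_io.

    Files: synergy.csv, drugs.csv, expression.tsv, mutations.tsv,
    tissues.csv — all in the dialects the readers expect. Deterministic
    per spec.seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    drugs = sample_molecules(spec.n_drugs, spec.seed, spec.max_atoms)
    expr_df, mut_df = synth_omics(spec.n_cells, spec.expr_factors,
                                  spec.mut_genes, spec.seed + 1)
    expr_z = zscore(expr_df.values, axis=0)
    cells = {
        cid: CellLineProfile(cell_id=cid, expr=expr_z[i],
                             mut=mut_df.values[i].astype(float),
                             tissue=_TISSUES[i % len(_TISSUES)])
        for i, cid in enumerate(expr_df.index)
    }

    featurizer = PairFeaturizer(FeaturizerConfig(
        max_atoms=max(spec.max_atoms, 32), cloud_points=max(spec.max_atoms, 32)))
    singles = {d.drug_id: featurizer.single(d) for d in drugs}
    pair_ids = [(a.drug_id, b.drug_id)
                for i, a in enumerate(drugs) for b in drugs[i + 1:]]
    pair_comp = {
        (a, b): _pair_components(singles[a]["fp"], singles[b]["fp"],
                                 singles[a]["graph"], singles[b]["graph"])
        for a, b in pair_ids
    }
    calib = calibrate_signal(pair_comp, expr_z, spec)

    cell_ids = list(expr_df.index)
    combos = [(pidx, cidx) for pidx in range(len(pair_ids))
              for cidx in range(len(cell_ids))]
    if spec.n_examples > len(combos):
        raise ValueError(
            f"n_examples={spec.n_examples} exceeds the "
            f"{len(combos)} distinct (pair, cell) combinations")
    chosen = rng.choice(len(combos), size=spec.n_examples, replace=False)

    examples = []
    for idx in chosen:
        pidx, cidx = combos[idx]
        a, b = pair_ids[pidx]
        cid = cell_ids[cidx]
        t, s, p = pair_comp[(a, b)]
        e = float(cells[cid].expr @ calib.w / np.sqrt(spec.expr_factors))
        v = _raw_v(t, s, p, e, calib, spec.score_tail_weight)
        score = spec.score_center + SCORE_SD * (v - calib.v_mean) / calib.v_sd
        if spec.noise_sd > 0:
            score += rng.normal(0.0, spec.noise_sd)
        examples.append(SynergyExample(a, b, cid, round(float(score), 4)))

    pd.DataFrame(
        [{"drug_a": e.drug_a, "drug_b": e.drug_b, "cell_line": e.cell_line,
          "synergy": e.score} for e in examples]
    ).to_csv(outdir / "synergy.csv", index=False)
    pd.DataFrame(
        [{"drug_id": d.drug_id, "smiles": d.smiles} for d in drugs]
    ).to_csv(outdir / "drugs.csv", index=False)
    expr_df.to_csv(outdir / "expression.tsv", sep="\t")
    mut_df.to_csv(outdir / "mutations.tsv", sep="\t")
    pd.DataFrame(
        [{"cell_line": c.cell_id, "tissue": c.tissue}
         for c in cells.values()]
    ).to_csv(outdir / "tissues.csv", index=False)

    return load_bundle(outdir / "synergy.csv", outdir / "drugs.csv",
                       outdir / "expression.tsv", outdir / "mutations.tsv",
                       outdir / "tissues.csv")
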
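"""Readers, writers and split utilities for synergy screens.

File dialects (all plain text):

* synergy table — CSV/TSV with header ``drug_a, drug_b, cell_line, synergy``;
* drug map — CSV with header ``drug_id, smiles`` (or an SDF with a
  ``drug_id`` property);
* omics — two TSV matrices with the cell id in the first column:
  expression factor loadings (dense reals, z-scored per factor at load)
  and mutations (strictly binary);
* optional tissue annotation — CSV with header ``cell_line, tissue``.

Readers validate and fail with line-addressed errors; there is no silent
coercion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_featurize import DrugRecord
from .encoders import zscore

__all__ = [
    "DataError",
    "SynergyExample",
    "CellLineProfile",
    "DatasetBundle",
    "read_synergy_table",
    "write_synergy_table",
    "read_drug_map",
    "read_omics",
    "read_tissues",
    "load_bundle",
    "split_train_test",
    "split_leave_drug_out",
    "kfold",
    "save_checkpoint",
    "load_checkpoint",
]


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class SynergyExample:
    """One screen quadruple: ordered drug pair, cell line, synergy score."""

    drug_a: str
    drug_b: str
    cell_line: str
    score: float


@dataclass
class CellLineProfile:
    cell_id: str
    expr: np.ndarray           # z-scored factor loadings (k,)
    mut: np.ndarray            # binary mutation indicators (m,)
    tissue: str | None = None


@dataclass
class DatasetBundle:
    """A fully resolvable dataset: examples + drug map + cell profiles."""

    examples: list[SynergyExample]
    drugs: dict[str, DrugRecord]
    cells: dict[str, CellLineProfile]

    def __post_init__(self):
        for ex in self.examples:
            for d in (ex.drug_a, ex.drug_b):
                if d not in self.drugs:
                    raise DataError(f"example references unknown drug {d!r}")
            if ex.cell_line not in self.cells:
                raise DataError(
                    f"example references unknown cell line {ex.cell_line!r}")

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.cells)

    def cell_matrix(self) -> tuple[np.ndarray, dict[str, int]]:
        """Stacked expr||mut rows and the cell-id → row map."""
        ids = self.cell_ids
        rows = [np.concatenate([self.cells[c].expr, self.cells[c].mut])
                for c in ids]
        return np.asarray(rows, dtype=np.float64), {c: i for i, c in enumerate(ids)}

    @property
    def expr_width(self) -> int:
        return len(next(iter(self.cells.values())).expr)

    @property
    def mut_width(self) -> int:
        return len(next(iter(self.cells.values())).mut)


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_synergy_table(path) -> list[SynergyExample]:
    df = pd.read_csv(path, sep=_sep(path))
    required = ["drug_a", "drug_b", "cell_line", "synergy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    examples: list[SynergyExample] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        score = row.synergy
        try:
            score = float(score)
        except (TypeError, ValueError):
            raise DataError(
                f"{path}, line {i}: non-numeric synergy {row.synergy!r}")
        if not np.isfinite(score):
            raise DataError(f"{path}, line {i}: non-finite synergy score")
        a, b, c = str(row.drug_a), str(row.drug_b), str(row.cell_line)
        # (a,b,c) and (b,a,c) denote the same combination
        key = (min(a, b), max(a, b), c)
        if key in seen:
            raise DataError(
                f"{path}, line {i}: duplicate combination {key} "
                f"(first seen at line {seen[key]})")
        seen[key] = i
        examples.append(SynergyExample(a, b, c, score))
    return examples


def write_synergy_table(examples, path) -> None:
    df = pd.DataFrame([dataclasses.asdict(ex) for ex in examples])
    df = df.rename(columns={"score": "synergy"})
    df.to_csv(path, sep=_sep(path), index=False)


def read_drug_map(path) -> dict[str, DrugRecord]:
    """Drug id → SMILES from CSV (``drug_id, smiles``) or SDF."""
    if str(path).endswith(".sdf"):
        from rdkit import Chem
        drugs = {}
        for mol in Chem.SDMolSupplier(str(path)):
            if mol is None or not mol.HasProp("drug_id"):
                raise DataError(f"{path}: unreadable SDF record or no drug_id")
            did = mol.GetProp("drug_id")
            drugs[did] = DrugRecord(did, Chem.MolToSmiles(mol))
        return drugs
    df = pd.read_csv(path, sep=_sep(path))
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    drugs = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        did = str(row.drug_id)
        if did in drugs:
            raise DataError(f"{path}, line {i}: duplicate drug_id {did!r}")
        drugs[did] = DrugRecord(did, str(row.smiles))
    return drugs


def read_tissues(path) -> dict[str, str]:
    df = pd.read_csv(path, sep=_sep(path))
    for col in ("cell_line", "tissue"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    return {str(r.cell_line): str(r.tissue) for r in df.itertuples(index=False)}


def read_omics(expr_path, mut_path, tissue_path=None,
               standardize: bool = True) -> dict[str, CellLineProfile]:
    """Build cell profiles from expression-factor and mutation TSVs.

    Expression columns are z-scored per factor at load (toggleable when the
    caller standardises with training-fold statistics instead). Mutation
    entries must be exactly 0 or 1. Cells present in only one file are
    excluded with a warning.
    """
    expr = pd.read_csv(expr_path, sep=_sep(expr_path), index_col=0)
    mut = pd.read_csv(mut_path, sep=_sep(mut_path), index_col=0)
    if not expr.index.is_unique or not mut.index.is_unique:
        raise DataError("duplicate cell ids in omics tables")
    bad = mut.values[~np.isin(mut.values, (0, 1))]
    if bad.size:
        raise DataError(
            f"{mut_path}: non-binary mutation value(s), e.g. {bad.flat[0]!r}")
    if not np.all(np.isfinite(expr.values)):
        raise DataError(f"{expr_path}: non-finite expression value")
    shared = [c for c in expr.index.astype(str) if c in set(mut.index.astype(str))]
    dropped = (set(expr.index.astype(str)) | set(mut.index.astype(str))) \
        - set(shared)
    if dropped:
        import warnings
        warnings.warn(f"cell lines present in only one omics file, excluded: "
                      f"{sorted(dropped)}")
    if not shared:
        raise DataError("no cell line present in both omics files")
    expr = expr.loc[shared]
    mut = mut.loc[shared]
    values = zscore(expr.values, axis=0) if standardize else \
        expr.values.astype(np.float64)
    tissues = read_tissues(tissue_path) if tissue_path else {}
    return {
        str(cid): CellLineProfile(
            cell_id=str(cid), expr=values[i],
            mut=mut.values[i].astype(np.float64),
            tissue=tissues.get(str(cid)))
        for i, cid in enumerate(shared)
    }


def load_bundle(synergy_path, drug_path, expr_path, mut_path,
                tissue_path=None) -> DatasetBundle:
    return DatasetBundle(
        examples=read_synergy_table(synergy_path),
        drugs=read_drug_map(drug_path),
        cells=read_omics(expr_path, mut_path, tissue_path),
    )


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def _canonical_order(examples) -> list:
    return sorted(examples, key=lambda e: (e.drug_a, e.drug_b, e.cell_line))


def _group_key(example, split_by: str):
    if split_by == "random":
        return example
    if split_by == "drug-pair":
        return tuple(sorted((example.drug_a, example.drug_b)))
    if split_by == "cell-line":
        return example.cell_line
    raise ValueError(f"unknown split_by {split_by!r}")


def split_leave_drug_out(examples, ratio: float, seed: int
                         ) -> tuple[list, list]:
    """Hold out whole drugs: test examples touch at least one unseen drug.

    Drugs are shuffled per seed and moved to the held-out set one at a
    time until the test portion reaches roughly (1 − ratio) of the
    examples. Training examples involve only seen drugs, so evaluation
    measures generalisation to new chemistry rather than recall of
    per-drug effects.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    examples = _canonical_order(examples)
    if not examples:
        raise ValueError("empty example list")
    rng = np.random.default_rng(seed)
    drugs = sorted({d for e in examples for d in (e.drug_a, e.drug_b)})
    order = rng.permutation(len(drugs))
    target = (1.0 - ratio) * len(examples)
    held: set[str] = set()
    for i in order:
        test = [e for e in examples
                if e.drug_a in held or e.drug_b in held]
        if len(test) >= target:
            break
        held.add(drugs[i])
    test = [e for e in examples if e.drug_a in held or e.drug_b in held]
    train = [e for e in examples
             if e.drug_a not in held and e.drug_b not in held]
    if not train or not test:
        raise ValueError("degenerate leave-drug-out split; adjust ratio")
    return train, test


def split_train_test(examples, ratio: float, seed: int,
                     split_by: str = "random") -> tuple[list, list]:
    """Disjoint, exhaustive split; train gets ⌊ratio·n⌋ examples (random mode).

    Independent of input row order (examples are canonically sorted before
    shuffling) and reproducible per seed. ``split_by`` offers stricter
    generalisation splits grouped by drug pair or cell line.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    examples = _canonical_order(examples)
    if not examples:
        raise ValueError("empty example list")
    rng = np.random.default_rng(seed)
    if split_by == "random":
        order = rng.permutation(len(examples))
        n_train = int(ratio * len(examples))
        train = [examples[i] for i in order[:n_train]]
        test = [examples[i] for i in order[n_train:]]
        return train, test
    groups = sorted({_group_key(e, split_by) for e in examples})
    order = rng.permutation(len(groups))
    n_train_groups = int(ratio * len(groups))
    train_groups = {groups[i] for i in order[:n_train_groups]}
    train = [e for e in examples if _group_key(e, split_by) in train_groups]
    test = [e for e in examples if _group_key(e, split_by) not in train_groups]
    return train, test


def kfold(examples, k: int, seed: int) -> list[tuple[list, list]]:
    """k (train, validation) partitions; folds differ in size by at most 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    examples = _canonical_order(examples)
    if k > len(examples):
        raise ValueError(f"k={k} exceeds number of examples {len(examples)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(examples))
    folds = [sorted(order[i::k]) for i in range(k)]
    out = []
    for i in range(k):
        val_idx = set(folds[i])
        train = [examples[j] for j in range(len(examples)) if j not in val_idx]
        val = [examples[j] for j in folds[i]]
        out.append((train, val))
    return out


def save_checkpoint(model, path) -> None:
    model.save(path)


def load_checkpoint(path):
    from .model import SynergyModel
    return SynergyModel.load(path)
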
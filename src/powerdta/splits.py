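"""Affinity tables, pKd conversion, and train/test split protocols.

Four protocols are provided: the random 5/6–1/6 split used for the main
benchmark protocol, and three cold-start protocols in which the test set's
drugs, proteins, or both never occur in training.  Entity identity is the
exact string, with drug SMILES canonicalized first so that different
spellings of one molecule cannot leak across the split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

SPLIT_MODES = ("random", "drug_cold", "target_cold", "pair_cold")


@dataclass
class AffinityRecord:
    drug_smiles: str
    protein_seq: str
    label: float
    label_kind: str = "synthetic"  # pKd | raw_kd_nM | kiba | synthetic

    def __post_init__(self):
        if not self.drug_smiles:
            raise ValueError("empty SMILES")
        if not self.protein_seq:
            raise ValueError("empty protein sequence")
        if not np.isfinite(self.label):
            raise ValueError(f"non-finite label {self.label}")


@dataclass
class SplitPlan:
    mode: str
    train_indices: list = field(default_factory=list)
    test_indices: list = field(default_factory=list)
    seed: int = 0
    dropped_indices: list = field(default_factory=list)  # pair_cold mixed records

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "seed": self.seed,
                "train_indices": list(map(int, self.train_indices)),
                "test_indices": list(map(int, self.test_indices)),
                "dropped_indices": list(map(int, self.dropped_indices)),
            },
            **kw,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            mode=d["mode"],
            train_indices=d["train_indices"],
            test_indices=d["test_indices"],
            seed=d["seed"],
            dropped_indices=d.get("dropped_indices", []),
        )


def kd_to_pkd(kd_nM: float) -> float:
    """pKd = −log10(Kd / 10⁹) for a dissociation constant given in nM."""
    if kd_nM <= 0:
        raise ValueError(f"Kd must be positive, got {kd_nM}")
    return float(-np.log10(kd_nM / 1e9))


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles  # leave unparsable strings as-is; identity is the string
    return Chem.MolToSmiles(mol)


def read_affinity_table(
    path: str | Path,
    smiles_col: str = "smiles",
    seq_col: str = "sequence",
    label_col: str = "label",
    label_kind: str = "synthetic",
) -> list[AffinityRecord]:
    """Read a three-column (SMILES, sequence, label) CSV into records.

    Malformed rows raise with their 1-based data line number; duplicated
    (drug, protein) pairs are kept but logged as warnings.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"empty affinity table: {path}")
    missing = [c for c in (smiles_col, seq_col, label_col) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path} (found {list(df.columns)})")
    records = []
    seen: dict[tuple, int] = {}
    for i in range(len(df)):
        line = i + 2  # header is line 1
        smiles = df.iloc[i][smiles_col]
        seq = df.iloc[i][seq_col]
        label = df.iloc[i][label_col]
        if not isinstance(smiles, str) or not smiles.strip():
            raise ValueError(f"line {line}: empty or missing SMILES")
        if not isinstance(seq, str) or not seq.strip():
            raise ValueError(f"line {line}: empty or missing protein sequence")
        try:
            label = float(label)
        except (TypeError, ValueError):
            raise ValueError(f"line {line}: label {label!r} is not a number") from None
        if not np.isfinite(label):
            raise ValueError(f"line {line}: non-finite label")
        key = (smiles, seq)
        if key in seen:
            logger.warning(
                "duplicate (drug, protein) pair at line %d (first seen line %d)",
                line, seen[key],
            )
        else:
            seen[key] = line
        records.append(AffinityRecord(smiles, seq, label, label_kind))
    return records


def write_affinity_table(records: list[AffinityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "smiles": [r.drug_smiles for r in records],
            "sequence": [r.protein_seq for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, index=False)


def _canonical_order(records: list[AffinityRecord]) -> np.ndarray:
    """Index order independent of input row order (stable sort on content)."""
    keys = [(r.drug_smiles, r.protein_seq, r.label) for r in records]
    return np.array(sorted(range(len(records)), key=lambda i: keys[i]), dtype=int)


def random_split(records: list[AffinityRecord], seed: int = 0) -> SplitPlan:
    """Seeded shuffle into six near-equal folds; fold 0 is the test set.

    |test| is ⌊N/6⌋ or ⌈N/6⌉; folds 1–5 form the training set (≈5/6).
    """
    n = len(records)
    if n < 6:
        raise ValueError(f"need at least 6 records for a 6-fold split, got {n}")
    order = _canonical_order(records)
    rng = np.random.default_rng(seed)
    perm = order[rng.permutation(n)]
    base, extra = divmod(n, 6)
    test_size = base + (1 if extra > 0 else 0)  # fold 0 takes the first remainder slot
    test = perm[:test_size]
    train = perm[test_size:]
    return SplitPlan(
        mode="random",
        train_indices=sorted(int(i) for i in train),
        test_indices=sorted(int(i) for i in test),
        seed=seed,
    )


def cold_start_split(
    records: list[AffinityRecord],
    mode: str,
    test_fraction: float = 1.0 / 6.0,
    seed: int = 0,
) -> SplitPlan:
    """Cold-start protocols with unseen drugs, proteins, or both in test.

    ``drug_cold`` holds out a fraction of distinct drugs: every record of a
    held-out drug is test, everything else is train.  ``target_cold`` is
    symmetric on proteins.  ``pair_cold`` holds out disjoint drug and
    protein sets; test records have BOTH entities held out, train records
    have NEITHER, and mixed records (exactly one held-out entity) are
    dropped, since no assignment keeps both sides clean.
    """
    if mode not in ("drug_cold", "target_cold", "pair_cold"):
        raise ValueError(f"unknown cold-start mode {mode!r}")
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(records)
    drug_ids = [canonical_smiles(r.drug_smiles) for r in records]
    prot_ids = [r.protein_seq for r in records]
    rng = np.random.default_rng(seed)

    def held_out(ids: list[str]) -> set:
        uniq = sorted(set(ids))
        k = max(1, int(round(test_fraction * len(uniq))))
        if k >= len(uniq):
            raise ValueError("test_fraction leaves no training entities")
        return set(rng.choice(uniq, size=k, replace=False).tolist())

    if mode == "drug_cold":
        test_drugs = held_out(drug_ids)
        test = [i for i in range(n) if drug_ids[i] in test_drugs]
        train = [i for i in range(n) if drug_ids[i] not in test_drugs]
        dropped: list[int] = []
    elif mode == "target_cold":
        test_prots = held_out(prot_ids)
        test = [i for i in range(n) if prot_ids[i] in test_prots]
        train = [i for i in range(n) if prot_ids[i] not in test_prots]
        dropped = []
    else:  # pair_cold
        test_drugs = held_out(drug_ids)
        test_prots = held_out(prot_ids)
        test, train, dropped = [], [], []
        for i in range(n):
            d_out = drug_ids[i] in test_drugs
            p_out = prot_ids[i] in test_prots
            if d_out and p_out:
                test.append(i)
            elif not d_out and not p_out:
                train.append(i)
            else:
                dropped.append(i)
        logger.info(
            "pair_cold split: %d train, %d test, %d mixed records dropped",
            len(train), len(test), len(dropped),
        )
    if not test or not train:
        raise ValueError(f"{mode} split produced an empty side (fraction {test_fraction})")
    return SplitPlan(mode=mode, train_indices=train, test_indices=test,
                     seed=seed, dropped_indices=dropped)


def audit_split(records: list[AffinityRecord], plan: SplitPlan) -> None:
    """Verify a plan's structural guarantees; raises AssertionError on breach."""
    train, test = set(plan.train_indices), set(plan.test_indices)
    dropped = set(plan.dropped_indices)
    assert not train & test, "train/test overlap"
    assert not (train | test) & dropped, "dropped records reused"
    assert train | test | dropped == set(range(len(records))), "records lost"
    if plan.mode == "random":
        n = len(records)
        assert len(test) in (n // 6, -(-n // 6)), "random test fold size off"
        return
    drug = {i: canonical_smiles(records[i].drug_smiles) for i in range(len(records))}
    prot = {i: records[i].protein_seq for i in range(len(records))}
    train_drugs = {drug[i] for i in train}
    test_drugs = {drug[i] for i in test}
    train_prots = {prot[i] for i in train}
    test_prots = {prot[i] for i in test}
    if plan.mode in ("drug_cold", "pair_cold"):
        assert not train_drugs & test_drugs, "drug leakage across cold split"
    if plan.mode in ("target_cold", "pair_cold"):
        assert not train_prots & test_prots, "protein leakage across cold split"
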
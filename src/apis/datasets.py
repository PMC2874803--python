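"""Mutation tables and hot-spot labeling rules.

Alanine-scanning data come in two dialects:

* ΔΔG tables (ASEdb-style): a residue is *hot* when its binding free-energy
  change on alanine substitution is at least 2.0 kcal/mol, *non-hot* below
  0.4 kcal/mol, and *excluded* in between (0.4 itself is excluded);
* strength categories (BID-style): ``strong`` mutations are hot, the other
  three categories (``intermediate``, ``weak``, ``insignificant``) non-hot.

The packaged training table (``training_mutations_synthetic.tsv``) is a
synthetic stand-in distributed over the published training-complex roster;
its ΔΔG values are generated, not experimental, but the labeling rules
recover the published class composition (62 hot / 92 non-hot).
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "HOT",
    "NON_HOT",
    "EXCLUDED",
    "STRENGTH_CATEGORIES",
    "MutationRecord",
    "label_ddg",
    "label_bid",
    "load_mutations",
    "label_records",
    "packaged_training_table",
    "training_manifest",
    "write_labels",
    "read_labels",
    "DDG_HOT_MIN",
    "DDG_NONHOT_MAX",
]

HOT = "hot"
NON_HOT = "non_hot"
EXCLUDED = "excluded"

DDG_HOT_MIN = 2.0  # kcal/mol, inclusive
DDG_NONHOT_MAX = 0.4  # kcal/mol, exclusive upper bound of the non-hot region

STRENGTH_CATEGORIES = ("strong", "intermediate", "weak", "insignificant")


@dataclasses.dataclass(frozen=True)
class MutationRecord:
    """One alanine mutation: residue identity plus ΔΔG or a strength class."""

    pdb_id: str
    chain: str
    seq_num: int
    icode: str = ""
    wild_type: str = "UNK"
    ddg: float | None = None  # kcal/mol
    strength: str | None = None

    def __post_init__(self) -> None:
        if (self.ddg is None) == (self.strength is None):
            raise ValueError("exactly one of ddg/strength must be present")
        if self.ddg is not None and not math.isfinite(self.ddg):
            raise ValueError("ddg must be finite")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.pdb_id, self.chain, self.seq_num, self.icode)

    def label(self) -> str:
        if self.ddg is not None:
            return label_ddg(self.ddg)
        return label_bid(self.strength)


def label_ddg(ddg: float) -> str:
    """Tri-state ΔΔG labeling: >= 2.0 hot, < 0.4 non-hot, else excluded."""
    ddg = float(ddg)
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    if ddg >= DDG_HOT_MIN:
        return HOT
    if ddg < DDG_NONHOT_MAX:
        return NON_HOT
    return EXCLUDED


def label_bid(strength: str) -> str:
    """Binary strength labeling: 'strong' is hot, the rest non-hot."""
    s = str(strength).strip().lower()
    if s not in STRENGTH_CATEGORIES:
        raise ValueError(
            f"unknown strength {strength!r}; expected one of {STRENGTH_CATEGORIES}"
        )
    return HOT if s == "strong" else NON_HOT


def load_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a delimited mutation table into records.

    The header must name pdb, chain and residue columns plus exactly one of
    ``ddg`` / ``strength``.  Duplicate residues are rejected with their row
    numbers.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    colmap = {
        "pdb": "pdb_id", "pdb_id": "pdb_id",
        "chain": "chain",
        "residue": "seq_num", "seq_num": "seq_num", "resnum": "seq_num",
        "icode": "icode",
        "wild_type": "wild_type", "aa": "wild_type", "wt": "wild_type",
        "ddg": "ddg", "strength": "strength",
    }
    df = df.rename(columns={c: colmap[c] for c in df.columns if c in colmap})
    required = {"pdb_id", "chain", "seq_num"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: header must name {sorted(required)}")
    has_ddg = "ddg" in df.columns
    has_strength = "strength" in df.columns
    if has_ddg == has_strength:
        raise ValueError(f"{path}: need exactly one of ddg / strength columns")

    keys = list(
        zip(df["pdb_id"].astype(str), df["chain"].astype(str), df["seq_num"].astype(int))
    )
    seen: dict[tuple, int] = {}
    dup_rows = []
    for i, k in enumerate(keys):
        if k in seen:
            dup_rows.append((seen[k] + 2, i + 2))  # 1-based incl. header
        seen[k] = i
    if dup_rows:
        raise ValueError(f"{path}: duplicate residue rows at lines {dup_rows}")

    records = []
    for _, row in df.iterrows():
        records.append(
            MutationRecord(
                pdb_id=str(row["pdb_id"]).strip(),
                chain=str(row["chain"]).strip(),
                seq_num=int(row["seq_num"]),
                icode=str(row["icode"]).strip() if "icode" in df.columns and pd.notna(row.get("icode")) else "",
                wild_type=str(row["wild_type"]).strip().upper() if "wild_type" in df.columns else "UNK",
                ddg=float(row["ddg"]) if has_ddg else None,
                strength=str(row["strength"]).strip() if has_strength else None,
            )
        )
    return records


def label_records(records: list[MutationRecord]) -> pd.DataFrame:
    """Label each record; returns a tidy frame with a ``label`` column."""
    rows = [
        {
            "pdb_id": r.pdb_id,
            "chain": r.chain,
            "seq_num": r.seq_num,
            "icode": r.icode,
            "wild_type": r.wild_type,
            "label": r.label(),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def packaged_training_table() -> list[MutationRecord]:
    """The packaged (synthetic stand-in) ΔΔG training mutation table."""
    with resources.as_file(
        resources.files("apis.data").joinpath("training_mutations_synthetic.tsv")
    ) as p:
        return load_mutations(p)


def training_manifest() -> dict:
    """The training-complex roster (PDB id, partner molecules, chain split).

    The roster records the 15 printed entries; the source text counts 17
    complexes, and the manifest carries a ``note`` flagging the discrepancy.
    """
    text = resources.files("apis.data").joinpath("training_manifest.yaml").read_text()
    return yaml.safe_load(text)


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""]).fillna({"icode": ""})
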
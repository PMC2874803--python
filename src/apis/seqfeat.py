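"""Sequence-derived residue features: physicochemical values, conservation, Pp.

Three feature groups that need no geometry of their own:

* ten physicochemical values per residue *type* (atom counts, charge,
  hydrogen-bonding capacity, hydrophobicity/hydrophilicity, propensity,
  isoelectric point, mass, expected contact number, electron-ion
  interaction potential), shipped as an overridable table;
* an evolutionary-rate conservation score (Rc) read from Rate4Site /
  ConSurf-style output files — lower means more conserved, values pass
  through unscaled;
* a knowledge-based residue-pair potential (Pp) summed over partner-side
  residues in atomic contact, with the 20x20 matrix supplied externally.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import AA3, Residue, StructureModel

__all__ = [
    "PHYSCHEM_PROPERTIES",
    "assemble_features",
    "load_physchem_table",
    "physchem_vector",
    "ConservationMap",
    "read_conservation",
    "PotentialMatrix",
    "pairwise_potential",
    "ConservationParseError",
]

#: Column names of the ten physicochemical properties, in shipped-table order.
PHYSCHEM_PROPERTIES = (
    "n_atoms",
    "charge",
    "h_bonds",
    "hydrophobicity",
    "hydrophilicity",
    "propensity",
    "isoelectric_point",
    "mass",
    "Enc",
    "eiip",
)

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class ConservationParseError(ValueError):
    """Malformed conservation file row (carries the 1-based line number)."""


def load_physchem_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the 20 x 10 physicochemical table (shipped default or user file).

    User files are tab-delimited with a header row naming ``aa`` plus any of
    the :data:`PHYSCHEM_PROPERTIES`; rows given override the defaults.
    """
    text = resources.files("apis.data").joinpath("physchem.tsv").read_text()
    table = _parse_physchem(text)
    if path is not None:
        user = _parse_physchem(Path(path).read_text())
        for aa, row in user.iterrows():
            for col, val in row.items():
                table.loc[aa, col] = val
    return table


def _parse_physchem(text: str) -> pd.DataFrame:
    rows: list[list[str]] = [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    header, data = rows[0], rows[1:]
    df = pd.DataFrame(data, columns=header).set_index("aa").astype(float)
    return df


def physchem_vector(aa_type: str, table: pd.DataFrame | None = None) -> np.ndarray:
    """The 10-vector of physicochemical values for one standard residue type."""
    if table is None:
        table = load_physchem_table()
    aa = aa_type.strip().upper()
    if aa not in AA3:
        raise KeyError(f"no physicochemical values for non-standard residue {aa!r}")
    return table.loc[aa, list(PHYSCHEM_PROPERTIES)].to_numpy(dtype=float)


@dataclasses.dataclass
class ConservationMap:
    """Per-residue evolutionary rate scores; lower = more conserved."""

    scores: dict[tuple[str, int], float]

    def get(self, chain: str, seq_num: int) -> float:
        """Score for a residue, NaN when the residue was not in the file."""
        return self.scores.get((chain, seq_num), float("nan"))

    def __len__(self) -> int:
        return len(self.scores)


def read_conservation(path: str | Path, default_chain: str = "A") -> ConservationMap:
    """Parse a Rate4Site / ConSurf grades style table.

    Accepted data rows are whitespace-delimited starting with a position,
    then a residue token, then the score.  A ConSurf ``3LATOM`` token like
    ``MET1:A`` supplies the chain; otherwise ``default_chain`` is used.
    Comment lines (``#``) and blank lines are skipped.
    """
    scores: dict[tuple[str, int], float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ConservationParseError(f"line {lineno}: expected >= 3 columns")
        try:
            pos = int(parts[0])
        except ValueError:
            raise ConservationParseError(f"line {lineno}: bad position {parts[0]!r}")
        chain = default_chain
        seq_num = pos
        token = parts[1]
        if ":" in token:  # e.g. MET1:A
            res_part, chain = token.rsplit(":", 1)
            digits = "".join(ch for ch in res_part if ch.isdigit() or ch == "-")
            if digits:
                seq_num = int(digits)
        try:
            score = float(parts[2])
        except ValueError:
            raise ConservationParseError(f"line {lineno}: bad score {parts[2]!r}")
        scores[(chain, seq_num)] = score
    return ConservationMap(scores)


@dataclasses.dataclass
class PotentialMatrix:
    """Symmetric 20x20 residue-pair potential with an atomic contact cutoff."""

    values: pd.DataFrame  # index/columns: three-letter codes
    contact_cutoff: float = 6.5  # Å, minimum heavy-atom distance

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        v = self.values.loc[AA3, AA3].to_numpy(dtype=float)
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("potential matrix must be symmetric")

    @classmethod
    def identity_zero(cls, contact_cutoff: float = 6.5) -> "PotentialMatrix":
        """All-zero default matrix (Pp contributes nothing until overridden)."""
        zeros = pd.DataFrame(0.0, index=list(AA3), columns=list(AA3))
        return cls(zeros, contact_cutoff)

    @classmethod
    def from_tsv(cls, path: str | Path, contact_cutoff: float = 6.5) -> "PotentialMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = [str(i).upper() for i in df.index]
        df.columns = [str(c).upper() for c in df.columns]
        return cls(df, contact_cutoff)

    def lookup(self, aa_i: str, aa_j: str) -> float:
        return float(self.values.loc[aa_i, aa_j])


def assemble_features(
    model: StructureModel,
    part,
    params=None,
    conservation: ConservationMap | None = None,
    potential: PotentialMatrix | None = None,
    physchem_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """The full per-residue feature table for one complex.

    Joins the 49 structural features + Tf with the 10 physicochemical values
    and, when their inputs are supplied, the conservation score Rc and the
    interface pair potential Pp — 62 features in total.  Conservation and Pp
    are optional: without their input files the pipeline simply runs with
    60 features (the columns are dropped, not zero-filled).
    """
    from .geometry import compute_struct_features
    from .structures import partition as _partition

    table = compute_struct_features(model, part, params)
    if physchem_table is None:
        physchem_table = load_physchem_table()
    for prop in PHYSCHEM_PROPERTIES:
        table[prop] = [
            float(physchem_table.loc[aa, prop]) if aa in physchem_table.index else float("nan")
            for aa in table["aa"]
        ]
    if potential is not None:
        unbound_a, unbound_b, bound = _partition(model, part)
        partner = {"a": unbound_b, "b": unbound_a}
        by_key = {res.key: res for res in bound.residues()}
        pp = []
        for _, row in table.iterrows():
            res = by_key[(row["chain"], row["seq_num"], row["icode"] if row["icode"] else "")]
            side = part.side_of(res.chain_id)
            pp.append(pairwise_potential(res, partner[side], potential))
        table["Pp"] = pp
    if conservation is not None:
        table["Rc"] = [
            conservation.get(row["chain"], int(row["seq_num"]))
            for _, row in table.iterrows()
        ]
    return table


def pairwise_potential(
    residue: Residue,
    partner_side: StructureModel,
    matrix: PotentialMatrix,
) -> float:
    """Interface pair-potential feature Pp for one residue.

    Sums the matrix entry over every partner-side residue whose minimum
    heavy-atom distance to this residue is within the contact cutoff.
    Non-standard residues in contact are skipped; no contacts gives 0.
    """
    if residue.aa_type not in AA3:
        return 0.0
    coords_i = np.array([a.coord for a in residue.atoms])
    tree = cKDTree(coords_i)
    total = 0.0
    for partner in partner_side.residues():
        coords_j = np.array([a.coord for a in partner.atoms])
        dmin = tree.query(coords_j)[0].min()
        if dmin <= matrix.contact_cutoff:
            if partner.aa_type not in AA3:
                continue
            total += matrix.lookup(residue.aa_type, partner.aa_type)
    return total
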
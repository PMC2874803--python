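"""Deterministic toy inputs: small structures and labeled feature tables.

Every stage of the pipeline is testable without downloading anything:

* ``single_atom`` — one isolated carbon (closed-form ASA/PI checks);
* ``cage`` — a central atom fully occluded by a dense spherical shell
  (zero-ASA construction);
* ``helix_pair_complex`` — two idealized contacting chains A and B whose
  interface residues necessarily lose surface on complexation;
* ``random_cloud`` — a protein-density random carbon cloud for oracle
  comparisons;
* ``gaussian_two_class`` — a labeled feature table with exact class sizes
  and controlled per-feature mean gaps.

All generators draw from one RNG seeded per call; a fixed seed reproduces
outputs exactly.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .selection import HOT, NON_HOT, FeatureMatrix
from .structures import Atom, ComplexPartition, Residue, StructureModel

__all__ = [
    "make_structure",
    "make_feature_table",
    "helix_pair_partition",
    "STRUCTURE_KINDS",
]

STRUCTURE_KINDS = ("single_atom", "cage", "helix_pair_complex", "random_cloud")


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _single_atom() -> StructureModel:
    atom = Atom(name="CA", element="C", coord=np.zeros(3), bfactor=10.0, serial=1)
    res = Residue(chain_id="A", seq_num=1, icode="", aa_type="ALA", atoms=[atom])
    return StructureModel(pdb_id="single", chains={"A": [res]})


def _cage(n_shell: int = 80, shell_radius: float = 2.8) -> StructureModel:
    """A carbon at the origin inside a shell dense enough to occlude it."""
    serial = 1
    center = Residue(
        chain_id="A",
        seq_num=1,
        icode="",
        aa_type="GLY",
        atoms=[Atom(name="CA", element="C", coord=np.zeros(3), bfactor=10.0, serial=serial)],
    )
    residues = [center]
    for i, u in enumerate(_fibonacci_sphere(n_shell)):
        serial += 1
        residues.append(
            Residue(
                chain_id="A",
                seq_num=i + 2,
                icode="",
                aa_type="ALA",
                atoms=[
                    Atom(
                        name="CB",
                        element="C",
                        coord=shell_radius * u,
                        bfactor=10.0,
                        serial=serial,
                    )
                ],
            )
        )
    return StructureModel(pdb_id="cage", chains={"A": residues})


def _strand_chain(
    chain_id: str,
    n_res: int,
    origin: np.ndarray,
    cb_direction: float,
    serial_start: int,
) -> tuple[list[Residue], int]:
    """An idealized extended chain with CB side chains facing one way."""
    residues = []
    serial = serial_start
    for i in range(n_res):
        p = origin + np.array([3.8 * i, 0.0, 0.0])
        spec = [
            ("N", "N", p + np.array([-1.20, 0.90, 0.0])),
            ("CA", "C", p),
            ("C", "C", p + np.array([1.30, 0.80, 0.0])),
            ("O", "O", p + np.array([1.40, 2.00, 0.0])),
            ("CB", "C", p + np.array([0.30, -0.60, 1.40 * cb_direction])),
        ]
        atoms = []
        for name, element, coord in spec:
            serial += 1
            atoms.append(
                Atom(
                    name=name,
                    element=element,
                    coord=coord,
                    bfactor=8.0 + 4.0 * i + (5.0 if chain_id == "B" else 0.0),
                    serial=serial,
                )
            )
        residues.append(
            Residue(chain_id=chain_id, seq_num=i + 1, icode="", aa_type="ALA", atoms=atoms)
        )
    return residues, serial


def _helix_pair(n_res: int = 6, gap: float = 6.6) -> StructureModel:
    """Two parallel contacting chains; CB atoms face each other across z.

    With the default gap the facing CB atoms sit 3.8 Å apart, well inside
    the 5 Å interface criterion, so every aligned residue pair is in
    contact and loses accessible surface in the bound form.
    """
    chain_a, serial = _strand_chain("A", n_res, np.zeros(3), +1.0, 0)
    chain_b, _ = _strand_chain("B", n_res, np.array([0.0, 0.0, gap]), -1.0, serial)
    return StructureModel(pdb_id="pair", chains={"A": chain_a, "B": chain_b})


def helix_pair_partition() -> ComplexPartition:
    """The A|B split matching ``helix_pair_complex`` output."""
    return ComplexPartition(side_a={"A"}, side_b={"B"})


def _random_cloud(n: int, rng: np.random.Generator) -> StructureModel:
    """n carbon atoms uniform in a cube at roughly protein packing density."""
    box = (n / 0.045) ** (1.0 / 3.0)  # ~0.045 heavy atoms per Å^3
    coords = rng.uniform(0.0, box, size=(n, 3))
    residues = [
        Residue(
            chain_id="A",
            seq_num=i + 1,
            icode="",
            aa_type="ALA",
            atoms=[
                Atom(
                    name="CA",
                    element="C",
                    coord=coords[i],
                    bfactor=float(10.0 + 2.0 * i),
                    serial=i + 1,
                )
            ],
        )
        for i in range(n)
    ]
    return StructureModel(pdb_id=f"cloud{n}", chains={"A": residues})


def make_structure(kind: str, seed: int = 0, n: int = 50) -> StructureModel:
    """Generate one toy structure of the requested kind (seed-deterministic)."""
    if kind == "single_atom":
        return _single_atom()
    if kind == "cage":
        return _cage()
    if kind == "helix_pair_complex":
        return _helix_pair()
    if kind == "random_cloud":
        if n < 1:
            raise ValueError("random_cloud needs n >= 1")
        return _random_cloud(n, np.random.default_rng(seed))
    raise ValueError(f"unknown structure kind {kind!r}; choose from {STRUCTURE_KINDS}")


def make_feature_table(
    n_pos: int,
    n_neg: int,
    gaps: Sequence[float],
    sds: Sequence[float] | float = 1.0,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> FeatureMatrix:
    """A two-class Gaussian feature table with controlled separations.

    Feature *j* is drawn N(0, sd_j) for non-hot rows and N(gap_j, sd_j) for
    hot rows; class sizes are exact and a fixed seed reproduces the table
    byte-identically.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    gaps = np.asarray(gaps, dtype=float)
    if np.isscalar(sds) or isinstance(sds, float):
        sds = np.full(len(gaps), float(sds))
    sds = np.asarray(sds, dtype=float)
    if (sds <= 0).any():
        raise ValueError("per-feature SDs must be positive")
    if feature_names is None:
        feature_names = [f"f{j:02d}" for j in range(len(gaps))]
    rng = np.random.default_rng(seed)
    pos = rng.normal(loc=gaps, scale=sds, size=(n_pos, len(gaps)))
    neg = rng.normal(loc=0.0, scale=sds, size=(n_neg, len(gaps)))
    X = pd.DataFrame(np.vstack([pos, neg]), columns=list(feature_names))
    y = pd.Series([HOT] * n_pos + [NON_HOT] * n_neg, index=X.index, dtype=object)
    return FeatureMatrix(X=X, y=y)
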
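"""Structural residue features: ASA, RASA, depth index, protrusion index, Tf.

Per-residue features are computed in two structural contexts with identical
coordinates: the *bound* form (the full complex) and the *unbound* form (the
residue's own side of the complex viewed alone).  Relative changes upon
complexation,

    rc(x) = (x_unbound - x_bound) / x_unbound        (0 when x_unbound = 0),

make burial on binding come out positive.  Together the ASA (5 attributes x
3 contexts), RASA (5 x 2), depth index (4 x 3) and protrusion index (4 x 3)
blocks give 49 structural features; the normalized Cα temperature factor Tf
adds one more.

Solvent-accessible surface areas use the Shrake-Rupley rolling-probe
algorithm on a deterministic Fibonacci sphere lattice; the accessible dots
it retains double as the surface sample for the depth index.  The protrusion
index of an atom is the empty-to-occupied volume ratio inside a fixed-radius
sphere, with occupied volume estimated as (heavy-atom count) x (mean atom
volume).
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache
from importlib import resources
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import ComplexPartition, Residue, StructureModel, classify_atom

__all__ = [
    "GeometryParams",
    "DEFAULT_VDW_RADII",
    "STRUCT_FEATURE_NAMES",
    "ALL_STRUCT_COLUMNS",
    "atom_asa",
    "accessible_surface",
    "residue_asa_features",
    "relative_change",
    "residue_depth",
    "protrusion_index",
    "normalize_bfactor",
    "compute_struct_features",
    "load_rasa_reference",
    "BuriedModelError",
]

#: Van der Waals radii (Å) per element for the probe-sphere computation.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.80  # unknown heavy element fallback

_ASA_ATTRS = ("total", "backbone", "side_chain", "polar", "non_polar")
_DIPI_ATTRS = ("total_mean", "side_chain_mean", "max", "min")
_ASA_CODE = {"total": "t", "backbone": "b", "side_chain": "s",
             "polar": "p", "non_polar": "n"}
_DIPI_CODE = {"total_mean": "tm", "side_chain_mean": "sm",
              "max": "max", "min": "min"}


class BuriedModelError(ValueError):
    """Raised when a model exposes no solvent-accessible surface at all."""


def _feature_names() -> list[str]:
    names: list[str] = []
    for ctx in ("U", "B", "Rc"):
        names += [f"{ctx}{_ASA_CODE[a]}ASA" for a in _ASA_ATTRS]
    for ctx in ("U", "B"):
        names += [f"{ctx}{_ASA_CODE[a]}RASA" for a in _ASA_ATTRS]
    for block in ("DI", "PI"):
        for ctx in ("U", "B", "Rc"):
            names += [f"{ctx}{_DIPI_CODE[a]}{block}" for a in _DIPI_ATTRS]
    return names


#: The 49 structural feature column names (symbols like RcsASA, BtRASA, RcsmPI).
STRUCT_FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names())
assert len(STRUCT_FEATURE_NAMES) == 49

#: 49 structural features plus the normalized temperature factor.
ALL_STRUCT_COLUMNS: tuple[str, ...] = STRUCT_FEATURE_NAMES + ("Tf",)


def load_rasa_reference() -> dict[str, dict[str, float]]:
    """Load the shipped per-attribute-class maximum-ASA reference table.

    The table is computed by this package's own ASA engine on ideal isolated
    residue conformations (see ``scripts/generate_reference_data.py``); the
    glycine side-chain entry uses the Cα atom as pseudo-side-chain so the
    RASA denominator is never zero.
    """
    text = resources.files("apis.data").joinpath("rasa_reference.tsv").read_text()
    table: dict[str, dict[str, float]] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        table[parts[0]] = {h: float(v) for h, v in zip(header[1:], parts[1:])}
    return table


@dataclasses.dataclass
class GeometryParams:
    """Tunable constants of the geometric feature computations.

    probe_radius : solvent probe, Å (water, 1.4 by convention)
    sphere_points : Shrake-Rupley lattice resolution (points per atom sphere)
    vdw_radii : element -> van der Waals radius, Å
    pi_sphere_radius : neighborhood radius of the protrusion index, Å
    mean_atom_volume : assumed volume per heavy atom, Å³
    rasa_reference : aa -> attribute-class -> maximum ASA, Å²
    rc_denominator : which context normalizes the relative change
    strict_elements : raise on an element missing from vdw_radii
    """

    probe_radius: float = 1.4
    sphere_points: int = 960
    vdw_radii: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_VDW_RADII)
    )
    pi_sphere_radius: float = 10.0
    mean_atom_volume: float = 20.1
    rasa_reference: dict[str, dict[str, float]] | None = None
    rc_denominator: Literal["unbound", "bound"] = "unbound"
    strict_elements: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.sphere_points < 92:
            raise ValueError("sphere_points must be >= 92")
        if any(r <= 0 for r in self.vdw_radii.values()):
            raise ValueError("all vdW radii must be positive")

    def radius_of(self, element: str) -> float:
        try:
            return self.vdw_radii[element.upper()]
        except KeyError:
            if self.strict_elements:
                raise KeyError(f"no vdW radius for element {element!r}")
            return DEFAULT_RADIUS

    def reference(self) -> dict[str, dict[str, float]]:
        if self.rasa_reference is None:
            self.rasa_reference = load_rasa_reference()
        return self.rasa_reference


@lru_cache(maxsize=8)
def _unit_sphere(n: int) -> np.ndarray:
    """Deterministic Fibonacci lattice of n points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k  # golden angle
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _model_arrays(model: StructureModel, params: GeometryParams):
    coords = model.coords()
    radii = np.array([params.radius_of(a.element) for a in model.atoms()])
    return coords, radii


def _canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axes frame with deterministic sign fixing.

    Computing the dot lattice in this frame makes the sampled areas exactly
    invariant under rigid-body motion of the input (the lattice co-rotates
    with the molecule instead of staying fixed in the lab frame).
    """
    center = coords.mean(axis=0)
    X = coords - center
    if len(coords) < 3:
        return np.eye(3), center
    _, V = np.linalg.eigh(X.T @ X)
    V = V[:, ::-1]  # descending variance
    weights = np.arange(1, len(X) + 1, dtype=float)
    for k in range(2):  # third axis follows by right-handedness
        proj = X @ V[:, k]
        # atom-order-weighted projection: invariant under rigid motion and,
        # unlike odd geometric moments, nonzero even for mirror-symmetric
        # configurations
        s = float(weights @ proj)
        if abs(s) <= 1e-9 * max(float(np.abs(proj).sum()) * len(X), 1e-30):
            s = float(np.sum(proj**3))
        if s < 0:
            V[:, k] = -V[:, k]
    V[:, 2] = np.cross(V[:, 0], V[:, 1])
    return V, center


def _sasa_arrays(
    coords: np.ndarray, radii: np.ndarray, params: GeometryParams,
    keep_dots: bool = False,
):
    """Per-atom accessible areas (and optionally accessible dots).

    Returns (areas, dots) where dots is the stacked (m, 3) array of retained
    accessible surface sample points (lab frame), or None when keep_dots is
    false.  The computation runs in the molecule's canonical frame so the
    sampling error does not depend on the input's orientation.
    """
    frame, center = _canonical_frame(coords)
    coords = (coords - center) @ frame
    n = len(coords)
    sphere = _unit_sphere(params.sphere_points)
    ext = radii + params.probe_radius
    areas = np.zeros(n)
    dots_out: list[np.ndarray] = []
    tree = cKDTree(coords)
    max_ext = ext.max() if n else 0.0
    for i in range(n):
        pts = coords[i] + ext[i] * sphere
        neighbors = tree.query_ball_point(coords[i], ext[i] + max_ext)
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= ext[j] * ext[j]
            if not accessible.any():
                break
        frac = accessible.mean()
        areas[i] = 4.0 * math.pi * ext[i] * ext[i] * frac
        if keep_dots and accessible.any():
            dots_out.append(pts[accessible])
    dots = None
    if keep_dots:
        dots = np.vstack(dots_out) if dots_out else np.empty((0, 3))
        dots = dots @ frame.T + center  # back to the lab frame
    return areas, dots


def atom_asa(model: StructureModel, params: GeometryParams | None = None) -> dict[int, float]:
    """Solvent-accessible surface area per atom, keyed by atom serial, Å²."""
    params = params or GeometryParams()
    coords, radii = _model_arrays(model, params)
    if len(coords) == 0:
        raise ValueError("empty model")
    areas, _ = _sasa_arrays(coords, radii, params)
    return {a.serial: areas[i] for i, a in enumerate(model.atoms())}


def accessible_surface(
    model: StructureModel, params: GeometryParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(per-atom areas, retained accessible surface dots) for a model."""
    params = params or GeometryParams()
    coords, radii = _model_arrays(model, params)
    if len(coords) == 0:
        raise ValueError("empty model")
    areas, dots = _sasa_arrays(coords, radii, params, keep_dots=True)
    return areas, dots


def relative_change(
    unbound_value: float, bound_value: float,
    denominator: Literal["unbound", "bound"] = "unbound",
) -> float:
    """Relative change of a feature upon complexation.

    Default convention: (unbound - bound) / unbound, so that burial on
    binding (ASA decrease) is positive; 0/0 is defined as 0.
    """
    if unbound_value < 0 or bound_value < 0:
        raise ValueError("relative_change requires non-negative inputs")
    denom = unbound_value if denominator == "unbound" else bound_value
    if denom == 0:
        return 0.0
    return (unbound_value - bound_value) / denom


def _aggregate_asa(res: Residue, area_of: dict[int, float]) -> dict[str, float]:
    """Sum atom areas into the five ASA attribute classes."""
    out = {a: 0.0 for a in _ASA_ATTRS}
    for atom in res.atoms:
        area = area_of[atom.serial]
        part, polarity = classify_atom(res.aa_type, atom.name)
        out["total"] += area
        out[part] += area
        if polarity == "polar":
            out["polar"] += area
        elif polarity == "non_polar":
            out["non_polar"] += area
    return out


def _aggregate_dipi(res: Residue, value_of: dict[int, float]) -> dict[str, float]:
    """Mean/extreme atom values into the four DI/PI attribute classes.

    Glycine has no side-chain atoms; its side-chain mean falls back to the
    Cα value (pseudo-side-chain) so the attribute is always defined.
    """
    values = [value_of[a.serial] for a in res.atoms]
    side = [
        value_of[a.serial]
        for a in res.atoms
        if classify_atom(res.aa_type, a.name)[0] == "side_chain"
    ]
    if not side:
        ca = res.atom("CA")
        side = [value_of[ca.serial]] if ca is not None else values
    return {
        "total_mean": float(np.mean(values)),
        "side_chain_mean": float(np.mean(side)),
        "max": float(np.max(values)),
        "min": float(np.min(values)),
    }


def residue_asa_features(
    model: StructureModel,
    part: ComplexPartition,
    params: GeometryParams | None = None,
) -> pd.DataFrame:
    """Bound and unbound ASA + RASA attributes for every residue.

    Rows are indexed by (chain, seq_num, icode); columns are the 25 ASA/RASA
    feature symbols (15 ASA incl. relative changes + 10 RASA).
    """
    params = params or GeometryParams()
    from .structures import partition as _partition

    unbound_a, unbound_b, bound = _partition(model, part)
    area_bound = atom_asa(bound, params)
    area_unbound = {**atom_asa(unbound_a, params), **atom_asa(unbound_b, params)}
    ref = params.reference()

    rows = {}
    for res in bound.residues():
        asa_u = _aggregate_asa(res, area_unbound)
        asa_b = _aggregate_asa(res, area_bound)
        if res.aa_type not in ref:
            raise KeyError(f"residue type {res.aa_type!r} missing from RASA reference")
        ref_row = ref[res.aa_type]
        row: dict[str, float] = {}
        for attr in _ASA_ATTRS:
            code = _ASA_CODE[attr]
            row[f"U{code}ASA"] = asa_u[attr]
            row[f"B{code}ASA"] = asa_b[attr]
            row[f"Rc{code}ASA"] = relative_change(
                asa_u[attr], asa_b[attr], params.rc_denominator
            )
            row[f"U{code}RASA"] = asa_u[attr] / ref_row[attr]
            row[f"B{code}RASA"] = asa_b[attr] / ref_row[attr]
        rows[res.key] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["chain", "seq_num", "icode"])
    return df


def residue_depth(
    model: StructureModel, params: GeometryParams | None = None
) -> pd.DataFrame:
    """Depth-index attributes per residue for one structural context.

    The depth of an atom is its minimum Euclidean distance to the retained
    solvent-accessible surface dots of the whole model; surface atoms sit at
    roughly (vdW radius + probe), buried atoms farther.
    """
    params = params or GeometryParams()
    _, dots = accessible_surface(model, params)
    if len(dots) == 0:
        raise BuriedModelError("model exposes no accessible surface")
    tree = cKDTree(dots)
    coords = model.coords()
    depths, _ = tree.query(coords)
    depth_of = {a.serial: depths[i] for i, a in enumerate(model.atoms())}
    rows = {res.key: _aggregate_dipi(res, depth_of) for res in model.residues()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["chain", "seq_num", "icode"])
    return df


def atom_protrusion(
    model: StructureModel, params: GeometryParams | None = None
) -> dict[int, float]:
    """Per-atom protrusion index: V_ext / V_int inside a fixed sphere.

    V_int = (heavy atoms within pi_sphere_radius, including self) x
    mean_atom_volume; V_ext is the remaining sphere volume clamped at 0.
    """
    params = params or GeometryParams()
    coords = model.coords()
    tree = cKDTree(coords)
    counts = np.array(
        [len(tree.query_ball_point(c, params.pi_sphere_radius)) for c in coords]
    )
    v_sphere = 4.0 / 3.0 * math.pi * params.pi_sphere_radius**3
    v_int = counts * params.mean_atom_volume
    v_ext = np.clip(v_sphere - v_int, 0.0, None)
    pi = v_ext / v_int
    return {a.serial: pi[i] for i, a in enumerate(model.atoms())}


def protrusion_index(
    model: StructureModel, params: GeometryParams | None = None
) -> pd.DataFrame:
    """Protrusion-index attributes per residue for one structural context."""
    params = params or GeometryParams()
    pi_of = atom_protrusion(model, params)
    rows = {res.key: _aggregate_dipi(res, pi_of) for res in model.residues()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["chain", "seq_num", "icode"])
    return df


def normalize_bfactor(residues: Iterable[Residue]) -> dict[tuple[str, int, str], float]:
    """Z-scored Cα temperature factors over one chain.

    Tf(r) = (B_r - mean(B)) / sd(B) with the population standard deviation
    over the chain's Cα atoms; a zero-variance chain maps to all zeros, and
    a residue without a Cα gets NaN (feature flagged missing).
    """
    residues = list(residues)
    ca_b: dict[tuple[str, int, str], float] = {}
    for res in residues:
        ca = res.atom("CA")
        if ca is not None:
            ca_b[res.key] = ca.bfactor
    if len(ca_b) < 2:
        raise ValueError("need at least 2 residues with a CA atom")
    values = np.array(list(ca_b.values()))
    mean, sd = values.mean(), values.std()  # population SD
    out: dict[tuple[str, int, str], float] = {}
    for res in residues:
        if res.key not in ca_b:
            out[res.key] = float("nan")
        elif sd == 0:
            out[res.key] = 0.0
        else:
            out[res.key] = (ca_b[res.key] - mean) / sd
    return out


def _dipi_block(
    unbound: pd.DataFrame, bound: pd.DataFrame, symbol: str, params: GeometryParams
) -> pd.DataFrame:
    cols = {}
    for attr in _DIPI_ATTRS:
        code = _DIPI_CODE[attr]
        cols[f"U{code}{symbol}"] = unbound[attr]
        cols[f"B{code}{symbol}"] = bound[attr]
        cols[f"Rc{code}{symbol}"] = [
            relative_change(u, b, params.rc_denominator)
            for u, b in zip(unbound[attr], bound[attr])
        ]
    return pd.DataFrame(cols, index=bound.index)


def compute_struct_features(
    model: StructureModel,
    part: ComplexPartition,
    params: GeometryParams | None = None,
) -> pd.DataFrame:
    """The full per-residue structural feature table (49 features + Tf).

    Returns a tidy frame: one row per residue of the partitioned complex with
    columns pdb_id, chain, seq_num, icode, aa, n_atoms, sparse, then the 50
    feature columns of :data:`ALL_STRUCT_COLUMNS`.
    """
    params = params or GeometryParams()
    from .structures import partition as _partition

    unbound_a, unbound_b, bound = _partition(model, part)

    asa = residue_asa_features(model, part, params)

    di_b = residue_depth(bound, params)
    pi_b = protrusion_index(bound, params)
    di_u = pd.concat([residue_depth(m, params) for m in (unbound_a, unbound_b)])
    pi_u = pd.concat([protrusion_index(m, params) for m in (unbound_a, unbound_b)])
    di = _dipi_block(di_u.loc[di_b.index], di_b, "DI", params)
    pi = _dipi_block(pi_u.loc[pi_b.index], pi_b, "PI", params)

    tf: dict[tuple[str, int, str], float] = {}
    for cid, chain_residues in bound.chains.items():
        try:
            tf.update(normalize_bfactor(chain_residues))
        except ValueError:
            tf.update({r.key: float("nan") for r in chain_residues})

    meta = pd.DataFrame.from_dict(
        {
            res.key: {
                "pdb_id": model.pdb_id,
                "aa": res.aa_type,
                "present_atoms": res.n_atoms,
                "sparse": res.is_sparse,
            }
            for res in bound.residues()
        },
        orient="index",
    )
    meta.index = pd.MultiIndex.from_tuples(meta.index, names=["chain", "seq_num", "icode"])

    out = pd.concat([meta, asa, di, pi], axis=1)
    out["Tf"] = [tf.get(k, float("nan")) for k in out.index]
    out = out.reset_index()
    ordered = ["pdb_id", "chain", "seq_num", "icode", "aa", "present_atoms", "sparse"]
    return out[ordered + list(ALL_STRUCT_COLUMNS)]
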
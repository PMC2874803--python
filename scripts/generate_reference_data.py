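"""Regenerate the packaged data files that are computed rather than typed.

Writes, deterministically:

* ``src/apis/data/rasa_reference.tsv`` — per-attribute-class maximum ASA
  values computed by the package's own ASA engine on ideal isolated residue
  conformations from the chemical component dictionary bundled with biotite
  (heavy atoms only, default probe and lattice).  The glycine side-chain
  entry uses the Cα atom as pseudo-side-chain.
* ``src/apis/data/training_mutations_synthetic.tsv`` — a synthetic stand-in
  ΔΔG training table (generated values, not experimental measurements)
  spread over the packaged training-complex roster, constructed to carry
  62 hot and 92 non-hot labels under the standard thresholds.

Run from the repository root:  python scripts/generate_reference_data.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import biotite.structure.info as struc_info  # noqa: E402

from apis.geometry import GeometryParams, _sasa_arrays  # noqa: E402
from apis.structures import AA3, classify_atom  # noqa: E402

DATA = ROOT / "src" / "apis" / "data"
ATTRS = ("total", "backbone", "side_chain", "polar", "non_polar")


def rasa_reference_rows() -> list[str]:
    params = GeometryParams()
    lines = [
        "# Maximum ASA reference (A^2) per residue type and attribute class,",
        "# computed by this package's Shrake-Rupley engine on ideal isolated",
        "# residue conformations (CCD geometry, heavy atoms, probe 1.4 A,",
        "# 960 lattice points). GLY side_chain uses CA as pseudo-side-chain.",
        "# Regenerate with scripts/generate_reference_data.py",
        "aa\t" + "\t".join(ATTRS),
    ]
    for aa in AA3:
        template = struc_info.residue(aa)
        heavy = template[(template.element != "H") & (template.element != "D")]
        # drop the terminal OXT: residues in a chain lack it
        heavy = heavy[heavy.atom_name != "OXT"]
        coords = np.asarray(heavy.coord, dtype=float)
        radii = np.array([params.radius_of(e) for e in heavy.element])
        areas, _ = _sasa_arrays(coords, radii, params)
        sums = {a: 0.0 for a in ATTRS}
        ca_area = 0.0
        for name, area in zip(heavy.atom_name, areas):
            part, polarity = classify_atom(aa, name)
            sums["total"] += area
            sums[part] += area
            if polarity == "polar":
                sums["polar"] += area
            elif polarity == "non_polar":
                sums["non_polar"] += area
            if name == "CA":
                ca_area = area
        if aa == "GLY":
            sums["side_chain"] = ca_area  # pseudo-side-chain
        lines.append(aa + "\t" + "\t".join(f"{sums[a]:.2f}" for a in ATTRS))
    return lines


def synthetic_training_rows() -> list[str]:
    """62 hot (ddg >= 2.0) + 92 non-hot (ddg < 0.4) synthetic records."""
    pdbs = [
        "1a4y", "1a22", "1ahw", "1brs", "1bxi", "1cbw", "1dan", "1dvf",
        "1fc2", "1fcc", "1gc1", "1jrh", "1vfb", "2ptc", "3hfm",
    ]
    rng = np.random.default_rng(20100408)
    aa_pool = [a for a in AA3 if a != "ALA"]
    lines = [
        "# SYNTHETIC stand-in training mutation table: residue identities and",
        "# ddG values are generated, not experimental; the class composition",
        "# (62 hot / 92 non-hot under ddG >= 2.0 / < 0.4 kcal/mol) matches the",
        "# published training set. Regenerate with",
        "# scripts/generate_reference_data.py",
        "pdb_id\tchain\tseq_num\twild_type\tddg",
    ]
    n_hot, n_non = 62, 92
    records = []
    for i in range(n_hot):
        ddg = 2.0 + float(rng.gamma(2.0, 1.2))
        records.append((True, ddg))
    for i in range(n_non):
        ddg = float(rng.uniform(-0.5, 0.399))
        records.append((False, ddg))
    rng.shuffle(records)
    used: set[tuple[str, str, int]] = set()
    for is_hot, ddg in records:
        pdb = pdbs[int(rng.integers(len(pdbs)))]
        chain = "AB"[int(rng.integers(2))]
        while True:
            seq = int(rng.integers(5, 250))
            if (pdb, chain, seq) not in used:
                used.add((pdb, chain, seq))
                break
        wt = aa_pool[int(rng.integers(len(aa_pool)))]
        lines.append(f"{pdb}\t{chain}\t{seq}\t{wt}\t{ddg:.3f}")
    return lines


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    (DATA / "rasa_reference.tsv").write_text("\n".join(rasa_reference_rows()) + "\n")
    (DATA / "training_mutations_synthetic.tsv").write_text(
        "\n".join(synthetic_training_rows()) + "\n"
    )
    print("wrote", DATA / "rasa_reference.tsv")
    print("wrote", DATA / "training_mutations_synthetic.tsv")


if __name__ == "__main__":
    main()
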
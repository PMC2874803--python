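"""Reproduce the full benchmark workflow on user-supplied inputs.

The published benchmark numbers (per-feature F-scores near 0.82 for RcsASA,
the inter-feature correlation table, the cross-validated and independent-set
classifier tables, and the calmodulin/MLCK and HslUV case-study calls)
depend on externally distributed inputs this package does not ship: the PDB
entries of the training/test complexes, the alanine-scanning ΔΔG tables and
strength-category lists derived from ASEdb/BID, and per-chain conservation
files.  Given those files, this script runs the complete pipeline —
featurize every complex, label residues, rank features by F-score, train
per-feature RBF-SVMs, cross-validate, build the 3-member majority-vote
ensemble — and prints the corresponding tables.

Usage:
    python scripts/reproduce_study.py \
        --structures DIR            # PDB files named <pdb_id>.pdb \
        --partitions FILE           # TSV: pdb_id, side_a, side_b (comma lists)
        --train-mutations FILE      # ddG dialect (see apis.datasets)
        [--test-mutations FILE]     # strength dialect
        [--conservation DIR]        # <pdb_id>_<chain>.grades files
        [--potential FILE]          # 20x20 pair-potential matrix TSV
        [--threshold 0.60] [--members 3] [--seed 0]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd

from apis.datasets import load_mutations
from apis.evaluation import metrics
from apis.geometry import GeometryParams
from apis.models import CVConfig, build_apis, cross_validate, cross_validate_ensemble
from apis.selection import FeatureMatrix, correlation_matrix, f_score_report, select_features
from apis.seqfeat import PotentialMatrix, assemble_features, read_conservation
from apis.structures import ComplexPartition, read_pdb


def featurize_all(structures_dir, partitions_path, conservation_dir, potential):
    partitions = pd.read_csv(partitions_path, sep="\t")
    tables = []
    params = GeometryParams()
    for _, row in partitions.iterrows():
        pdb_id = str(row["pdb_id"])
        model = read_pdb(Path(structures_dir) / f"{pdb_id}.pdb", pdb_id=pdb_id)
        part = ComplexPartition(
            side_a=str(row["side_a"]).split(","),
            side_b=str(row["side_b"]).split(","),
        )
        conservation = None
        if conservation_dir is not None:
            maps = {}
            for grades in Path(conservation_dir).glob(f"{pdb_id}_*.grades"):
                chain = grades.stem.split("_")[-1]
                maps.update(read_conservation(grades, default_chain=chain).scores)
            if maps:
                from apis.seqfeat import ConservationMap

                conservation = ConservationMap(maps)
        tables.append(
            assemble_features(model, part, params,
                              conservation=conservation, potential=potential)
        )
    return pd.concat(tables, ignore_index=True)


def attach_labels(features, mutations_path):
    records = load_mutations(mutations_path)
    labels = {
        (r.pdb_id, r.chain, r.seq_num): r.label() for r in records
    }
    features = features.copy()
    features["label"] = [
        labels.get((row["pdb_id"], row["chain"], int(row["seq_num"])))
        for _, row in features.iterrows()
    ]
    features = features[features["label"].isin(["hot", "non_hot"])]
    meta = {"pdb_id", "chain", "seq_num", "icode", "aa", "present_atoms", "sparse", "label"}
    feature_cols = [c for c in features.columns if c not in meta]
    return FeatureMatrix(
        X=features[feature_cols].reset_index(drop=True),
        y=features["label"].reset_index(drop=True),
    )


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--structures", required=True)
    ap.add_argument("--partitions", required=True)
    ap.add_argument("--train-mutations", required=True)
    ap.add_argument("--test-mutations")
    ap.add_argument("--conservation")
    ap.add_argument("--potential")
    ap.add_argument("--threshold", type=float, default=0.60)
    ap.add_argument("--members", type=int, default=3)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args(argv)

    potential = (
        PotentialMatrix.from_tsv(args.potential) if args.potential else None
    )
    features = featurize_all(args.structures, args.partitions,
                             args.conservation, potential)
    train = attach_labels(features, args.train_mutations)
    print(f"labeled training residues: {train.n} "
          f"({(train.y == 'hot').sum()} hot)")

    report = f_score_report(train)
    print("\nTop features by F-score:")
    print(report.stats.sort_values("fscore", ascending=False)
          .head(15).to_string(index=False))
    selected = select_features(report, threshold=args.threshold)
    print(f"\nSelected (F > {args.threshold}): {', '.join(selected)}")

    print("\nInter-feature correlations of the selected features:")
    print(correlation_matrix(train, selected).round(4).to_string())

    cv = CVConfig(k=10, seed=args.seed)
    print("\nSingle-feature classifiers, 10-fold CV on the training set:")
    for feature in selected:
        cm = cross_validate(train, [feature], cv)
        m = metrics(cm).rounded()
        print(f"  {feature:10s} " + "  ".join(f"{k}={v:.2f}" for k, v in m.items()))

    ensemble = build_apis(train, selected, member_rule="top_k",
                          k=args.members, cv=cv)
    print(f"\nEnsemble members: {', '.join(ensemble.member_features)}")
    cm = cross_validate_ensemble(train, ensemble.member_features, cv)
    print("Ensemble training-CV metrics: "
          + "  ".join(f"{k}={v:.2f}" for k, v in metrics(cm).rounded().items()))

    if args.test_mutations:
        test = attach_labels(features, args.test_mutations)
        preds = ensemble.predict(test.X)
        from apis.evaluation import ConfusionMatrix

        cm = ConfusionMatrix(
            tp=int(((test.y == "hot") & (preds == "hot")).sum()),
            tn=int(((test.y == "non_hot") & (preds == "non_hot")).sum()),
            fp=int(((test.y == "non_hot") & (preds == "hot")).sum()),
            fn=int(((test.y == "hot") & (preds == "non_hot")).sum()),
        )
        print("\nIndependent test set: "
              + "  ".join(f"{k}={v:.2f}" for k, v in metrics(cm).rounded().items()))
    return 0


if __name__ == "__main__":
    sys.exit(main())
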
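"""Optional experiment on user-supplied gene collections.

Given a FASTA of gene sequences and an id/label TSV (labels ``intronless``
or ``intron_containing``), this script extracts the seven feature
parameters and compares the 7-feature model with the 3-feature
(Z-curve-exponents-only) model by K-fold cross-validation on identical
partitions.  It exists for validating against real downloaded gene sets;
nothing in the test suite depends on it.

Usage:
    python scripts/external_benchmark.py genes.fa labels.tsv --k 5 --seed 0
"""

from __future__ import annotations

import argparse

import numpy as np

import dfa7
from dfa7 import model


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("fasta")
    ap.add_argument("labels")
    ap.add_argument("--k", type=int, default=5)
    ap.add_argument("--k-inner", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--min-length", type=int, default=256)
    args = ap.parse_args()

    label_map = dfa7.read_labels(args.labels)
    seqs = dfa7.read_fasta(args.fasta, labels=label_map)
    seqs = [s for s in seqs if s.label is not None]
    config = dfa7.FeatureConfig(min_length=args.min_length)
    X, ids, labels = dfa7.feature_matrix(seqs, config, skip_errors=True)
    y = np.asarray(labels, dtype=int)
    print(f"{len(ids)} usable sequences "
          f"({np.sum(y == 1)} intronless, {np.sum(y == -1)} intron-containing)")

    folds = model.kfold_partition(len(y), args.k, seed=args.seed, stratify_labels=y)
    for name, mask in (("7-feature", tuple(range(7))), ("3-feature", (0, 1, 2))):
        rep = model.cross_validate(
            X, y, K=args.k, K_inner=args.k_inner, seed=args.seed,
            feature_mask=mask, folds=folds,
        )
        per_fold = "  ".join(f"{a:.2f}" for a in rep.fold_accuracies)
        print(f"{name}: folds {per_fold}  average {rep.average_accuracy:.2f}%")


if __name__ == "__main__":
    main()
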
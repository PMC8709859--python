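#!/usr/bin/env python
"""Quantile-normalize each study and run sample quality control.

Brain and blood studies are normalized separately. After normalization the
per-array medians are identical by construction (the property box plots are
used to check on real arrays). QC computes the sample-sample Pearson
correlation matrix, an average-linkage two-cluster cut, PCA scores, and
flags samples lying more than 5x the median PC1-2 distance from their
(tissue, condition) group centroid; flagged samples are removed.

Reads results/data/, writes normalized matrices and QC reports to
results/preprocess/.
"""

import argparse
from pathlib import Path

from cernet import io, preprocess


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/preprocess"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for name in ("brain", "blood"):
        raw = io.read_expression_study(
            args.data / f"{name}_expression.tsv",
            args.data / f"{name}_samples.tsv",
            scale="linear",
        )
        normed = preprocess.quantile_normalize(raw)
        medians = normed.matrix.median(axis=0)
        assert medians.nunique() == 1, "normalization failed to equalize medians"
        qc = preprocess.qc_report(normed.to_log2())
        dropped = preprocess.flag_outliers(qc)
        clean = normed.drop_samples(dropped) if dropped else normed
        io.write_expression_study(
            clean,
            args.out / f"{name}_normalized.tsv",
            args.out / f"{name}_samples.tsv",
        )
        io.write_json(qc.to_dict(), args.out / f"{name}_qc.json")
        cl = qc.cluster_labels
        print(
            f"{name}: median intensity {medians.iloc[0]:.1f} on every array; "
            f"two-cluster cut sizes {sorted(cl.value_counts().to_list())}; "
            f"PC1/PC2 variance {qc.variance_fractions[0]:.1%}/{qc.variance_fractions[1]:.1%}; "
            f"flagged: {dropped or 'none'}"
        )


if __name__ == "__main__":
    main()
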
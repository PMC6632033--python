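#!/usr/bin/env python
"""Compare tRNAomes and codon occupancies across the models.

Pairwise per-codon ribosome-occupancy differences with Tukey-fence
outliers, a recurrence tally of repeatedly extreme codons, the Pearson
correlation matrix of isoacceptor fractions, and per-codon occupancy
dispersion. Writes tables under results/comparison/.
"""

import argparse
from pathlib import Path

import pandas as pd

from trnatempo import (
    all_pairwise_diffs,
    fraction_correlation,
    io,
    occupancy,
    per_codon_sd,
    recurrence,
)
from trnatempo.synthetic_data import STUDY_MODELS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    ap.add_argument("--recurrence-threshold", type=int, default=10)
    args = ap.parse_args()

    out = args.out_root / "comparison"
    out.mkdir(parents=True, exist_ok=True)
    fr_dir = args.out_root / "fractions"

    fractions = [io.read_fractions(fr_dir / f"fractions_{m}.tsv") for m in STUDY_MODELS]
    codon_fr = [
        io.read_codon_fractions(fr_dir / f"codon_fractions_{m}.tsv") for m in STUDY_MODELS
    ]
    occs = [occupancy(cf) for cf in codon_fr]

    pairs = all_pairwise_diffs(occs)
    pd.DataFrame(
        [
            {"model_a": p.model_a, "model_b": p.model_b, "codon": c, "diff": d,
             "outlier": int(c in p.outliers)}
            for p in pairs
            for c, d in sorted(p.diff.items())
        ]
    ).to_csv(out / "pairwise_diffs.tsv", sep="\t", index=False)

    table = recurrence(pairs)
    pd.DataFrame(
        {"codon": list(table.counts), "n_pairs_outlier": list(table.counts.values())}
    ).to_csv(out / "recurrence.tsv", sep="\t", index=False)

    labels, r = fraction_correlation(fractions)
    pd.DataFrame(r, index=labels, columns=labels).to_csv(out / "fraction_correlation.tsv", sep="\t")

    sd = per_codon_sd(occs)
    pd.DataFrame({"codon": list(sd), "occupancy_sd": list(sd.values())}).to_csv(
        out / "per_codon_sd.tsv", sep="\t", index=False
    )

    off_diag = [r[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))]
    recurrent = table.recurrent(args.recurrence_threshold)
    sd_sorted = sorted(sd, key=sd.get, reverse=True)
    print(f"{len(pairs)} model pairs compared; tables in {out}/")
    print(f"Isoacceptor-fraction correlations: {min(off_diag):.3f} to {max(off_diag):.3f} between models.")
    print(
        f"Codons extreme in > {args.recurrence_threshold} of {table.n_pairs} pairs: "
        f"{', '.join(recurrent) if recurrent else 'none'}"
    )
    print(f"Most variable codons by occupancy SD: {', '.join(sd_sorted[:5])}")


if __name__ == "__main__":
    main()
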
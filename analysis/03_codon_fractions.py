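#!/usr/bin/env python
"""Convert comparative ratios to absolute tRNA fractions and codon availability.

Anchors every model's representative array to the HeLa absolute tRNAome
(the comparative HeLa-vs-reference array cancels the shared reference
pool), then splits each isoacceptor's fraction across its decoded codons by
genomic codon usage. Writes probe-level fractions and 61-codon availability
tables under results/fractions/, and reports recovery accuracy against the
simulation ground truths.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from trnatempo import (
    BaselineTRNAome,
    calibrate_absolute,
    codon_fractions_for_model,
    io,
)
from trnatempo.synthetic_data import STUDY_MODELS


def load_representative(out_root, model):
    reps = pd.read_csv(out_root / "ratios" / "representatives.tsv", sep="\t")
    rep = int(reps.loc[reps.model_id == model, "representative"].iloc[0])
    return io.read_ratios(out_root / "ratios" / f"ratios_{model}_rep{rep}.tsv")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.out_root / "fractions"
    out.mkdir(parents=True, exist_ok=True)
    panel = io.read_panel(args.out_root / "arrays" / "panel.tsv")

    # the HeLa ground truth plays the role of the published absolute tRNAome
    hela_truth = pd.read_csv(args.out_root / "arrays" / "truth_HeLa.tsv", sep="\t")
    baseline = BaselineTRNAome("HeLa", dict(zip(hela_truth.probe_id, hela_truth.fraction)))
    baseline_ratios = load_representative(args.out_root, "HeLa")

    correlations = {}
    for model in STUDY_MODELS:
        fractions = calibrate_absolute(
            load_representative(args.out_root, model), baseline_ratios, baseline, panel
        )
        io.write_fractions(fractions, out / f"fractions_{model}.tsv")
        cf = codon_fractions_for_model(fractions, panel)
        io.write_codon_fractions(cf, out / f"codon_fractions_{model}.tsv")
        truth = pd.read_csv(args.out_root / "arrays" / f"truth_{model}.tsv", sep="\t")
        t = dict(zip(truth.probe_id, truth.fraction))
        ids = sorted(t)
        correlations[model] = float(
            np.corrcoef([t[i] for i in ids], [fractions.fractions[i] for i in ids])[0, 1]
        )

    print(f"Wrote probe- and codon-level fraction tables for {len(STUDY_MODELS)} models to {out}/")
    worst = min(correlations, key=correlations.get)
    print(
        "Recovery vs simulation ground truth: Pearson r "
        f"median {np.median(list(correlations.values())):.4f}, "
        f"worst {correlations[worst]:.4f} ({worst})."
    )
    print("Pro codons (CCN) are flagged ambiguous: the Pro isoacceptors are one array group.")


if __name__ == "__main__":
    main()
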
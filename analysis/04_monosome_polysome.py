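#!/usr/bin/env python
"""N-terminal charge across monosome/polysome translation categories.

Classifies the synthetic genes into the five translation categories
(ORF < 590 nt, monosome-enriched, no-enrichment, polysome-enriched,
top-300 polysome) from their planted monosome:polysome scores, then
stratifies first-window net charge across categories: per-category sign
fractions, segment means (N-terminal / core / C-terminal windows), and
the 16-bin charge-by-category percentage table with its all-protein
baseline.  Tables go to results/mp/.
"""

import argparse
from pathlib import Path

import pandas as pd

from chargescape.proteome_io import read_fasta
from chargescape.translation_groups import (
    CATEGORIES,
    charge_bin_group_percentages,
    classify_mp,
    group_charge_histogram,
    group_segment_means,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/mp"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = read_fasta(args.data / "proteome.fasta")
    scores = pd.read_csv(args.data / "mp_scores.tsv", sep="\t")
    by_id = {r.id: r for r in records}
    for row in scores.itertuples(index=False):
        rec = by_id[row.accession]
        rec.orf_length_nt = int(row.orf_length_nt)
        rec.mp_score = float(row.mp_score)

    classification = classify_mp(records)
    sizes = pd.Series([c.category for c in classification]).value_counts()
    print("category sizes:", dict(sizes))

    hists = group_charge_histogram(records, classification)
    rows = []
    for cat in CATEGORIES:
        if cat not in hists:
            continue
        counter, frac = hists[cat]
        rows.append({"category": cat, "n": frac.n,
                     "positive_pct": 100 * frac.positive,
                     "neutral_pct": 100 * frac.neutral,
                     "negative_pct": 100 * frac.negative})
    sign_df = pd.DataFrame(rows)
    sign_df.to_csv(args.out / "sign_fractions.tsv", sep="\t", index=False)
    print(sign_df.to_string(index=False))

    hist_rows = [
        {"category": cat, "net_charge": q, "count": n}
        for cat, (counter, _) in hists.items()
        for q, n in sorted(counter.items())
    ]
    pd.DataFrame(hist_rows).to_csv(args.out / "charge_histograms.tsv", sep="\t", index=False)

    segments = group_segment_means(records, classification)
    segments.to_csv(args.out / "segment_means.tsv", sep="\t", index=False)
    nterm = segments.query("segment == 'nterm'").set_index("category")["mean"]
    print("N-terminal mean net charge by category: "
          + ", ".join(f"{c}: {nterm[c]:+.2f}" for c in CATEGORIES if c in nterm.index))

    bins, baseline = charge_bin_group_percentages(records, classification)
    bins.to_csv(args.out / "charge_bins.tsv", sep="\t", index=False)
    baseline.rename_axis("category").reset_index(name="percent").to_csv(
        args.out / "baseline.tsv", sep="\t", index=False
    )
    lo = bins.set_index("bin")
    if "<=-7" in lo.index and ">=+8" in lo.index:
        print(f"monosome-side share rises with charge: "
              f"{lo.loc['<=-7', 'monosome'] + lo.loc['<=-7', 'orf_lt_590']:.0f}% at <=-7 vs "
              f"{lo.loc['>=+8', 'monosome'] + lo.loc['>=+8', 'orf_lt_590']:.0f}% at >=+8 "
              f"(baseline {baseline['monosome'] + baseline['orf_lt_590']:.0f}%)")


if __name__ == "__main__":
    main()
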
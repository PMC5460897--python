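# chargescape

Proteome-wide profiling of protein net charge in 30-residue sliding
windows, and its coupling to translation: ribosome occupancy by
N-terminal charge, and monosome/polysome stratification.

## The problem

The ribosome exit tunnel holds roughly 30 residues of nascent chain and
is electrostatically negative, so positively charged nascent segments
can interact with the tunnel walls and slow elongation. That makes the
*net charge of every 30-residue window* of a protein a quantity of
direct interest for translation: are strongly positive windows rare in
proteomes? Where along the sequence do positive windows sit? Do basic
N-termini carry more ribosomes, and are they translated by monosomes or
polysomes? This package implements that whole analysis chain for anyone
studying charge effects on elongation, plus a seeded synthetic-data
generator so every stage is testable without external downloads.

## The model

Per-residue charges at pH 7.4 follow the Henderson–Hasselbalch
equation: a basic group carries `+1/(1 + 10^(pH−pKa))`, an acidic group
`−1/(1 + 10^(pKa−pH))`. With the package's default pKa set this gives
Lys +0.999, Arg +1.000, His +0.048, Glu −0.999, Asp −1.000, Cys −0.085,
free α-amino +0.996 and α-carboxyl −1.000; all other residues are
exactly 0. The default analysis mode rounds these to integers (K/R → +1,
D/E → −1, everything else 0, His configurable to +1), drops the termini,
and sums over each window:

```
q(i) = Σ_{j=i}^{i+29} charge(residue_j),   i = 1 … L−29
```

Windows with |q| ≥ 14 are *supercharged*. For translation, genes are
grouped by q(1) — the first-window net charge — and per-codon
ribosome-profiling read counts are normalized per gene to mean 1; the
group metagene's trapezoidal area over codons 0–90 (the span during
which the first 30 residues occupy the tunnel), divided by that of the
charge-0 group, is the occupancy **AUC ratio**.

## Worked example

The analysis is driven by the numbered scripts under `analysis/`
(each is a thin wrapper over the library in `src/chargescape/`):

```sh
python analysis/01_simulate_data.py        # writes results/data/
python analysis/02_charge_landscape.py     # writes results/landscape/
python analysis/03_ribosome_occupancy.py   # writes results/occupancy/
python analysis/04_monosome_polysome.py    # writes results/mp/
```

With the default seed, step 02 prints

```
2000 proteins, 814360 windows: 41.1% positive, 14.8% neutral, 44.1% negative
per-position means: positions 3-10 average +0.095 vs -0.003 beyond position 10 (planted N-terminal K/R enrichment recovered)
supercharged stretches: 22 detected; 20/20 planted offsets recovered exactly
```

i.e. negative windows outnumber positive ones, the planted N-terminal
K/R composition boost shows up exactly where it was planted, and every
planted +15 stretch is found at its true window start. Step 03 prints

```
group  n_genes  auc_ratio_vs_reference  expected_auc_ratio  rel_error_pct
 >=+8      145                1.590905            1.603368       0.777316
 ...
 <=-7       99                0.840306            0.842819       0.298096
```

so genes whose first 30 residues sum to ≥ +8 carry ~1.6× the normalized
read density of the charge-0 group over codons 0–90 (the generator's
closed-form expectation for a 2.0× planted occupancy multiplier after
per-gene normalization), while acidic N-termini fall to ~0.84×. Step 04
shows the monosome-enriched categories accumulating positively charged
N-termini and the top-300 polysome genes skewing negative.

The same operations are exposed as a CLI (`chargescape scan | stats |
heatmap | supercharged | ribo | mp | simulate | run`); `chargescape run
--config run.toml` executes configured stages end-to-end and writes a
manifest of outputs.

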
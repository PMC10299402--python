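# raidesign

Design tool for conditional knockout alleles built on **recombinase-regulated
artificial introns (rAIs)** — short synthetic introns (DECAI/AIv4, 201 bp;
SCON, 189 bp) that carry loxP or FRT direct repeats around their branchpoint.
Knocked into a coding exon, an intact rAI splices itself out and the gene works
normally; after Cre/Flp excises the branchpoint, the shortened residual intron
(54 nt for DECAI, 55 nt for SCON) can no longer self-splice, the transcript is
frameshifted or interrupted by premature termination codons (PTCs), and the
mRNA is destroyed by nonsense-mediated decay (NMD) or long-3′UTR turnover.

The approach only works when the cassette is placed correctly. `raidesign`
encodes the published placement rules as an executable rule engine for mouse
(or any GFF3 + FASTA) genes, aimed at labs planning tissue-specific knockouts:

- **Exon selection** — constitutive exons only; never the last exon (no
  downstream exon-junction complex → no NMD); ≥150 bp (prefer ≥200 bp);
  exon ≥500 nt (prefer ≥1000 nt) upstream of the polyA in spliced coordinates;
  insertion ≥200 nt downstream of the start codon.
- **Within-exon position** — insert at a MAG-R context ((C/A)AG↓(G/A), which
  recreates the canonical MAG|GTRAGT donor and CAG|G acceptor junctions),
  ≥100 nt from the exon 5′ end, ≥55 nt (prefer ≥100 nt) but ≤400 nt from the
  3′ end, as close to the 3′ end as feasible.
- **Frame planning** — both major post-recombinase products must be out of
  frame: scenario (1), the rAI donor splicing to the downstream exon acceptor
  (shift = exon-tail length mod 3), and scenario (2), retention of the residual
  (shift = residual length mod 3 — the reason SCON's 55 nt beats DECAI's 54).
- **Splice-outcome simulation** — pre-recombinase self-splicing (must restore
  the wild-type mRNA byte-for-byte), the two major products, cryptic-donor
  fusions with the residual's acceptor, and whole-exon skipping, each with PTC
  annotation and 3′UTR length.
- **NMD classification** — the NMDetective-B nested tests (last exon /
  last 50 nt of the penultimate exon / <150 nt from the start codon /
  long exon >407 nt) plus a long-3′UTR flag (>800 nt).
- **Splice-score auditing** — a documented PWM proxy scores donors/acceptors
  in [0, 1]; externally computed predictor scores can be supplied as TSV and
  take precedence. A relative drop <1 % passes, 1–4 % warns, ≥4 % fails
  (the published failing placement dropped 0.981→0.935 ≈ 4.7 %; a tolerated
  one dropped 0.977→0.961 = 1.6 %).
- **HDR donor design** — ssDNA donor = upstream arm + cassette + downstream
  arm, presets 55/56, 37/100 and 58/60 nt; guide cut site within 10 bp.

The packaged cassette sequences are **synthetic stand-ins** (see
`src/raidesign/data/cassettes_synthetic.fasta`) that reproduce the published
architecture and arithmetic exactly — lengths, GT…AG ends, real loxP/FRT
direct repeats, residual lengths, stop-codon frame counts, and the single
AIv4 75A>G substitution. Replace them with your own construct via
`--cassette <fasta> --cassette-sidecar <yaml>` for production designs.

## Worked example

Generate a seeded toy gene (3 exons, 300/250/1200 nt) and design against the
SCON-loxP cassette:

```sh
raidesign fixtures --out-dir fx --seed 1
raidesign design --gff3 fx/toygene.gff3 --fasta fx/toygene.fasta \
    --gene toygene --cassette SCON-loxP --out-dir out --seed 1
# 4 passing candidate(s) of 32; outputs in out
```

`out/candidates.tsv` begins:

```text
rank exon_id offset motif tail_to_exon_3prime rank_score frameshift_ok scenario1_shift scenario2_shift ptc_count_scenario1 ptc_count_scenario2 failed_rules warned_rules
1    exon2   132    AAG-A 118                 955.8      True          1               1               0                   3
2    exon1   242    CAG-G 58                  938.2      True          1               1               1                   6                    three_prime_exclusion
```

The top candidate inserts SCON in exon 2 between positions 132 and 133 at an
AAG-A context, 118 nt from the exon 3′ end: every placement rule passes, both
post-recombinase scenarios are out of frame (shifts 1 and 1), and the
retained-residual product carries 3 PTCs inside the 55–400 nt
junction window where NMD is most efficient. `out/products.tsv` shows the
simulated outcomes for it:

```text
state             scenario                   frame_shift n_ptcs utr3_len composite
pre_recombinase   normal_self_splice         0           0      31
post_recombinase  rai_sds_to_downstream_sas  1           22     1041     0.25
post_recombinase  exon_sds_retained_residual 1           21     1352     1.0
post_recombinase  exon_skip                  1           22     1041     0.25
```

Pre-recombinase, the cassette splices out silently (`restores_wild_type:
true`, zero PTCs). Post-recombinase, every product is frameshifted with
PTCs and a long 3′UTR (>800 nt). `out/donor.fasta` holds the 300-nt ssDNA
donor (55 + 189 + 56 nt). Audit an existing design instead with:

```sh
raidesign check --gff3 ... --fasta ... --gene ... --exon exon2 --offset 132 \
    --cassette SCON-loxP --external-scores scores.tsv --out-dir out
```

which exits 3 (reports still written) when a hard rule or the score-drop
rule fails.

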
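# Methods

## The model

An rAI (recombinase-regulated artificial intron) is treated as a major-class
U2 intron: it must begin `GT`, end `AG`, and carry two identical direct-repeat
recombinase sites (34-bp loxP for Cre, 34-bp FRT for Flp) flanking its
branchpoint. Recombination is simulated as standard direct-repeat excision:
everything from the start of site 1 through the end of site 2 is replaced by a
single, left-anchored site copy. The operation is deterministic and idempotent
on its own output. The residual lengths this produces for the packaged
cassettes — 54 nt (DECAI/AIv4, divisible by 3) and 55 nt (SCON, not divisible
by 3) — drive all downstream frame arithmetic.

Mosaic (incomplete) recombination and inverted-repeat inversion are not
modeled.

### Packaged cassettes are synthetic stand-ins

The published cassette sequences are distributed only as figure artwork, so
the package ships synthetic constructs
(`data/cassettes_synthetic.fasta` + YAML sidecar with site spans,
branchpoint span and SHA-256 checksums) built to reproduce every stated
property: DECAI/AIv4 201 nt with a 54-nt residual and stop codons in all
three frames; AIv4 = DECAI with the single 75A>G substitution; SCON-loxP/-FRT
189 nt with a 55-nt residual; SCON-FRT with stop codons in exactly two
frames; consensus `GTAAGT` donor ends and polypyrimidine + `CAG` acceptor
ends; a `CTAAC` branchpoint motif between the sites. All arithmetic the tool
reports is computed from these sequences at run time, never hard-coded.
Users supply their own construct sequence for production work.

## Coordinates and gene models

Internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the I/O boundary only. Minus-strand genes are
reverse-complemented at sequence extraction, so all analysis is sense-strand;
a minus-strand gene and its plus-strand mirror produce identical reports.
Insertion points are *gap indices*: "between the 46th and 47th base pair"
(1-based counting) is offset 46.

"Constitutive" means identical genomic (contig, start, end, strand) in every
annotated transcript of the gene — a boundary-variant exon is not
constitutive, because a changed boundary changes the splice context. The
canonical transcript (longest CDS, ties broken lexicographically by id)
carries all spliced-coordinate rules; other isoforms matter only for
constitutivity. Annotation incompleteness is inherited: an exon is only as
constitutive as the annotation is complete.

## Rule engine

Every rule reports pass/warn/fail with the measured value, units and
threshold; nothing is filtered silently, because soft rules can legitimately
be bent with predictor evidence. Where the literature gives a range, the
conservative bound fails and the permissive bound warns:

| rule | fail | warn | units |
|---|---|---|---|
| min_exon_len | <150 | <200 | nt |
| polyA_min_distance (exon 3′ end → polyA, spliced) | <500 | <1000 | nt |
| start_codon_exclusion (gap − ATG, spliced) | <200 | — | nt |
| five_prime_exclusion (gap from exon 5′ end) | <100 | — | nt |
| three_prime_exclusion (exon 3′ tail) | <55 | <100 | nt |
| ptc_window_max (exon 3′ tail) | >400 | — | nt |
| last_exon / constitutive | violated | — | — |
| flanking_constitutive | — | violated | — |

Choices worth noting:

- The 100-bp 5′ rule measures to the insertion gap, not to the cassette's 3′
  boundary after insertion (noted in report footnotes).
- The polyA rule for the last exon is reported as subsumed by the hard
  last-exon failure rather than double-failing; for single-exon genes the
  junction-dependent rules (last-exon, polyA) are waived and the report notes
  that knockout must rely on long-3′UTR degradation and truncation.
- Exceeding 400 nt from the exon 3′ end is a hard fail: beyond that window
  NMD efficiency falls off and the checklist treats it as a requirement.
- In a combined candidate report the coarse exon-level start-codon
  reachability check is replaced by the exact position-level measurement, so
  each conceptual rule appears exactly once.

Ranking is a lexicographic total order — (no fails, fewer fails, fewer warns,
frameshift-proof, more PTCs in the 55–400 nt window, smaller 3′ tail, smaller
score drop, exon order, offset) — and therefore byte-stable across runs. The
0–1000 `rank_score` written to BED is a display projection of the same
components, not the sort key.

## Splice-outcome simulation

Pre-recombinase, the cassette is excised at its annotated span after
validating `GT…AG`, then natural introns are removed; the invariant that this
equals the wild-type mRNA byte-for-byte for every MAG-R placement is enforced
by a property test over 100 seeded genes. Post-recombinase, four products are
enumerated:

1. **rai_sds_to_downstream_sas** — rAI donor → downstream exon acceptor;
   deletes the exon 3′ tail (shift = tail mod 3).
2. **exon_sds_retained_residual** — normal exon donor; residual retained
   (shift = residual length mod 3).
3. **rai_sas_upstream_fusion** — a cryptic donor *inside the upstream
   mini-exon* (PWM score ≥ 0.8, configurable) pairs with the residual's
   still-strong acceptor. Fusion driven by the natural upstream-exon donor is
   not enumerated separately: the natural donor always scores high, which
   would make the product unconditional and uninformative; the mini-exon
   scan captures the actionable risk.
4. **exon_skip** — the whole edited exon is skipped. Branchpoint loss
   classically skips the exon downstream of the broken intron, which here is
   the second mini-exon — a product identical to (1); to keep the enum
   informative this scenario instead models skipping of the entire host exon.

Product abundances are deliberately not estimated (assembly and degradation
rates are unknowable at design time); instead a placement is
`frameshift_ok` only if both major products (1) and (2) are out of frame.

PTC annotation scans the single reading frame from the start codon; every
stop 5′ of the position the natural stop occupies in that product is a PTC
(scanning continues past the first stop — the count feeds the
readthrough-robustness argument for multiple PTCs). Junction distances are
measured from the stop codon's first base. The start codon and natural stop
are re-located by longest-common-prefix against the wild-type mRNA, which is
exact for the single contiguous edits these scenarios produce. A product
whose edit removes the start codon is annotated as having no ORF. The 55–400
nt PTC-to-junction window is inclusive at both bounds. Translation uses the
standard nuclear code; stop-codon readthrough is not modeled.

## Splice-site scoring

The deep-learning splice predictors the field uses are not re-implemented.
The built-in scorer is a PWM: log-odds against a uniform background, min-max
normalised per window so the consensus context scores exactly 1.0. Donor
window = 3 exonic + 6 intronic nt seeded from MAG|GTRAGT (degenerate M/R
split equally, pseudocount 0.03); acceptor window = 24 nt (20-nt
polypyrimidine tract at C/T 0.4 each, intronic CAG, one exonic G) — the
window length is a design choice; only the CAG|G consensus and the tract
concept are given. Every reported score carries a `pwm`/`external` source
tag, and externally computed predictor scores ingested from TSV take
precedence. The <1 % / 1–4 % / ≥4 % score-drop bands were calibrated on
predictor scores; whether they transfer to the PWM proxy is untested, which
is why reports always label the scorer.

## NMD classification and degradation score

The classifier applies the NMDetective-B nested tests strictly in order:
(i) PTC in the last exon → evading; (ii) in the last 50 nt of the penultimate
exon → evading; (iii) <150 nt from the start codon → evading; (iv) in a
>407 nt exon → *attenuated* (NMD weakens with distance upstream of the
junction; no quantitative decay curve is invented); otherwise targeted.
These NMDetective values (50/150/407) are deliberately separate knobs from
the placement engine's conservative 55/400/200 — they come from different
rules and are configurable independently. The long-3′UTR flag is strict:
utr3 > 800 nt, measured from the first PTC (or natural stop) to the polyA.

The composite degradation score,
`0.6·min(1, n_targeted/3) + 0.25·[long_utr3] + 0.15·min(1, n_window/3)`,
is an explicit invention of this package — no published aggregation exists —
and exists only to order candidates; it is monotone in each component,
bounded in [0, 1], and its weights are configurable and surfaced in reports.
NMD resistance by dosage compensation (common for X-linked genes) cannot be
computed and is emitted as a standing warning.

## Donor design

ssDNA donor = upstream arm + full cassette + downstream arm, arms copied
verbatim from the reference flanks of the gap on the gene's sense strand
(antisense available by flag; the literature does not prescribe a strand).
Defaults 55/56 nt with 37/100 and 58/60 presets. Guide design is out of
scope; a user-supplied cut position is checked against the 10-bp proximity
bound (pass/warn). Arms may span exon ends; no constraint is imposed.

## Synthetic fixtures

The generator emulates only what the rules need: gene architecture, canonical
junction context (exons end `CAG`, introns `GTAAGT…CTAAC…pyrimidines…CAG`,
exons resume `G`), a clean ORF (no unplanted in-frame stop), and planted
features at exact offsets (MAG-R gaps, consensus cryptic-donor 9-mers,
stops), with seeded rejection/repair removing accidental confounders. It does
not emulate realistic base composition, splicing-regulatory-element
landscapes, RNA structure, or repeats — so a green suite demonstrates the
rule arithmetic and simulation logic, not in-vivo splicing outcomes. Default
geometry: 3 exons of 300/250/1200 nt, 150-nt introns, CDS from position 30 —
sized so the middle exon admits both passing and warning placements and the
polyA distance rule is satisfiable. The rule-violation suite contains one
fixture per fail-able rule, each engineered to fail exactly that rule
(single-fail is cross-validated over the full merged report).

## Problem sizes and numerical choices

Property tests run 100 seeded toy genes (~1.3k MAG-R self-splice identity
checks) and 10-gene oracle sweeps; the whole suite completes in seconds.
All randomness flows through explicit seeds; pipelines contain no hidden
randomness, so two runs on the same inputs serialize byte-identical JSON.
Score normalisation clamps to [0, 1] against floating-point overshoot.
Ties in ranking break by (exon order, offset).

## Known limitations

- The PWM proxy is far weaker than the neural predictors it stands in for;
  its verdicts are labelled and replaceable, not authoritative.
- Branchpoint strength, cryptic branchpoint usage by the residual's acceptor,
  isoform abundances, SRE/hnRNP/SR effects and RNA structure are not modeled.
- UTR annotation beyond CDS bounds, alternative polyadenylation, and
  automatic discovery of "known-KO" exons are out of scope; the user asserts
  exon essentiality.
- Readthrough of PTCs is not modeled, only mitigated by preferring many PTCs
  in the efficient-NMD window.
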
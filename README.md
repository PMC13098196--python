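# umbrannot

Rule-based annotation of the cis-acting RNA elements that control
replication, translation and ribosomal frameshifting in umbravirus (UV)
and umbra-like virus (ULV) genomes — small (2.5–4.5 kb), single-component,
plus-sense RNA genomes of the *Tombusviridae*.  The package is aimed at
plant-virus RNA biologists who screen new metagenomic genome sequences
for these elements and need calls that are deterministic, auditable and
testable without downloads.

## What it annotates

For one genome (FASTA in; GFF3 + JSON + TSV out) the pipeline makes the
following calls:

* **Terminus completeness.**  A complete 5′ end begins with a carmovirus
  consensus sequence (CCS), `G{2,3}(A|U|C)(A|U){3,8}`, within the first
  10 nt.  A complete 3′ end carries hairpin H5 with a 5′-GGGC segment,
  an intervening terminal hairpin Pr, and 3′-terminal residues (usually
  GCCC-OH) that pair with the GGGC to form the pseudoknot ψ1; missing
  terminal cytidylates flip the truncation call.  H5 conformations are
  classified (GGGC on the apical loop's 5′ side; on the 3′ side of an
  internal loop; or in an internal loop with an empty opposing side).
* **ORFs and architecture.**  AUG-initiated ORFs (first-AUG-per-stop),
  sgRNA-start support from a CCS within 20 nt upstream of each start
  (with downstream re-annotation suggestions when support is missing),
  fusion of ORF1 into the −1 frame across the slippery site, and an
  architecture call: UV-like (intergenic region, ORF3/ORF4 overlapping
  with ~13-nt start spacing), Group 1 ULV-like (ORF3 overlapping ORF2's
  3′ end), or Group 2 ULV-like.
* **The −1 frameshift recoding site.**  Slippery heptamer (from the set
  `GGAUUUU, GGGUUUU, AAAUUUU, GGGAAAC, GGGUUUC`) 0–12 nt upstream of the
  ORF1 stop with its offset; hairpins HA (upstream of the frameshift
  stimulatory element), FSE (just downstream of the stop, with the
  lower internal loop that donates the 3′-end long-distance interaction),
  HB and HC; pseudoknots PK1/PK2 from the HB/HC apical loops (4–8 pairs
  within 50 nt); the CA consensus `CACAACAACUCC` (≤ 2 mismatches) and
  its placement at HC's base or in HC's apical loop; and the FSE↔3′-end
  long-distance interaction.
* **3′CITE classification.**  The CITE-associated structure (CAS) and
  its upstream kissing-loop hairpin pair, then the cap-independent
  translation enhancer class in fixed precedence TSS → ISS → UTE → BTE:
  TSS (three hairpins, the 5′ two juxtaposed, with two pseudoknots
  reaching past the third), ISS (one stem with two opposing bulged
  loops carrying conserved motifs; a branched variant with a separate
  LDI hairpin and a GNRA/UNCG cap), UTE (three hairpins atop an
  extended scaffold stem), and motif-only BTE; plus the CITE↔5′-end
  interaction against the genomic 5′ region or sgRNA starts.

Hairpins and pseudoknots come from a deterministic base-pair
maximization fold under explicit structural caps (see
`docs/methods.md`), not from a thermodynamic model: every call is
reproducible and checkable by exhaustive enumeration on small inputs.

The package also ships two curated literature-derived tables covering
17 UVs, 8 Group 1 ULVs and the Group 2 representative CY1 (ψ1/TSS/CITE
class/LDI pair/CAS/KL presence; slippery strings, PK1/PK2 pairs, CA
placement), together with tally and audit operations that reproduce the
published per-group counts, and a synthetic-genome generator that
plants every element class with ground truth so all annotators are
benchmarked end to end.

## Worked example

Simulate one fully planted UV-architecture genome and annotate it:

```
$ umbrannot simulate --seed 7 --out-fasta g.fa --out-manifest g.json
synth_7: 3049 nt, 3 attempt(s)
$ umbrannot annotate g.fa -o out
synth_7: group=UV_like cite=TSS
wrote 1 report(s) to out
$ column -t out/elements.tsv | cut -c1-100
```

The TSV row for this genome reads:

| field | value | meaning |
|---|---|---|
| `group_call` | `UV_like` | intergenic region + overlapping ORFs 3/4 with 13-nt start spacing |
| `psi1` | `yes` | 3′-terminal GCCC pairs a GGGC in hairpin H5 |
| `slippery` / `offset` | `GGAUUUU` / `3` | heptamer 3 nt upstream of the ORF1 stop |
| `pk1` / `pk2` | `CCGUA-UACGG` / `AAUUC-GAAUU` | HB / HC apical-loop pseudoknot duplexes |
| `ca_placement` | `HC_base` | the CA consensus's final residues form HC's lower stem |
| `cite_type` | `TSS` | three juxtaposed hairpins + two pseudoknots |
| `ldi_pair` | `UUGGCC-GGCCAA` | CITE apical loop pairing a 5′-proximal hairpin loop |
| `truncated_5p` / `truncated_3p` | `False` / `False` | both termini complete |

`out/synth_7.gff3` holds the same calls as 1-based GFF3 features and
`out/synth_7.json` the full evidence bundle.  `umbrannot tally` prints
the ten published element counts recomputed from the shipped tables
(all PASS) and the duplex-orientation audit, which flags the two
printed pairs that do not read as antiparallel duplexes.

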
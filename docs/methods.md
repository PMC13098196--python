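# Methods

## Scope and model

`umbrannot` encodes, as explicit testable rules, the cis-element
grammar shared by umbraviruses (UVs) and umbra-like viruses (ULVs):
5′-terminal carmovirus consensus sequences (CCS) marking genomic and
subgenomic RNA starts; a −1 programmed ribosomal frameshifting site
around the ORF1 stop codon (slippery heptamer, hairpins HA/FSE/HB/HC,
pseudoknots PK1/PK2, the CA consensus); a 3′ terminus built from
hairpin H5, the terminal hairpin Pr and the ψ1 pseudoknot between the
3′-terminal GCCC-OH and a GGGC segment in H5; cap-independent
translation enhancers (3′CITEs) of the TSS, ISS (plain and branched),
UTE and BTE classes with their CAS/kissing-loop context; and the two
long-distance RNA:RNA interactions (FSE↔3′ end, CITE↔5′ end).

The working assumption throughout is that these elements are compact,
locally folded stem-loops whose identity is positional (HA is the
hairpin upstream of the FSE, the FSE is the hairpin just downstream of
the ORF1 stop) or motif-defined (CCS, CA, slippery heptamers), not
sequence families.  Elements that cannot be located are reported as
absent — absence is a result.

## Folding: constrained base-pair maximization

Curated secondary structures in this literature are drawn by hand
around conserved motifs; thermodynamic parameter sets are not part of
the published rule set.  The fold engine therefore uses a
Nussinov-style base-pair maximization restricted to single stem-loops,
with every decision explicit and checkable:

* a *hairpin* is one inward-nested chain of Watson-Crick pairs (G:U
  optional, off by default) with at most `max_bulge = 6` unpaired nt
  per side between consecutive pairs, at most `max_internal_loops = 2`
  non-stacked steps, an apical loop of 3–`max_loop = 12` nt, a span of
  at most `max_span = 80` nt and at least `min_stem = 3` pairs;
* a hairpin's *score* is its pair count minus, per internal-loop/bulge
  event, `loop_penalty = 2` plus one per six unpaired loop nucleotides.
  Raw pair maximization under the bulge caps lets sparse chains of
  one- and two-pair runs dominate random sequence — structures no
  curator would draw — so ranking is by this score.  The event cap and
  the gentle size term were chosen together so that one large designed
  internal loop (e.g. the FSE's LDI-carrying loop) outranks
  re-parses that bridge it with isolated pairs;
* per anchor pair the single best chain is traced (budgeted dynamic
  programme over remaining loop events); sub-stems are suppressed as
  non-maximal only when the chain that absorbs them scores at least as
  well, so a compact high-scoring stem is always reported even when a
  sprawling super-chain exists;
* ties are broken toward more pairs, then the smallest inward step
  (stacked first), then 5′ position — folding is fully deterministic.

Loop-closing pairs breathe: duplex searches that read an apical loop
(pseudoknots, kissing loops, LDIs) pad it by one stem residue per side.
Pseudoknots are the longest 4–8-pair duplex between a loop and a 50-nt
downstream window, ties to the most-5′ partner.  General (multi-helix)
nested pair maximization is also exposed and, like the hairpin DP, is
checked exactly against exhaustive enumeration on sequences up to 30 nt
(branch-and-bound over all nested pairings; all stem chains).

## Selection rules

Recoding-site roles are proximity-first: among hairpins whose 5′ arm
starts (HA: 3′ arm ends) in the role's 40-nt window and whose score
reaches `role_min_score = 7`, the one closest to its anchor wins; if
none reaches the bar the best-scoring candidate is still reported.
The CA consensus is searched with ≤ 2 mismatches downstream of HB
(which subsumes the PK1-partner anchor without inheriting a
mis-resolved pseudoknot); `HC_base` requires at least 3 of CA's final
6 nt paired on HC's 5′ side, `in_HC` requires overlap with HC's apical
loop.  At the 3′ end, H5 and Pr are chosen jointly: among hairpins
presenting GGGC in a loop, the one followed by the best-scoring
intervening terminal hairpin wins, which rejects merged parses that
swallow Pr.  The 3′ UTR (last ORF end to H5) is folded once and the
same parse feeds the CAS search and the CITE classifier — region
boundaries shift which chains a fold reports, so consistency matters —
with hairpins upstream of the CAS apical excluded from CITE evidence.

CITE geometry is anchored on apical loops rather than stem boundaries
(chance flank pairing wanders the latter): TSS requires three hairpins
with apical separations of 8–18 nt (juxtaposed pair; a 1-nt spacer
variant still passes) and 8–40 nt, plus two ≥ 5-pair pseudoknots from
the 5′ pair's loops landing beyond the third apical; ISS requires both
configured conserved motifs in one internal loop, with a branched call
when a solid (≥ 5 pairs, score ≥ 5) hairpin emanates just 3′ of the
stem and a GNRA/UNCG flag for the cap; UTE requires three hairpins at
4–24-nt apical spacing enclosed by a ≥ 5-pair scaffold duplex; BTE is
a motif match only.  Precedence is fixed: TSS → ISS → UTE → BTE →
unknown.

The conserved *letters* of CAS, ISS and BTE live in an editable
signature file (`data/signatures.yaml`), not in code: the structural
rules are the model, the residues are data to be refined against
curated alignments.  The shipped CAS/ISS defaults are the values the
synthetic benchmark plants; the BTE-A default is the widely used 17-nt
conserved translation-enhancer core.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `ccs_gate_n` | 10 nt | a complete 5′ end has a CCS beginning within this window |
| `ccs_max_gap` | 20 nt | CCS 3′ end to AUG distance for sgRNA-start support |
| `slippery_max_upstream` | 20 nt | gate from heptamer 3′ end to the ORF1 stop |
| `element_window` (W) | 40 nt | proximity between consecutive recoding elements |
| `pk_search_window` | 50 nt | downstream window for pseudoknot partners |
| `pk_min_len`–`pk_max_len` | 4–8 | pseudoknot duplex length |
| `tss_pk_min_len` | 5 | the two TSS pseudoknot duplexes |
| `ca_max_mismatch` | 2 | Hamming allowance on CACAACAACUCC |
| `three_prime_window` | 120 nt | terminal window folded for H5/Pr/ψ1 |
| `psi1_min_pairs` | 3 | terminal GCC↔GGC accepted, warned below 4 |
| `orf34_spacing` ± tol | 13 ± 6 nt | expected ORF4 start offset in the UV architecture |
| `min_protein_aa` | 40 | ORF length cutoff |

All of these, and the fold caps, can be overridden from YAML.

## The synthetic benchmark

The generator emulates the study conditions: 3,000-nt backbones at GC
0.45 (genome sizes in the family run 4.1–4.5 kb; the default is scaled
for test throughput and sits inside the stated 2.5–4.5 kb range)
carrying a full planted element set — CCS, ORF1 with slippery heptamer
at offset 0 or 3, HA/FSE/HB/HC with PK1/PK2 and CA, a −1-frame ORF2
continuation, a UV / Group 1 / Group 2 ORF architecture, KL pair + CAS,
one CITE archetype, an H5–Pr–ψ1 terminus ending GCCC-OH, and both
long-distance interactions.  Designed stems are 6–10 perfect pairs;
the arm set was searched so that elements able to share one 80-nt
folding window have no cross-complementary run longer than 4 nt beyond
the intended interactions.  Coding fillers are sampled codon-aware so
no required reading frame acquires a stop codon; backbones are
rejected and resampled (attempts logged in the manifest) when chance
content would corrupt the ground truth: decoy slippery heptamers in
the detector's gate, spurious ORFs beyond ORF2, stray GGGC in the ψ1
window, decoy pseudoknot partners upstream of the planted ones,
side-hairpins that would mimic a branched ISS, or backbones whose
realized fold does not present the planted hairpins as separate
structures with their designed apical loops.  Generation is fully
deterministic per (design, seed).

What passing recovery shows, and what it does not: the benchmark
demonstrates that the annotators recover exactly what was planted in
random sequence context at high rate (exact-motif elements at 100%,
structural roles and CITE labels above 95%, remaining misses traced to
constraint-valid alternative parses).  Real genomes differ in ways the
generator does not emulate — codon usage and coding constraints,
covariation, elements weaker or longer-range than the designed ones,
G:U-rich stems, and annotation noise — so benchmark rates are upper
bounds on real-data behaviour, not estimates of it.  The
dinucleotide-preserving shuffle provides the matching negative
control.

## Numerical and engineering choices

* Internal coordinates are 0-based half-open; all external output
  (GFF3, JSON, TSV) is 1-based inclusive, converted at the writers.
* Only the "+" strand is modelled; IUPAC ambiguity codes are rejected.
* Every tie-break in folding, motif search and selection is
  lexicographic and documented at the function; there is no randomness
  outside the seeded generator, and identical inputs give
  byte-identical reports.
* The curated tables are checksummed at load; printed strings are kept
  verbatim (the slippery markup and spacing, the "?" unknowns, the
  duplex pairs in their printed orientation).  The orientation audit
  reports, rather than repairs, the two printed pairs that do not read
  as antiparallel duplexes, and the one slippery string whose markup
  implies a 4-nt heptamer–stop gap is surfaced by value.
* Problem sizes in the shipped experiments (200 genomes for recovery,
  500 sequences for the enumeration comparison) were chosen to give
  tight rate estimates while keeping the default suite fast.

## Known limitations

* The fold is nested-only: pseudoknots are modelled as loop↔window
  duplexes, and the alternative nested parse of a pseudoknot's duplex
  can compete with the hairpin parse on adjacent elements; selection
  rules mitigate but cannot eliminate this.
* PTE-class and other CITEs whose geometry is not encoded come out as
  `unknown`; BTE detection is motif-only.
* CAS/ISS signature defaults are benchmark values; genome screens
  should supply curated motifs.
* Architecture classification is rule-based on ORF geometry only; it
  does not consult protein structure, so the Group 1 / Group 2
  boundary for single-overlapping-ORF genomes follows the documented
  precedence rather than phylogeny.
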
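# Sequence signatures used by the CAS / ISS / BTE classifiers.
#
# The classifiers' structural rules live in code; the conserved letters
# live here so they can be refined against curated alignments without
# touching the code.  Provenance of the shipped defaults:
#   - bte_a_motif: the 17-nt conserved core of barley yellow dwarf-type
#     translation enhancers (field-standard).
#   - bte_b_motif: package default variant; replace for real screens.
#   - cas_* and iss_* motifs: package defaults used by the synthetic
#     benchmark generator; the conserved residues of real CAS and ISS
#     elements are curated-figure data and should be supplied by the
#     user for genome screens.
provenance: defaults-for-synthetic-benchmark
cas_apical_motif: ACGGAC
cas_stem_base_motif: GGUG
iss_bulge5_motif: AGUCC
iss_bulge3_motif: UUACG
bte_a_motif: GGAUCCUGGGAAACAGG
bte_b_motif: GGGUCCUGGUAAACAGG
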
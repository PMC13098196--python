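# Packaged data

`translation_elements.tsv` and `recoding_elements.tsv` are curated,
literature-derived per-virus element tables for the 17 umbraviruses,
8 Group 1 umbra-like viruses and the Group 2 representative CY1 (one
row per virus, same virus set in both files).  Printed values are kept
verbatim: slippery-site strings retain their `*heptamer*` markup and
the space that encodes heptamer/stop adjacency; duplex pairs keep their
printed orientation even where it does not read as an antiparallel
duplex (the loader's audit flags those); `?` is a distinct unknown
state.  `umbrannot.tables` verifies both files against frozen SHA-256
checksums at load time.

`signatures.yaml` holds the editable sequence signatures used by the
CAS / ISS / BTE classifiers; see the provenance comment in the file.
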
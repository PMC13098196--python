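"""Run configuration: every tunable window and threshold in one place.

Defaults reflect the rule set the annotators implement: a 5' CCS gate of
10 nt, a 20-nt CCS-to-AUG gating distance for subgenomic RNA starts, a
40-nt proximity window between consecutive recoding-site elements,
pseudoknot duplexes of 4-8 pairs searched within 50 nt, and a 120-nt
3'-terminal window for H5/Pr/psi1.  All values can be overridden from a
YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fold import FoldParams
from .motifs import DEFAULT_SLIPPERY_MOTIFS


@dataclass(frozen=True)
class SignatureConfig:
    """Editable sequence signatures for CAS / ISS / BTE classification.

    The structural rules (internal-loop geometry, branched scaffolds,
    hairpin counts) are fixed in code; the conserved *letters* are data.
    The shipped defaults are representative working values: the BTE-A
    motif is the widely used 17-nt conserved translation-enhancer core,
    the others are package defaults chosen for the synthetic benchmark
    and meant to be replaced with curated alignments for real screens
    (see data/signatures.yaml).
    """

    cas_apical_motif: str = "ACGGAC"
    cas_stem_base_motif: str = "GGUG"
    iss_bulge5_motif: str = "AGUCC"
    iss_bulge3_motif: str = "UUACG"
    bte_a_motif: str = "GGAUCCUGGGAAACAGG"
    bte_b_motif: str = "GGGUCCUGGUAAACAGG"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SignatureConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("provenance", None)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def default_signature_path() -> Path:
    return Path(__file__).parent / "data" / "signatures.yaml"


@dataclass(frozen=True)
class RunConfig:
    """Parameters for the full annotation pipeline."""

    # 5' end
    ccs_gate_n: int = 10  # CCS must begin within this many nt of the 5' end
    ccs_max_gap: int = 20  # CCS end -> AUG gating distance for sgRNA starts
    # ORFs
    min_protein_aa: int = 40
    orf34_spacing: int = 13  # expected ORF4 start offset from ORF3 start
    orf34_spacing_tol: int = 6
    # recoding site
    slippery_motifs: tuple[str, ...] = DEFAULT_SLIPPERY_MOTIFS
    slippery_max_upstream: int = 20
    ca_max_mismatch: int = 2
    element_window: int = 40  # proximity window W between recoding elements
    role_min_score: int = 7  # minimum fold score for a positional hairpin role
    pk_search_window: int = 50
    pk_min_len: int = 4
    pk_max_len: int = 8
    tss_pk_min_len: int = 5  # the two TSS pseudoknot duplexes
    # 3' end and CITEs
    three_prime_window: int = 120
    fse_ldi_region: int = 150  # 3'-terminal region searched for the FSE LDI
    cite_ldi_5p_window: int = 100
    ldi_min_len: int = 4
    psi1_min_pairs: int = 3  # terminal GCC vs GGC accepted, warned below 4
    # folding
    fold: FoldParams = field(default_factory=FoldParams)
    # signatures
    signatures: SignatureConfig = field(default_factory=SignatureConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key == "fold":
                kwargs["fold"] = FoldParams(**value)
            elif key == "signatures":
                kwargs["signatures"] = SignatureConfig(**value)
            elif key == "slippery_motifs":
                kwargs["slippery_motifs"] = tuple(value)
            elif key in known:
                kwargs[key] = value
        return cls(**kwargs)


DEFAULT_CONFIG = RunConfig()
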
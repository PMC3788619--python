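"""Run-wide configuration.

All tunable thresholds of the pipeline live in one dataclass so the CLI, the
library functions and the test fixtures agree on defaults.  The defaults are
the thresholds of the published analysis design: ±7-residue flanks, ±2
proximal windows, refinement outlier cutoff 0.2, a 20-sequence minimum and an
AUROC gate of 0.75 for kinase models, loss/gain p-value thresholds 0.05/0.1,
and FDR levels 0.05 (domains) and 0.01 (pathways).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass
class RunConfig:
    flank_width: int = 7
    proximal_width: int = 2
    outlier_cutoff: float = 0.2
    min_training_seqs: int = 20
    auroc_min: float = 0.75
    p_ref_sig: float = 0.05
    p_mut_nonsig: float = 0.1
    fdr_domain: float = 0.05
    fdr_pathway: float = 0.01
    snv_pathway_exclusion: float = 0.1
    pseudocount: float = 0.01
    rng_seed: int = 0
    hypermutation_cap: int | None = None
    #: use information weights I(i); if False every scored column weighs 1
    use_info_weights: bool = True
    #: score refinement members leave-one-out instead of against the full set
    refine_leave_one_out: bool = False
    #: (k+1)/(N+1) smoothing for empirical p-values (default: plain fraction)
    smooth_empirical_p: bool = False
    #: display threshold for domain reporting (>= this many pSNVs)
    domain_display_min_psnvs: int = 25

    def __post_init__(self) -> None:
        if not (self.flank_width >= self.proximal_width >= 0):
            raise ValueError(
                "flank_width >= proximal_width >= 0 required, got "
                f"{self.flank_width} / {self.proximal_width}"
            )
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.p_ref_sig >= self.p_mut_nonsig:
            warnings.warn(
                "p_ref_sig >= p_mut_nonsig: loss and gain regions may overlap",
                stacklevel=2,
            )


DEFAULT_CONFIG = RunConfig()
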
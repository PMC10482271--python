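"""Central container for every numeric threshold used by the analyses.

Keeping the thresholds in one frozen dataclass makes every cutoff auditable
and lets a user rerun the whole pipeline under alternative settings without
touching analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable thresholds of the N-terminome analyses.

    Attributes
    ----------
    hgt_screen_min
        Minimum signed HGT score for a (GO term, residue) pair to be
        retained by the GO scan (strict ``>``).
    fold_change_min
        Minimum position-2 fold change (subset frequency / proteome
        frequency) for a screened GO term to survive the generic-term
        filter (inclusive ``>=``).
    bestN_overlap_max
        Maximum pairwise protein-set overlap (|A∩B| / |smaller|) tolerated
        between selected BestN GO terms.
    bestF_containment_min
        Minimum containment (|F∩B| / |F|) of a BestF candidate inside its
        parent BestN term.
    bestF_overlap_max
        Maximum overlap tolerated between accepted BestF terms.
    bestF_bias_gain
        A BestF candidate must improve on its parent's best fold change by
        at least this multiplicative factor.
    aspecificity_window
        Length (in positions) of the sliding window of the aspecificity
        score.
    aspecificity_span
        Number of leading proteome positions scanned by the aspecificity
        windows.
    sweep_min, sweep_max, sweep_step
        Enrichment-threshold grid of the sel-TRAP threshold sweep
        (log2 units).
    target_threshold
        Mean corrected log2 enrichment above which a gene is called a
        putative co-translational target (inclusive ``>=``).
    mascot_cutoff
        Minimum Mascot score in the tagged immunoprecipitation for a
        protein partner to be considered (strict ``>``); also the maximum
        tolerated score in the untagged control (inclusive ``<=``).
    mascot_ratio_min
        Minimum tagged/control Mascot score ratio.
    mascot_specificity_fold
        Fold difference in Mascot score over every other bait required to
        call a partner bait-specific.
    dedup_prefix_len
        N-terminal prefix length used to collapse proteins sharing the
        same N-terminus into one identifier.
    """

    hgt_screen_min: float = 4.0
    fold_change_min: float = 1.8
    bestN_overlap_max: float = 0.40
    bestF_containment_min: float = 0.40
    bestF_overlap_max: float = 0.30
    bestF_bias_gain: float = 1.30
    aspecificity_window: int = 100
    aspecificity_span: int = 500
    sweep_min: float = -3.0
    sweep_max: float = 4.0
    sweep_step: float = 0.1
    target_threshold: float = 0.8
    mascot_cutoff: float = 250.0
    mascot_ratio_min: float = 2.0
    mascot_specificity_fold: float = 5.0
    dedup_prefix_len: int = 10

    def __post_init__(self) -> None:
        positive = (
            "hgt_screen_min", "fold_change_min", "bestF_bias_gain",
            "aspecificity_window", "aspecificity_span", "sweep_step",
            "target_threshold", "mascot_cutoff", "mascot_ratio_min",
            "mascot_specificity_fold", "dedup_prefix_len",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("bestN_overlap_max", "bestF_containment_min",
                     "bestF_overlap_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.sweep_min >= self.sweep_max:
            raise ValueError("sweep_min must be below sweep_max")
        if self.aspecificity_window > self.aspecificity_span:
            raise ValueError("aspecificity_window exceeds aspecificity_span")


DEFAULT_CONFIG = AnalysisConfig()
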
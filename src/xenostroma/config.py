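"""Pipeline configuration.

Every tunable of the analysis lives here with its default, so a run is fully
specified by one small YAML-compatible file plus a seed.  The config hash is
stamped into every output table, which makes outputs traceable to the exact
parameter set that produced them.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

log = logging.getLogger("xenostroma")


def _child_seed(seed: int, offset: int) -> int:
    """Expand one global seed into a per-stage seed by a fixed offset."""
    return (int(seed) + 1_000_003 * offset) % (2**31 - 1)


# fixed offsets per pipeline stage: stage-level reproducibility
STAGE_OFFSETS = {
    "references": 1,
    "counts": 2,
    "reads": 3,
    "proteomics": 4,
    "cohort": 5,
    "maxstat": 6,
}


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their defaults.

    Attributes
    ----------
    seed : global seed; per-stage seeds derive from it by fixed offsets.
    k : k-mer length for species classification (nt).
    min_specific : species-specific k-mer hits required to assign a read.
    cpm_log2_threshold, max_low_samples : low-expression filter; a gene is
        removed when log2(CPM+1) falls below the threshold in more than
        ``max_low_samples`` samples.
    de_fdr, de_fold : significance filter (strict FDR < de_fdr and fold
        change > de_fold).
    zfpkm_threshold : expressed-gene call threshold on the zFPKM scale.
    top_n_variable : genes kept for PCA / heatmap-style summaries.
    gsva_kernel, gsva_tau, gsva_mode : single-sample scoring parameters.
    max_missed, min_len, min_unique : tryptic digestion and protein filter.
    prior_df : prior degrees of freedom for quasi-dispersion moderation.
    minprop, n_perm : maximally-selected-rank cutpoint parameters.
    c4_baseline : cross-model contrast for C4, "castrated" or "intact".
    """

    seed: int = 0
    # species assignment
    k: int = 21
    min_specific: int = 2
    # expression filtering / DE
    cpm_log2_threshold: float = 1.0
    max_low_samples: int = 3
    de_fdr: float = 0.05
    de_fold: float = 2.0
    zfpkm_threshold: float = -3.0
    top_n_variable: int = 500
    prior_df: float = 10.0
    pca_scale: bool = False
    # set scoring
    gsva_kernel: str = "gaussian"
    gsva_tau: float = 1.0
    gsva_mode: str = "max_diff"
    # proteomics
    max_missed: int = 2
    min_len: int = 7
    min_unique: int = 2
    il_equivalent: bool = False
    # survival
    minprop: float = 0.1
    n_perm: int = 10000
    maxstat_pmethod: str = "permutation"
    cox_ties: str = "breslow"
    # signatures
    c4_baseline: str = "castrated"

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k-mer length must be >= 8")
        if self.min_specific < 1:
            raise ValueError("min_specific must be >= 1")
        if not (0 < self.de_fdr < 1):
            raise ValueError("de_fdr must lie in (0, 1)")
        if self.de_fold < 1:
            raise ValueError("de_fold must be >= 1")
        if self.cpm_log2_threshold < 0 or self.max_low_samples < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.gsva_kernel not in ("gaussian", "poisson"):
            raise ValueError("gsva_kernel must be 'gaussian' or 'poisson'")
        if self.gsva_mode not in ("max_diff",):
            raise ValueError("only max_diff scoring is supported")
        if not (0 < self.minprop < 0.5):
            raise ValueError("minprop must lie in (0, 0.5)")
        if self.c4_baseline not in ("castrated", "intact"):
            raise ValueError("c4_baseline must be 'castrated' or 'intact'")
        if self.maxstat_pmethod not in ("permutation", "approx"):
            raise ValueError("maxstat_pmethod must be 'permutation' or 'approx'")
        if self.cox_ties not in ("breslow", "efron"):
            raise ValueError("cox_ties must be 'breslow' or 'efron'")

    # -- serialization ----------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        return _child_seed(self.seed, STAGE_OFFSETS[stage])

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
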
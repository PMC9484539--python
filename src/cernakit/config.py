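"""Analysis thresholds and simulation configuration.

``Thresholds`` collects every numeric cut used across the pipeline in
one place: the expression filter (count > 5 in at least 20% of
samples), the dysregulation cuts for tumorigenesis (adjusted p < 0.1)
and subclass (adjusted p < 0.25) contrasts with fold change > 2, the
miRNA–target anti-correlation cut (PCC at or below −0.4), and the
three ceRNA-network criteria (hypergeometric p < 1e-6, sponge–mRNA
PCC > 0.6, shared miRNAs > 4). Inequality strictness follows the
printed signs; only the −0.4 miRNA–target cut is inclusive ("threshold
at −0.4") and its boundary behavior is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class Thresholds:
    min_count: int = 5
    min_sample_frac: float = 0.2
    padj_tumorigenesis: float = 0.1
    padj_subclass: float = 0.25
    fdr_prognosis: float = 0.05
    fc: float = 2.0
    pcc_mirna_target: float = -0.4
    #: True: retain PCC == pcc_mirna_target (inclusive boundary)
    pcc_mirna_target_inclusive: bool = True
    pcc_cerna_mrna: float = 0.6
    min_shared_mirnas: int = 4  # strict: edges need k > this
    hypergeom_p: float = 1e-6
    pcc_cis_pair: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_sample_frac <= 1.0:
            raise ValueError("min_sample_frac must be in [0, 1]")
        for name in ("padj_tumorigenesis", "padj_subclass", "fdr_prognosis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fc <= 1.0:
            raise ValueError("fc must be > 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        return cls(**d)


#: sponge-module coupling presets (latent-factor loading, log2 units)
SPONGE_EFFECT_LOW = 0.4
SPONGE_EFFECT_DEFAULT = 0.8
SPONGE_EFFECT_HIGH = 1.2


def _default_features() -> dict:
    return {"mRNA": 1000, "lncRNA": 300, "circRNA": 150, "miRNA": 600}


def _default_subclasses() -> dict:
    return {"S1": 3, "S2": 3, "S3": 2}


@dataclass
class SimulationConfig:
    """Ground-truth cohort generator settings.

    Defaults emulate the study design the pipeline targets: a small
    paired tumor/normal cohort (8 pairs), negative-binomial counts with
    moderate over-dispersion, a minority of features carrying a planted
    4-fold shift, sponge modules coupling one lncRNA/circRNA, several
    miRNAs and one mRNA through a shared per-sample latent factor,
    signed subclass templates, and Weibull survival times whose hazard
    is log-linear in a planted prognostic score.
    """

    n_pairs: int = 8
    n_features_by_biotype: dict = field(default_factory=_default_features)
    de_fraction: float = 0.1
    log2fc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    n_sponge_triplets: int = 10
    mirnas_per_triplet: int = 6
    sponge_effect: float = SPONGE_EFFECT_DEFAULT
    subclass_sizes: dict = field(default_factory=_default_subclasses)
    n_signature_genes: int = 30
    subclass_shift: float = 2.0
    n_prognostic: int = 5
    prognostic_coef: float = 1.0
    survival_baseline_scale: float = 60.0
    survival_shape: float = 1.5
    survival_effect: float = 0.7
    censor_rate: float = 0.3
    size_factor_sigma: float = 0.2
    base_log2_mu_range: tuple = (5.0, 9.0)
    # annotation / sequence substrate
    n_junctions: int = 200
    origin_proportions: tuple = (0.8582, 0.0718, 0.07)  # exonic, intronic, intergenic
    mirna_length: int = 22
    target_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for bt, n in self.n_features_by_biotype.items():
            if n < 0:
                raise ValueError(f"negative feature count for {bt}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
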
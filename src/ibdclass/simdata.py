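"""Synthetic four-class mucosal RNA-seq count matrices with ground truth.

The generator emulates the statistical structure the two-stage analysis
assumes: a cohort split into CD-inflamed / CD-normal / UC-inflamed /
UC-normal classes (default sizes 29/65/20/13), a dominant inflammation
expression axis, a weaker disease axis confined to inflamed tissue, and a
normal-tissue gut-segment confound (terminal ileum vs rectum) confined to
normal tissue. Counts are negative-binomial (Gamma-Poisson) with a shared
dispersion phi, variance mu + phi * mu^2, and log-normal per-sample library
size factors applied multiplicatively to the means.

Three disjoint planted gene sets carry the signal:

* inflammation genes — shifted equally (half up, half down) in both
  inflamed classes relative to normal tissue;
* disease genes — differ between CD-inflamed and UC-inflamed only;
* segment genes — differ between CD-normal and UC-normal only, emulating
  the biopsy-site confound that the pruning stage is designed to remove.

Segment effects default to a *graded* magnitude profile (geometric decay
across the set): inter-segment expression differences in real gut tissue
span much of the transcriptome with a heavy-tailed magnitude distribution,
and it is exactly this spread that makes progressively deeper pruning
progressively more harmful to the normal-tissue classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "GroundTruth", "simulate_counts"]

CLASSES = ("CD_inflamed", "CD_normal", "UC_inflamed", "UC_normal")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Class sizes default to the study design (29/65/20/13); the gene
    universe defaults to 2000 (a desk-scale stand-in for the ~19.6k
    protein-coding genes). Effects are log2 fold changes between the two
    classes a set distinguishes; ``nb_dispersion`` is the negative-binomial
    phi with variance mu + phi mu^2.
    """

    n_cd_inflamed: int = 29
    n_cd_normal: int = 65
    n_uc_inflamed: int = 20
    n_uc_normal: int = 13
    n_genes: int = 2000
    n_inflammation_genes: int = 300
    n_disease_genes: int = 20
    n_segment_genes: int = 1000
    effect_log2fc_inflammation: float = 2.0
    effect_log2fc_disease: float = 1.5
    effect_log2fc_segment: float = 1.5
    effect_profile_inflammation: str = "constant"
    effect_profile_disease: str = "constant"
    effect_profile_segment: str = "graded"
    graded_floor: float = 0.05
    nb_dispersion: float = 0.1
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.3
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        sizes = {
            "n_cd_inflamed": self.n_cd_inflamed,
            "n_cd_normal": self.n_cd_normal,
            "n_uc_inflamed": self.n_uc_inflamed,
            "n_uc_normal": self.n_uc_normal,
        }
        for name, v in sizes.items():
            if v < 2:
                raise ValueError(f"invariant violated: class size {name} must be >= 2, got {v}")
        n_planted = self.n_inflammation_genes + self.n_disease_genes + self.n_segment_genes
        if min(self.n_inflammation_genes, self.n_disease_genes, self.n_segment_genes) < 0:
            raise ValueError("invariant violated: planted gene-set sizes must be non-negative")
        if n_planted > self.n_genes:
            raise ValueError(
                "invariant violated: planted gene-set sizes sum to "
                f"{n_planted} > n_genes = {self.n_genes}"
            )
        for name in ("inflammation", "disease", "segment"):
            eff = getattr(self, f"effect_log2fc_{name}")
            if eff < 0:
                raise ValueError(f"invariant violated: effect_log2fc_{name} must be >= 0")
            prof = getattr(self, f"effect_profile_{name}")
            if prof not in ("constant", "graded"):
                raise ValueError(
                    f"invariant violated: effect_profile_{name} must be "
                    f"'constant' or 'graded', got {prof!r}"
                )
        if self.nb_dispersion <= 0:
            raise ValueError("invariant violated: nb_dispersion must be > 0")
        if not (0 < self.graded_floor <= 1):
            raise ValueError("invariant violated: graded_floor must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_cd_inflamed + self.n_cd_normal + self.n_uc_inflamed + self.n_uc_normal

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Read a config from a YAML or JSON file (unknown keys rejected)."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class GroundTruth:
    """Planted gene sets and the per-gene per-class expected log2 mean."""

    inflammation_genes: list
    disease_genes: list
    segment_genes: list
    expected_log2_mean: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "inflammation_genes": list(self.inflammation_genes),
            "disease_genes": list(self.disease_genes),
            "segment_genes": list(self.segment_genes),
            "expected_log2_mean": {
                "gene_ids": list(self.expected_log2_mean.index),
                "classes": list(self.expected_log2_mean.columns),
                "values": self.expected_log2_mean.to_numpy().tolist(),
            },
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def _signed_magnitudes(
    n: int, effect: float, profile: str, floor: float
) -> np.ndarray:
    """Per-gene signed log2 effects: half up / half down, constant or graded."""
    if n == 0:
        return np.zeros(0)
    if profile == "constant" or n == 1:
        mag = np.full(n, effect)
    else:
        mag = np.geomspace(effect, effect * floor, n) if effect > 0 else np.zeros(n)
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)  # alternate: sign ⟂ magnitude
    return signs * mag


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a genes x samples count matrix, sample metadata and ground truth.

    Counts for gene g in a sample of class c are negative binomial with
    mean ``2**(baseline_g + effect_gc) * s_j`` (s_j the sample's library
    size factor) and dispersion ``nb_dispersion``. Identical config (seed
    included) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    sizes = {
        "CD_inflamed": config.n_cd_inflamed,
        "CD_normal": config.n_cd_normal,
        "UC_inflamed": config.n_uc_inflamed,
        "UC_normal": config.n_uc_normal,
    }
    class_of_sample = np.concatenate(
        [np.full(sizes[c], i) for i, c in enumerate(CLASSES)]
    )
    n_samples = class_of_sample.size
    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)

    n_inf, n_dis, n_seg = (
        config.n_inflammation_genes,
        config.n_disease_genes,
        config.n_segment_genes,
    )
    planted = rng.choice(n_genes, size=n_inf + n_dis + n_seg, replace=False)
    inf_idx = planted[:n_inf]
    dis_idx = planted[n_inf : n_inf + n_dis]
    seg_idx = planted[n_inf + n_dis :]

    delta = np.zeros((n_genes, 4))  # log2 offsets per class, columns follow CLASSES
    d_inf = _signed_magnitudes(
        n_inf, config.effect_log2fc_inflammation, config.effect_profile_inflammation,
        config.graded_floor,
    )
    delta[inf_idx, 0] += d_inf  # CD_inflamed
    delta[inf_idx, 2] += d_inf  # UC_inflamed
    d_dis = _signed_magnitudes(
        n_dis, config.effect_log2fc_disease, config.effect_profile_disease,
        config.graded_floor,
    )
    delta[dis_idx, 0] += d_dis / 2.0
    delta[dis_idx, 2] -= d_dis / 2.0
    d_seg = _signed_magnitudes(
        n_seg, config.effect_log2fc_segment, config.effect_profile_segment,
        config.graded_floor,
    )
    delta[seg_idx, 1] += d_seg / 2.0  # CD_normal (terminal ileum)
    delta[seg_idx, 3] -= d_seg / 2.0  # UC_normal (rectum)

    expected_log2 = baseline[:, None] + delta

    size_factor = np.exp(rng.normal(config.libsize_log_mean, config.libsize_log_sd, n_samples))
    mu = np.exp2(expected_log2)[:, class_of_sample] * size_factor
    phi = config.nb_dispersion
    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "disease": [CLASSES[c].split("_")[0] for c in class_of_sample],
            "status": [CLASSES[c].split("_")[1] for c in class_of_sample],
        }
    )
    gene_arr = np.asarray(gene_ids, dtype=object)
    truth = GroundTruth(
        inflammation_genes=sorted(gene_arr[inf_idx]),
        disease_genes=sorted(gene_arr[dis_idx]),
        segment_genes=sorted(gene_arr[seg_idx]),
        expected_log2_mean=pd.DataFrame(
            expected_log2, index=gene_ids, columns=list(CLASSES)
        ),
    )
    return counts_df, meta, truth
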
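"""Preset generator configurations.

``paper_scale()`` returns the eight (genotype x age) group configurations
matching the published striatal medium-spiny-neuron dataset this pipeline
was built around: WT and A53T-BAC-SNCA mice at 1, 3, 6 and 22 months, with
the printed per-group dendrite counts, dendrite lengths, spine densities,
head-volume mean/median pairs, neck lengths and perforation percentages.
Dendrite-length and neck-length spreads are recovered from the printed SEMs
(sd = SEM * sqrt(n)).
"""

from __future__ import annotations

import math

from .synthetic import SynthGroupConfig

# (genotype, age_months, n_dendrites,
#  dendrite_length_mean, dendrite_length_sem,
#  spine_density, head_volume_mean, head_volume_median,
#  neck_length_mean, neck_length_sem, n_neck_spines, perforated_pct)
_PAPER_GROUPS = [
    ("WT",   1,  7,  9.2, 0.61, 2.0, 0.050, 0.027, 1.00, 0.045, 132,  1.52),
    ("WT",   3,  8, 12.4, 0.52, 1.8, 0.074, 0.041, 1.13, 0.043, 176,  4.52),
    ("WT",   6,  7, 11.8, 0.85, 1.3, 0.084, 0.045, 0.98, 0.054, 108,  6.42),
    ("WT",  22, 11, 13.4, 0.83, 1.1, 0.143, 0.047, 1.03, 0.043, 156, 21.15),
    ("A53T",  1,  7,  8.7, 0.75, 2.5, 0.077, 0.042, 1.14, 0.047, 148,  2.70),
    ("A53T",  3,  8, 13.8, 1.20, 2.4, 0.089, 0.032, 1.11, 0.036, 249,  9.96),
    ("A53T",  6,  7, 11.0, 0.72, 2.0, 0.088, 0.028, 1.21, 0.052, 149,  5.96),
    ("A53T", 22, 10, 11.7, 1.49, 1.4, 0.089, 0.030, 1.11, 0.045, 159,  9.94),
]


def paper_scale(
    section_thickness_nm: float = 50.0, pixel_size_nm: float = 4.5
) -> list[SynthGroupConfig]:
    """The eight study-scale group configurations (65 dendrites in total)."""
    configs = []
    for (geno, age, n_d, len_mean, len_sem, dens, v_mean, v_median,
         neck_mean, neck_sem, n_neck, _perf_pct) in _PAPER_GROUPS:
        configs.append(
            SynthGroupConfig(
                genotype=geno,
                age_months=age,
                n_dendrites=n_d,
                dendrite_length_mean=len_mean,
                dendrite_length_sd=len_sem * math.sqrt(n_d),
                spine_density=dens,
                head_volume_mean=v_mean,
                head_volume_median=v_median,
                neck_length_mean=neck_mean,
                neck_length_sd=neck_sem * math.sqrt(n_neck),
                perforation_prob=_perf_pct / 100.0,
                section_thickness_nm=section_thickness_nm,
                pixel_size_nm=pixel_size_nm,
            )
        )
    return configs


def tiny_preset(
    n_dendrites: int = 2, dendrite_length_mean: float = 6.0
) -> list[SynthGroupConfig]:
    """A small two-group preset for quick runs and tests."""
    base = dict(
        dendrite_length_mean=dendrite_length_mean,
        dendrite_length_sd=0.5,
        n_dendrites=n_dendrites,
        head_volume_mean=0.074,
        head_volume_median=0.041,
        neck_length_mean=1.0,
        neck_length_sd=0.5,
        perforation_prob=0.1,
    )
    return [
        SynthGroupConfig(genotype="WT", age_months=3, spine_density=1.8, **base),
        SynthGroupConfig(genotype="A53T", age_months=3, spine_density=2.4, **base),
    ]
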
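# spinemorph

Serial-section dendritic spine morphometry and group statistics.

Dendritic spines — the micron-scale protrusions that receive most excitatory
synaptic input — are routinely quantified from serial-section electron
microscopy (FIB/SEM) by manually tracing dendrite shafts, spine heads, spine
necks and postsynaptic densities (PSDs) on each section. `spinemorph` turns
such contour stacks into the standard morphometric battery used in
ultrastructural aging and disease studies (e.g. striatal medium spiny
neurons in α-synuclein mouse models of prodromal Parkinson's disease):

* **head volume** `V = Σ_k A_k · t` — per-section contour area times section
  thickness `t` (rectangle rule);
* **surface area** `S = Σ_k P_k · t + A_first + A_last` — perimeter times
  thickness plus end caps;
* **PSD area** `A_PSD = t · Σ_k L_k` — thickness times the summed length of
  the open PSD traces;
* **neck length** and **dendrite length** — 3D polyline lengths (shaft
  length through per-section contour centroids);
* **spine density** — spines per µm of dendrite length;
* **small/large (thin/mushroom) classification** by a head-volume cutoff
  (default 0.04 µm³, ties → small), binned head-volume distributions,
  **perforated vs macular PSD** detection from trace topology, relative
  frequencies and fold changes;
* **group statistics** with the normality-gated battery: Shapiro–Wilk gate,
  Student's t / Mann–Whitney U for two groups, one-way ANOVA /
  Kruskal–Wallis with Bonferroni-adjusted pairwise follow-up (t tests /
  Dunn rank tests) for three or more, two-sample Kolmogorov–Smirnov for
  distribution shape, Spearman rank correlation for the PSD–volume coupling.

Because raw segmentations are rarely deposited, the package includes a
**synthetic serial-section generator**: tortuous tube dendrites carrying
spherical spine heads (lognormal volumes matched to printed group
mean/median pairs), cylindrical necks, and spherical-cap PSDs (annular when
perforated) coupled to head volume — sliced into the same trace format the
measurement code consumes. Every sampled quantity is recorded as ground
truth, so parameter recovery through the full pipeline is testable end to
end.

## Worked example

```python
from spinemorph import generate_group, measure_series, summarize_metric, spearman_corr
from spinemorph.presets import tiny_preset

cfg = tiny_preset(n_dendrites=3, dendrite_length_mean=7.0)[0]
truth, series, manifest = generate_group(cfg, seed=7)

spines, dendrites = [], []
for metadata, contours, hierarchy in series:
    m = measure_series(metadata, contours, hierarchy)
    spines += m.spines
    dendrites += m.dendrites

print(summarize_metric([s.head_volume for s in spines], "WT", 3, "head volume (um3)"))
print(summarize_metric([d.spine_density for d in dendrites], "WT", 3, "spine density (/um)"))
res = spearman_corr([s.head_volume for s in spines], [s.psd_area for s in spines])
print(f"PSD area vs head volume: Spearman r = {res.statistic:.3f}, p = {res.p_value:.2e}")
```

prints

```
head volume (um3) [WT 3 mo]: 0.0383 ± 0.0055 (median = 0.0287, range = 0.00755–0.179, n = 41)
spine density (/um) [WT 3 mo]: 2.01 ± 0.36 (median = 2.32, range = 1.29–2.42, n = 3)
PSD area vs head volume: Spearman r = 0.919, p = 2.37e-17
```

Three 7-µm dendrites generated at 1.8 spines/µm yield 41 measured spines at
2.01 spines/µm; the measured head volumes reproduce the configured
right-skewed distribution (mean well above median), and the PSD–volume
coupling built into the generator comes back as a strong positive rank
correlation.

The same flow from a shell, over the full eight-group study-scale preset
(65 dendrites, WT and A53T-BAC-SNCA at 1/3/6/22 months):

```sh
spinemorph all --preset paper_scale --seed 1 --out results/
```

which writes `spines.csv`, `dendrites.csv`, `frequency_tables.csv`,
`histogram.csv`, `stats_report.json` and a human-readable `summary.txt`
("mean ± SEM (median, range)" per group, plus small/large/perforated
percentages and perforation fold changes). `spinemorph generate`,
`spinemorph measure` and `spinemorph analyze` run the individual stages.

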
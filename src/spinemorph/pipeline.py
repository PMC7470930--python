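"""End-to-end orchestration: generate/load -> measure -> classify -> test.

The pipeline mirrors the structure of a serial-section spine-morphometry
study: per-dendrite spine densities, per-spine head volumes, neck lengths
and PSD areas are summarized per (genotype, age) group; ages are compared
within genotype by the normality-gated omnibus battery; genotypes are
compared per age by the gated two-sample test; large-spine head-volume
distributions are compared across ages by Kolmogorov–Smirnov; and the
PSD-area/head-volume coupling is tested per group by Spearman rank
correlation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as gstats
from .classify import FrequencyTable, bin_volumes, fold_change, frequency_table
from .geometry import MorphometryConfig, measure_series
from .synthetic import generate_dataset
from .trace_io import dendrite_table, load_series, spine_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_dir: Optional[Path] = None     # directory of series files + manifest
    preset: Optional[str] = None         # generator preset name (alternative)
    out_dir: Path = Path("results")
    size_cutoff: float = 0.04            # µm³
    bin_width: float = 0.04              # µm³
    alpha: float = 0.05
    boundary_policy: str = "exclude_touching"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.size_cutoff <= 0 or self.bin_width <= 0:
            raise ValueError("size_cutoff and bin_width must be > 0")
        if self.input_dir is None and self.preset is None:
            raise ValueError("either input_dir or preset must be given")


def measure_directory(
    in_dir: str | Path, config: Optional[MorphometryConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every series file in a directory.

    Group labels are taken from ``manifest.csv`` when present; otherwise
    every file is assigned to one unlabeled group.  Returns (spines,
    dendrites) data frames in the spines.csv / dendrites.csv layout plus
    genotype / age columns.
    """
    in_dir = Path(in_dir)
    config = config or MorphometryConfig()
    manifest_path = in_dir / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
    else:
        files = sorted(p.name for p in in_dir.glob("*.json"))
        if not files:
            raise FileNotFoundError(f"no series files found in {in_dir}")
        manifest = pd.DataFrame(
            {"file": files, "genotype": "all", "age_months": np.nan}
        )
    spine_frames = []
    dendrite_frames = []
    for row in manifest.itertuples():
        md, contours, hierarchy = load_series(in_dir / row.file)
        m = measure_series(md, contours, hierarchy, config)
        sdf = spine_table(m.spines)
        ddf = dendrite_table(m.dendrites)
        for df in (sdf, ddf):
            df["genotype"] = row.genotype
            df["age_months"] = row.age_months
        spine_frames.append(sdf)
        dendrite_frames.append(ddf)
    spines = pd.concat(spine_frames, ignore_index=True)
    dendrites = pd.concat(dendrite_frames, ignore_index=True)
    if config.boundary_policy == "exclude_touching":
        n_drop = int(spines["touches_boundary"].sum())
        if n_drop:
            logger.info("excluding %d boundary-touching spines", n_drop)
        spines = spines[~spines["touches_boundary"]].reset_index(drop=True)
    return spines, dendrites


def _result_dict(res: gstats.StatResult) -> dict:
    out = {
        "test": res.test_name,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "labels": list(res.labels),
    }
    if res.normal is not None:
        out["normal"] = res.normal
    if res.pairwise:
        out["pairwise"] = [
            {
                "a": pc.label_a, "b": pc.label_b,
                "p_raw": pc.p_raw, "p_adjusted": pc.p_adjusted,
            }
            for pc in res.pairwise
        ]
    return out


def _group_label(genotype: str, age: float) -> str:
    return f"{genotype}_{age:g}mo"


def analyze_tables(
    spines: pd.DataFrame,
    dendrites: pd.DataFrame,
    size_cutoff: float = 0.04,
    bin_width: float = 0.04,
    alpha: float = 0.05,
) -> dict:
    """Run the full statistical battery over measured tables.

    Returns a nested report dict (serializable to stats_report.json) with
    per-group summaries, frequency tables, histograms, omnibus and pairwise
    comparisons, KS distribution tests and Spearman correlations.
    """
    report: dict = {"groups": [], "metrics": {}, "frequencies": [],
                    "histograms": {}, "ks": {}, "spearman": {}}

    group_keys = (
        spines[["genotype", "age_months"]].drop_duplicates()
        .sort_values(["genotype", "age_months"], ascending=[False, True])
        .itertuples(index=False)
    )
    group_keys = [(g.genotype, g.age_months) for g in group_keys]
    report["groups"] = [_group_label(g, a) for g, a in group_keys]

    metric_values: dict[str, dict[tuple, np.ndarray]] = {
        "spine_density_per_um": {}, "head_volume_um3": {},
        "neck_length_um": {}, "psd_area_um2": {},
    }
    tables: list[FrequencyTable] = []
    for geno, age in group_keys:
        s = spines[(spines.genotype == geno) & (spines.age_months == age)]
        d = dendrites[(dendrites.genotype == geno) & (dendrites.age_months == age)]
        metric_values["spine_density_per_um"][(geno, age)] = d[
            "spine_density_per_um"].to_numpy()
        metric_values["head_volume_um3"][(geno, age)] = s["head_volume_um3"].to_numpy()
        metric_values["neck_length_um"][(geno, age)] = s[
            "neck_length_um"].dropna().to_numpy()
        metric_values["psd_area_um2"][(geno, age)] = s["psd_area_um2"].to_numpy()
        if len(s):
            tables.append(
                frequency_table(
                    geno, age, s["head_volume_um3"], s["perforated"], size_cutoff
                )
            )
            hist = bin_volumes(s["head_volume_um3"].to_numpy(), bin_width)
            report["histograms"][_group_label(geno, age)] = {
                "bin_width": bin_width,
                "edges": hist.edges.tolist(),
                "counts": hist.counts.tolist(),
                "frequencies": hist.frequencies.tolist(),
            }

    report["frequencies"] = [
        {
            "group": _group_label(t.genotype, t.age_months),
            "n_total": t.n_total, "n_small": t.n_small, "n_large": t.n_large,
            "n_perforated": t.n_perforated,
            "pct_small": t.pct_small, "pct_large": t.pct_large,
            "pct_perforated": t.pct_perforated,
        }
        for t in tables
    ]

    genotypes = sorted({g for g, _ in group_keys}, reverse=True)
    ages = sorted({a for _, a in group_keys})
    for metric, per_group in metric_values.items():
        entry: dict = {"per_group": {}, "omnibus": {}, "between_genotypes": {}}
        for (geno, age), vals in per_group.items():
            if len(vals):
                entry["per_group"][_group_label(geno, age)] = dataclasses.asdict(
                    gstats.summarize_metric(vals, geno, age, metric)
                )
        for geno in genotypes:
            groups = [per_group[(geno, a)] for a in ages if (geno, a) in per_group]
            labels = [_group_label(geno, a) for a in ages if (geno, a) in per_group]
            usable = [g for g in groups if len(g) >= 3]
            if len(usable) == len(groups) and len(groups) >= 3:
                entry["omnibus"][geno] = _result_dict(
                    gstats.compare_many(groups, labels, alpha_normality=alpha)
                )
        if len(genotypes) == 2:
            for age in ages:
                pair = [(g, age) for g in genotypes if (g, age) in per_group]
                if len(pair) == 2:
                    x, y = (per_group[k] for k in pair)
                    if len(x) >= 3 and len(y) >= 3:
                        entry["between_genotypes"][f"{age:g}mo"] = _result_dict(
                            gstats.compare_two(
                                x, y,
                                labels=(_group_label(*pair[0]), _group_label(*pair[1])),
                                alpha_normality=alpha,
                            )
                        )
        report["metrics"][metric] = entry

    # distribution shift of large-spine head volumes between consecutive ages
    vols = metric_values["head_volume_um3"]
    for geno in genotypes:
        present = [a for a in ages if (geno, a) in vols]
        for a0, a1 in zip(present, present[1:]):
            big0 = vols[(geno, a0)][vols[(geno, a0)] > size_cutoff]
            big1 = vols[(geno, a1)][vols[(geno, a1)] > size_cutoff]
            if len(big0) and len(big1):
                key = f"{geno}_large_{a0:g}mo_vs_{a1:g}mo"
                report["ks"][key] = _result_dict(
                    gstats.ks_two_sample(
                        big0, big1,
                        labels=(_group_label(geno, a0), _group_label(geno, a1)),
                    )
                )

    for geno, age in group_keys:
        s = spines[(spines.genotype == geno) & (spines.age_months == age)]
        if len(s) >= 4 and s["psd_area_um2"].nunique() > 1:
            res = gstats.spearman_corr(
                s["head_volume_um3"], s["psd_area_um2"],
                labels=("head_volume_um3", "psd_area_um2"),
            )
            report["spearman"][_group_label(geno, age)] = {
                "r": res.statistic, "p_value": res.p_value, "n": int(len(s)),
            }
    return report


def report_frequencies(tables: Sequence[FrequencyTable]) -> str:
    """Human-readable frequency table with within-genotype fold changes.

    Percentages are printed to one decimal, fold changes (older vs younger
    age, perforated spines) to two decimals.
    """
    lines = ["group           n    small%  large%  perf%"]
    for t in tables:
        lines.append(
            f"{_group_label(t.genotype, t.age_months):<14} {t.n_total:>4} "
            f"{t.pct_small:>7.1f} {t.pct_large:>7.1f} {t.pct_perforated:>6.2f}"
        )
    by_geno: dict[str, list[FrequencyTable]] = {}
    for t in tables:
        by_geno.setdefault(t.genotype, []).append(t)
    fold_lines = []
    for geno, ts in by_geno.items():
        ts = sorted(ts, key=lambda t: t.age_months)
        for i in range(len(ts)):
            for j in range(i):
                hi, lo = ts[i], ts[j]
                if lo.pct_perforated > 0:
                    f = fold_change(hi.pct_perforated, lo.pct_perforated)
                    fold_lines.append(
                        f"{geno} perforated {hi.age_months:g} vs "
                        f"{lo.age_months:g} mo: {f:.2f}-fold"
                    )
    if len(tables) > 1 and fold_lines:
        lines.append("")
        lines.extend(fold_lines)
    return "\n".join(lines)


def _summary_text(report: dict, spines: pd.DataFrame, dendrites: pd.DataFrame) -> str:
    lines = [
        f"groups analyzed: {len(report['groups'])} "
        f"({', '.join(report['groups'])})",
        f"dendrites: {len(dendrites)}   spines: {len(spines)}",
        "",
    ]
    for metric, entry in report["metrics"].items():
        for label, s in entry["per_group"].items():
            lines.append(
                f"{metric} [{label}]: {s['mean']:.3g} ± {s['sem']:.2g} "
                f"(median = {s['median']:.3g}, range = "
                f"{s['min']:.3g}–{s['max']:.3g}, n = {s['n']})"
            )
        lines.append("")
    return "\n".join(lines)


def run_full_analysis(config: RunConfig) -> dict:
    """Run generate (optional) -> measure -> classify -> test -> report.

    Writes spines.csv, dendrites.csv, frequency_tables.csv, histogram.csv,
    stats_report.json and summary.txt into the output directory and returns
    the stats report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        in_dir = Path(config.input_dir)
    else:
        from . import presets

        if not hasattr(presets, config.preset):
            raise ValueError(f"unknown preset {config.preset!r}")
        in_dir = out / "traces"
        generate_dataset(getattr(presets, config.preset)(), config.seed, in_dir)

    morpho = MorphometryConfig(
        size_cutoff=config.size_cutoff, boundary_policy=config.boundary_policy
    )
    spines, dendrites = measure_directory(in_dir, morpho)
    spines.to_csv(out / "spines.csv", index=False, float_format="%.8g")
    dendrites.to_csv(out / "dendrites.csv", index=False, float_format="%.8g")

    report = analyze_tables(
        spines, dendrites,
        size_cutoff=config.size_cutoff, bin_width=config.bin_width,
        alpha=config.alpha,
    )
    report["run"] = {
        "seed": config.seed,
        "size_cutoff": config.size_cutoff,
        "bin_width": config.bin_width,
        "alpha": config.alpha,
        "boundary_policy": config.boundary_policy,
        "n_dendrites": int(len(dendrites)),
        "n_spines": int(len(spines)),
    }
    pd.DataFrame(report["frequencies"]).to_csv(
        out / "frequency_tables.csv", index=False
    )
    hist_rows = []
    for label, h in report["histograms"].items():
        for k, freq in enumerate(h["frequencies"]):
            hist_rows.append(
                {
                    "group": label,
                    "bin_left": h["edges"][k], "bin_right": h["edges"][k + 1],
                    "count": h["counts"][k], "frequency": freq,
                }
            )
    pd.DataFrame(hist_rows).to_csv(out / "histogram.csv", index=False)
    with open(out / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=1)

    tables = [
        FrequencyTable(
            genotype=f["group"].rsplit("_", 1)[0],
            age_months=float(f["group"].rsplit("_", 1)[1].removesuffix("mo")),
            n_total=f["n_total"], n_small=f["n_small"], n_large=f["n_large"],
            n_perforated=f["n_perforated"],
        )
        for f in report["frequencies"]
    ]
    summary = _summary_text(report, spines, dendrites)
    summary += "\n" + report_frequencies(tables) + "\n"
    (out / "summary.txt").write_text(summary)
    logger.info("analysis complete: %d dendrites, %d spines", len(dendrites), len(spines))
    return report
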
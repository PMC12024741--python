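"""Study-level orchestration: config parsing and the full report bundle.

A study config (YAML) names samples with group labels, the comparisons to
run, and analysis options.  ``run_study`` computes per-sample metrics, size
bins, pooled trend fits, damage profiles/summaries and the configured group
comparisons, writing deterministic TSVs plus a JSON manifest with per-file
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import yaml

from . import alignment_io, damage, group_stats, qc_metrics

logger = logging.getLogger("endoqc.study")

METRIC_SOURCES = ("r_m", "r_m0", "a_l", "n_db", "r_dm")


@dataclass(slots=True)
class SampleSpec:
    sample_id: str
    path: str
    groups: dict[str, str] = field(default_factory=dict)
    pair_id: str | None = None


@dataclass(slots=True)
class ComparisonSpec:
    label: str
    variable: str
    metric: str
    paired: bool = False
    levels: tuple[str, str] | None = None  # explicit level pair, else first two seen


@dataclass(slots=True)
class StudyOptions:
    seed: int = 0
    damage_window: int = 25
    bin_step: int = 10
    min_reads: int = 100
    alpha: float = 0.05
    multi_def: str = "mapq0"
    a_l_scope: str = "all"
    count_duplicates: bool = True


@dataclass(slots=True)
class StudyConfig:
    samples: list[SampleSpec]
    comparisons: list[ComparisonSpec]
    options: StudyOptions = field(default_factory=StudyOptions)
    reference: str | None = None
    base_dir: str = "."

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample_ids must be unique")
        for comp in self.comparisons:
            if comp.metric not in METRIC_SOURCES:
                raise ValueError(f"unknown comparison metric: {comp.metric!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "StudyConfig":
        path = os.fspath(path)
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "samples" not in doc:
            raise ValueError(f"{path}: not a study config (missing 'samples')")
        samples = [
            SampleSpec(
                sample_id=e["sample_id"],
                path=e["path"],
                groups=dict(e.get("groups", {})),
                pair_id=e.get("pair_id"),
            )
            for e in doc["samples"]
        ]
        comparisons = [
            ComparisonSpec(
                label=e["label"],
                variable=e["variable"],
                metric=e["metric"],
                paired=bool(e.get("paired", False)),
                levels=tuple(e["levels"]) if e.get("levels") else None,
            )
            for e in doc.get("comparisons", [])
        ]
        opts = StudyOptions(**doc.get("options", {}))
        return cls(
            samples=samples,
            comparisons=comparisons,
            options=opts,
            reference=doc.get("reference"),
            base_dir=os.path.dirname(path) or ".",
        )


def _resolve(base_dir: str, path: str) -> str:
    return path if os.path.isabs(path) else os.path.join(base_dir, path)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_study(config: StudyConfig, out_dir: str | os.PathLike, force: bool = False) -> dict:
    """Run the full per-sample + comparison workflow; return the manifest."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    opts = config.options

    for spec in config.samples:
        p = _resolve(config.base_dir, spec.path)
        if not os.path.exists(p):
            raise FileNotFoundError(f"sample {spec.sample_id!r}: alignment file not found: {p}")

    reference = None
    if config.reference:
        reference = alignment_io.read_reference(_resolve(config.base_dir, config.reference))

    metric_rows = []
    bin_rows = []
    profile_rows = []
    summary_rows = []
    sample_values: dict[str, dict[str, float | None]] = {}
    pooled_bins: list[qc_metrics.SizeBin] = []

    for spec in config.samples:
        path = _resolve(config.base_dir, spec.path)
        records = list(alignment_io.read_alignments(path))
        metrics = qc_metrics.compute_sample_metrics(
            records,
            sample_id=spec.sample_id,
            count_duplicates=opts.count_duplicates,
            multi_def=opts.multi_def,
            a_l_scope=opts.a_l_scope,
        )
        metric_rows.append(
            {
                "sample_id": metrics.sample_id,
                "n_total": metrics.n_total,
                "n_mapped": metrics.n_mapped,
                "n_multi": metrics.n_multi,
                "R_m": metrics.r_m,
                "R_m0": metrics.r_m0,
                "A_L": metrics.a_l,
            }
        )
        if metrics.r_m0 is None:
            logger.warning("sample %s: R_m0 undefined (no mapped reads)", spec.sample_id)

        bins = qc_metrics.bin_by_read_size(
            records,
            step=opts.bin_step,
            min_reads=opts.min_reads,
            count_duplicates=opts.count_duplicates,
            multi_def=opts.multi_def,
        )
        pooled_bins.extend(bins)
        n_excluded = sum(not b.included_in_fit for b in bins)
        if n_excluded:
            logger.warning("sample %s: %d size bins below min_reads", spec.sample_id, n_excluded)
        for b in bins:
            bin_rows.append(
                {
                    "sample_id": spec.sample_id,
                    "lower": b.lower,
                    "upper": b.upper,
                    "midpoint": b.midpoint,
                    "n_total": b.n_total,
                    "n_mapped": b.n_mapped,
                    "n_multi": b.n_multi,
                    "R_m": b.r_m,
                    "R_m0": b.r_m0,
                    "included_in_fit": b.included_in_fit,
                }
            )

        values: dict[str, float | None] = {
            "r_m": metrics.r_m,
            "r_m0": metrics.r_m0,
            "a_l": metrics.a_l,
            "n_db": None,
            "r_dm": None,
        }
        mapped = [r for r in records if r.is_mapped and r.is_primary]
        if mapped:
            for end in damage.ENDS:
                profile = damage.compute_damage_profile(
                    mapped,
                    end=end,
                    window=opts.damage_window,
                    reference=reference,
                    count_duplicates=opts.count_duplicates,
                )
                try:
                    summary = damage.summarize_damage(profile)
                except ValueError:
                    logger.warning("sample %s: %s damage summary undefined", spec.sample_id, end)
                    continue
                for i, (rc, dc, rate) in enumerate(
                    zip(profile.ref_base_count, profile.damage_count, profile.rates), start=1
                ):
                    profile_rows.append(
                        {
                            "sample_id": spec.sample_id,
                            "end": end,
                            "substitution": profile.substitution,
                            "position": i,
                            "ref_base_count": rc,
                            "damage_count": dc,
                            "rate": rate if not math.isnan(rate) else None,
                        }
                    )
                summary_rows.append(
                    {
                        "sample_id": spec.sample_id,
                        "end": end,
                        "N_db": summary.n_db,
                        "R_dm": summary.r_dm,
                        "window_mean": summary.window_mean,
                    }
                )
                if end == damage.THREE_PRIME:
                    values["n_db"] = float(summary.n_db)
                    values["r_dm"] = summary.r_dm
        sample_values[spec.sample_id] = values

    trend_rows = []
    for response in ("r_m", "r_m0"):
        try:
            fit = qc_metrics.fit_size_trend(pooled_bins, response=response)
        except ValueError as exc:
            logger.warning("size trend for %s skipped: %s", response, exc)
            continue
        trend_rows.append(
            {
                "response": fit.response,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n_points": fit.n_points,
            }
        )

    comparison_rows = []
    for comp in config.comparisons:
        row = _run_comparison(comp, config.samples, sample_values, opts.alpha)
        if row is not None:
            comparison_rows.append(row)

    outputs = {
        "sample_metrics.tsv": (
            metric_rows,
            ["sample_id", "n_total", "n_mapped", "n_multi", "R_m", "R_m0", "A_L"],
        ),
        "size_bins.tsv": (
            bin_rows,
            ["sample_id", "lower", "upper", "midpoint", "n_total", "n_mapped", "n_multi",
             "R_m", "R_m0", "included_in_fit"],
        ),
        "trend_fits.tsv": (
            trend_rows,
            ["response", "slope", "intercept", "r_squared", "p_value", "n_points"],
        ),
        "damage_profiles.tsv": (
            profile_rows,
            ["sample_id", "end", "substitution", "position", "ref_base_count", "damage_count", "rate"],
        ),
        "damage_summaries.tsv": (
            summary_rows,
            ["sample_id", "end", "N_db", "R_dm", "window_mean"],
        ),
        "comparisons.tsv": (
            comparison_rows,
            ["label", "variable", "metric", "test_used", "paired", "statistic", "p_value",
             "n_a", "n_b", "mean_a", "sd_a", "mean_b", "sd_b",
             "normality_p_a", "normality_p_b", "normality_p_diff", "degenerate"],
        ),
    }

    checksums = {}
    for name, (rows, columns) in outputs.items():
        path = os.path.join(out_dir, name)
        if os.path.exists(path) and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        alignment_io.write_report(path, rows, columns=columns)
        checksums[name] = _sha256(path)

    config_blob = json.dumps(
        {
            "schema": "endoqc-study-v1",
            "samples": [[s.sample_id, s.path, s.groups, s.pair_id] for s in config.samples],
            "comparisons": [[c.label, c.variable, c.metric, c.paired, c.levels] for c in config.comparisons],
            "options": {k: getattr(opts, k) for k in (
                "seed", "damage_window", "bin_step", "min_reads", "alpha",
                "multi_def", "a_l_scope", "count_duplicates")},
        },
        sort_keys=True,
    )
    manifest = {
        "schema": "endoqc-study-v1",
        "seed": opts.seed,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "files": checksums,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _run_comparison(
    comp: ComparisonSpec,
    samples: list[SampleSpec],
    sample_values: dict[str, dict[str, float | None]],
    alpha: float,
) -> dict | None:
    if comp.levels is not None:
        levels = list(comp.levels)
    else:
        levels = []
        for s in samples:
            lvl = s.groups.get(comp.variable)
            if lvl is not None and lvl not in levels:
                levels.append(lvl)
        if len(levels) < 2:
            logger.warning("comparison %s skipped: <2 levels of %s", comp.label, comp.variable)
            return None
        levels = levels[:2]

    def value_of(s: SampleSpec) -> float | None:
        return sample_values[s.sample_id][comp.metric]

    if comp.paired:
        pairs: dict[str, dict[str, float]] = {}
        for s in samples:
            lvl = s.groups.get(comp.variable)
            if lvl in levels and s.pair_id and value_of(s) is not None:
                pairs.setdefault(s.pair_id, {})[lvl] = value_of(s)
        complete = sorted(pid for pid, d in pairs.items() if len(d) == 2)
        if len(complete) < len(pairs):
            logger.warning("comparison %s: %d incomplete pairs dropped",
                           comp.label, len(pairs) - len(complete))
        a = [pairs[pid][levels[0]] for pid in complete]
        b = [pairs[pid][levels[1]] for pid in complete]
    else:
        a = [value_of(s) for s in samples
             if s.groups.get(comp.variable) == levels[0] and value_of(s) is not None]
        b = [value_of(s) for s in samples
             if s.groups.get(comp.variable) == levels[1] and value_of(s) is not None]

    if len(a) < 3 or len(b) < 3:
        logger.warning("comparison %s skipped: group sizes %d vs %d (< 3)", comp.label, len(a), len(b))
        return None

    result = group_stats.compare_groups(a, b, paired=comp.paired, alpha=alpha, label=comp.label)
    return {
        "label": comp.label,
        "variable": comp.variable,
        "metric": comp.metric,
        "test_used": result.test_used,
        "paired": comp.paired,
        "statistic": result.statistic,
        "p_value": result.p_value,
        "n_a": result.n_a,
        "n_b": result.n_b,
        "mean_a": result.summary_a.mean,
        "sd_a": result.summary_a.sd,
        "mean_b": result.summary_b.mean,
        "sd_b": result.summary_b.sd,
        "normality_p_a": result.normality_p_a,
        "normality_p_b": result.normality_p_b,
        "normality_p_diff": result.normality_p_diff,
        "degenerate": result.degenerate,
    }
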
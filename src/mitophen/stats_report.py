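"""Per-condition summaries, group comparisons, and the end-to-end pipeline.

Summaries are mean +/- SEM per condition.  Group comparisons follow the
study's figure-legend procedures: a classic one-way ANOVA across conditions
followed by either Tukey's HSD (studentized-range) or Sidak-adjusted
pairwise t-tests, with significance bands at the conventional thresholds
0.05 (*), 0.01 (**), 0.001 (***) and 0.0001 (****).

:func:`run_pipeline` drives simulate -> quantify -> summarize -> compare for
one assay and writes CSV/JSON reports with full seed provenance.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import __version__
from .errors import DegenerateVarianceError, SampleSizeError, StageError

_BAND_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class GroupSummary:
    condition: str
    n: int
    mean: float
    sem: float                  # sample SD / sqrt(n); 0 by convention at n=1
    single_value: bool = False  # flags the degenerate n=1 case


@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[str, str]
    p_adjusted: float
    method: str                 # tukey | sidak
    significance_band: str      # ns / * / ** / *** / ****


@dataclass(frozen=True)
class GroupComparisons:
    anova_f: float
    anova_p: float
    results: list[ComparisonResult]


def significance_band(p: float) -> str:
    for thr, band in _BAND_THRESHOLDS:
        if p < thr:
            return band
    return "ns"


def summarize(measurements: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Mean and SEM per condition, ordered by condition label."""
    out = []
    for cond in sorted(measurements):
        vals = np.asarray(measurements[cond], dtype=float)
        if vals.size == 0:
            raise SampleSizeError(f"group '{cond}' is empty")
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out.append(
            GroupSummary(
                condition=cond,
                n=int(vals.size),
                mean=float(vals.mean()),
                sem=sem,
                single_value=vals.size == 1,
            )
        )
    return out


def compare_groups(
    measurements: Mapping[str, Sequence[float]],
    method: str = "tukey",
) -> GroupComparisons:
    """One-way ANOVA plus pairwise multiple comparisons.

    ``method="tukey"`` uses Tukey's HSD via the studentized-range
    distribution; ``method="sidak"`` applies the Sidak correction
    ``1 - (1 - p)^m`` to pairwise two-sample t-tests.
    """
    conds = sorted(measurements)
    if len(conds) < 2:
        raise SampleSizeError("need at least 2 groups to compare")
    groups = [np.asarray(measurements[c], dtype=float) for c in conds]
    if any(g.size < 2 for g in groups):
        raise SampleSizeError("each group needs at least 2 values")
    if all(g.std(ddof=1) == 0 for g in groups):
        raise DegenerateVarianceError(
            "zero within-group variance in every group"
        )
    f_stat, f_p = sps.f_oneway(*groups)

    pairs = list(itertools.combinations(range(len(conds)), 2))
    results: list[ComparisonResult] = []
    if method == "tukey":
        values = np.concatenate(groups)
        labels = np.concatenate(
            [np.full(g.size, c) for g, c in zip(groups, conds)]
        )
        tukey = pairwise_tukeyhsd(values, labels)
        # statsmodels orders rows as combinations of sorted unique labels
        for (i, j), p in zip(pairs, tukey.pvalues):
            p = float(min(max(p, 0.0), 1.0))
            results.append(
                ComparisonResult(
                    pair=(conds[i], conds[j]),
                    p_adjusted=p,
                    method="tukey",
                    significance_band=significance_band(p),
                )
            )
    elif method == "sidak":
        m = len(pairs)
        for i, j in pairs:
            p_raw = float(sps.ttest_ind(groups[i], groups[j]).pvalue)
            p_adj = float(min(1.0, 1.0 - (1.0 - p_raw) ** m))
            results.append(
                ComparisonResult(
                    pair=(conds[i], conds[j]),
                    p_adjusted=p_adj,
                    method="sidak",
                    significance_band=significance_band(p_adj),
                )
            )
    else:
        raise ValueError(f"unknown comparison method '{method}'")
    return GroupComparisons(
        anova_f=float(f_stat), anova_p=float(f_p), results=results
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline

def _condition_seed(base: int, cond_index: int, item: int) -> int:
    return (int(base) * 100003 + cond_index * 10007 + item) % 2**31


def _quantify_condition(
    assay: str,
    preset_name: str,
    n: int,
    seeds: list[int],
    acq,
) -> dict[str, list[float]]:
    """Generate and quantify one condition; returns named measurement lists."""
    from . import anaphase_quant, intensity_quant, nuclear_morphometry, pef_assay
    from . import synthetic_data as syn

    preset = syn.get_preset(preset_name)
    out: dict[str, list[float]] = {}
    if assay == "anaphase":
        chrom, pole = [], []
        for s in seeds:
            movie, _ = syn.generate_anaphase_movie(preset, acq, seed=s)
            series = anaphase_quant.track_movie(movie)
            chrom.append(series.max_chrom_separation_um)
            pole.append(series.max_pole_separation_um)
        out["max_chrom_separation_um"] = chrom
        out["max_pole_separation_um"] = pole
    elif assay == "pef":
        dists = []
        for s in seeds:
            image, _ = syn.generate_monopolar_image(preset, acq, seed=s)
            dists.append(pef_assay.measure_pef(image).pef_distance_um)
        out["pef_distance_um"] = dists
    elif assay == "nuclei":
        per_field = 16
        field_acq = syn.nucleus_acquisition(per_field, acq)
        sols: list[float] = []
        i = 0
        while len(sols) < n:
            stack, _ = syn.generate_nucleus_field(
                preset, field_acq, per_field,
                seed=(seeds[i % len(seeds)] + i) % 2**31,
            )
            sols.extend(
                r.solidity for r in nuclear_morphometry.measure_nuclei(stack)
            )
            i += 1
        out["solidity"] = sols[:n]
    elif assay == "expression":
        means = []
        for s in seeds:
            image, _ = syn.generate_expression_image(preset, acq, seed=s)
            mask = intensity_quant.spindle_mask(image)
            means.append(intensity_quant.masked_mean_intensity(image, mask))
        out["masked_mean"] = means
    else:
        raise ValueError(f"unknown assay '{assay}'")
    return out


_PRIMARY_MEASUREMENT = {
    "anaphase": "max_chrom_separation_um",
    "pef": "pef_distance_um",
    "nuclei": "solidity",
    "expression": "masked_mean",
}


def run_pipeline(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    """Execute simulate -> quantify -> summarize -> compare for one assay.

    ``config`` is a mapping (or path to a YAML file) with keys: ``assay``
    (anaphase | pef | nuclei | expression), ``presets`` (condition labels),
    ``n_per_condition``, ``seed``, optional ``acquisition`` overrides,
    ``comparison`` (tukey | sidak), ``control`` (condition label for
    expression normalization and the nuclei threshold; default gfp_ctrl when
    present) and ``out_dir``.  Writes a measurements CSV, a summary JSON and
    a plain-text log; reruns with the same config are bitwise identical.
    Returns the summary dictionary.
    """
    from . import intensity_quant, nuclear_morphometry
    from . import synthetic_data as syn

    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    try:
        assay = cfg["assay"]
        presets = list(cfg["presets"])
        n = int(cfg.get("n_per_condition", 10))
        seed = int(cfg.get("seed", 0))
        out_dir = Path(cfg["out_dir"])
    except KeyError as exc:
        raise StageError("config", f"missing key {exc}") from exc
    if not presets:
        raise StageError("config", "no presets requested")
    method = cfg.get("comparison", "tukey")
    control = cfg.get("control", "gfp_ctrl" if "gfp_ctrl" in presets else None)
    acq_over = cfg.get("acquisition") or {}
    try:
        acq = syn.AcquisitionParams(
            **{**{}, **acq_over}
        ) if acq_over else syn.AcquisitionParams()
    except (TypeError, ValueError) as exc:
        raise StageError("config", f"bad acquisition overrides: {exc}") from exc

    # quantify
    measurements: dict[str, dict[str, list[float]]] = {}
    seeds_used: dict[str, list[int]] = {}
    for ci, name in enumerate(presets):
        seeds = [_condition_seed(seed, ci, i) for i in range(n)]
        seeds_used[name] = seeds
        try:
            measurements[name] = _quantify_condition(assay, name, n, seeds, acq)
        except Exception as exc:
            raise StageError("quantify", f"condition '{name}': {exc}") from exc

    primary = _PRIMARY_MEASUREMENT[assay]
    primary_by_cond = {c: m[primary] for c, m in measurements.items()}

    try:
        summaries = summarize(primary_by_cond)
        comparisons = compare_groups(primary_by_cond, method=method)
    except Exception as exc:
        raise StageError("summarize", str(exc)) from exc

    extras: dict[str, Any] = {}
    if assay == "anaphase":
        extras["pole_summaries"] = [
            asdict(s)
            for s in summarize(
                {c: m["max_pole_separation_um"] for c, m in measurements.items()}
            )
        ]
    elif assay == "nuclei":
        if control is None or control not in measurements:
            raise StageError(
                "classify", "nuclei assay needs a generated control condition"
            )
        threshold = nuclear_morphometry.control_threshold(
            measurements[control]["solidity"]
        )
        fractions = {
            c: float(np.mean(np.asarray(m["solidity"]) < threshold))
            for c, m in measurements.items()
        }
        extras["threshold"] = threshold
        extras["abnormal_fraction"] = fractions
    elif assay == "expression":
        if control is None or control not in measurements:
            raise StageError(
                "normalize", "expression assay needs a control condition"
            )
        _, table = intensity_quant.normalize_and_summarize(
            {c: m["masked_mean"] for c, m in measurements.items()}, control
        )
        extras["expression_table"] = table.reset_index().to_dict("records")

    # reports
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"condition": c, "cell_index": i, "measurement": key, "value": v}
        for c, m in measurements.items()
        for key, vals in m.items()
        for i, v in enumerate(vals)
    ]
    pd.DataFrame(rows).to_csv(out_dir / f"{assay}_measurements.csv", index=False)

    summary = {
        "assay": assay,
        "package_version": __version__,
        "config": {
            "presets": presets,
            "n_per_condition": n,
            "seed": seed,
            "comparison": method,
            "control": control,
            "acquisition": acq_over,
        },
        "seeds": seeds_used,
        "groups": [asdict(s) for s in summaries],
        "anova": {"f": comparisons.anova_f, "p": comparisons.anova_p},
        "comparisons": [
            {
                "pair": list(r.pair),
                "p_adjusted": r.p_adjusted,
                "method": r.method,
                "band": r.significance_band,
            }
            for r in comparisons.results
        ],
        "band_thresholds": [t for t, _ in _BAND_THRESHOLDS],
        **extras,
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log_lines = [
        f"mitophen {__version__}",
        f"assay: {assay}",
        f"seed: {seed}",
        *(f"condition {c}: n={n}, seeds={s[:3]}..." for c, s in seeds_used.items()),
    ]
    (out_dir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return summary


__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "GroupComparisons",
    "significance_band",
    "summarize",
    "compare_groups",
    "run_pipeline",
]
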
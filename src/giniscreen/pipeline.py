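"""Pipeline orchestration: simulate -> normalize -> test -> screen -> report.

One YAML config drives a full run. The config either names input files
(expression TSV + sample sheet CSV) or a simulation block; a seed is
mandatory so every run is reproducible bit-for-bit. Outputs land in one
results directory:

    sample_sheet.csv, expression_raw.tsv, truth.json   (simulated runs)
    expression_normalized.tsv
    contrast_<individual>.tsv       per-individual moderated contrasts
    global_response.tsv             pooled treated-vs-untreated gene set
    candidates.tsv / exclusions.tsv family-level selection
    report.md                       design summary, counts, config echo
    run.log                         stage timings
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .core import (
    ExpressionMatrix,
    SampleSheet,
    ScreenPolicy,
    ValidationError,
    read_expression,
    read_sample_sheet,
    validate_design,
    write_expression,
    write_sample_sheet,
)
from .diffexpr import ebayes, fit_contrast, write_contrast
from .normalize import log2_transform, quantile_normalize
from .screen import (
    global_response,
    select_family_candidates,
    summarize_candidates,
    write_candidates,
)
from .simulate import PlantedGene, SimParams, SimTruth, design_from_family_spec, simulate_expression

__all__ = ["load_config", "run_pipeline", "make_truth_eval"]

logger = logging.getLogger(__name__)

_POLICY_KEYS = {
    "alpha",
    "require_positive_B",
    "direction",
    "affected_rule",
    "k",
    "unaffected_exclusion",
    "fold_report_thresholds",
}

_SIM_KEYS = {
    "n_probes",
    "probes_per_gene",
    "baseline_mean",
    "baseline_sd",
    "sigma_bio",
    "sigma_tech",
    "array_scale_sd",
    "p_global",
    "global_effect_sd",
    "global_effect_min",
    "eta_range",
    "positive_control_gene",
    "positive_control_fold",
    "ct_noise_sd",
    "ct_replicates",
}


def load_config(path: str | Path) -> dict:
    """Read and schema-check a pipeline config."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValidationError("config must set an explicit seed")
    has_sim = "simulation" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ValidationError("config needs exactly one of 'simulation' or 'inputs'")
    if has_sim:
        sim = cfg["simulation"]
        if "families" not in sim:
            raise ValidationError("simulation block needs 'families'")
        unknown = set(sim) - _SIM_KEYS - {"families", "replicates", "planted"}
        if unknown:
            raise ValidationError(f"unknown simulation key {sorted(unknown)[0]!r}")
    else:
        inputs = cfg["inputs"]
        for key in ("expression", "sample_sheet"):
            if key not in inputs:
                raise ValidationError(f"inputs block needs {key!r}")
    unknown = set(cfg.get("policy", {})) - _POLICY_KEYS
    if unknown:
        raise ValidationError(f"unknown policy key {sorted(unknown)[0]!r}")
    return cfg


def _build_policy(cfg: dict) -> ScreenPolicy:
    pol = dict(cfg.get("policy", {}))
    if "fold_report_thresholds" in pol:
        pol["fold_report_thresholds"] = tuple(pol["fold_report_thresholds"])
    return ScreenPolicy(**pol)


def _resolve_planted(raw: list[dict], sheet: SampleSheet) -> tuple[PlantedGene, ...]:
    planted = []
    for item in raw:
        carriers = item.get("carriers", "all_affected")
        if carriers == "all_affected":
            carriers = tuple(sheet.family_members(item["family"], "affected"))
        else:
            carriers = tuple(carriers)
        planted.append(
            PlantedGene(
                gene=item["gene"],
                family_id=item["family"],
                log2_fold=float(item["log2_fold"]),
                carriers=carriers,
            )
        )
    return tuple(planted)


def _simulate_stage(cfg: dict, outdir: Path) -> tuple[ExpressionMatrix, SampleSheet]:
    sim = cfg["simulation"]
    sheet = design_from_family_spec(
        [tuple(f) for f in sim["families"]], int(sim.get("replicates", 3))
    )
    params_kwargs = {k: v for k, v in sim.items() if k in _SIM_KEYS}
    if "eta_range" in params_kwargs:
        params_kwargs["eta_range"] = tuple(params_kwargs["eta_range"])
    params = SimParams(
        planted=_resolve_planted(sim.get("planted", []), sheet),
        seed=int(cfg["seed"]),
        **params_kwargs,
    )
    matrix, truth = simulate_expression(sheet, params)
    write_sample_sheet(sheet, outdir / "sample_sheet.csv")
    write_expression(matrix, outdir / "expression_raw.tsv")
    truth.to_json(outdir / "truth.json")
    return matrix, sheet


def run_pipeline(
    config: str | Path, outdir: str | Path, seed: int | None = None
) -> Path:
    """Run the full screen from a config file; returns the results directory.

    ``seed`` overrides the config's seed (e.g. from the command line).
    Fails fast on any schema violation or missing input; partial runs are
    not resumed.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("giniscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings: dict[str, float] = {}

    try:
        t0 = time.perf_counter()
        if "simulation" in cfg:
            matrix, sheet = _simulate_stage(cfg, outdir)
        else:
            matrix = read_expression(cfg["inputs"]["expression"], scale="raw")
            sheet = read_sample_sheet(cfg["inputs"]["sample_sheet"])
        design = validate_design(sheet)
        timings["input"] = time.perf_counter() - t0
        logger.info("design: %d individuals, %d arrays", design.n_individuals, design.n_arrays)

        t0 = time.perf_counter()
        normed = log2_transform(quantile_normalize(matrix))
        write_expression(normed, outdir / "expression_normalized.tsv")
        timings["normalize"] = time.perf_counter() - t0

        policy = _build_policy(cfg)
        p1 = float(cfg.get("p1", 0.01))

        t0 = time.perf_counter()
        per_individual = {}
        for ind in sheet.individuals:
            result = ebayes(fit_contrast(normed, sheet, ind), p1=p1)
            per_individual[ind] = result
            write_contrast(result, outdir / f"contrast_{ind}.tsv")
        timings["contrasts"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        global_set, fold_counts = global_response(normed, sheet, policy, p1=p1)
        gr_out = global_set.drop(columns=["probe"], errors="ignore")
        gr_out.to_csv(outdir / "global_response.tsv", sep="\t", lineterminator="\n")
        timings["global_response"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        all_records = []
        for fam in sheet.families:
            if not sheet.family_members(fam, "affected"):
                logger.info("family %s has no affected members; skipped", fam)
                continue
            all_records.extend(
                select_family_candidates(per_individual, sheet, fam, global_set, policy)
            )
        write_candidates(all_records, outdir / "candidates.tsv")
        write_candidates(
            [r for r in all_records if r.excluded_by != "none"],
            outdir / "exclusions.tsv",
            include_excluded=True,
        )
        timings["screen"] = time.perf_counter() - t0

        summary = summarize_candidates(all_records)
        _write_report(outdir, cfg, design, len(global_set), fold_counts, summary, timings)
        logger.info("run complete: %s", json.dumps(summary["per_family"], sort_keys=True))
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def _write_report(
    outdir: Path,
    cfg: dict,
    design,
    n_global: int,
    fold_counts: dict[float, int],
    summary: dict,
    timings: dict[str, float],
) -> None:
    lines = ["# GINI screen run report", ""]
    lines += ["## Design", ""]
    lines.append("```")
    lines.append(design.per_family.to_string())
    lines.append("```")
    lines.append("")
    lines.append(f"Total: {design.n_individuals} individuals, {design.n_arrays} arrays.")
    lines += ["", "## Global caffeine response", ""]
    lines.append(f"{n_global} genes differentially expressed between all treated and all untreated arrays.")
    for thr, count in sorted(fold_counts.items()):
        lines.append(f"- {count} changed more than {thr}-fold")
    lines += ["", "## Candidates", ""]
    per_fam = summary["per_family"]
    for fam in sorted(per_fam):
        lines.append(f"- Family {fam}: {per_fam[fam]} candidate gene(s)")
    lines.append(f"- {summary['n_distinct_genes']} distinct genes overall")
    if summary["multi_family_genes"]:
        lines.append(
            "- in more than one family: " + ", ".join(summary["multi_family_genes"])
        )
    lines += ["", "## Stage timings (s)", ""]
    for stage, secs in timings.items():
        lines.append(f"- {stage}: {secs:.2f}")
    lines += ["", "## Config", "", "```yaml", yaml.safe_dump(cfg, sort_keys=True).rstrip(), "```", ""]
    (outdir / "report.md").write_text("\n".join(lines), encoding="utf-8")


def make_truth_eval(results_dir: str | Path, truth_path: str | Path | None = None) -> dict:
    """Score a simulated run's candidates against its planted truth.

    Returns planted-gene recall and per-family false-candidate counts,
    and writes ``eval.json`` next to the candidates table.
    """
    results_dir = Path(results_dir)
    truth_path = Path(truth_path) if truth_path else results_dir / "truth.json"
    if not truth_path.exists():
        raise ValidationError(f"truth file not found: {truth_path}")
    truth = SimTruth.from_json(truth_path)
    cand = pd.read_csv(results_dir / "candidates.tsv", sep="\t")

    planted_pairs = {(p.family_id, p.gene) for p in truth.planted}
    found_pairs = {
        (row["Family"], row["Gene"]) for _, row in cand.iterrows()
    }
    recovered = planted_pairs & found_pairs
    recall = len(recovered) / len(planted_pairs) if planted_pairs else float("nan")
    false_by_family: dict[str, int] = {}
    for fam, gene in found_pairs - planted_pairs:
        false_by_family[fam] = false_by_family.get(fam, 0) + 1

    out = {
        "n_planted": len(planted_pairs),
        "n_recovered": len(recovered),
        "recall": recall,
        "false_candidates_per_family": dict(sorted(false_by_family.items())),
        "n_false_candidates": int(sum(false_by_family.values())),
    }
    (results_dir / "eval.json").write_text(json.dumps(out, indent=1, sort_keys=True) + "\n")
    return out
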
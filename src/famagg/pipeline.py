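"""One-shot pipeline: simulate -> pairs -> associate -> survival -> report.

A run is fully described by a plain-text ``key=value`` config (paths, study
window, exclusion-rule parameters, estimator flags, seed).  The config is
echoed into the output directory, every stage logs input hashes and row
counts, and a single seed drives all randomness, so re-running the same
config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from . import association, pairs as pairs_mod, report, survival, zygosity
from .registry import (Registry, STUDY_END, STUDY_START, follow_up_table,
                       read_registry, write_registry)
from .simulate import LiabilityParams, simulate_registry


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run."""

    out_dir: str = "famagg_run"
    registry_dir: Optional[str] = None   # read persons/diagnoses here; else simulate
    study_start: int = STUDY_START
    study_end: int = STUDY_END
    seed: int = 0
    adjust: Tuple[str, ...] = association.DEFAULT_ADJUST
    single_entry: bool = False
    exclude_differential: bool = False
    stratify_by: Tuple[str, ...] = ("sex_pair",)
    apply_exclusions: bool = True
    plots: bool = False
    sim: LiabilityParams = field(default_factory=LiabilityParams)
    rules: pairs_mod.ExclusionRules = field(default_factory=pairs_mod.ExclusionRules)

    def validate(self) -> None:
        if self.study_end < self.study_start:
            raise PipelineError("config: study_end precedes study_start")
        self.sim.seed = self.seed
        self.sim.study_start = self.study_start
        self.sim.study_end = self.study_end
        self.sim.validate()


_BOOL = {"1": True, "0": False, "true": True, "false": False,
         "yes": True, "no": False}


def load_config(path) -> RunConfig:
    """Parse a plain-text key=value config (``#`` comments allowed).

    Keys matching LiabilityParams fields may be prefixed ``sim.``; exclusion
    rule fields use ``rules.``; everything else maps to RunConfig fields.
    """
    cfg = RunConfig()
    sim_fields = {f.name: f for f in fields(LiabilityParams)}
    rule_fields = {f.name: f for f in fields(pairs_mod.ExclusionRules)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise PipelineError(f"config line {lineno}: expected key=value")
        key, val = (s.strip() for s in line.split("=", 1))

        def coerce(ftype, v):
            if ftype in ("int", int):
                return int(v)
            if ftype in ("float", float):
                return float(v)
            if ftype in ("bool", bool):
                return _BOOL[v.lower()]
            return v

        if key.startswith("sim.") and key[4:] in sim_fields:
            name = key[4:]
            f = sim_fields[name]
            setattr(cfg.sim, name, coerce(f.type, val))
        elif key.startswith("rules.") and key[6:] in rule_fields:
            name = key[6:]
            f = rule_fields[name]
            if "Tuple" in str(f.type):
                lo, hi = (int(x) for x in val.split(","))
                setattr(cfg.rules, name, (lo, hi))
            else:
                setattr(cfg.rules, name, coerce(f.type, val))
        elif key in ("out_dir", "registry_dir"):
            setattr(cfg, key, val)
        elif key in ("study_start", "study_end", "seed"):
            setattr(cfg, key, int(val))
        elif key in ("single_entry", "exclude_differential", "apply_exclusions",
                     "plots"):
            setattr(cfg, key, _BOOL[val.lower()])
        elif key == "adjust":
            cfg.adjust = tuple(s for s in val.split(",") if s)
        elif key == "stratify_by":
            cfg.stratify_by = tuple(s for s in val.split(",") if s)
        else:
            raise PipelineError(f"config line {lineno}: unknown key {key!r}")
    return cfg


def _echo_config(cfg: RunConfig, out: Path) -> None:
    lines = []
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if dataclasses.is_dataclass(v):
            for g in fields(v):
                prefix = "sim" if isinstance(v, LiabilityParams) else "rules"
                gv = getattr(v, g.name)
                if isinstance(gv, dict):
                    continue
                if isinstance(gv, tuple):
                    gv = ",".join(str(x) for x in gv)
                lines.append(f"{prefix}.{g.name}={gv}")
        else:
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
    (out / "run.cfg").write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(cfg: RunConfig, log_stream=None) -> Dict[str, object]:
    """Execute every stage; returns the in-memory artefacts and writes the
    report bundle under cfg.out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        print(msg, file=log_stream or sys.stderr)

    _echo_config(cfg, out)

    # stage: registry ---------------------------------------------------
    try:
        if cfg.registry_dir:
            pdir = Path(cfg.registry_dir)
            registry = read_registry(pdir / "persons.tsv", pdir / "diagnoses.tsv")
            log(f"[registry] read {len(registry.persons)} persons, "
                f"{len(registry.events)} events "
                f"(sha {_sha256(pdir / 'persons.tsv')})")
            truth = None
        else:
            registry, truth = simulate_registry(cfg.sim)
            write_registry(registry, out / "persons.tsv", out / "diagnoses.tsv")
            truth.liabilities.to_csv(out / "truth.tsv", sep="\t", index=False)
            truth.zygosity.to_csv(out / "truth_zygosity.tsv", sep="\t", index=False)
            log(f"[simulate] seed={cfg.sim.seed} -> {len(registry.persons)} persons, "
                f"{len(registry.events)} events "
                f"(sha {_sha256(out / 'persons.tsv')})")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage registry/simulate failed: {exc}") from exc

    # stage: pairs ------------------------------------------------------
    try:
        all_pairs = pairs_mod.build_all_pairs(registry)
        if cfg.apply_exclusions:
            all_pairs, excl_log = pairs_mod.apply_exclusions(
                all_pairs, registry, cfg.rules)
            pd.Series(excl_log, name="dropped_pairs").rename_axis("rule") \
                .to_csv(out / "exclusions.log", sep="\t")
            log(f"[pairs] exclusions: {excl_log}")
        if cfg.exclude_differential:
            before = len(all_pairs)
            all_pairs = association.differential_family_filter(registry, all_pairs)
            log(f"[pairs] differential-dx filter dropped {before - len(all_pairs)} rows")
        all_pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
        counts = all_pairs["relation"].value_counts().to_dict()
        log(f"[pairs] rows per relation: {counts}")
    except Exception as exc:
        raise PipelineError(f"stage pairs failed: {exc}") from exc

    # stage: zygosity ---------------------------------------------------
    zyg = None
    try:
        twin_pairs = all_pairs[all_pairs["relation"] == "twin"]
        if len(twin_pairs):
            zyg = zygosity.weinberg_from_pairs(twin_pairs, registry.persons)
            (out / "zygosity.tsv").write_text(
                "n_opposite_sex\tn_same_sex\tn_dz\tn_mz\tmean_resemblance\n"
                f"{zyg.n_opposite_sex}\t{zyg.n_same_sex}\t{zyg.n_dz}\t"
                f"{zyg.n_mz}\t{zyg.mean_resemblance:.4f}\n")
            log(f"[zygosity] mean resemblance {zyg.mean_resemblance:.4f}")
    except zygosity.ZygosityError as exc:
        log(f"[zygosity] skipped: {exc}")

    # stage: associate --------------------------------------------------
    try:
        follow = follow_up_table(registry, cfg.study_start, cfg.study_end)
        model = association.FamilialAggregation.from_registry(
            registry, pairs=all_pairs, study_start=cfg.study_start,
            study_end=cfg.study_end)
        results = model.fit(adjust=cfg.adjust, single_entry_mode=cfg.single_entry)
        results.to_frame().to_csv(out / "estimates.tsv", sep="\t", index=False)
        report.familial_risk_table(results).to_csv(
            out / "table_familial_risk.tsv", sep="\t", index=False)
        datasets = {"all": registry.persons["person_id"]}
        for rel in results.exposure:
            sub = all_pairs[all_pairs["relation"] == rel]
            datasets[rel] = pd.unique(sub[["index_id", "relative_id"]]
                                      .to_numpy().ravel())
        report.cohort_table(registry, follow, datasets).to_csv(
            out / "table_cohort.tsv", sep="\t", index=False)
        for by in cfg.stratify_by:
            results.stratified(by).to_csv(
                out / f"stratified_{by}.tsv", sep="\t", index=False)
        log("[associate] wrote estimates.tsv, tables, stratified estimates")
    except Exception as exc:
        raise PipelineError(f"stage associate failed: {exc}") from exc

    # stage: survival ---------------------------------------------------
    try:
        curve_frames, lr_rows = [], []
        for rel in results.exposure:
            curves, lr = survival.familial_survival(follow, all_pairs, rel)
            for c in curves.values():
                df = c.to_frame()
                df.insert(0, "relation", rel)
                curve_frames.append(df)
            lr_rows.append({"relation": rel, "chi_square": lr.chi_square,
                            "df": lr.df, "p_value": lr.p_value})
            if cfg.plots:
                survival.plot_curves(curves, out / f"km_{rel}.png", title=rel)
        pd.concat(curve_frames, ignore_index=True).to_csv(
            out / "curves.tsv", sep="\t", index=False)
        pd.DataFrame(lr_rows).to_csv(out / "logrank.tsv", sep="\t", index=False)
        log(f"[survival] log-rank: {lr_rows}")
    except Exception as exc:
        raise PipelineError(f"stage survival failed: {exc}") from exc

    # stage: sensitivity deltas ----------------------------------------
    try:
        _, delta_se = association.sensitivity_filters(
            registry, all_pairs, "single_entry", adjust=cfg.adjust)
        delta_se.to_csv(out / "sensitivity_single_entry.tsv", sep="\t", index=False)
        _, delta_dx = association.sensitivity_filters(
            registry, all_pairs, "exclude_differential_dx", adjust=cfg.adjust)
        delta_dx.to_csv(out / "sensitivity_differential.tsv", sep="\t", index=False)
        log("[sensitivity] wrote delta reports")
    except Exception as exc:
        raise PipelineError(f"stage sensitivity failed: {exc}") from exc

    (out / "summary.txt").write_text(results.summary() + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {"registry": registry, "pairs": all_pairs, "results": results,
            "zygosity": zyg, "config": cfg}
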
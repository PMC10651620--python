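"""End-to-end pipeline: filter → phenotype → preprocess → screen → enrich → modules.

A single :class:`PipelineConfig` (YAML/JSON-serializable, unknown keys
rejected) drives the full analysis; one global seed fans out to
deterministic per-stage child seeds so stages can be rerun in isolation.
Every stage writes its table as it completes, so a failure retains partial
outputs, and a markdown report is regenerable from the tables alone.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cohort as cio
from . import enrich as en
from . import network as nw
from . import phenotype as ph
from . import preprocess as pp
from . import screen as sc
from . import simulate as sim

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "make_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline knobs in one serializable object."""

    # input: either simulate at a preset scale, or read cohort files
    simulate: str | None = "desk"          # smoke | desk | full | None
    subjects_path: str | None = None
    visits_path: str | None = None
    panel_path: str | None = None
    meta_path: str | None = None
    out_dir: str = "dualtraj_run"
    seed: int = 0
    # baseline filters
    min_age: float = 50.0
    min_gait: float = 0.6
    # phenotyping
    min_visits: int = 2
    exclude_post_dementia: bool = True
    override_cuts: tuple[float, float] | None = None  # signed (memory, gait)
    # preprocessing
    max_below_frac: float = 0.20
    # screening
    alpha: float = 0.05
    m_total: int | None = None
    # stage toggles
    run_ratios: bool = True
    run_enrichment: bool = True
    run_network: bool = True
    # network
    beta: int = 6
    cut_height: float | None = 0.75
    min_module_size: int = 5

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("override_cuts") is not None:
            d["override_cuts"] = tuple(float(x) for x in d["override_cuts"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["override_cuts"] is not None:
            d["override_cuts"] = list(d["override_cuts"])
        return d


def _stage_seed(seed: int, index: int) -> int:
    """Deterministic per-stage child seed from the global seed."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> str:
    """Execute the full analysis; returns the run directory path."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    def _save(name: str, df: pd.DataFrame) -> None:
        df.to_csv(os.path.join(out, f"{name}.tsv"), sep="\t", index=False)

    # ---- load or simulate -------------------------------------------------
    stage = "load"
    try:
        truth = None
        if config.simulate is not None:
            params = sim.default_params(config.simulate, seed=_stage_seed(config.seed, 0))
            dataset, truth = sim.generate_cohort(params)
            cio.write_cohort(dataset, out)
            truth.group.rename("group").to_frame().reset_index(names="subject_id").to_csv(
                os.path.join(out, "truth_groups.tsv"), sep="\t", index=False
            )
        else:
            dataset = cio.read_cohort(
                config.subjects_path, config.visits_path,
                config.panel_path, config.meta_path,
            )
        stage = "baseline_filter"
        dataset, exclusions = cio.apply_baseline_filters(
            dataset, min_age=config.min_age, min_gait=config.min_gait
        )
        _save("exclusions", exclusions)

        # ---- phenotyping --------------------------------------------------
        stage = "phenotype"
        slopes, slope_log = ph.estimate_annual_slopes(
            dataset, min_visits=config.min_visits,
            exclude_post_dementia=config.exclude_post_dementia,
        )
        if config.override_cuts is not None:
            cuts = ph.Cutpoints(*config.override_cuts)
        else:
            cuts = ph.tertile_cutpoints(slopes)
        labels, label_log = ph.classify_phenotypes(slopes, cuts)
        _save("slopes", slopes)
        _save("phenotypes", labels)
        _save("phenotype_log", pd.concat([slope_log, label_log], ignore_index=True))
        with open(os.path.join(out, "cutpoints.json"), "w") as fh:
            json.dump({"memory_cut": cuts.memory_cut, "gait_cut": cuts.gait_cut}, fh, indent=2)

        # ---- preprocessing ------------------------------------------------
        stage = "preprocess"
        processed = pp.preprocess_panel(
            dataset.panel, max_below_frac=config.max_below_frac,
            seed=_stage_seed(config.seed, 2),
        )
        lod_report = pd.DataFrame(
            {
                "metabolite": processed.metabolites,
                "below_lod_fraction": processed.below_lod_fraction.reindex(
                    processed.metabolites
                ).to_numpy(),
                "n_imputed": processed.imputed.sum(axis=0).reindex(processed.metabolites).to_numpy(),
            }
        )
        _save("lod_report", lod_report)
        _save("lod_excluded", processed.excluded)

        # ---- screening ----------------------------------------------------
        stage = "screen"
        design = sc.build_design(dataset, labels, processed.log2.index)
        keep_rows = processed.log2.index[
            pd.Index(processed.log2.index.get_level_values(0)).isin(
                set(labels["subject_id"])
            )
        ]
        log2 = processed.log2.loc[keep_rows]
        screen_table = sc.screen_all(log2, design, apply_bh=True, m_total=config.m_total)
        _save("screen_results", screen_table)

        ratio_table = None
        if config.run_ratios:
            stage = "ratios"
            # ratios on imputed concentrations (2**log2), then log2 for modeling
            conc = np.power(2.0, log2)
            ratios = pp.compute_ratio_panel(conc)
            vals = ratios.values.where(ratios.values > 0)
            ratio_table = sc.screen_all(np.log2(vals), design, apply_bh=False)
            ratio_table = ratio_table.rename(columns={"metabolite": "ratio"})
            _save("ratio_results", ratio_table)

        enrichment = None
        if config.run_enrichment:
            stage = "enrich"
            enrichment = en.enrich_classes(
                screen_table, processed.meta["class_label"]
            )
            _save("enrichment", enrichment)

        # ---- network modules ----------------------------------------------
        modules_tab = None
        module_lme_tab = None
        if config.run_network:
            stage = "modules"
            cor = nw.spearman_matrix(log2)
            adj = nw.soft_adjacency(cor, beta=config.beta, signed=True)
            tom = nw.topological_overlap(adj)
            ncfg = nw.NetworkConfig(
                beta=config.beta, cut_height=config.cut_height,
                min_module_size=config.min_module_size,
            )
            assignment = nw.detect_modules(tom, ncfg)
            hubs = nw.hub_metabolite(assignment, adj)
            modules_tab = pd.DataFrame(
                {
                    "metabolite": assignment.modules.index,
                    "module": assignment.modules.to_numpy(),
                }
            )
            modules_tab["hub"] = [
                hubs.get(m) == n for n, m in
                zip(modules_tab["metabolite"], modules_tab["module"])
            ]
            _save("modules", modules_tab)
            if hubs:
                scores, varex = nw.module_scores(log2, assignment)
                sc_out = scores.reset_index()
                sc_out.columns = ["subject_id", "time_years"] + [
                    f"module_{c}" for c in scores.columns
                ]
                _save("module_scores", sc_out)
                module_lme_tab = nw.module_group_lme(scores, design)
                _save("module_lme", module_lme_tab)

        # ---- manifest + report --------------------------------------------
        stage = "report"
        import scipy
        import statsmodels

        cfg_dict = config.to_dict()
        cfg_dict.pop("out_dir")  # identical runs should be byte-identical
        manifest = {
            "config": cfg_dict,
            "seed": config.seed,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        make_report(out, alpha=config.alpha)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage then re-raise
        raise StageError(stage, exc) from exc
    return out


def _maybe_read(run_dir: str, name: str) -> pd.DataFrame | None:
    path = os.path.join(run_dir, f"{name}.tsv")
    if not os.path.exists(path):
        return None
    return pd.read_csv(path, sep="\t")


def make_report(run_dir: str, alpha: float = 0.05) -> str:
    """Render ``report.md`` from the stage tables alone (idempotent)."""
    lines = ["# Dual-decline metabolomics run report", ""]

    phen = _maybe_read(run_dir, "phenotypes")
    if phen is not None:
        lines += ["## Phenotypic groups", ""]
        counts = phen["label"].value_counts()
        for lab in ph.LABELS:
            lines.append(f"- {lab}: {int(counts.get(lab, 0))}")
        cuts_path = os.path.join(run_dir, "cutpoints.json")
        if os.path.exists(cuts_path):
            with open(cuts_path) as fh:
                cuts = json.load(fh)
            lines.append(
                f"- tertile cut-points (signed slopes): memory "
                f"{cuts['memory_cut']:.3f} points/yr, gait {cuts['gait_cut']:.4f} m/s/yr"
            )
        lines.append("")
    else:
        lines += ["## Phenotypic groups", "", "stage skipped", ""]

    scr = _maybe_read(run_dir, "screen_results")
    if scr is not None:
        sig = scr[scr["q_omnibus"] < alpha]
        lines += ["## Metabolite screening", ""]
        lines.append(f"- metabolites screened: {len(scr)}")
        lines.append(f"- omnibus q < {alpha:g}: {len(sig)}")
        for rec in sig.head(10).itertuples(index=False):
            lines.append(
                f"  - {rec.metabolite}: p = {rec.p_omnibus:.3g}, q = {rec.q_omnibus:.3g}"
            )
        lines.append("")
    else:
        lines += ["## Metabolite screening", "", "stage skipped", ""]

    rat = _maybe_read(run_dir, "ratio_results")
    if rat is not None:
        lines += ["## Ratio biomarkers", ""]
        for rec in rat.itertuples(index=False):
            flag = " *" if rec.p_omnibus < alpha else ""
            lines.append(
                f"- {rec.ratio}: omnibus p = {rec.p_omnibus:.3g}{flag}; "
                f"dual-decline slope contrast β = {rec.beta_dual_decline:.4f} "
                f"(p = {rec.p_dual_decline:.3g})"
            )
        lines.append("")

    enr = _maybe_read(run_dir, "enrichment")
    if enr is not None:
        lines += ["## Class enrichment", ""]
        ok = enr[enr["status"] == "ok"]
        for _, row in ok.head(8).iterrows():
            lines.append(f"- {row['class']}: n = {int(row['size'])}, p = {row['p_value']:.3g}")
        ne = enr[enr["status"] != "ok"]["class"].tolist()
        if ne:
            lines.append(f"- not estimable (size < 2): {', '.join(map(str, ne))}")
        lines.append("")

    mods = _maybe_read(run_dir, "modules")
    if mods is not None:
        lines += ["## Network modules", ""]
        assigned = mods[mods["module"] > 0]
        lines.append(f"- modules detected: {assigned['module'].nunique()}")
        for mod, g in assigned.groupby("module"):
            hub = g.loc[g["hub"], "metabolite"]
            hubname = hub.iloc[0] if len(hub) else "?"
            lines.append(f"  - module {mod}: {len(g)} metabolites, hub {hubname}")
        mlme = _maybe_read(run_dir, "module_lme")
        if mlme is not None:
            for rec in mlme.itertuples(index=False):
                lines.append(
                    f"  - module {rec.module} dual-decline slope contrast: "
                    f"β = {rec.beta_dual_decline:.4f}, p = {rec.p_dual_decline:.3g}"
                )
        lines.append("")

    path = os.path.join(run_dir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
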
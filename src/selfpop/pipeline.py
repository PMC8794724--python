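"""End-to-end pipeline: filter -> diversity -> MLG -> temporal Ne -> gradients
-> drift neutrality test, with a single master seed and a JSON report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diversity as dv
from . import drift as dr
from . import gradients as gr
from . import io as pio
from . import mlg as ml
from . import temporal as tp

log = logging.getLogger("selfpop")


@dataclass
class PipelineConfig:
    genotypes: str
    phenotypes: str | None = None
    genotype_format: str = "genepop"  # or "csv"
    pop_years: tuple[str, str] = ("1987", "2009")
    t_generations: int = 22
    max_missing: float = 0.10
    error_rate: float = 1.0 / 16.0
    fis_eff: float = 1.0
    n_boot: int = 5000
    ci_method: str = "abc"
    drift_reps: int = 10_000
    drift_sample: int = 75
    drift_init_mode: str = "sample_year1"
    ne_grid: tuple[int, ...] = ()
    short_treatment: str = "short"
    restrict_to_year1: bool = False
    outdir: str = "selfpop_out"
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _child_seed(master: int, tag: str) -> int:
    ss = np.random.SeedSequence([master, abs(hash(tag)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if hasattr(obj, "tolist"):
        return _jsonable(obj.tolist())
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config": {k: _jsonable(v) for k, v in vars(cfg).items() if k != "extra"}}

    log.info("reading genotypes from %s", cfg.genotypes)
    if cfg.genotype_format == "genepop":
        gm = pio.read_genepop(cfg.genotypes, pop_years=list(cfg.pop_years))
    else:
        gm = pio.read_genotype_csv(cfg.genotypes)
    y1, y2 = gm.year_labels[:2]

    gm, filt = pio.filter_genotypes(gm, max_missing=cfg.max_missing)
    report["filter"] = json.loads(filt.to_json())
    (out / "filter_report.json").write_text(filt.to_json())

    seed_div = _child_seed(cfg.seed, "diversity")
    div = dv.diversity_summary(gm, n_boot=cfg.n_boot, seed=seed_div)
    report["diversity"] = {
        "rarefaction_g": div["rarefaction_g"],
        "per_year": {
            y: {
                "He_mean": float(np.nanmean(d["He"])),
                "Na_rar_mean": float(np.nanmean(d["Na_rar"])),
                "fis": d["fis"],
                "selfing_proxy": d["selfing_proxy"],
            }
            for y, d in div["per_year"].items()
        },
        "tests": div.get("tests"),
    }

    seed_mlg = _child_seed(cfg.seed, "mlg")
    catalog = ml.cluster_mlgs(gm, error_rate=cfg.error_rate, seed=seed_mlg)
    catalog.to_frame().to_csv(out / "mlg_catalog.tsv", sep="\t", index=False)
    triads = ml.detect_recombinants(catalog)
    n_homo = sum(r.fully_homozygous for r in catalog.mlgs)
    report["mlg"] = {
        "n_mlgs": catalog.n_mlgs,
        "n_fully_homozygous": n_homo,
        "n_recombinant_triads": len(triads),
        "distance_spectrum": ml.distance_spectrum(catalog) if catalog.n_mlgs > 1 else {},
    }
    freq = ml.frequency_change(
        catalog, y1, y2, homozygous_only=True, restrict_to_year1=cfg.restrict_to_year1
    )
    freq.table.to_csv(out / "mlg_frequency_change.tsv", sep="\t", index=False)

    seed_ne = _child_seed(cfg.seed, "ne")
    ne_est = tp.TemporalNeEstimator(
        year1=y1,
        year2=y2,
        t=cfg.t_generations,
        fis_eff=cfg.fis_eff,
        n_boot=cfg.n_boot,
        ci_method=cfg.ci_method,
        random_state=seed_ne,
    ).fit(gm)
    ne_est.per_locus_.to_csv(out / "fst_per_locus.tsv", sep="\t")
    report["temporal_ne"] = {
        "fst": ne_est.fst_,
        "fst_ci95": list(ne_est.fst_ci_),
        "ne": ne_est.ne_,
        "ne_display": ne_est.estimate_.ne_display,
        "ne_ci95": list(ne_est.ne_ci_) if ne_est.ne_ci_ else None,
        "t": cfg.t_generations,
    }
    try:
        sfst = tp.superlocus_fst(freq)
        report["temporal_ne"]["superlocus_fst"] = sfst
        if 0 < sfst < 1:
            report["temporal_ne"]["superlocus_ne"] = tp.ne_from_fst(
                sfst, cfg.t_generations, mode="superlocus"
            ).ne
    except ValueError as exc:
        report["temporal_ne"]["superlocus_fst_error"] = str(exc)

    traits = None
    if cfg.phenotypes:
        pheno = pio.read_phenotypes(cfg.phenotypes)
        report["phenotypes"] = {"n_plants": len(pheno.data), "n_excluded": pheno.n_excluded}
        overlap = set(pheno.data["family"]) & set(catalog.labels)
        if overlap:
            mlg_ids = freq.table["mlg"].to_numpy()
            try:
                traits = gr.mlg_trait_values(
                    pheno, catalog.labels, mlg_ids, treatment=cfg.short_treatment
                )
            except ValueError as exc:
                log.warning("trait values unavailable: %s", exc)
                traits = None
            if traits is not None:
                rg = gr.realized_fitness_gradient(freq, traits)
                report["realized_fitness_gradient"] = _jsonable(vars(rg))
                if pheno.has_seeds:
                    seeds = gr.mlg_trait_values(
                        pheno, catalog.labels, mlg_ids, trait="seeds", treatment=None
                    )
                    report["fitness_proxy"] = _jsonable(vars(gr.fitness_proxy_check(freq, seeds)))
                    for year in sorted(pheno.data["year"].unique()):
                        rp = gr.robertson_price_gradient(
                            pheno, year=year, treatment=cfg.short_treatment
                        )
                        report.setdefault("robertson_price", {})[year] = _jsonable(vars(rp))

    if traits is not None:
        ne_round = max(2, int(round(ne_est.ne_)))
        seed_drift = _child_seed(cfg.seed, "drift")
        test = dr.DriftNeutralityTest(
            ne=ne_round,
            t=cfg.t_generations,
            n_reps=cfg.drift_reps,
            n_sample_final=cfg.drift_sample,
            init_mode=cfg.drift_init_mode,
            random_state=seed_drift,
        ).fit(freq, traits)
        report["drift_test"] = test.result_.to_dict()
        np.savetxt(out / "null_slopes.tsv", test.null_slopes_, fmt="%.6e")
        if cfg.ne_grid:
            curve = dr.ne_sensitivity(
                freq,
                traits,
                np.asarray(cfg.ne_grid),
                t=cfg.t_generations,
                n_reps=cfg.drift_reps,
                n_sample_final=cfg.drift_sample,
                init_mode=cfg.drift_init_mode,
                seed=_child_seed(cfg.seed, "ne_grid"),
            )
            curve.table.to_csv(out / "ne_sensitivity.tsv", sep="\t", index=False)
            report["ne_sensitivity"] = {
                "grid": curve.grid.tolist(),
                "p_values": curve.p_values.tolist(),
                "threshold_ne": curve.threshold_ne,
            }

    text = json.dumps(_jsonable(report), sort_keys=True, indent=2)
    (out / "report.json").write_text(text)
    return report
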
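"""End-to-end synthetic pipeline: generate inputs, assign reads, run the
stroma differential analysis and signature extraction, score the
signatures, run the proteomic fraction analysis, and evaluate prognostic
value on the synthetic cohort.  Writes versioned TSV outputs, a markdown
report and (optionally) figure analogues of the study's main panels.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as ex
from . import proteomics as prot
from . import setscore, species, survival, synthetic
from .config import PipelineConfig
from .containers import CountMatrix, OrthologTable
from .io import write_gmt, write_tsv
from .signatures import load_ob_bmst, map_orthologs, stroma_signatures

log = logging.getLogger("xenostroma")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: str | Path, synthetic_mode: bool = True,
                 n_background: int = 2000, n_reads_per_sample: int = 2000,
                 make_plots: bool = False) -> Path:
    """Run the full synthetic analysis and write a report directory.

    Returns the output directory.  Every table carries the config hash; a
    stage failure halts with a stage-tagged diagnostic.
    """
    if not synthetic_mode:
        raise NotImplementedError("only the synthetic input path is implemented")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    summary: dict = {"config_hash": h, "seed": config.seed}

    # -- stage: references + read-level species assignment (desk scale) ----
    stage = "assign"
    try:
        ref_h, ref_m, orth = synthetic.make_references(
            20, 20, 10, 0.85, seed=config.stage_seed("references"), n_decoys=3)
        design_small = synthetic.default_design(("BM18like",))
        truth_small = synthetic.SimulationTruth(
            {}, {m.sample_id: synthetic.DEFAULT_STROMA_FRACTION[(m.model, m.condition)]
                 for m in design_small},
            dispersion=0.1, library_size=200_000, seed=config.stage_seed("counts"))
        _, _, mixed = synthetic.simulate_counts(ref_h, ref_m, design_small, truth_small)
        index = species.build_index(ref_h, ref_m, k=config.k)
        assignments = []
        for i, s in enumerate(design_small):
            reads = synthetic.simulate_reads(
                ref_h, ref_m, synthetic.expression_weights(mixed, s.sample_id),
                read_length=75, error_rate=0.005, n_reads=n_reads_per_sample,
                seed=config.stage_seed("reads") + i, sample_id=s.sample_id)
            assignments.extend(species.classify_reads(reads, index, config.min_specific))
        cm_h, cm_m, tally = species.count_by_gene(assignments, index,
                                                  mixed.meta)
        frac = species.stroma_fraction(tally)
        write_tsv(tally, out / "assignment_tally.tsv", h)
        write_tsv(frac.to_frame(), out / "stroma_fraction.tsv", h)
        summary["stroma_fraction"] = frac.round(4).to_dict()
    except Exception as exc:  # noqa: BLE001 - halt with stage tag
        raise StageError(stage, exc) from exc

    # -- stage: stroma counts, DE and signatures (count scale) -------------
    stage = "signatures"
    try:
        design = synthetic.default_design()
        genes_m = synthetic.gene_universe(n_background + 133, "MMU_G")
        genes_h = synthetic.gene_universe(200, "HSA_G")
        truth = synthetic.default_truth(genes_m, design, seed=config.stage_seed("counts"))
        _, mouse, _ = synthetic.simulate_counts(genes_h, genes_m, design, truth)
        mouse = ex.filter_low(mouse, config.cpm_log2_threshold, config.max_low_samples)
        sigs = stroma_signatures(mouse, fdr=config.de_fdr, fold=config.de_fold,
                                 prior_df=config.prior_df, c4_baseline=config.c4_baseline)
        write_gmt(out / "signatures.gmt", {k: v.members for k, v in sigs.items()})
        write_tsv(synthetic.truth_table(truth).set_index("gene"),
                  out / "planted_truth.tsv", h)
        lc = ex.cpm_log2(mouse)
        hv = ex.top_variable(lc, min(config.top_n_variable, len(lc)))
        coords = ex.pca(lc.loc[hv], n_components=2)
        write_tsv(coords, out / "pca_coordinates.tsv", h)
        truth_sets = {k: set(v.genes) for k, v in truth.planted_sets.items()}
        summary["signature_sizes"] = {k: len(v) for k, v in sigs.items()}
        summary["signature_recovery_jaccard"] = {
            k: round(len(set(sigs[k].members) & truth_sets[k])
                     / max(len(set(sigs[k].members) | truth_sets[k]), 1), 4)
            for k in sigs}
        # confidence-1 ortholog pairs for 90% of the count-level gene universe
        rng = np.random.default_rng(config.stage_seed("references"))
        has_orth = rng.random(len(genes_m)) < 0.9
        orth_counts = OrthologTable(pd.DataFrame(
            {"mouse_gene": np.array(genes_m)[has_orth],
             "human_gene": [g.replace("MMU_G", "HSA_O") for g, k in
                            zip(genes_m, has_orth) if k],
             "confidence": 1}))
        write_tsv(orth_counts.table, out / "orthologs.tsv", h, index=False)
        mapped = {k: map_orthologs(v, orth_counts) for k, v in sigs.items()}
        summary["mapped_sizes"] = {k: len(v) for k, v in mapped.items()}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- stage: single-sample scoring --------------------------------------
    stage = "score"
    try:
        ob = load_ob_bmst()
        score_sets = {k: v.members for k, v in sigs.items() if v.members}
        scores = setscore.gsva_scores(ex.cpm_log2(mouse), score_sets,
                                      kernel=config.gsva_kernel, tau=config.gsva_tau,
                                      mode=config.gsva_mode)
        write_tsv(scores, out / "gsva_scores.tsv", h)
        summary["score_range"] = [float(scores.values.min()), float(scores.values.max())]
        summary["ob_bmst"] = ob.members
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- stage: proteomic fractions ----------------------------------------
    stage = "prot"
    try:
        abundance = synthetic.default_protein_abundance(
            ref_h, ref_m, seed=config.stage_seed("proteomics"))
        fractions, _ = synthetic.simulate_proteomics(
            ref_h, ref_m, abundance, contamination_rate=0.1, channel_noise_sd=0.1,
            seed=config.stage_seed("proteomics"))
        db = prot.build_combined_db(ref_h, ref_m, config.max_missed, config.min_len,
                                    config.il_equivalent)
        for name, quant in fractions.items():
            table = prot.infer_proteins(quant, db, ref_h.species_label,
                                        ref_m.species_label, min_unique=config.min_unique)
            write_tsv(table, out / f"proteins_{name}.tsv", h)
            counts = prot.species_annotation_counts(quant, db, ref_h.species_label,
                                                    ref_m.species_label)
            summary[f"protein_categories_{name}"] = counts
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- stage: cohort survival --------------------------------------------
    stage = "surv"
    try:
        cohort_truth = synthetic.CohortTruth()
        raw = synthetic.simulate_cohort(cohort_truth, seed=config.stage_seed("cohort"))
        records = survival.derive_endpoints(raw)
        frame = survival.endpoint_frame(records, "clinical_progression")
        cut = survival.maxstat_cutpoint(
            frame["time"], frame["event"], frame["marker"], minprop=config.minprop,
            pmethod=config.maxstat_pmethod, n_perm=min(config.n_perm, 2000),
            seed=config.stage_seed("maxstat"))
        groups = np.where(frame["marker"] > cut.cutpoint, "high", "low")
        chi2, df, p = survival.logrank(frame["time"], frame["event"], groups)
        cox = survival.cox_fit(frame["time"], frame["event"],
                               (frame["marker"] > cut.cutpoint).astype(float),
                               ties=config.cox_ties)
        write_tsv(frame, out / "cohort_clinical_progression.tsv", h)
        summary["maxstat"] = {"cutpoint": round(cut.cutpoint, 3),
                              "statistic": round(cut.statistic, 3),
                              "p_adjusted": round(cut.p_adjusted, 5)}
        summary["logrank"] = {"chi2": round(chi2, 3), "df": df, "p": round(p, 5)}
        summary["cox_hr_high_vs_low"] = round(float(cox.hr[0]), 3)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    if make_plots:
        _make_plots(out, coords, mouse, scores, frame, groups)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_report(out, summary)
    return out


def _write_report(out: Path, summary: dict) -> None:
    lines = ["# xenostroma synthetic run", "",
             f"config hash: `{summary['config_hash']}`  seed: {summary['seed']}", "",
             "## Stroma content (mouse read share)", ""]
    for s, f in summary["stroma_fraction"].items():
        lines.append(f"- {s}: {f}")
    lines += ["", "## Signature extraction", ""]
    for k, v in summary["signature_sizes"].items():
        j = summary["signature_recovery_jaccard"][k]
        lines.append(f"- {k}: {v} genes (truth Jaccard {j})")
    lines += ["", "## Proteomic fraction annotation", ""]
    for key in sorted(k for k in summary if k.startswith("protein_categories")):
        lines.append(f"- {key.split('protein_categories_')[1]}: {summary[key]}")
    lines += ["", "## Cohort survival", "",
              f"- maxstat cutpoint {summary['maxstat']['cutpoint']} "
              f"(|z| = {summary['maxstat']['statistic']}, "
              f"adjusted p = {summary['maxstat']['p_adjusted']})",
              f"- log-rank chi2 {summary['logrank']['chi2']} "
              f"(p = {summary['logrank']['p']})",
              f"- Cox HR (high vs low marker) = {summary['cox_hr_high_vs_low']}", ""]
    (out / "report.md").write_text("\n".join(lines))


def _make_plots(out: Path, coords: pd.DataFrame, mouse: CountMatrix,
                scores: pd.DataFrame, frame: pd.DataFrame, groups: np.ndarray) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for (model, cond), sub in coords.join(mouse.meta).groupby(["model", "condition"]):
        ax.scatter(sub["PC1"], sub["PC2"], label=f"{model}/{cond}", s=25)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=6)
    fig.savefig(out / "pca.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3))
    scores.T.boxplot(ax=ax)
    ax.set_ylabel("enrichment score")
    fig.savefig(out / "scores.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in np.unique(groups):
        km = survival.km_fit(frame["time"][groups == lab], frame["event"][groups == lab])
        ax.step(np.r_[0, km.times], np.r_[1.0, km.survival], where="post", label=lab)
    ax.set_xlabel("months")
    ax.set_ylabel("progression-free probability")
    ax.legend()
    fig.savefig(out / "km.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
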
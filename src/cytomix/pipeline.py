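"""End-to-end orchestration: simulate -> preprocess -> learn -> signature ->
deconvolve -> perturb -> cocktail, with per-stage artifacts and resume.

Glue only: every scientific operation lives in its stage module. Each
artifact is a TSV carrying the configuration hash in its header comment, so
two outputs with equal hashes are bit-identical reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (archetypes, cocktail as cocktail_mod, deconvolution, perturbation,
               preprocess, signature as signature_mod, synthetic)
from .io_formats import SampleMeta, write_results

__all__ = ["RunConfig", "run_workflow"]

log = logging.getLogger("cytomix")


@dataclass
class RunConfig:
    """All stage parameters with their pipeline defaults, plus paths/toggles."""

    outdir: str = "cytomix_run"
    seed: int = 0
    # synthetic fixture (used when no external inputs are supplied)
    n_genes: int = 1000
    n_subpops: int = 6
    n_markers_per_subpop: int = 25
    fold_change: float = 8.0
    n_cells_per_subpop: int = 333
    capture_depth: int = 5000
    screen_noise_sd: float = 0.1
    # preprocess / learn
    n_pca: int = 10
    batch_correct: bool = True
    harmony_theta: float = 2.0
    k_max: int = 30
    prune_threshold: float = 0.6
    resolution: float = 1.0
    n_neighbors: int = 50
    # signature / deconvolution
    alpha: float = 0.01
    min_expression: float = 0.5
    nperm: int = 500
    compute_pvalues: bool = False
    nu_grid: tuple = deconvolution.DEFAULT_NU_GRID
    n_artificial_mixtures: int = 60
    smode: bool = True
    # perturbation / cocktail
    kill_threshold: float = -90.0
    consistency_threshold: float = -80.0
    min_replicates: int = 3
    resume: bool = False

    def config_hash(self) -> str:
        """Fingerprint of the scientific parameters (paths and the resume
        toggle excluded: they do not affect the computed numbers)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        payload.pop("resume")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_done(path: Path, resume: bool) -> bool:
    return resume and path.exists()


def run_workflow(config: RunConfig, truth=None, cells=None, screen=None) -> Path:
    """Execute the full pipeline, writing every intermediate to ``outdir``.

    When ``truth``/``cells``/``screen`` are not supplied, a synthetic
    fixture with the configured sizes is generated (the ``simulate`` stage).
    Returns the artifact directory. Stages whose artifact already exists
    are skipped when ``config.resume`` is set.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    params = {"config_hash": h, "seed": config.seed}
    rng = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(8)]

    # --- simulate ------------------------------------------------------
    if truth is None:
        log.info("stage=simulate generating synthetic ground truth")
        truth = synthetic.make_ground_truth(
            n_genes=config.n_genes, n_subpops=config.n_subpops,
            n_markers_per_subpop=config.n_markers_per_subpop,
            fold_change=config.fold_change, seed=seeds[0],
        )
    if cells is None:
        cells = synthetic.sample_cells(
            truth, n_cells_per_subpop=config.n_cells_per_subpop,
            capture_depth=config.capture_depth, seed=seeds[1],
        )
    if screen is None:
        design = synthetic.ScreenDesign(
            perturbagens=["drugA", "drugB", "drugC", "drugD"],
            doses={"drugA": [0.1, 1.0], "drugB": [0.1, 1.0],
                   "drugC": [0.5, 5.0], "drugD": [0.5, 5.0]},
        )
        truth.kill_rates = synthetic.make_kill_rates(design, truth, seed=seeds[2])
        screen = synthetic.simulate_perturbation_screen(
            truth, design, noise_sd=config.screen_noise_sd, seed=seeds[3],
        )
    screen_bulk, screen_meta, _true_comp = screen

    # --- preprocess + learn -------------------------------------------
    labels_path = out / "subpop_labels.tsv"
    if _stage_done(labels_path, config.resume):
        log.info("stage=learn resuming from %s", labels_path)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0, comment="#")["subpop"]
        cpm = preprocess.cpm_normalize(cells)
    else:
        log.info("stage=preprocess CPM + PCA on %d cells", cells.n_cells)
        cpm = preprocess.cpm_normalize(cells)
        logged = dataclasses.replace(cpm, counts=np.log1p(cpm.counts))
        emb = archetypes.embed_pca(logged, n_components=config.n_pca, seed=seeds[4])
        if config.batch_correct and "batch" in cells.cell_meta.columns and \
                cells.cell_meta["batch"].nunique() > 1:
            log.info("stage=preprocess batch correction over %d batches",
                     cells.cell_meta["batch"].nunique())
            emb = preprocess.correct_batches(
                emb, cells.cell_meta["batch"].to_numpy(),
                theta=config.harmony_theta, seed=seeds[4],
            )
        log.info("stage=learn archetypal analysis k_max=%d", config.k_max)
        model = archetypes.fit_archetypes(emb, k_max=config.k_max, seed=seeds[5])
        model = archetypes.prune_ambiguous_cells(model, config.prune_threshold)
        labels = archetypes.cluster_subpopulations(
            model, n_neighbors=min(config.n_neighbors, model.n_cells - 1),
            resolution=config.resolution, seed=seeds[5],
        )
        labels.to_frame().to_csv(labels_path, sep="\t")
        fp = pd.DataFrame(model.footprints,
                          columns=model.cell_ids).T
        fp.to_csv(out / "footprints.tsv", sep="\t")
        log.info("stage=learn found %d subpopulations / %d archetypes",
                 labels.nunique(), model.n_archetypes)

    # --- signature -----------------------------------------------------
    sig_path = out / "signature.tsv"
    labelled = cpm.subset_cells(np.asarray([c in labels.index for c in cpm.cell_ids]))
    raw_labelled = cells.subset_cells(
        np.asarray([c in labels.index for c in cells.cell_ids]))
    de = signature_mod.wilcoxon_de(labelled, labels, alpha=config.alpha)
    sig = signature_mod.build_signature(labelled, labels, de,
                                        min_expression=config.min_expression,
                                        cells_raw=raw_labelled)
    write_results(sig, sig_path, "signature", params)
    log.info("stage=signature %d genes x %d subpops", len(sig.gene_ids),
             len(sig.subpop_ids))

    # --- deconvolution -------------------------------------------------
    comp_path = out / "compositions.tsv"
    mixtures, mix_fr = deconvolution.make_artificial_mixtures(
        labelled, labels, n_mixtures=config.n_artificial_mixtures, seed=seeds[6])
    bulk_lin = preprocess.cpm_normalize(screen_bulk)
    used_sig = sig
    if config.smode:
        used_sig = deconvolution.smode_adjust(sig, mixtures, mix_fr, bulk_lin)
    comps = deconvolution.deconvolve(bulk_lin, used_sig, nu_grid=config.nu_grid)
    if config.compute_pvalues:
        pos = {g: i for i, g in enumerate(bulk_lin.gene_ids)}
        rows = np.asarray([pos[g] for g in used_sig.gene_ids])
        pvals = [deconvolution.permutation_significance(
                     bulk_lin.values[rows, s], used_sig, n_perm=config.nperm,
                     seed=seeds[7])
                 for s in range(bulk_lin.n_samples)]
        comps.diagnostics["p_value"] = pvals
    write_results(comps, comp_path, "composition", params)
    log.info("stage=deconvolve %d samples decomposed", len(comps.sample_ids))

    # --- perturbation + cocktail --------------------------------------
    sus = perturbation.build_susceptibility_table(
        comps, screen_meta, kill_threshold=config.kill_threshold,
        min_replicates=config.min_replicates)
    write_results(sus, out / "susceptibility.tsv", "susceptibility", params)
    ctl = cocktail_mod.greedy_cocktail(
        sus, kill_threshold=config.kill_threshold,
        consistency_threshold=config.consistency_threshold)
    write_results(ctl, out / "cocktail.tsv", "cocktail", params)
    log.info("stage=cocktail %d selections, residual=%s",
             len(ctl.selections), list(ctl.residual))

    manifest = {"config": dataclasses.asdict(config), "config_hash": h,
                "stages": ["simulate", "preprocess", "learn", "signature",
                            "deconvolve", "perturb", "cocktail"]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
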
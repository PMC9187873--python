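"""Ground-truth simulators for every stage of the pipeline.

The generators emulate the statistical structure the framework assumes:
cells drawn from a small number of subpopulations with disjoint marker
programs, nuisance signal shared across subpopulations (a cell-cycle-like
program and per-batch gene factors), bulk mixtures of known composition
observed through a gene-wise platform shift, and dose-laddered perturbation
screens in which each subpopulation survives a treatment at a known rate.

Everything is a pure function of its parameters and a seed. They do not
model doublets, ambient RNA or zero inflation beyond what multinomial
sampling produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BulkMatrix, CellMatrix, SampleMeta

__all__ = [
    "GroundTruth",
    "ScreenDesign",
    "make_ground_truth",
    "sample_cells",
    "mix_bulk",
    "make_kill_rates",
    "simulate_perturbation_screen",
]


@dataclass
class GroundTruth:
    """True generative parameters shared by all simulators.

    ``profiles`` holds the mean expression of each subpopulation
    (genes x subpops, non-negative, arbitrary linear scale). ``markers``
    maps subpop id -> index array of its up-regulated genes; the sets are
    pairwise disjoint. ``batch_factors`` maps batch label -> gene-wise
    multiplicative vector; ``platform_shift`` is the gene-wise multiplicative
    scRNA -> bulk distortion. ``kill_rates`` (may be None until a screen is
    designed) is indexed by (perturbagen, concentration, time) with one
    survival column per subpop, values in [0, 1].
    """

    profiles: np.ndarray
    gene_ids: list[str]
    subpop_ids: list[str]
    markers: dict[str, np.ndarray]
    fold_change: float
    batch_factors: dict[str, np.ndarray]
    platform_shift: np.ndarray
    seed: int
    kill_rates: pd.DataFrame | None = None

    def __post_init__(self):
        if (self.profiles < 0).any():
            raise ValueError("subpop profiles must be non-negative")
        all_markers = np.concatenate([v for v in self.markers.values()]) if self.markers else []
        if len(all_markers) != len(set(all_markers)):
            raise ValueError("marker sets must be disjoint across subpops")
        if self.kill_rates is not None:
            vals = self.kill_rates.to_numpy(float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError("survival fractions must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_subpops(self) -> int:
        return self.profiles.shape[1]


@dataclass
class ScreenDesign:
    """Layout of a perturbation screen: dose ladders, times, replicates, plates."""

    perturbagens: list[str]
    doses: dict[str, list[float]]  # uM, per perturbagen
    times: list[float] = field(default_factory=lambda: [24.0])
    replicates: int = 3
    controls_per_plate: int = 2
    pcts_per_plate: int = 4

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.controls_per_plate < 1:
            raise ValueError("every plate needs at least one control")

    def pct_pairs(self) -> list[tuple[str, float, float]]:
        out = []
        for pert in self.perturbagens:
            for conc in self.doses[pert]:
                for t in self.times:
                    out.append((pert, float(conc), float(t)))
        return out

    def plate_of(self, pct_index: int) -> str:
        return f"plate{pct_index // self.pcts_per_plate + 1}"


def make_ground_truth(
    n_genes: int = 1000,
    n_subpops: int = 6,
    n_markers_per_subpop: int = 25,
    base_expression_spec: tuple[float, float] = (1.0, 1.0),
    fold_change: float = 8.0,
    batch_spec: dict | None = None,
    platform_spec: float = 0.5,
    seed: int = 0,
) -> GroundTruth:
    """Draw subpopulation mean profiles and nuisance factors.

    Base expression per gene is log-normal with the given (mean, sigma) of
    the underlying normal; each subpopulation's disjoint marker block is
    multiplied by ``fold_change``. ``batch_spec`` is a mapping
    ``{label: {"n_genes": int, "fold": float}}`` describing per-batch
    gene-wise multiplicative programs drawn on non-marker genes (a batch with
    fold 1 or absent from the mapping is the unshifted reference).
    ``platform_spec`` is the sigma of the log-normal gene-wise platform
    shift applied by :func:`mix_bulk`.
    """
    if n_markers_per_subpop * n_subpops > n_genes:
        raise ValueError(
            f"cannot allocate {n_subpops} x {n_markers_per_subpop} disjoint "
            f"markers among {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    mu, sigma = base_expression_spec
    base = rng.lognormal(mean=mu, sigma=sigma, size=n_genes)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    subpop_ids = [f"S{k + 1}" for k in range(n_subpops)]

    marker_pool = rng.permutation(n_genes)
    markers: dict[str, np.ndarray] = {}
    profiles = np.tile(base[:, None], (1, n_subpops))
    for k, sp in enumerate(subpop_ids):
        idx = np.sort(marker_pool[k * n_markers_per_subpop:(k + 1) * n_markers_per_subpop])
        markers[sp] = idx
        profiles[idx, k] *= fold_change

    non_marker = np.setdiff1d(np.arange(n_genes), marker_pool[: n_subpops * n_markers_per_subpop])
    batch_factors: dict[str, np.ndarray] = {}
    for label, spec in (batch_spec or {}).items():
        factor = np.ones(n_genes)
        nb = int(spec.get("n_genes", 0))
        fold = float(spec.get("fold", 1.0))
        if nb > 0 and fold != 1.0:
            chosen = rng.choice(non_marker, size=min(nb, len(non_marker)), replace=False)
            factor[chosen] = fold
        batch_factors[label] = factor

    platform_shift = rng.lognormal(mean=0.0, sigma=platform_spec, size=n_genes)
    return GroundTruth(
        profiles=profiles,
        gene_ids=gene_ids,
        subpop_ids=subpop_ids,
        markers=markers,
        fold_change=fold_change,
        batch_factors=batch_factors,
        platform_shift=platform_shift,
        seed=seed,
    )


def sample_cells(
    truth: GroundTruth,
    n_cells_per_subpop: int = 333,
    capture_depth: int = 5000,
    batches: dict[str, float] | None = None,
    cycle_signal: dict | None = None,
    seed: int = 0,
) -> CellMatrix:
    """Draw single cells multinomially from batch-scaled subpop profiles.

    ``batches`` maps batch label -> probability of a cell belonging to that
    batch (labels must exist in ``truth.batch_factors`` or be the implicit
    unshifted reference); omitted means a single reference batch.
    ``cycle_signal`` plants a shared program in a random subset of cells:
    ``{"n_genes": int, "fold": float, "fraction": float}`` — affected cells
    are labelled phase ``"CYC"``, the rest ``"G1"``. True subpop, batch and
    phase labels are recorded in ``cell_meta``.
    """
    rng = np.random.default_rng(seed)
    n_genes, n_subpops = truth.profiles.shape
    batches = batches or {"batch1": 1.0}
    labels = list(batches)
    probs = np.asarray([batches[b] for b in labels], float)
    probs = probs / probs.sum()
    if truth.batch_factors:
        unknown = [b for b in labels if b not in truth.batch_factors]
        if unknown:
            raise ValueError(f"unknown batch labels {unknown}; "
                             f"known: {sorted(truth.batch_factors)}")

    cyc_genes = None
    cyc_fold = 1.0
    cyc_frac = 0.0
    if cycle_signal:
        if "genes" in cycle_signal:
            gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
            cyc_genes = np.asarray([gene_index[g] if isinstance(g, str) else int(g)
                                    for g in cycle_signal["genes"]])
        else:
            marker_union = np.concatenate(list(truth.markers.values()))
            batch_genes = np.concatenate(
                [np.flatnonzero(f != 1.0) for f in truth.batch_factors.values()]
            ) if truth.batch_factors else np.array([], int)
            free = np.setdiff1d(np.arange(n_genes),
                                np.concatenate([marker_union, batch_genes]))
            cyc_genes = rng.choice(free, size=min(int(cycle_signal["n_genes"]), len(free)),
                                   replace=False)
        cyc_fold = float(cycle_signal["fold"])
        cyc_frac = float(cycle_signal["fraction"])

    counts_cols, cell_ids, meta_rows = [], [], []
    cell_no = 0
    for k, sp in enumerate(truth.subpop_ids):
        base_p = truth.profiles[:, k]
        for _ in range(n_cells_per_subpop):
            batch = labels[rng.choice(len(labels), p=probs)]
            p = base_p * truth.batch_factors.get(batch, 1.0)
            phase = "G1"
            if cyc_genes is not None and rng.random() < cyc_frac:
                p = p.copy()
                p[cyc_genes] *= cyc_fold
                phase = "CYC"
            p = p / p.sum()
            counts_cols.append(rng.multinomial(capture_depth, p))
            cell_ids.append(f"cell{cell_no:05d}")
            meta_rows.append({"subpop": sp, "batch": f"{batch}_{phase}",
                              "clone": batch, "phase": phase})
            cell_no += 1
    counts = np.stack(counts_cols, axis=1).astype(float)
    meta = pd.DataFrame(meta_rows, index=pd.Index(cell_ids))
    return CellMatrix(counts, truth.gene_ids, cell_ids, meta)


def mix_bulk(
    truth: GroundTruth,
    fraction_matrix: np.ndarray | pd.DataFrame,
    depth: float = 1e6,
    noise_sd: float = 0.0,
    apply_platform_shift: bool = True,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> tuple[BulkMatrix, pd.DataFrame]:
    """Mix subpop profiles into bulk samples with known fractions.

    Each sample's expected value is the fraction-weighted sum of subpop
    profiles, gene-wise multiplied by the platform-shift vector when
    enabled, then perturbed by multiplicative log-normal noise of the given
    sd (in log space), and scaled so columns sum to ``depth``.
    """
    F = np.asarray(fraction_matrix, dtype=float)
    if F.ndim != 2 or F.shape[1] != truth.n_subpops:
        raise ValueError("fraction matrix must be samples x n_subpops")
    if (F < 0).any() or not np.allclose(F.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("fraction rows must be non-negative and sum to 1 within 1e-8")
    rng = np.random.default_rng(seed)
    expected = truth.profiles @ F.T  # genes x samples
    if apply_platform_shift:
        expected = expected * truth.platform_shift[:, None]
    if noise_sd > 0:
        expected = expected * rng.lognormal(mean=0.0, sigma=noise_sd, size=expected.shape)
    expected = expected * (depth / expected.sum(axis=0, keepdims=True))
    if sample_ids is None:
        sample_ids = [f"bulk{i:03d}" for i in range(F.shape[0])]
    bulk = BulkMatrix(expected, truth.gene_ids, sample_ids, scale="linear")
    fr = pd.DataFrame(F, index=pd.Index(sample_ids), columns=truth.subpop_ids)
    return bulk, fr


def make_kill_rates(
    design: ScreenDesign,
    truth: GroundTruth,
    seed: int = 0,
    p_resistant: float = 0.35,
    hill_slope: float = 2.0,
) -> pd.DataFrame:
    """Draw a dose-monotone survival table for every (PCT, subpop) cell.

    Per (perturbagen, subpop) a coin decides resistance: resistant
    subpopulations survive near-fully at every dose; susceptible ones follow
    a Hill-type survival curve ``1 / (1 + (c / EC50)^slope)`` with a random
    EC50 drawn log-uniformly between a quarter of the lowest and half of
    the highest dose, floored to exactly 0 at doses at least 8 x EC50 so
    the screen contains complete kills. Survival is non-increasing in dose
    by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    for pert in design.perturbagens:
        resist = rng.random(truth.n_subpops) < p_resistant
        ladder = np.asarray(design.doses[pert], float)
        ec50 = np.exp(rng.uniform(np.log(ladder.min() / 4.0), np.log(ladder.max() / 2.0),
                                  size=truth.n_subpops))
        for conc in design.doses[pert]:
            for t in design.times:
                surv = np.where(
                    resist,
                    1.0,
                    1.0 / (1.0 + (conc / ec50) ** hill_slope),
                )
                surv = np.where(~resist & (conc >= 8.0 * ec50), 0.0, surv)
                rows.append(surv)
                index.append((pert, float(conc), float(t)))
    idx = pd.MultiIndex.from_tuples(index, names=["perturbagen", "concentration", "time"])
    return pd.DataFrame(np.asarray(rows), index=idx, columns=truth.subpop_ids)


def simulate_perturbation_screen(
    truth: GroundTruth,
    design: ScreenDesign,
    baseline: np.ndarray | None = None,
    noise_sd: float = 0.05,
    apply_platform_shift: bool = True,
    seed: int = 0,
) -> tuple[BulkMatrix, SampleMeta, pd.DataFrame]:
    """Generate the bulk profiles of a dose-laddered perturbation screen.

    Control samples carry the baseline composition; a treated sample's true
    composition is ``baseline * survival`` renormalized (survival acts on
    relative composition, not absolute cell number). Every replicate is an
    independent :func:`mix_bulk` draw; each plate carries its own controls.
    Returns the bulk matrix, sample metadata, and the true per-sample
    compositions (including controls).
    """
    if truth.kill_rates is None:
        raise ValueError("truth.kill_rates is not set; use make_kill_rates first")
    if baseline is None:
        baseline = np.full(truth.n_subpops, 1.0 / truth.n_subpops)
    baseline = np.asarray(baseline, float)
    baseline = baseline / baseline.sum()

    pcts = design.pct_pairs()
    for pct in pcts:
        if pct not in truth.kill_rates.index:
            raise ValueError(f"missing kill-rate entry for PCT {pct}")

    rng = np.random.default_rng(seed)
    frac_rows, ids, meta_rows = [], [], []
    plates_done = set()
    for i, (pert, conc, t) in enumerate(pcts):
        plate = design.plate_of(i)
        if plate not in plates_done:
            plates_done.add(plate)
            for c in range(design.controls_per_plate):
                ids.append(f"{plate}_ctrl{c + 1}")
                frac_rows.append(baseline)
                meta_rows.append({"perturbagen": "DMSO", "concentration": 0.0,
                                  "time": t, "plate": plate, "is_control": True})
        surv = truth.kill_rates.loc[(pert, conc, t)].to_numpy(float)
        post = baseline * surv
        total = post.sum()
        if total <= 0:
            raise ValueError(f"all subpopulations killed at {pert} {conc} uM {t} h; "
                             "composition undefined")
        post = post / total
        for r in range(design.replicates):
            ids.append(f"{pert}_{conc}uM_{t}h_rep{r + 1}")
            frac_rows.append(post)
            meta_rows.append({"perturbagen": pert, "concentration": conc,
                              "time": t, "plate": plate, "is_control": False})

    F = np.asarray(frac_rows)
    bulk, fractions = mix_bulk(
        truth, F, noise_sd=noise_sd, apply_platform_shift=apply_platform_shift,
        seed=int(rng.integers(2**31)), sample_ids=ids,
    )
    meta = SampleMeta(pd.DataFrame(meta_rows, index=pd.Index(ids)))
    return bulk, meta, fractions
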
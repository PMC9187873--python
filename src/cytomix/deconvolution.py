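"""Regression-based digital cytometry with cross-platform adjustment.

Fraction estimation follows the nu-support-vector-regression convention:
per bulk sample, the standardized observed profile is regressed on the
standardized signature columns for each nu in a small grid, the best fit by
reconstruction RMSE is kept, negative coefficients are clamped and the rest
renormalized to the simplex. Cross-platform (single-cell vs bulk) technical
variation is handled beforehand in the style of S-mode: artificial mixtures
of known composition are drawn from the labelled cells, their per-gene
location and scale are matched to the real bulk, and an adjusted signature
is re-derived from the corrected mixtures by non-negative least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.svm import NuSVR

from .io_formats import BulkMatrix, CellMatrix
from .signature import SignatureMatrix

__all__ = [
    "CompositionTable",
    "make_artificial_mixtures",
    "smode_adjust",
    "deconvolve",
    "permutation_significance",
    "DEFAULT_NU_GRID",
]

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class CompositionTable:
    """Samples x subpopulations fraction estimates plus per-sample diagnostics.

    ``fractions`` rows lie on the simplex. ``diagnostics`` carries the fit
    RMSE, the Pearson correlation between reconstructed and observed
    standardized profiles, and (when computed) the permutation p-value.
    """

    fractions: pd.DataFrame
    diagnostics: pd.DataFrame | None = None

    def __post_init__(self):
        vals = self.fractions.to_numpy(float)
        if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
            raise ValueError("fractions must lie in [0, 1]")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("fraction rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def subpop_ids(self) -> list[str]:
        return list(self.fractions.columns)


def make_artificial_mixtures(
    cells_cpm: CellMatrix,
    labels,
    n_mixtures: int = 60,
    cells_per_mixture: int = 200,
    seed: int = 0,
    fractions: np.ndarray | None = None,
) -> tuple[BulkMatrix, pd.DataFrame]:
    """Mix labelled single cells into pseudo-bulk samples of known fractions.

    Compositions are drawn from a flat Dirichlet over the subpopulations
    (or supplied via ``fractions``); cells are sampled with replacement
    accordingly, their CPM profiles summed and renormalized to CPM.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(cells_cpm.cell_ids).to_numpy()
    labels = np.asarray(labels)
    subpops = sorted(pd.unique(labels), key=str)
    k = len(subpops)
    if n_mixtures < k:
        warnings.warn(f"n_mixtures={n_mixtures} < {k} subpopulations; the "
                      "signature adjustment may be rank-deficient", stacklevel=2)
    rng = np.random.default_rng(seed)
    by_sp = {sp: np.flatnonzero(labels == sp) for sp in subpops}
    for sp, idx in by_sp.items():
        if len(idx) == 0:
            raise ValueError(f"subpopulation {sp!r} has no cells")

    if fractions is None:
        F = rng.dirichlet(np.ones(k), size=n_mixtures)
    else:
        F = np.asarray(fractions, float)
        n_mixtures = F.shape[0]
    cols = []
    for s in range(n_mixtures):
        n_per = rng.multinomial(cells_per_mixture, F[s])
        profile = np.zeros(cells_cpm.n_genes)
        for sp, n_sp in zip(subpops, n_per):
            if n_sp == 0:
                continue
            chosen = rng.choice(by_sp[sp], size=n_sp, replace=True)
            profile += cells_cpm.counts[:, chosen].sum(axis=1)
        cols.append(profile * (1e6 / profile.sum()))
    ids = [f"mix{s:03d}" for s in range(n_mixtures)]
    bulk = BulkMatrix(np.stack(cols, axis=1), cells_cpm.gene_ids, ids,
                      scale="linear-normalized")
    return bulk, pd.DataFrame(F, index=pd.Index(ids), columns=[str(s) for s in subpops])


def _log_joint_mean_composition(S: np.ndarray, R: np.ndarray,
                                max_nfev: int = 200) -> np.ndarray:
    """Mean composition of the real bulk, estimated free of platform bias.

    Fits all samples' fractions jointly by least squares on double-centered
    log expression: a gene-wise multiplicative platform factor adds a
    per-gene constant in log space and a library-size difference adds a
    per-sample constant, so both cancel under double centering. Fractions
    are parameterized through a softmax to stay on the simplex.
    """
    m, n = R.shape
    k = S.shape[1]
    eps = 1e-6
    L = np.log(R + eps)
    Lc = L - L.mean(1, keepdims=True) - L.mean(0, keepdims=True) + L.mean()

    def unpack(theta):
        W = theta.reshape(n, k)
        E = np.exp(W - W.max(1, keepdims=True))
        return E / E.sum(1, keepdims=True)

    def resid(theta):
        P = np.log(S @ unpack(theta).T + eps)
        Pc = P - P.mean(1, keepdims=True) - P.mean(0, keepdims=True) + P.mean()
        return (Pc - Lc).ravel()

    sol = scipy.optimize.least_squares(resid, np.zeros(n * k), method="lm",
                                       max_nfev=max_nfev)
    return unpack(sol.x).mean(axis=0)


def smode_adjust(
    signature: SignatureMatrix,
    artificial_mixtures: BulkMatrix,
    artificial_fractions: pd.DataFrame,
    real_bulk: BulkMatrix,
    prior_weight: float = 4.0,
) -> SignatureMatrix:
    """Re-derive the signature on the real platform's scale (S-mode style).

    Genes are intersected across signature, mixtures and real bulk. The
    cross-platform batch effect is modelled as a gene-wise multiplicative
    factor: the real bulk's mean composition is first estimated jointly in
    double-centered log space (where the platform factor cancels; see
    :func:`_log_joint_mean_composition`), the factor is then the ratio of
    each gene's observed bulk mean to the mixture-side expectation at that
    composition, the artificial mixtures are rescaled onto the real
    platform with it, and the adjusted signature is re-solved per gene from
    the corrected mixtures and their known fractions by non-negative least
    squares. Per-gene location/scale moment matching was deliberately
    avoided: with desk-scale bulk cohorts the per-gene moments are
    dominated by the composition sampling noise of the cohort, which this
    estimator cancels by construction.
    """
    if real_bulk.scale == "log2":
        raise ValueError("real bulk must be de-logged before S-mode adjustment")
    shared = [g for g in signature.gene_ids
              if g in set(artificial_mixtures.gene_ids) and g in set(real_bulk.gene_ids)]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared across signature, mixtures "
                         "and bulk; need >= 10")
    mix_pos = {g: i for i, g in enumerate(artificial_mixtures.gene_ids)}
    bulk_pos = {g: i for i, g in enumerate(real_bulk.gene_ids)}
    sig_pos = {g: i for i, g in enumerate(signature.gene_ids)}
    M = artificial_mixtures.values[[mix_pos[g] for g in shared], :]
    Rb = real_bulk.values[[bulk_pos[g] for g in shared], :]
    S = signature.values[[sig_pos[g] for g in shared], :]

    F = artificial_fractions.reindex(columns=signature.subpop_ids).to_numpy(float)
    if np.isnan(F).any():
        raise ValueError("artificial fractions do not cover the signature subpops")

    fbar_real = _log_joint_mean_composition(S, Rb)
    e_real = S @ fbar_real                      # single-cell-platform expectation
    m_r = Rb.mean(axis=1)
    alpha = np.where(e_real > 0, m_r / np.where(e_real > 0, e_real, 1.0), 1.0)

    # rescale mixtures onto the real platform: their own per-gene level is
    # m_a ~ S @ fbar_mix, the target level alpha * (S @ fbar_mix)
    m_a = M.mean(axis=1)
    e_mix = S @ F.mean(axis=0)
    factor = alpha * np.where(m_a > 0, e_mix / np.where(m_a > 0, m_a, 1.0), 1.0)
    M_corr = M * factor[:, None]

    # per-gene NNLS from corrected mixtures and known fractions, shrunk
    # toward the anchored signature alpha*S: the anchor carries no
    # mixture-sampling noise, so the shrinkage keeps repeated runs with
    # different mixture draws essentially identical
    P, k = F.shape
    w = np.sqrt(prior_weight * P / k)
    A = np.vstack([F, w * np.eye(k)])
    prior = S * alpha[:, None]
    adjusted = np.empty((len(shared), k))
    for g in range(len(shared)):
        b = np.concatenate([M_corr[g], w * prior[g]])
        adjusted[g], _ = scipy.optimize.nnls(A, b)
    nonzero = adjusted.sum(axis=1) > 0
    return SignatureMatrix(
        adjusted[nonzero],
        [g for g, nz in zip(shared, nonzero) if nz],
        signature.subpop_ids,
        provenance={**(signature.provenance or {}), "smode": True},
    )


def _fit_sample(y_std: np.ndarray, X_std: np.ndarray, nu_grid) -> tuple[np.ndarray, float, float]:
    """Best nu-SVR fit of one standardized sample; returns (coef, rmse, corr)."""
    best = None
    for nu in nu_grid:
        model = NuSVR(nu=nu, C=1.0, kernel="linear", tol=1e-6)
        model.fit(X_std, y_std)
        coef = model.coef_.ravel()
        recon = X_std @ coef + model.intercept_[0]
        rmse = float(np.sqrt(np.mean((recon - y_std) ** 2)))
        if best is None or rmse < best[1]:
            sd = recon.std()
            corr = float(np.corrcoef(recon, y_std)[0, 1]) if sd > 0 else 0.0
            best = (coef, rmse, corr)
    return best


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def deconvolve(
    bulk: BulkMatrix,
    signature: SignatureMatrix,
    nu_grid=DEFAULT_NU_GRID,
) -> CompositionTable:
    """Estimate subpopulation fractions per bulk sample by nu-SVR.

    The bulk must be on linear scale. Signature genes are intersected with
    the bulk (warning below 50% coverage); sample and signature columns are
    z-standardized over the shared genes; for each nu in the grid a linear
    nu-SVR is fitted and the lowest-RMSE fit kept; negative coefficients
    are clamped to zero and the rest normalized to sum 1. Output is
    invariant to positive rescaling of the bulk.
    """
    if bulk.scale == "log2":
        raise ValueError("refusing to deconvolve a log2-scaled matrix; delog first")
    bulk_pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    shared = [g for g in signature.gene_ids if g in bulk_pos]
    if len(shared) < max(2, len(signature.subpop_ids)):
        raise ValueError("too few signature genes present in bulk")
    if len(shared) < 0.5 * len(signature.gene_ids):
        warnings.warn(
            f"only {len(shared)}/{len(signature.gene_ids)} signature genes found in "
            "bulk; estimates may be degraded", stacklevel=2)
    sig_pos = {g: i for i, g in enumerate(signature.gene_ids)}
    S = signature.values[[sig_pos[g] for g in shared], :]
    B = bulk.values[[bulk_pos[g] for g in shared], :]
    # the signature is standardized by its global mean/sd so the relative
    # scale of the subpop columns is preserved; each sample separately
    X_std = (S - S.mean()) / S.std()

    rows, diags = [], []
    for s in range(bulk.n_samples):
        y_std = _standardize(B[:, s])
        coef, rmse, corr = _fit_sample(y_std, X_std, nu_grid)
        f = np.maximum(coef, 0.0)
        if f.sum() == 0:
            warnings.warn(f"sample {bulk.sample_ids[s]!r}: all coefficients <= 0; "
                          "returning uniform fractions", stacklevel=2)
            f = np.ones_like(f)
            corr = 0.0
        rows.append(f / f.sum())
        diags.append({"rmse": rmse, "r": corr})
    fractions = pd.DataFrame(np.stack(rows), index=pd.Index(bulk.sample_ids),
                             columns=signature.subpop_ids)
    diagnostics = pd.DataFrame(diags, index=fractions.index)
    return CompositionTable(fractions, diagnostics)


def permutation_significance(
    sample_values: np.ndarray,
    signature: SignatureMatrix,
    n_perm: int = 500,
    seed: int = 0,
    nu_grid=DEFAULT_NU_GRID,
) -> float:
    """Permutation p-value for one sample's deconvolution fit.

    The null distribution of the reconstruction correlation is built by
    shuffling the sample's gene values ``n_perm`` times and re-fitting;
    p = (1 + #{null >= observed}) / (n_perm + 1), so p is always within
    [1/(n_perm+1), 1].
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    y = np.asarray(sample_values, float)
    if y.shape[0] != len(signature.gene_ids):
        raise ValueError("sample must be aligned to the signature gene set")
    X_std = (signature.values - signature.values.mean()) / signature.values.std()
    _, _, obs = _fit_sample(_standardize(y), X_std, nu_grid)
    null_ge = 0
    for _ in range(n_perm):
        _, _, corr = _fit_sample(_standardize(rng.permutation(y)), X_std, nu_grid)
        if corr >= obs:
            null_ge += 1
    return (1 + null_ge) / (n_perm + 1)
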
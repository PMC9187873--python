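"""Per-subpopulation drug susceptibility, consistency and heterogeneity.

The susceptibility of subpopulation k under a perturbagen-concentration-
time (PCT) condition with replicate set P is

    S_k = 100 / |P| * sum_{j in P} (TC_{j,k} - CbarC_k) / (TC_{j,k} + CbarC_k)

where TC_j is the estimated composition of treated replicate j and CbarC
the average composition of control samples from the same detection plates.
Each replicate's term lies in [-1, 1], so S_k is bounded by [-100, 100]%;
a subpopulation completely absent after treatment scores exactly -100%.
Consistency is the median susceptibility of the same drug at strictly
higher doses (same time point by default) — a reproducibility guard; a
subpopulation is called "killed" when its susceptibility is strictly below
the kill threshold (-90% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolution import CompositionTable
from .io_formats import SampleMeta

__all__ = [
    "SusceptibilityTable",
    "average_plate_controls",
    "susceptibility",
    "consistency",
    "classify_killed",
    "shannon_entropy",
    "build_susceptibility_table",
]


@dataclass
class SusceptibilityTable:
    """Rows keyed by (perturbagen, concentration, time); one block of columns
    per statistic: susceptibility %, consistency % (NaN when no higher dose
    exists), killed flags, replicate count and plates used for the control
    average."""

    susceptibility: pd.DataFrame  # PCT x subpop, percent
    consistency: pd.DataFrame     # PCT x subpop, percent, NaN = undefined
    killed: pd.DataFrame          # PCT x subpop, bool
    n_replicates: pd.Series
    plates: pd.Series
    kill_threshold: float = -90.0

    def __post_init__(self):
        vals = self.susceptibility.to_numpy(float)
        if (vals < -100 - 1e-9).any() or (vals > 100 + 1e-9).any():
            raise ValueError("susceptibility must lie within [-100, 100]")

    @property
    def subpop_ids(self) -> list[str]:
        return list(self.susceptibility.columns)

    def to_frame(self) -> pd.DataFrame:
        sus = self.susceptibility.add_prefix("sus_")
        con = self.consistency.add_prefix("con_")
        kil = self.killed.add_prefix("killed_")
        out = pd.concat([sus, con, kil], axis=1)
        out["n_replicates"] = self.n_replicates
        out["plates"] = self.plates
        return out


def average_plate_controls(compositions: CompositionTable, meta: SampleMeta) -> pd.DataFrame:
    """Mean control composition per plate, renormalized to the simplex."""
    ctrl = meta.controls()
    treated_plates = set(meta.treated()["plate"])
    missing = treated_plates - set(ctrl["plate"])
    if missing:
        raise ValueError(f"plates without control samples: {sorted(missing)}")
    fr = compositions.fractions
    rows = {}
    for plate, grp in ctrl.groupby("plate"):
        mean = fr.loc[[s for s in grp.index if s in fr.index]].mean(axis=0)
        rows[plate] = mean / mean.sum()
    return pd.DataFrame(rows).T


def susceptibility(treated_rows, control_mean) -> np.ndarray:
    """The replicate-averaged normalized-difference statistic, in percent.

    ``treated_rows`` is |P| x k (one row per replicate), ``control_mean``
    length k. The degenerate 0/0 term (subpopulation absent in both
    treated replicate and control) contributes 0 — the limit along
    TC = CbarC -> 0, which keeps the TC = CbarC identity exact.
    """
    TC = np.atleast_2d(np.asarray(treated_rows, float))
    CC = np.asarray(control_mean, float)
    if (TC < 0).any() or (CC < 0).any():
        raise ValueError("compositions must be non-negative")
    num = TC - CC[None, :]
    den = TC + CC[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return 100.0 * terms.mean(axis=0)


def consistency(sus_table: pd.DataFrame, pct_key: tuple, across_time: bool = False) -> pd.Series:
    """Median susceptibility of the same drug at strictly higher doses.

    ``sus_table`` is indexed by (perturbagen, concentration, time). By
    default only PCTs at the same time point count; ``across_time`` relaxes
    that. Returns NaN per subpopulation when no higher dose exists.
    """
    pert, conc, time = pct_key
    idx = sus_table.index.to_frame(index=False)
    mask = (idx["perturbagen"] == pert) & (idx["concentration"] > conc)
    if not across_time:
        mask &= idx["time"] == time
    if not mask.any():
        return pd.Series(np.nan, index=sus_table.columns)
    return sus_table.loc[mask.to_numpy()].median(axis=0)


def classify_killed(sus, threshold: float = -90.0):
    """Killed iff susceptibility is strictly below the threshold."""
    return sus < threshold


def shannon_entropy(fractions) -> float:
    """Shannon entropy of a composition, in bits (0 log 0 = 0)."""
    f = np.asarray(fractions, float)
    if (f < 0).any() or not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("fractions must be a simplex row")
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


def build_susceptibility_table(
    compositions: CompositionTable,
    meta: SampleMeta,
    kill_threshold: float = -90.0,
    min_replicates: int = 3,
    across_time: bool = False,
) -> SusceptibilityTable:
    """Compose control averaging, susceptibility, consistency and kill calls.

    PCT conditions with fewer than ``min_replicates`` replicates are
    dropped (the pipeline default of 3 mirrors the replicate filter applied
    to screen data).
    """
    cbar = average_plate_controls(compositions, meta)
    fr = compositions.fractions
    treated = meta.treated()

    rows, reps, plates, index = [], [], [], []
    for (pert, conc, time), grp in treated.groupby(
            ["perturbagen", "concentration", "time"], sort=True):
        sample_ids = [s for s in grp.index if s in fr.index]
        if len(sample_ids) < min_replicates:
            continue
        used_plates = sorted(set(grp.loc[sample_ids, "plate"]))
        cc = cbar.loc[used_plates].mean(axis=0)
        cc = cc / cc.sum()
        rows.append(susceptibility(fr.loc[sample_ids].to_numpy(), cc.to_numpy()))
        reps.append(len(sample_ids))
        plates.append(",".join(str(p) for p in used_plates))
        index.append((pert, float(conc), float(time)))
    if not rows:
        raise ValueError("no PCT condition meets the replicate minimum")
    idx = pd.MultiIndex.from_tuples(index, names=["perturbagen", "concentration", "time"])
    sus = pd.DataFrame(np.stack(rows), index=idx, columns=fr.columns)
    con = pd.DataFrame(
        {pct: consistency(sus, pct, across_time=across_time) for pct in sus.index}
    ).T
    con.index = idx
    killed = classify_killed(sus, kill_threshold)
    return SusceptibilityTable(
        sus, con, killed,
        n_replicates=pd.Series(reps, index=idx),
        plates=pd.Series(plates, index=idx),
        kill_threshold=kill_threshold,
    )
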
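"""Greedy search for a minimal drug cocktail covering all killable subpops.

Each iteration selects the perturbagen-concentration-time (PCT) condition
that kills the greatest number of still-surviving subpopulations, where a
kill requires susceptibility strictly below the kill threshold and the
per-subpopulation consistency (median susceptibility at higher doses of the
same drug) at or below the consistency threshold. Ties are broken by lowest
concentration, then shortest time, then lexicographic perturbagen id. The
selected condition's killed subpopulations and every PCT of the selected
perturbagen are removed, and the loop repeats until no condition kills
anything. Greedy cover is not guaranteed minimal; the classical ln(n)
approximation bound applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .perturbation import SusceptibilityTable

__all__ = ["Cocktail", "CocktailSelection", "greedy_cocktail"]


@dataclass(frozen=True)
class CocktailSelection:
    perturbagen: str
    concentration: float
    time: float
    killed_subpops: tuple[str, ...]
    susceptibility: dict
    consistency: dict


@dataclass
class Cocktail:
    """Ordered PCT selections with their credited kill sets and the residual
    (subpopulations no eligible condition could kill)."""

    selections: list[CocktailSelection]
    residual: tuple[str, ...]
    all_subpops: tuple[str, ...]

    def __post_init__(self):
        perts = [s.perturbagen for s in self.selections]
        if len(perts) != len(set(perts)):
            raise ValueError("a perturbagen may appear only once in a cocktail")
        credited: set[str] = set()
        for s in self.selections:
            if credited & set(s.killed_subpops):
                raise ValueError("credited kill sets must be disjoint")
            credited |= set(s.killed_subpops)
        if credited | set(self.residual) != set(self.all_subpops):
            raise ValueError("kill sets plus residual must cover all subpops")

    @property
    def killed_union(self) -> set:
        return {sp for s in self.selections for sp in s.killed_subpops}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "perturbagen": s.perturbagen,
                "concentration": s.concentration,
                "time": s.time,
                "killed_subpops": ",".join(s.killed_subpops),
            }
            for s in self.selections
        ]
        df = pd.DataFrame(rows, columns=["perturbagen", "concentration", "time",
                                         "killed_subpops"])
        df.index.name = "step"
        return df


def _eligible_kills(sus_row: pd.Series, con_row: pd.Series, remaining: list[str],
                    kill_threshold: float, consistency_threshold: float,
                    strict_consistency: bool) -> tuple[str, ...]:
    """Subpops this PCT is allowed to claim: kill gate is strict (<), the
    consistency gate inclusive (<=). An undefined consistency (highest dose
    of its drug) passes via the condition's own susceptibility unless
    ``strict_consistency`` makes it failing."""
    out = []
    for sp in remaining:
        s = sus_row[sp]
        if not s < kill_threshold:
            continue
        c = con_row[sp]
        if pd.isna(c):
            if strict_consistency:
                continue
            c = s  # own susceptibility as surrogate at the highest dose
        if c <= consistency_threshold:
            out.append(sp)
    return tuple(out)


def greedy_cocktail(
    table: SusceptibilityTable,
    kill_threshold: float = -90.0,
    consistency_threshold: float = -80.0,
    strict_consistency: bool = False,
) -> Cocktail:
    """Run the greedy selection loop over a susceptibility table."""
    subpops = list(table.subpop_ids)
    sus, con = table.susceptibility, table.consistency
    remaining = list(subpops)
    available = list(sus.index)
    selections: list[CocktailSelection] = []

    while remaining and available:
        best_key, best_kills = None, ()
        for key in available:
            kills = _eligible_kills(sus.loc[key], con.loc[key], remaining,
                                    kill_threshold, consistency_threshold,
                                    strict_consistency)
            if not kills:
                continue
            if best_key is None or _beats(key, len(kills), best_key, len(best_kills)):
                best_key, best_kills = key, kills
        if best_key is None:
            break
        pert, conc, time = best_key
        selections.append(CocktailSelection(
            perturbagen=str(pert),
            concentration=float(conc),
            time=float(time),
            killed_subpops=best_kills,
            susceptibility={sp: float(sus.loc[best_key, sp]) for sp in best_kills},
            consistency={sp: (None if pd.isna(con.loc[best_key, sp])
                              else float(con.loc[best_key, sp])) for sp in best_kills},
        ))
        remaining = [sp for sp in remaining if sp not in best_kills]
        available = [k for k in available if k[0] != pert]

    return Cocktail(selections, tuple(remaining), tuple(subpops))


def _beats(key, n_kills, best_key, best_n) -> bool:
    """Full tie-break chain: kill count desc, concentration asc, time asc,
    perturbagen id lexicographic asc."""
    a = (-n_kills, float(key[1]), float(key[2]), str(key[0]))
    b = (-best_n, float(best_key[1]), float(best_key[2]), str(best_key[0]))
    return a < b
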
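"""Greedy cocktail search against an independently coded oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import cytomix as cm
from cytomix.perturbation import SusceptibilityTable, classify_killed


def make_table(rows, subpops):
    """rows: {(pert, conc, time): {"sus": {...}, "con": {...}}}"""
    idx = pd.MultiIndex.from_tuples(list(rows),
                                    names=["perturbagen", "concentration", "time"])
    sus = pd.DataFrame([[rows[k]["sus"].get(sp, 0.0) for sp in subpops] for k in rows],
                       index=idx, columns=subpops)
    con = pd.DataFrame([[rows[k].get("con", {}).get(sp, np.nan) for sp in subpops]
                        for k in rows], index=idx, columns=subpops)
    return SusceptibilityTable(sus, con, classify_killed(sus),
                               n_replicates=pd.Series(3, index=idx),
                               plates=pd.Series("p", index=idx))


def oracle(table, kill=-90.0, cons=-80.0, strict=False):
    """Independent re-implementation with plain dict/loop machinery."""
    sus = {k: dict(v) for k, v in table.susceptibility.iterrows()}
    con = {k: dict(v) for k, v in table.consistency.iterrows()}
    remaining = set(table.subpop_ids)
    avail = list(sus)
    picks = []
    while True:
        best = None
        for key in avail:
            kills = []
            for sp in sorted(remaining, key=str):
                s = sus[key][sp]
                if not (s < kill):
                    continue
                c = con[key][sp]
                if c != c:  # NaN: undefined consistency
                    if strict:
                        continue
                    c = s
                if c <= cons:
                    kills.append(sp)
            if kills:
                rank = (-len(kills), float(key[1]), float(key[2]), str(key[0]))
                if best is None or rank < best[0]:
                    best = (rank, key, kills)
        if best is None:
            break
        _, key, kills = best
        picks.append((key, tuple(sorted(kills, key=str))))
        remaining -= set(kills)
        avail = [k for k in avail if k[0] != key[0]]
    return picks, tuple(sorted(remaining, key=str))


def random_instance(rng):
    n_subpops = int(rng.integers(2, 7))
    subpops = [f"P{i}" for i in range(n_subpops)]
    n_drugs = int(rng.integers(1, 6))
    rows = {}
    for d in range(n_drugs):
        doses = sorted(rng.choice([0.1, 0.5, 1.0, 5.0, 10.0],
                                  size=int(rng.integers(1, 5)), replace=False))
        times = rng.choice([6.0, 24.0], size=int(rng.integers(1, 3)), replace=False)
        for conc in doses:
            for t in times:
                sus = {sp: float(rng.uniform(-100, 20)) for sp in subpops}
                con = {sp: (float(rng.uniform(-100, 0)) if rng.random() < 0.7
                            else np.nan) for sp in subpops}
                rows[(f"d{d}", float(conc), float(t))] = {"sus": sus, "con": con}
        if len(rows) >= 20:
            break
    return make_table(rows, subpops)


class TestGreedyExamples:
    def test_empty_table_empty_cocktail(self):
        tbl = make_table({("d", 1.0, 24.0): {"sus": {"A": 0.0}, "con": {}}},
                         ["A"])
        out = cm.greedy_cocktail(tbl)
        assert out.selections == []
        assert out.residual == ("A",)

    def test_worked_two_drug_example(self):
        """alpha@10 kills {A,B,C} and wins; alpha@1 leaves with its drug;
        beta@0.5 then takes D."""
        subpops = ["A", "B", "C", "D"]
        ok = {sp: -95.0 for sp in subpops}
        rows = {
            ("alpha", 1.0, 24.0): {"sus": {"A": -95, "B": -95, "C": 0, "D": 0},
                                   "con": ok},
            ("alpha", 10.0, 24.0): {"sus": {"A": -99, "B": -97, "C": -95, "D": 0},
                                    "con": ok},
            ("beta", 0.5, 24.0): {"sus": {"A": 0, "B": 0, "C": 0, "D": -95},
                                  "con": ok},
        }
        out = cm.greedy_cocktail(make_table(rows, subpops))
        assert [(s.perturbagen, s.concentration) for s in out.selections] == \
            [("alpha", 10.0), ("beta", 0.5)]
        assert out.selections[0].killed_subpops == ("A", "B", "C")
        assert out.residual == ()

    def test_consistency_gate_blocks_unreliable_kill(self):
        rows = {
            ("d", 1.0, 24.0): {"sus": {"A": -95.0}, "con": {"A": -50.0}},
        }
        out = cm.greedy_cocktail(make_table(rows, ["A"]))
        assert out.selections == []

    def test_undefined_consistency_passes_by_default(self):
        rows = {("d", 1.0, 24.0): {"sus": {"A": -95.0}, "con": {}}}
        tbl = make_table(rows, ["A"])
        assert len(cm.greedy_cocktail(tbl).selections) == 1
        assert cm.greedy_cocktail(tbl, strict_consistency=True).selections == []


class TestGreedyOracle:
    def test_matches_independent_oracle_on_200_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            tbl = random_instance(rng)
            ours = cm.greedy_cocktail(tbl)
            picks, residual = oracle(tbl)
            got = [((s.perturbagen, s.concentration, s.time),
                    tuple(sorted(s.killed_subpops, key=str)))
                   for s in ours.selections]
            assert got == picks
            assert tuple(sorted(ours.residual, key=str)) == residual
            # termination invariant: no PCT of an unselected drug can kill a
            # residual subpop (a residual may still be killable by a removed
            # dose of a drug that was selected at another dose)
            used = {s.perturbagen for s in ours.selections}
            for key in tbl.susceptibility.index:
                if key[0] in used:
                    continue
                for sp in ours.residual:
                    s = tbl.susceptibility.loc[key, sp]
                    c = tbl.consistency.loc[key, sp]
                    if pd.isna(c):
                        c = s
                    assert not (s < -90 and c <= -80)

    def test_union_equals_killable_for_single_dose_drugs(self):
        """With one PCT per drug nothing is ever stranded: the cocktail's
        kill-set union is exactly the killable set."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_subpops = int(rng.integers(2, 7))
            subpops = [f"P{i}" for i in range(n_subpops)]
            rows = {}
            for d in range(int(rng.integers(1, 8))):
                rows[(f"d{d}", float(rng.choice([0.1, 1.0, 10.0])), 24.0)] = {
                    "sus": {sp: float(rng.uniform(-100, 20)) for sp in subpops},
                    "con": {sp: float(rng.uniform(-100, 0)) for sp in subpops}}
            tbl = make_table(rows, subpops)
            ours = cm.greedy_cocktail(tbl)
            killable = {
                sp for key in tbl.susceptibility.index for sp in tbl.subpop_ids
                if tbl.susceptibility.loc[key, sp] < -90
                and tbl.consistency.loc[key, sp] <= -80
            }
            assert ours.killed_union == killable

    def test_deterministic_under_row_shuffling(self):
        rng = np.random.default_rng(7)
        tbl = random_instance(rng)
        out1 = cm.greedy_cocktail(tbl)
        perm = rng.permutation(len(tbl.susceptibility))
        tbl2 = SusceptibilityTable(
            tbl.susceptibility.iloc[perm], tbl.consistency.iloc[perm],
            tbl.killed.iloc[perm], tbl.n_replicates.iloc[perm],
            tbl.plates.iloc[perm])
        out2 = cm.greedy_cocktail(tbl2)
        assert [(s.perturbagen, s.concentration, s.time) for s in out1.selections] == \
            [(s.perturbagen, s.concentration, s.time) for s in out2.selections]

    def test_monotone_progress(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            tbl = random_instance(rng)
            out = cm.greedy_cocktail(tbl)
            sizes = [len(s.killed_subpops) for s in out.selections]
            assert all(n >= 1 for n in sizes)


def exhaustive_min_cover(kill_sets, universe):
    """Smallest number of PCTs (over distinct drugs) covering the universe."""
    best = None
    items = list(kill_sets.items())
    for r in range(1, len(items) + 1):
        for combo in itertools.combinations(items, r):
            drugs = [k[0][0] for k in combo]
            if len(set(drugs)) != len(drugs):
                continue
            covered = set().union(*(set(v) for _, v in combo))
            if covered >= universe:
                return r
    return best


class TestGreedyBound:
    def test_within_harmonic_factor_of_optimum(self):
        """Greedy cover size <= (1 + H(n)) x optimum on small instances."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            tbl = random_instance(rng)
            ours = cm.greedy_cocktail(tbl)
            kill_sets = {}
            for key in tbl.susceptibility.index:
                kills = [sp for sp in tbl.subpop_ids
                         if tbl.susceptibility.loc[key, sp] < -90
                         and (pd.isna(tbl.consistency.loc[key, sp])
                              or tbl.consistency.loc[key, sp] <= -80)]
                if kills:
                    kill_sets[key] = kills
            universe = ours.killed_union
            if not universe:
                continue
            opt = exhaustive_min_cover(kill_sets, universe)
            h = sum(1 / i for i in range(1, len(universe) + 1))
            assert len(ours.selections) <= (1 + h) * opt
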
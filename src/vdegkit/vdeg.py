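"""VDEG screening: contrast families, the per-day three-way Venn classifier,
direction calls and cross-period sharing.

For each post-baseline day d three DEG sets are formed:

* ``A`` — control day d vs the shared day-0 baseline (natural response, NS),
* ``B`` — treatment day d vs day-0 (treatment-induced response, TS),
* ``X`` — treatment vs control at day d (TC).

"Value DEGs" are the members of X that also respond to at least one arm:

* class ``g`` = A n B n X   (responds in both arms at different levels),
* class ``f`` = (B n X) \\ A (treatment-only response),
* class ``e`` = (A n X) \\ B (natural response suppressed by treatment).

Genes in (A n B) \\ X — equal response in both arms — are excluded.  The union
e u f u g equals X n (A u B), which the property tests verify.  Direction is
the sign of the same-day T-over-C log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .de import ContrastSpec, DegSet
from .errors import ConfigError, DataError

STRATEGIES = ("TC", "NS", "TS")


@dataclass
class StrategyResult:
    """Per-day DEG sets for one contrast strategy."""

    strategy: str
    by_day: dict[int, DegSet]


def build_contrasts(design: pd.DataFrame, strategy: str) -> list[ContrastSpec]:
    """TC: (T_d vs C_d); NS: (C_d vs C0); TS: (T_d vs C0), numerator first."""
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    days = sorted(int(d) for d in design["day"].unique() if int(d) != 0)
    cells = {(r["condition"], int(r["day"])) for _, r in design.iterrows()}
    specs = []
    for d in days:
        if strategy == "TC":
            num, den = ("T", d), ("C", d)
        elif strategy == "NS":
            num, den = ("C", d), ("C", 0)
        else:
            num, den = ("T", d), ("C", 0)
        for cell in (num, den):
            if cell not in cells:
                raise DataError(f"design is missing the {cell[0]}{cell[1]} cell")
        specs.append(ContrastSpec(name=f"{strategy}_d{d}", numerator=num, denominator=den))
    return specs


def vdeg_classify(a: DegSet, b: DegSet, x: DegSet) -> pd.DataFrame:
    """Classify one day's VDEGs from the (A, B, X) DEG sets.

    Returns a frame with columns ``gene, day, klass`` where klass is one of
    e/f/g.  Raises if the three sets disagree on the day.
    """
    days = {s.day for s in (a, b, x) if s.day is not None}
    if len(days) > 1:
        raise DataError(f"DEG sets come from different days: {sorted(days)}")
    day = days.pop() if days else None
    ga, gb, gx = a.genes, b.genes, x.genes
    rows = []
    for gene in sorted(gx):
        in_a, in_b = gene in ga, gene in gb
        if in_a and in_b:
            klass = "g"
        elif in_b:
            klass = "f"
        elif in_a:
            klass = "e"
        else:
            continue  # X-only: not a VDEG
        rows.append((gene, day, klass))
    return pd.DataFrame(rows, columns=["gene", "day", "klass"])


def vdeg_direction(records: pd.DataFrame, tc_table: pd.DataFrame) -> pd.DataFrame:
    """Attach direction from the same-day T-over-C log2FC: up iff > 0."""
    missing = [g for g in records["gene"] if g not in tc_table.index]
    if missing:
        raise DataError(f"genes missing from the TC table: {missing[:5]}")
    out = records.copy()
    lfc = tc_table["log2FC"].reindex(records["gene"]).to_numpy()
    out["log2FC_TC"] = lfc
    out["padj_TC"] = tc_table["padj"].reindex(records["gene"]).to_numpy()
    out["direction"] = ["up" if v > 0 else "down" for v in lfc]
    return out


def shared_across_periods(
    up_sets: dict[int, set[str]], down_sets: dict[int, set[str]], k: int = 3
) -> tuple[set[str], set[str]]:
    """Genes appearing in >= k of the per-day up (resp. down) sets.

    Up and down tallies are independent: a gene flipping direction across days
    can in principle enter both shared lists.
    """
    if k > len(up_sets) or k > len(down_sets):
        raise ConfigError(f"k={k} exceeds the number of periods")

    def shared(sets: dict[int, set[str]]) -> set[str]:
        tally: dict[str, int] = {}
        for s in sets.values():
            for g in s:
                tally[g] = tally.get(g, 0) + 1
        return {g for g, n in tally.items() if n >= k}

    return shared(up_sets), shared(down_sets)


def venn_summary(sets: dict[str, set[str]]) -> dict:
    """Exact element counts for every intersection region of 2-5 sets.

    Region keys are '+'-joined sorted member names (e.g. ``"C1+C2"`` = in C1
    and C2 and in no other set).  Also reports the union size and the all-way
    intersection size.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 5:
        raise ConfigError("venn_summary supports 2-5 sets (use upset_table beyond)")
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions["+".join(combo)] = len(inside - outside)
    union = set.union(*(sets[n] for n in names))
    core = set.intersection(*(sets[n] for n in names))
    return {"regions": regions, "union": len(union), "all_way": len(core)}


def upset_table(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Upset-style membership table for any number of sets: one row per
    nonempty membership pattern with its element count, largest first."""
    names = sorted(sets)
    tally: dict[tuple[bool, ...], int] = {}
    for g in set().union(*sets.values()):
        key = tuple(g in sets[n] for n in names)
        tally[key] = tally.get(key, 0) + 1
    rows = [dict(zip(names, key), count=count) for key, count in tally.items()]
    out = pd.DataFrame(rows, columns=[*names, "count"])
    return out.sort_values("count", ascending=False).reset_index(drop=True)
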
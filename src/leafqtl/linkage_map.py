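"""Pseudo-testcross linkage mapping for an outbred F1 population.

Both parents of an outbred cross are heterozygous at different loci.  A
marker heterozygous in one parent and homozygous in the other segregates
1:1 (A:H) in the F1 and is informative only for the heterozygous parent's
meioses — so the population yields two separate maps, one per parent.
Markers heterozygous in both parents (3:1 class) or uninformative in both
are excluded.

Two-point recombination fractions are estimated per phase (coupling vs
repulsion of the unknown linkage phase), markers are grouped by
single-linkage closure on (rf, LOD) thresholds, ordered by minimising the
sum of adjacent recombination fractions (exhaustive for small groups,
greedy + 2-opt otherwise), and cM positions assigned through a map function
(Haldane default, Kosambi optional).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .band_io import MarkerGenotypes

__all__ = [
    "TestcrossPartition",
    "LinkageGroup",
    "GeneticMap",
    "classify_testcross_markers",
    "estimate_rf",
    "pairwise_rf_table",
    "group_markers",
    "order_markers",
    "rf_to_distance",
    "distance_to_rf",
    "build_maps",
]


@dataclass
class TestcrossPartition:
    """Markers split by informative parent; the three sets are disjoint and
    cover all markers."""

    p1_markers: list[str]
    p2_markers: list[str]
    excluded: dict[str, str]  # marker -> reason

    def __post_init__(self) -> None:
        sets = [set(self.p1_markers), set(self.p2_markers), set(self.excluded)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("partition sets overlap")


@dataclass
class LinkageGroup:
    parent_of_origin: str            # "P1" | "P2"
    markers: list[str]               # in map order
    adjacent_rf: list[float]         # len = len(markers) - 1
    positions_cM: list[float]        # starting at 0, nondecreasing

    @property
    def length_cM(self) -> float:
        return self.positions_cM[-1] if self.positions_cM else 0.0


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    map_function: str = "haldane"

    @property
    def total_length_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    def summary(self) -> dict:
        n_int = sum(max(len(g.markers) - 1, 0) for g in self.groups)
        return {
            "n_groups": len(self.groups),
            "n_groups_P1": sum(g.parent_of_origin == "P1" for g in self.groups),
            "n_groups_P2": sum(g.parent_of_origin == "P2" for g in self.groups),
            "n_markers": self.n_markers,
            "total_length_cM": round(self.total_length_cM, 2),
            "mean_group_length_cM": round(
                self.total_length_cM / len(self.groups), 2) if self.groups else 0.0,
            "mean_marker_spacing_cM": round(
                self.total_length_cM / n_int, 2) if n_int else 0.0,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.groups, start=1):
            gid = f"{i}.{g.parent_of_origin}"
            for m, pos in zip(g.markers, g.positions_cM):
                rows.append({"group_id": gid, "parent": g.parent_of_origin,
                             "marker": m, "position_cM": round(pos, 4)})
        return pd.DataFrame(rows)


def classify_testcross_markers(g: MarkerGenotypes,
                               distortion_alpha: float = 0.001,
                               ) -> TestcrossPartition:
    """Assign each marker to the P1 map, the P2 map, or exclusion.

    A P1-map marker is heterozygous in P1 and homozygous in P2 (1:1 A:H
    expected in the F1); symmetric for P2.  Markers informative in both or
    neither parent are excluded, as are markers with a missing parent
    genotype and markers whose F1 segregation rejects 1:1 by chi-square at
    ``distortion_alpha`` (distortion breeds pseudo-linkage).
    """
    p1 = g.parent_genotypes.iloc[0]
    p2 = g.parent_genotypes.iloc[1]
    p1_markers: list[str] = []
    p2_markers: list[str] = []
    excluded: dict[str, str] = {}
    for m in g.marker_names:
        a, b = p1[m], p2[m]
        if a == "-" or b == "-":
            excluded[m] = "parent genotype missing"
            continue
        if a == "H" and b == "A":
            target = p1_markers
        elif a == "A" and b == "H":
            target = p2_markers
        elif a == "H" and b == "H":
            excluded[m] = "heterozygous in both parents"
            continue
        else:
            excluded[m] = "uninformative (homozygous in both parents)"
            continue
        col = g.f1_genotypes[m].to_numpy()
        n_a = int((col == "A").sum())
        n_h = int((col == "H").sum())
        n = n_a + n_h
        if n == 0:
            excluded[m] = "no called F1 genotypes"
            continue
        chi2 = (n_a - n / 2) ** 2 / (n / 2) + (n_h - n / 2) ** 2 / (n / 2)
        p = stats.chi2.sf(chi2, df=1)
        if p < distortion_alpha:
            excluded[m] = f"segregation distortion (chi2 p={p:.2e})"
            continue
        target.append(m)
    return TestcrossPartition(p1_markers=p1_markers, p2_markers=p2_markers,
                              excluded=excluded)


def estimate_rf(mi: np.ndarray, mj: np.ndarray, min_informative: int = 10,
                ) -> tuple[float, float, str]:
    """Two-point recombination fraction between same-parent testcross markers.

    Linkage phase is unknown, so both codings of ``mj`` are tried: the raw
    coding (coupling) and the flipped one (repulsion); the phase with
    r ≤ 0.5 is kept.  Returns ``(r_hat, lod, phase)``; with fewer than
    ``min_informative`` pairwise-complete individuals the estimate is
    undefined and ``(nan, nan, 'na')`` is returned.

    LOD is the base-10 likelihood ratio of linkage at r_hat against free
    recombination (r = 0.5):  R·log10(r/0.5) + (n−R)·log10((1−r)/0.5),
    which tends to n·log10 2 as r → 0.
    """
    mi = np.asarray(mi)
    mj = np.asarray(mj)
    ok = (mi != "-") & (mj != "-")
    n = int(ok.sum())
    if n < min_informative:
        return float("nan"), float("nan"), "na"
    diff = int((mi[ok] != mj[ok]).sum())  # recombinants under coupling
    if diff <= n - diff:
        recomb, phase = diff, "coupling"
    else:
        recomb, phase = n - diff, "repulsion"
    r = recomb / n
    if r == 0:
        lod = n * np.log10(2.0)
    elif r >= 0.5:
        lod = 0.0
    else:
        lod = (recomb * np.log10(r / 0.5)
               + (n - recomb) * np.log10((1 - r) / 0.5))
    return float(r), float(lod), phase


def pairwise_rf_table(g: MarkerGenotypes, markers: list[str],
                      min_informative: int = 10) -> pd.DataFrame:
    """All-pairs (r, LOD, phase) for one parent's testcross markers.

    Vectorised over the 0/1 recoded genotype matrix; missing cells are
    pairwise-deleted, no imputation.
    """
    sub = g.f1_genotypes[markers].to_numpy()
    coded = np.where(sub == "H", 1.0, np.where(sub == "A", 0.0, np.nan))
    obs = ~np.isnan(coded)
    z = np.nan_to_num(coded)
    n_both = obs.T.astype(float) @ obs.astype(float)
    # pairwise count of (1,1), (1,0), (0,1) -> differences
    n11 = z.T @ z
    n1_ = z.T @ obs.astype(float)
    n_1 = obs.T.astype(float) @ z
    ndiff = n1_ + n_1 - 2 * n11

    rows = []
    m = len(markers)
    for i in range(m):
        for j in range(i + 1, m):
            n = n_both[i, j]
            if n < min_informative:
                rows.append((markers[i], markers[j], np.nan, np.nan, "na"))
                continue
            diff = ndiff[i, j]
            if diff <= n - diff:
                recomb, phase = diff, "coupling"
            else:
                recomb, phase = n - diff, "repulsion"
            r = recomb / n
            if r == 0:
                lod = n * np.log10(2.0)
            elif r >= 0.5:
                lod = 0.0
            else:
                lod = (recomb * np.log10(r / 0.5)
                       + (n - recomb) * np.log10((1 - r) / 0.5))
            rows.append((markers[i], markers[j], float(r), float(lod), phase))
    return pd.DataFrame(rows, columns=["m1", "m2", "rf", "lod", "phase"])


def _rf_lookup(rf_table: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    d: dict[tuple[str, str], tuple[float, float]] = {}
    for m1, m2, r, lod in rf_table[["m1", "m2", "rf", "lod"]].itertuples(index=False):
        d[(m1, m2)] = (r, lod)
        d[(m2, m1)] = (r, lod)
    return d


def group_markers(rf_table: pd.DataFrame, max_rf: float = 0.35,
                  min_lod: float = 3.0) -> list[list[str]]:
    """Single-linkage transitive closure: markers join a group when
    r ≤ max_rf and LOD ≥ min_lod.  Groups are numbered deterministically by
    their first marker name; singletons are allowed."""
    markers = sorted(set(rf_table["m1"]) | set(rf_table["m2"]))
    parent = {m: m for m in markers}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m1, m2, r, lod in rf_table[["m1", "m2", "rf", "lod"]].itertuples(index=False):
        if np.isfinite(r) and r <= max_rf and lod >= min_lod:
            ra, rb = find(m1), find(m2)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for m in markers:
        groups.setdefault(find(m), []).append(m)
    return [sorted(groups[k]) for k in sorted(groups)]


def _tour_cost(order: tuple[str, ...] | list[str],
               lut: dict[tuple[str, str], tuple[float, float]]) -> float:
    cost = 0.0
    for a, b in zip(order, order[1:]):
        r = lut.get((a, b), (np.nan, np.nan))[0]
        cost += r if np.isfinite(r) else 0.5  # unknown pairs priced as unlinked
    return cost


def _normalize_orientation(order: list[str]) -> list[str]:
    return order if order[0] <= order[-1] else order[::-1]


def order_markers(group: list[str], rf_table: pd.DataFrame,
                  exhaustive_limit: int = 8) -> list[str]:
    """Order a linkage group by minimising the sum of adjacent recombination
    fractions.

    Exact (exhaustive over permutations, up to reversal) for groups of at
    most ``exhaustive_limit`` markers; larger groups use a greedy
    nearest-neighbour chain seeded at the most distant marker pair, refined
    by 2-opt until no improvement.  Orientation is normalised so the
    lexicographically smaller terminal marker comes first.
    """
    if len(group) <= 2:
        return _normalize_orientation(sorted(group)) if len(group) == 2 else list(group)
    lut = _rf_lookup(rf_table)

    if len(group) <= exhaustive_limit:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(sorted(group)):
            if perm[0] > perm[-1]:
                continue  # reversal duplicate
            c = _tour_cost(perm, lut)
            if c < best_cost - 1e-15:
                best, best_cost = list(perm), c
        return _normalize_orientation(best)

    # greedy: seed at the pair with maximum rf (presumed chromosome ends)
    pairs = [(a, b) for a in group for b in group if a < b]
    ends = max(pairs, key=lambda p: (lut.get(p, (0.5, 0))[0]
                                     if np.isfinite(lut.get(p, (0.5, 0))[0]) else 0.5))
    start = ends[0]
    order = [start]
    remaining = set(group) - {start}
    while remaining:
        last = order[-1]
        nxt = min(sorted(remaining),
                  key=lambda m: lut.get((last, m), (0.5, 0))[0]
                  if np.isfinite(lut.get((last, m), (0.5, 0))[0]) else 0.5)
        order.append(nxt)
        remaining.discard(nxt)

    # 2-opt refinement
    improved = True
    while improved:
        improved = False
        for i in range(len(order) - 1):
            for j in range(i + 2, len(order) + 1):
                cand = order[:i] + order[i:j][::-1] + order[j:]
                if _tour_cost(cand, lut) < _tour_cost(order, lut) - 1e-12:
                    order = cand
                    improved = True
    return _normalize_orientation(order)


def rf_to_distance(r: float, map_function: str = "haldane") -> float:
    """Recombination fraction → genetic distance in cM.

    Haldane (no interference): d = −50·ln(1−2r).
    Kosambi (partial interference): d = 25·ln((1+2r)/(1−2r)).
    """
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} out of [0, 0.5): unlinked")
    if map_function == "haldane":
        return float(-50.0 * np.log(1 - 2 * r))
    if map_function == "kosambi":
        return float(25.0 * np.log((1 + 2 * r) / (1 - 2 * r)))
    raise ValueError(f"unknown map function {map_function!r}")


def distance_to_rf(d_cM: float, map_function: str = "haldane") -> float:
    """Inverse map function: cM distance → recombination fraction."""
    if d_cM < 0:
        raise ValueError("negative distance")
    m = d_cM / 100.0
    if map_function == "haldane":
        return float(0.5 * (1 - np.exp(-2 * m)))
    if map_function == "kosambi":
        return float(0.5 * np.tanh(2 * m))
    raise ValueError(f"unknown map function {map_function!r}")


def build_maps(g: MarkerGenotypes, map_function: str = "haldane",
               max_rf: float = 0.35, min_lod: float = 3.0,
               distortion_alpha: float = 0.001,
               min_informative: int = 10) -> GeneticMap:
    """Full map construction: classify → pairwise rf → group → order → cM.

    Runs separately per parent (pseudo-testcross), producing one
    :class:`GeneticMap` holding both parents' linkage groups.  Adjacent
    recombination fractions ≥ 0.5 (possible after greedy ordering of weakly
    linked groups) are clipped just below 0.5 before distance conversion.
    """
    part = classify_testcross_markers(g, distortion_alpha=distortion_alpha)
    groups: list[LinkageGroup] = []
    for parent, markers in (("P1", part.p1_markers), ("P2", part.p2_markers)):
        if not markers:
            continue
        rf_table = pairwise_rf_table(g, markers, min_informative=min_informative)
        lut = _rf_lookup(rf_table)
        for grp in group_markers(rf_table, max_rf=max_rf, min_lod=min_lod):
            order = order_markers(grp, rf_table)
            adj = []
            for a, b in zip(order, order[1:]):
                r = lut.get((a, b), (np.nan, np.nan))[0]
                r = min(r if np.isfinite(r) else 0.49, 0.49)
                adj.append(r)
            pos = [0.0]
            for r in adj:
                pos.append(pos[-1] + rf_to_distance(r, map_function))
            groups.append(LinkageGroup(parent_of_origin=parent, markers=order,
                                       adjacent_rf=adj, positions_cM=pos))
    return GeneticMap(groups=groups, map_function=map_function)
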
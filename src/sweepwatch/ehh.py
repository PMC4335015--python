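"""Extended haplotype homozygosity (EHH) and haplotype bifurcation trees.

EHH at a target site, for the class of chromosomes sharing one allele at
the core site, is the probability that two randomly drawn chromosomes of
the class are identical over every site from the core to the target
(inclusive):

    EHH = sum_h C(c_h, 2) / C(n, 2)

where c_h are the sizes of the distinct extended haplotypes. EHH equals 1
at the core by construction and is non-increasing with distance. Relative
EHH is the derived/ancestral ratio at the same site; it is undefined (NaN),
not 0 or infinity, where the ancestral EHH has reached 0.

The bifurcation tree records how a class splits into extended haplotypes
site by site away from the core; node counts are the branch thicknesses of
the classic bifurcation diagram, and summing C(c, 2)/C(n, 2) over any level
recovers the EHH at that depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hapio import CoreVariant, HaplotypeMatrix

DIRECTIONS = ("upstream", "downstream")


def _class_rows(hap: HaplotypeMatrix, core: CoreVariant, allele_class: str) -> np.ndarray:
    j = hap.site_index(core.chrom, core.pos)
    col = hap.data[:, j]
    if allele_class == "derived":
        keep = col == core.derived_allele_code
    elif allele_class == "ancestral":
        keep = col != core.derived_allele_code
    else:
        raise ValueError("allele_class must be 'derived' or 'ancestral'")
    return np.flatnonzero(keep)


def _homozygosity(labels: np.ndarray) -> float:
    n = labels.size
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_at(
    hap: HaplotypeMatrix,
    core: CoreVariant,
    allele_class: str,
    target_pos: int,
) -> float:
    """EHH of ``allele_class`` over the span from the core to ``target_pos``
    (both sites inclusive)."""
    rows = _class_rows(hap, core, allele_class)
    if rows.size < 2:
        raise ValueError(
            f"EHH undefined: {allele_class} class has {rows.size} chromosome(s)"
        )
    j_core = hap.site_index(core.chrom, core.pos)
    j_tgt = hap.site_index(core.chrom, target_pos)
    lo, hi = min(j_core, j_tgt), max(j_core, j_tgt)
    X = hap.data[np.ix_(rows, np.arange(lo, hi + 1))]
    _, labels = np.unique(X, axis=0, return_inverse=True)
    return _homozygosity(labels)


@dataclass
class EHHCurve:
    """EHH of both classes along one direction away from the core.

    ``points`` columns: pos, distance_bp, ehh_derived, ehh_ancestral,
    rel_ehh (NaN once ancestral EHH is 0). ``truncated_at`` is the first
    position where relative EHH became undefined, if any.
    """

    direction: str
    points: pd.DataFrame
    truncated_at: int | None = None


def ehh_curve(hap: HaplotypeMatrix, core: CoreVariant) -> tuple[EHHCurve, EHHCurve]:
    """EHH evaluated at every observed site moving away from the core, in
    both directions. Returns (upstream, downstream)."""
    der = _class_rows(hap, core, "derived")
    anc = _class_rows(hap, core, "ancestral")
    if der.size < 2 or anc.size < 2:
        raise ValueError(
            f"both classes need >= 2 chromosomes (derived={der.size}, "
            f"ancestral={anc.size})"
        )
    j_core = hap.site_index(core.chrom, core.pos)
    contig_mask = hap.site_chroms == core.chrom
    positions = hap.positions

    curves = []
    for direction in DIRECTIONS:
        if direction == "upstream":
            cols = np.arange(j_core, -1, -1)
        else:
            cols = np.arange(j_core, hap.n_sites)
        cols = cols[contig_mask[cols]]
        rec = {
            "pos": [], "distance_bp": [],
            "ehh_derived": [], "ehh_ancestral": [], "rel_ehh": [],
        }
        lab_d = np.zeros(der.size, dtype=np.int64)
        lab_a = np.zeros(anc.size, dtype=np.int64)
        truncated_at = None
        for j in cols:
            col = hap.data[:, j]
            _, lab_d = np.unique(
                np.column_stack([lab_d, col[der]]), axis=0, return_inverse=True
            )
            _, lab_a = np.unique(
                np.column_stack([lab_a, col[anc]]), axis=0, return_inverse=True
            )
            e_d = _homozygosity(lab_d)
            e_a = _homozygosity(lab_a)
            if e_a > 0:
                rel = e_d / e_a
            else:
                rel = float("nan")
                if truncated_at is None:
                    truncated_at = int(positions[j])
            rec["pos"].append(int(positions[j]))
            rec["distance_bp"].append(abs(int(positions[j]) - core.pos))
            rec["ehh_derived"].append(e_d)
            rec["ehh_ancestral"].append(e_a)
            rec["rel_ehh"].append(rel)
        curves.append(
            EHHCurve(direction, pd.DataFrame(rec), truncated_at=truncated_at)
        )
    return curves[0], curves[1]


def ehh_table(upstream: EHHCurve, downstream: EHHCurve) -> pd.DataFrame:
    """Concatenate both directions into one tidy table."""
    parts = []
    for c in (upstream, downstream):
        df = c.points.copy()
        df.insert(0, "direction", c.direction)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


@dataclass
class BifNode:
    """One node of the bifurcation tree: the class subset still identical
    up to ``pos``; ``count`` is the branch thickness."""

    pos: int
    count: int
    children: dict[int, "BifNode"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pos": self.pos,
            "count": self.count,
            "children": {
                str(a): child.to_dict()
                for a, child in sorted(self.children.items())
            },
        }


@dataclass
class BifurcationTree:
    allele_class: str
    direction: str
    root: BifNode

    def levels(self) -> list[list[BifNode]]:
        out, frontier = [], [self.root]
        while frontier:
            out.append(frontier)
            frontier = [
                c for node in frontier
                for _, c in sorted(node.children.items())
            ]
        return out

    def ehh_by_depth(self) -> list[float]:
        """EHH recomputed from node counts level by level (consistency
        route: must match :func:`ehh_curve`)."""
        n = self.root.count
        if n < 2:
            raise ValueError("EHH from tree undefined for class size < 2")
        return [
            sum(node.count * (node.count - 1) for node in level)
            / (n * (n - 1))
            for level in self.levels()
        ]

    def to_dict(self) -> dict:
        return {
            "allele_class": self.allele_class,
            "direction": self.direction,
            "tree": self.root.to_dict(),
        }


def bifurcation_tree(
    hap: HaplotypeMatrix,
    core: CoreVariant,
    allele_class: str,
    direction: str,
    max_sites: int | None = None,
) -> BifurcationTree:
    """Build the bifurcation tree for one class and direction.

    The root holds the whole class at the core; each successive site splits
    every current branch by allele (branches that do not split are simply
    extended, keeping their membership). ``max_sites`` caps the depth for
    plotting/serialization; child order is allele 0 before 1.
    """
    rows = _class_rows(hap, core, allele_class)
    if rows.size == 0:
        raise ValueError(f"{allele_class} class is empty")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    j_core = hap.site_index(core.chrom, core.pos)
    contig_mask = hap.site_chroms == core.chrom
    if direction == "upstream":
        cols = np.arange(j_core - 1, -1, -1)
    else:
        cols = np.arange(j_core + 1, hap.n_sites)
    cols = cols[contig_mask[cols]]
    if max_sites is not None:
        cols = cols[:max_sites]

    root = BifNode(pos=core.pos, count=int(rows.size))
    frontier: list[tuple[BifNode, np.ndarray]] = [(root, rows)]
    positions = hap.positions
    for j in cols:
        col = hap.data[:, j]
        new_frontier = []
        for node, members in frontier:
            for allele in (0, 1):
                sub = members[col[members] == allele]
                if sub.size == 0:
                    continue
                child = BifNode(pos=int(positions[j]), count=int(sub.size))
                node.children[allele] = child
                new_frontier.append((child, sub))
        frontier = new_frontier
    return BifurcationTree(allele_class, direction, root)
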
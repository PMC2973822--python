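"""Synthetic panels, haplotype pools, frequency tables and tip states.

Real KIR panels (a 39-chimpanzee panel typed at 14 presence/absence
markers; human A/B haplotype compilations; the 33-population KIR/HLA
frequency table) are not redistributable as plain text, so every analysis
stage here is exercised against generated data with the same statistical
structure:

* **chimp-like pools** — haplotypes arise from independent presence of
  recombination *units* confined to the centromeric interval; some pairs
  of variable genes are in absolute linkage and move as one unit.
* **human-like pools** — haplotypes are the cross product of centromeric
  and telomeric gene-content motifs, with product frequencies.
* **diploid genotypes** — an individual's gene-content genotype is the
  logical OR of two haplotypes drawn i.i.d. from the pool frequencies
  (Hardy-Weinberg pairing).
* **frequency tables** — per-population phenotype frequencies drawn
  uniformly within realistic ranges, with the B*46 ligand present only in
  designated populations.
* **tip states** — a root state propagated down a tree with substitution
  events placed on chosen edges, the ground truth for parsimony counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import dendropy
import numpy as np
import pandas as pd

from .core_model import (
    FrequencyTable,
    GenotypePanel,
    HaplotypeTable,
    LocusRegistry,
    TipStateTree,
)

__all__ = [
    "Unit",
    "Motif",
    "PoolSpec",
    "chimp_like_default_spec",
    "human_like_default_spec",
    "simulate_haplotype_pool",
    "simulate_genotypes",
    "simulate_frequency_table",
    "simulate_tip_states",
    "DEFAULT_FREQUENCY_RANGES",
]


@dataclass(frozen=True)
class Unit:
    """A recombination unit: loci that co-occur, with a presence probability."""

    name: str
    loci: tuple[str, ...]
    probability: float

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"unit {self.name!r}: probability outside [0, 1]")


@dataclass(frozen=True)
class Motif:
    """A regional gene-content motif with a haplotype frequency."""

    name: str
    loci: tuple[str, ...]
    frequency: float


@dataclass
class PoolSpec:
    """Specification of a haplotype pool generator.

    ``chimp-like`` mode: haplotypes are formed by independent presence of
    each unit; ``pair_constraints`` lists locus pairs in absolute linkage,
    whose units are merged before enumeration. ``human-like`` mode:
    haplotypes are centromeric × telomeric motif combinations.
    """

    registry: LocusRegistry
    mode: str = "chimp-like"
    units: tuple[Unit, ...] = ()
    pair_constraints: tuple[tuple[str, str], ...] = ()
    centromeric_motifs: tuple[Motif, ...] = ()
    telomeric_motifs: tuple[Motif, ...] = ()
    framework: tuple[str, ...] = ()  # loci present on every haplotype

    def __post_init__(self):
        if self.mode not in {"chimp-like", "human-like"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        known = set(self.registry.loci)
        if self.mode == "chimp-like":
            if not self.units:
                raise ValueError("chimp-like spec needs at least one unit")
            for unit in self.units:
                bad = set(unit.loci) - known
                if bad:
                    raise ValueError(f"unit {unit.name!r} references unknown loci {sorted(bad)}")
            for a, b in self.pair_constraints:
                if a not in known or b not in known:
                    raise ValueError(f"constraint ({a!r}, {b!r}) references unknown locus")
        else:
            for motifs, region in (
                (self.centromeric_motifs, "centromeric"),
                (self.telomeric_motifs, "telomeric"),
            ):
                if not motifs:
                    raise ValueError(f"human-like spec needs {region} motifs")
                total = sum(m.frequency for m in motifs)
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(f"{region} motif frequencies sum to {total}, not 1")
                for m in motifs:
                    bad = set(m.loci) - known
                    if bad:
                        raise ValueError(f"motif {m.name!r} references unknown loci {sorted(bad)}")
        bad = set(self.framework) - known
        if bad:
            raise ValueError(f"framework loci not in registry: {sorted(bad)}")


# ---------------------------------------------------------------------------
# default study-like specifications
# ---------------------------------------------------------------------------

#: Chimpanzee-style registry: 14 markers for 13 genes (the fused 3DL1/2
#: region carries two markers, kept distinct), 4 framework markers and
#: 5 pairs of variable genes, all centromeric.
CHIMP_LOCI = (
    "3DL3", "2DL5", "2DL8", "3DL5", "2DL9", "2DL6", "2DL7",
    "3DL4", "3DS2", "2DS4", "3DS6", "2DL4", "3DL1/2a", "3DL1/2b",
)
_CHIMP_FRAMEWORK = ("3DL3", "2DL4", "3DL1/2a", "3DL1/2b")


def chimp_like_default_spec() -> PoolSpec:
    """Chimpanzee-style pool: seven recombination units in the centromeric
    interval.

    Three of the five variable-gene pairs are in absolute linkage and act
    as single units; the genes of the other two pairs segregate
    individually. Unit probabilities are anchored to the study panel's
    printed haplotype statistics: the 2DS4-carrying unit sits at 8% of
    haplotypes, and the 2DL5 unit at 52% so that ~44% of haplotypes carry
    neither 2DS4 nor 2DL5 (0.48 x 0.92 = 0.44).
    """
    region = {name: "centromeric" for name in CHIMP_LOCI}
    region.update({"2DL4": "framework", "3DL3": "framework",
                   "3DL1/2a": "framework", "3DL1/2b": "framework"})
    registry = LocusRegistry(CHIMP_LOCI, region)
    units = (
        Unit("pair1", ("2DL5", "2DL8"), 0.52),
        Unit("pair2a", ("3DL5",), 0.85),
        Unit("pair2b", ("2DL9",), 0.80),
        Unit("pair3", ("2DL6", "2DL7"), 0.90),
        Unit("pair4a", ("3DL4",), 0.70),
        Unit("pair4b", ("3DS2",), 0.60),
        Unit("pair5", ("2DS4", "3DS6"), 0.08),
    )
    return PoolSpec(
        registry,
        mode="chimp-like",
        units=units,
        pair_constraints=(("2DL5", "2DL8"), ("2DL6", "2DL7"), ("2DS4", "3DS6")),
        framework=_CHIMP_FRAMEWORK,
    )


HUMAN_LOCI = (
    "3DL3", "2DS2", "2DL2", "2DL3", "2DL5B", "2DS3", "2DP1", "2DL1",
    "3DP1", "2DL4", "3DL1", "3DS1", "2DL5A", "2DS5", "2DS1", "2DS4", "3DL2",
)


def human_like_default_spec() -> PoolSpec:
    """Human-style pool: centromeric × telomeric gene-content motifs.

    Motifs follow the canonical A/B-haplotype structure — cA carries 2DL3,
    cB carries 2DL2-2DS2 (with or without 2DL5B-2DS3), tA carries
    3DL1-2DS4, tB carries 3DS1-2DL5A-2DS5-2DS1 — at frequencies typical of
    European-ancestry panels, which puts 2DS4 on ~55% of haplotypes.
    """
    region = {name: "unassigned" for name in HUMAN_LOCI}
    cen = ("2DS2", "2DL2", "2DL3", "2DL5B", "2DS3")
    tel = ("3DL1", "3DS1", "2DL5A", "2DS5", "2DS1", "2DS4")
    region.update({n: "centromeric" for n in cen})
    region.update({n: "telomeric" for n in tel})
    region.update({"3DL3": "framework", "2DP1": "framework", "2DL1": "framework",
                   "3DP1": "framework", "2DL4": "framework", "3DL2": "framework"})
    registry = LocusRegistry(HUMAN_LOCI, region)
    framework = ("3DL3", "2DP1", "2DL1", "3DP1", "2DL4", "3DL2")
    cen_motifs = (
        Motif("cA01", ("2DL3",), 0.55),
        Motif("cB01", ("2DS2", "2DL2", "2DL5B", "2DS3"), 0.25),
        Motif("cB02", ("2DS2", "2DL2"), 0.20),
    )
    tel_motifs = (
        Motif("tA01", ("3DL1", "2DS4"), 0.55),
        Motif("tB01", ("3DS1", "2DL5A", "2DS5", "2DS1"), 0.45),
    )
    return PoolSpec(
        registry,
        mode="human-like",
        centromeric_motifs=cen_motifs,
        telomeric_motifs=tel_motifs,
        framework=framework,
    )


# ---------------------------------------------------------------------------
# haplotype pool
# ---------------------------------------------------------------------------


def _merge_units_for_constraints(spec: PoolSpec) -> list[Unit]:
    """Merge units joined by pair constraints so constrained loci co-occur.

    A merged unit's presence probability is the arithmetic mean of its
    members' — the constraint asserts the pair segregates as one block, so
    a single probability must govern it.
    """
    units = [Unit(u.name, tuple(u.loci), u.probability) for u in spec.units]
    locus_to_unit = {}
    for idx, unit in enumerate(units):
        for locus in unit.loci:
            locus_to_unit[locus] = idx
    parent = list(range(len(units)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in spec.pair_constraints:
        ia, ib = locus_to_unit.get(a), locus_to_unit.get(b)
        if ia is None or ib is None:
            raise ValueError(f"constraint ({a!r}, {b!r}) references locus outside all units")
        ra, rb = find(ia), find(ib)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[Unit]] = {}
    for idx, unit in enumerate(units):
        groups.setdefault(find(idx), []).append(unit)
    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
        else:
            loci = tuple(l for u in members for l in u.loci)
            prob = float(np.mean([u.probability for u in members]))
            merged.append(Unit("+".join(u.name for u in members), loci, prob))
    return merged


def simulate_haplotype_pool(spec: PoolSpec, seed: int | None = None) -> HaplotypeTable:
    """Build the exact haplotype distribution a spec implies.

    Both modes admit closed-form enumeration (product of independent unit
    Bernoullis, or the motif cross product), so the returned table is the
    exact distribution rather than a finite sample; ``seed`` is accepted
    for interface symmetry with the sampling operations but unused.
    Identical gene-content vectors are merged with summed frequencies so
    the table is a proper distribution over unique haplotypes.
    """
    registry = spec.registry
    locus_index = {l: j for j, l in enumerate(registry.loci)}
    rows: list[tuple[np.ndarray, float]] = []
    if spec.mode == "chimp-like":
        units = _merge_units_for_constraints(spec)
        for included in product([False, True], repeat=len(units)):
            freq = 1.0
            vec = np.zeros(len(registry), dtype=bool)
            for l in spec.framework:
                vec[locus_index[l]] = True
            for unit, on in zip(units, included):
                freq *= unit.probability if on else (1.0 - unit.probability)
                if on:
                    for l in unit.loci:
                        vec[locus_index[l]] = True
            if freq > 0.0:
                rows.append((vec, freq))
    else:
        for cm, tm in product(spec.centromeric_motifs, spec.telomeric_motifs):
            freq = cm.frequency * tm.frequency
            if freq <= 0.0:
                continue
            vec = np.zeros(len(registry), dtype=bool)
            for l in spec.framework:
                vec[locus_index[l]] = True
            for l in cm.loci + tm.loci:
                vec[locus_index[l]] = True
            rows.append((vec, freq))
    # merge identical vectors
    merged: dict[bytes, tuple[np.ndarray, float]] = {}
    for vec, freq in rows:
        key = vec.tobytes()
        if key in merged:
            merged[key] = (vec, merged[key][1] + freq)
        else:
            merged[key] = (vec, freq)
    items = sorted(merged.values(), key=lambda vf: (-vf[1], vf[0].tobytes()))
    vectors = np.array([v for v, _ in items], dtype=bool)
    freqs = np.array([f for _, f in items], dtype=float)
    freqs = freqs / freqs.sum()
    names = tuple(f"H{i + 1}" for i in range(len(items)))
    return HaplotypeTable(registry, names, vectors, freqs)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    table: HaplotypeTable,
    n: int,
    seed: int,
    unrelated: bool = True,
) -> GenotypePanel:
    """Draw n diploid individuals; genotype = OR of two i.i.d. haplotypes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(table.names) == 0:
        raise ValueError("empty haplotype table")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(table.names), size=(n, 2), p=table.frequencies)
    matrix = table.vectors[picks[:, 0]] | table.vectors[picks[:, 1]]
    ids = tuple(f"ind{i + 1:03d}" for i in range(n))
    mask = np.full(n, bool(unrelated))
    return GenotypePanel(table.registry, ids, matrix, mask)


# ---------------------------------------------------------------------------
# population frequency tables
# ---------------------------------------------------------------------------

#: Realistic per-key phenotype-frequency ranges for worldwide populations
#: (KIR2DL1 nearly universal; 2DL2 and C2 the most variable; 2DL3 common;
#: B*46 confined to East/Southeast Asia at carrier frequencies up to ~0.28).
DEFAULT_FREQUENCY_RANGES = {
    "2DL1": (0.90, 1.00),
    "2DL2": (0.30, 0.92),
    "2DL3": (0.75, 1.00),
    "C1": (0.55, 1.00),
    "C2": (0.15, 0.80),
    "B46": (0.08, 0.28),
}

_DEFAULT_GROUPS = ("AFR", "EUR", "SWA", "EAS", "OCE", "NEA", "NAM", "SAM")


def simulate_frequency_table(
    n_pops: int = 33,
    ranges: dict[str, tuple[float, float]] | None = None,
    b46_pops: list[str] | None = None,
    seed: int = 0,
    groups: tuple[str, ...] = _DEFAULT_GROUPS,
) -> FrequencyTable:
    """Uniform per-key draws for ``n_pops`` populations split into groups.

    ``b46_pops`` names the populations that carry B*46 (default: every
    population assigned to the EAS group, mirroring its East/Southeast
    Asian confinement); elsewhere the B46 column is zero.
    """
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    full = dict(DEFAULT_FREQUENCY_RANGES)
    if ranges:
        full.update(ranges)
    for key, (lo, hi) in full.items():
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    pops = [f"pop{i + 1:02d}" for i in range(n_pops)]
    grp = [groups[i * len(groups) // n_pops] for i in range(n_pops)]
    if b46_pops is None:
        b46_pops = [p for p, g in zip(pops, grp) if g == "EAS"]
    b46_set = set(b46_pops)
    cols = {"population": pops, "group": grp}
    for key in ("2DL1", "2DL2", "2DL3", "C1", "C2"):
        lo, hi = full[key]
        cols[key] = rng.uniform(lo, hi, size=n_pops)
    lo, hi = full["B46"]
    b46 = rng.uniform(lo, hi, size=n_pops)
    cols["B46"] = [b if p in b46_set else 0.0 for p, b in zip(pops, b46)]
    cols["use_b46"] = [p in b46_set for p in pops]
    return FrequencyTable(pd.DataFrame(cols))


# ---------------------------------------------------------------------------
# tip states from placed events
# ---------------------------------------------------------------------------


def _edge_signature(node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def simulate_tip_states(
    newick: str,
    events: list[tuple[object, str, str]],
    root_state: str,
) -> TipStateTree:
    """Propagate a root state down a tree, applying substitution events.

    Each event is ``(edge, from_state, to_state)`` where ``edge`` names the
    branch above a node — either the node's label (tips) or a frozenset /
    iterable of the tip labels the node subtends (the tip-set signature;
    Newick has no canonical edge labels). Two events on one edge are
    contradictory and rejected.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    by_label: dict[str, object] = {}
    by_signature: dict[frozenset, object] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.taxon is not None:
            by_label[node.taxon.label] = node
        elif node.label:
            by_label[node.label] = node
        by_signature[_edge_signature(node)] = node

    resolved: dict[int, tuple[str, str]] = {}
    node_event: dict[object, tuple[str, str]] = {}
    for edge, src, dst in events:
        if isinstance(edge, str):
            node = by_label.get(edge)
            if node is None:
                raise ValueError(f"unknown edge {edge!r}")
        else:
            node = by_signature.get(frozenset(edge))
            if node is None:
                raise ValueError(f"no edge subtends tips {sorted(edge)}")
        if id(node) in resolved:
            raise ValueError(f"contradictory events on one edge ({edge!r})")
        resolved[id(node)] = (src, dst)
        node_event[node] = (src, dst)

    states: dict[str, str] = {}
    stack = [(tree.seed_node, root_state)]
    while stack:
        node, state = stack.pop()
        ev = node_event.get(node)
        if ev is not None:
            src, dst = ev
            if src != state:
                raise ValueError(
                    f"event {src}->{dst} placed on an edge whose parent state is {state}"
                )
            state = dst
        if node.is_leaf():
            states[node.taxon.label] = state
        else:
            for child in node.child_nodes():
                stack.append((child, state))
    return TipStateTree(tree, states)
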
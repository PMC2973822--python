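"""Domain types and file IO for gene-content analyses of KIR loci.

The central objects are small, validated containers:

* :class:`LocusRegistry` — the ordered set of typed loci and their genomic
  region (centromeric / telomeric / framework / unassigned).
* :class:`GenotypePanel` — an individuals × loci presence/absence matrix.
  A locus is "present" when at least one copy exists on either chromosome,
  i.e. a genotype is the logical OR of two haplotype gene-content vectors;
  copy number is not modelled.
* :class:`HaplotypeTable` — gene-content vectors with frequencies on the
  simplex.
* :class:`FrequencyTable` — per-population phenotype (carrier) frequencies
  for the KIR2DL1-3 receptors and the HLA-C1/C2/B*46 ligand epitopes.
* :class:`ResiduePair` — the two MHC class I residues (positions 76 and 80
  of the mature protein) that determine the C1/C2/Bw4 epitopes.
* :class:`TipStateTree` — a Newick tree with a single-character state at
  every tip, input to parsimony change counting.

All tabular formats are tab-delimited UTF-8 text with ``#`` comment lines;
protein alignments are FASTA; trees are Newick.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "REGIONS",
    "UNKNOWN_RESIDUE",
    "LocusRegistry",
    "GenotypePanel",
    "HaplotypeTable",
    "FrequencyTable",
    "ResiduePair",
    "TipStateTree",
    "LoadError",
    "load_genotype_panel",
    "write_genotype_panel",
    "load_haplotype_table",
    "write_haplotype_table",
    "load_frequency_table",
    "write_frequency_table",
    "load_residue_pairs",
    "load_tip_state_tree",
]

#: Closed set of genomic-region tags for KIR loci.
REGIONS = frozenset({"centromeric", "telomeric", "framework", "unassigned"})

#: Marker used for an unknown/gapped residue.
UNKNOWN_RESIDUE = "X"

_AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")

#: Frequency columns a FrequencyTable must (or may, for B46) carry.
FREQUENCY_KEYS = ("2DL1", "2DL2", "2DL3", "C1", "C2", "B46")


class LoadError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# locus registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusRegistry:
    """Ordered list of locus names with genomic-region tags.

    The registry size is data-driven: a chimpanzee-style panel is typed at
    14 presence/absence markers (13 genes, the fused 3DL1/2 region carrying
    two markers), while a human-style registry lists the A/B-haplotype loci.
    Region tags default to ``unassigned``; region-aware operations require
    explicit tags.
    """

    loci: tuple[str, ...]
    region: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        loci = tuple(self.loci)
        object.__setattr__(self, "loci", loci)
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus names in registry")
        full = {name: self.region.get(name, "unassigned") for name in loci}
        bad = set(full.values()) - REGIONS
        if bad:
            raise ValueError(f"unknown region tags: {sorted(bad)}")
        unknown = set(self.region) - set(loci)
        if unknown:
            raise ValueError(f"region tags for unknown loci: {sorted(unknown)}")
        object.__setattr__(self, "region", full)

    def __len__(self) -> int:
        return len(self.loci)

    def index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Individuals × loci presence/absence matrix.

    Missing cells are rejected at load time rather than imputed: the
    downstream statistics (distinct-genotype counting, pairwise difference,
    EM haplotype inference) all assume complete typing.
    """

    registry: LocusRegistry
    individuals: tuple[str, ...]
    matrix: np.ndarray  # bool, shape (n_individuals, n_loci)
    unrelated_mask: np.ndarray  # bool, shape (n_individuals,)

    def __post_init__(self):
        self.individuals = tuple(self.individuals)
        self.matrix = np.asarray(self.matrix, dtype=bool)
        self.unrelated_mask = np.asarray(self.unrelated_mask, dtype=bool)
        if len(set(self.individuals)) != len(self.individuals):
            raise LoadError("duplicated individual id")
        if self.matrix.shape != (len(self.individuals), len(self.registry)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.registry)} loci"
            )
        if self.unrelated_mask.shape != (len(self.individuals),):
            raise ValueError("unrelated_mask length mismatch")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def select(self, unrelated_only: bool = False) -> np.ndarray:
        """Genotype matrix restricted to the chosen subset."""
        if unrelated_only:
            if not self.unrelated_mask.any():
                raise ValueError("no individuals flagged as unrelated")
            return self.matrix[self.unrelated_mask]
        return self.matrix


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


_CELL_MAP = {"0": False, "1": True, "-": False, "+": True}


def load_genotype_panel(path, registry: LocusRegistry) -> GenotypePanel:
    """Read a presence/absence panel TSV, realigned to registry order.

    The first column holds individual identifiers; remaining columns are
    locus names in any order. Cells are ``0``/``1`` or ``-``/``+``. An
    optional ``unrelated`` column (0/1) marks the unrelated subset; absent,
    all individuals are treated as unrelated.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise LoadError("panel needs an id column plus at least one locus")
    id_col = df.columns[0]
    ids = [str(x) for x in df[id_col]]
    if len(set(ids)) != len(ids):
        raise LoadError("duplicated individual id")
    cols = [c for c in df.columns[1:] if c != "unrelated"]
    unknown = set(cols) - set(registry.loci)
    if unknown:
        raise LoadError(f"unknown locus name(s): {sorted(unknown)}")
    missing = set(registry.loci) - set(cols)
    if missing:
        raise LoadError(f"panel lacks registry loci: {sorted(missing)}")

    mat = np.empty((len(ids), len(registry)), dtype=bool)
    for j, locus in enumerate(registry.loci):
        col = df[locus]
        for i, raw in enumerate(col):
            cell = str(raw).strip()
            if cell not in _CELL_MAP:
                raise LoadError(
                    f"non-binary value {raw!r} for individual {ids[i]!r}, locus {locus!r}"
                )
            mat[i, j] = _CELL_MAP[cell]
    if "unrelated" in df.columns:
        unrel = np.array([_parse_flag(x) for x in df["unrelated"]], dtype=bool)
    else:
        unrel = np.ones(len(ids), dtype=bool)
    return GenotypePanel(registry, tuple(ids), mat, unrel)


def _parse_flag(raw) -> bool:
    cell = str(raw).strip()
    if cell not in _CELL_MAP:
        raise LoadError(f"non-binary unrelated flag {raw!r}")
    return _CELL_MAP[cell]


def write_genotype_panel(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(
        panel.matrix.astype(int), columns=list(panel.registry.loci)
    )
    df.insert(0, "individual", list(panel.individuals))
    df["unrelated"] = panel.unrelated_mask.astype(int)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# haplotype table
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeTable:
    """Named gene-content vectors with frequencies summing to one."""

    registry: LocusRegistry
    names: tuple[str, ...]
    vectors: np.ndarray  # bool, shape (n_haplotypes, n_loci)
    frequencies: np.ndarray  # float, shape (n_haplotypes,)

    def __post_init__(self):
        self.names = tuple(self.names)
        self.vectors = np.asarray(self.vectors, dtype=bool)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate haplotype names")
        if self.vectors.shape != (len(self.names), len(self.registry)):
            raise ValueError("haplotype vector shape mismatch")
        if self.frequencies.shape != (len(self.names),):
            raise ValueError("frequency length mismatch")
        if np.any(self.frequencies < 0):
            raise ValueError("negative haplotype frequency")
        if abs(self.frequencies.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"haplotype frequencies sum to {self.frequencies.sum()!r}, not 1"
            )

    def presence_frequency(self, locus: str) -> float:
        """Haplotype-frequency-weighted presence frequency of one locus."""
        j = self.registry.index(locus)
        return float(self.frequencies[self.vectors[:, j]].sum())


def load_haplotype_table(path, registry: LocusRegistry) -> HaplotypeTable:
    """Read a haplotype TSV: name, frequency, then locus columns (0/1)."""
    df = _read_table(path)
    if df.shape[1] < 3:
        raise LoadError("haplotype table needs name, frequency and locus columns")
    names = [str(x) for x in df[df.columns[0]]]
    try:
        freqs = df["frequency"].astype(float).to_numpy()
    except KeyError:
        raise LoadError("haplotype table lacks a 'frequency' column") from None
    cols = [c for c in df.columns if c not in (df.columns[0], "frequency")]
    unknown = set(cols) - set(registry.loci)
    if unknown:
        raise LoadError(f"unknown locus name(s): {sorted(unknown)}")
    missing = set(registry.loci) - set(cols)
    if missing:
        raise LoadError(f"haplotype table lacks registry loci: {sorted(missing)}")
    mat = np.empty((len(names), len(registry)), dtype=bool)
    for j, locus in enumerate(registry.loci):
        for i, raw in enumerate(df[locus]):
            cell = str(raw).strip()
            if cell not in _CELL_MAP:
                raise LoadError(f"non-binary value {raw!r} in haplotype {names[i]!r}")
            mat[i, j] = _CELL_MAP[cell]
    return HaplotypeTable(registry, tuple(names), mat, freqs)


def write_haplotype_table(table: HaplotypeTable, path) -> None:
    df = pd.DataFrame(table.vectors.astype(int), columns=list(table.registry.loci))
    df.insert(0, "haplotype", list(table.names))
    df.insert(1, "frequency", table.frequencies)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# population frequency table
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Per-population phenotype frequencies for KIR2DL1-3, C1, C2 and B*46.

    Frequencies are carrier (phenotype) frequencies in [0, 1]. The B46
    column is optional on disk (absent means 0 everywhere); ``use_b46``
    flags the populations whose ANDI should include the B*46 ligand terms.
    """

    data: pd.DataFrame  # columns: population, group, 2DL1..B46, use_b46

    def __post_init__(self):
        df = self.data.copy()
        if "population" not in df.columns or "group" not in df.columns:
            raise ValueError("frequency table needs 'population' and 'group' columns")
        if df["population"].duplicated().any():
            raise ValueError("duplicate population names")
        if "B46" not in df.columns:
            df["B46"] = 0.0
        for key in FREQUENCY_KEYS:
            if key not in df.columns:
                raise ValueError(f"frequency table lacks column {key!r}")
            df[key] = df[key].astype(float)
            if ((df[key] < 0) | (df[key] > 1)).any():
                raise ValueError(f"{key} frequency outside [0, 1]")
        if "use_b46" not in df.columns:
            df["use_b46"] = df["B46"] > 0
        df["use_b46"] = df["use_b46"].astype(bool)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @staticmethod
    def allele_to_phenotype(allele_frequency) -> float:
        """Carrier frequency under Hardy-Weinberg: PF = 1 - (1 - af)^2."""
        af = np.asarray(allele_frequency, dtype=float)
        if np.any((af < 0) | (af > 1)):
            raise ValueError("allele frequency outside [0, 1]")
        out = 1.0 - (1.0 - af) ** 2
        return float(out) if out.ndim == 0 else out


def load_frequency_table(path) -> FrequencyTable:
    df = _read_table(path)
    for key in FREQUENCY_KEYS:
        if key in df.columns:
            df[key] = df[key].astype(float)
    if "use_b46" in df.columns:
        df["use_b46"] = df["use_b46"].astype(int).astype(bool)
    return FrequencyTable(df)


def write_frequency_table(table: FrequencyTable, path) -> None:
    df = table.data.copy()
    df["use_b46"] = df["use_b46"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# residue pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResiduePair:
    """Residues at the two epitope-determining MHC positions (76 and 80)."""

    name: str
    residue76: str
    residue80: str

    def __post_init__(self):
        for res in (self.residue76, self.residue80):
            if res not in _AA_CODES and res != UNKNOWN_RESIDUE:
                raise ValueError(f"invalid residue code {res!r}")


def _normalise_residue(raw: str) -> str:
    res = raw.strip().upper()
    if res in _AA_CODES:
        return res
    if res in {"-", ".", "*", "X", "?", ""}:
        return UNKNOWN_RESIDUE
    raise LoadError(f"unrecognised residue {raw!r}")


def load_residue_pairs(path, pos76: int = 76, pos80: int = 80) -> list[ResiduePair]:
    """Extract (res76, res80) per allotype from FASTA or a 3-column TSV.

    Positions are 1-based in the mature protein; any leader-peptide offset
    must be pre-applied by the caller. A gap at either position yields the
    unknown marker.
    """
    if pos76 < 1 or pos80 < 1:
        raise ValueError("positions are 1-based and must be >= 1")
    text = _read_text(path)
    stripped = text.lstrip()
    if not stripped:
        raise LoadError("empty residue input")
    if stripped.startswith(">"):
        pairs = []
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            seq = str(rec.seq)
            if len(seq) < max(pos76, pos80):
                raise LoadError(
                    f"record {rec.id!r} shorter than position {max(pos76, pos80)}"
                )
            pairs.append(
                ResiduePair(
                    rec.id,
                    _normalise_residue(seq[pos76 - 1]),
                    _normalise_residue(seq[pos80 - 1]),
                )
            )
        if not pairs:
            raise LoadError("empty FASTA input")
        return pairs
    pairs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise LoadError(f"expected 3 columns, got {line!r}")
        if fields[1].lower() in {"res76", "residue76"}:  # header row
            continue
        pairs.append(
            ResiduePair(
                fields[0], _normalise_residue(fields[1]), _normalise_residue(fields[2])
            )
        )
    if not pairs:
        raise LoadError("empty residue table")
    return pairs


def _read_text(path) -> str:
    if hasattr(path, "read"):
        return path.read()
    with open(path, encoding="utf-8") as fh:
        return fh.read()


# ---------------------------------------------------------------------------
# tip-state tree
# ---------------------------------------------------------------------------


@dataclass
class TipStateTree:
    """Tree topology with a single-character state at every tip.

    Polytomies are allowed (change counting is Sankoff-style). Internal
    node labels, if any, are ignored.
    """

    tree: dendropy.Tree
    states: dict[str, str]

    def __post_init__(self):
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = tips - set(self.states)
        if missing:
            raise ValueError(f"unstated tip(s): {sorted(missing)}")
        for tip, state in self.states.items():
            if len(state) != 1:
                raise ValueError(f"state for {tip!r} must be a single character")
        # states for labels absent from the tree are tolerated but unused
        self.states = {t: self.states[t] for t in tips}

    @property
    def alphabet(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.states.values())))


def load_tip_state_tree(newick_path, states_path) -> TipStateTree:
    """Read a Newick tree and a 2-column (tip, state) TSV."""
    tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
    states = {}
    with open(states_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise LoadError(f"expected 2 columns, got {line!r}")
            if fields[1].lower() == "state":
                continue
            states[fields[0]] = fields[1]
    return TipStateTree(tree, states)
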
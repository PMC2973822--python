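"""Gene-content linkage disequilibrium on haplotype tables.

Three views of pairwise association between KIR loci across a haplotype
frequency distribution:

* **pairing frequency** — the frequency with which two genes are jointly
  present or jointly absent, against its expectation under independence;
* **Fisher exact test** — a two-tailed exact test on the 2×2 haplotype
  count table (frequencies scaled to a user-supplied chromosome count);
* **association ratios** — for a reference gene (classically 2DL5), how
  much more common each other gene is on reference-positive than
  reference-negative haplotypes, as a ratio of conditional presence
  frequencies; absolute linkage (a gene never seen without the reference)
  is reported with the ``AL`` sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_model import HaplotypeTable

__all__ = [
    "PairingResult",
    "AssociationRatio",
    "AL",
    "pairing_frequency",
    "fisher_ld",
    "association_ratios",
    "DEFAULT_SIGNIFICANCE",
]

logger = logging.getLogger(__name__)

#: Significance threshold for declaring linkage disequilibrium.
DEFAULT_SIGNIFICANCE = 0.001

#: Sentinel ratio value for absolute linkage (gene never seen without the
#: reference); compares greater than any finite ratio.
AL = float("inf")


@dataclass(frozen=True)
class PairingResult:
    gene_a: str
    gene_b: str
    observed: float
    expected: float
    fisher_p: float | None = None
    significant: bool | None = None

    def __post_init__(self):
        for value, label in ((self.observed, "observed"), (self.expected, "expected")):
            if not 0.0 <= value <= 1.0 + 1e-12:
                raise ValueError(f"{label} pairing frequency outside [0, 1]")


@dataclass(frozen=True)
class AssociationRatio:
    gene: str
    ratio: float  # >= 0, AL (inf) for absolute linkage, nan when 0/0
    n_ref_pos: float  # haplotype mass on reference-positive haplotypes
    n_ref_neg: float
    constrained: bool = False  # ratio derives from a declared absolute linkage


def _presence(table: HaplotypeTable, gene: str) -> np.ndarray:
    return table.vectors[:, table.registry.index(gene)]


def pairing_frequency(table: HaplotypeTable, gene_a: str, gene_b: str) -> PairingResult:
    """Observed vs expected frequency of joint presence-or-absence.

    observed = sum of frequencies of haplotypes where A and B are both
    present or both absent; expected = pA*pB + (1-pA)(1-pB) with pA, pB
    the frequency-weighted presence frequencies.
    """
    a = _presence(table, gene_a)
    b = _presence(table, gene_b)
    f = table.frequencies
    observed = float(f[a == b].sum())
    pa = float(f[a].sum())
    pb = float(f[b].sum())
    expected = pa * pb + (1.0 - pa) * (1.0 - pb)
    return PairingResult(gene_a, gene_b, observed, expected)


def _counts_2x2(table: HaplotypeTable, gene_a: str, gene_b: str, hap_count: int) -> np.ndarray:
    """Scale joint frequencies to integer haplotype counts summing to hap_count.

    Cells are rounded to nearest; any rounding deficit/excess is assigned by
    largest remainder so the table stays consistent with the total.
    """
    a = _presence(table, gene_a)
    b = _presence(table, gene_b)
    f = table.frequencies
    joint = np.array(
        [
            [f[a & b].sum(), f[a & ~b].sum()],
            [f[~a & b].sum(), f[~a & ~b].sum()],
        ]
    )
    raw = joint * hap_count
    counts = np.floor(raw).astype(int)
    remainder = (raw - counts).ravel()
    deficit = hap_count - counts.sum()
    for idx in np.argsort(-remainder)[:deficit]:
        counts.ravel()[idx] += 1
    return counts


def fisher_ld(
    table: HaplotypeTable,
    gene_a: str,
    gene_b: str,
    hap_count: int,
    significance: float = DEFAULT_SIGNIFICANCE,
) -> PairingResult:
    """Two-tailed Fisher exact test of gene-content LD.

    Haplotype frequencies are scaled to ``hap_count`` chromosomes (2N for
    a panel of N individuals) and the exact test run on the resulting 2×2
    table of (A±, B±) counts. Two-tailed means summing the probabilities
    of all tables with the observed margins whose point probability does
    not exceed the observed table's. A zero marginal makes the test
    undefined; p is reported as 1.0 with a warning.
    """
    if hap_count < 1:
        raise ValueError("hap_count must be >= 1")
    base = pairing_frequency(table, gene_a, gene_b)
    counts = _counts_2x2(table, gene_a, gene_b, hap_count)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        logger.warning(
            "zero marginal in 2x2 table for (%s, %s); p set to 1.0", gene_a, gene_b
        )
        p = 1.0
    else:
        p = float(stats.fisher_exact(counts, alternative="two-sided")[1])
        p = min(p, 1.0)
    return PairingResult(
        gene_a, gene_b, base.observed, base.expected, fisher_p=p,
        significant=p < significance,
    )


def association_ratios(
    table: HaplotypeTable,
    reference: str,
    constraints: list[tuple[str, str]] | None = None,
) -> list[AssociationRatio]:
    """Normalized association of every other gene with a reference gene.

    For gene g the ratio is P(g present | reference present) /
    P(g present | reference absent), with conditional frequencies weighted
    by haplotype frequency — normalizing for the unequal mass of
    reference-positive and reference-negative haplotypes. The ``AL``
    sentinel (infinity) marks absolute linkage (denominator 0, numerator
    > 0); 0/0 is reported as NaN.

    ``constraints`` lists (gene, partner) pairs declared to be in absolute
    linkage: before computing the gene's ratio its presence vector is
    replaced by the partner's (the pair co-segregates by assumption), and
    the output row is flagged ``constrained``.
    """
    f = table.frequencies
    ref = _presence(table, reference)
    mass_pos = float(f[ref].sum())
    mass_neg = float(f[~ref].sum())
    if mass_pos == 0.0 or mass_neg == 0.0:
        raise ValueError(
            f"reference {reference!r} is fixed "
            f"{'present' if mass_neg == 0 else 'absent'} across haplotypes"
        )
    constraint_map = {g: partner for g, partner in (constraints or [])}
    out = []
    for gene in table.registry.loci:
        if gene == reference:
            continue
        partner = constraint_map.get(gene)
        vec = _presence(table, partner if partner is not None else gene)
        p_pos = float(f[ref & vec].sum()) / mass_pos
        p_neg = float(f[~ref & vec].sum()) / mass_neg
        if p_neg > 0.0:
            ratio = p_pos / p_neg
        elif p_pos > 0.0:
            ratio = AL
        else:
            ratio = float("nan")
        out.append(
            AssociationRatio(
                gene=gene,
                ratio=ratio,
                n_ref_pos=mass_pos,
                n_ref_neg=mass_neg,
                constrained=partner is not None,
            )
        )
    return out
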